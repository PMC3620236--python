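"""Stratified X/Y-parent transmission analysis."""

import pytest

from haplorisk import (
    TrioFamily,
    compare_strata,
    count_transmissions,
    stratified_tdt,
    tdt_vs_rest,
)

import oracles

RISK = "*03:01-*02:01"


def _fam(fid, father, mother, child, status="affected"):
    return TrioFamily(fid, father, mother, [(child, status)])


class TestCountTransmissions:
    def test_definition_case(self):
        """Child (R, A) with father (R, C) and mother (A, B): the mother is the
        X/Y parent; she transmitted A and withheld B; stratum risk-positive."""
        fam = _fam("f1", (RISK, "C"), ("A", "B"), (RISK, "A"))
        pos, neg, acct = count_transmissions([fam], RISK)
        assert pos.counts == {"A": [1, 0], "B": [0, 1]}
        assert neg.counts == {}
        assert pos.n_informative == 1

    def test_risk_negative_child_uses_both_parents(self):
        fam = _fam("f1", ("A", "B"), ("C", "D"), ("A", "C"))
        pos, neg, acct = count_transmissions([fam], RISK)
        assert neg.n_informative == 2
        assert neg.counts == {"A": [1, 0], "B": [0, 1], "C": [1, 0], "D": [0, 1]}

    def test_both_parents_carrying_risk_excluded(self):
        fam = _fam("f1", (RISK, "A"), (RISK, "B"), (RISK, "A"))
        pos, neg, acct = count_transmissions([fam], RISK)
        assert pos.n_informative == 0 and neg.n_informative == 0
        assert acct.n_both_parents_carry_risk == 1

    def test_homozygous_parent_skipped(self):
        fam = _fam("f1", ("A", "A"), ("B", "C"), ("A", "B"))
        pos, neg, acct = count_transmissions([fam], RISK)
        assert neg.counts == {"B": [1, 0], "C": [0, 1]}
        assert acct.n_homozygous_parents_skipped == 1

    def test_only_requested_status_counts(self):
        fam = TrioFamily(
            "f1", ("A", "B"), ("C", "D"),
            [(("A", "C"), "affected"), (("B", "D"), "unaffected")],
        )
        pos, neg, _ = count_transmissions([fam], RISK, "unaffected")
        assert neg.counts == {"B": [1, 0], "A": [0, 1], "D": [1, 0], "C": [0, 1]}

    def test_accounting_identity_on_simulated_families(self):
        """Every informative parent contributes exactly one T and one NT."""
        from haplorisk import SimulationConfig, generate_trios

        cfg = SimulationConfig(
            haplotype_freqs={"R": 0.3, "A": 0.3, "B": 0.4},
            baseline_risk=0.1,
            haplotype_rr={"R": 2.0},
            n_families=300,
            seed=11,
        )
        fams = generate_trios(cfg)
        pos, neg, _ = count_transmissions(fams, "R")
        for table in (pos, neg):
            assert sum(t for t, _ in table.counts.values()) == table.n_informative
            assert sum(nt for _, nt in table.counts.values()) == table.n_informative

    def test_matches_exhaustive_two_haplotype_enumeration(self):
        """All 16 phased mating/transmission configurations, tallied by hand."""
        expected = oracles.enumerate_transmissions("R", "x")
        fams = []
        i = 0
        for father in [("R", "R"), ("R", "x"), ("x", "R"), ("x", "x")]:
            for mother in [("R", "R"), ("R", "x"), ("x", "R"), ("x", "x")]:
                for fi in (0, 1):
                    for mi in (0, 1):
                        i += 1
                        fams.append(
                            _fam(f"f{i}", father, mother, (father[fi], mother[mi]))
                        )
        pos, neg, _ = count_transmissions(fams, "R")
        for table, stratum in ((pos, "risk_positive"), (neg, "risk_negative")):
            got = {lab: list(tn) for lab, tn in table.counts.items() if any(tn)}
            want = {
                lab: tn for lab, tn in expected[stratum].items() if any(tn)
            }
            assert got == want


class TestVsRest:
    def test_overtransmitted_risk_partner(self):
        """35 T vs 12 NT among 269 informative parents: OR 3.2, p 4.5e-4."""
        or_, chi2, p = tdt_vs_rest(35, 12, 269)
        assert round(or_, 1) == 3.2
        assert float(f"{p:.1e}") == 4.5e-04

    def test_never_transmitted_haplotype(self):
        or_, chi2, p = tdt_vs_rest(0, 10, 269)
        assert or_ == 0.0
        assert float(f"{p:.1e}") == 1.4e-03

    def test_published_or_is_vs_rest_not_ratio(self):
        """(9 T, 1 NT) prints OR 9.3 = (9*268)/(1*260), not 9/1."""
        or_, _, _ = tdt_vs_rest(9, 1, 269)
        assert round(or_, 1) == 9.3

    def test_mcnemar_variant_differs(self):
        """The paired statistic gives 1.2e-3 for (30, 61), the vs-rest 3.6e-4:
        only the latter matches the published value."""
        _, _, p_vs = tdt_vs_rest(30, 61, 269)
        _, _, p_mc = tdt_vs_rest(30, 61, 269, use_mcnemar=True)
        assert float(f"{p_vs:.1e}") == 3.6e-04
        assert float(f"{p_mc:.1e}") == 1.2e-03

    def test_balanced_transmission_is_null(self):
        or_, chi2, p = tdt_vs_rest(20, 20, 100)
        assert (or_, chi2, p) == (1.0, 0.0, 1.0)

    def test_complement_or_is_reciprocal(self):
        n = 269
        t, nt = 35, 12
        or_h, _, _ = tdt_vs_rest(t, nt, n)
        or_rest, _, _ = tdt_vs_rest(n - t, n - nt, n)
        assert or_rest == pytest.approx(1 / or_h)

    def test_zero_informative_rejected(self):
        with pytest.raises(ValueError):
            tdt_vs_rest(1, 1, 0)


class TestCompareStrata:
    def test_opposite_trend_haplotype(self):
        """T:NT of 8:14 vs 29:14 across strata: chi2 5.7, p 1.7e-2."""
        chi2, p = compare_strata(8, 14, 29, 14)
        assert round(chi2, 1) == 5.7
        assert float(f"{p:.1e}") == 1.7e-02

    def test_same_trend_haplotype(self):
        chi2, p = compare_strata(30, 61, 101, 148)
        assert round(chi2, 1) == 1.6
        assert float(f"{p:.1e}") == 2.0e-01

    def test_identical_ratios_give_zero(self):
        chi2, p = compare_strata(10, 20, 30, 60)
        assert chi2 == pytest.approx(0.0)

    def test_empty_margin_warns(self):
        with pytest.warns(UserWarning):
            chi2, p = compare_strata(0, 0, 0, 5)
        assert (chi2, p) == (0.0, 1.0)


class TestStratifiedTDT:
    def test_informativeness_gate(self):
        fams = [_fam("f1", ("R", "A"), ("B", "C"), ("R", "B"))]
        with pytest.raises(ValueError, match="heterozygous parents"):
            stratified_tdt(fams, "R", min_het_parents=250)

    def test_runs_end_to_end_on_simulated_families(self):
        from haplorisk import SimulationConfig, generate_trios

        cfg = SimulationConfig(
            haplotype_freqs={"R": 0.25, "A": 0.25, "B": 0.25, "C": 0.25},
            baseline_risk=0.1,
            haplotype_rr={"R": 3.0},
            n_families=400,
            seed=5,
        )
        fams = generate_trios(cfg)
        results, pos, neg, acct = stratified_tdt(fams, "R", min_het_parents=100)
        assert pos.n_informative > 0 and neg.n_informative > 0
        labels = {r.label for r in results}
        assert {"A", "B", "C"} <= labels

    def test_unaffected_siblings_are_a_negative_control(self):
        """Repeating the stratified analysis on unaffected siblings of the
        ascertained children: for a neutral haplotype the between-strata
        comparison rejects at p<0.05 close to its nominal 5% rate."""
        import numpy as np

        from haplorisk import SimulationConfig, generate_trios

        cfg = SimulationConfig(
            haplotype_freqs={"R": 0.25, "A": 0.15, **{f"h{i}": 0.1 for i in range(6)}},
            baseline_risk=0.1,
            haplotype_rr={"R": 2.0},
            n_families=400,
            seed=0,
        )
        rng = np.random.default_rng(20260906)
        reps, hits = 250, 0
        for _ in range(reps):
            fams = generate_trios(cfg, rng=rng, include_sibling=True)
            pos, neg, _ = count_transmissions(fams, "R", "unaffected")
            _, p = compare_strata(*pos.t_nt("A"), *neg.t_nt("A"))
            hits += p < 0.05
        se = (0.05 * 0.95 / reps) ** 0.5
        assert abs(hits / reps - 0.05) <= 2 * se
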