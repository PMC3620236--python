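"""Simulate a cohort with known haplotype risks and recover them.

Builds a Sardinian-like population (15 haplotypes at the bundled control
frequencies, relative risks set to the published odds ratios), rejection-
samples a case-control cohort of the study size, and re-estimates the odds
ratios — an end-to-end self-check of the whole pipeline.  Trio families
ascertained on an affected child are generated from the same population and
validated for Mendelian consistency.
"""

from haplorisk import associate_table, generate_cohort, generate_trios, validate_trios
from haplorisk.datasets import sardinian_simulation_config

cfg = sardinian_simulation_config(n_cases=2555, n_controls=1365, n_families=300, seed=42)
cohort = generate_cohort(cfg)
results = {r.label: r for r in associate_table(cohort.haplotype_counts())}

print(f"{'haplotype':20s} {'true rr':>8s} {'estimated OR':>13s} {'95% CI':>13s}")
for label, rr in sorted(cfg.haplotype_rr.items(), key=lambda kv: -kv[1]):
    r = results[label]
    print(
        f"{label:20s} {rr:8.1f} {r.odds_ratio:13.2f} "
        f"{r.ci_low:6.2f}-{r.ci_high:5.2f}"
    )

fams = generate_trios(cfg, include_sibling=True)
print(f"\n{len(fams)} trio families ascertained on an affected child;")
print(validate_trios(fams).summary() + ".")
print(
    "\nEstimated ORs track the generating relative risks (for very common"
    "\nhaplotypes the population OR deviates from the per-chromosome rr, as"
    "\nexpected under a multiplicative penetrance model)."
)
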