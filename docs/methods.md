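# Methods

This note records the statistical conventions the package implements, why
they were chosen, and what the bundled simulator does and does not emulate.

## Data model

Haplotypes at the linked DRB1-DQB1 loci are atomic string labels; no
within-haplotype linkage structure is modelled. Count tables carry cohort
totals separately from the displayed rows: published tables list only
categories above a reporting threshold (≥ 1% of either group), so the row
sums (e.g. 5,038 / 2,695 chromosomes) fall short of the totals
(5,110 / 2,730). All denominators use the totals. The frequency filter uses
the *either-group* rule — a category is kept when it reaches the threshold in
cases **or** controls — because protective categories are, by definition,
rare in cases. Typographic variants of published labels (ratio colon ∶,
en/em dashes) are normalized to ASCII on input.

Trio files must already be phased; the package validates Mendelian
consistency (one child haplotype matching a paternal and one a maternal one)
and flags intercross matings (both parents heterozygous for the same pair,
where transmissions cannot be phased), but never imputes or resolves
ambiguity itself.

## Case-control association

Each category defines the 2×2 table `[[a, b], [N₁−a, N₂−b]]` against the
cohort totals. Conventions, each verifiable against the bundled reference
tables:

* **Odds ratio** — the sample cross-product ratio. Denominators are the
  cohort totals, not displayed-row sums (97/5013 vs 16/2714 gives the
  reference OR 3.3; row-sum denominators do not).
* **Confidence interval** — Woolf's log method. It reproduces every
  published interval checked (e.g. 1.9–5.6).
* **p-value** — Pearson χ², 1 df, without Yates continuity correction; with
  the correction the published corrected p-values (5.1×10⁻⁵, 6.0×10⁻⁷) are
  not recovered.
* **Multiplicity** — Bonferroni, `min(1, m·p)`, with `m` the number of
  categories screened (15 haplotypes, 28 genotypes in the reference data).
  Results always carry a numeric corrected p plus a significance flag; the
  reference tables are inconsistent about printing "NS" versus leaving a
  blank, so nothing is suppressed.
* **Zero cells** — OR reported as 0 or ∞ with a flag and no interval, which
  is how the reference transmission table reports a never-transmitted
  haplotype. The Haldane-Anscombe +0.5 correction is available behind
  `haldane=True`; it is off by default to keep exact reproduction.
* Results are sorted by descending OR, the layout of published tables.

## Sequential RPE procedure

Round structure: expected case counts from the current control distribution
(`E_i = control_i · caseT/ctrlT` at post-removal totals), overall
χ² = Σ(O−E)²/E over remaining categories with df = (#categories − 1), stop at
P ≥ 0.001 (the reference analysis' threshold; configurable, plus a
`max_rounds` override), otherwise remove the argmax-contribution haplotype
and renormalize. The per-round z uses the *unpooled* two-proportion variance:
the pooled form gives 9.88 for the first round of the reference data where
10.31 is printed.

Two choices deserve comment:

* **The residual category.** Undisplayed rare chromosomes (72 / 35 in the
  reference table) are carried as an explicit, non-selectable category inside
  the overall χ². This keeps ΣE equal to the remaining case total every
  round, and it is required to reproduce the reference trace: without the
  residual the overall p crosses the 0.001 threshold after eight rounds
  (χ² 22.3, df 6, p 1.06×10⁻³) and the ninth removal never happens.
* **Conditioning on controls.** The procedure treats the control counts as a
  fixed reference distribution; its null is "cases are drawn from the control
  distribution". When control counts are themselves sampled, the overall χ²
  is inflated (roughly doubled for equal group sizes) and the procedure
  becomes anticonservative. The type-I calibration test therefore holds the
  control table fixed, matching the procedure's own null; the conservative
  0.001 stopping threshold is what keeps the procedure usable on real data
  where both groups are sampled.

The selection rule is argmax of the round's contribution at *current* totals;
a haplotype removed later can display a larger contribution than an earlier
round's (14.11 after 13.40 in the reference trace) because the totals shrink.

## Stratified transmission analysis

Offspring are stratified by carriage (≥ 1 copy) of the risk haplotype. Every
parent carrying no copy of the risk haplotype is informative — in the
risk-negative stratum both parents can qualify, which is how 422 reference
patients yield 634 informative parents — while homozygous parents (T ≡ NT)
and parents whose transmission cannot be phased uniquely are skipped and
counted in an accounting report. Families in which both parents carry the
risk haplotype have no eligible X/Y parent and are excluded; the reference
analysis is silent on them, so the exclusion is surfaced in the accounting.
A configurable informativeness gate (default 250 heterozygous carrier
parents) controls which haplotypes may index the stratification.

The per-haplotype test is the haplotype-vs-rest Pearson χ² on
`[[T, NT], [n−T, n−NT]]`, not the paired McNemar statistic: McNemar gives
1.2×10⁻³ where the reference table prints 3.6×10⁻⁴, and the vs-rest OR
`T(n−NT)/(NT(n−T))` reproduces the printed 3.2, 0.4, and 9.3 (e.g.
9·268/(1·260), not 9/1). McNemar remains available behind a flag. Note the
vs-rest statistic is mildly anticonservative when the haplotype is common
among informative parents (variance inflation factor 2n/(2n−m) for m carrier
parents of n); the calibration test uses a haplotype at 4% frequency, where
the inflation is negligible.

## Interaction alpha

`α = log₁₀(OR_g_obs) − log₁₀(OR_ha·OR_hb)`. Base 10 is the default because
every published alpha value is reproduced only on that scale (a natural-log
reading gives 0.14 and −0.41 where 0.06 and −0.18 are printed), although the
base is configurable. Two combination modes exist: *reproduction* rounds all
odds ratios to one decimal before combining — the precision of published
association tables, enabling exact comparison — and *full* keeps full
precision. The two agree closely but not always at the second decimal
(−0.195 vs −0.18 for the strongest protective pairing). The expected
genotypic OR is always computed from the haplotypic ORs, never copied from a
table (one published expected value, 1.2, is inconsistent with its own alpha;
the product of the rounded inputs is 1.02).

The neutral band [0.01, 0.09] is treated with inclusive endpoints. It is
asymmetric and excludes zero, so a value in [0, 0.01) is classified as a
(weak) negative interaction while being non-negative; such values carry an
explicit `below_band_positive` flag and the sign is always reported
separately from the classification. No p-value is attached to alpha: the
model is an empirical probe, and its significance is read qualitatively off
the genotypic OR's own test.

## Simulator

The generator emulates exactly the assumptions under which the statistics
are derived: haplotypes drawn independently with fixed frequencies (random
mating, Hardy-Weinberg at the haplotype level), penetrance
`baseline · rr(ha) · rr(hb) · 10^α(ha,hb)` clipped to 1, case-control status
by rejection sampling to quota, trio families ascertained on an affected
child with parental affection ignored, and an optional sibling drawn from
the same parents as the negative control. The interaction dial is
parameterized directly as the target log₁₀ alpha. A single seeded
`numpy.random.Generator` drives all sampling; identical seeds give identical
cohorts.

What it does **not** emulate: linkage disequilibrium between loci within a
haplotype (labels are atomic), class I loci, population stratification,
genotyping or phasing error, and ascertainment quirks of real registries.
Passing recovery tests therefore validate the statistical machinery under
its own assumptions, not robustness to those real-data complications.

Two quantitative caveats, both visible in the recovery tests:

* For a *common* haplotype the population chromosome-level OR is not the
  per-chromosome relative risk: under the multiplicative model
  OR_h = r_h(1−f_h)/(R̄−f_h r_h) with R̄ = Σf·r, so e.g. the most common risk
  haplotype in the Sardinian-like configuration (rr 1.7 at 22% frequency)
  induces a population OR near 2.0. Sign is preserved (OR_h > 1 iff
  r_h > R̄); recovery tests on rare haplotypes use the exact identity
  OR = rr.
* The plug-in alpha estimator is slightly attenuated toward 0 when the
  interacting haplotypes are common, because the interaction term leaks into
  both haplotypic marginals (bias ≈ (f_a+f_b)(1−10^α)/ln 10). The recovery
  test uses 5%-frequency haplotypes, quantifies the exact population-level
  plug-in value by enumeration, and checks the Monte-Carlo mean against it.

## Problem sizes in the test suite

Calibration and recovery tests run at sizes chosen to make the asymptotic
approximations they test valid while keeping the default suite quick:
1,000 replicates for the two type-I checks (multinomial tables of 6
categories at n = 3,000; 400 trio families per replicate), 200 replicates of
2,500/1,250 individuals for OR recovery, 100 replicates of 4,000/2,000 for
alpha recovery, and 50 replicates at the full reference size
(2,555/1,365 individuals) for the end-to-end sign check. All are seeded and
deterministic.

## Known limitations

* No exact (Fisher) tests, covariate adjustment, or regression-based
  haplotype conditioning; the multivariate analysis that complements RPE in
  the literature is ordinary logistic regression and is out of scope here.
* Statistical phasing is not implemented; upstream tools must deliver phased
  haplotypes.
* Alpha carries no significance measure (see above), and the "full" model of
  which log-additivity is the first-order approximation is not specified in
  the source literature, hence not implemented.
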