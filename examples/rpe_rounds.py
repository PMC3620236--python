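"""Sequential relative-predispositional-effect (RPE) analysis.

A strongly over-represented haplotype mechanically depresses the frequency of
every other haplotype in cases, so apparent protection can be an artifact of
displacement.  The RPE procedure removes the strongest-deviating haplotype
round by round, renormalizing the control-based expectation, until the
remaining distribution no longer deviates (overall chi-square P >= 0.001).
"""

from haplorisk import run_rpe
from haplorisk.datasets import sardinian_haplotype_counts

trace = run_rpe(sardinian_haplotype_counts(), alpha_overall=0.001)

print(f"{'round':>5s} {'haplotype':20s} {'obs':>5s} {'exp':>5s} "
      f"{'(O-E)^2/E':>9s} {'|z|':>6s} {'p(z)':>8s}")
for r in trace.rounds:
    print(
        f"{r.index:5d} {r.label:20s} {r.observed:5d} {r.expected:5.0f} "
        f"{r.contribution:9.2f} {abs(r.z):6.2f} {r.p_z:8.1e}"
    )
print(
    f"\nStopped after {len(trace.rounds)} rounds ({trace.stop_reason}): "
    f"remaining chi2 {trace.final_chi2:.1f} on {trace.final_df} df, "
    f"p {trace.final_p:.3f}."
)
print(
    "Haplotypes removed with observed > expected carry genuine predisposition,"
    "\nobserved < expected genuine protection; haplotypes never selected (here"
    "\nincluding *11) show no effect beyond displacement."
)
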