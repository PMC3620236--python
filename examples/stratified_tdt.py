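"""Stratified transmission analysis around the *03:01-*02:01 risk haplotype.

Within trio families, offspring are split by carriage of the risk haplotype
and the transmissions of the parent carrying neither copy of it (the X/Y
parent) are tested haplotype-vs-rest.  A haplotype whose transmission odds
differ between the two strata interacts with the risk haplotype.  This
example uses the bundled transmission counts (269 and 634 informative
parents).
"""

from haplorisk import compare_strata, tdt_vs_rest
from haplorisk.datasets import sardinian_transmission_tables

pos, neg = sardinian_transmission_tables()

print(f"{'haplotype':20s} {'T+':>4s} {'NT+':>4s} {'OR+':>5s}   "
      f"{'T-':>4s} {'NT-':>4s} {'OR-':>5s}   {'chi2':>5s} {'p':>8s}")
for label in pos.labels:
    t_pos, nt_pos = pos.t_nt(label)
    t_neg, nt_neg = neg.t_nt(label)
    if t_pos + nt_pos == 0 or t_neg + nt_neg == 0:
        continue
    or_pos, _, _ = tdt_vs_rest(t_pos, nt_pos, pos.n_informative)
    or_neg, _, _ = tdt_vs_rest(t_neg, nt_neg, neg.n_informative)
    chi2, p = compare_strata(t_pos, nt_pos, t_neg, nt_neg)
    print(
        f"{label:20s} {t_pos:4d} {nt_pos:4d} {or_pos:5.1f}   "
        f"{t_neg:4d} {nt_neg:4d} {or_neg:5.1f}   {chi2:5.1f} {p:8.1e}"
    )

print(
    "\nOR > 1 marks over-transmission to affected offspring in that stratum."
    "\nThe *13 haplogroup flips direction between strata (chi2 5.7, p 0.017),"
    "\nsuggesting its effect depends on the risk-haplotype background."
)
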