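"""Binned and subgroup decay statistics on a four-condition rescue design.

Simulates parental cells, a destabilizing knockout, a full wild-type rescue,
and a partial rescue whose deficit is confined to long-lived mRNAs, then
reads the pattern out through per-bin median ratios and paired tests.
"""

import decaykit as dk
from decaykit.synthetic import rescue_design_config

config = rescue_design_config(seed=20406)
matrix, truth = dk.simulate_chase(config)
table, summary = dk.run_halflife_pipeline(matrix)
print(f"{summary['n_retained']} genes quantified in all four conditions")

for alt in ("KO", "WT", "RINGmut"):
    res = dk.compare_paired(table, "parental", alt)
    print(f"parental vs {alt}: median ratio "
          f"{res.median_b / res.median_a:.3f}, p = {res.p_value:.2e}")

print("\nper-bin median ratios vs parental (binned on parental t1/2):")
header = f"{'bin':>12}  " + "  ".join(f"{c:>8}" for c in ("KO", "WT", "RINGmut"))
print(header)
bins = {alt: dk.bin_halflives(table, "parental", alt) for alt in
        ("KO", "WT", "RINGmut")}
for i, bc in enumerate(bins["KO"]):
    if bc.result is None:
        continue
    ratios = [bins[alt][i].result.median_b / bins[alt][i].result.median_a
              for alt in ("KO", "WT", "RINGmut")]
    print(f"{bc.label:>12}  " + "  ".join(f"{r:8.3f}" for r in ratios))

# The knockout destabilizes every bin; the WT rescue restores parental decay
# throughout; the partial rescue tracks WT in short-lived bins but stays
# destabilized beyond 9 h.  (Within-bin ratios of all conditions drift from 1
# in the extreme bins because genes are binned on the noisy parental
# estimate; comparing a condition against the WT rescue inside a bin cancels
# that shared bias.)
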