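"""Stratified 10-fold stability of PAD selection.

Re-runs the whole funnel on each leave-one-fold-out subset (90% of the
data, class proportions preserved) and compares how often each PAD
reoccurs with the chance baseline ((k-2)/(k-1))^m = 0.88889^m.
"""

from padmine import run_stability
from padmine.synth import generate, sibling_family_plants

plants = sibling_family_plants(target=0.95)
outlier = plants[0].pattern.notation
dataset = generate(200, plants, seed=3)

report = run_stability(
    dataset,
    params=dict(min_support=10, max_order=3, delta=1.64,
                network_level="pharmacophore"),
    k=10,
    seed=3,
)
print("fold  pharmacophores  SECs  PADs(+)  PADs(-)")
for i, (n_pharm, n_sec, pos, neg) in enumerate(report.per_fold, 1):
    print(f"F{i:<4} {n_pharm:>13} {n_sec:>5} {pos:>8} {neg:>8}")

print(f"\nplanted PAD {outlier} reoccurs in "
      f"{report.reoccurrence.get(outlier, 0)}/{report.n_folds} folds")
print("\ncumulative presence vs chance baseline:")
print("m     PADs>=m   chance 0.88889^m")
for m in (10, 8, 5, 3, 1):
    print(f"{m:<5} {report.cumulative.get(m, 0):>7}   {report.chance_curve[m]:.4f}")
# A PAD reoccurring in far more folds than the chance curve suggests is a
# stable finding rather than an artifact of the particular sample.
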