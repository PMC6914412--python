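"""Tumor-vs-normal differential screen with variance moderation.

Simulates a two-cohort microarray-style study, runs the moderated t-test per
cohort, applies the per-class significance gates (|FC| > 2 and p < 0.05 for
mRNA), and intersects the cohorts requiring a consistent direction.
"""

from cernanet import diffexpr as de
from cernanet.synthetic_data import SimulationConfig, generate

bundle = generate(
    SimulationConfig(n_cohorts=2, n_mRNA=400, n_lncRNA=80, n_miRNA=40, n_triplets=5, seed=1)
)

per_cohort = {}
for cohort in bundle.mrna.cohorts:
    records = de.run_de(bundle.mrna, cohort=cohort)
    selected = de.select_de(records)
    per_cohort[cohort] = selected
    print(f"cohort {cohort}: {len(selected)} significant mRNAs "
          f"(of {len(records)} tested; strongest FC {selected['fc_signed'].abs().max():.1f})")

intersected, venn = de.intersect_de(per_cohort)
planted = {f for f in bundle.truth.de_features if f.startswith("G")}
hits = len(set(intersected["feature_id"]) & planted)
summary = de.screen_summary(
    int((intersected["direction"] == "up").sum()), int((intersected["direction"] == "down").sum())
)
print(f"\nintersection: {summary['total']} genes, "
      f"{summary['pct_up']}% up / {summary['pct_down']}% down (venn {venn})")
print(f"{hits}/{len(planted)} planted DE genes recovered; "
      "the intersection keeps only genes significant with the same direction in every cohort")
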