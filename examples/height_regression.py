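"""Height estimation: raw linear distance vs LOOCV linear regression.

Runs the full default study (31 participants x 3 sessions x 8 photos),
measures every photo with the reference-object back-end, and sweeps all 31
view combinations of the linear-distance regression estimator.
"""

from photoanthro.estimators import measure_photo
from photoanthro.regression_eval import sweep_view_combinations
from photoanthro.synthetic import SceneConfig, generate_bundle

bundle = generate_bundle(SceneConfig(seed=0))
records = [measure_photo(p.noisy, "reference") for p in bundle.photos]
table = sweep_view_combinations(records, bundle.manual, "height_ld", "reference")

raw = table[table.method == "linear_distance"]
reg = table[table.method == "linear_distance_regression"]
print("raw linear distance, per single view (reference backend):")
for row in raw.itertuples(index=False):
    print(f"  view {row.view_set}: MAD {row.mad_mean_mm:6.2f} mm  TEM {row.tem_mm:5.2f} mm  R {row.r:.3f}")

best = reg[reg.optimal].iloc[0]
print(f"\nbest regression view set {best.view_set}: "
      f"MAD {best.mad_mean_mm:.2f} +/- {best.mad_sd_mm:.2f} mm, "
      f"MAPD {best.mapd_mean_pct:.2f} %, TEM {best.tem_mm:.2f} mm, R {best.r:.3f}")
print(f"manual-height TEM for comparison: {bundle.manual.tem('height'):.2f} mm")

# The raw method carries the subject-plane misalignment bias (~20 mm);
# the cross-validated regression absorbs it and lands within a few mm.
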