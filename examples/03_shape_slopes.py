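"""Estimate shape-sensitivity slopes across object-scrambling conditions.

Simulates one control subject viewing the five scrambling levels (S256 most
scrambled ... S1 intact) plus rest, computes rest-normalized source
contribution measures per condition, fits the per-source regression slope,
and compares parcel means with the planted values.  A positive slope means
the source responds more strongly to intact shapes.
"""

import numpy as np

import eegsilence as es

sc = es.SyntheticScenario(seed=7, bands=("Full",), rest_duration_s=60,
                          condition_duration_s=30, band_fs={"Full": 128.0})
montage, sources, lf = sc.build_geometry()
recs, truth = es.simulate_scenario(sc, lf, subject="ctrl01", role="control",
                                   bands=("Full",))

cond_recs = {c: recs[(c, "Full")] for c in ("rest",) + es.slopes.SCRAMBLING_ORDER}
cc = es.condition_contributions(cond_recs, lf, band="Full")
slope_map = es.fit_shape_slope(cc)

print("parcel              planted   estimated")
for parcel in ("ventral_L", "ventral_R", "dorsal_L", "dorsal_R", "dlpfc_L", "other"):
    mask = sources.parcels == parcel
    print(f"{parcel:18s}  {truth.slopes['Full'][mask].mean():7.3f}   "
          f"{slope_map.alpha[mask].mean():7.3f}")
# Visual parcels carry the planted positive slope (recovered within ~10%,
# the residual shrinkage being cross-talk from unresponsive neighbors);
# frontal and other parcels sit near zero.
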