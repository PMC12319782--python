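"""Localize a planted region of silence from synthetic scalp EEG.

Simulates a subject whose right-hemisphere lesion silences 100 contiguous
sources (1% residual variance), plus an intact baseline subject, then runs
the iterative contiguity-constrained localizer and reports the overlap with
the planted region and the center-of-mass error in mm.  Uses a reduced
sampling rate (128 Hz) and 60 s recordings so it finishes in ~10 s.
"""

import numpy as np

import eegsilence as es

sc = es.SyntheticScenario(seed=42, bands=("Full",), fs=128.0,
                          rest_duration_s=60, condition_duration_s=60)
montage, sources, lf = sc.build_geometry()

lesioned, truth = es.simulate_scenario(sc, lf, subject="case", role="case",
                                       conditions=("rest",))
intact, _ = es.simulate_scenario(sc, lf, subject="baseline", role="control",
                                 conditions=("rest",))

roi = es.localize_region(lesioned[("rest", "Full")], intact[("rest", "Full")],
                         lf, "R", es.CSpeCConfig(k=100), mode="silence")

planted = set(truth.silent_indices.tolist())
found = roi.index_set()
jaccard = len(found & planted) / len(found | planted)
com_err = np.linalg.norm(sources.positions[roi.indices].mean(0)
                         - sources.positions[truth.silent_indices].mean(0))

print(f"planted silent region: {len(planted)} sources in hemisphere R")
print(f"recovered region:      {len(found)} sources "
      f"(iterations {roi.provenance['iterations']}, "
      f"lambda {roi.provenance['lambda']})")
print(f"Jaccard overlap with truth: {jaccard:.2f}  (1 = perfect)")
print(f"center-of-mass error:       {com_err:.1f} mm "
      "(~1 cm is the method's spatial resolution)")
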