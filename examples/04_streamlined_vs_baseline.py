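"""Streamlined model variants vs the fully patient-specific baseline.

Simulates a small synthetic cohort three times: with every clinical
input patient-specific (baseline), with MAP/HR/hematocrit/inlet-CO
generalized (semi-streamlined), and additionally with a generalized
30 mm distal location (streamlined).  Scores each variant against the
baseline with agreement and classification statistics.
"""

import numpy as np

import coroflow as cf
from coroflow.synthetic import CohortRecipe, generate_cohort

cases = generate_cohort(CohortRecipe(n_patients=4, seed=42))
controls = cf.SolverControls(dt_s=None, dx_um=1500.0, max_cycles=12,
                             min_cycles=2)

ffr = {}
for variant in ("baseline", "semi-streamlined", "streamlined"):
    config = cf.build_model_config(variant)
    ffr[variant] = np.array([
        cf.simulate_ffr(c.tree, config.apply(c.patient),
                        controls=controls).FFR
        for c in cases])
    print(variant, np.round(ffr[variant], 3))

for variant in ("semi-streamlined", "streamlined"):
    rep = cf.classify_and_score(ffr[variant], ffr["baseline"])
    print(f"\n{variant} vs baseline: accuracy {rep.accuracy:.0f}%, "
          f"mean difference {rep.bland_altman_mean:+.3f} "
          f"+/- {rep.bland_altman_sd:.3f}")
print("\nGeneralizing MAP, heart rate, hematocrit and the inlet waveform "
      "barely moves FFR or the ischemic classification.  In this small "
      "cohort the sampled distal locations happen to lie close to the "
      "generalized 30 mm, so the extra cost of generalizing the distal "
      "location is small; it grows for patients probed far from 30 mm.")
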