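"""Estimate the restitution-dispersion index DRest for one subject.

DRest = dTpe/dRR after removing rate memory: the beat series is filtered
into a surrogate RR, and the slope of Tpe against it is the index.
Healthy values sit around 0.02-0.06; torsadogenic patients under IKr
block have shown ~0.2.
"""

import numpy as np

from drest import SubjectProfile, estimate_drest, generate_beat_series, make_step_schedule
from drest.memory import fit_memory_model, surrogate_rr

for label, slope in (("healthy-like", 0.04), ("torsadogenic-like", 0.20)):
    rng = np.random.default_rng(3)
    profile = SubjectProfile(
        drest_true=slope, noise_sd_ms=2.0, rr_mean_ms=900.0,
        rr_step_schedule=make_step_schedule(rng, 1800.0, 900.0), seed=4)
    gen = generate_beat_series(profile, duration_s=1800.0)

    model = fit_memory_model(gen.series, target="Tpe")
    z = surrogate_rr(model, gen.series)
    est = estimate_drest(gen.series, z, seed=0)
    print(f"{label}: true {slope:.3f}  estimated {est.drest:.4f}  "
          f"95% CI [{est.ci_95[0]:.4f}, {est.ci_95[1]:.4f}]  "
          f"({est.n_beats} beats over {est.rr_range_ms[0]:.0f}-"
          f"{est.rr_range_ms[1]:.0f} ms surrogate RR)")
# The estimate should match the generator's slope within the CI; the
# surrogate-RR span shows the heart-rate range that identified it.
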