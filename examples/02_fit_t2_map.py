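"""Fit a voxel-wise T2 map from a multi-echo series and check its quality.

ln S(TE) = ln S0 - TE/T2 is fitted per voxel by ordinary least squares;
echoes below the noise floor are dropped, voxels with non-decaying signal
are flagged invalid.
"""

import numpy as np

from t2rp import PhantomConfig, fit_t2_loglinear, qc_report
from t2rp.phantom import generate_anatomy, generate_t2_truth, simulate_multiecho

cfg = PhantomConfig(seed=1)
rng = np.random.default_rng(cfg.seed)
structs = generate_anatomy(cfg, rng)
truth, _ = generate_t2_truth(structs, cfg, is_rp=True, rng=rng)
body = structs["lung"] | structs["gtv"]
series = simulate_multiecho(truth, cfg, rng, s0=np.where(body, cfg.s0, 0.0))

fit = fit_t2_loglinear(series)
report = qc_report(fit, mask=structs["lung"])
lung_valid = fit.t2.valid_mask & structs["lung"]

print(f"echo times (ms):        {list(cfg.te_ms)}")
print(f"valid-fit fraction:     {report['valid_fraction']:.2f} (air voxels are rejected)")
print(f"median R^2 over lung:   {report['median_r2']:.4f}")
print(f"median lung T2 fitted:  {np.median(fit.t2.values[lung_valid]):.1f} ms "
      f"(simulated background {cfg.lung_t2_ms:.0f} ms)")
err = fit.t2.values[lung_valid] - truth.values[lung_valid]
print(f"median |T2 error|:      {np.median(np.abs(err)):.2f} ms at noise sigma {cfg.noise_sigma}")
# The fitted lung T2 tracks the simulated ground truth to a couple of ms;
# only voxels inside the body yield trustworthy (valid) fits.
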