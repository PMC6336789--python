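"""Detect spots with the GLRT and fit them by Poisson maximum likelihood.

A frame with three emitters on a 5-photon background is scanned with the
generalized likelihood ratio test at a per-pixel false-alarm probability
of 1e-6, and each detected site is fitted with the pixel-integrated
Gaussian model; the Cramér–Rao lower bound (CRLB) reported with each fit
is the best achievable precision for that photon count.
"""

import numpy as np

from cosmotrace import DetectionParams, glrt_detect, mle_fit
from cosmotrace.localization import cut_window
from cosmotrace.psf import render_scene_frame

rng = np.random.default_rng(1)
spots = [(12.3, 14.7, 800.0, 1.3), (30.0, 8.5, 500.0, 1.3),
         (22.6, 28.1, 1200.0, 1.3)]
frame = rng.poisson(render_scene_frame((40, 40), spots, 5.0)).astype(float)

params = DetectionParams(sigma_psf=1.3, p_fa=1e-6)
candidates = glrt_detect(frame, params)
print(f"{len(candidates)} candidate site(s) detected:")
for _, c in candidates.iterrows():
    win, x0, y0 = cut_window(frame, c.x_ref, c.y_ref, 4)
    fit = mle_fit(win, sigma_psf=1.3)
    print(f"  site at ({fit.x + x0:5.2f}, {fit.y + y0:5.2f}) px "
          f"+- {fit.crlb_x:.3f} px | I = {fit.intensity:6.1f} "
          f"+- {fit.crlb_intensity:.0f} photons | sigma = {fit.sigma:.2f} px")
# Position uncertainties of a few hundredths of a pixel at ~1000 photons
# are the CRLB regime: the fitter attains the information-theoretic limit.
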