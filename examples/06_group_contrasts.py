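"""Per-window group contrasts and the divergence-onset estimate.

Contrasts cumulative depth-point dwell ratio between the two cohorts in
every cumulative window (stratified Mann-Whitney, rank-biserial effect
size) and estimates when a sustained divergence begins.
"""

from eden_gaze import (
    SynthConfig,
    cohort_assignments,
    estimate_divergence_onset,
    group_timecourse_contrast,
    simulate_localization,
    simulate_trials,
)
from eden_gaze.depth_rois import rois_for_stimuli
from eden_gaze.io import normalize_coordinates
from eden_gaze.window_metrics import cumulative_dwell_table

cfg = SynthConfig(n_participants_per_cohort=16, n_stimuli=6,
                  occupancy_boost=0.15, divergence_onset_s=6.0, seed=3)
trials, truth = simulate_trials(cfg)
norm = [normalize_coordinates(t, cfg.stim_width_px, cfg.stim_height_px)
        for t in trials]
rois = rois_for_stimuli(simulate_localization(truth, seed=3), truth.stimulus_meta())
dwell = cumulative_dwell_table(norm, rois)
assignments = cohort_assignments(truth.cohort, sorted(truth.state_means))

contrast = group_timecourse_contrast(dwell, assignments,
                                     metric="dwell_ratio",
                                     design="between_pooled")
print("cumulative dwell-ratio contrast (high vs low cohort):")
print(contrast[["window_end_s", "n_high", "n_low", "effect_r", "p"]]
      .round(4).to_string(index=False))
# effect_r hovers near 0 through 6 s (the cohorts are identical there by
# construction) and becomes large and positive afterwards.

onset = estimate_divergence_onset(contrast, threshold=0.2)
print(f"\nestimated sustained divergence onset: 0-{onset:g} s window "
      f"(true transition injected at {cfg.divergence_onset_s:g} s)")
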