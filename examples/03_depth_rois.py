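"""Derive depth-point ROIs from pointer responses.

Responses are binned on a 32 x 16 grid, cells with enough respondents are
grouped into contiguous components, and each component becomes a
rectangular ROI (at most six per stimulus, ranked by support).
"""

from eden_gaze import SynthConfig, simulate_localization, simulate_trials
from eden_gaze.depth_rois import bin_responses, default_threshold, extract_rois

cfg = SynthConfig(n_participants_per_cohort=12, n_stimuli=1, seed=7)
_, truth = simulate_trials(cfg)
responses = simulate_localization(truth, pointing_sd_px=25, seed=7)

meta = truth.stimulus_meta()["S00"]
grid = bin_responses(responses, meta)
thr = default_threshold(len(responses))
print(f"{len(responses)} responses binned; occupied cells: "
      f"{(grid.counts > 0).sum()}; per-cell threshold: {thr}")

roi_set = extract_rois(grid, threshold=thr)
print(f"extracted {len(roi_set.rois)} ROI(s):")
for roi in roi_set.rois:
    print(f"  roi {roi.roi_id}: x [{roi.min_x:.3f}, {roi.max_x:.3f}) "
          f"y [{roi.min_y:.3f}, {roi.max_y:.3f}) "
          f"support={roi.support} cells={roi.n_cells}")

print("\ntrue depth-point centres (normalized):")
for cx, cy in truth.depth_centers_px["S00"]:
    print(f"  ({cx / meta['width_px']:.3f}, {cy / meta['height_px']:.3f})")
# each extracted rectangle should cover one of the true centres: the ROI
# procedure recovers where viewers agree the greatest depth lies.
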