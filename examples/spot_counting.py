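"""smFISH spot counting on a rendered 3-D stack with known truth.

Renders diffraction-limited foci in 12 synthetic cells, chooses the
detection threshold from a spot-free negative control, quantifies
background-subtracted disc sums, calibrates the single-mRNA intensity as
the histogram mode, and reports per-cell counts against the ground
truth.
"""

import numpy as np

from telekin import (
    calibrate_single_mrna,
    choose_threshold,
    counts_from_spots,
    detect_spots,
    make_cell_masks,
    quantify_spots,
    render_fish_stack,
)

masks = make_cell_masks(12, shape=(200, 200), cell_half=(14, 14))
rng = np.random.default_rng(0)
truth = {label: int(rng.integers(0, 5)) for label in range(1, 13)}

img = render_fish_stack(masks, truth, unit_intensity=20000.0,
                        brightness_sd=0.2, background=30.0, seed=1)
control = render_fish_stack(masks, {lab: 0 for lab in truth},
                            background=30.0, seed=2)

threshold = choose_threshold(control.voxels, k_max=0)
calls = detect_spots(img.voxels, threshold, cell_masks=masks)
calls = quantify_spots(img.voxels, calls, control_pixel_level=30.0)
cal = calibrate_single_mrna([c.integrated_intensity for c in calls])
table = counts_from_spots(calls, cal.unit_intensity, cell_labels=list(truth))

print(f"threshold from control   {threshold:.1f}")
print(f"spots detected           {len(calls)} (rendered: {sum(truth.values())})")
print(f"single-mRNA intensity    {cal.unit_intensity:.0f} (rendered unit 20000)")
print("cell  truth  counted")
for _, row in table.df.iterrows():
    label = int(row["cell_id"][4:])
    print(f"{label:4d}  {truth[label]:5d}  {row['mrna_count']:7.2f}")
# Counted values are real-valued intensity ratios; at this SNR they
# track the rendered truth to within a fraction of one transcript.
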