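"""smFISH spot detection, quantification and single-mRNA calibration.

A 3-D fluorescence stack is mildly Gaussian-smoothed, 3-D local maxima are
called, dim maxima are discarded at a threshold set so that at most a
handful of spots survive in a negative-control stack, and each surviving
spot is quantified as a background-subtracted disc sum in its own focal
plane (overlapping same-plane discs are merged).  The intensity of a
single transcript is calibrated as the mode of the spot-intensity
histogram in a strongly repressed strain, where nearly every spot holds
one mRNA; per-cell counts follow by dividing summed spot intensity by that
unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter

from .inference import CountTable

DETECT_SIGMA_XY = 1.0
DETECT_SIGMA_Z = 0.7
QUANT_RADIUS = 5.0
CONTROL_MAX_SPOTS = 3  # "a handful"
BORDER_XY = 2  # maxima this close to the xy edge are discarded
BORDER_Z = 0


@dataclass
class SpotCall:
    """A detected fluorescent focus."""

    z_plane: int
    y: int
    x: int
    peak_value: float
    integrated_intensity: float = float("nan")
    cell_label: int | None = None


@dataclass
class CalibrationResult:
    """Single-mRNA intensity from the histogram mode."""

    unit_intensity: float
    histogram_bin_width: float
    n_spots: int


def _smooth(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (planes, rows, cols)")
    return gaussian_filter(stack, sigma=(DETECT_SIGMA_Z, DETECT_SIGMA_XY, DETECT_SIGMA_XY))


def _local_maxima(smoothed: np.ndarray) -> list[tuple[int, int, int, float]]:
    """Strict 26-connected 3-D local maxima away from the border."""
    mx = maximum_filter(smoothed, size=3, mode="nearest")
    cand = np.argwhere((smoothed == mx) & (smoothed > np.min(smoothed)))
    nz, ny, nx = smoothed.shape
    out = []
    for z, y, x in cand:
        if not (BORDER_Z <= z <= nz - 1 - BORDER_Z):
            continue
        if not (BORDER_XY <= y <= ny - 1 - BORDER_XY and BORDER_XY <= x <= nx - 1 - BORDER_XY):
            continue
        # break plateau ties: keep only the lexicographically first voxel
        patch = smoothed[
            max(0, z - 1) : z + 2, max(0, y - 1) : y + 2, max(0, x - 1) : x + 2
        ]
        peak = smoothed[z, y, x]
        ties = np.argwhere(patch == peak)
        if len(ties) > 1:
            first = ties[0] + [max(0, z - 1), max(0, y - 1), max(0, x - 1)]
            if tuple(first) != (z, y, x):
                continue
        out.append((int(z), int(y), int(x), float(peak)))
    return out


def detect_spots(
    stack: np.ndarray, threshold: float = 0.0, cell_masks: np.ndarray | None = None
) -> list[SpotCall]:
    """3-D local maxima of the smoothed stack with peak >= threshold.

    Returns calls sorted by peak value, descending.  An all-constant image
    yields no calls.  With ``cell_masks``, each call is tagged with the
    label under it (None outside any cell).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    smoothed = _smooth(stack)
    calls = []
    for z, y, x, peak in _local_maxima(smoothed):
        if peak < threshold:
            continue
        label = None
        if cell_masks is not None:
            lab = int(cell_masks[y, x])
            label = lab if lab > 0 else None
        calls.append(SpotCall(z, y, x, peak, cell_label=label))
    calls.sort(key=lambda c: -c.peak_value)
    return calls


def choose_threshold(control_stack: np.ndarray, k_max: int = CONTROL_MAX_SPOTS) -> float:
    """Smallest threshold at which <= k_max maxima survive in the control.

    With fewer than k_max+1 maxima in the control the threshold falls back
    to the control's smoothed intensity ceiling (conservative: nothing in
    the control is called).  Raising k_max never raises the threshold.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    smoothed = _smooth(control_stack)
    peaks = sorted((p for _, _, _, p in _local_maxima(smoothed)), reverse=True)
    if len(peaks) > k_max:
        return float(np.nextafter(peaks[k_max], np.inf))
    return float(smoothed.max())


def _disc_offsets(radius: float) -> np.ndarray:
    r = int(math.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def quantify_spots(
    stack: np.ndarray,
    calls: list[SpotCall],
    radius: float = QUANT_RADIUS,
    control_pixel_level: float = 0.0,
) -> list[SpotCall]:
    """Background-subtracted disc sums; merge same-plane overlapping discs.

    Each call's intensity is the sum of (pixel - control level) inside a
    circle of ``radius`` px around the maximum, in the single XY plane of
    the maximum (pixel centres within Euclidean distance <= radius).
    Same-plane calls whose discs overlap are merged into one call (the
    brightest peak survives) whose intensity is the union-region sum, so no
    pixel is double counted.  Merging is idempotent and order-independent.
    """
    stack = np.asarray(stack, dtype=float)
    nz, ny, nx = stack.shape
    offsets = _disc_offsets(radius)

    # group same-plane calls into overlap components (centres closer than 2r)
    by_plane: dict[int, list[SpotCall]] = {}
    for c in calls:
        by_plane.setdefault(c.z_plane, []).append(c)
    out: list[SpotCall] = []
    for z, plane_calls in by_plane.items():
        plane_calls = sorted(plane_calls, key=lambda c: (c.y, c.x))
        k = len(plane_calls)
        parent = list(range(k))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(k):
            for j in range(i + 1, k):
                ci, cj = plane_calls[i], plane_calls[j]
                if (ci.y - cj.y) ** 2 + (ci.x - cj.x) ** 2 < (2 * radius) ** 2:
                    parent[find(i)] = find(j)
        groups: dict[int, list[SpotCall]] = {}
        for i in range(k):
            groups.setdefault(find(i), []).append(plane_calls[i])
        for members in groups.values():
            pixels: set[tuple[int, int]] = set()
            for c in members:
                for dy, dx in offsets:
                    yy, xx = c.y + dy, c.x + dx
                    if 0 <= yy < ny and 0 <= xx < nx:
                        pixels.add((int(yy), int(xx)))
            total = sum(stack[z, yy, xx] - control_pixel_level for yy, xx in pixels)
            best = max(members, key=lambda c: c.peak_value)
            out.append(
                SpotCall(z, best.y, best.x, best.peak_value, float(total), best.cell_label)
            )
    out.sort(key=lambda c: -c.peak_value)
    return out


def calibrate_single_mrna(
    intensities: np.ndarray, bin_width: float | None = None
) -> CalibrationResult:
    """Single-mRNA intensity as the mode of the spot-intensity histogram.

    Run on a strongly repressed strain (mean well below one transcript per
    cell) where almost every detected spot holds a single mRNA, so the
    histogram mode sits at the one-transcript intensity.  Default bin width
    is Freedman-Diaconis; mode ties break toward the lower bin.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size < 10:
        raise ValueError("need at least 10 spot intensities for calibration")
    if bin_width is None:
        edges = np.histogram_bin_edges(intensities, bins="fd")
        bin_width = float(edges[1] - edges[0])
    else:
        if bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        lo, hi = intensities.min(), intensities.max()
        n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
        edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(intensities, bins=edges)
    mode_bin = int(np.argmax(counts))  # argmax takes the first (lower) tie
    unit = float(0.5 * (edges[mode_bin] + edges[mode_bin + 1]))
    return CalibrationResult(unit, float(bin_width), int(intensities.size))


def counts_from_spots(
    calls: list[SpotCall],
    unit_intensity: float,
    cell_labels: list[int] | None = None,
    round_counts: bool = False,
    sentinel_length_um: float = 1.9,
) -> CountTable:
    """Per-cell mRNA counts: summed spot intensity / single-mRNA intensity.

    Counts are real-valued by default (a rounding switch is provided).
    ``cell_labels`` lists the cells that must appear even with zero calls.
    """
    if unit_intensity <= 0:
        raise ValueError("unit_intensity must be > 0")
    sums: dict[int, float] = {int(lab): 0.0 for lab in (cell_labels or [])}
    for c in calls:
        if c.cell_label is None:
            continue
        sums[int(c.cell_label)] = sums.get(int(c.cell_label), 0.0) + c.integrated_intensity
    labels = sorted(sums)
    counts = [sums[lab] / unit_intensity for lab in labels]
    if round_counts:
        counts = [round(v) for v in counts]
    df = pd.DataFrame(
        {
            "cell_id": [f"cell{lab}" for lab in labels],
            "length_um": sentinel_length_um,
            "mrna_count": np.maximum(0.0, counts),
        }
    )
    return CountTable(df)


def counts_from_total_fluorescence(
    stack: np.ndarray,
    cell_masks: np.ndarray,
    negative_control_level: float,
    unit_intensity: float,
    round_counts: bool = False,
    sentinel_length_um: float = 1.9,
) -> CountTable:
    """Whole-cell counts for high-expression (repressor-deletion) samples.

    For each cell, the plane with the largest in-mask summed intensity is
    selected, the control pixel level is subtracted from every pixel, and
    the background-corrected sum is divided by the single-mRNA intensity.
    """
    if unit_intensity <= 0:
        raise ValueError("unit_intensity must be > 0")
    stack = np.asarray(stack, dtype=float)
    masks = np.asarray(cell_masks)
    labels = [int(v) for v in np.unique(masks) if v > 0]
    if not labels:
        raise ValueError("cell_masks label no cells")
    rows = []
    for lab in labels:
        sel = masks == lab
        npix = int(sel.sum())
        plane_sums = stack[:, sel].sum(axis=1)
        best = int(np.argmax(plane_sums))
        corrected = float(plane_sums[best] - negative_control_level * npix)
        count = max(0.0, corrected / unit_intensity)
        rows.append((f"cell{lab}", sentinel_length_um, round(count) if round_counts else count))
    df = pd.DataFrame(rows, columns=["cell_id", "length_um", "mrna_count"])
    return CountTable(df)
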