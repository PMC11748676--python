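"""Synthetic data generators with known ground truth.

Emulates every input the inference pipeline consumes: steady-state
copy-number populations (analytic or SSA sampler), per-mRNA fluorescence
measurement noise, operator panels along an anticorrelated (k_a0, k_d)
line with varying repressor copy number, exponential decay series, cell
lengths for gating, and diffraction-limited 3-D spot images with mask and
truth sidecars.  Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gillespie
from .inference import CountTable, DecaySeries
from .telegraph import RateParams, analytic_pmf

# Cell-length model: lognormal with median inside the 1.73-2.16 um
# single-copy gate, spanning roughly 1.4-3.25 um over a population,
# so the gating filter is exercised with realistic pass fractions.
LENGTH_LOG_MEDIAN = math.log(1.93)
LENGTH_LOG_SD = 0.17


@dataclass
class NoiseModel:
    """Per-mRNA fluorescence measurement noise.

    Each transcript contributes an intensity ~ Normal(mean, sd); per-cell
    intensities are summed, rounded to the nearest integer when
    ``rounding``, and clipped at zero.
    """

    per_mrna_mean: float = 1.0
    per_mrna_sd: float = 0.4
    rounding: bool = True

    def __post_init__(self) -> None:
        if self.per_mrna_sd < 0:
            raise ValueError("per_mrna_sd must be >= 0")


@dataclass
class PanelSpec:
    """A panel of simulated operators along an anticorrelated rate line.

    Per-repressor association rates ``ka0`` and dissociation rates ``kd``
    are linearly spaced between the endpoints, with ka0 decreasing as kd
    increases (strong operators bind fast and release slowly).  The full
    association rate scales with repressor copy number:
    k_a = n_repressor * ka0.  Defaults r = 22 min^-1, gamma = 0.80 min^-1,
    1000 cells per dataset.
    """

    n_operators: int = 50
    ka0_range: tuple[float, float] = (0.2, 0.005)
    kd_range: tuple[float, float] = (0.05, 2.0)
    repressor_copies: tuple[int, ...] = (1, 2, 5, 10, 50, 100)
    r: float = 22.0
    gamma: float = 0.80
    n_cells: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_operators < 2:
            raise ValueError("need at least 2 operators")
        for v in (*self.ka0_range, *self.kd_range, self.r, self.gamma):
            if v <= 0:
                raise ValueError("all rates must be > 0")
        d_ka = self.ka0_range[1] - self.ka0_range[0]
        d_kd = self.kd_range[1] - self.kd_range[0]
        if d_ka * d_kd >= 0:
            raise ValueError("ka0 and kd must vary in opposite directions")

    def line(self) -> tuple[np.ndarray, np.ndarray]:
        ka0 = np.linspace(*self.ka0_range, self.n_operators)
        kd = np.linspace(*self.kd_range, self.n_operators)
        return ka0, kd


@dataclass
class PanelEntry:
    """One (operator, repressor copy number) dataset with its truth."""

    operator_index: int
    n_repressor: int
    params: RateParams  # truth, with k_a = n_repressor * ka0
    ka0: float
    raw: CountTable
    noisy: CountTable


@dataclass
class SyntheticImage:
    """A rendered 3-D FISH stack with ground truth.

    ``truth_spots`` rows are (z, y, x, n_mrna, brightness); ``cell_masks``
    is a labeled 2-D array (0 = background).
    """

    voxels: np.ndarray
    plane_spacing_nm: float
    truth_spots: list[tuple[int, int, int, int, float]]
    cell_masks: np.ndarray
    background_level: float

    def truth_sidecar(self) -> dict:
        return {
            "plane_spacing_nm": self.plane_spacing_nm,
            "background_level": self.background_level,
            "spots": [
                {"z": int(z), "y": int(y), "x": int(x), "n_mrna": int(n), "brightness": float(b)}
                for z, y, x, n, b in self.truth_spots
            ],
        }


def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed) % (2**31), spawn_key=(stream,)))


def sample_cell_lengths(n: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal cell lengths (um), median 1.93 um, truncated to 1.4-3.25 um.

    The truncation bounds are the span observed in exponentially growing
    populations; clipping moves <2% of draws.
    """
    raw = np.exp(rng.normal(LENGTH_LOG_MEDIAN, LENGTH_LOG_SD, size=n))
    return np.clip(raw, 1.4, 3.25)


def generate_population(
    params: RateParams,
    n_cells: int,
    seed: int = 0,
    sampler: str = "analytic",
    operator_label: str = "",
    t_sample: float | None = None,
) -> CountTable:
    """Steady-state copy-number table with ground-truth kinetics.

    ``sampler='analytic'`` draws i.i.d. counts from the exact stationary
    pmf; ``sampler='ssa'`` runs one Gillespie trajectory per cell past
    burn-in.  Cell lengths are drawn from the package's lognormal length
    model so the single-copy gate is exercised.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if sampler == "analytic":
        rng = _rng(seed, 0)
        counts = analytic_pmf(params).sample(n_cells, rng)
    elif sampler == "ssa":
        counts = gillespie.sample_population(
            params, n_cells, t_sample=t_sample, seed=seed
        ).counts.astype(int)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    lengths = sample_cell_lengths(n_cells, _rng(seed, 1))
    df = pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(n_cells)],
            "length_um": lengths,
            "mrna_count": counts,
        }
    )
    return CountTable(df, operator_label)


def apply_intensity_noise(
    table: CountTable, noise: NoiseModel | None = None, seed: int = 0
) -> CountTable:
    """Observed counts under per-mRNA intensity noise.

    Each of a cell's m transcripts gets an intensity ~ Normal(mean, sd);
    the per-cell sum is rounded to the nearest integer (if configured) and
    clipped at zero.  Cells with zero true count stay zero.
    """
    if noise is None:
        noise = NoiseModel()
    counts = table.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("input counts must be integral")
    rng = _rng(seed, 2)
    observed = np.empty_like(counts)
    for i, m in enumerate(counts.astype(int)):
        if m == 0:
            observed[i] = 0.0
            continue
        total = noise.per_mrna_mean * m + noise.per_mrna_sd * rng.standard_normal(m).sum()
        if noise.rounding:
            total = np.round(total)
        observed[i] = max(0.0, total)
    df = table.df.copy()
    df["mrna_count"] = observed
    return CountTable(df, table.operator_label)


def generate_operator_panel(spec: PanelSpec, noise: NoiseModel | None = None) -> list[PanelEntry]:
    """Datasets for every (operator, repressor copy number) pair.

    Counts are sampled from the analytic stationary distribution; both the
    raw table and the intensity-noise-applied table are emitted, with the
    generating truth attached to each entry.
    """
    if noise is None:
        noise = NoiseModel()
    ka0s, kds = spec.line()
    entries: list[PanelEntry] = []
    stream = 0
    for j, (ka0, kd) in enumerate(zip(ka0s, kds)):
        for n_rep in spec.repressor_copies:
            params = RateParams(spec.r, spec.gamma, n_rep * ka0, kd)
            label = f"op{j:02d}_n{n_rep}"
            sub_seed = (spec.seed + 7919 * stream) % (2**31)
            raw = generate_population(
                params, spec.n_cells, seed=sub_seed, operator_label=label
            )
            noisy = apply_intensity_noise(raw, noise, seed=sub_seed)
            entries.append(PanelEntry(j, n_rep, params, float(ka0), raw, noisy))
            stream += 1
    return entries


def panel_manifest(spec: PanelSpec, entries: list[PanelEntry]) -> dict:
    """JSON-serializable record of the generating truth for a panel."""
    return {
        "spec": {
            "n_operators": spec.n_operators,
            "ka0_range": list(spec.ka0_range),
            "kd_range": list(spec.kd_range),
            "repressor_copies": list(spec.repressor_copies),
            "r": spec.r,
            "gamma": spec.gamma,
            "n_cells": spec.n_cells,
            "seed": spec.seed,
        },
        "entries": [
            {
                "operator_index": e.operator_index,
                "n_repressor": e.n_repressor,
                "ka0": e.ka0,
                "k_a": e.params.k_a,
                "k_d": e.params.k_d,
                "label": e.raw.operator_label,
            }
            for e in entries
        ],
    }


def generate_decay_series(
    gamma: float,
    times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0),
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    include_control: bool = False,
) -> list[DecaySeries]:
    """Post-rifampicin decay series, level = exp(-gamma*t) x lognormal noise.

    Each replicate is renormalized by its own t = 0 draw (the t = 0 sample
    defines level 1).  With ``include_control`` an untreated flat series is
    appended (replicate id prefixed ``con``), which degradation fitting
    must exclude.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    t = np.asarray(times, dtype=float)
    rng = _rng(seed, 3)
    out = []
    for rep in range(n_replicates):
        noise = np.exp(rng.normal(0.0, noise_sd, size=t.size))
        levels = np.exp(-gamma * t) * noise
        levels = levels / levels[0] if t[0] == 0 else levels
        out.append(DecaySeries(t, levels, replicate_id=f"rif{rep}"))
    if include_control:
        for rep in range(n_replicates):
            noise = np.exp(rng.normal(0.0, noise_sd, size=t.size))
            levels = noise / noise[0] if t[0] == 0 else noise
            out.append(DecaySeries(t, levels, replicate_id=f"con{rep}"))
    return out


def make_cell_masks(
    n_cells: int, shape: tuple[int, int] = (128, 128), cell_half: tuple[int, int] = (10, 5)
) -> np.ndarray:
    """Labeled 2-D mask with rectangular 'cells' on a grid (labels 1..n)."""
    masks = np.zeros(shape, dtype=np.int32)
    hy, hx = cell_half
    pitch_y, pitch_x = 2 * hy + 6, 2 * hx + 6
    per_row = max(1, (shape[1] - 6) // pitch_x)
    for i in range(n_cells):
        ry, rx = divmod(i, per_row)
        cy = 3 + hy + ry * pitch_y
        cx = 3 + hx + rx * pitch_x
        if cy + hy >= shape[0] or cx + hx >= shape[1]:
            raise ValueError("too many cells for mask shape")
        masks[cy - hy : cy + hy + 1, cx - hx : cx + hx + 1] = i + 1
    return masks


def render_fish_stack(
    cell_masks: np.ndarray,
    counts: dict[int, int],
    unit_intensity: float = 10000.0,
    brightness_sd: float = 0.4,
    psf_sigma_xy: float = 1.2,
    psf_sigma_z: float = 1.0,
    n_planes: int = 9,
    background: float = 50.0,
    plane_spacing_nm: float = 200.0,
    seed: int = 0,
    z_mode: str = "random",
    min_separation: float = 12.0,
) -> SyntheticImage:
    """Render diffraction-limited spots on a Poisson-noise background.

    Each mRNA becomes one 3-D Gaussian focus of brightness
    ``unit_intensity`` x Normal(1, brightness_sd), placed uniformly inside
    its cell's mask (non-overlapping by default: rejection sampling keeps
    spot centres at least ``min_separation`` px apart; set it to 0 to
    exercise merging).  Brightness is defined as the integrated in-plane
    intensity at the focal plane of the spot — the same single-plane
    quantity the spot-quantification pipeline measures.  ``z_mode`` places
    foci on a random interior plane ("random") or all on the centre plane
    ("center", the whole-cell fluorescence scenario).  Voxels are Poisson
    draws around background + signal; ground truth is retained.
    """
    masks = np.asarray(cell_masks)
    ny, nx = masks.shape
    rng = _rng(seed, 4)
    signal = np.zeros((n_planes, ny, nx), dtype=float)
    truth: list[tuple[int, int, int, int, float]] = []
    placed: list[tuple[int, int]] = []
    zz = np.arange(n_planes)
    for label, n_mrna in sorted(counts.items()):
        if n_mrna < 0:
            raise ValueError("spot count must be >= 0")
        ys, xs = np.nonzero(masks == label)
        if ys.size == 0:
            raise ValueError(f"no mask pixels for cell label {label}")
        for _ in range(int(n_mrna)):
            for _try in range(200):
                k = rng.integers(0, ys.size)
                y, x = int(ys[k]), int(xs[k])
                if min_separation <= 0 or all(
                    (y - py) ** 2 + (x - px) ** 2 >= min_separation**2 for py, px in placed
                ):
                    break
            if z_mode == "center" or n_planes <= 4:
                z = n_planes // 2
            else:
                z = int(rng.integers(2, n_planes - 2))
            brightness = float(unit_intensity * max(0.05, rng.normal(1.0, brightness_sd)))
            placed.append((y, x))
            truth.append((z, y, x, 1, brightness))
            # in-plane-normalized 3-D Gaussian: focal-plane xy integral = brightness
            ry = rx = int(math.ceil(4 * psf_sigma_xy))
            y0, y1 = max(0, y - ry), min(ny, y + ry + 1)
            x0, x1 = max(0, x - rx), min(nx, x + rx + 1)
            gy = np.exp(-0.5 * ((np.arange(y0, y1) - y) / psf_sigma_xy) ** 2)
            gx = np.exp(-0.5 * ((np.arange(x0, x1) - x) / psf_sigma_xy) ** 2)
            gz = np.exp(-0.5 * ((zz - z) / psf_sigma_z) ** 2)  # peak 1 at z
            norm = 2 * math.pi * psf_sigma_xy**2
            patch = brightness * np.einsum("z,y,x->zyx", gz, gy, gx) / norm
            signal[:, y0:y1, x0:x1] += patch
    voxels = rng.poisson(background + signal).astype(float)
    return SyntheticImage(
        voxels=voxels,
        plane_spacing_nm=plane_spacing_nm,
        truth_spots=truth,
        cell_masks=masks,
        background_level=background,
    )
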