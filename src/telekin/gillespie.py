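"""Exact stochastic simulation (SSA) of the two-state telegraph model.

Reactions: on -> off at rate k_a (binding, on state only); off -> on at
rate k_d (unbinding); m -> m+1 at rate r (on state only); m -> m-1 at rate
m*gamma.  The occlusion variant sets the binding hazard to zero for a
window after each transcription event, modelling the elongating polymerase
blocking the operator; windows are handled exactly by treating the window
end as a rate wall and re-drawing (memorylessness of the exponential).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import CountTable
from .telegraph import RateParams

#: sentinel cell length (um) used when no length model is attached; sits
#: inside the single-copy gate so gating is a no-op on simulated tables
SENTINEL_LENGTH_UM = 1.9


@dataclass
class OcclusionConfig:
    """Operator occlusion after transcription initiation.

    ``t_occlude_s`` is entered in seconds (rates are min^-1) and converted
    internally.
    """

    t_occlude_s: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.t_occlude_s < 0:
            raise ValueError("t_occlude_s must be >= 0")

    @property
    def window_min(self) -> float:
        return self.t_occlude_s / 60.0 if self.enabled else 0.0


@dataclass
class Trajectory:
    """One SSA sample path over [0, t_end] minutes."""

    event_times: np.ndarray
    event_kinds: list[str]
    mrna_path: np.ndarray
    promoter_path: np.ndarray  # True = on (repressor unbound), after each event
    t_end: float


def _child_seed(seed: int, i: int) -> int:
    return (int(seed) + 1_000_003 * (i + 1)) % (2**31)


def _step_to_end(
    params: RateParams,
    t_end: float,
    rng: random.Random,
    on: bool,
    m: int,
    window_min: float,
    record: bool,
):
    """Core SSA loop; returns (times, kinds, ms, ons, final_on, final_m)."""
    r, g, ka, kd = params.r, params.gamma, params.k_a, params.k_d
    t = 0.0
    occlude_until = -math.inf
    times: list[float] = []
    kinds: list[str] = []
    ms: list[int] = []
    ons: list[bool] = []
    exp = rng.expovariate
    uni = rng.random
    while True:
        occluded = on and t < occlude_until
        if on:
            a_bind = 0.0 if occluded else ka
            a_tx = r
            a_unbind = 0.0
        else:
            a_bind = 0.0
            a_tx = 0.0
            a_unbind = kd
        a_deg = m * g
        a_tot = a_bind + a_tx + a_unbind + a_deg
        wall = occlude_until if occluded else math.inf
        if a_tot <= 0.0:
            if wall < t_end:
                t = wall
                continue
            break
        dt = exp(a_tot)
        if t + dt >= wall:
            t = wall  # binding hazard switches back on; memoryless restart
            continue
        t = t + dt
        if t >= t_end:
            break
        u = uni() * a_tot
        if u < a_tx:
            m += 1
            kind = "transcribe"
            if window_min > 0.0:
                occlude_until = t + window_min
        elif u < a_tx + a_deg:
            m -= 1
            kind = "degrade"
        elif u < a_tx + a_deg + a_bind:
            on = False
            kind = "bind"
        else:
            on = True
            kind = "unbind"
        if record:
            times.append(t)
            kinds.append(kind)
            ms.append(m)
            ons.append(on)
    return times, kinds, ms, ons, on, m


def simulate_trajectory(
    params: RateParams,
    t_end: float,
    seed: int = 0,
    initial: tuple[bool, int] = (True, 0),
    occlusion: OcclusionConfig | None = None,
) -> Trajectory:
    """Exact SSA sample path, reproducible under ``seed``.

    ``initial`` is (promoter on?, mRNA copies) at t = 0.  Pass an
    :class:`OcclusionConfig` to forbid binding within the occlusion window
    after each transcription event.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    window = occlusion.window_min if occlusion is not None else 0.0
    rng = random.Random(int(seed) % (2**31))
    on0, m0 = initial
    times, kinds, ms, ons, _, _ = _step_to_end(
        params, t_end, rng, bool(on0), int(m0), window, record=True
    )
    return Trajectory(
        event_times=np.array(times),
        event_kinds=kinds,
        mrna_path=np.array(ms, dtype=int),
        promoter_path=np.array(ons, dtype=bool),
        t_end=t_end,
    )


def simulate_with_occlusion(
    params: RateParams, occ: OcclusionConfig, t_end: float, seed: int = 0
) -> Trajectory:
    """SSA with post-transcription operator occlusion (see module docstring)."""
    return simulate_trajectory(params, t_end, seed=seed, occlusion=occ)


def default_burn_in(params: RateParams) -> float:
    """Relaxation-based burn-in: 10/min(gamma, k_a+k_d), capped at 200 min."""
    scales = [params.gamma]
    if params.k_a + params.k_d > 0:
        scales.append(params.k_a + params.k_d)
    return min(200.0, 10.0 / min(scales))


def sample_population(
    params: RateParams,
    n_cells: int,
    t_sample: float | None = None,
    seed: int = 0,
    occlusion: OcclusionConfig | None = None,
    operator_label: str = "",
) -> CountTable:
    """Copy numbers of ``n_cells`` independent cells at steady state.

    Each cell runs its own SSA from (on, m=0) for ``t_sample`` minutes
    (default: :func:`default_burn_in`) on a per-cell substream derived from
    ``seed`` by fixed increments.  Lengths are filled with the in-gate
    sentinel 1.9 um.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    t = default_burn_in(params) if t_sample is None else float(t_sample)
    window = occlusion.window_min if occlusion is not None else 0.0
    counts = np.empty(n_cells, dtype=int)
    for i in range(n_cells):
        rng = random.Random(_child_seed(seed, i))
        _, _, _, _, _, m = _step_to_end(params, t, rng, True, 0, window, record=False)
        counts[i] = m
    df = pd.DataFrame(
        {
            "cell_id": [f"sim{i:06d}" for i in range(n_cells)],
            "length_um": SENTINEL_LENGTH_UM,
            "mrna_count": counts,
        }
    )
    return CountTable(df, operator_label)


def occupied_fraction(traj: Trajectory, initial_on: bool = True) -> float:
    """Time-weighted fraction of the trajectory spent with the promoter on."""
    ts = np.concatenate([[0.0], traj.event_times, [traj.t_end]])
    states = np.empty(len(ts) - 1)
    cur = 1.0 if initial_on else 0.0
    states[0] = cur
    for i, kind in enumerate(traj.event_kinds):
        if kind == "bind":
            cur = 0.0
        elif kind == "unbind":
            cur = 1.0
        if i + 1 < len(states):
            states[i + 1] = cur
    return float(np.sum(np.diff(ts) * states) / traj.t_end)
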