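"""Metropolis Monte Carlo and umbrella sampling on discrete 1-D landscapes.

The state space of each landscape is small and exactly enumerable, so the
samplers here are a verified methodology: every estimate can be checked
against the exact Boltzmann sum.  Moves are +/-1 on the state index with
rejection at the ends (which preserves detailed balance under the symmetric
proposal).  Umbrella windows add per-state bias energies; overlapping
biased histograms are recombined into an unbiased profile by iterative
multi-histogram reweighting (discrete-state WHAM), anchored to the
landscape's reference state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .landscapes import Landscape1D, OccupancyResult, toehold_availability
from .thermo import DEFAULT_MODEL, EnergyModel


class NonOverlapError(ValueError):
    """Umbrella windows do not share well-sampled states; reweighting impossible."""


@dataclass(frozen=True)
class UmbrellaWindow:
    """Per-state bias energies (kcal/mol) with a label."""

    bias: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.bias)):
            raise ValueError("bias energies must be finite")


@dataclass(frozen=True)
class SampledHistogram:
    counts: tuple[int, ...]
    n_steps: int
    seed: int
    window_label: str = ""

    def __post_init__(self) -> None:
        if sum(self.counts) != self.n_steps:
            raise ValueError("counts must sum to n_steps")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")


def exact_occupancy(
    landscape: Landscape1D,
    model: EnergyModel = DEFAULT_MODEL,
    open_coords: tuple[float, ...] = (0.0,),
) -> OccupancyResult:
    """Exact Boltzmann occupancy (the oracle for every sampler here)."""
    return toehold_availability(landscape, model, open_coords=open_coords)


def metropolis_sample(
    landscape: Landscape1D,
    model: EnergyModel = DEFAULT_MODEL,
    n_steps: int = 1_000_000,
    seed: int = 0,
    bias: Optional[Sequence[float]] = None,
    start_index: Optional[int] = None,
    label: str = "",
) -> SampledHistogram:
    """Single-state-increment Metropolis chain on the (optionally biased)
    landscape; reproducible for a fixed seed.

    The state after each of the ``n_steps`` proposals is counted, so counts
    sum to ``n_steps``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    energies = np.asarray(landscape.dG, dtype=float)
    if bias is not None:
        if len(bias) != len(energies):
            raise ValueError("bias length must match the number of states")
        energies = energies + np.asarray(bias, dtype=float)
    n = len(energies)
    # acceptance probability for each state and move direction
    acc_up = np.zeros(n)
    acc_down = np.zeros(n)
    def _acc(delta: float) -> float:
        return 1.0 if delta <= 0 else math.exp(-delta / model.RT)

    for s in range(n):
        if s + 1 < n:
            acc_up[s] = _acc(energies[s + 1] - energies[s])
        if s - 1 >= 0:
            acc_down[s] = _acc(energies[s - 1] - energies[s])

    rng = np.random.default_rng(seed)
    state = int(np.argmin(energies)) if start_index is None else start_index
    counts = np.zeros(n, dtype=np.int64)
    chunk = 1_000_000
    remaining = n_steps
    while remaining > 0:
        m = min(chunk, remaining)
        ups = rng.random(m) < 0.5
        us = rng.random(m)
        for k in range(m):
            if ups[k]:
                if us[k] < acc_up[state]:
                    state += 1
            else:
                if us[k] < acc_down[state]:
                    state -= 1
            counts[state] += 1
        remaining -= m
    return SampledHistogram(
        counts=tuple(int(c) for c in counts),
        n_steps=n_steps,
        seed=seed,
        window_label=label,
    )


def harmonic_windows(
    landscape: Landscape1D, k: float = 2.0, centers: Optional[Sequence[float]] = None
) -> list[UmbrellaWindow]:
    """Discrete harmonic-equivalent biases, one window per center.

    By default one window is centered on every coordinate value, which
    guarantees every state (including rare open states) is well sampled; the
    stiffness ``k`` (kcal/mol per squared coordinate step) keeps each window
    concentrated on its center while leaving nearest-neighbor overlap of
    order exp(-k/2RT).
    """
    coords = np.asarray(landscape.coords, dtype=float)
    if centers is None:
        centers = coords
    return [
        UmbrellaWindow(
            bias=tuple(0.5 * k * (coords - c) ** 2),
            label=f"center={c:g}",
        )
        for c in centers
    ]


def umbrella_sample(
    landscape: Landscape1D,
    model: EnergyModel = DEFAULT_MODEL,
    windows: Optional[Sequence[UmbrellaWindow]] = None,
    n_steps_per_window: int = 100_000,
    seed: int = 0,
) -> list[SampledHistogram]:
    """Run one biased Metropolis chain per umbrella window.

    Each window starts at the minimum of its biased landscape; per-window
    seeds are derived deterministically from ``seed``.
    """
    if windows is None:
        windows = harmonic_windows(landscape)
    if len(windows) < 1:
        raise ValueError("need at least one umbrella window")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(windows))
    out = []
    for w, wseed in zip(windows, child_seeds):
        out.append(
            metropolis_sample(
                landscape,
                model,
                n_steps=n_steps_per_window,
                seed=int(wseed) % (2**31),
                bias=w.bias,
                label=w.label,
            )
        )
    return out


def reweight(
    histograms: Sequence[SampledHistogram],
    windows: Sequence[UmbrellaWindow],
    model: EnergyModel = DEFAULT_MODEL,
    landscape: Optional[Landscape1D] = None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> Landscape1D:
    """Unbiased free-energy profile by iterative multi-histogram reweighting.

    Iterates the discrete WHAM equations until successive window free-energy
    shifts change by less than ``tol`` (kcal/mol).  Raises
    :class:`NonOverlapError` when the windows do not form one connected
    component through co-visited states.  The returned profile is anchored so
    the reference state (of ``landscape`` if given, else state 0) has dG 0.
    """
    if len(histograms) != len(windows):
        raise ValueError("one histogram per window required")
    n_w = len(windows)
    counts = np.array([h.counts for h in histograms], dtype=float)  # (W, S)
    n_states = counts.shape[1]
    biases = np.array([w.bias for w in windows], dtype=float)
    if biases.shape != counts.shape:
        raise ValueError("window bias length must match histogram length")

    # connectivity through co-visited states
    visited = counts > 0
    comp = np.full(n_w, -1)
    stack = [0]
    comp[0] = 0
    while stack:
        i = stack.pop()
        for j in range(n_w):
            if comp[j] == -1 and np.any(visited[i] & visited[j]):
                comp[j] = 0
                stack.append(j)
    if np.any(comp == -1):
        raise NonOverlapError("umbrella windows are not connected by visited states")

    N_w = counts.sum(axis=1)  # steps per window
    n_s = counts.sum(axis=0)  # total visits per state
    RT = model.RT
    f = np.zeros(n_w)  # window free-energy shifts, kcal/mol
    c = np.exp(-biases / RT)  # (W, S)
    for _ in range(max_iter):
        denom = (N_w * np.exp(f / RT)) @ c  # (S,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_s / denom, 0.0)
        p_sum = p.sum()
        p /= p_sum
        z_w = c @ p  # (W,)
        f_new = -RT * np.log(z_w)
        shift = np.max(np.abs(f_new - f))
        f = f_new
        if shift < tol:
            break

    if np.any((n_s > 0) & (p <= 0)) or np.any(p[n_s > 0] <= 0):
        raise NonOverlapError("reweighting produced zero probability for visited states")
    unvisited = n_s == 0
    if np.any(unvisited):
        raise NonOverlapError(
            f"states never visited in any window: {np.nonzero(unvisited)[0].tolist()}"
        )
    dG = -RT * np.log(p)
    coords = (
        landscape.coords if landscape is not None else tuple(range(n_states))
    )
    ref = landscape.reference_index if landscape is not None else 0
    return Landscape1D.from_energies(
        (landscape.coordinate_name if landscape is not None else "state"),
        coords,
        dG.tolist(),
        reference_index=ref,
    )
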