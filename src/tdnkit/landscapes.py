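"""Discrete base-pair-resolution free-energy landscapes.

Two one-dimensional landscapes describe the reconfiguration of the cleaved
nanostructure:

* **Fraying (toehold exposure)** — the retained duplex segment left after
  RNase H cleavage opens as a zipper from the cleavage-created free end.
  The coordinate is the number of intact base pairs counted from the
  anchored (covalently continuous) end; state 0 is the fully open toehold.
  Closing the first base pair from the open state pays a tethered-initiation
  entropy, which produces the entropic barrier to rebinding.

* **Toehold-mediated strand displacement** — the invading target first zips
  up the exposed toehold, then exchanges incumbent base pairs for invader
  base pairs one at a time through branch migration, passing over an
  intermediate plateau at each step; the incumbent's initiation penalty is
  refunded once when its last pair is lost and it dissociates.

Occupancies are exact Boltzmann sums over the finite state space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .strands import DuplexMap
from .thermo import DEFAULT_MODEL, EnergyModel, segment_stacks


@dataclass(frozen=True)
class Landscape1D:
    """Ordered reaction-coordinate states with relative free energies (kcal/mol).

    ``coords`` are strictly increasing (integers for real states;
    half-integers mark branch-migration plateau intermediates).  The state at
    ``reference_index`` has dG exactly 0.
    """

    coordinate_name: str
    coords: tuple[float, ...]
    dG: tuple[float, ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if len(self.coords) != len(self.dG):
            raise ValueError("coords and dG must have equal length")
        if not all(b > a for a, b in zip(self.coords, self.coords[1:])):
            raise ValueError("coordinate values must be strictly increasing")
        if not all(math.isfinite(g) for g in self.dG):
            raise ValueError("all dG must be finite")
        if not 0 <= self.reference_index < len(self.coords):
            raise ValueError("reference_index out of range")
        if abs(self.dG[self.reference_index]) > 1e-12:
            raise ValueError("reference state must have dG exactly 0")

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def from_energies(
        cls,
        coordinate_name: str,
        coords: Sequence[float],
        energies: Sequence[float],
        reference_index: int = 0,
    ) -> "Landscape1D":
        ref = energies[reference_index]
        return cls(
            coordinate_name=coordinate_name,
            coords=tuple(float(c) for c in coords),
            dG=tuple(float(e - ref) for e in energies),
            reference_index=reference_index,
        )


@dataclass(frozen=True)
class OccupancyResult:
    """Boltzmann occupancies of a landscape.

    ``open_fraction`` is the probability mass of the designated open
    state(s); ``delta_G_open`` is the free-energy difference between the two
    landscape endpoints (fully open minus fully bound), positive when the
    bound state is more stable.
    """

    probabilities: tuple[float, ...]
    open_fraction: float
    delta_G_open: float

    def __post_init__(self) -> None:
        total = sum(self.probabilities)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if not 0.0 <= self.open_fraction <= 1.0:
            raise ValueError("open_fraction outside [0, 1]")


def boltzmann_probabilities(
    landscape: Landscape1D, model: EnergyModel = DEFAULT_MODEL
) -> np.ndarray:
    g = np.asarray(landscape.dG, dtype=float)
    w = np.exp(-(g - g.min()) / model.RT)
    return w / w.sum()


def fraying_landscape(
    retained: DuplexMap,
    model: EnergyModel = DEFAULT_MODEL,
    free_end: str = "low",
) -> Landscape1D:
    """Zipper landscape for the retained duplex segment.

    ``free_end`` names the end of the cleaved strand (side A) created free by
    the cut: ``"low"`` (lower strand positions; the default layout, where the
    cut is 5' of the retained segment) or ``"high"``.  State s holds the s
    base pairs nearest the anchored end; E(0) = 0 (open reference), E(s>=1)
    = tether_init_dG + cumulative stacks from the anchor.
    """
    if len(retained) < 2:
        raise ValueError("retained segment must have at least 2 base pairs")
    stacks = segment_stacks(retained, model)  # ordered by ascending pos_a
    if free_end == "low":
        stacks = stacks[::-1]  # anchor at high-position end
    elif free_end != "high":
        raise ValueError("free_end must be 'low' or 'high'")
    L = len(retained)
    energies = [0.0]
    for s in range(1, L + 1):
        e = model.tether_init_dG + sum(stacks[: s - 1])
        energies.append(e)
    return Landscape1D.from_energies(
        "intact_bp_from_anchor", list(range(L + 1)), energies, reference_index=0
    )


def two_state_landscape(delta_G_open: float) -> Landscape1D:
    """Minimal open/bound landscape: coordinate 0 = open at +delta_G_open,
    coordinate 1 = bound at 0 (the reference)."""
    return Landscape1D(
        coordinate_name="intact_bp_from_anchor",
        coords=(0.0, 1.0),
        dG=(float(delta_G_open), 0.0),
        reference_index=1,
    )


def toehold_availability(
    landscape: Landscape1D,
    model: EnergyModel = DEFAULT_MODEL,
    open_coords: tuple[float, ...] = (0.0,),
) -> OccupancyResult:
    """Exact Boltzmann occupancy; open = coordinate value 0 by default.

    ``delta_G_open`` is read between the first (fully open) and last (fully
    bound) landscape states.
    """
    p = boltzmann_probabilities(landscape, model)
    open_set = set(open_coords)
    open_fraction = float(
        sum(pi for c, pi in zip(landscape.coords, p) if c in open_set)
    )
    delta = landscape.dG[0] - landscape.dG[-1]
    return OccupancyResult(
        probabilities=tuple(float(x) for x in p),
        open_fraction=open_fraction,
        delta_G_open=float(delta),
    )


def displacement_landscape(
    toehold_len: int,
    incumbent_len: int,
    model: EnergyModel = DEFAULT_MODEL,
    invader_stacks: Optional[Sequence[float]] = None,
    incumbent_stacks: Optional[Sequence[float]] = None,
    invader_init_dG: Optional[float] = None,
    incumbent_dissoc_credit: Optional[float] = None,
) -> Landscape1D:
    """Landscape over m = invader base pairs formed, m = 0..toehold+incumbent.

    Zippering down the toehold (m <= toehold_len) accrues invader stack
    terms after an initiation penalty at m = 1.  Each branch-migration step
    (m > toehold_len) trades one incumbent stack for one invader stack and
    passes over a plateau intermediate at coordinate m - 0.5, sitting
    ``bm_plateau_dG`` above the higher of its two neighbors.  At full
    displacement the incumbent's initiation penalty is refunded.

    Per-step stack energies default to the mean hybrid stack of the model; a
    design-specific profile can be supplied explicitly.
    """
    if toehold_len < 1 or incumbent_len < 1:
        raise ValueError("toehold_len and incumbent_len must be >= 1")
    T, I = toehold_len, incumbent_len
    n_inv_stacks = T + I - 1
    mean_hybrid = float(
        np.mean([model.dG_from_dHdS(dH, dS) for dH, dS in model.nn_hybrid.values()])
    )
    inv = (
        [mean_hybrid] * n_inv_stacks
        if invader_stacks is None
        else list(invader_stacks)
    )
    inc = (
        [mean_hybrid] * (I - 1)
        if incumbent_stacks is None
        else list(incumbent_stacks)
    )
    if len(inv) != n_inv_stacks:
        raise ValueError(f"need {n_inv_stacks} invader stacks, got {len(inv)}")
    if len(inc) != I - 1:
        raise ValueError(f"need {I - 1} incumbent stacks, got {len(inc)}")
    init = model.init_dG if invader_init_dG is None else invader_init_dG
    credit = model.init_dG if incumbent_dissoc_credit is None else incumbent_dissoc_credit

    e: dict[float, float] = {0.0: 0.0}
    for m in range(1, T + 1):
        e[float(m)] = init + sum(inv[: m - 1])
    # Branch-migration steps exchange one incumbent stack for one invader
    # stack.  The invader ends up with one more stack than the incumbent had
    # (the incumbent sat against a nick at the toehold junction); that
    # junction stack, index T-1, is realized at the commitment step together
    # with the incumbent's initiation refund.
    for j in range(1, I + 1):
        m = T + j
        prev = e[float(m - 1)]
        if j <= I - 1:
            cur = prev + inv[T + j - 1] - inc[j - 1]
        else:
            cur = prev + inv[T - 1] - credit
        e[float(m)] = cur
        e[m - 0.5] = max(prev, cur) + model.bm_plateau_dG
    coords = sorted(e)
    return Landscape1D.from_energies(
        "invader_bp_formed", coords, [e[c] for c in coords], reference_index=0
    )


def displacement_landscape_for_design(design, target_duplex: DuplexMap,
                                      model: EnergyModel = DEFAULT_MODEL) -> Landscape1D:
    """Displacement landscape using the design's actual stack energies.

    The toehold length and incumbent length come from the predicted main cut;
    invader stacks are taken from the target:gapmer duplex, incumbent stacks
    from the incumbent fragment:gapmer duplex.
    """
    from .cleavage import incumbent_duplex, predict_main_cut, retained_duplex

    result = predict_main_cut(design)
    toehold_len = result.retained_segment
    incumbent_len = result.five_prime_fragment
    # invader zips from the toehold end toward the incumbent end, i.e. from
    # high strand positions down: reverse the ascending-position stack order
    segs = target_duplex.segments()
    if len(segs) != 1:
        raise ValueError("target duplex must be a single contiguous segment")
    inv_stacks = segment_stacks(
        DuplexMap(a=target_duplex.a, b=target_duplex.b, pairs=segs[0]), model
    )
    # zippering starts at the toehold end, which sits at the high-position end
    # of the target strand under the default register: reverse the
    # ascending-position stack order before consuming
    inv_stacks = inv_stacks[::-1]
    n_needed = toehold_len + incumbent_len - 1
    if len(inv_stacks) < n_needed:
        raise ValueError("target duplex shorter than toehold + incumbent domain")
    inv_stacks = inv_stacks[:n_needed]
    inc_stacks = segment_stacks(incumbent_duplex(design), model)[::-1]
    return displacement_landscape(
        toehold_len,
        incumbent_len,
        model,
        invader_stacks=inv_stacks,
        incumbent_stacks=inc_stacks,
    )


def calibrate_increments(
    retained: DuplexMap,
    model: EnergyModel,
    target_delta_G_open: float,
    free_end: str = "low",
    tol: float = 1e-9,
    max_iter: int = 200,
) -> EnergyModel:
    """Rescale mod_increments by one factor so the fraying landscape's
    delta_G_open matches ``target_delta_G_open``.  Explicit calibration: the
    returned model is a new object; nothing is rescaled silently."""

    def delta(factor: float) -> float:
        m = model.with_scaled_increments(factor)
        ls = fraying_landscape(retained, m, free_end=free_end)
        return ls.dG[0] - ls.dG[-1]

    lo, hi = -50.0, 50.0
    dlo, dhi = delta(lo), delta(hi)
    if (dlo - target_delta_G_open) * (dhi - target_delta_G_open) > 0:
        raise ValueError("calibration target not bracketed by increment scaling")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        dmid = delta(mid)
        if abs(dmid - target_delta_G_open) < tol:
            return model.with_scaled_increments(mid)
        if (dlo - target_delta_G_open) * (dmid - target_delta_G_open) <= 0:
            hi = mid
        else:
            lo, dlo = mid, dmid
    return model.with_scaled_increments(0.5 * (lo + hi))


def delta_G_profile_report(landscape: Landscape1D) -> str:
    """TSV of (coordinate, dG); byte-stable for fixed input."""
    df = pd.DataFrame(
        {
            "coordinate": [f"{c:g}" for c in landscape.coords],
            "dG_kcal_mol": [f"{g:.6f}" for g in landscape.dG],
        }
    )
    buf = StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
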