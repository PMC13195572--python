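"""Physical-observable utilities: DLS weighting conversion and tetrahedron geometry."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SizeDistribution:
    """Binned particle-size distribution.

    ``bins`` are (diameter in nm, weight) pairs; weights are non-negative and
    sum to 1.  ``weighting`` records whether weights are scattering-intensity
    or particle-number fractions.
    """

    bins: tuple[tuple[float, float], ...]
    weighting: str = "intensity"

    def __post_init__(self) -> None:
        if self.weighting not in ("intensity", "number"):
            raise ValueError("weighting must be 'intensity' or 'number'")
        if not self.bins:
            raise ValueError("distribution has no bins")
        for d, w in self.bins:
            if d <= 0:
                raise ValueError("diameters must be positive")
            if w < 0:
                raise ValueError("weights must be non-negative")
        total = sum(w for _, w in self.bins)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, not 1")

    @classmethod
    def from_raw(
        cls, diameters, weights, weighting: str = "intensity"
    ) -> "SizeDistribution":
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights sum to zero")
        w = w / w.sum()
        return cls(
            bins=tuple((float(d), float(x)) for d, x in zip(diameters, w)),
            weighting=weighting,
        )


def intensity_to_number(dist: SizeDistribution) -> SizeDistribution:
    """Convert intensity weighting to number weighting.

    In the Rayleigh regime scattering intensity grows with the sixth power of
    particle radius (equivalently diameter), so the number weight of each bin
    is its intensity weight divided by d^6, renormalized.  Large particles
    dominate intensity-weighted distributions; this conversion removes that
    bias.
    """
    if dist.weighting != "intensity":
        raise ValueError("input distribution must be intensity-weighted")
    raw = [(d, w / d**6) for d, w in dist.bins]
    total = sum(w for _, w in raw)
    return SizeDistribution(
        bins=tuple((d, w / total) for d, w in raw), weighting="number"
    )


def number_to_intensity(dist: SizeDistribution) -> SizeDistribution:
    if dist.weighting != "number":
        raise ValueError("input distribution must be number-weighted")
    raw = [(d, w * d**6) for d, w in dist.bins]
    total = sum(w for _, w in raw)
    return SizeDistribution(
        bins=tuple((d, w / total) for d, w in raw), weighting="intensity"
    )


def tetrahedron_height(edge_bp: int, rise_nm_per_bp: float = 0.34) -> float:
    """Height of a regular tetrahedron with edges of ``edge_bp`` base pairs.

    The edge length is edge_bp x helical rise; h = edge x sqrt(2/3).  The
    helix diameter is deliberately not added (see the methods note).
    """
    if edge_bp < 1:
        raise ValueError("edge_bp must be >= 1")
    return edge_bp * rise_nm_per_bp * math.sqrt(2.0 / 3.0)
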