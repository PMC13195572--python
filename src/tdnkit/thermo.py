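"""Nearest-neighbor hybridization thermodynamics for chemically modified duplexes.

Free energies are decomposed into dinucleotide stack terms taken from the
unified DNA:DNA nearest-neighbor parameter set and an RNA:DNA hybrid set
(ΔH in kcal/mol, ΔS in cal/(mol·K)), temperature-adjusted as
ΔG(T) = ΔH − T·ΔS/1000, with a uniform per-stack monovalent-salt entropy
correction (0.368·ln[Na+] cal/(mol·K)).  Sugar modifications enter as
additive per-base-pair free-energy increments (LNA stabilizing, 2'-O-Me
mildly stabilizing), split half-and-half between the two stacks a pair
touches; phosphorothioate linkages add a small destabilizing term at their
stack.  Sign convention: more negative = more stable.

These defaults are the package's explicit parameter choice, exposed in
:class:`EnergyModel`; nothing downstream depends on their literal values
beyond orderings that hold for any physically reasonable set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .strands import DuplexMap, Nucleotide, is_watson_crick, reverse_complement

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.98720425e-3

# Unified DNA:DNA stacks, 5'->3' top-strand dinucleotide -> (dH kcal/mol, dS eu).
_DNA_NN_CORE = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}


def _complete_dna_table(core: dict) -> dict:
    """Fill all 16 dinucleotides via reverse-complement symmetry."""
    full = dict(core)
    for key, val in core.items():
        full.setdefault(reverse_complement(key), val)
    return full


DNA_NN = _complete_dna_table(_DNA_NN_CORE)

# RNA:DNA hybrid stacks keyed by the RNA-strand dinucleotide 5'->3'
# (rXY over its DNA complement): (dH kcal/mol, dS eu).
HYBRID_NN = {
    "AA": (-7.8, -21.9),
    "AC": (-5.9, -12.3),
    "AG": (-9.1, -23.5),
    "AU": (-8.3, -23.9),
    "CA": (-9.0, -26.1),
    "CC": (-9.3, -23.2),
    "CG": (-16.3, -47.1),
    "CU": (-7.0, -19.7),
    "GA": (-5.5, -13.5),
    "GC": (-8.0, -17.1),
    "GG": (-12.8, -31.9),
    "GU": (-7.8, -21.6),
    "UA": (-7.8, -23.2),
    "UC": (-8.6, -22.9),
    "UG": (-10.4, -28.4),
    "UU": (-11.5, -36.4),
}


class TableMissError(KeyError):
    """Dinucleotide absent from the selected nearest-neighbor table."""


@dataclass(frozen=True)
class EnergyModel:
    """Parameter set for duplex free-energy evaluation.

    Increments are kcal/mol per modified base pair (``mod_increments``) or per
    PS linkage (``ps_increment``); ``init_dG`` is the bimolecular duplex
    initiation penalty, ``tether_init_dG`` the entropic penalty for closing
    the first base pair of a tethered (covalently held) segment, and
    ``bm_plateau_dG`` the branch-migration intermediate plateau height used by
    the displacement landscape.
    """

    temperature: float = 310.15  # K
    salt_mM: float = 150.0  # monovalent-equivalent
    mod_increments: dict[str, float] = field(
        default_factory=lambda: {"LNA": -1.0, "OME": -0.2}
    )
    ps_increment: float = 0.1
    init_dG: float = 2.0
    tether_init_dG: float = 2.0
    bm_plateau_dG: float = 2.0
    nn_dna: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DNA_NN))
    nn_hybrid: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(HYBRID_NN)
    )

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.salt_mM <= 0:
            raise ValueError("salt_mM must be positive")

    @property
    def RT(self) -> float:
        return R_KCAL * self.temperature

    @property
    def salt_dS(self) -> float:
        """Per-stack salt entropy correction, cal/(mol·K)."""
        return 0.368 * math.log(self.salt_mM / 1000.0)

    def dG_from_dHdS(self, dH: float, dS: float) -> float:
        return dH - self.temperature * (dS + self.salt_dS) / 1000.0

    def with_scaled_increments(self, factor: float) -> "EnergyModel":
        return replace(
            self,
            mod_increments={k: v * factor for k, v in self.mod_increments.items()},
        )

    def to_json(self) -> str:
        doc = {
            "temperature": self.temperature,
            "salt_mM": self.salt_mM,
            "mod_increments": self.mod_increments,
            "ps_increment": self.ps_increment,
            "init_dG": self.init_dG,
            "tether_init_dG": self.tether_init_dG,
            "bm_plateau_dG": self.bm_plateau_dG,
            "nn_dna": {k: list(v) for k, v in sorted(self.nn_dna.items())},
            "nn_hybrid": {k: list(v) for k, v in sorted(self.nn_hybrid.items())},
        }
        return json.dumps(doc, indent=1, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "EnergyModel":
        doc = json.loads(text)
        for key in ("nn_dna", "nn_hybrid"):
            if key in doc:
                doc[key] = {k: tuple(v) for k, v in doc[key].items()}
        return cls(**doc)


DEFAULT_MODEL = EnergyModel()


def _normalize_rna_base(base: str) -> str:
    return "U" if base == "T" else base


def _normalize_dna_base(base: str) -> str:
    return "T" if base == "U" else base


def stack_dG(
    pair_i: tuple[Nucleotide, Nucleotide],
    pair_j: tuple[Nucleotide, Nucleotide],
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Free energy of the stack between two adjacent base pairs.

    ``pair_i`` and ``pair_j`` are (strand-A nucleotide, strand-B nucleotide)
    for consecutive positions i, i+1 on strand A (5'->3').  Table class is
    chosen by chemistry: any RNA sugar in the four nucleotides selects the
    RNA:DNA hybrid table keyed by the RNA-side dinucleotide; otherwise the
    DNA:DNA table keyed by the A-side dinucleotide.  Each modified nucleotide
    contributes half its per-pair increment; PS linkages on either backbone
    within the stack add ``ps_increment`` each.
    """
    ai, bi = pair_i
    aj, bj = pair_j
    for a, b in (pair_i, pair_j):
        if not is_watson_crick(a.base, b.base):
            raise ValueError(f"non-Watson-Crick pair {a.base}-{b.base}")

    nts = (ai, bi, aj, bj)
    if any(nt.sugar == "RNA" for nt in nts):
        # hybrid: key by the strand that carries RNA (A side wins ties)
        if ai.sugar == "RNA" or aj.sugar == "RNA":
            key = _normalize_rna_base(ai.base) + _normalize_rna_base(aj.base)
        else:
            # B side runs antiparallel: its 5'->3' dinucleotide is (bj, bi)
            key = _normalize_rna_base(bj.base) + _normalize_rna_base(bi.base)
        table = model.nn_hybrid
    else:
        key = _normalize_dna_base(ai.base) + _normalize_dna_base(aj.base)
        table = model.nn_dna
    if key not in table:
        raise TableMissError(key)
    dH, dS = table[key]
    dG = model.dG_from_dHdS(dH, dS)

    for nt in nts:
        dG += 0.5 * model.mod_increments.get(nt.sugar, 0.0)
    # PS linkages spanning this stack: A-side 3'-linkage of nt i, B-side
    # 3'-linkage of the pair-j nucleotide (antiparallel).
    if ai.linkage3 == "PS":
        dG += model.ps_increment
    if bj.linkage3 == "PS":
        dG += model.ps_increment
    return dG


def segment_stacks(
    duplex: DuplexMap, model: EnergyModel = DEFAULT_MODEL
) -> list[float]:
    """Stack energies along a single contiguous segment, 5'->3' on strand A."""
    segs = duplex.segments()
    if len(segs) != 1:
        raise ValueError("duplex is not a single contiguous segment")
    pairs = segs[0]
    out = []
    for (pa, pb), (qa, qb) in zip(pairs, pairs[1:]):
        out.append(
            stack_dG(
                (duplex.a.nt(pa), duplex.b.nt(pb)),
                (duplex.a.nt(qa), duplex.b.nt(qb)),
                model,
            )
        )
    return out


def duplex_dG(duplex: DuplexMap, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Initiation penalty plus the sum of stack terms over a contiguous segment."""
    if len(duplex) < 2:
        raise ValueError("duplex segment must have at least 2 base pairs")
    return model.init_dG + sum(segment_stacks(duplex, model))
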