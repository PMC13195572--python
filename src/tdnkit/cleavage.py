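"""RNase H cleavage-site prediction on DNA:RNA heteroduplexes.

RNase H hydrolyzes the RNA strand of an RNA:DNA hybrid, but not where either
strand of the local duplex carries a 2'-sugar modification (LNA or 2'-O-Me).
The model is a chemistry rule at base-pair resolution: the backbone linkage
between RNA nucleotides i and i+1 of the cleaved strand is competent iff
nucleotide i is RNA and the base pairs at both i and i+1 exist and contain no
sugar-modified nucleotide on either strand.  The main cut is the 3'-most
competent linkage — the cut immediately before the first modified base pair
toward the RNA 3' end, matching the 3'-directed cut pattern of RNase H on
gapmer substrates.

Cuts are reported as linkage indices on the cleaved strand: a cut at linkage
i (between nucleotides i and i+1) releases a 5' fragment of i nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .strands import DuplexMap, TDNDesign


class NoCutError(ValueError):
    """Duplex has no RNase H-competent linkage."""


@dataclass(frozen=True)
class CleavageResult:
    """Accounting of the predicted main cut on the cleaved strand.

    ``retained_segment`` is the part of the originally paired region 3' of
    the cut that stays hybridized and covalently continuous with the rest of
    the strand (for the nanostructure: still integrated in the framework).
    """

    strand_name: str
    competent_linkages: tuple[int, ...]
    main_cut: int
    five_prime_fragment: int
    fragment_chemistry: dict[str, int]
    retained_segment: int
    post_cleavage_strand_length: int

    def __post_init__(self) -> None:
        if self.main_cut not in self.competent_linkages:
            raise ValueError("main_cut must be one of the competent linkages")
        if self.five_prime_fragment != self.main_cut:
            raise ValueError("5' fragment length must equal the cut linkage index")

    @property
    def original_strand_length(self) -> int:
        return self.five_prime_fragment + self.post_cleavage_strand_length


def _as_cleaved_duplex(design: Union[TDNDesign, DuplexMap]) -> DuplexMap:
    """Duplex with the cleaved (RNA-containing) strand on side A."""
    if isinstance(design, TDNDesign):
        return design.heteroduplex()
    return design


def enumerate_competent_linkages(design: Union[TDNDesign, DuplexMap]) -> list[int]:
    """Linkage indices on the cleaved strand where RNase H can cut.

    Linkage i joins nucleotides i and i+1.  Competence requires (a) sugar RNA
    at nucleotide i and (b) existing base pairs at both i and i+1 with no LNA
    or 2'-O-Me nucleotide on either strand.  An RNA-free duplex yields an
    empty list, not an error.
    """
    duplex = _as_cleaved_duplex(design)
    strand = duplex.a
    paired = {pa: pb for pa, pb in duplex.pairs}
    out = []
    for i in range(1, len(strand)):
        if strand.nt(i).sugar != "RNA":
            continue
        if i not in paired or (i + 1) not in paired:
            continue
        nts = [strand.nt(i), strand.nt(i + 1), duplex.b.nt(paired[i]), duplex.b.nt(paired[i + 1])]
        if any(nt.is_modified for nt in nts):
            continue
        out.append(i)
    return out


def predict_main_cut(design: Union[TDNDesign, DuplexMap]) -> CleavageResult:
    """Predict the main cut (3'-most competent linkage) and account fragments."""
    duplex = _as_cleaved_duplex(design)
    competent = enumerate_competent_linkages(duplex)
    if not competent:
        raise NoCutError(
            f"no RNase H-competent linkage on strand {duplex.a.name!r}"
        )
    main = max(competent)
    strand = duplex.a
    paired_positions = sorted(pa for pa, _ in duplex.pairs)
    paired_len = len(paired_positions)
    frag_chem: dict[str, int] = {}
    for p in range(1, main + 1):
        s = strand.nt(p).sugar
        frag_chem[s] = frag_chem.get(s, 0) + 1
    return CleavageResult(
        strand_name=strand.name,
        competent_linkages=tuple(competent),
        main_cut=main,
        five_prime_fragment=main,
        fragment_chemistry=frag_chem,
        retained_segment=paired_len - main,
        post_cleavage_strand_length=len(strand) - main,
    )


def post_cleavage_length_range(
    design: Union[TDNDesign, DuplexMap]
) -> tuple[int, int]:
    """(min, max) length of the covalent remainder over all competent cuts.

    The minimum corresponds to the 3'-most cut (largest released fragment),
    the maximum to the 5'-most cut.
    """
    duplex = _as_cleaved_duplex(design)
    competent = enumerate_competent_linkages(duplex)
    if not competent:
        raise NoCutError(
            f"no RNase H-competent linkage on strand {duplex.a.name!r}"
        )
    n = len(duplex.a)
    return n - max(competent), n - min(competent)


def cleave_target_duplex(target_duplex: DuplexMap) -> CleavageResult:
    """Apply the cleavage rule with the (all-RNA) target strand as side A.

    Used by the catalytic cycle: after the target has displaced the incumbent
    fragment it sits on the gapmer as a fresh RNA:DNA hybrid and is cleaved
    by the same rule.  A fully modified steric-blocker complement yields
    :class:`NoCutError`.
    """
    if any(nt.sugar != "RNA" for nt in target_duplex.a.nts):
        raise NoCutError(
            f"target strand {target_duplex.a.name!r} is not all-RNA"
        )
    return predict_main_cut(target_duplex)


def retained_duplex(design: Union[TDNDesign, DuplexMap]) -> DuplexMap:
    """The still-hybridized duplex 3' of the main cut on the cleaved strand.

    For the default nanostructure layout this is the 7-bp segment whose
    fraying exposes the toehold; its anchored end is the high-position end of
    the cleaved strand (covalently continuous with the framework).
    """
    duplex = _as_cleaved_duplex(design)
    result = predict_main_cut(duplex)
    pairs = tuple(
        (pa, pb) for pa, pb in sorted(duplex.pairs) if pa > result.main_cut
    )
    return DuplexMap(a=duplex.a, b=duplex.b, pairs=pairs)


def incumbent_duplex(design: Union[TDNDesign, DuplexMap]) -> DuplexMap:
    """The duplex held by the released 5' fragment (the incumbent) before
    displacement: pairs at positions <= main cut on the cleaved strand."""
    duplex = _as_cleaved_duplex(design)
    result = predict_main_cut(duplex)
    pairs = tuple(
        (pa, pb) for pa, pb in sorted(duplex.pairs) if pa <= result.main_cut
    )
    return DuplexMap(a=duplex.a, b=duplex.b, pairs=pairs)
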