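"""Chemically annotated oligonucleotide strands, duplex pairing, and the
tetrahedral-nanostructure (TDN) design container.

A strand is an ordered list of nucleotides, each carrying a base, a sugar
chemistry (unmodified DNA, RNA, locked nucleic acid LNA, or 2'-O-methyl OME)
and the backbone linkage on its 3' side (phosphodiester PO or
phosphorothioate PS).  Positions are 1-based and inclusive throughout, with
position 1 at the 5' end; ranges are closed intervals.

A gapmer is an antisense strand with a central block of unmodified DNA (the
RNase H-competent "gap") flanked by symmetric wings of modified sugars.  The
tetrahedron is the classic four-strand design: six duplex edges, each strand
traversing three edges with short unpaired hinges at the vertices it turns
through.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

BASES = frozenset("ACGTUN")  # N = placeholder base, never valid in a pair
SUGARS = ("DNA", "RNA", "LNA", "OME")
LINKAGES = ("PO", "PS")
MODIFIED_SUGARS = frozenset({"LNA", "OME"})

#: Watson-Crick partners; T-A and U-A only, no G-U wobble.
WC_PARTNERS = {
    "A": frozenset("TU"),
    "T": frozenset("A"),
    "U": frozenset("A"),
    "G": frozenset("C"),
    "C": frozenset("G"),
    "N": frozenset(),
}

_DNA_COMPLEMENT = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}


class StrandError(ValueError):
    """Invalid strand, scheme, or pairing input."""


class MismatchError(StrandError):
    """Attempted pairing contains non-Watson-Crick positions."""

    def __init__(self, positions: list[tuple[int, int]]):
        self.positions = positions
        super().__init__(f"non-complementary base pairs at positions {positions}")


class InvalidSchemeError(StrandError):
    """Gapmer scheme violates its own constraints."""


def is_watson_crick(base_a: str, base_b: str) -> bool:
    return base_b in WC_PARTNERS.get(base_a, frozenset())


def complement_base(base: str, *, as_rna: bool = False) -> str:
    comp = _DNA_COMPLEMENT[base]
    return "U" if (as_rna and comp == "T") else comp


def reverse_complement(seq: str, *, as_rna: bool = False) -> str:
    return "".join(complement_base(b, as_rna=as_rna) for b in reversed(seq))


@dataclass(frozen=True)
class Nucleotide:
    """One residue: base, sugar chemistry, and 3'-side backbone linkage.

    ``linkage3`` is None for the 3'-terminal nucleotide of a strand.
    """

    base: str
    sugar: str = "DNA"
    linkage3: Optional[str] = "PO"

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise StrandError(f"unknown base {self.base!r}")
        if self.sugar not in SUGARS:
            raise StrandError(f"unknown sugar {self.sugar!r}")
        if self.linkage3 is not None and self.linkage3 not in LINKAGES:
            raise StrandError(f"unknown linkage {self.linkage3!r}")
        if self.base == "U" and self.sugar == "DNA":
            raise StrandError("uracil on an unmodified DNA sugar is not allowed")

    @property
    def is_modified(self) -> bool:
        """True for sugar modifications that block RNase H (LNA, 2'-O-Me)."""
        return self.sugar in MODIFIED_SUGARS


@dataclass(frozen=True)
class ModifiedStrand:
    """Named strand of nucleotides with optional named loci.

    ``loci`` maps a name (e.g. ``"gapmer"``, ``"rna_block"``) to a closed
    1-based range ``(start, end)``.  Loci must lie within the strand and must
    not overlap each other.
    """

    name: str
    nts: tuple[Nucleotide, ...]
    loci: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.nts) < 1:
            raise StrandError(f"strand {self.name!r} is empty")
        object.__setattr__(self, "nts", tuple(self.nts))
        occupied: set[int] = set()
        for lname, (start, end) in self.loci.items():
            if not (1 <= start <= end <= len(self.nts)):
                raise StrandError(
                    f"locus {lname!r} range ({start},{end}) outside strand "
                    f"{self.name!r} of length {len(self.nts)}"
                )
            span = set(range(start, end + 1))
            if span & occupied:
                raise StrandError(f"locus {lname!r} overlaps another locus")
            occupied |= span

    def __len__(self) -> int:
        return len(self.nts)

    def nt(self, pos: int) -> Nucleotide:
        """Nucleotide at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.nts):
            raise StrandError(f"position {pos} outside strand {self.name!r}")
        return self.nts[pos - 1]

    @property
    def sequence(self) -> str:
        return "".join(nt.base for nt in self.nts)

    @property
    def sugars(self) -> tuple[str, ...]:
        return tuple(nt.sugar for nt in self.nts)

    @property
    def linkages(self) -> tuple[str, ...]:
        """The len-1 internal linkages, 5' to 3'."""
        return tuple(nt.linkage3 or "PO" for nt in self.nts[:-1])

    def longest_sugar_run(self, sugar: str) -> int:
        """Length of the maximal run of consecutive nucleotides with ``sugar``."""
        best = cur = 0
        for nt in self.nts:
            cur = cur + 1 if nt.sugar == sugar else 0
            best = max(best, cur)
        return best


@dataclass(frozen=True)
class GapmerScheme:
    """Chemistry layout of a gapmer: symmetric modified wings around a DNA gap.

    ``wing`` is the sugar pattern applied from each end inward (the 3' wing is
    the mirror image), e.g. ``("LNA",)*4 + ("OME",)*2``.  ``ps_per_end``
    phosphorothioate linkages are placed at each end (all linkages if
    ``fully_ps``).  A fully modified steric-blocker pattern is a wing covering
    half the strand from each side (empty central block).
    """

    total_length: int
    wing: tuple[str, ...] = ()
    ps_per_end: int = 0
    fully_ps: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "wing", tuple(self.wing))
        if self.total_length < 1:
            raise InvalidSchemeError("total_length must be >= 1")
        for s in self.wing:
            if s not in SUGARS:
                raise InvalidSchemeError(f"unknown wing sugar {s!r}")
        if 2 * len(self.wing) > self.total_length:
            raise InvalidSchemeError(
                f"wing of {len(self.wing)} nt longer than half of "
                f"{self.total_length}-nt gapmer"
            )
        if self.ps_per_end < 0 or 2 * self.ps_per_end > self.total_length - 1:
            raise InvalidSchemeError("ps_per_end exceeds available linkages")

    @property
    def central_length(self) -> int:
        return self.total_length - 2 * len(self.wing)

    def sugar_pattern(self) -> tuple[str, ...]:
        central = ("DNA",) * self.central_length
        return self.wing + central + tuple(reversed(self.wing))


#: Gapmer-B layout: 20 nt, 4 LNA + 2 OME wings, 8-nt DNA gap, 3 PS per end.
GAPMER_B_SCHEME = GapmerScheme(
    total_length=20, wing=("LNA",) * 4 + ("OME",) * 2, ps_per_end=3
)

#: Fully 2'-O-Me steric-blocker control: no DNA gap, 3 PS per end.
STERIC_BLOCKER_SCHEME = GapmerScheme(
    total_length=20, wing=("OME",) * 10, ps_per_end=3
)


def _harmonize_base(base: str, sugar: str) -> str:
    """Apply base-identity conventions: ribose-like sugars carry U, DNA/LNA carry T."""
    if sugar in ("RNA", "OME") and base == "T":
        return "U"
    if sugar in ("DNA", "LNA") and base == "U":
        return "T"
    return base


def build_gapmer_pattern(
    scheme: GapmerScheme,
    seed_sequence: Optional[str] = None,
    name: str = "gapmer",
) -> ModifiedStrand:
    """Build a gapmer strand from a chemistry scheme.

    If ``seed_sequence`` is absent, bases are 'N' placeholders to be filled by
    the design generator.  Base identity is harmonized to the sugar (T on
    DNA/LNA, U on RNA/2'-O-Me).
    """
    sugars = scheme.sugar_pattern()
    if seed_sequence is None:
        bases: Sequence[str] = "N" * scheme.total_length
    else:
        if len(seed_sequence) != scheme.total_length:
            raise InvalidSchemeError(
                f"seed sequence length {len(seed_sequence)} != "
                f"scheme total_length {scheme.total_length}"
            )
        bases = seed_sequence.upper()

    n = scheme.total_length
    ps = set()
    if scheme.fully_ps:
        ps = set(range(1, n))  # linkage i joins nt i and i+1
    else:
        ps = set(range(1, scheme.ps_per_end + 1)) | set(
            range(n - scheme.ps_per_end, n)
        )
    nts = []
    for i in range(1, n + 1):
        base = bases[i - 1]
        if base != "N":
            base = _harmonize_base(base, sugars[i - 1])
        link = None if i == n else ("PS" if i in ps else "PO")
        nts.append(Nucleotide(base=base, sugar=sugars[i - 1], linkage3=link))
    loci = {}
    if scheme.central_length > 0:
        loci["gap"] = (len(scheme.wing) + 1, len(scheme.wing) + scheme.central_length)
    return ModifiedStrand(name=name, nts=tuple(nts), loci=loci)


@dataclass(frozen=True)
class DuplexMap:
    """Antiparallel base pairing between ranges of two strands.

    ``pairs`` lists ``(pos_a, pos_b)`` (1-based, on strands ``a`` and ``b``);
    within one contiguous segment pos_a increases while pos_b decreases.
    """

    a: ModifiedStrand
    b: ModifiedStrand
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        seen_a: set[int] = set()
        seen_b: set[int] = set()
        for pa, pb in self.pairs:
            if pa in seen_a or pb in seen_b:
                raise StrandError("position paired more than once")
            seen_a.add(pa)
            seen_b.add(pb)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_set(self) -> frozenset[tuple[str, int, str, int]]:
        """Role-symmetric pair set (strand name, pos, strand name, pos)."""
        out = set()
        for pa, pb in self.pairs:
            key = tuple(sorted([(self.a.name, pa), (self.b.name, pb)]))
            out.add((key[0][0], key[0][1], key[1][0], key[1][1]))
        return frozenset(out)

    def partner_of_a(self, pos_a: int) -> Optional[int]:
        for pa, pb in self.pairs:
            if pa == pos_a:
                return pb
        return None

    def nts_at(self, pair: tuple[int, int]) -> tuple[Nucleotide, Nucleotide]:
        pa, pb = pair
        return self.a.nt(pa), self.b.nt(pb)

    def segments(self) -> list[tuple[tuple[int, int], ...]]:
        """Maximal contiguous antiparallel runs, ordered by pos_a."""
        ordered = sorted(self.pairs)
        segs: list[list[tuple[int, int]]] = []
        for pa, pb in ordered:
            if segs and segs[-1][-1] == (pa - 1, pb + 1):
                segs[-1].append((pa, pb))
            else:
                segs.append([(pa, pb)])
        return [tuple(s) for s in segs]

    def swapped(self) -> "DuplexMap":
        return DuplexMap(
            a=self.b, b=self.a, pairs=tuple((pb, pa) for pa, pb in self.pairs)
        )


def pair_strands(
    strand_a: ModifiedStrand,
    range_a: tuple[int, int],
    strand_b: ModifiedStrand,
    range_b: tuple[int, int],
) -> DuplexMap:
    """Pair two equal-length closed ranges antiparallel and Watson-Crick check.

    Position ``start_a + i`` of strand A pairs ``end_b - i`` of strand B.
    Raises :class:`MismatchError` listing every non-complementary position
    pair.
    """
    sa, ea = range_a
    sb, eb = range_b
    if ea - sa != eb - sb:
        raise StrandError(f"ranges {range_a} and {range_b} differ in length")
    pairs = []
    bad = []
    for i in range(ea - sa + 1):
        pa, pb = sa + i, eb - i
        if not is_watson_crick(strand_a.nt(pa).base, strand_b.nt(pb).base):
            bad.append((pa, pb))
        pairs.append((pa, pb))
    if bad:
        raise MismatchError(bad)
    return DuplexMap(a=strand_a, b=strand_b, pairs=tuple(pairs))


@dataclass(frozen=True)
class TDNDesign:
    """Four strands, six duplex edges, hinges, and the gapmer/RNA loci.

    ``gapmer_edge`` indexes into ``edges``; on that edge, strand
    ``gapmer_strand`` carries the ``"gapmer"`` locus and ``rna_strand``
    carries the ``"rna_block"`` locus paired to it (the DNA:RNA
    heteroduplex).
    """

    strands: dict[str, ModifiedStrand]
    edges: tuple[DuplexMap, ...]
    hinges: dict[str, tuple[tuple[int, int], ...]]
    gapmer_edge: int
    gapmer_strand: str
    rna_strand: str

    def heteroduplex(self) -> DuplexMap:
        """The gapmer edge oriented with the RNA-containing strand as side A."""
        edge = self.edges[self.gapmer_edge]
        if edge.a.name == self.rna_strand:
            return edge
        if edge.b.name == self.rna_strand:
            return edge.swapped()
        raise StrandError("gapmer edge does not involve the RNA-containing strand")


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[ValidationCheck, ...]
    strand_lengths: dict[str, int]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]


def validate_design(design: TDNDesign) -> ValidationReport:
    """Independent per-pair re-check of a design.

    Checks per-edge Watson-Crick complementarity (base by base, independent of
    how the edges were built), gapmer integrity (contiguous locus inside a
    single strand and a single edge segment), and the heteroduplex annotation
    (every rna_block position paired to a gapmer-locus position).  Failures
    are reported, never raised.
    """
    checks: list[ValidationCheck] = []

    checks.append(
        ValidationCheck(
            "strand_count", len(design.strands) == 4, f"{len(design.strands)} strands"
        )
    )
    checks.append(
        ValidationCheck("edge_count", len(design.edges) == 6, f"{len(design.edges)} edges")
    )

    for i, edge in enumerate(design.edges):
        bad = [
            (pa, pb)
            for pa, pb in edge.pairs
            if not is_watson_crick(edge.a.nt(pa).base, edge.b.nt(pb).base)
        ]
        checks.append(
            ValidationCheck(
                f"edge_{i}_complementarity",
                not bad,
                "" if not bad else f"mismatches at {bad[:5]}",
            )
        )

    # gapmer integrity: contiguous locus fully covered by one edge segment
    gs = design.strands.get(design.gapmer_strand)
    ok = gs is not None and "gapmer" in gs.loci
    detail = ""
    if ok:
        start, end = gs.loci["gapmer"]
        edge = design.edges[design.gapmer_edge]
        side_positions: set[int] = set()
        for seg in edge.segments():
            if edge.a.name == design.gapmer_strand:
                side_positions.update(pa for pa, _ in seg)
            if edge.b.name == design.gapmer_strand:
                side_positions.update(pb for _, pb in seg)
        missing = [p for p in range(start, end + 1) if p not in side_positions]
        ok = not missing
        detail = "" if ok else f"gapmer positions unpaired on its edge: {missing[:5]}"
    else:
        detail = "gapmer locus missing"
    checks.append(ValidationCheck("gapmer_integrity", bool(ok), detail))

    # heteroduplex annotation: rna_block paired to gapmer-locus positions
    rs = design.strands.get(design.rna_strand)
    ok = rs is not None and "rna_block" in rs.loci and gs is not None and "gapmer" in gs.loci
    detail = ""
    if ok:
        rstart, rend = rs.loci["rna_block"]
        gstart, gend = gs.loci["gapmer"]
        het = design.heteroduplex()
        bad_pos = []
        for p in range(rstart, rend + 1):
            q = het.partner_of_a(p)
            if q is None or not (gstart <= q <= gend):
                bad_pos.append(p)
            elif rs.nt(p).sugar != "RNA":
                bad_pos.append(p)
        ok = not bad_pos
        detail = "" if ok else f"rna_block positions not RNA-paired-to-gapmer: {bad_pos[:5]}"
    else:
        detail = "rna_block or gapmer locus missing"
    checks.append(ValidationCheck("heteroduplex_annotation", bool(ok), detail))

    return ValidationReport(
        checks=tuple(checks),
        strand_lengths={name: len(s) for name, s in design.strands.items()},
    )
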