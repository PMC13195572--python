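"""Constraint-satisfying synthetic TDN designs and target strands.

The generator emulates the published layout of the gapmer-bearing
tetrahedron without its (unpublished) sequences: four strands, six 20-bp
duplex edges, 2-nt unpaired hinges at the two interior vertex passages of
each strand (strand length 3x20 + 2x2 = 64 nt), a 20-nt gapmer locus at the
5' end of strand S1, and on the partner strand S4 a 10-nt RNA block starting
at position 7 followed by 6 nt of unmodified DNA, so the S4:gapmer edge is
the DNA:RNA heteroduplex.  Sequences are random under GC-content bounds and
a crosstalk screen that rejects unintended complementary runs.

The cleavage arithmetic of the default layout (13-nt main fragment, 7-nt
retained segment, 51-57 nt covalent remainder) depends only on this layout,
never on the drawn sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .strands import (
    GAPMER_B_SCHEME,
    GapmerScheme,
    ModifiedStrand,
    Nucleotide,
    TDNDesign,
    _harmonize_base,
    complement_base,
    pair_strands,
    reverse_complement,
    validate_design,
)

STRAND_NAMES = ("S1", "S2", "S3", "S4")

# Each strand traverses three edges; every unordered strand pair shares
# exactly one edge.  (strand, segment-slot) assignments per edge; slot 0 is
# the 5'-most segment.  Edge 0 is the gapmer/heteroduplex edge S1:S4.
_EDGE_PLAN = (
    (("S1", 0), ("S4", 0)),
    (("S1", 1), ("S2", 0)),
    (("S1", 2), ("S3", 0)),
    (("S2", 1), ("S3", 1)),
    (("S2", 2), ("S4", 1)),
    (("S3", 2), ("S4", 2)),
)


class GenerationError(RuntimeError):
    """Constraint satisfaction failed after bounded retries."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for design generation.

    ``rna_block`` is (start, length) on the RNA-containing strand (S4);
    ``flank_dna_nt`` unmodified DNA nucleotides continue the heteroduplex 3'
    of the RNA block.  ``crosstalk_k`` is the maximum tolerated unintended
    complementary run between non-partner segments.
    """

    seed: int = 1
    edge_bp: int = 20
    hinge_nt: int = 2
    gapmer_scheme: GapmerScheme = field(default_factory=lambda: GAPMER_B_SCHEME)
    rna_block: tuple[int, int] = (7, 10)
    flank_dna_nt: int = 6
    gc_bounds: tuple[float, float] = (0.3, 0.7)
    crosstalk_k: int = 8
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.edge_bp < 1 or self.hinge_nt < 0:
            raise ValueError("edge_bp must be >= 1 and hinge_nt >= 0")
        if self.gapmer_scheme.total_length != self.edge_bp:
            raise ValueError("gapmer must span exactly one edge")
        start, length = self.rna_block
        if not (1 <= start and start + length - 1 <= self.edge_bp):
            raise ValueError("rna_block must lie inside the gapmer-paired segment")
        if self.crosstalk_k < 4:
            raise ValueError("crosstalk_k must be >= 4")

    @property
    def strand_length(self) -> int:
        return 3 * self.edge_bp + 2 * self.hinge_nt

    def segment_range(self, slot: int) -> tuple[int, int]:
        start = 1 + slot * (self.edge_bp + self.hinge_nt)
        return start, start + self.edge_bp - 1

    def hinge_ranges(self) -> tuple[tuple[int, int], ...]:
        if self.hinge_nt == 0:
            return ()
        out = []
        for slot in (0, 1):
            _, end = self.segment_range(slot)
            out.append((end + 1, end + self.hinge_nt))
        return tuple(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _gc_fraction(seq: str) -> float:
    return sum(1 for b in seq if b in "GC") / len(seq)


def _find_complementary_runs(seq_a: str, seq_b: str, k: int):
    """All antiparallel Watson-Crick runs of length >= k between two DNA-
    normalized sequences, as lists of 1-based (pos_a, pos_b) pairs."""
    rc_b = reverse_complement(seq_b)
    la, lb = len(seq_a), len(seq_b)
    runs = []
    # common substrings of seq_a and reverse_complement(seq_b)
    for diag in range(-(lb - 1), la):
        i = max(0, diag)
        j = i - diag
        run_start = None
        while i < la and j < lb:
            if seq_a[i] == rc_b[j]:
                if run_start is None:
                    run_start = (i, j)
            else:
                if run_start is not None:
                    length = i - run_start[0]
                    if length >= k:
                        runs.append((run_start, length))
                    run_start = None
            i += 1
            j += 1
        if run_start is not None:
            length = i - run_start[0]
            if length >= k:
                runs.append((run_start, length))
    out = []
    for (i0, j0), length in runs:
        pairs = [(i0 + t + 1, lb - (j0 + t)) for t in range(length)]
        out.append(pairs)
    return out


def crosstalk_screen(
    strands: dict[str, ModifiedStrand],
    k: int,
    intended: Optional[set[tuple[str, int, str, int]]] = None,
) -> list[dict]:
    """Unintended antiparallel complementary runs >= k between any two strands
    (including a strand against itself).

    ``intended`` holds role-symmetric (name, pos, name, pos) tuples of
    designed pairs; runs made entirely of intended pairs are ignored.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    intended = intended or set()
    names = sorted(strands)
    report = []
    for i, na in enumerate(names):
        for nb in names[i:]:
            sa = strands[na].sequence.replace("U", "T")
            sb = strands[nb].sequence.replace("U", "T")
            for pairs in _find_complementary_runs(sa, sb, k):
                keys = {
                    tuple(
                        x
                        for pair in sorted([(na, pa), (nb, pb)])
                        for x in pair
                    )
                    for pa, pb in pairs
                }
                if keys <= intended:
                    continue
                if na == nb and all(pa >= pb for pa, pb in pairs):
                    continue  # mirror image of an already-reported self run
                report.append(
                    {
                        "strand_a": na,
                        "strand_b": nb,
                        "start_a": pairs[0][0],
                        "start_b": pairs[0][1],
                        "length": len(pairs),
                    }
                )
    return report


def _intended_pairs(design: TDNDesign) -> set[tuple[str, int, str, int]]:
    out: set[tuple[str, int, str, int]] = set()
    for edge in design.edges:
        out |= edge.pair_set
    return out


def _attempt_design(spec: GeneratorSpec, rng: np.random.Generator) -> TDNDesign:
    E, H = spec.edge_bp, spec.hinge_nt
    lo, hi = spec.gc_bounds

    def draw_edge_seq() -> str:
        for _ in range(200):
            s = _random_seq(rng, E)
            if lo <= _gc_fraction(s) <= hi:
                return s
        raise GenerationError(
            f"gc_bounds {spec.gc_bounds} unsatisfiable for edge of {E} nt"
        )

    edge_seqs = [draw_edge_seq() for _ in range(len(_EDGE_PLAN))]
    segments: dict[tuple[str, int], str] = {}
    for edge_idx, ((sa, slot_a), (sb, slot_b)) in enumerate(_EDGE_PLAN):
        seq = edge_seqs[edge_idx]
        segments[(sa, slot_a)] = seq
        segments[(sb, slot_b)] = reverse_complement(seq)

    hinge_seqs = {
        (name, h): _random_seq(rng, H) for name in STRAND_NAMES for h in (0, 1)
    }

    rna_start, rna_len = spec.rna_block
    strands: dict[str, ModifiedStrand] = {}
    for name in STRAND_NAMES:
        seq = ""
        for slot in range(3):
            seq += segments[(name, slot)]
            if slot < 2:
                seq += hinge_seqs[(name, slot)]
        sugars = ["DNA"] * len(seq)
        loci: dict[str, tuple[int, int]] = {}
        if name == "S1":
            pattern = spec.gapmer_scheme.sugar_pattern()
            sugars[:E] = list(pattern)
            loci["gapmer"] = (1, E)
        if name == "S4":
            for p in range(rna_start, rna_start + rna_len):
                sugars[p - 1] = "RNA"
            loci["rna_block"] = (rna_start, rna_start + rna_len - 1)
            flank_end = min(rna_start + rna_len - 1 + spec.flank_dna_nt, len(seq))
            if flank_end >= rna_start + rna_len:
                loci["dna_flank"] = (rna_start + rna_len, flank_end)
        nts = []
        n = len(seq)
        ps_linkages: set[int] = set()
        if name == "S1":
            npe = spec.gapmer_scheme.ps_per_end
            if spec.gapmer_scheme.fully_ps:
                ps_linkages = set(range(1, E))
            else:
                ps_linkages = set(range(1, npe + 1)) | set(range(E - npe, E))
        for i in range(1, n + 1):
            base = _harmonize_base(seq[i - 1], sugars[i - 1])
            link = None if i == n else ("PS" if i in ps_linkages else "PO")
            nts.append(Nucleotide(base=base, sugar=sugars[i - 1], linkage3=link))
        strands[name] = ModifiedStrand(name=name, nts=tuple(nts), loci=loci)

    edges = []
    for (sa, slot_a), (sb, slot_b) in _EDGE_PLAN:
        edges.append(
            pair_strands(
                strands[sa],
                spec.segment_range(slot_a),
                strands[sb],
                spec.segment_range(slot_b),
            )
        )
    hinges = {name: spec.hinge_ranges() for name in STRAND_NAMES}
    return TDNDesign(
        strands=strands,
        edges=tuple(edges),
        hinges=hinges,
        gapmer_edge=0,
        gapmer_strand="S1",
        rna_strand="S4",
    )


def generate_design(spec: GeneratorSpec = GeneratorSpec()) -> TDNDesign:
    """Generate a complete design satisfying all constraints.

    Retries (up to ``spec.max_retries``) until the crosstalk screen is empty
    at ``crosstalk_k`` and independent validation passes; raises
    :class:`GenerationError` naming the violated constraint otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    last_violation = "no attempt made"
    for _ in range(spec.max_retries):
        try:
            design = _attempt_design(spec, rng)
        except GenerationError as exc:
            raise GenerationError(str(exc)) from None
        report = validate_design(design)
        if not report.passed:
            last_violation = "; ".join(c.name for c in report.failures())
            continue
        xtalk = crosstalk_screen(
            design.strands, spec.crosstalk_k, intended=_intended_pairs(design)
        )
        if xtalk:
            last_violation = (
                f"crosstalk runs >= {spec.crosstalk_k}: "
                f"{[(r['strand_a'], r['strand_b'], r['length']) for r in xtalk[:3]]}"
            )
            continue
        return design
    raise GenerationError(
        f"no valid design in {spec.max_retries} attempts; last violation: {last_violation}"
    )


def generate_target(
    spec: GeneratorSpec, design: TDNDesign, name: str = "miR_target"
) -> ModifiedStrand:
    """22-nt all-RNA target fully complementary to the 20-nt gapmer.

    Under the declared register the target carries a 2-nt overhang at its 5'
    end: target positions 3..22 pair gapmer positions 20..1.
    """
    gs = design.strands[design.gapmer_strand]
    gstart, gend = gs.loci["gapmer"]
    gseq = gs.sequence[gstart - 1 : gend].replace("U", "T")
    rng = np.random.default_rng(spec.seed + 7919)
    overhang = _random_seq(rng, 2).replace("T", "U")
    core = reverse_complement(gseq, as_rna=True)
    seq = overhang + core
    nts = []
    for i, base in enumerate(seq):
        link = None if i == len(seq) - 1 else "PO"
        nts.append(Nucleotide(base=base, sugar="RNA", linkage3=link))
    return ModifiedStrand(name=name, nts=tuple(nts), loci={"gapmer_complement": (3, 22)})


def target_gapmer_duplex(design: TDNDesign, target: ModifiedStrand):
    """Pair the target onto the gapmer under the declared register (target as
    side A, the cleaved strand of the catalytic step)."""
    gs = design.strands[design.gapmer_strand]
    gstart, gend = gs.loci["gapmer"]
    start_a, end_a = target.loci.get("gapmer_complement", (3, len(target)))
    return pair_strands(target, (start_a, end_a), gs, (gstart, gend))
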