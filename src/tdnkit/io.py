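"""Annotated-FASTA and design-JSON serialization.

Bases travel in a standard FASTA file; chemistry travels in a sidecar file
holding, per record, a sugar line over {D,R,L,M} (aligned to the sequence)
and a linkage line over {o,s} (length = sequence length - 1).  The design
JSON is a single versioned document with strands, loci, edges and hinges.
Writers are byte-stable for fixed input.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path
from typing import Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .strands import (
    DuplexMap,
    ModifiedStrand,
    Nucleotide,
    StrandError,
    TDNDesign,
)

SCHEMA_VERSION = "1"

_SUGAR_TO_CODE = {"DNA": "D", "RNA": "R", "LNA": "L", "OME": "M"}
_CODE_TO_SUGAR = {v: k for k, v in _SUGAR_TO_CODE.items()}
_LINK_TO_CODE = {"PO": "o", "PS": "s"}
_CODE_TO_LINK = {v: k for k, v in _LINK_TO_CODE.items()}


def sugar_string(strand: ModifiedStrand) -> str:
    return "".join(_SUGAR_TO_CODE[nt.sugar] for nt in strand.nts)


def linkage_string(strand: ModifiedStrand) -> str:
    return "".join(_LINK_TO_CODE[l] for l in strand.linkages)


def write_annotated_fasta(
    strands: list[ModifiedStrand],
    fasta_path: Union[str, Path],
    chem_path: Union[str, Path],
) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.name, description="") for s in strands
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    lines = []
    for s in strands:
        lines.append(f">{s.name}")
        lines.append(sugar_string(s))
        lines.append(linkage_string(s))
    Path(chem_path).write_text("\n".join(lines) + "\n")


def read_annotated_fasta(
    fasta_path: Union[str, Path], chem_path: Union[str, Path]
) -> list[ModifiedStrand]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    chem: dict[str, tuple[str, str]] = {}
    lines = Path(chem_path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StrandError(f"chemistry sidecar: expected header at line {i + 1}")
        name = lines[i][1:].strip()
        if i + 2 >= len(lines):
            raise StrandError(f"chemistry sidecar: truncated record {name!r}")
        chem[name] = (lines[i + 1].strip(), lines[i + 2].strip())
        i += 3
    strands = []
    for name, seq in seqs.items():
        if name not in chem:
            raise StrandError(f"no chemistry record for {name!r}")
        sugars, links = chem[name]
        if len(sugars) != len(seq):
            raise StrandError(
                f"{name!r}: sugar line length {len(sugars)} != sequence length {len(seq)}"
            )
        if len(links) != len(seq) - 1:
            raise StrandError(
                f"{name!r}: linkage line length {len(links)} != sequence length - 1"
            )
        nts = []
        for k, base in enumerate(seq):
            link = None if k == len(seq) - 1 else _CODE_TO_LINK[links[k]]
            nts.append(
                Nucleotide(base=base, sugar=_CODE_TO_SUGAR[sugars[k]], linkage3=link)
            )
        strands.append(ModifiedStrand(name=name, nts=tuple(nts)))
    return strands


def _strand_to_dict(s: ModifiedStrand) -> dict:
    return {
        "name": s.name,
        "sequence": s.sequence,
        "sugars": sugar_string(s),
        "linkages": linkage_string(s),
        "loci": {k: list(v) for k, v in sorted(s.loci.items())},
    }


def _strand_from_dict(d: dict) -> ModifiedStrand:
    seq, sugars, links = d["sequence"], d["sugars"], d["linkages"]
    nts = []
    for k, base in enumerate(seq):
        link = None if k == len(seq) - 1 else _CODE_TO_LINK[links[k]]
        nts.append(Nucleotide(base=base, sugar=_CODE_TO_SUGAR[sugars[k]], linkage3=link))
    return ModifiedStrand(
        name=d["name"],
        nts=tuple(nts),
        loci={k: tuple(v) for k, v in d.get("loci", {}).items()},
    )


def design_to_json(design: TDNDesign) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "strands": [_strand_to_dict(design.strands[k]) for k in sorted(design.strands)],
        "edges": [
            {"a": e.a.name, "b": e.b.name, "pairs": [list(p) for p in e.pairs]}
            for e in design.edges
        ],
        "hinges": {k: [list(h) for h in v] for k, v in sorted(design.hinges.items())},
        "gapmer_edge": design.gapmer_edge,
        "gapmer_strand": design.gapmer_strand,
        "rna_strand": design.rna_strand,
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def design_from_json(text: str) -> TDNDesign:
    doc = json.loads(text)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise StrandError(f"unsupported design schema {doc.get('schema_version')!r}")
    strands = {d["name"]: _strand_from_dict(d) for d in doc["strands"]}
    edges = tuple(
        DuplexMap(
            a=strands[e["a"]],
            b=strands[e["b"]],
            pairs=tuple(tuple(p) for p in e["pairs"]),
        )
        for e in doc["edges"]
    )
    return TDNDesign(
        strands=strands,
        edges=edges,
        hinges={k: tuple(tuple(h) for h in v) for k, v in doc["hinges"].items()},
        gapmer_edge=doc["gapmer_edge"],
        gapmer_strand=doc["gapmer_strand"],
        rna_strand=doc["rna_strand"],
    )


def save_design(design: TDNDesign, path: Union[str, Path]) -> None:
    Path(path).write_text(design_to_json(design))


def load_design(path: Union[str, Path]) -> TDNDesign:
    return design_from_json(Path(path).read_text())
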