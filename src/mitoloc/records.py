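"""Protein records, labels and FASTA input.

A protein is assigned to one of four sub-mitochondrial compartments:
outer membrane, inner membrane, intermembrane space or matrix. Labels use
the short spellings ``outer | inner | intermembrane | matrix`` throughout.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

from Bio import SeqIO

#: Fixed compartment (class) order used everywhere: confusion matrices,
#: network outputs and serialized scores all follow this order.
COMPARTMENTS: tuple[str, ...] = ("outer", "inner", "intermembrane", "matrix")

#: Gene Ontology Cellular Component term for each compartment.
GO_TERMS: dict[str, str] = {
    "outer": "GO:0005741",
    "inner": "GO:0005743",
    "intermembrane": "GO:0005758",
    "matrix": "GO:0005759",
}


@dataclass
class ProteinRecord:
    """One protein sequence with an optional compartment label.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header token up to the first whitespace).
    sequence : str
        Residue string over the 20 canonical one-letter codes; ambiguity
        letters (X, B, Z, U, O, J) are tolerated and encoded as zero rows.
    label : str, optional
        One of :data:`COMPARTMENTS`.
    kingdom : str, optional
        Free-form taxonomic tag used only for stratified reporting.
    """

    id: str
    sequence: str
    label: str | None = None
    kingdom: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must have length >= 1")
        self.sequence = self.sequence.upper()
        if self.label is not None and self.label not in COMPARTMENTS:
            raise ValueError(
                f"{self.id}: unknown compartment {self.label!r}; "
                f"expected one of {COMPARTMENTS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved; the header token up to the first whitespace is the
    id. Duplicate ids and text before the first header are rejected.
    An empty file yields an empty list.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA at line {lineno}: "
                    f"expected '>' header, got {line.strip()!r}"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq)))
    return records


def write_fasta(records: list[ProteinRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping (byte-reproducible)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a 2-column TSV ``id<TAB>compartment`` into a dict.

    Lines starting with ``#`` are comments. Compartments must be one of
    :data:`COMPARTMENTS`.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            pid, comp = parts
            if comp not in COMPARTMENTS:
                raise ValueError(
                    f"{path}:{lineno}: unknown compartment {comp!r}"
                )
            if pid in labels:
                raise ValueError(f"{path}:{lineno}: duplicate id {pid!r}")
            labels[pid] = comp
    return labels


def write_labels(labels: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#id\tcompartment\n")
        for pid, comp in labels.items():
            fh.write(f"{pid}\t{comp}\n")


def attach_labels(records: list[ProteinRecord], labels: dict[str, str]) -> None:
    """Set ``record.label`` in place from a label dict (missing ids left None)."""
    for rec in records:
        if rec.id in labels:
            rec.label = labels[rec.id]
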