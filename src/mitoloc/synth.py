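"""Deterministic synthetic benchmark generator.

Emulates the inputs the classifier consumes — labelled protein
sequences, per-sequence evolutionary profiles and an all-against-all
similarity hit list — without any external database or search:

* each compartment gets a planted motif; a sequence of its class
  contains the motif at a random interior position, each motif position
  emitted verbatim with probability ``motif_strength`` and drawn from
  the background otherwise (strength 0 makes labels independent of
  sequence — the null model; strength 1 plants the motif exactly);
* a pseudo-profile per sequence mimics a PSI-BLAST log-odds matrix:
  small integer noise centred at 0 everywhere, with a strong positive
  score (+5) for the residue actually emitted at each motif position,
  so conservation peaks where the planted signal lies;
* optional near-duplicate records (a few point mutations of an existing
  sequence) are appended together with high-identity hits, giving the
  fold-partitioning code real redundancy structure to confine.

Everything is reproducible byte-for-byte from the spec's seed, and the
emitted files are exactly the formats the I/O layer reads back.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoding import AMINO_ACIDS, PSSM_FILE_ORDER, RawPSSM
from .partition import SimilarityHit, write_hits
from .records import COMPARTMENTS, ProteinRecord, write_fasta, write_labels

#: Default planted 8-mer motif per compartment (distinct, low mutual overlap).
DEFAULT_MOTIFS: tuple[str, str, str, str] = (
    "WKYRWDHE",  # outer
    "CPNCGKAF",  # inner
    "MLRSTQIV",  # intermembrane
    "DEGHKLNP",  # matrix
)

#: Log-odds score planted for the emitted residue at motif positions.
MOTIF_LOG_ODDS = 5


@dataclass
class SyntheticSpec:
    """Generation parameters; the defaults define the benchmark conditions."""

    n_per_class: int = 60
    length_range: tuple[int, int] = (50, 120)
    motif_per_class: tuple[str, str, str, str] = DEFAULT_MOTIFS
    motif_strength: float = 1.0
    background: dict[str, float] | None = None  # None = uniform over 20
    n_duplicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length range")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must be in [0, 1]")
        if len(self.motif_per_class) != len(COMPARTMENTS):
            raise ValueError("need one motif per compartment")
        if any(not m for m in self.motif_per_class):
            raise ValueError("motifs must be non-empty")
        if max(len(m) for m in self.motif_per_class) > lo - 2:
            raise ValueError(
                "motif longer than the minimum sequence length allows "
                "(interior placement needs length >= len(motif) + 2)"
            )
        if self.background is not None:
            total = sum(self.background.values())
            if not np.isclose(total, 1.0) or set(self.background) - set(AMINO_ACIDS):
                raise ValueError("background must be a distribution over canonical residues")


@dataclass
class SyntheticDataset:
    """In-memory result of :func:`generate`."""

    records: list[ProteinRecord]
    pssms: dict[str, RawPSSM]
    hits: list[SimilarityHit]
    motif_positions: dict[str, int]


def _background_sampler(spec: SyntheticSpec):
    if spec.background is None:
        probs = np.full(20, 1.0 / 20)
    else:
        probs = np.array([spec.background.get(aa, 0.0) for aa in AMINO_ACIDS])
    aa = np.array(list(AMINO_ACIDS))
    return aa, probs


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the labelled benchmark described by ``spec``.

    Returns 4 * n_per_class fresh records plus ``n_duplicates`` appended
    near-duplicate records (ids suffixed ``d``), one pseudo-profile per
    record, and a hit list containing self-hits, a scatter of
    sub-threshold background hits and one >90%-identity hit per planted
    duplicate pair.
    """
    rng = np.random.default_rng(spec.seed)
    aa, probs = _background_sampler(spec)
    records: list[ProteinRecord] = []
    pssms: dict[str, RawPSSM] = {}
    motif_positions: dict[str, int] = {}

    def make_pssm(seq: str, start: int, motif_len: int) -> RawPSSM:
        L = len(seq)
        values = np.clip(np.rint(rng.normal(0.0, 2.0, size=(L, 20))), -9, 9)
        for pos in range(start, start + motif_len):
            j = AMINO_ACIDS.find(seq[pos])
            if j >= 0:
                values[pos, j] = MOTIF_LOG_ODDS
        return RawPSSM(values=values, query_sequence=seq)

    lo, hi = spec.length_range
    for ci, compartment in enumerate(COMPARTMENTS):
        motif = spec.motif_per_class[ci]
        for i in range(spec.n_per_class):
            L = int(rng.integers(lo, hi + 1))
            seq = list(rng.choice(aa, size=L, p=probs))
            start = int(rng.integers(1, L - len(motif)))  # interior
            for m, res in enumerate(motif):
                if rng.random() < spec.motif_strength:
                    seq[start + m] = res
            pid = f"{compartment[:3].upper()}{i:04d}"
            sequence = "".join(seq)
            records.append(ProteinRecord(id=pid, sequence=sequence, label=compartment))
            motif_positions[pid] = start
            pssms[pid] = make_pssm(sequence, start, len(motif))

    hits: list[SimilarityHit] = [
        SimilarityHit(r.id, r.id, 100.0, 1e-180) for r in records
    ]
    # Background scatter of sub-threshold hits between unrelated records.
    n_bg = 2 * len(records)
    for _ in range(n_bg):
        i, j = rng.integers(len(records)), rng.integers(len(records))
        if i == j:
            continue
        hits.append(
            SimilarityHit(
                records[i].id,
                records[j].id,
                float(rng.uniform(15.0, 28.0)),
                float(10.0 ** rng.uniform(-6, -3)),
            )
        )
    # Planted near-duplicates: appended mutated copies + high-identity hits.
    base_count = len(records)
    for j in range(spec.n_duplicates):
        src = records[int(rng.integers(base_count))]
        seq = list(src.sequence)
        n_mut = max(1, len(seq) // 25)
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            seq[pos] = str(rng.choice(aa))
        dup_id = f"{src.id}d"
        if dup_id in motif_positions:  # same source drawn twice
            dup_id = f"{src.id}d{j}"
        sequence = "".join(seq)
        records.append(ProteinRecord(id=dup_id, sequence=sequence, label=src.label))
        start = motif_positions[src.id]
        motif_positions[dup_id] = start
        motif_len = len(spec.motif_per_class[COMPARTMENTS.index(src.label)])
        pssms[dup_id] = make_pssm(sequence, start, motif_len)
        identity = 100.0 * (1 - n_mut / len(seq))
        hits.append(SimilarityHit(src.id, dup_id, round(identity, 2), 1e-50))
    return SyntheticDataset(records, pssms, hits, motif_positions)


def write_pssm(raw: RawPSSM, path: str | os.PathLike) -> None:
    """Write a profile in PSI-BLAST ASCII matrix format.

    The log-odds block holds the raw (integer-valued) scores in the
    standard A R N D ... file column order; the percentage block is a
    placeholder. Round-trips exactly through the PSSM parser.
    """
    perm = [AMINO_ACIDS.index(c) for c in PSSM_FILE_ORDER]
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        header = " ".join(f"{c:>3}" for c in PSSM_FILE_ORDER)
        fh.write("           " + header + "  " + header + "\n")
        for i, res in enumerate(raw.query_sequence, start=1):
            row = raw.values[i - 1][perm]
            scores = " ".join(f"{int(round(v)):>3d}" for v in row)
            pct = " ".join(f"{0:>3d}" for _ in range(20))
            fh.write(f"{i:>5d} {res}  {scores}  {pct}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3176\n")


def write_dataset(dataset: SyntheticDataset, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write FASTA, per-id ``<id>.pssm`` files, labels TSV and hit list.

    Returns the paths written (keys: fasta, labels, hits, pssm_dir).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    fasta = outdir / "sequences.fasta"
    labels = outdir / "labels.tsv"
    hitfile = outdir / "hits.tsv"
    write_fasta(dataset.records, fasta)
    write_labels({r.id: r.label for r in dataset.records}, labels)
    write_hits(dataset.hits, hitfile)
    for pid, raw in sorted(dataset.pssms.items()):
        write_pssm(raw, pssm_dir / f"{pid}.pssm")
    return {"fasta": fasta, "labels": labels, "hits": hitfile, "pssm_dir": pssm_dir}
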