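"""Per-residue feature encodings.

Three per-residue descriptors feed the convolutional classifier:

``SEQ``
    One-hot: each residue is a 20-dimensional indicator vector, so a
    sequence of length L becomes an L x 20 matrix.
``PROP``
    Ten orthogonal physico-chemical property factors per residue (the
    Kidera factors, derived by multivariate analysis of 188 amino-acid
    properties), giving an L x 10 matrix.
``PSSM``
    The log-odds block of a PSI-BLAST ASCII position-specific scoring
    matrix, squashed elementwise into (0, 1) with the logistic sigmoid
    f(x) = 1 / (1 + exp(-x)), giving an L x 20 matrix.

Descriptors are combined by column-wise concatenation (e.g. PSSM+PROP is
L x 30). Canonical residue column order is alphabetical by one-letter
code; PSSM files use PSI-BLAST's own column order and are remapped on
read. Non-canonical letters (X, B, Z, U, O, J, ...) encode as all-zero
rows in every descriptor: absence of signal rather than an arbitrary
imputation.
"""
from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np

from .records import ProteinRecord

#: Canonical internal residue/column order (alphabetical one-letter codes).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Column order used in PSI-BLAST ASCII PSSM files.
PSSM_FILE_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Valid feature-set names and their channel counts.
FEATURE_SETS: dict[str, int] = {
    "SEQ": 20,
    "PROP": 10,
    "PSSM": 20,
    "SEQ+PROP": 30,
    "PSSM+PROP": 30,
}

# Ten orthogonal property factors per residue (Kidera et al., J. Protein
# Chem. 4:23-55, 1985; Table: factors KF1-KF10), transcribed verbatim in
# the source's A/R/N/D/... order. Values are dimensionless factor scores.
KIDERA_FACTORS: dict[str, tuple[float, ...]] = {
    "A": (-1.56, -1.67, -0.97, -0.27, -0.93, -0.78, -0.20, -0.08, 0.21, -0.48),
    "R": (0.22, 1.27, 1.37, 1.87, -1.70, 0.46, 0.92, -0.39, 0.23, 0.93),
    "N": (1.14, -0.07, -0.12, 0.81, 0.18, 0.37, -0.09, 1.23, 1.10, -1.73),
    "D": (0.58, -0.22, -1.58, 0.81, -0.92, 0.15, -1.52, 0.47, 0.76, 0.70),
    "C": (0.12, -0.89, 0.45, -1.05, -0.71, 2.41, 1.52, -0.69, 1.13, 1.10),
    "Q": (-0.47, 0.24, 0.07, 1.10, 1.10, 0.59, 0.84, -0.71, -0.03, -2.33),
    "E": (-1.45, 0.19, -1.61, 1.17, -1.31, 0.40, 0.04, 0.38, -0.35, -0.12),
    "G": (1.46, -1.96, -0.23, -0.16, 0.10, -0.11, 1.32, 2.36, -1.66, 0.46),
    "H": (-0.41, 0.52, -0.28, 0.28, 1.61, 1.01, -1.85, 0.47, 1.13, 1.63),
    "I": (-0.73, -0.16, 1.79, -0.77, -0.54, 0.03, -0.83, 0.51, 0.66, -1.78),
    "L": (-1.04, 0.00, -0.24, -1.10, -0.55, -2.05, 0.96, -0.76, 0.45, 0.93),
    "K": (-0.34, 0.82, -0.23, 1.70, 1.54, -1.62, 1.15, -0.08, -0.48, 0.60),
    "M": (-1.40, 0.18, -0.42, -0.73, 2.00, 1.52, 0.26, 0.11, -1.27, 0.27),
    "F": (-0.21, 0.98, -0.36, -1.43, 0.22, -0.81, 0.67, 1.10, 1.71, -0.44),
    "P": (2.06, -0.33, -1.15, -0.75, 0.88, -0.45, 0.30, -2.30, 0.74, -0.28),
    "S": (0.81, -1.08, 0.16, 0.42, -0.21, -0.43, -1.89, -1.15, -0.97, -0.23),
    "T": (0.26, -0.70, 1.21, 0.63, -0.10, 0.21, 0.24, -1.15, -0.56, 0.19),
    "W": (0.30, 2.10, -0.72, -1.57, -1.16, 0.57, -0.48, -0.40, -2.30, -0.60),
    "Y": (1.38, 1.48, 0.80, -0.56, 0.00, -0.68, -0.31, 1.03, -0.05, 0.53),
    "V": (-0.74, -0.71, 2.04, -0.40, 0.50, -0.81, -1.07, 0.06, -0.46, 0.65),
}

# Lookup matrix in canonical alphabetical order for fast per-residue lookup.
_KIDERA_MATRIX = np.array([KIDERA_FACTORS[aa] for aa in AMINO_ACIDS])


@dataclass
class FeatureMatrix:
    """An L x d matrix of per-residue channels for one protein."""

    values: np.ndarray
    channel_names: list[str]
    feature_set: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        d = FEATURE_SETS[self.feature_set]
        if self.values.shape[1] != d or len(self.channel_names) != d:
            raise ValueError(
                f"feature set {self.feature_set} requires {d} channels, "
                f"got matrix width {self.values.shape[1]}"
            )

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class RawPSSM:
    """Unsquashed PSI-BLAST log-odds profile, columns in canonical order."""

    values: np.ndarray
    query_sequence: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.query_sequence), 20):
            raise ValueError(
                f"PSSM shape {self.values.shape} does not match query "
                f"length {len(self.query_sequence)}"
            )


def encode_onehot(record: ProteinRecord) -> FeatureMatrix:
    """One-hot encode a sequence into an L x 20 matrix.

    Row i has a single 1 in the column of residue i; non-canonical
    letters give an all-zero row.
    """
    seq = record.sequence
    mat = np.zeros((len(seq), 20))
    for i, aa in enumerate(seq):
        j = _AA_INDEX.get(aa)
        if j is not None:
            mat[i, j] = 1.0
    return FeatureMatrix(mat, [f"SEQ:{aa}" for aa in AMINO_ACIDS], "SEQ")


def encode_prop(record: ProteinRecord) -> FeatureMatrix:
    """Encode a sequence with the 10 property factors (L x 10).

    Non-canonical letters give a zero row.
    """
    seq = record.sequence
    mat = np.zeros((len(seq), 10))
    for i, aa in enumerate(seq):
        j = _AA_INDEX.get(aa)
        if j is not None:
            mat[i] = _KIDERA_MATRIX[j]
    return FeatureMatrix(mat, [f"KF{i + 1}" for i in range(10)], "PROP")


_ROW_RE = re.compile(r"^\s*(\d+)\s+([A-Za-z])\s+(-?\d.*)$")


def parse_pssm(path: str | os.PathLike, expected_query: str | None = None) -> RawPSSM:
    """Parse a PSI-BLAST ASCII PSSM file.

    The first 20-column (log-odds) block is read; columns are remapped
    from the file's residue order to the canonical alphabetical order.

    Parameters
    ----------
    path : path to the ASCII matrix file.
    expected_query : optional sequence; a mismatch with the file's
        per-row residue column raises ``ValueError``.
    """
    rows: list[list[float]] = []
    residues: list[str] = []
    file_order: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if file_order is None:
                # Header: 20 or 40 single residue letters.
                toks = stripped.split()
                if len(toks) in (20, 40) and all(
                    len(t) == 1 and t.isalpha() for t in toks
                ):
                    file_order = "".join(toks[:20])
                continue
            m = _ROW_RE.match(line)
            if m is None:
                if rows:
                    break  # footer (K/Lambda statistics) reached
                continue
            idx, aa, rest = int(m.group(1)), m.group(2).upper(), m.group(3)
            fields = rest.split()
            if len(fields) < 20:
                raise ValueError(f"{path}: row {idx} (line {lineno}): fewer than 20 scores")
            try:
                scores = [float(x) for x in fields[:20]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: row {idx} (line {lineno}): non-numeric cell ({exc})"
                ) from None
            if idx != len(rows) + 1:
                raise ValueError(
                    f"{path}: row index {idx} out of order at line {lineno}"
                )
            rows.append(scores)
            residues.append(aa)
    if file_order is None:
        raise ValueError(f"{path}: no PSSM header line found")
    if not rows:
        raise ValueError(f"{path}: empty PSSM matrix section")
    query = "".join(residues)
    if expected_query is not None and query != expected_query.upper():
        raise ValueError(
            f"{path}: PSSM sequence column does not match expected query"
        )
    # Remap file column order -> canonical alphabetical order.
    perm = [file_order.index(aa) for aa in AMINO_ACIDS]
    values = np.asarray(rows, dtype=float)[:, perm]
    return RawPSSM(values=values, query_sequence=query)


def squash_pssm(raw: RawPSSM) -> FeatureMatrix:
    """Map raw log-odds scores into (0, 1) with the logistic sigmoid."""
    squashed = 1.0 / (1.0 + np.exp(-raw.values))
    return FeatureMatrix(squashed, [f"PSSM:{aa}" for aa in AMINO_ACIDS], "PSSM")


def concat_features(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate feature matrices column-wise, in the given order."""
    if not parts:
        raise ValueError("concat_features requires at least one part")
    if len(parts) == 1:
        return parts[0]
    lengths = {p.L for p in parts}
    if len(lengths) > 1:
        raise ValueError(f"mismatched sequence lengths among parts: {sorted(lengths)}")
    values = np.concatenate([p.values for p in parts], axis=1)
    names = [n for p in parts for n in p.channel_names]
    feature_set = "+".join(p.feature_set for p in parts)
    if feature_set not in FEATURE_SETS:
        # Arbitrary combinations are allowed internally; fall back to a
        # plain container without the registered-set width check.
        fm = FeatureMatrix.__new__(FeatureMatrix)
        fm.values = values
        fm.channel_names = names
        fm.feature_set = feature_set
        return fm
    return FeatureMatrix(values, names, feature_set)


def encode_features(
    record: ProteinRecord,
    feature_set: str,
    pssm: RawPSSM | None = None,
) -> FeatureMatrix:
    """Build the requested feature set for one record.

    ``PSSM``-containing sets require the record's profile; its sequence
    must match the record's.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    parts: list[FeatureMatrix] = []
    for name in feature_set.split("+"):
        if name == "SEQ":
            parts.append(encode_onehot(record))
        elif name == "PROP":
            parts.append(encode_prop(record))
        elif name == "PSSM":
            if pssm is None:
                raise ValueError(f"{record.id}: feature set {feature_set} requires a PSSM")
            if len(pssm.query_sequence) != len(record.sequence):
                raise ValueError(
                    f"{record.id}: PSSM length {len(pssm.query_sequence)} != "
                    f"sequence length {len(record.sequence)}"
                )
            parts.append(squash_pssm(pssm))
    return concat_features(parts)
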