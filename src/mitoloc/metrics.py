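"""Multi-class scoring: confusion matrix, per-class MCC, GCC and Q2mem.

The confusion matrix M has M[i, j] = number of proteins of true class i
predicted as class j. From it:

* MCC_k — the Matthews correlation coefficient of class k against the
  rest, computed from the one-vs-rest collapse of M:

      MCC_k = (M_kk * n_k - o_k * u_k) /
              sqrt((M_kk + o_k)(M_kk + u_k)(n_k + o_k)(n_k + u_k))

  with o_k the over-predictions (column k off-diagonal), u_k the
  under-predictions (row k off-diagonal) and n_k the true negatives.
  A zero denominator factor returns 0 by convention.

* GCC — the generalized correlation coefficient, a chi-square-based
  single score for K classes:

      GCC = sqrt( sum_ij (M_ij - e_ij)^2 / e_ij / (N (K - 1)) ),

  where e_ij = a_i b_j / N are the expected counts under independence
  (a_i row sums, b_j column sums). Cells with e_ij = 0 contribute 0.
  As a square root the value lies in [0, 1]; 0 means predictions no
  better than random, 1 perfect association. (For K = 2 it equals the
  absolute value of the binary MCC.)

* Q2mem — among proteins truly in either membrane (outer or inner), the
  percentage predicted into either membrane compartment, regardless of
  which.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import COMPARTMENTS

MEMBRANE_CLASSES = ("outer", "inner")


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows true classes, columns predicted classes."""

    counts: np.ndarray
    class_order: tuple[str, ...] = COMPARTMENTS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        K = len(self.class_order)
        if self.counts.shape != (K, K):
            raise ValueError(f"counts must be {K}x{K}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def K(self) -> int:
        return len(self.class_order)

    @property
    def N(self) -> int:
        return int(self.counts.sum())


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: tuple[str, ...] = COMPARTMENTS,
) -> ConfusionMatrix:
    """Tally aligned true/predicted label lists into a confusion matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)


def mcc(M: ConfusionMatrix, k: int | str) -> float:
    """One-vs-rest Matthews correlation coefficient of class k.

    ``k`` may be a class index or a class name. Returns 0 when any
    denominator factor vanishes (class absent in truth or predictions).
    """
    if isinstance(k, str):
        if k not in M.class_order:
            raise ValueError(f"unknown class {k!r}")
        k = M.class_order.index(k)
    if not 0 <= k < M.K:
        raise ValueError(f"class index {k} out of range")
    C = M.counts.astype(float)
    tp = C[k, k]
    o_k = C[:, k].sum() - tp  # over-predictions
    u_k = C[k, :].sum() - tp  # under-predictions
    n_k = C.sum() - tp - o_k - u_k  # true negatives
    denom = (tp + o_k) * (tp + u_k) * (n_k + o_k) * (n_k + u_k)
    if denom == 0:
        return 0.0
    return float((tp * n_k - o_k * u_k) / math.sqrt(denom))


def gcc(M: ConfusionMatrix) -> float:
    """Generalized correlation coefficient of a K-class confusion matrix."""
    C = M.counts.astype(float)
    N = C.sum()
    if N == 0:
        raise ValueError("empty confusion matrix (N = 0)")
    a = C.sum(axis=1)  # proteins in each true class
    b = C.sum(axis=0)  # proteins predicted in each class
    e = np.outer(a, b) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(e > 0, (C - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
    chi2 = terms.sum()
    return float(math.sqrt(chi2 / (N * (M.K - 1))))


def q2mem(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    membrane_classes: tuple[str, str] = MEMBRANE_CLASSES,
) -> float:
    """Percent of true membrane proteins predicted into either membrane.

    Restricted to proteins whose true class is outer or inner membrane;
    a prediction counts as correct if it lands in either membrane class,
    even the wrong one. Raises on an empty restriction.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    pairs = [
        (t, p) for t, p in zip(true_labels, predicted_labels) if t in membrane_classes
    ]
    if not pairs:
        raise ValueError("no membrane proteins among the true labels")
    hit = sum(1 for _, p in pairs if p in membrane_classes)
    return 100.0 * hit / len(pairs)


def evaluation_report(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: tuple[str, ...] = COMPARTMENTS,
    strata: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-class MCC, GCC and Q2mem, overall and optionally per stratum.

    ``strata`` is an aligned sequence of group tags (e.g. kingdom); each
    group's scores are computed from its subset of the pooled
    predictions, plus one ``all`` row.
    """
    rows = []
    groups: list[tuple[str, list[int]]] = [("all", list(range(len(true_labels))))]
    if strata is not None:
        if len(strata) != len(true_labels):
            raise ValueError("strata must align with the label lists")
        for tag in sorted(set(strata)):
            groups.append((tag, [i for i, s in enumerate(strata) if s == tag]))
    for tag, idx in groups:
        t = [true_labels[i] for i in idx]
        p = [predicted_labels[i] for i in idx]
        M = confusion(t, p, class_order)
        row: dict[str, object] = {"stratum": tag, "n": len(idx)}
        for c in class_order:
            row[f"mcc_{c}"] = mcc(M, c)
        row["gcc"] = gcc(M) if len(idx) else float("nan")
        try:
            row["q2mem_percent"] = q2mem(t, p)
        except ValueError:
            row["q2mem_percent"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def write_report_tsv(report: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(report.columns) + "\n")
        report.to_csv(fh, sep="\t", header=False, index=False, float_format="%.4f")
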