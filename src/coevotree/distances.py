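"""Maximum-likelihood pairwise distances under the JTT+gamma model.

For two gapped rows, sites where either row carries a gap or X are excluded
pairwise, the remaining site pairs are compressed to a 20x20 count table, and
the evolutionary distance d maximises

    sum_ab N_ab log sum_k w_k pi_a [exp(Q d r_k)]_ab

over d in (1e-8, d_max].  Distances that hit the cap are flagged saturated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .records import Alignment
from .substitution import SubstitutionModel

D_MAX_DEFAULT = 10.0
_OPT_TOL = 1e-6


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-entry saturation flags."""

    labels: list[str]
    matrix: np.ndarray
    saturated: np.ndarray = field(default=None)  # boolean, same shape
    d_max: float | None = None  # defaults to max(10, largest entry)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.d_max is None:
            self.d_max = max(D_MAX_DEFAULT, float(self.matrix.max(initial=0.0)))
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match number of labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.matrix < 0).any() or (self.matrix > self.d_max + 1e-12).any():
            raise ValueError(f"entries must lie in [0, d_max={self.d_max}]")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow([""] + self.labels)
            for i, label in enumerate(self.labels):
                writer.writerow([label] + [f"{x:.8f}" for x in self.matrix[i]])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            labels = header[1:]
            rows = [list(map(float, row[1:])) for row in reader]
        return cls(labels=labels, matrix=np.array(rows))


def _pair_counts(row_a: str, row_b: str, model: SubstitutionModel) -> np.ndarray:
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal (aligned) length")
    ia = model.encode(row_a)
    ib = model.encode(row_b)
    usable = (ia >= 0) & (ib >= 0)
    if not usable.any():
        raise ValueError("zero comparable sites between rows")
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia[usable], ib[usable]), 1.0)
    return counts


def ml_distance(
    row_a: str,
    row_b: str,
    model: SubstitutionModel,
    d_max: float = D_MAX_DEFAULT,
) -> tuple[float, bool]:
    """ML distance between two gapped rows; returns (distance, saturated)."""
    counts = _pair_counts(row_a, row_b, model)
    pi = model.frequencies

    def neg_loglik(d: float) -> float:
        mix = np.zeros((20, 20))
        for rate, weight in zip(model.category_rates, model.category_weights):
            if rate == 0.0:
                mix += weight * np.eye(20)
            else:
                mix += weight * model.transition_matrix(d * rate)
        site_lik = pi[:, None] * mix
        with np.errstate(divide="ignore"):
            logs = np.where(site_lik > 0, np.log(np.maximum(site_lik, 1e-300)), -1e300)
        return -float((counts * logs).sum())

    res = minimize_scalar(
        neg_loglik,
        bounds=(1e-8, d_max),
        method="bounded",
        options={"xatol": _OPT_TOL},
    )
    d_hat = float(res.x)
    saturated = d_hat >= d_max - 10 * _OPT_TOL
    if saturated:
        d_hat = d_max
    return d_hat, saturated


def distance_matrix(
    alignment: Alignment,
    model: SubstitutionModel,
    d_max: float = D_MAX_DEFAULT,
) -> DistanceMatrix:
    """All-pairs ML distances for an alignment (>= 2 rows)."""
    if alignment.n_rows < 2:
        raise ValueError("need at least 2 rows for a distance matrix")
    labels = alignment.ids
    n = len(labels)
    mat = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d, flag = ml_distance(alignment.rows[i][1], alignment.rows[j][1], model, d_max)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = d
            sat[i, j] = sat[j, i] = flag
    return DistanceMatrix(labels=labels, matrix=mat, saturated=sat, d_max=d_max)
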