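"""Amino-acid substitution model: JTT exchangeabilities with discrete-gamma
rate heterogeneity, optional empirical frequencies (+F) and an invariant-site
fraction (+I).

The rate matrix is Q = S diag(pi) with diagonal set so rows sum to zero,
normalised so the mean substitution rate at stationarity is 1.  Because the
model is time-reversible, Q is diagonalised once through the symmetrised form
diag(sqrt pi) Q diag(1/sqrt pi), and transition matrices P(t) = exp(Qt) are
assembled from the cached eigensystem.

Gamma rate heterogeneity uses the standard discretisation: K equal-probability
categories, each represented by its conditional mean rate.  An invariant-site
fraction p adds a zero-rate category of weight p and rescales the gamma rates
by 1/(1-p) so the overall mean rate stays 1.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .records import GAP, Alignment

#: Amino-acid ordering used by the model matrices (the PAML convention).
MODEL_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(MODEL_ALPHABET)}

# Jones-Taylor-Thornton (1992) accepted-mutation exchangeabilities,
# lower triangle stored column-wise in MODEL_ALPHABET order.
_JTT_LOWER_COLWISE = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9, 11, 298,
    45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64, 126, 20, 17,
    528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232, 8, 70, 16,
    10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46, 31,
    9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323,
    26, 597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119,
    26, 12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6,
    6, 27, 14, 5, 24, 201, 33, 55, 8, 47, 16, 56,
    45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21,
    479, 89, 10, 40, 245, 9, 32, 961, 14, 388,
    248, 102, 59, 25, 52, 24, 180, 65, 4,
    21, 47, 103, 10, 8, 14, 43, 16,
    29, 226, 24, 18, 323, 17, 92,
    12, 53, 536, 62, 285, 118,
    6, 10, 23, 477, 35,
    63, 38, 12, 21,
    112, 71, 25,
    16,
]

#: JTT stationary amino-acid frequencies (MODEL_ALPHABET order).
JTT_FREQUENCIES = np.array([
    0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846, 0.0198029802,
    0.04075195925, 0.06182993817, 0.07315192685, 0.02294397706, 0.05376094624,
    0.0919039081, 0.05867594132, 0.02382597617, 0.04012595987, 0.0509009491,
    0.06876493124, 0.05856494144, 0.01426098574, 0.0321019679, 0.066004934,
])


def _jtt_exchangeabilities() -> np.ndarray:
    S = np.zeros((20, 20))
    idx = 0
    for col in range(19):
        for row in range(col + 1, 20):
            S[row, col] = S[col, row] = _JTT_LOWER_COLWISE[idx]
            idx += 1
    assert idx == len(_JTT_LOWER_COLWISE) == 190
    return S


JTT_EXCHANGEABILITIES = _jtt_exchangeabilities()


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of K equal-probability categories of Gamma(alpha, 1/alpha)."""
    if alpha <= 0:
        raise ValueError(f"gamma shape alpha must be positive, got {alpha}")
    if n_categories < 1:
        raise ValueError("need at least 1 rate category")
    K = n_categories
    if K == 1:
        return np.array([1.0])
    bounds = _gamma_dist.ppf(np.arange(K + 1) / K, a=alpha, scale=1.0 / alpha)
    # E[X ; X <= b] for Gamma(alpha, scale 1/alpha) is the regularised
    # incomplete gamma with shape alpha+1 evaluated at alpha*b.
    cum = gammainc(alpha + 1.0, alpha * bounds[1:-1])
    cum = np.concatenate([[0.0], cum, [1.0]])
    return K * np.diff(cum)


class SubstitutionModel:
    """A reversible amino-acid model with discrete-gamma rates.

    Parameters
    ----------
    alpha:
        Gamma shape of among-site rate variation.
    n_categories:
        Number of discrete gamma categories (default 4).
    frequencies:
        Stationary frequencies in :data:`MODEL_ALPHABET` order; defaults to
        the JTT values.  Use :meth:`with_empirical_frequencies` for "+F".
    invariant_fraction:
        Proportion of invariant sites in [0, 1) ("+I"; default 0).
    """

    def __init__(
        self,
        alpha: float = 1.0,
        n_categories: int = 4,
        frequencies: np.ndarray | None = None,
        invariant_fraction: float = 0.0,
        exchangeabilities: np.ndarray | None = None,
    ):
        if not (0 <= invariant_fraction < 1):
            raise ValueError("invariant_fraction must be in [0, 1)")
        self.alpha = float(alpha)
        self.n_categories = int(n_categories)
        self.invariant_fraction = float(invariant_fraction)
        S = JTT_EXCHANGEABILITIES if exchangeabilities is None else np.asarray(exchangeabilities, float)
        if S.shape != (20, 20) or not np.allclose(S, S.T) or (S < 0).any():
            raise ValueError("exchangeabilities must be a symmetric nonnegative 20x20 table")
        pi = JTT_FREQUENCIES if frequencies is None else np.asarray(frequencies, float)
        if pi.shape != (20,) or abs(pi.sum() - 1.0) > 1e-9 or (pi <= 0).any():
            raise ValueError("frequencies must be 20 positive values summing to 1")
        self.exchangeabilities = S
        self.frequencies = pi / pi.sum()

        Q = S * self.frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.dot(self.frequencies, np.diag(Q))
        Q /= mean_rate
        self.Q = Q

        sqrt_pi = np.sqrt(self.frequencies)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = eigvals
        self._left = eigvecs / sqrt_pi[None, :].T  # diag(1/sqrt pi) @ U
        self._right = (eigvecs * sqrt_pi[:, None]).T  # U.T @ diag(sqrt pi)

        gamma_rates = discrete_gamma_rates(self.alpha, self.n_categories)
        if self.invariant_fraction > 0:
            p = self.invariant_fraction
            rates = np.concatenate([[0.0], gamma_rates / (1.0 - p)])
            weights = np.concatenate([[p], np.full(self.n_categories, (1.0 - p) / self.n_categories)])
        else:
            rates = gamma_rates
            weights = np.full(self.n_categories, 1.0 / self.n_categories)
        self.category_rates = rates
        self.category_weights = weights

    def with_empirical_frequencies(self, alignment: Alignment, floor: float = 1e-6) -> "SubstitutionModel":
        """Return a "+F" copy with frequencies counted from the alignment
        (gaps and X excluded; zero counts floored at ``floor`` and renormalised)."""
        counts = np.zeros(20)
        for _, gapped in alignment.rows:
            for ch in gapped:
                if ch != GAP and ch in _AA_INDEX:
                    counts[_AA_INDEX[ch]] += 1
        if counts.sum() == 0:
            raise ValueError("alignment has no countable residues")
        freqs = np.maximum(counts / counts.sum(), floor)
        freqs /= freqs.sum()
        return SubstitutionModel(
            alpha=self.alpha,
            n_categories=self.n_categories,
            frequencies=freqs,
            invariant_fraction=self.invariant_fraction,
            exchangeabilities=self.exchangeabilities,
        )

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows index the starting residue."""
        if t < 0:
            raise ValueError("time must be >= 0")
        P = self._left @ (np.exp(self._eigvals * t)[:, None] * self._right)
        return np.clip(P, 0.0, None)

    def encode(self, residues: str) -> np.ndarray:
        """Indices into MODEL_ALPHABET; gaps and X map to -1."""
        return np.array([_AA_INDEX.get(ch, -1) for ch in residues], dtype=np.int64)

    def decode(self, indices: np.ndarray) -> str:
        return "".join(MODEL_ALPHABET[i] for i in indices)
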