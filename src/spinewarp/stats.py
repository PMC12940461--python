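"""Paired nonparametric testing and chance-corrected observer agreement.

``wilcoxon_signed_rank`` uses exact enumeration of all 2^m sign assignments
for m ≤ 12 nonzero differences (with mid-ranks for ties) and a tie-corrected
normal approximation with continuity correction otherwise — small palliative
cohorts sit squarely in the exact branch.

``gwet_ac2`` implements Gwet's weighted chance-corrected agreement with
quadratic ordinal weights w_kl = 1 − (k−l)²/(K−1)², K = 5 rating categories
(1 Poor … 5 Perfect), which is robust to the prevalence imbalance that
deflates Cohen's kappa when raters mostly agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.stats import norm

N_CATEGORIES = 5
EXACT_LIMIT = 12


@dataclass
class RatingTable:
    """Ordinal scores, shape (raters, cases), integers in 1..5."""

    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[0] < 2:
            raise ValueError("need a 2-D table with at least 2 raters")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(self.scores == np.round(self.scores)):
                raise ValueError("scores must be integers")
            self.scores = self.scores.astype(int)
        if np.any((self.scores < 1) | (self.scores > N_CATEGORIES)):
            raise ValueError(f"scores must lie in 1..{N_CATEGORIES}")

    @property
    def n_raters(self) -> int:
        return self.scores.shape[0]

    @property
    def n_cases(self) -> int:
        return self.scores.shape[1]


def _signed_ranks(diffs: np.ndarray, zero_method: str) -> np.ndarray:
    d = np.asarray(diffs, dtype=float)
    if zero_method == "drop":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise ValueError("zero_method must be 'drop' or 'pratt'")
    if d.size == 0 or np.all(d == 0):
        raise ValueError("degenerate sample: all differences are zero")
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(d.size, dtype=float)
    sorted_abs = absd[order]
    i = 0
    while i < d.size:
        j = i
        while j < d.size and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)  # mid-rank
        i = j
    if zero_method == "pratt":
        keep = d != 0
        return np.sign(d[keep]) * ranks[keep]
    return np.sign(d) * ranks


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray | None = None,
    alternative: str = "two-sided",
    zero_method: str = "drop",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples (or differences).

    Returns (W, p) where W is the sum of positive signed ranks.  Exact
    enumeration for ≤ 12 nonzero differences; otherwise normal approximation
    with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    diffs = x if y is None else x - np.asarray(y, dtype=float)
    if not np.all(np.isfinite(diffs)):
        raise ValueError("differences must be finite")
    sr = _signed_ranks(diffs, zero_method)
    ranks = np.abs(sr)
    w = float(np.sum(sr[sr > 0]))
    m = sr.size
    mu = float(ranks.sum()) / 2.0

    if m <= EXACT_LIMIT:
        # enumerate all sign assignments of the (tied) ranks
        ws = np.zeros(1)
        for r in ranks:
            ws = np.concatenate([ws, ws + r])
        if alternative == "two-sided":
            p = float(np.mean(np.abs(ws - mu) >= abs(w - mu) - 1e-12))
        elif alternative == "greater":
            p = float(np.mean(ws >= w - 1e-12))
        elif alternative == "less":
            p = float(np.mean(ws <= w + 1e-12))
        else:
            raise ValueError(f"bad alternative {alternative!r}")
        return w, min(p, 1.0)

    var = float(np.sum(ranks**2)) / 4.0  # tie-corrected: uses actual ranks
    sd = np.sqrt(var)
    if alternative == "two-sided":
        z = (abs(w - mu) - 0.5) / sd
        p = 2.0 * norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (w - mu - 0.5) / sd
        p = norm.sf(z)
    elif alternative == "less":
        z = (w - mu + 0.5) / sd
        p = norm.cdf(z)
    else:
        raise ValueError(f"bad alternative {alternative!r}")
    return w, float(min(p, 1.0))


def quadratic_weights(K: int = N_CATEGORIES) -> np.ndarray:
    k = np.arange(1, K + 1)
    return 1.0 - ((k[:, None] - k[None, :]) ** 2) / (K - 1) ** 2


def gwet_ac2(table: RatingTable, K: int = N_CATEGORIES) -> float:
    """Gwet's AC2 with quadratic weights: (p_a − p_e) / (1 − p_e)."""
    w = quadratic_weights(K)
    scores = table.scores
    r, n = scores.shape
    # per-case category counts r_ik
    counts = np.zeros((n, K))
    for k in range(1, K + 1):
        counts[:, k - 1] = np.sum(scores == k, axis=0)
    # weighted per-case agreement
    rstar = counts @ w.T  # r*_ik = Σ_l w_kl r_il
    pa_i = np.sum(counts * (rstar - 1.0), axis=1) / (r * (r - 1.0))
    p_a = float(np.mean(pa_i))
    # Gwet's weighted chance term
    pi_k = counts.mean(axis=0) / r
    Tw = float(w.sum())
    p_e = Tw / (K * (K - 1.0)) * float(np.sum(pi_k * (1.0 - pi_k)))
    if np.isclose(p_e, 1.0):
        raise ValueError("degenerate categories: chance agreement is 1")
    return float((p_a - p_e) / (1.0 - p_e))


def pairwise_agreement(table: RatingTable) -> tuple[float, float]:
    """(exact-match %, ≤1-step %) averaged over all rater pairs."""
    scores = table.scores
    r = table.n_raters
    exact, within = [], []
    for a in range(r):
        for b in range(a + 1, r):
            d = np.abs(scores[a] - scores[b])
            exact.append(100.0 * np.mean(d == 0))
            within.append(100.0 * np.mean(d <= 1))
    return float(np.mean(exact)), float(np.mean(within))


_AC2_BANDS = [
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
]


def interpret_ac2(value: float) -> str:
    """Conventional agreement band for a chance-corrected coefficient.

    Values at a band's upper edge belong to that band (0.80 → "substantial",
    0.81 → "almost perfect"); anything in (0.20, 0.21) reads "fair".
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError("coefficient must lie in [-1, 1]")
    for upper, label in _AC2_BANDS:
        if value <= upper:
            return label
    return "almost perfect"
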