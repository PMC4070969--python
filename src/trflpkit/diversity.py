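"""Richness, Shannon–Weiner diversity, evenness, and rarefaction.

All logarithms are base 2: H' = -sum p_i log2 p_i (bits), E = H'/log2(S).
Many ecology packages default to natural log; results here differ from
those by a factor of ln 2.

Rarefaction gives the expected number of OTUs in a random subsample of n
clones drawn without replacement from a library of N, by the exact
hypergeometric formula E[S_n] = sum_i (1 - C(N-N_i, n)/C(N, n)), with a
normal-approximation 95% interval from the exact hypergeometric variance,
or by Monte-Carlo resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .peaks import BinnedProfile


@dataclass(frozen=True)
class DiversityStats:
    """Richness S, Shannon H' (bits), evenness E, and H_max = log2(S)."""

    S: int
    H_prime: float
    E: float
    H_max: float


@dataclass(frozen=True)
class RarefactionCurve:
    """Expected richness (with 95% bounds) vs subsample size 1..N.

    ``sd`` is the exact hypergeometric standard deviation of S_n for the
    analytic method, or the sample standard deviation across resamples.
    """

    n: np.ndarray
    expected: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    sd: np.ndarray
    method: str


def shannon(abundances) -> DiversityStats:
    """Diversity statistics of a relative-abundance vector.

    Zero entries are skipped; proportions must be nonnegative and sum to 1
    within 1e-6.  E is defined as 0 for a single-species profile, where
    H_max = 0 makes the ratio indeterminate.
    """
    p = np.asarray(abundances, float)
    if p.size == 0 or not (p > 0).any():
        raise ValueError("empty profile")
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("abundances must sum to 1")
    p = p[p > 0]
    s = int(p.size)
    h = float(-(p * np.log2(p)).sum())
    h_max = float(np.log2(s)) if s > 0 else 0.0
    e = h / h_max if s > 1 else 0.0
    return DiversityStats(S=s, H_prime=h, E=e, H_max=h_max)


def richness(binned: BinnedProfile, dye: str | None = None) -> int:
    """Number of retained T-RF bins (in one dye channel, or in total)."""
    sub = binned.bins if dye is None else binned.channel(dye)
    return int(len(sub))


def profile_diversity(binned: BinnedProfile, dye: str) -> DiversityStats:
    """Shannon statistics of one dye channel, renormalized within channel."""
    return shannon(binned.abundances(dye))


def _absence_probs(counts: np.ndarray, n: np.ndarray) -> np.ndarray:
    """q[i, j] = P(species i absent from a subsample of size n[j])."""
    N = counts.sum()
    q = np.empty((counts.size, n.size))
    for i, c in enumerate(counts):
        # C(N-c, n)/C(N, n) == hypergeometric P(0 successes)
        q[i] = stats.hypergeom.pmf(0, N, c, n)
    return q


def expected_richness(counts, n: int) -> float:
    """Analytic E[S_n] for a single subsample size (errors when n > N)."""
    c = _check_counts(counts)
    if n > c.sum():
        raise ValueError("subsample exceeds library")
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    return float((1.0 - _absence_probs(c, np.array([n]))).sum())


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0 or (c <= 0).any() or not np.issubdtype(c.dtype, np.integer):
        c = c.astype(float)
        if c.size == 0 or (c <= 0).any() or (c != np.round(c)).any():
            raise ValueError("counts must be positive integers")
    return c.astype(int)


def rarefy(counts, method: str = "analytic", n_resamples: int = 1000,
           seed: int = 0, ci: float = 0.95) -> RarefactionCurve:
    """Rarefaction curve over subsample sizes 1..N.

    ``analytic`` uses the hypergeometric expectation with a
    normal-approximation interval from the exact variance of S_n (which
    needs the pairwise joint absence probabilities); ``resample`` draws
    ``n_resamples`` subsamples without replacement and reports the mean
    and the (1-ci)/2 and 1-(1-ci)/2 percentiles.
    """
    c = _check_counts(counts)
    N = int(c.sum())
    grid = np.arange(1, N + 1)
    if method == "analytic":
        q = _absence_probs(c, grid)
        expected = (1.0 - q).sum(axis=0)
        var = (q * (1.0 - q)).sum(axis=0)
        for i in range(c.size):
            for j in range(i + 1, c.size):
                qij = stats.hypergeom.pmf(0, N, c[i] + c[j], grid)
                var += 2.0 * (qij - q[i] * q[j])
        sd = np.sqrt(np.clip(var, 0.0, None))
        z = stats.norm.ppf(0.5 + ci / 2.0)
        lower = np.clip(expected - z * sd, 1.0, None)
        upper = np.clip(expected + z * sd, None, float(c.size))
    elif method == "resample":
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(c.size), c)
        richness_curves = np.empty((n_resamples, N))
        for r in range(n_resamples):
            perm = rng.permutation(labels)
            # S_n = number of first occurrences among the first n draws
            first = np.zeros(N, bool)
            first[np.unique(perm, return_index=True)[1]] = True
            richness_curves[r] = np.cumsum(first)
        expected = richness_curves.mean(axis=0)
        sd = richness_curves.std(axis=0, ddof=1)
        lo_pct, hi_pct = 100 * (0.5 - ci / 2), 100 * (0.5 + ci / 2)
        lower = np.percentile(richness_curves, lo_pct, axis=0)
        upper = np.percentile(richness_curves, hi_pct, axis=0)
    else:
        raise ValueError("method must be 'analytic' or 'resample'")
    return RarefactionCurve(grid, expected, lower, upper, sd, method)
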