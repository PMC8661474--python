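"""Pairwise Spearman correlations and non-rejection rates (NRR).

With 39 matched pairs and ~200 features, marginal correlations on the
fold-change matrix are dense with indirect associations. The NRR of a
feature pair (i, j) estimates how often the hypothesis of *conditional*
independence survives: repeatedly draw a conditioning set Q of q other
features, compute the q-order sample partial correlation r(i,j | Q), and
test H0: r = 0 with the Fisher z statistic

    z = sqrt(n - q - 3) * atanh(r),

non-rejecting when |z| <= z_{1-alpha/2}. The NRR is the fraction of
non-rejections over many such tests. A *low* NRR means the association
persists under conditioning — it is unlikely to be spurious — so edges are
retained when NRR falls at or below a threshold (0.1 by default downstream).

Partial correlations are computed from the inverse of the correlation
submatrix on {i, j} | Q: r = -W_ij / sqrt(W_ii * W_jj) with W the inverse.
Because every test only needs a submatrix of the feature correlation
matrix, the matrix is computed once and tests are evaluated in vectorized
batches of conditioning sets.

An ``exhaustive`` mode enumerates *all* conditioning sets of each order and
is the exact brute-force average; Monte-Carlo mode samples them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .preprocess import FoldChangeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "NRRMatrix",
    "NRRConfig",
    "spearman_matrix",
    "partial_correlation",
    "nonrejection_rate",
    "nrr_matrix",
    "nrr_histogram",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho matrix over features (diagonal = 1)."""

    feature_ids: list[str]
    rho: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.feature_ids, columns=self.feature_ids)


@dataclass
class NRRMatrix:
    """Symmetric matrix of non-rejection rates; the diagonal is undefined (NaN)."""

    feature_ids: list[str]
    nrr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.nrr, index=self.feature_ids, columns=self.feature_ids)


@dataclass
class NRRConfig:
    """Parameters of the NRR estimation.

    alpha : two-sided level of each Fisher-z partial-correlation test.
    n_tests : Monte-Carlo tests per feature pair (ignored in exhaustive mode).
    q_policy : "uniform" draws the conditioning order q uniformly from
        1..q_max per test; "fixed" always uses order ``q``.
    q : conditioning order when q_policy="fixed".
    q_max : largest order under the uniform policy; when None it resolves to
        min(p - 2, n - 4, 20) at run time, keeping the Fisher-z degrees of
        freedom n - q - 3 positive.
    mode : "monte_carlo" (sampled conditioning sets) or "exhaustive"
        (all subsets of every configured order).
    seed : master seed; each unordered pair gets its own derived substream.
    """

    alpha: float = 0.05
    n_tests: int = 100
    q_policy: str = "uniform"
    q: int | None = None
    q_max: int | None = None
    mode: str = "monte_carlo"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.q_policy not in ("uniform", "fixed"):
            raise ValidationError(f"unknown q_policy {self.q_policy!r}")
        if self.mode not in ("monte_carlo", "exhaustive"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.q_policy == "fixed" and (self.q is None or self.q < 1):
            raise ValidationError("q_policy='fixed' requires a positive q")
        if self.n_tests < 1:
            raise ValidationError("n_tests must be positive")

    def orders(self, n_rows: int, n_features: int) -> list[int]:
        """Resolve and validate the set of conditioning orders for given data."""
        cap = min(n_features - 2, n_rows - 4)
        if cap < 1:
            raise ValidationError(
                f"data too small for any conditioning order (n={n_rows}, p={n_features})"
            )
        if self.q_policy == "fixed":
            qs = [int(self.q)]
        else:
            q_max = min(cap, 20) if self.q_max is None else int(self.q_max)
            if q_max < 1:
                raise ValidationError("q_max must be >= 1")
            qs = list(range(1, q_max + 1))
        if qs[-1] > cap:
            raise ValidationError(
                f"conditioning order {qs[-1]} infeasible: requires q <= min(p-2, n-4) = {cap}"
            )
        return qs


# ---------------------------------------------------------------------------
# Spearman matrix


def spearman_matrix(fc: FoldChangeMatrix | pd.DataFrame | np.ndarray) -> CorrelationMatrix:
    """Pairwise Spearman correlation of all feature columns.

    Equals the Pearson correlation of columnwise average ranks (ties get
    average ranks). Constant columns have undefined rank correlation; their
    entries are set to 0 with a warning.
    """
    if isinstance(fc, FoldChangeMatrix):
        values, ids = fc.values, list(fc.feature_ids)
    elif isinstance(fc, pd.DataFrame):
        values, ids = fc.to_numpy(float), list(map(str, fc.columns))
    else:
        values = np.asarray(fc, float)
        ids = [f"f{i}" for i in range(values.shape[1])]
    if values.shape[0] < 3:
        raise ValidationError("Spearman matrix needs at least 3 rows")
    ranks = stats.rankdata(values, axis=0)
    constant = ranks.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    if constant.any():
        logger.warning(
            "constant column(s) %s: Spearman correlations set to 0",
            [ids[i] for i in np.flatnonzero(constant)],
        )
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(ids, np.clip(rho, -1.0, 1.0))


# ---------------------------------------------------------------------------
# partial correlation


def _check_invertible(sub: np.ndarray, label: str) -> np.ndarray:
    try:
        inv = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        raise ValidationError(f"singular covariance submatrix for {label}") from None
    if not np.all(np.isfinite(inv)) or np.linalg.cond(sub) > 1e12:
        raise ValidationError(f"singular covariance submatrix for {label}")
    return inv


def partial_correlation(
    data: np.ndarray, i: int, j: int, Q: Iterable[int] = ()
) -> float:
    """Sample partial correlation of columns i and j given the columns in Q.

    Computed by inverting the sample covariance of the submatrix on
    {i, j} | Q: r = -W_ij / sqrt(W_ii * W_jj) with W the inverse. With
    Q empty this is the plain Pearson correlation; in general it equals the
    correlation of the residuals of i and j after regression on Q.
    """
    Q = list(Q)
    data = np.asarray(data, float)
    if i == j or i in Q or j in Q:
        raise ValidationError("i, j and Q must be distinct")
    if data.shape[0] <= len(Q) + 3:
        raise ValidationError(
            f"need more than |Q| + 3 = {len(Q) + 3} rows, got {data.shape[0]}"
        )
    cols = [i, j, *Q]
    cov = np.cov(data[:, cols], rowvar=False)
    inv = _check_invertible(np.atleast_2d(cov), f"(i={i}, j={j}, Q={sorted(Q)})")
    return float(-inv[0, 1] / math.sqrt(inv[0, 0] * inv[1, 1]))


def _partials_from_corr(corr: np.ndarray, index_sets: np.ndarray) -> np.ndarray:
    """Batched partial correlation of columns 0,1 of each index row given the rest.

    index_sets has shape (k, q+2); rows index into the global correlation
    matrix ``corr``. Returns an array of k partial correlations.
    """
    sub = corr[index_sets[:, :, None], index_sets[:, None, :]]
    try:
        inv = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        # exactly singular sets (e.g. an affine-copy feature pair) imply
        # |r| = 1, which downstream counts as a rejection; invert set-by-set
        # and mark failures that way instead of aborting the whole batch
        rs = np.empty(len(sub))
        for k, s in enumerate(sub):
            try:
                w = np.linalg.inv(s)
                rs[k] = -w[0, 1] / np.sqrt(w[0, 0] * w[1, 1])
            except np.linalg.LinAlgError:
                rs[k] = 1.0
        return rs
    with np.errstate(invalid="ignore", divide="ignore"):
        r = -inv[:, 0, 1] / np.sqrt(inv[:, 0, 0] * inv[:, 1, 1])
    return r


def _nonrejections(r: np.ndarray, n_rows: int, q: int, crit: float) -> np.ndarray:
    """Fisher-z non-rejection indicators; |r| >= 1 counts as rejection."""
    r = np.asarray(r, float)
    out = np.zeros(r.shape, bool)
    ok = np.isfinite(r) & (np.abs(r) < 1.0)
    z = np.sqrt(n_rows - q - 3) * np.arctanh(r[ok])
    out[ok] = np.abs(z) <= crit
    return out


def _pair_nrr(
    corr: np.ndarray,
    n_rows: int,
    i: int,
    j: int,
    config: NRRConfig,
    orders: Sequence[int],
    rng: np.random.Generator,
) -> float:
    p = corr.shape[0]
    others = np.array([k for k in range(p) if k not in (i, j)])
    crit = stats.norm.ppf(1 - config.alpha / 2)
    hits = 0
    total = 0
    if config.mode == "exhaustive":
        for q in orders:
            sets = np.array(list(combinations(others, q)), dtype=int)
            idx = np.concatenate(
                [np.broadcast_to([i, j], (len(sets), 2)), sets], axis=1
            )
            r = _partials_from_corr(corr, idx)
            hits += int(_nonrejections(r, n_rows, q, crit).sum())
            total += len(sets)
    else:
        if config.q_policy == "fixed":
            qs = np.full(config.n_tests, orders[0])
        else:
            qs = rng.integers(1, orders[-1] + 1, size=config.n_tests)
        # one argsort of uniforms yields, per test, a random permutation of
        # the candidate features; the first q entries form Q (no replacement
        # within a test, independent across tests)
        perm = np.argsort(rng.random((config.n_tests, len(others))), axis=1)
        for q in np.unique(qs):
            rows = np.flatnonzero(qs == q)
            sets = others[perm[rows, :q]]
            idx = np.concatenate(
                [np.broadcast_to([i, j], (len(rows), 2)), sets], axis=1
            )
            r = _partials_from_corr(corr, idx)
            hits += int(_nonrejections(r, n_rows, int(q), crit).sum())
            total += len(rows)
    return hits / total


def nonrejection_rate(
    data: np.ndarray,
    i: int,
    j: int,
    config: NRRConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """NRR of one feature pair: fraction of partial-correlation tests not rejecting.

    ``rng`` drives the conditioning-set sampling in Monte-Carlo mode; when
    omitted, a substream derived from ``config.seed`` and the sorted pair is
    used (matching :func:`nrr_matrix`).
    """
    data = np.asarray(data, float)
    n, p = data.shape
    orders = config.orders(n, p)
    if rng is None:
        rng = _pair_rng(config.seed, i, j)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    if not np.all(np.isfinite(corr)):
        bad = np.flatnonzero(~np.isfinite(np.diag(np.atleast_2d(corr))) | (data.std(axis=0) == 0))
        raise ValidationError(f"constant column(s) {bad.tolist()}: correlations undefined")
    return _pair_nrr(corr, n, i, j, config, orders, rng)


def _pair_rng(seed: int, i: int, j: int) -> np.random.Generator:
    a, b = sorted((int(i), int(j)))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(a, b)))


def nrr_matrix(
    data: FoldChangeMatrix | pd.DataFrame | np.ndarray, config: NRRConfig
) -> NRRMatrix:
    """NRR for every unordered feature pair.

    Each pair uses an independent substream keyed by the sorted pair
    indices, so results are reproducible and independent of evaluation
    order; the matrix is symmetric by construction.
    """
    if isinstance(data, FoldChangeMatrix):
        values, ids = data.values, list(data.feature_ids)
    elif isinstance(data, pd.DataFrame):
        values, ids = data.to_numpy(float), list(map(str, data.columns))
    else:
        values = np.asarray(data, float)
        ids = [f"f{i}" for i in range(values.shape[1])]
    n, p = values.shape
    if p < 2:
        raise ValidationError("need at least 2 features")
    orders = config.orders(n, p)
    if values.std(axis=0).min() == 0:
        bad = [ids[k] for k in np.flatnonzero(values.std(axis=0) == 0)]
        raise ValidationError(f"constant column(s) {bad}: correlations undefined")
    corr = np.corrcoef(values, rowvar=False)
    out = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(i + 1, p):
            rng = _pair_rng(config.seed, i, j)
            out[i, j] = out[j, i] = _pair_nrr(corr, n, i, j, config, orders, rng)
    return NRRMatrix(ids, out)


def nrr_histogram(nrr: NRRMatrix, n_bins: int = 20) -> pd.DataFrame:
    """Histogram of off-diagonal (upper-triangle) NRR values on uniform [0,1] bins.

    The shape of this histogram is how a conservative retention threshold is
    judged: spurious associations pile up near 1 - alpha, persistent ones
    near 0.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    iu = np.triu_indices_from(nrr.nrr, k=1)
    vals = nrr.nrr[iu]
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts.astype(int)}
    )
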