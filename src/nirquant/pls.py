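"""NIPALS PLS1 regression with LOOCV rank screening and synergy-interval
(SiPLS) band selection.

The factorization is classical single-response NIPALS on mean-centered
data: for each latent factor, the weight vector is the normalized X'y
covariance direction, scores/loadings follow, and X and y are deflated.
Regression coefficients at every rank a <= A are recovered from
W (P'W)^{-1} q.  Rank ("number of principal factors") is screened by
leave-one-out cross-validation in which *all* data-dependent state —
the MSC reference of the pretreatment chain, the column means, the PLS
fit — is refitted on each fold's n-1 training samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import FittedPretreatment, apply_pretreatments
from .spectra import SpectraSet, WavenumberGrid

__all__ = [
    "PLSModel",
    "LOOCVResult",
    "IntervalSet",
    "SiPLSRecord",
    "fit_pls",
    "pls_predict",
    "pls_scores",
    "loocv_curve",
    "select_rank",
    "divide_intervals",
    "interval_mask",
    "sipls_search",
]


@dataclass(frozen=True)
class PLSModel:
    """Centered NIPALS PLS1 factorization.

    Attributes
    ----------
    x_mean, y_mean
        Calibration means removed before factorization.
    W, P : (p, A) arrays
        Weight and loading vectors per latent factor.
    q : (A,) array
        y-loadings.
    T : (n, A) array
        Calibration scores (mutually orthogonal columns).
    coefs : (p, A) array
        Regression coefficient vector for every rank a = 1..A (column
        a-1); predictions are (X - x_mean) @ coefs[:, a-1] + y_mean.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    coefs: np.ndarray
    rank: int
    window: tuple | None = None
    lineage: str | None = None


def fit_pls(X: np.ndarray, y: np.ndarray, A: int, *,
            window: tuple | None = None,
            lineage: str | None = None) -> PLSModel:
    """Fit NIPALS PLS1 with ``A`` latent factors on (pretreated) data.

    ``A`` is truncated with a warning when it exceeds the data rank
    (deflation leaves no covariance to extract).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y sample counts differ")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to regress")
    if A < 1:
        raise ValueError("rank A must be >= 1")
    A = min(A, n - 1, p)

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    actual = 0
    for a in range(A):
        cov = Xd.T @ yd
        norm = np.linalg.norm(cov)
        if norm < 1e-13:
            import warnings
            warnings.warn(
                f"rank truncated to {actual}: no covariance left to extract",
                stacklevel=2)
            break
        w = cov / norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-26:
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        actual += 1
    if actual == 0:
        raise ValueError("could not extract any latent factor")
    W, P, T, q = W[:, :actual], P[:, :actual], T[:, :actual], q[:actual]

    # b_a = W_a (P_a' W_a)^{-1} q_a for every rank a
    PtW = P.T @ W
    coefs = np.zeros((p, actual))
    for a in range(1, actual + 1):
        coefs[:, a - 1] = W[:, :a] @ np.linalg.solve(PtW[:a, :a], q[:a])
    return PLSModel(x_mean, y_mean, W, P, q, T, coefs, actual,
                    window=window, lineage=lineage)


def pls_predict(model: PLSModel, X_new: np.ndarray,
                a: int | None = None) -> np.ndarray:
    """Predict at rank ``a`` (default: the model's full rank).

    Rank 0 returns the null model, i.e. the calibration mean for every row.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X has {X_new.shape[1]} columns, model expects {model.x_mean.size} "
            "(wavenumber window or pretreatment mismatch)")
    a = model.rank if a is None else a
    if not 0 <= a <= model.rank:
        raise ValueError(f"rank {a} outside [0, {model.rank}]")
    if a == 0:
        return np.full(X_new.shape[0], model.y_mean)
    return (X_new - model.x_mean) @ model.coefs[:, a - 1] + model.y_mean


def pls_scores(model: PLSModel, X: np.ndarray, k: int | None = None) -> np.ndarray:
    """Deflation-consistent scores of new data (t_a = X_deflated w_a).

    On the calibration matrix this reproduces the stored T exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError("column count mismatch with the fitted model")
    k = model.rank if k is None else k
    if not 0 <= k <= model.rank:
        raise ValueError(f"requested {k} scores, model holds {model.rank}")
    Xd = X - model.x_mean
    T = np.zeros((X.shape[0], k))
    for a in range(k):
        t = Xd @ model.W[:, a]
        Xd -= np.outer(t, model.P[:, a])
        T[:, a] = t
    return T


@dataclass(frozen=True)
class LOOCVResult:
    """Leave-one-out curve over ranks 0..A_max.

    ``rmsecv[a]`` / ``r2[a]`` correspond to rank ``ranks[a]``; rank 0 is
    the leave-one-out mean (null model).  ``predictions[i, a]`` is the
    held-out prediction for sample i at rank ``ranks[a]``.
    """

    ranks: np.ndarray
    rmsecv: np.ndarray
    r2: np.ndarray
    predictions: np.ndarray

    def curve(self) -> np.ndarray:
        """RMSECV for ranks 1..A_max (drops the rank-0 null model)."""
        return self.rmsecv[1:]


def _prepare_fold(spectra_or_X, steps):
    """Normalize input: SpectraSet + chain, or a plain matrix (no chain)."""
    if isinstance(spectra_or_X, SpectraSet):
        return spectra_or_X, tuple(steps or ())
    X = np.asarray(spectra_or_X, dtype=float)
    if steps:
        raise ValueError("pretreatment chains require a SpectraSet input")
    return X, ()


def loocv_curve(spectra_or_X, y: np.ndarray, A_max: int,
                pretreatment: Sequence = ()) -> LOOCVResult:
    """LOOCV over ranks 0..A_max with full per-fold refit.

    For each left-out sample the pretreatment state (e.g. MSC reference),
    the centering and the PLS factorization are all re-estimated on the
    remaining n-1 samples; the left-out spectrum is pushed through that
    frozen fold pipeline.  RMSECV(a) = sqrt(mean((y_i - yhat_{-i}(a))^2)).
    """
    data, steps = _prepare_fold(spectra_or_X, pretreatment)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    is_set = isinstance(data, SpectraSet)
    if (data.n_samples if is_set else data.shape[0]) != n:
        raise ValueError("X and y sample counts differ")
    A_max = min(A_max, n - 2, (data.grid.n_points if is_set else data.shape[1]))
    preds = np.zeros((n, A_max + 1))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if is_set:
            train_ids = [s for j, s in enumerate(data.sample_ids) if keep[j]]
            train_set = data.subset(train_ids)
            test_set = data.subset([data.sample_ids[i]])
            train_t, state = apply_pretreatments(train_set, steps)
            test_t, _ = apply_pretreatments(test_set, steps, state)
            Xtr, Xte = train_t.absorbance, test_t.absorbance
        else:
            Xtr, Xte = data[keep], data[i:i + 1]
        model = fit_pls(Xtr, y[keep], A_max)
        for a in range(A_max + 1):
            preds[i, a] = pls_predict(model, Xte, min(a, model.rank))[0]
    resid = preds - y[:, None]
    rmsecv = np.sqrt((resid ** 2).mean(axis=0))
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 100.0 * (1.0 - (resid ** 2).sum(axis=0) / sst)
    return LOOCVResult(np.arange(A_max + 1), rmsecv, r2, preds)


def select_rank(rmsecv: np.ndarray, rmsep: np.ndarray) -> int:
    """Rank (1-indexed) minimizing RMSECV(a) + RMSEP(a); ties go to the
    smaller rank.  Input curves start at rank 1."""
    rmsecv = np.asarray(rmsecv, dtype=float)
    rmsep = np.asarray(rmsep, dtype=float)
    if rmsecv.shape != rmsep.shape or rmsecv.size < 1:
        raise ValueError("curves must have equal non-zero length")
    return int(np.argmin(rmsecv + rmsep)) + 1


@dataclass(frozen=True)
class IntervalSet:
    """Contiguous, non-overlapping wavenumber windows covering a range.

    Each interval is (lo, hi) in cm^-1 with lo < hi, ordered high to low
    (matching the spectral storage order).
    """

    intervals: tuple

    def __post_init__(self) -> None:
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for lo, hi in ivs:
            if not lo < hi:
                raise ValueError(f"interval ({lo}, {hi}) has lo >= hi")
        for (lo1, _), (_, hi2) in zip(ivs, ivs[1:]):
            if hi2 > lo1 + 1e-9:
                raise ValueError("intervals overlap or are out of order")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def union_bounds(self, members: Sequence[int]) -> tuple[float, float]:
        los = [self.intervals[m][0] for m in members]
        his = [self.intervals[m][1] for m in members]
        return min(los), max(his)


def divide_intervals(window: tuple[float, float], n_intervals: int = 5,
                     edges: Sequence[float] | None = None) -> IntervalSet:
    """Split a working range into sub-windows for SiPLS.

    By default ``n_intervals`` equal-width contiguous pieces; explicit
    ``edges`` (any order) override the equal division, for instruments
    whose automatic division is not equal-width.
    """
    lo, hi = sorted(map(float, window))
    if edges is not None:
        e = sorted(set(float(v) for v in edges), reverse=True)
        if len(e) < 2:
            raise ValueError("need at least two edges")
        return IntervalSet(tuple((e[i + 1], e[i]) for i in range(len(e) - 1)))
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    cuts = np.linspace(hi, lo, n_intervals + 1)
    return IntervalSet(tuple((float(cuts[i + 1]), float(cuts[i]))
                             for i in range(n_intervals)))


def interval_mask(grid: WavenumberGrid, intervals: IntervalSet,
                  members: Sequence[int]) -> np.ndarray:
    """Boolean column mask selecting grid points inside the chosen intervals.

    Interval edges are treated as half-open (lo, hi]; the lowest interval
    additionally keeps its bottom edge — so adjacent intervals never
    share an on-grid column and the union over all intervals is exactly
    the working window.
    """
    v = grid.values
    mask = np.zeros(v.size, dtype=bool)
    last = len(intervals.intervals) - 1
    for m in members:
        lo, hi = intervals.intervals[m]
        sel = (v > lo + 1e-9) & (v <= hi + 1e-9)
        if m == last:  # lowest interval: include its bottom edge
            sel |= np.abs(v - lo) <= 1e-9
        mask |= sel
    return mask


@dataclass(frozen=True)
class SiPLSRecord:
    """One evaluated interval combination in a SiPLS search."""

    members: tuple
    bounds: tuple
    n_variables: int
    rank: int
    rmsecv: float
    r2_cv: float
    rmsep_val: float
    r2_val: float


def sipls_search(cal_spectra: SpectraSet, y_cal: np.ndarray,
                 intervals: IntervalSet, A_max: int,
                 val_spectra: SpectraSet, y_val: np.ndarray,
                 pretreatment: Sequence = ()) -> tuple[SiPLSRecord, list[SiPLSRecord]]:
    """Exhaustive synergy-interval PLS search.

    All 2^k - 1 non-empty interval combinations are evaluated: columns
    are restricted to the union, LOOCV screens the rank (RMSECV-minimal,
    ties to the smaller rank), and external validation on
    ``val_spectra`` is recorded.  The winner minimizes RMSECV at its
    selected rank; ties prefer fewer intervals, then lower rank.
    Validation metrics are reported, not optimized.
    """
    if len(intervals) < 1:
        raise ValueError("need at least one interval")
    y_val = np.asarray(y_val, dtype=float).ravel()
    if val_spectra.n_samples == 0 or y_val.size != val_spectra.n_samples:
        raise ValueError("validation set empty or mismatched")
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    steps = tuple(pretreatment or ())

    cal_t, state = apply_pretreatments(cal_spectra, steps)
    val_t, _ = apply_pretreatments(val_spectra, steps, state)

    records: list[SiPLSRecord] = []
    k = len(intervals)
    for r in range(1, k + 1):
        for members in itertools.combinations(range(k), r):
            mask = interval_mask(cal_spectra.grid, intervals, members)
            if not mask.any():
                continue
            Xc = cal_t.absorbance[:, mask]
            Xv = val_t.absorbance[:, mask]
            cv = loocv_curve(Xc, y_cal, A_max)
            rank = int(np.argmin(cv.rmsecv[1:])) + 1
            model = fit_pls(Xc, y_cal, rank)
            yhat = pls_predict(model, Xv, min(rank, model.rank))
            rmsep = float(np.sqrt(np.mean((yhat - y_val) ** 2)))
            r2v = 100.0 * (1.0 - ((yhat - y_val) ** 2).sum()
                           / ((y_val - y_val.mean()) ** 2).sum())
            records.append(SiPLSRecord(
                members=members,
                bounds=intervals.union_bounds(members),
                n_variables=int(mask.sum()),
                rank=rank,
                rmsecv=float(cv.rmsecv[rank]),
                r2_cv=float(cv.r2[rank]),
                rmsep_val=rmsep,
                r2_val=r2v,
            ))
    best = min(records, key=lambda rec: (rec.rmsecv, len(rec.members), rec.rank))
    return best, records
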