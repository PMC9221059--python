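"""Mutual-information network inference by adaptive partitioning.

The estimator works on copula-transformed data: each protein's profile is
mapped to ranks ``1/N .. 1`` (uniform marginals on the unit interval), so
the joint density of a pair lives on the unit square and its MI equals the
negative copula entropy.  Adaptive partitioning estimates it by recursively
quad-splitting the square at cell midpoints: a cell holding ``n`` points is
split when a chi-square test rejects local uniformity across its four
quadrants (``X^2 = sum (n_q - n/4)^2 / (n/4)`` against a critical value,
default the 95% point at 3 df) and ``n`` is at least ``min_points``;
otherwise the cell is a leaf contributing the plug-in term
``(n/N) * ln[(n/N) / area]``.  The sum over leaves is the MI in nats,
floored at zero.

Edge significance comes from a permutation null: MI is computed for many
pairs in which one profile is randomly permuted, and the tail of the pooled
null distribution is summarised by a linear law ``log10 P(MI >= x) = a + b x``
fitted to the top tail.  The fitted line extrapolates p-values far below the
empirical floor, which is what a cutoff as strict as ``p < 1e-8`` requires
at feasible permutation counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import rankdata

from .errors import CalibrationError, InputError
from .matrix import ExpressionMatrix
from .network import Network

logger = logging.getLogger(__name__)

#: chi-square critical value at 95%, 3 degrees of freedom
CHI2_CRIT = 7.814727903251179
MIN_POINTS = 8
_MAX_DEPTH = 60  # bounds recursion when duplicated coordinates stall splitting


@njit(cache=True)
def _apmi_kernel(x, y, chi2_crit, min_points):  # pragma: no cover - numba
    n = x.shape[0]
    tx = np.empty(n, np.float64)
    ty = np.empty(n, np.float64)
    cap = 16 * _MAX_DEPTH
    slo = np.empty(cap, np.int64)
    shi = np.empty(cap, np.int64)
    sx0 = np.empty(cap, np.float64)
    sx1 = np.empty(cap, np.float64)
    sy0 = np.empty(cap, np.float64)
    sy1 = np.empty(cap, np.float64)
    sd = np.empty(cap, np.int64)
    slo[0] = 0
    shi[0] = n
    sx0[0] = 0.0
    sx1[0] = 1.0
    sy0[0] = 0.0
    sy1[0] = 1.0
    sd[0] = 0
    top = 1
    mi = 0.0
    while top > 0:
        top -= 1
        lo = slo[top]
        hi = shi[top]
        x0 = sx0[top]
        x1 = sx1[top]
        y0 = sy0[top]
        y1 = sy1[top]
        depth = sd[top]
        m = hi - lo
        xm = 0.5 * (x0 + x1)
        ym = 0.5 * (y0 + y1)
        c1 = 0
        c2 = 0
        c3 = 0
        c4 = 0
        for i in range(lo, hi):
            if x[i] <= xm:
                if y[i] <= ym:
                    c1 += 1
                else:
                    c2 += 1
            else:
                if y[i] <= ym:
                    c3 += 1
                else:
                    c4 += 1
        e = m / 4.0
        chi2 = ((c1 - e) ** 2 + (c2 - e) ** 2 + (c3 - e) ** 2 + (c4 - e) ** 2) / e
        if m >= min_points and chi2 > chi2_crit and depth < _MAX_DEPTH:
            o1 = lo
            o2 = o1 + c1
            o3 = o2 + c2
            o4 = o3 + c3
            p1 = o1
            p2 = o2
            p3 = o3
            p4 = o4
            for i in range(lo, hi):
                if x[i] <= xm:
                    if y[i] <= ym:
                        tx[p1] = x[i]
                        ty[p1] = y[i]
                        p1 += 1
                    else:
                        tx[p2] = x[i]
                        ty[p2] = y[i]
                        p2 += 1
                else:
                    if y[i] <= ym:
                        tx[p3] = x[i]
                        ty[p3] = y[i]
                        p3 += 1
                    else:
                        tx[p4] = x[i]
                        ty[p4] = y[i]
                        p4 += 1
            for i in range(lo, hi):
                x[i] = tx[i]
                y[i] = ty[i]
            if c1 > 0:
                slo[top] = o1; shi[top] = o2
                sx0[top] = x0; sx1[top] = xm; sy0[top] = y0; sy1[top] = ym
                sd[top] = depth + 1
                top += 1
            if c2 > 0:
                slo[top] = o2; shi[top] = o3
                sx0[top] = x0; sx1[top] = xm; sy0[top] = ym; sy1[top] = y1
                sd[top] = depth + 1
                top += 1
            if c3 > 0:
                slo[top] = o3; shi[top] = o4
                sx0[top] = xm; sx1[top] = x1; sy0[top] = y0; sy1[top] = ym
                sd[top] = depth + 1
                top += 1
            if c4 > 0:
                slo[top] = o4; shi[top] = hi
                sx0[top] = xm; sx1[top] = x1; sy0[top] = ym; sy1[top] = y1
                sd[top] = depth + 1
                top += 1
        else:
            pr = m / n
            area = (x1 - x0) * (y1 - y0)
            mi += pr * np.log(pr / area)
    if mi < 0.0:
        mi = 0.0
    return mi


@njit(cache=True)
def _all_pairs_kernel(R, chi2_crit, min_points):  # pragma: no cover - numba
    n = R.shape[0]
    out = np.empty(n * (n - 1) // 2, np.float64)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            x = R[i].copy()
            y = R[j].copy()
            out[idx] = _apmi_kernel(x, y, chi2_crit, min_points)
            idx += 1
    return out


def apmi(x, y, chi2_crit: float = CHI2_CRIT, min_points: int = MIN_POINTS) -> float:
    """Adaptive-partitioning MI (nats) of two rank vectors on (0, 1].

    Symmetric in its arguments and deterministic.  Inputs are expected to be
    copula-transformed (see :func:`copula_rank_transform`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"x and y must be 1-d and same length, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise InputError("need at least 2 observations")
    if np.any((x <= 0) | (x > 1)) or np.any((y <= 0) | (y > 1)):
        raise InputError("values must lie in (0, 1]; apply copula_rank_transform first")
    return float(_apmi_kernel(x.copy(), y.copy(), float(chi2_crit), int(min_points)))


def copula_rank_transform(m: ExpressionMatrix | pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Row-wise rank/N transform with seeded jitter tie-breaking.

    Each row of the result is a permutation of ``{1/N, ..., 1}``.  Ties are
    broken by adding a jitter many orders of magnitude below the data scale
    before ranking, drawn from a generator seeded with ``seed``, so the
    output is reproducible.  A constant row triggers a warning; the jitter
    alone then decides its (arbitrary but reproducible) ordering.
    """
    values = m.values if isinstance(m, ExpressionMatrix) else m
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise InputError("matrix has missing values; impute before rank transform")
    n = arr.shape[1]
    rng = np.random.default_rng(seed)
    scale = np.ptp(arr, axis=1)
    n_const = int((scale == 0).sum())
    if n_const:
        logger.warning("%d constant rows; rank order decided by seeded jitter", n_const)
    jitter_scale = np.where(scale > 0, scale, 1.0) * 1e-10
    jittered = arr + rng.uniform(-0.5, 0.5, size=arr.shape) * jitter_scale[:, None]
    ranks = np.apply_along_axis(lambda r: rankdata(r, method="ordinal"), 1, jittered)
    return pd.DataFrame(ranks / n, index=values.index, columns=values.columns)


@dataclass(frozen=True)
class NullModel:
    """Permutation null for MI: empirical survival plus a fitted tail law.

    The adaptive-partitioning null at copula margins is highly discrete —
    under independence the root chi-square test rarely rejects, so most
    null MI values are exactly zero and the positive part is a mixture of
    atoms (shallow recursions) that only smooths out deep in the tail.
    P-values are therefore estimated from the empirical survival function
    wherever at least ``min_tail_count`` permutation values support it, and
    from the fitted tail law ``log10 P(MI >= x) = intercept + slope * x``
    below that floor — extrapolation is the fitted line's only job, and it
    is what a cutoff such as 1e-8 requires.

    ``tail_values``/``tail_surv`` hold the distinct positive null MI values
    (ascending) and the fraction of permutations at or above each.
    """

    intercept: float
    slope: float
    n_samples: int
    n_perm: int
    seed: int
    r2: float
    tail_values: np.ndarray
    tail_surv: np.ndarray
    tail_frac: float = 0.05
    min_tail_count: int = 50

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise CalibrationError(
                f"null tail slope must be negative, got {self.slope}; "
                "increase the permutation count"
            )
        object.__setattr__(self, "tail_values", np.asarray(self.tail_values, dtype=float))
        object.__setattr__(self, "tail_surv", np.asarray(self.tail_surv, dtype=float))

    @property
    def p_switch(self) -> float:
        """Below this p the empirical survival runs out and the line takes over."""
        return self.min_tail_count / self.n_perm

    def _line(self, mi):
        with np.errstate(over="ignore"):
            return np.power(10.0, self.intercept + self.slope * mi)

    def p_of_mi(self, mi):
        """Estimated p-value(s) for observed MI, clipped to (0, 1].

        MI <= 0 carries no evidence against independence (p = 1).
        """
        mi = np.asarray(mi, dtype=float)
        scalar = mi.ndim == 0
        mi = np.atleast_1d(mi)
        idx = np.searchsorted(self.tail_values, mi, side="left")
        in_range = idx < len(self.tail_values)
        p_emp = np.where(in_range, self.tail_surv[np.minimum(idx, len(self.tail_values) - 1)], 0.0)
        use_line = ~in_range | (p_emp < self.p_switch)
        p = np.where(use_line, np.minimum(self._line(mi), self.p_switch), p_emp)
        p = np.where(mi <= 0, 1.0, p)
        p = np.clip(p, 1e-300, 1.0)
        return float(p[0]) if scalar else p

    def mi_at_p(self, p: float) -> float:
        """Smallest MI whose estimated p-value is at or below ``p``."""
        if not 0 < p <= 1:
            raise InputError(f"p must be in (0, 1], got {p}")
        if p < self.p_switch:
            return (math.log10(p) - self.intercept) / self.slope
        below = np.flatnonzero(self.tail_surv <= p)
        if below.size:
            return float(self.tail_values[below[0]])
        return (math.log10(p) - self.intercept) / self.slope

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "n_samples": self.n_samples,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "r2": self.r2,
            "tail_values": list(map(float, self.tail_values)),
            "tail_surv": list(map(float, self.tail_surv)),
            "tail_frac": self.tail_frac,
            "min_tail_count": self.min_tail_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NullModel":
        d = dict(d)
        d["tail_values"] = np.asarray(d["tail_values"], dtype=float)
        d["tail_surv"] = np.asarray(d["tail_surv"], dtype=float)
        return cls(**d)


def null_mi_samples(
    ranked: pd.DataFrame,
    n_perm: int,
    seed: int,
    chi2_crit: float = CHI2_CRIT,
    min_points: int = MIN_POINTS,
) -> np.ndarray:
    """MI values for ``n_perm`` random pairs with one profile permuted."""
    R = np.ascontiguousarray(ranked.to_numpy(dtype=float))
    n_prot, n_samp = R.shape
    if n_samp < 8:
        raise InputError(f"need >= 8 samples for null calibration, got {n_samp}")
    if n_prot < 2:
        raise InputError("need >= 2 proteins")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_perm)
    for t in range(n_perm):
        i = int(rng.integers(n_prot))
        j = int(rng.integers(n_prot - 1))
        if j >= i:
            j += 1
        x = R[i].copy()
        y = rng.permutation(R[j])
        vals[t] = _apmi_kernel(x, y, chi2_crit, min_points)
    return vals


def fit_null_tail(null_mi: np.ndarray, tail_frac: float = 0.05):
    """Summarise the null tail: distinct survival points plus a line fit.

    The fit window is the top ``tail_frac`` of the pooled null values,
    restricted to positive MI (the atom at zero carries no tail
    information).  One regression point per distinct MI value —
    ``log10 P(MI >= v)`` against ``v`` — keeps the handful of heavy
    shallow-recursion atoms from dominating the slope.

    Returns ``(intercept, slope, r2, tail_values, tail_surv)`` where the
    arrays cover all distinct positive values (ascending).
    """
    v = np.asarray(null_mi, dtype=float)
    M = v.size
    vals, counts = np.unique(v[v > 0], return_counts=True)
    if vals.size < 3:
        raise CalibrationError(
            f"only {vals.size} distinct positive null MI values; "
            "increase the permutation count"
        )
    surv = counts[::-1].cumsum()[::-1] / M  # P(MI >= vals[i])
    k_tail = max(int(math.ceil(tail_frac * M)), 50)
    in_window = surv <= (k_tail / M)
    if in_window.sum() < 3:
        in_window = np.ones_like(in_window, dtype=bool)
    x = vals[in_window]
    logs = np.log10(surv[in_window])
    slope, intercept = np.polyfit(x, logs, 1)
    pred = intercept + slope * x
    ss_res = float(np.sum((logs - pred) ** 2))
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(intercept), float(slope), r2, vals, surv


def calibrate_null(
    ranked: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
    tail_frac: float = 0.05,
    chi2_crit: float = CHI2_CRIT,
    min_points: int = MIN_POINTS,
) -> NullModel:
    """Permutation-calibrate the MI null for this matrix's sample count.

    ``n_perm >= 1e5`` is recommended so the fitted 5% tail rests on several
    thousand points.  Raises :class:`CalibrationError` when the fitted slope
    is not negative (degenerate null).
    """
    if n_perm < 1000:
        logger.warning("n_perm=%d is very small; the tail fit will be noisy", n_perm)
    vals = null_mi_samples(ranked, n_perm, seed, chi2_crit, min_points)
    intercept, slope, r2, tail_values, tail_surv = fit_null_tail(vals, tail_frac)
    logger.info(
        "null tail fit: log10 p = %.3f %+.3f * MI (R^2 = %.4f)", intercept, slope, r2
    )
    return NullModel(
        intercept=intercept,
        slope=slope,
        n_samples=ranked.shape[1],
        n_perm=n_perm,
        seed=seed,
        r2=r2,
        tail_values=tail_values,
        tail_surv=tail_surv,
        tail_frac=tail_frac,
    )


def pairwise_mi(
    ranked: pd.DataFrame,
    chi2_crit: float = CHI2_CRIT,
    min_points: int = MIN_POINTS,
) -> np.ndarray:
    """Condensed vector of MI over all protein pairs (scipy pdist order)."""
    R = np.ascontiguousarray(ranked.to_numpy(dtype=float))
    return _all_pairs_kernel(R, float(chi2_crit), int(min_points))


def infer_network(
    m: ExpressionMatrix | pd.DataFrame,
    null: NullModel,
    p_thresh: float = 1e-8,
    seed: int | None = None,
    chi2_crit: float = CHI2_CRIT,
    min_points: int = MIN_POINTS,
) -> Network:
    """All-pairs MI network thresholded at ``p < p_thresh``.

    ``m`` may be a raw :class:`ExpressionMatrix` (rank-transformed here,
    using ``seed`` or the null model's seed) or an already rank-transformed
    DataFrame.  The null model must have been calibrated at the same sample
    count.  All input proteins become nodes; proteins whose every pair falls
    below threshold are isolated nodes.
    """
    if isinstance(m, ExpressionMatrix):
        ranked = copula_rank_transform(m, seed=null.seed if seed is None else seed)
    else:
        ranked = m
    if ranked.shape[1] != null.n_samples:
        raise InputError(
            f"null model calibrated for {null.n_samples} samples, matrix has {ranked.shape[1]}"
        )
    proteins = list(ranked.index.astype(str))
    mi = pairwise_mi(ranked, chi2_crit, min_points)
    p = null.p_of_mi(mi)
    keep = p < p_thresh
    iu = np.triu_indices(len(proteins), k=1)
    idx_a = iu[0][keep]
    idx_b = iu[1][keep]
    edges = pd.DataFrame(
        {
            "protein_a": np.asarray(proteins, dtype=object)[idx_a],
            "protein_b": np.asarray(proteins, dtype=object)[idx_b],
            "mi": mi[keep],
            "p": p[keep],
        }
    )
    edges = edges.sort_values("mi", ascending=False, kind="mergesort").reset_index(drop=True)
    return Network(
        edges,
        nodes=sorted(proteins),
        provenance={
            "p_threshold": p_thresh,
            "n_pairs_tested": int(mi.size),
            "null": null.to_dict(),
        },
    )


def apply_dpi(net: Network, tolerance: float = 0.0) -> Network:
    """Data-processing-inequality pruning of indirect edges.

    For every triangle the weakest edge is marked when its MI is strictly
    below ``min(other two) * (1 - tolerance)``; all marked edges are removed
    simultaneously.  With tolerance 0 ties survive (strict inequality) and
    the operation is idempotent.
    """
    if not 0.0 <= tolerance < 1.0:
        raise InputError(f"tolerance must be in [0, 1), got {tolerance}")
    mi_of: dict[tuple[str, str], float] = {}
    adj: dict[str, set[str]] = {}
    for a, b, w in zip(net.edges["protein_a"], net.edges["protein_b"], net.edges["mi"]):
        mi_of[(a, b)] = float(w)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def _mi(u: str, v: str) -> float:
        return mi_of[(u, v)] if u < v else mi_of[(v, u)]

    doomed: set[tuple[str, str]] = set()
    for (a, b), w in mi_of.items():
        for c in adj[a] & adj[b]:
            if w < min(_mi(a, c), _mi(b, c)) * (1.0 - tolerance):
                doomed.add((a, b))
                break
    keep = [
        (a, b) not in doomed
        for a, b in zip(net.edges["protein_a"], net.edges["protein_b"])
    ]
    prov = dict(net.provenance)
    prov.update({"dpi_tolerance": tolerance, "dpi_removed": len(doomed)})
    return Network(net.edges[keep].copy(), nodes=list(net.nodes), provenance=prov)


def top_k_edges(net: Network, k: int = 10_000) -> Network:
    """Keep the k highest-MI edges; ties with the k-th value are all kept."""
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    edges = net.edges.sort_values(
        ["mi", "protein_a", "protein_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    if len(edges) > k:
        thresh = edges["mi"].iloc[k - 1]
        edges = edges[edges["mi"] >= thresh]
        if len(edges) > k:
            logger.info("top-k tie at MI=%.6g: keeping %d edges for k=%d", thresh, len(edges), k)
    prov = dict(net.provenance)
    prov["top_k"] = k
    return Network(edges.copy(), nodes=list(net.nodes), provenance=prov)
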