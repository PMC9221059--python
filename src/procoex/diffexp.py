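"""Two-group differential expression with empirical-Bayes variance moderation.

The model is the standard moderated t-statistic for a tumor-vs-healthy
contrast: per protein ``g``, an ordinary two-sample fit gives the log2 fold
change ``lfc_g`` and pooled within-group variance ``s2_g`` on
``df = n1 + n2 - 2`` residual degrees of freedom.  Variances are assumed
exchangeable, ``s2_g ~ s0^2 * F(df, d0)``, and the hyperparameters
``(d0, s0^2)`` are estimated by the method of moments on log variances:
with ``e_g = log s2_g``,

    trigamma(d0 / 2) = var(e) - trigamma(df / 2)
    log s0^2 = mean(e) - digamma(df / 2) + log(df / 2)
                        + digamma(d0 / 2) - log(d0 / 2)

When the empirical spread of ``e`` does not exceed what sampling alone
explains, ``d0`` is infinite and all proteins share ``s0^2``.  The posterior
variance ``s2_post = (d0 * s0^2 + df * s2) / (d0 + df)`` shrinks each
protein's variance towards the prior, and

    t_mod = lfc / sqrt(s2_post * (1/n1 + 1/n2))

is referred to a t-distribution on ``d0 + df`` degrees of freedom
(two-sided).  Multiple testing is controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EBayesHyper:
    """Prior degrees of freedom and prior variance of the variance model."""

    d0: float  # may be math.inf when variances are homogeneous
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise InputError(f"d0 must be > 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise InputError(f"s0_sq must be > 0, got {self.s0_sq}")


def fit_two_group(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-protein lfc, pooled variance and residual df for tumor vs healthy.

    ``lfc = mean(tumor) - mean(healthy)`` in the (log2) units of the input
    matrix; ``s2`` is the pooled within-group variance on
    ``n_tumor + n_healthy - 2`` degrees of freedom.  Requires a complete
    matrix and at least two samples per group.
    """
    tumor = m.samples_in_group("tumor")
    healthy = m.samples_in_group("healthy")
    if len(tumor) < 2 or len(healthy) < 2:
        raise InputError(
            f"need >= 2 samples per group, got {len(tumor)} tumor / {len(healthy)} healthy"
        )
    if m.values.isna().any().any():
        raise InputError("matrix has missing values; impute or filter first")

    xt = m.values[tumor].to_numpy()
    xh = m.values[healthy].to_numpy()
    n1, n2 = xt.shape[1], xh.shape[1]
    lfc = xt.mean(axis=1) - xh.mean(axis=1)
    s2 = ((n1 - 1) * xt.var(axis=1, ddof=1) + (n2 - 1) * xh.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    return pd.DataFrame(
        {"lfc": lfc, "s2": s2, "df_resid": n1 + n2 - 2},
        index=m.values.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return math.inf
    return float(
        optimize.brentq(lambda x: special.polygamma(1, x) - y, 1e-9, 1e9, xtol=1e-12)
    )


def estimate_hyperparams(s2, df_resid: int) -> EBayesHyper:
    """Method-of-moments fit of (d0, s0^2) from the observed variances.

    Zero or non-finite variances are excluded from the fit; at least 10
    positive variances are required for the moments to be usable.
    """
    s2 = np.asarray(s2, dtype=float)
    usable = s2[np.isfinite(s2) & (s2 > 0)]
    if usable.size < 10:
        raise InputError(
            f"only {usable.size} proteins with positive variance; "
            "need >= 10 to estimate moderation hyperparameters"
        )
    df = float(df_resid)
    e = np.log(usable)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    emean = e.mean() - special.polygamma(0, df / 2.0) + math.log(df / 2.0)
    if evar <= 0:
        return EBayesHyper(d0=math.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(float(evar))
    s0_sq = float(np.exp(emean + special.polygamma(0, d0 / 2.0) - math.log(d0 / 2.0)))
    return EBayesHyper(d0=d0, s0_sq=s0_sq)


def moderated_t(lfc, s2, df_resid: int, hyper: EBayesHyper, n1: int, n2: int):
    """Moderated t statistics and two-sided p-values.

    Limit behaviour: ``d0 -> 0`` recovers the ordinary pooled two-sample t;
    ``d0 = inf`` uses the common prior variance for every protein (normal
    reference).  A posterior variance of exactly zero (exact separation with
    zero spread everywhere) yields ``p = 0`` with a warning.
    """
    lfc = np.asarray(lfc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = float(df_resid)
    if math.isinf(hyper.d0):
        s2_post = np.full_like(s2, hyper.s0_sq)
        df_total = math.inf
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + df * s2) / (hyper.d0 + df)
        df_total = hyper.d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.sign(lfc) * np.inf)
    if np.any(se == 0):
        logger.warning("%d proteins with zero posterior variance: p set to 0", int((se == 0).sum()))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se == 0, 0.0, np.minimum(p, 1.0))
    return t, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_diffexp(m: ExpressionMatrix) -> pd.DataFrame:
    """Full DE table: lfc, s2, moderated t, p, BH q and expression sign.

    ``sign`` is +1 for overexpressed (lfc >= 0, zero mapping to +1 by
    convention so labels are binary) and -1 for underexpressed.
    """
    fit = fit_two_group(m)
    n1 = len(m.samples_in_group("tumor"))
    n2 = len(m.samples_in_group("healthy"))
    hyper = estimate_hyperparams(fit["s2"], int(fit["df_resid"].iloc[0]))
    t, p = moderated_t(fit["lfc"], fit["s2"], int(fit["df_resid"].iloc[0]), hyper, n1, n2)
    q = bh_adjust(p)
    out = fit.copy()
    out["t_mod"] = t
    out["p"] = p
    out["q"] = q
    out["sign"] = np.where(out["lfc"] < 0, -1, 1)
    out.attrs["hyper"] = hyper
    return out


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="pGene")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
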