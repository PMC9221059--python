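"""Quality-control filters applied to the abundance matrix before inference.

The pipeline applies them in a fixed order: missingness filter, removal of
decay-flagged samples, completeness in the healthy (control) group, then
median imputation of whatever gaps remain.  Each filter is idempotent.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import InputError
from .matrix import GROUPS, ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_pgenes_by_missingness(
    m: ExpressionMatrix, max_missing: int = 60, max_missing_fraction: float | None = None
) -> ExpressionMatrix:
    """Drop proteins missing in more than ``max_missing`` samples.

    The threshold is an absolute sample count (default 60).  Pass
    ``max_missing_fraction`` instead to express it as a fraction of the
    matrix width, for matrices of other sizes.
    """
    if max_missing_fraction is not None:
        max_missing = int(np.floor(max_missing_fraction * m.n_samples))
    if max_missing < 0:
        raise InputError("max_missing must be >= 0")
    counts = m.missing_mask.sum(axis=1)
    keep = counts.index[counts <= max_missing]
    if len(keep) == 0:
        logger.warning("missingness filter removed every protein")
    return m.select_proteins(keep)


def drop_flagged_samples(m: ExpressionMatrix, flagged) -> ExpressionMatrix:
    """Remove samples flagged as unreliable (e.g. significant protein decay)."""
    flagged = set(flagged)
    unknown = flagged - set(m.sample_ids)
    if unknown:
        raise InputError(f"flagged sample ids not in matrix: {sorted(unknown)}")
    keep = [s for s in m.sample_ids if s not in flagged]
    return m.select_samples(keep)


def require_complete_in_group(m: ExpressionMatrix, group: str = "healthy") -> ExpressionMatrix:
    """Keep only proteins measured in every sample of ``group``.

    With only a handful of control samples, a protein unobserved in any of
    them cannot be contrasted against tumors at all, hence the hard rule.
    """
    if group not in GROUPS:
        raise InputError(f"unknown group {group!r}; expected one of {GROUPS}")
    samples = m.samples_in_group(group)
    if not samples:
        raise InputError(f"group {group!r} has no samples")
    complete = ~m.values[samples].isna().any(axis=1)
    return m.select_proteins(complete.index[complete])


def impute_missing(m: ExpressionMatrix) -> ExpressionMatrix:
    """Fill remaining gaps with the per-protein median of observed values.

    Downstream mutual-information estimation works on ranks, so any monotone
    per-protein fill is equivalent up to tie handling; the median keeps the
    imputed value inside the observed range.  Observed values are never
    altered.
    """
    values = m.values.copy()
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        raise InputError(
            f"proteins with no observed values: {list(values.index[all_missing])}"
        )
    medians = values.median(axis=1)
    values = values.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    return ExpressionMatrix(values, m.groups)


def qc_report(before: ExpressionMatrix, after: ExpressionMatrix) -> dict:
    """Summarise a QC pass for the run directory."""
    return {
        "proteins_before": before.n_proteins,
        "proteins_after": after.n_proteins,
        "samples_before": before.n_samples,
        "samples_after": after.n_samples,
        "missing_before": before.n_missing,
        "missing_after": after.n_missing,
    }
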