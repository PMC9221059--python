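"""The root data container: a proteins x samples abundance matrix.

Rows are gene-symbol protein identifiers ("pGenes": gene-level identifiers
inferred from protein abundance), columns are samples, values are log-ratio
abundances.  Missing measurements are carried as NaN; sample group labels
(tumor / healthy) live alongside the matrix so two-group contrasts and
group-completeness filters can be expressed on the object itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

TUMOR = "tumor"
HEALTHY = "healthy"
GROUPS = (TUMOR, HEALTHY)


@dataclass
class ExpressionMatrix:
    """Proteins x samples log-abundance matrix with missing mask and groups.

    Parameters
    ----------
    values
        DataFrame indexed by unique upper-case protein symbols with unique
        sample-id columns; NaN marks a missing measurement.
    groups
        Optional Series mapping every sample id to ``"tumor"`` or
        ``"healthy"``.  Operations that contrast groups raise
        :class:`~procoex.errors.InputError` when it is absent.
    """

    values: pd.DataFrame
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        dup_p = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_p):
            raise FormatError(f"duplicate protein identifiers: {sorted(dup_p)}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_s):
            raise FormatError(f"duplicate sample identifiers: {sorted(dup_s)}")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)
            if self.groups.isna().any():
                missing = list(self.groups.index[self.groups.isna()])
                raise InputError(f"samples without a group label: {missing}")
            bad = set(self.groups.unique()) - set(GROUPS)
            if bad:
                raise InputError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")

    # -- basic accessors -------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the measurement is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def group_of(self, sample_id: str) -> str:
        if self.groups is None:
            raise InputError("matrix has no sample group labels attached")
        return str(self.groups.loc[sample_id])

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise InputError(f"unknown group {group!r}; expected one of {GROUPS}")
        if self.groups is None:
            raise InputError("matrix has no sample group labels attached")
        return list(self.groups.index[self.groups == group])

    # -- derived constructors --------------------------------------------
    def select_proteins(self, proteins) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(proteins)].copy(), self.groups)

    def select_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        groups = self.groups.loc[samples] if self.groups is not None else None
        return ExpressionMatrix(self.values[samples].copy(), groups)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)
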