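"""Readers and writers for the pipeline's plain-text formats.

Formats handled here:

* expression matrix — TSV, first column protein symbol, header row of sample
  ids, empty cells or NA tokens mark missing measurements;
* sample metadata — TSV with columns ``sample_id``, ``group``, ``flagged``;
* chromosome map — two-column TSV (gene symbol, chromosome label);
* gene-set collections — standard GMT (set name, description, member genes).

Gene symbols are upper-cased on input so downstream joins never depend on
source-specific capitalisation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .matrix import GROUPS, ExpressionMatrix

logger = logging.getLogger(__name__)

NA_TOKENS = {"", "NA", "N/A", "NAN", "NULL", "NONE"}


def _is_missing(token: str) -> bool:
    return token.strip().upper() in NA_TOKENS


def read_expression_matrix(path, metadata=None) -> ExpressionMatrix:
    """Read a proteins x samples TSV; NA tokens and empty cells become NaN.

    ``metadata`` may be a path to a sample-metadata TSV or a Series of group
    labels; when omitted the matrix carries no group information.

    Raises
    ------
    FormatError
        On duplicate protein symbols (listing them) or a non-numeric cell
        (naming its row and column).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str).str.strip().str.upper()
    dup = raw.index[raw.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path.name}: duplicate protein identifiers: {sorted(dup)}")

    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        tokens = raw[col]
        keep = ~tokens.map(_is_missing)
        try:
            values.loc[keep, col] = tokens[keep].astype(float)
        except ValueError:
            for protein, token in tokens[keep].items():
                try:
                    float(token)
                except ValueError:
                    raise FormatError(
                        f"{path.name}: non-numeric value {token!r} "
                        f"at row {protein!r}, column {col!r}"
                    ) from None

    groups = None
    if metadata is not None:
        if isinstance(metadata, (str, Path)):
            meta = read_sample_metadata(metadata)
            groups = meta["group"]
        else:
            groups = pd.Series(metadata)
    return ExpressionMatrix(values, groups)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write the matrix as TSV; missing values are written as ``NA``.

    Finite values round-trip bit-exactly through
    :func:`read_expression_matrix` (floats are serialised with ``repr``).
    """
    m.values.to_csv(
        path, sep="\t", na_rep="NA", index_label="pGene",
        float_format=lambda v: repr(float(v)),
    )


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV with columns sample_id, group, flagged."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group"}
    if not required.issubset(meta.columns):
        raise FormatError(f"{path.name}: metadata needs columns {sorted(required)}")
    bad = set(meta["group"].unique()) - set(GROUPS)
    if bad:
        raise FormatError(f"{path.name}: unknown group labels {sorted(bad)}")
    if "flagged" not in meta.columns:
        meta["flagged"] = False
    meta["flagged"] = meta["flagged"].astype(bool)
    return meta.set_index("sample_id")


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_chromosome_map(path) -> dict[str, str]:
    """Read a two-column (gene, chromosome) TSV into a dict.

    A gene listed twice with conflicting chromosomes keeps its first
    assignment; the conflict is logged as a warning.  A header line whose
    first field looks like a column name ("gene", "symbol", ...) is skipped.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path.name}:{lineno}: expected 2 tab-separated fields")
            gene = fields[0].strip().upper()
            chrom = canonical_chromosome(fields[1])
            if lineno == 1 and gene in {"GENE", "SYMBOL", "GENE_SYMBOL", "PGENE"}:
                continue
            if gene in mapping:
                if mapping[gene] != chrom:
                    logger.warning(
                        "%s:%d: gene %s mapped to both %s and %s; keeping %s",
                        path.name, lineno, gene, mapping[gene], chrom, mapping[gene],
                    )
                continue
            mapping[gene] = chrom
    return mapping


def write_chromosome_map(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchromosome\n")
        for gene, chrom in mapping.items():
            fh.write(f"{gene}\t{chrom}\n")


def canonical_chromosome(label: str) -> str:
    """Normalise chromosome labels: strip 'chr' prefix, upper-case X/Y/MT."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label.upper()


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: member genes} (members deduplicated).

    Raises
    ------
    FormatError
        On any line with fewer than three tab-separated fields, naming the
        line number.
    """
    path = Path(path)
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name = fields[0].strip()
            members = {g.strip().upper() for g in fields[2:] if g.strip()}
            if name in collections:
                logger.warning("%s:%d: duplicate set name %s; keeping first", path.name, lineno, name)
                continue
            collections[name] = members
    return collections


def write_gmt(collections: Mapping[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in collections.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
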