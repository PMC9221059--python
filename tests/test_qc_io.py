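"""Matrix / metadata / GMT / chromosome-map I/O and the QC filter rules."""

import logging

import numpy as np
import pandas as pd
import pytest

import procoex as px
from procoex.errors import FormatError, InputError
from procoex.io import canonical_chromosome
from procoex.qc import qc_report


def _matrix(rows: dict, groups: dict) -> px.ExpressionMatrix:
    values = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    values.columns = list(groups)
    return px.ExpressionMatrix(values, pd.Series(groups))


# ---------------------------------------------------------------- reading
def test_read_matrix_counts_na_tokens(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("pGene\tS1\tS2\nG1\t1.5\tNA\nG2\t2\t3\nG3\t0\t-1\n")
    m = px.read_expression_matrix(path)
    assert m.n_proteins == 3 and m.n_samples == 2
    assert m.n_missing == 1
    assert bool(m.missing_mask.loc["G1", "S2"])


def test_read_matrix_duplicate_protein_named(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("pGene\tS1\nTP53\t1\nEGFR\t2\ntp53\t3\n")
    with pytest.raises(FormatError, match="TP53"):
        px.read_expression_matrix(path)


def test_read_matrix_non_numeric_cell_located(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("pGene\tS1\tS2\nG1\t1\t2\nG2\tbogus\t3\n")
    with pytest.raises(FormatError) as err:
        px.read_expression_matrix(path)
    assert "G2" in str(err.value) and "S1" in str(err.value)


def test_write_read_roundtrip_bit_exact(tmp_path):
    cfg = px.SyntheticConfig(n_proteins=30, n_tumor=8, n_healthy=3,
                             n_modules=2, submodules_per_module=1,
                             missing_rate=0.15, seed=5)
    m, _ = px.generate_dataset(cfg)
    path = tmp_path / "m.tsv"
    px.write_expression_matrix(m, path)
    back = px.read_expression_matrix(path)
    assert list(back.protein_ids) == list(m.protein_ids)
    assert back.values.equals(m.values)  # exact floats, NaN-aware
    assert back.missing_mask.equals(m.missing_mask)


def test_symbols_upper_cased(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("pGene\tS1\nbrca1\t1\n")
    assert px.read_expression_matrix(path).protein_ids == ["BRCA1"]


# ---------------------------------------------------------------- filters
def test_missingness_filter_counts():
    n = 111
    rows = {
        "G0": [1.0] * n,
        "G60": [np.nan] * 60 + [1.0] * (n - 60),
        "G61": [np.nan] * 61 + [1.0] * (n - 61),
    }
    groups = {f"S{i}": "tumor" for i in range(n)}
    m = _matrix(rows, groups)
    kept = px.filter_pgenes_by_missingness(m, max_missing=60)
    assert kept.protein_ids == ["G0", "G60"]
    # vacuous threshold
    assert px.filter_pgenes_by_missingness(m, max_missing=n).protein_ids == list(rows)


def test_missingness_filter_fraction_mode():
    rows = {"G1": [np.nan, 1.0, 1.0, 1.0], "G2": [np.nan, np.nan, 1.0, 1.0]}
    m = _matrix(rows, {f"S{i}": "tumor" for i in range(4)})
    kept = px.filter_pgenes_by_missingness(m, max_missing_fraction=0.25)
    assert kept.protein_ids == ["G1"]


def test_drop_flagged_samples():
    n = 111
    m = _matrix({"G1": list(range(n))}, {f"S{i}": "tumor" for i in range(n)})
    assert px.drop_flagged_samples(m, set()).sample_ids == m.sample_ids
    reduced = px.drop_flagged_samples(m, {f"S{i}" for i in range(28)})
    assert reduced.n_samples == 83
    with pytest.raises(InputError, match="sampleX"):
        px.drop_flagged_samples(m, {"sampleX"})


def test_require_complete_in_group():
    # healthy-missing counts per protein: 0, 0, 1, 3
    rows = {
        "G1": [1.0, 1, 1, 1, 1, 1],
        "G2": [np.nan, 1, 1, 1, 1, 1],
        "G3": [1.0, 1, 1, np.nan, 1, 1],
        "G4": [1.0, 1, 1, np.nan, np.nan, np.nan],
    }
    groups = {"T1": "tumor", "T2": "tumor", "T3": "tumor",
              "H1": "healthy", "H2": "healthy", "H3": "healthy"}
    m = _matrix(rows, groups)
    kept = px.require_complete_in_group(m, "healthy")
    assert kept.protein_ids == ["G1", "G2"]
    complete = px.impute_missing(m)
    assert px.require_complete_in_group(complete, "healthy").protein_ids == list(rows)
    with pytest.raises(InputError):
        px.require_complete_in_group(
            _matrix({"G1": [1.0]}, {"S1": "tumor"}), "healthy"
        )


def test_impute_median_and_identity():
    rows = {"G1": [1.0, np.nan, 3.0, 2.0], "G2": [5.0, np.nan, np.nan, 5.0]}
    m = _matrix(rows, {f"S{i}": "tumor" for i in range(4)})
    out = px.impute_missing(m)
    assert out.values.loc["G1"].tolist() == [1.0, 2.0, 3.0, 2.0]
    assert out.values.loc["G2"].tolist() == [5.0, 5.0, 5.0, 5.0]
    # observed entries untouched, idempotent on complete input
    again = px.impute_missing(out)
    assert again.values.equals(out.values)
    all_missing = _matrix({"G1": [np.nan, np.nan]}, {"S1": "tumor", "S2": "tumor"})
    with pytest.raises(InputError, match="G1"):
        px.impute_missing(all_missing)


def test_qc_report_counts(toy_matrix):
    after = px.impute_missing(toy_matrix)
    rep = qc_report(toy_matrix, after)
    assert rep["missing_before"] == 1 and rep["missing_after"] == 0
    assert rep["proteins_before"] == rep["proteins_after"] == 4


# ---------------------------------------------------------- maps and GMT
def test_chromosome_map_basics(tmp_path, caplog):
    path = tmp_path / "chrom.tsv"
    path.write_text("gene\tchromosome\nTP53\t17\ng1\tchr1\nG1\t2\nMTCO1\tchrMT\n")
    with caplog.at_level(logging.WARNING):
        cmap = px.read_chromosome_map(path)
    assert cmap["TP53"] == "17"
    assert cmap["G1"] == "1"  # first assignment wins on conflict
    assert "G1" in caplog.text
    assert cmap["MTCO1"] == "MT"


def test_chromosome_canonicalisation():
    assert canonical_chromosome("chrX") == "X"
    assert canonical_chromosome(" 7 ") == "7"


def test_gmt_dedup_and_errors(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("setA\tdesc\tg1\tg2\tg2\nsetB\tdesc\tg3\tg4\tg5\n")
    sets = px.read_gmt(path)
    assert sets["setA"] == {"G1", "G2"}
    assert len(sets["setB"]) == 3
    bad = tmp_path / "bad.gmt"
    bad.write_text("setA\tdesc\tg1\nshort\tonly-two-fields\n")
    with pytest.raises(FormatError, match=":2"):
        px.read_gmt(bad)


def test_gmt_roundtrip(tmp_path):
    sets = {"sA": {"G1", "G2"}, "sB": {"G9"}}
    path = tmp_path / "w.gmt"
    px.write_gmt(sets, path)
    assert px.read_gmt(path) == sets
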