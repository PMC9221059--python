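"""End-to-end orchestration: matrix (real or synthetic) to network reports.

The pipeline runs the stages in a fixed order — QC, differential
expression, MI network inference with a permutation-calibrated null,
top-k thinning, two-level community detection, over-representation
analysis, and topology/annotation statistics — and writes every artefact
to a run directory.  A single master seed is fanned out to per-stage seeds
through named :class:`numpy.random.SeedSequence` children, so any stage
can be reproduced in isolation and a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import communities as comm
from . import diffexp as de
from . import enrichment as enr
from . import io as pio
from . import mi as pmi
from . import netstats as ns
from . import qc as pqc
from .errors import ConfigError, ProcoexError
from .matrix import ExpressionMatrix
from .network import Network
from .synthetic import PlantedTruth, SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("synthetic", "jitter", "null", "misc")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Fan a master seed out to named per-stage seeds (< 2**31).

    The derivation is fixed: child ``i`` of ``SeedSequence(master_seed)``
    in the order ``synthetic, jitter, null, misc``.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


@dataclass
class QCSettings:
    max_missing: int = 60
    max_missing_fraction: float | None = None
    flagged_samples: list[str] = field(default_factory=list)
    complete_group: str = "healthy"
    impute: bool = True


@dataclass
class MISettings:
    p_threshold: float = 1e-8
    n_perm: int = 100_000
    top_k: int = 10_000
    dpi: bool = False
    dpi_tolerance: float = 0.0
    chi2_crit: float = pmi.CHI2_CRIT
    min_points: int = pmi.MIN_POINTS


@dataclass
class EnrichSettings:
    min_size: int = 5
    max_size: int = 2000
    min_query_mapped: int = 3
    heatmap_q_cut: float = 1e-5
    global_fdr: bool = False


@dataclass
class PipelineConfig:
    """Everything a run needs; either input paths or a synthetic block."""

    matrix_path: str | None = None
    metadata_path: str | None = None
    chromosome_map_path: str | None = None
    gmt_paths: list[str] = field(default_factory=list)
    synthetic: SyntheticConfig | None = None
    qc: QCSettings = field(default_factory=QCSettings)
    mi: MISettings = field(default_factory=MISettings)
    enrichment: EnrichSettings = field(default_factory=EnrichSettings)
    assortativity_min_edges: int = 10
    weighted_communities: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.matrix_path is None and self.synthetic is None:
            raise ConfigError(
                "config needs either matrix_path or a synthetic block; both absent"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if kwargs.get("synthetic") is not None:
            kwargs["synthetic"] = SyntheticConfig(**kwargs["synthetic"])
        for key, klass in (("qc", QCSettings), ("mi", MISettings),
                           ("enrichment", EnrichSettings)):
            if kwargs.get(key) is not None and not isinstance(kwargs[key], klass):
                kwargs[key] = klass(**kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("procoex", "numpy", "scipy", "pandas", "networkx",
                "scikit-learn", "statsmodels", "numba"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Run all stages, writing every artefact under ``outdir``.

    On a stage failure a ``FAILED`` marker naming the stage is written and
    the exception re-raised; artefacts of completed stages are retained.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    stage = "setup"
    try:
        # ---------------- input / synthesis ----------------
        stage = "input"
        truth: PlantedTruth | None = None
        chrom_map: dict[str, str] | None = None
        collections: dict[str, set[str]] = {}
        if cfg.synthetic is not None:
            # the master seed drives the generator through its stage seed
            matrix, truth = generate_dataset(
                cfg.synthetic.with_seed(seeds["synthetic"])
            )
            pio.write_expression_matrix(matrix, outdir / "matrix.tsv")
            truth.write(outdir / "truth.tsv")
            chrom_map = dict(truth.chromosome_of)
            pio.write_chromosome_map(chrom_map, outdir / "chromosome_map.tsv")
            collections = {"planted": truth.genesets()}
            pio.write_gmt(collections["planted"], outdir / "planted_sets.gmt")
        else:
            matrix = pio.read_expression_matrix(cfg.matrix_path, cfg.metadata_path)
        if cfg.chromosome_map_path:
            chrom_map = pio.read_chromosome_map(cfg.chromosome_map_path)
        for gmt in cfg.gmt_paths:
            collections[Path(gmt).stem] = pio.read_gmt(gmt)

        # ---------------- QC ----------------
        stage = "qc"
        before = matrix
        matrix = pqc.filter_pgenes_by_missingness(
            matrix, cfg.qc.max_missing, cfg.qc.max_missing_fraction
        )
        flagged = set(cfg.qc.flagged_samples)
        if cfg.metadata_path:
            meta = pio.read_sample_metadata(cfg.metadata_path)
            flagged |= set(meta.index[meta["flagged"]])
        if flagged:
            matrix = pqc.drop_flagged_samples(matrix, flagged)
        if matrix.groups is not None and cfg.qc.complete_group:
            matrix = pqc.require_complete_in_group(matrix, cfg.qc.complete_group)
        if cfg.qc.impute:
            matrix = pqc.impute_missing(matrix)
        report = pqc.qc_report(before, matrix)
        (outdir / "qc_report.json").write_text(json.dumps(report, indent=2))

        # ---------------- differential expression ----------------
        stage = "diffexp"
        de_table = None
        if matrix.groups is not None and \
                len(matrix.samples_in_group("tumor")) >= 2 and \
                len(matrix.samples_in_group("healthy")) >= 2:
            de_table = de.run_diffexp(matrix)
            de.write_de_table(de_table, outdir / "de_table.tsv")

        # ---------------- MI network ----------------
        stage = "network"
        ranked = pmi.copula_rank_transform(matrix, seed=seeds["jitter"])
        null = pmi.calibrate_null(
            ranked, n_perm=cfg.mi.n_perm, seed=seeds["null"],
            chi2_crit=cfg.mi.chi2_crit, min_points=cfg.mi.min_points,
        )
        (outdir / "null_model.json").write_text(json.dumps(null.to_dict(), indent=2))
        net = pmi.infer_network(
            ranked, null, p_thresh=cfg.mi.p_threshold,
            chi2_crit=cfg.mi.chi2_crit, min_points=cfg.mi.min_points,
        )
        if cfg.mi.dpi:
            net = pmi.apply_dpi(net, cfg.mi.dpi_tolerance)
        net.write_edge_list(outdir / "edges_full.tsv")
        topk = pmi.top_k_edges(net, cfg.mi.top_k)
        topk.write_edge_list(outdir / "edges_topk.tsv")
        topk.write_sif(outdir / "edges_topk.sif")

        # ---------------- communities ----------------
        stage = "communities"
        partition = comm.detect_communities(topk, weighted=cfg.weighted_communities)
        partition = comm.subpartition(topk, partition, weighted=cfg.weighted_communities)
        partition.write(outdir / "partition.tsv")

        # ---------------- enrichment ----------------
        stage = "enrichment"
        enrichment_table = pd.DataFrame()
        if collections:
            universe = set(matrix.protein_ids)
            merged: dict[str, set[str]] = {}
            for cname, sets in collections.items():
                for sname, members in sets.items():
                    merged[f"{cname}:{sname}" if len(collections) > 1 else sname] = members
            enrichment_table = enr.enrich_partition(
                partition, merged, universe,
                min_size=cfg.enrichment.min_size, max_size=cfg.enrichment.max_size,
                min_query_mapped=cfg.enrichment.min_query_mapped,
                global_fdr=cfg.enrichment.global_fdr,
            )
            enr.write_enrichment_table(enrichment_table, outdir / "enrichment.tsv")
            heat = enr.enrichment_heatmap_table(
                enrichment_table, q_cut=cfg.enrichment.heatmap_q_cut
            )
            heat.to_csv(outdir / "enrichment_heatmap.tsv", sep="\t")

        # ---------------- network statistics ----------------
        stage = "stats"
        stats: dict = {"edge_sets": {}}
        for name, network in (("full_threshold", net), ("top_k", topk)):
            entry: dict = {
                "n_nodes": network.n_nodes,
                "n_edges": network.n_edges,
                "component_sizes_top10": ns.component_sizes(network)[:10],
            }
            fit = ns.fit_power_law(ns.degree_distribution(network))
            if fit is not None:
                entry["degree_fit"] = {
                    "alpha": fit.alpha, "corr": fit.corr,
                    "abs_corr": fit.abs_corr, "n_points": fit.n_points,
                }
            if chrom_map is not None:
                summary, breakdown = ns.classify_cis_trans(network, chrom_map)
                entry["cis_trans"] = summary.to_dict()
                breakdown.to_csv(
                    outdir / f"cis_by_chromosome_{name}.tsv", sep="\t", index=False
                )
            stats["edge_sets"][name] = entry
        if de_table is not None:
            expass = ns.expression_assortativity(
                topk, partition, de_table["sign"],
                min_edges=cfg.assortativity_min_edges,
            )
            expass.to_csv(outdir / "assortativity.tsv", sep="\t", index=False)
            stats["assortativity"] = {
                "n_subcommunities": int(len(expass)),
                "median_expass": float(expass["expass"].median()) if len(expass) else None,
            }
        if truth is not None:
            from sklearn.metrics import adjusted_rand_score

            stats["planted_recovery"] = {
                "ari_level1": float(adjusted_rand_score(
                    truth.module_of.loc[partition.community.index],
                    partition.community,
                )),
                "ari_level2": float(adjusted_rand_score(
                    truth.submodule_labels().loc[partition.subcommunity.index],
                    partition.subcommunity,
                )),
            }
        stats["modularity"] = {"q_level1": partition.q_level1,
                               "q_level2": partition.q_level2}
        (outdir / "stats.json").write_text(json.dumps(stats, indent=2))

        # ---------------- provenance ----------------
        stage = "provenance"
        checksums = {}
        for p in (cfg.matrix_path, cfg.metadata_path, cfg.chromosome_map_path,
                  *cfg.gmt_paths):
            if p:
                checksums[str(p)] = _sha256(Path(p))
        provenance = {
            "config": cfg.to_dict(),
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "versions": _versions(),
            "input_checksums": checksums,
        }
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, ProcoexError):
            raise
        raise ProcoexError(f"stage {stage!r} failed: {exc}") from exc
    return outdir


def compare_networks(
    net_a: Network, net_b: Network, chrom_map: dict[str, str] | None = None
) -> dict:
    """Side-by-side comparison of two edge lists.

    Reports cis/trans summaries (when a chromosome map is given), component
    sizes and the edge overlap — Jaccard index of the two edge sets as a
    percentage (identical lists = 100, disjoint = 0).
    """
    ea, eb = net_a.edge_set(), net_b.edge_set()
    union = ea | eb
    overlap = 100.0 * len(ea & eb) / len(union) if union else 100.0
    out: dict = {
        "edge_overlap_percent": overlap,
        "n_shared_edges": len(ea & eb),
        "networks": {},
    }
    for name, net in (("a", net_a), ("b", net_b)):
        entry: dict = {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "component_sizes_top10": ns.component_sizes(net)[:10],
        }
        if chrom_map is not None:
            summary, _ = ns.classify_cis_trans(net, chrom_map)
            entry["cis_trans"] = summary.to_dict()
        out["networks"][name] = entry
    return out
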