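"""Synthetic proteomic matrices with known planted structure.

The generator emulates the shape of a tumor proteomics study — on the order
of a hundred tumor samples against a small healthy control group, thousands
of protein rows — with four planted features that the downstream stages must
recover:

* **nested co-expression modules.**  Protein ``p`` in module ``m``,
  submodule ``k``, measured in sample ``s``, is drawn as::

      x[p, s] = lam * f[m, s] + (lam / 2) * g[m, k, s] + eps,   eps ~ N(0, sd^2)

  where ``f`` and ``g`` are per-sample standard-normal latent factors and
  ``lam`` is ``module_loading``.  The submodule coefficient is fixed at half
  the module loading, so submodules only become separable after the
  first-level communities are found — a two-level hierarchy.  With one
  submodule per module the ``g`` term is omitted and the within-module
  correlation is exactly ``lam^2 / (lam^2 + sd^2)``.
* **differential expression.**  A ``de_fraction`` of proteins receive a
  ``+/- de_effect`` shift in tumor samples (log2 units).  Signs are random
  per protein, or aligned per module with ``align_de_with_modules`` so that
  all shifted proteins of one module share a sign.
* **missingness.**  Entries are masked missing completely at random at
  ``missing_rate``, applied after signal generation.
* **chromosomes.**  Uniform random assignment over ``n_chromosomes`` labels,
  independent of modules — so the expected cis (same-chromosome) edge
  fraction is analytically ``1 / n_chromosomes``.  With
  ``align_chromosomes_with_modules`` each module sits on one chromosome,
  pushing the cis fraction of a module-structured network towards 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrix import ExpressionMatrix

CHROMOSOME_LABELS = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    Defaults mirror the shape of the breast-cancer proteome study this
    package targets: 105 tumor vs 3 healthy samples, about a 10% missing
    rate, 23 chromosome labels (1-22, X).  The protein count defaults to
    2000 — thousands of rows, but small enough that all-pairs mutual
    information stays a desk-scale computation.
    """

    n_proteins: int = 2000
    n_tumor: int = 105
    n_healthy: int = 3
    n_modules: int = 8
    submodules_per_module: int = 3
    module_loading: float = 2.0
    noise_sd: float = 1.0
    de_fraction: float = 0.2
    de_effect: float = 2.0
    missing_rate: float = 0.1
    n_chromosomes: int = 23
    seed: int = 0
    align_de_with_modules: bool = False
    align_chromosomes_with_modules: bool = False

    def validate(self) -> None:
        for name in ("n_proteins", "n_tumor", "n_healthy", "n_modules",
                     "submodules_per_module", "n_chromosomes"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("de_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_modules * self.submodules_per_module > self.n_proteins:
            raise ConfigError(
                "n_modules * submodules_per_module exceeds n_proteins "
                f"({self.n_modules} * {self.submodules_per_module} > {self.n_proteins})"
            )
        if self.n_chromosomes > len(CHROMOSOME_LABELS):
            raise ConfigError(
                f"n_chromosomes must be <= {len(CHROMOSOME_LABELS)}, got {self.n_chromosomes}"
            )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


@dataclass
class PlantedTruth:
    """Ground truth of a generated dataset, one row per protein.

    ``table`` columns: ``module`` (1-based id), ``submodule`` (1-based id
    within the module), ``de_sign`` (+1 / -1 / 0), ``chromosome`` (label).
    """

    table: pd.DataFrame

    @property
    def module_of(self) -> pd.Series:
        return self.table["module"]

    @property
    def submodule_of(self) -> pd.Series:
        return self.table["submodule"]

    @property
    def de_sign_of(self) -> pd.Series:
        return self.table["de_sign"]

    @property
    def chromosome_of(self) -> pd.Series:
        return self.table["chromosome"]

    def module_labels(self) -> pd.Series:
        """Level-1 labels, one string per protein ("M3")."""
        return self.table["module"].map(lambda m: f"M{m}")

    def submodule_labels(self) -> pd.Series:
        """Level-2 labels, one string per protein ("M3.2")."""
        return self.table.apply(lambda r: f"M{r.module}.{r.submodule}", axis=1)

    def genesets(self) -> dict[str, set[str]]:
        """Planted submodules as a gene-set collection (GMT-compatible)."""
        labels = self.submodule_labels()
        return {
            str(lab): set(labels.index[labels == lab])
            for lab in sorted(labels.unique())
        }

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="pGene")

    @classmethod
    def read(cls, path) -> "PlantedTruth":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def generate_dataset(config: SyntheticConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate a matrix plus its planted truth; deterministic in the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    P = config.n_proteins
    n_samples = config.n_tumor + config.n_healthy
    M = config.n_modules
    K = config.submodules_per_module
    lam = config.module_loading
    sd = config.noise_sd

    protein_ids = [f"G{i:05d}" for i in range(1, P + 1)]
    sample_ids = [f"T{i:03d}" for i in range(1, config.n_tumor + 1)] + [
        f"H{i:03d}" for i in range(1, config.n_healthy + 1)
    ]
    is_tumor = np.array([s.startswith("T") for s in sample_ids])
    groups = pd.Series(
        np.where(is_tumor, "tumor", "healthy"), index=sample_ids, name="group"
    )

    # contiguous near-equal module blocks, submodule blocks inside them
    module = (np.arange(P) * M // P) + 1
    submodule = np.empty(P, dtype=int)
    for m in range(1, M + 1):
        idx = np.flatnonzero(module == m)
        submodule[idx] = (np.arange(idx.size) * K // idx.size) + 1

    f = rng.standard_normal((M, n_samples))
    g = rng.standard_normal((M, K, n_samples))
    x = sd * rng.standard_normal((P, n_samples))
    x += lam * f[module - 1]
    if K > 1:  # a single submodule IS the module; no second factor
        x += (lam / 2.0) * g[module - 1, submodule - 1]

    # planted differential expression: shift tumor columns
    de_sign = np.zeros(P, dtype=int)
    n_de = int(round(config.de_fraction * P))
    de_idx = rng.choice(P, size=n_de, replace=False)
    if config.align_de_with_modules:
        module_sign = np.where(rng.random(M) < 0.5, 1, -1)
        de_sign[de_idx] = module_sign[module[de_idx] - 1]
    else:
        de_sign[de_idx] = np.where(rng.random(n_de) < 0.5, 1, -1)
    x[:, is_tumor] += (config.de_effect * de_sign)[:, None]

    # MCAR missingness, after signal generation
    if config.missing_rate > 0:
        mask = rng.random((P, n_samples)) < config.missing_rate
        x[mask] = np.nan

    labels = CHROMOSOME_LABELS[: config.n_chromosomes]
    if config.align_chromosomes_with_modules:
        chrom = [labels[(m - 1) % len(labels)] for m in module]
    else:
        chrom = [labels[i] for i in rng.integers(0, len(labels), size=P)]

    values = pd.DataFrame(x, index=protein_ids, columns=sample_ids)
    truth = PlantedTruth(
        pd.DataFrame(
            {
                "module": module,
                "submodule": submodule,
                "de_sign": de_sign,
                "chromosome": chrom,
            },
            index=pd.Index(protein_ids, name="pGene"),
        )
    )
    return ExpressionMatrix(values, groups), truth
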