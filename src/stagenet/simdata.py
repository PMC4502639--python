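"""Seeded synthetic expression data with planted modules, batches and DE genes.

The generator emulates the statistical structure of a merged multi-cohort
tumor/normal microarray compendium on the log2 scale: several batches with
additive and multiplicative batch effects, a block of genes differentially
expressed between tumor and normal samples, and a set of coexpression modules
driven by per-sample latent factors.  Exactly one module's factor is mixed
with the (standardized) binary early/late stage indicator so that its
correlation with stage is a tunable parameter; within each module a fraction
of genes carry a high factor loading and act as planted hubs.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` sub-streams, so a fixed configuration is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "ExpressionDataset",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
    "ConfigError",
    "ParseError",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


class ParseError(ValueError):
    """Raised when an on-disk dataset is malformed."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic expression generator.

    Defaults are a desk-scale rendition of a merged tumor/normal oral-cancer
    compendium: a few hundred samples in several batches, modules of a few
    dozen genes (the real study's modules spanned 35-339 genes), log2
    expression with about two-fold differential expression for DE genes and
    sub-unit residual noise.
    """

    n_genes: int = 2000
    n_normal: int = 60
    n_tumor_early: int = 100
    n_tumor_late: int = 100
    n_batches: int = 3
    batch_shift_sd: float = 0.4      # additive per gene x batch, log2 units
    batch_scale_sd: float = 0.1      # log-normal sd of residual-noise scaling
    n_modules: int = 5
    module_sizes: tuple[int, ...] = (80, 60, 50, 40, 35)
    stage_module_index: int = 2      # which planted module tracks stage
    stage_effect: float = 0.5        # target cor(stage, module factor), 0..1
    hub_fraction: float = 0.3        # fraction of module genes with high loading
    loading_high: float = 0.85
    loading_low: float = 0.7
    n_de_genes: int = 400            # first n genes get a tumor-vs-normal shift
    de_lfc: float = 1.5              # log2 fold change of the planted shift
    noise_sd: float = 0.5            # residual noise, log2 units
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        for name in ("n_normal", "n_tumor_early", "n_tumor_late"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be at least 1")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes must have n_modules entries")
        if any(s < 3 for s in self.module_sizes):
            raise ConfigError("module_sizes entries must all be >= 3")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("module_sizes must sum to at most n_genes")
        if self.n_modules and not (0 <= self.stage_module_index < self.n_modules):
            raise ConfigError("stage_module_index out of range")
        if not 0.0 <= self.stage_effect <= 1.0:
            raise ConfigError("stage_effect must lie in [0, 1]")
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise ConfigError("hub_fraction must lie in [0, 1]")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ConfigError("n_de_genes must lie in [0, n_genes]")
        for name in ("batch_shift_sd", "batch_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class ExpressionDataset:
    """A genes x samples log2 expression matrix with per-sample phenotype.

    ``expr`` is indexed by gene id (rows) and sample id (columns).
    ``phenotype`` is indexed by sample id with columns ``group`` (normal or
    tumor), ``stage`` (early or late for tumor samples, missing for normals)
    and ``batch``.  ``truth``, present only for simulated data, records the
    planted module label, hub flag and DE log-fold-change per gene.
    """

    expr: pd.DataFrame
    phenotype: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.expr.index.duplicated().any():
            dup = self.expr.index[self.expr.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.expr.columns.duplicated().any():
            dup = self.expr.columns[self.expr.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        missing = set(self.expr.columns) - set(self.phenotype.index)
        if missing:
            raise ValueError(
                f"samples missing from phenotype table: {sorted(missing)}"
            )
        if self.expr.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        tumor = self.phenotype.loc[list(self.expr.columns)]
        tumor = tumor[tumor["group"] == "tumor"]
        if tumor["stage"].isna().any():
            bad = tumor.index[tumor["stage"].isna()][0]
            raise ValueError(f"tumor sample {bad!r} has no stage label")

    # -- convenience views -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)

    def samples_in_group(self, group: str) -> list[str]:
        ph = self.phenotype.loc[list(self.expr.columns)]
        return list(ph.index[ph["group"] == group])

    def tumor_subset(self) -> "ExpressionDataset":
        """Dataset restricted to tumor samples (network samples)."""
        cols = self.samples_in_group("tumor")
        return ExpressionDataset(
            self.expr[cols], self.phenotype.loc[cols].copy(), self.truth
        )

    def stage_trait(self) -> pd.Series:
        """Binary stage trait over tumor samples: early = 0, late = 1."""
        cols = self.samples_in_group("tumor")
        stage = self.phenotype.loc[cols, "stage"]
        return (stage == "late").astype(float)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        truth = self.truth.loc[list(genes)] if self.truth is not None else None
        return ExpressionDataset(self.expr.loc[list(genes)], self.phenotype, truth)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def simulate_dataset(config: SimConfig) -> ExpressionDataset:
    """Draw one synthetic dataset under ``config``.

    Module genes follow a latent-factor model ``x = baseline + loading *
    factor + noise``; the designated stage module's factor is mixed with the
    standardized stage indicator so its correlation with stage across tumor
    samples is ``stage_effect`` in expectation.  The first ``n_de_genes``
    genes (module genes first, by construction) receive a +/- ``de_lfc``
    shift in tumor samples.  Batch effects add a N(0, batch_shift_sd^2)
    gene-by-batch offset and scale the residual noise log-normally.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (rng_assign, rng_factor, rng_base, rng_noise, rng_batch, rng_de) = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    n_samples = config.n_normal + config.n_tumor_early + config.n_tumor_late
    if n_samples < 2:
        raise ConfigError("need at least 2 samples in total")
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    group = np.array(
        ["normal"] * config.n_normal
        + ["tumor"] * (config.n_tumor_early + config.n_tumor_late)
    )
    stage = np.array(
        [None] * config.n_normal
        + ["early"] * config.n_tumor_early
        + ["late"] * config.n_tumor_late,
        dtype=object,
    )
    # Round-robin batch assignment within each phenotype stratum keeps every
    # batch a mixture of groups and stages (no confounding by design).
    batch = np.empty(n_samples, dtype=object)
    for mask in (
        group == "normal",
        (group == "tumor") & (stage == "early"),
        (group == "tumor") & (stage == "late"),
    ):
        idx = np.flatnonzero(mask)
        rng_assign.shuffle(idx)
        for j, i in enumerate(idx):
            batch[i] = f"batch_{j % config.n_batches + 1}"

    is_tumor = group == "tumor"
    stage01 = (stage == "late").astype(float)

    # Latent module factors (one value per sample).
    factors = rng_factor.standard_normal((config.n_modules, n_samples))
    if config.n_modules:
        m = config.stage_module_index
        z = rng_factor.standard_normal(n_samples)
        fac = factors[m].copy()
        tum = np.flatnonzero(is_tumor)
        if len(tum) >= 2 and 0 < stage01[tum].std():
            z_stage = _standardize(stage01[tum])
            rho = config.stage_effect
            fac[tum] = rho * z_stage + math.sqrt(1.0 - rho**2) * z[tum]
        factors[m] = fac

    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    baseline = rng_base.normal(7.0, 1.0, size=config.n_genes)

    # Gene-level planted structure: modules occupy the leading genes.
    module_label = np.array(["none"] * config.n_genes, dtype=object)
    hub_flag = np.zeros(config.n_genes, dtype=bool)
    loading = np.zeros(config.n_genes)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        n_hub = max(1, int(round(config.hub_fraction * size))) if size else 0
        sl = slice(pos, pos + size)
        module_label[sl] = f"planted_{m + 1}"
        hub_flag[pos : pos + n_hub] = True
        loading[sl] = config.loading_low
        loading[pos : pos + n_hub] = config.loading_high
        pos += size

    de_lfc = np.zeros(config.n_genes)
    if config.n_de_genes:
        signs = rng_de.choice([1.0, -1.0], size=config.n_de_genes)
        de_lfc[: config.n_de_genes] = signs * config.de_lfc

    # Assemble the matrix: baseline + module signal + DE shift + batch shift
    # + (batch-scaled) residual noise.
    X = np.tile(baseline[:, None], (1, n_samples))
    for m in range(config.n_modules):
        rows = module_label == f"planted_{m + 1}"
        X[rows] += loading[rows, None] * factors[m][None, :]
    X += de_lfc[:, None] * is_tumor[None, :].astype(float)

    noise = rng_noise.standard_normal((config.n_genes, n_samples)) * config.noise_sd
    batch_names = sorted(set(batch))
    for b in batch_names:
        cols = batch == b
        shift = rng_batch.normal(0.0, config.batch_shift_sd, size=config.n_genes)
        scale = np.exp(rng_batch.normal(0.0, config.batch_scale_sd, size=config.n_genes))
        X[:, cols] += shift[:, None]
        noise[:, cols] *= scale[:, None]
    X += noise

    expr = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    phenotype = pd.DataFrame(
        {"group": group, "stage": stage, "batch": batch}, index=pd.Index(sample_ids)
    )
    phenotype.index.name = "sample_id"
    truth = pd.DataFrame(
        {
            "module": module_label,
            "hub": hub_flag,
            "loading": loading,
            "de_lfc": de_lfc,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionDataset(expr, phenotype, truth)


# ---------------------------------------------------------------------------
# On-disk format: a directory holding expression.tsv and phenotype.tsv
# (plus truth.tsv when planted labels are available).
# ---------------------------------------------------------------------------

EXPRESSION_FILE = "expression.tsv"
PHENOTYPE_FILE = "phenotype.tsv"
TRUTH_FILE = "truth.tsv"


def write_dataset(ds: ExpressionDataset, path: str | Path) -> Path:
    """Write ``ds`` as TSV files under the directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    expr = ds.expr.copy()
    expr.index.name = "gene_id"
    expr.to_csv(path / EXPRESSION_FILE, sep="\t", lineterminator="\n",
                float_format="%.17g")
    ph = ds.phenotype.copy()
    ph.index.name = "sample_id"
    ph = ph.fillna("NA")
    ph.to_csv(path / PHENOTYPE_FILE, sep="\t", lineterminator="\n")
    if ds.truth is not None:
        ds.truth.to_csv(path / TRUTH_FILE, sep="\t", lineterminator="\n")
    return path


def _read_tsv_table(path: Path) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path.name}: empty file")
    header = lines[0].split("\t")
    width = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != width:
            raise ParseError(
                f"{path.name}, line {lineno}: expected {width} fields, "
                f"found {len(fields)}"
            )
        rows.append(fields)
    return header, rows


def read_dataset(path: str | Path) -> ExpressionDataset:
    """Read a dataset previously written with :func:`write_dataset`.

    Raises :class:`ParseError` on ragged rows, duplicate gene/sample ids or
    samples present in the matrix but absent from the phenotype table.
    """
    path = Path(path)
    header, rows = _read_tsv_table(path / EXPRESSION_FILE)
    sample_ids = header[1:]
    seen: dict[str, int] = {}
    gene_ids, values = [], []
    for lineno, fields in zip(range(2, 2 + len(rows)), rows):
        gid = fields[0]
        if gid in seen:
            raise ParseError(
                f"{EXPRESSION_FILE}, line {lineno}: duplicate gene id {gid!r} "
                f"(first seen on line {seen[gid]})"
            )
        seen[gid] = lineno
        try:
            values.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{EXPRESSION_FILE}, line {lineno}: {exc}") from None
        gene_ids.append(gid)
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{EXPRESSION_FILE}: duplicate sample id in header")
    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)

    ph_header, ph_rows = _read_tsv_table(path / PHENOTYPE_FILE)
    required = {"sample_id", "group", "stage", "batch"}
    if not required.issubset(ph_header):
        raise ParseError(
            f"{PHENOTYPE_FILE}: missing columns {sorted(required - set(ph_header))}"
        )
    ph = pd.DataFrame(ph_rows, columns=ph_header).set_index("sample_id")
    if ph.index.duplicated().any():
        dup = ph.index[ph.index.duplicated()][0]
        raise ParseError(f"{PHENOTYPE_FILE}: duplicate sample id {dup!r}")
    ph = ph.replace("NA", None)
    missing = [s for s in sample_ids if s not in ph.index]
    if missing:
        raise ParseError(
            f"{PHENOTYPE_FILE}: sample {missing[0]!r} present in expression "
            "matrix but missing from phenotype table"
        )

    truth = None
    truth_path = path / TRUTH_FILE
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        truth["hub"] = truth["hub"].astype(bool)
    return ExpressionDataset(expr, ph, truth)
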