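"""Synthetic expression data generators.

These generators emulate the inputs the scoring algorithm is designed for:
a two-condition (query vs reference) expression matrix with per-gene
baselines, a planted upward shift of selected gene-set genes in the query
condition, optional dropout zero-inflation for single-cell-like data,
pseudobulk aggregation, and an additive Gaussian noise protocol
(mean 0.01, SD on a grid up to 0.06) used to probe score robustness.

Baselines: each gene's mean is drawn from a log-normal distribution and its
biological SD is proportional to the mean (a gene-specific coefficient of
variation drawn uniformly); expression values are Gaussian around the gene
baseline, truncated at zero to stay on a non-negative normalized-counts
scale. Planted sets shift their member genes upward by delta * sigma_gene
in the query condition only, so delta is an effect size in units of the
per-gene reference SD. All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection
from .errors import ConfigurationError, DataError

__all__ = [
    "SimulationConfig",
    "simulate_two_condition",
    "simulate_single_cell",
    "simulate_cell_types",
    "aggregate_pseudobulk",
    "inject_gaussian_noise",
    "NOISE_SD_GRID",
]

#: The additive-noise SD grid used in the robustness protocol (noise mean 0.01).
NOISE_SD_GRID = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06)


@dataclass
class SimulationConfig:
    """Parameters of the two-condition simulation.

    Attributes
    ----------
    n_genes, n_query, n_reference
        Matrix geometry: gene count and samples per condition (C1 / C2).
    baseline_log_mean, baseline_log_sd
        Log-normal hyperparameters for per-gene baseline means
        (natural-log scale).
    cv_range
        Per-gene coefficient of variation (sigma_gene / mean_gene) is drawn
        uniformly from this interval.
    set_size, n_planted, n_decoy
        Gene sets: ``n_planted`` sets of ``set_size`` genes are shifted in
        the query condition; ``n_decoy`` sets are drawn from unshifted genes.
    effect_size
        Planted shift delta, in units of each member gene's SD.
    dropout_rate
        Probability of zeroing each entry independently (single-cell mode).
    noise_mean, noise_sd
        Additive Gaussian noise parameters (applied by
        :func:`inject_gaussian_noise`).
    """

    n_genes: int = 500
    n_query: int = 30
    n_reference: int = 30
    baseline_log_mean: float = 1.5
    baseline_log_sd: float = 0.6
    cv_range: tuple[float, float] = (0.15, 0.35)
    set_size: int = 25
    n_planted: int = 5
    n_decoy: int = 20
    effect_size: float = 2.0
    dropout_rate: float = 0.0
    noise_mean: float = 0.01
    noise_sd: float = 0.0
    seed: int | None = None
    planted_sets: list = field(default_factory=list)  # filled by the generator

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_query", "n_reference", "set_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_planted < 0 or self.n_decoy < 0:
            raise ConfigurationError("set counts must be non-negative")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if (self.n_planted + self.n_decoy) * self.set_size > self.n_genes:
            raise ConfigurationError(
                "gene pool too small for the requested disjoint gene sets"
            )


def _simulate(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ExpressionMatrix, GeneSetCollection, dict]:
    g, nq, nr = config.n_genes, config.n_query, config.n_reference
    gene_ids = [f"g{i:05d}" for i in range(g)]
    samples = [f"q{i:03d}" for i in range(nq)] + [f"r{i:03d}" for i in range(nr)]
    labels = pd.Series(["query"] * nq + ["reference"] * nr, index=samples)

    mean_g = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=g)
    cv_g = rng.uniform(*config.cv_range, size=g)
    sd_g = mean_g * cv_g

    vals = rng.normal(mean_g[:, None], sd_g[:, None], size=(g, nq + nr))

    # disjoint planted and decoy sets drawn from a shuffled gene pool
    order = rng.permutation(g)
    sets: dict[str, list[str]] = {}
    truth: dict[str, dict] = {}
    pos = 0
    for i in range(config.n_planted):
        idx = order[pos : pos + config.set_size]
        pos += config.set_size
        name = f"planted_{i:02d}"
        sets[name] = [gene_ids[j] for j in idx]
        truth[name] = {"active": True, "effect_size": config.effect_size}
        vals[np.ix_(idx, np.arange(nq))] += config.effect_size * sd_g[idx, None]
    for i in range(config.n_decoy):
        idx = order[pos : pos + config.set_size]
        pos += config.set_size
        name = f"decoy_{i:02d}"
        sets[name] = [gene_ids[j] for j in idx]
        truth[name] = {"active": False, "effect_size": 0.0}

    np.clip(vals, 0.0, None, out=vals)
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=gene_ids, columns=samples),
        labels,
        reference_level="reference",
    )
    collection = GeneSetCollection(sets) if sets else None
    return expr, collection, truth


def simulate_two_condition(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneSetCollection, dict]:
    """Simulate a bulk two-condition matrix with planted gene-set activation.

    Returns the labeled matrix, the gene-set collection (planted + decoy,
    mutually disjoint) and a truth table mapping each set name to its
    activation status and effect size. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    return _simulate(config, rng)


def simulate_single_cell(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneSetCollection, dict]:
    """Two-condition simulation followed by Bernoulli dropout zero-masking.

    Dropout is uniform: each entry is independently set to zero with
    probability ``config.dropout_rate``, emulating the capture failures that
    inflate zeros in single-cell data. ``dropout_rate = 0`` reproduces the
    bulk simulation exactly.
    """
    rng = np.random.default_rng(config.seed)
    expr, sets, truth = _simulate(config, rng)
    if config.dropout_rate > 0:
        mask = rng.random(expr.shape) < config.dropout_rate
        vals = expr.values.to_numpy().copy()
        vals[mask] = 0.0
        if config.dropout_rate >= 1.0:
            warnings.warn("dropout_rate = 1 produced an all-zero matrix")
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=expr.gene_ids, columns=expr.sample_ids),
            expr.labels,
            expr.reference_level,
        )
    return expr, sets, truth


def simulate_cell_types(
    n_types: int = 3,
    cells_per_type: int = 30,
    n_genes: int = 300,
    markers_per_type: int = 20,
    marker_shift: float = 4.0,
    dropout_rate: float = 0.0,
    baseline_log_mean: float = 1.5,
    baseline_log_sd: float = 0.6,
    cv_range: tuple[float, float] = (0.15, 0.35),
    seed: int | None = None,
) -> tuple[ExpressionMatrix, GeneSetCollection]:
    """Simulate a cell-type-labeled matrix with per-type marker signatures.

    Each type gets a disjoint block of marker genes shifted upward by
    ``marker_shift`` SDs in its own cells; the returned signature collection
    maps each type label to its marker set, ready for one-vs-rest scoring.
    """
    if n_types < 2:
        raise ConfigurationError("need at least two cell types")
    if n_types * markers_per_type > n_genes:
        raise ConfigurationError("gene pool too small for disjoint marker sets")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    types = [f"type{chr(ord('A') + t)}" for t in range(n_types)]
    cells, labels = [], []
    for t in types:
        cells += [f"{t}_c{i:03d}" for i in range(cells_per_type)]
        labels += [t] * cells_per_type

    mean_g = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n_genes)
    sd_g = mean_g * rng.uniform(*cv_range, size=n_genes)
    vals = rng.normal(mean_g[:, None], sd_g[:, None], size=(n_genes, len(cells)))

    order = rng.permutation(n_genes)
    signatures = {}
    for ti, t in enumerate(types):
        idx = order[ti * markers_per_type : (ti + 1) * markers_per_type]
        cols = np.flatnonzero(np.asarray(labels) == t)
        vals[np.ix_(idx, cols)] += marker_shift * sd_g[idx, None]
        signatures[t] = [gene_ids[j] for j in idx]

    np.clip(vals, 0.0, None, out=vals)
    if dropout_rate > 0:
        mask = rng.random(vals.shape) < dropout_rate
        vals[mask] = 0.0
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=gene_ids, columns=cells),
        pd.Series(labels, index=cells),
    )
    return expr, GeneSetCollection(signatures)


def aggregate_pseudobulk(
    sc: ExpressionMatrix,
    sample_assignment: Mapping[str, str] | pd.Series,
) -> ExpressionMatrix:
    """Sum single-cell expression into pseudobulk samples.

    ``sample_assignment`` maps every cell identifier to a pseudobulk sample
    identifier; per-gene values are summed across the cells of each sample,
    conserving total counts per gene. Each pseudobulk sample inherits its
    cells' condition label (majority label with a warning if mixed).
    """
    assign = pd.Series(sample_assignment)
    missing = sc.sample_ids.difference(assign.index)
    if len(missing):
        raise DataError(f"cells without a pseudobulk assignment: {missing.tolist()[:10]}")
    assign = assign.reindex(sc.sample_ids)

    grouped = sc.values.T.groupby(assign, sort=False).sum().T
    new_labels = {}
    for sample, cells in assign.groupby(assign).groups.items():
        lv = sc.labels.loc[cells]
        counts = lv.value_counts()
        if len(counts) > 1:
            warnings.warn(
                f"pseudobulk sample {sample!r} mixes labels {counts.index.tolist()}; "
                "using the majority label"
            )
        new_labels[sample] = counts.index[0]
    labels = pd.Series(new_labels).reindex(grouped.columns)
    ref = sc.reference_level if sc.reference_level in set(labels) else None
    return ExpressionMatrix(grouped, labels, ref)


def inject_gaussian_noise(
    expr: ExpressionMatrix,
    noise_sd: float,
    noise_mean: float = 0.01,
    seed: int | None = None,
    clamp: bool = False,
) -> ExpressionMatrix:
    """Add iid Gaussian noise to every entry of the matrix.

    A noise matrix of identical shape is drawn iid Normal(noise_mean,
    noise_sd) and added entrywise across ALL samples, both conditions.
    Literal addition: values are not clamped at zero unless ``clamp=True``
    (for count-like downstream use). ``noise_sd = 0`` shifts every entry by
    exactly ``noise_mean``. Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(noise_mean, noise_sd, size=expr.shape)
    vals = expr.values.to_numpy(dtype=float) + noise
    if clamp:
        np.clip(vals, 0.0, None, out=vals)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=expr.gene_ids, columns=expr.sample_ids),
        expr.labels,
        expr.reference_level,
    )
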