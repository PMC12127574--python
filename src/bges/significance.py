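"""Permutation significance and null calibration.

The significance of a gene set's enrichment is assessed by permuting the
condition labels: each permutation reshuffles the label vector (preserving
the C1/C2 group sizes), recomputes the reference statistics, the binarized
matrix and the enrichment scores, and records the dataset-level statistic
ES_perm (by default the mean enrichment score over the permuted C1 samples).
The one-sided p-value is

    p = #{permutations with ES_perm >= ES_obs} / n

which can be exactly 0; the small-sample corrected variant
(count + 1) / (n + 1) is always reported alongside, never substituted.

The null-calibration harness checks that these p-values are uniform when no
true label association exists: the sample labels are shuffled n_perm times,
a full permutation test is run inside each shuffled dataset for every gene
set, and the pooled null p-values are compared against Uniform(0, 1) with a
KS test and a 100-bin quantile-quantile summary of mean observed vs expected
-log10(p). The -log10 summaries use the corrected p-values (the paper-exact
formula can produce p = 0, whose log diverges); the KS test runs on the
exact ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, GeneSetCollection
from .errors import ConfigurationError, DataError

__all__ = [
    "PermutationResult",
    "NullCalibrationReport",
    "paper_exact_pvalue",
    "corrected_pvalue",
    "permutation_pvalue",
    "null_calibration",
    "plot_qq",
]

_AGGREGATORS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": np.mean,
    "median": np.median,
}


def paper_exact_pvalue(es_perm: Sequence[float], es_obs: float) -> float:
    """One-sided permutation p-value: #{ES_perm >= ES_obs} / n. Can be 0."""
    es_perm = np.asarray(es_perm, dtype=float)
    if es_perm.size == 0:
        raise DataError("need at least one permutation statistic")
    return float((es_perm >= es_obs).sum() / es_perm.size)


def corrected_pvalue(es_perm: Sequence[float], es_obs: float) -> float:
    """Small-sample corrected variant (count + 1) / (n + 1); never 0."""
    es_perm = np.asarray(es_perm, dtype=float)
    if es_perm.size == 0:
        raise DataError("need at least one permutation statistic")
    return float(((es_perm >= es_obs).sum() + 1) / (es_perm.size + 1))


@dataclass
class PermutationResult:
    """Outcome of a label-permutation test for one gene set."""

    set_name: str
    es_obs: float
    es_perm: np.ndarray
    n: int
    p_value: float
    p_corrected: float
    statistic: str
    seed: int | None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PermutationResult({self.set_name!r}, es_obs={self.es_obs:.4g}, "
            f"p={self.p_value:.4g}, n={self.n})"
        )


def _membership(
    gene_ids: pd.Index,
    sets: GeneSetCollection,
    denominator_mode: str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Dense sets x genes indicator matrix and per-set denominators."""
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    M = np.zeros((len(sets), len(gene_ids)))
    denoms = np.empty(len(sets))
    names = []
    for i, name in enumerate(sets):
        idx = [gene_pos[g] for g in sets[name] if g in gene_pos]
        if not idx:
            raise DataError(f"gene set {name!r} has no measured genes")
        M[i, idx] = 1.0
        denoms[i] = len(idx) if denominator_mode == "measured" else len(sets[name])
        names.append(name)
    return M, denoms, names


def _per_set_statistic(
    values: np.ndarray,
    ref_mask: np.ndarray,
    M: np.ndarray,
    denoms: np.ndarray,
    aggregate: Callable[[np.ndarray], float],
) -> np.ndarray:
    """Dataset-level statistic per set for one label assignment."""
    ref = values[:, ref_mask]
    thr = ref.mean(axis=1) + ref.std(axis=1, ddof=0)
    binary = values[:, ~ref_mask] > thr[:, None]
    es = (M @ binary) / denoms[:, None]  # sets x |C1|
    if aggregate is np.mean:  # fast path for the default statistic
        return es.mean(axis=1)
    if aggregate is np.median:
        return np.median(es, axis=1)
    return np.apply_along_axis(aggregate, 1, es)


def _resolve_statistic(statistic: str | Callable) -> tuple[str, Callable]:
    if callable(statistic):
        return getattr(statistic, "__name__", "custom"), statistic
    try:
        return statistic, _AGGREGATORS[statistic]
    except KeyError:
        raise ConfigurationError(
            f"unknown statistic {statistic!r}; choose from {sorted(_AGGREGATORS)} "
            "or pass a callable"
        ) from None


def permutation_pvalue(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    n: int = 1000,
    statistic: str | Callable = "mean",
    seed: int | None = None,
    denominator_mode: str = "measured",
    set_name: str = "gene_set",
) -> PermutationResult:
    """Label-permutation p-value for one gene set.

    Each of the ``n`` permutations shuffles the sample label vector uniformly
    at random (preserving |C1| and |C2|), recomputes reference statistics,
    binarization and enrichment, and aggregates the per-sample scores of the
    permuted C1 samples with ``statistic`` (default: mean). Reproducible for
    a fixed ``seed``.
    """
    if n < 1:
        raise ConfigurationError("permutation count n must be >= 1")
    stat_name, aggregate = _resolve_statistic(statistic)
    sets = GeneSetCollection({set_name: list(gene_set)})
    M, denoms, _ = _membership(expr.gene_ids, sets, denominator_mode)
    values = expr.values.to_numpy(dtype=float)
    ref_mask = expr.reference_mask

    es_obs = _per_set_statistic(values, ref_mask, M, denoms, aggregate)[0]
    rng = np.random.default_rng(seed)
    es_perm = np.empty(n)
    for j in range(n):
        perm_mask = rng.permutation(ref_mask)
        es_perm[j] = _per_set_statistic(values, perm_mask, M, denoms, aggregate)[0]

    return PermutationResult(
        set_name=set_name,
        es_obs=float(es_obs),
        es_perm=es_perm,
        n=n,
        p_value=paper_exact_pvalue(es_perm, es_obs),
        p_corrected=corrected_pvalue(es_perm, es_obs),
        statistic=stat_name,
        seed=seed,
    )


@dataclass
class NullCalibrationReport:
    """Null p-value matrix and its uniformity diagnostics."""

    p_matrix: pd.DataFrame  # sets x permutations, paper-exact p
    p_corrected_matrix: pd.DataFrame
    n_perm: int
    n_inner: int
    seed: int | None
    n_bins: int
    bin_edges: np.ndarray
    observed_mean_neglog10: np.ndarray  # per bin; NaN where the bin is empty
    expected_mean_neglog10: np.ndarray
    bin_counts: np.ndarray
    empty_bins: list = field(default_factory=list)
    qq_slope: float = float("nan")
    ks_statistic: float = float("nan")
    ks_pvalue: float = float("nan")
    degenerate: bool = False

    def to_dict(self) -> dict:
        """Machine-readable summary (JSON-safe)."""
        return {
            "n_sets": int(self.p_matrix.shape[0]),
            "n_perm": self.n_perm,
            "n_inner": self.n_inner,
            "seed": self.seed,
            "n_bins": self.n_bins,
            "qq_slope": float(self.qq_slope),
            "ks_statistic": float(self.ks_statistic),
            "ks_pvalue": float(self.ks_pvalue),
            "degenerate": self.degenerate,
            "empty_bins": list(map(int, self.empty_bins)),
            "observed_mean_neglog10": [
                None if np.isnan(x) else float(x) for x in self.observed_mean_neglog10
            ],
            "expected_mean_neglog10": [float(x) for x in self.expected_mean_neglog10],
            "bin_counts": [int(c) for c in self.bin_counts],
        }


def null_calibration(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    n_inner: int = 200,
    seed: int | None = None,
    statistic: str | Callable = "mean",
    denominator_mode: str = "measured",
) -> NullCalibrationReport:
    """Label-permutation null calibration of the permutation p-values.

    ``n_perm`` outer label shuffles each yield one dataset with no true label
    association; inside each, a full permutation test with ``n_inner``
    permutations produces one p-value per gene set, giving a
    (sets x n_perm) null p-value matrix. The pooled p-values are sorted,
    paired with uniform plotting positions (i - 0.5)/N, binned into 100
    equal-width quantile bins, and summarized as mean observed vs expected
    -log10(p) per bin plus a through-the-origin QQ regression slope.
    """
    if n_perm < 1 or n_inner < 1:
        raise ConfigurationError("n_perm and n_inner must be >= 1")
    stat_name, aggregate = _resolve_statistic(statistic)
    del stat_name
    M, denoms, names = _membership(expr.gene_ids, sets, denominator_mode)
    values = expr.values.to_numpy(dtype=float)
    ref_mask = expr.reference_mask

    rng = np.random.default_rng(seed)
    p_exact = np.empty((len(names), n_perm))
    p_corr = np.empty((len(names), n_perm))
    for k in range(n_perm):
        outer_mask = rng.permutation(ref_mask)
        obs = _per_set_statistic(values, outer_mask, M, denoms, aggregate)
        counts = np.zeros(len(names))
        for _ in range(n_inner):
            inner_mask = rng.permutation(outer_mask)
            perm = _per_set_statistic(values, inner_mask, M, denoms, aggregate)
            counts += perm >= obs
        p_exact[:, k] = counts / n_inner
        p_corr[:, k] = (counts + 1) / (n_inner + 1)

    pooled_exact = np.sort(p_exact.ravel())
    pooled_corr = np.sort(p_corr.ravel())
    N = pooled_exact.size

    n_bins = 100
    if N < n_bins:
        import warnings

        n_bins = max(1, N)
        warnings.warn(
            f"only {N} pooled p-values; using {n_bins} quantile bins instead of 100"
        )
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    expected_q = (np.arange(N) + 0.5) / N
    bin_idx = np.clip(np.searchsorted(edges, expected_q, side="right") - 1, 0, n_bins - 1)

    obs_nl = np.full(n_bins, np.nan)
    exp_nl = np.empty(n_bins)
    counts_per_bin = np.zeros(n_bins, dtype=int)
    neglog_obs = -np.log10(pooled_corr)
    neglog_exp = -np.log10(expected_q)
    for b in range(n_bins):
        in_bin = bin_idx == b
        counts_per_bin[b] = int(in_bin.sum())
        lo, hi = edges[b], edges[b + 1]
        # expected mean of -log10(p) for p uniform on (lo, hi]
        if counts_per_bin[b]:
            exp_nl[b] = float(neglog_exp[in_bin].mean())
            obs_nl[b] = float(neglog_obs[in_bin].mean())
        else:
            mid = (lo + hi) / 2 if hi > lo else hi
            exp_nl[b] = -np.log10(mid) if mid > 0 else np.nan
    empty = [b for b in range(n_bins) if counts_per_bin[b] == 0]

    ok = ~np.isnan(obs_nl)
    denom = float((exp_nl[ok] ** 2).sum())
    qq_slope = float((obs_nl[ok] * exp_nl[ok]).sum() / denom) if denom > 0 else float("nan")

    ks = sps.kstest(pooled_exact, "uniform")
    degenerate = bool(np.allclose(pooled_exact, 1.0))

    return NullCalibrationReport(
        p_matrix=pd.DataFrame(p_exact, index=names),
        p_corrected_matrix=pd.DataFrame(p_corr, index=names),
        n_perm=n_perm,
        n_inner=n_inner,
        seed=seed,
        n_bins=n_bins,
        bin_edges=edges,
        observed_mean_neglog10=obs_nl,
        expected_mean_neglog10=exp_nl,
        bin_counts=counts_per_bin,
        empty_bins=empty,
        qq_slope=qq_slope,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        degenerate=degenerate,
    )


def plot_qq(report: NullCalibrationReport, path=None, ax=None):
    """QQ plot of observed vs expected -log10(p) bin means."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x, y = report.expected_mean_neglog10, report.observed_mean_neglog10
    ax.scatter(x, y, s=12)
    lim = np.nanmax([np.nanmax(x), np.nanmax(y)])
    ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--")
    ax.set_xlabel("expected $-\\log_{10}(p)$")
    ax.set_ylabel("observed $-\\log_{10}(p)$")
    ax.set_title(f"QQ slope = {report.qq_slope:.3f}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
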