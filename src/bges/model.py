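"""Model/Results interface over the scoring pipeline.

:class:`GeneSetEnrichment` is constructed from data (expression, labels,
gene sets) and ``fit()`` returns an :class:`EnrichmentResults` carrying the
enrichment matrix, the per-gene reference statistics behind it, bookkeeping
diagnostics and a ``summary()`` table; permutation testing and plotting hang
off the results object. :class:`OneVsRestEnrichment` does the same for the
cell-type workflow where each type is scored against all other cells.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import core, significance
from .containers import EnrichmentMatrix, ExpressionMatrix, GeneSetCollection
from .errors import ConfigurationError

__all__ = [
    "GeneSetEnrichment",
    "EnrichmentResults",
    "OneVsRestEnrichment",
    "OneVsRestResults",
]


class GeneSetEnrichment:
    """Two-condition gene-set enrichment model.

    Parameters
    ----------
    expression
        Genes x samples DataFrame of non-negative normalized expression, or
        an :class:`ExpressionMatrix` (in which case ``labels`` and
        ``reference_level`` are taken from it).
    labels
        Per-sample condition label (Series indexed by sample id, or mapping).
    gene_sets
        A :class:`GeneSetCollection` or mapping of set name -> member genes.
    reference_level
        The label level forming the reference condition (C2).
    denominator
        ``"measured"`` (default) divides each set's hit count by the number
        of member genes present in the matrix; ``"full"`` divides by the
        full set size.
    score_samples
        ``"query"`` (default) scores only C1 samples; ``"all"`` scores every
        sample against the C2-derived thresholds.

    Examples
    --------
    >>> model = GeneSetEnrichment(expr_df, labels, sets, reference_level="normal")
    >>> res = model.fit()
    >>> res.scores            # sets x samples DataFrame in [0, 1]
    >>> print(res.summary())
    """

    def __init__(
        self,
        expression: pd.DataFrame | ExpressionMatrix,
        labels: pd.Series | Mapping | None = None,
        gene_sets: GeneSetCollection | Mapping[str, Sequence[str]] | None = None,
        reference_level: str | None = None,
        denominator: str = "measured",
        score_samples: str = "query",
    ) -> None:
        if isinstance(expression, ExpressionMatrix):
            if reference_level is not None:
                expression = ExpressionMatrix(
                    expression.values, expression.labels, reference_level
                )
            self.data = expression
        else:
            if labels is None:
                raise ConfigurationError("labels are required with a plain matrix")
            self.data = ExpressionMatrix(expression, pd.Series(labels), reference_level)
        if self.data.reference_level is None:
            raise ConfigurationError("a reference_level is required")
        if gene_sets is None:
            raise ConfigurationError("gene_sets are required")
        self.gene_sets = (
            gene_sets
            if isinstance(gene_sets, GeneSetCollection)
            else GeneSetCollection(gene_sets)
        )
        self.denominator = denominator
        self.score_samples = score_samples

    @classmethod
    def from_dataframe(
        cls,
        expression: pd.DataFrame,
        labels: pd.Series,
        gene_sets,
        reference_level: str,
        **kwargs,
    ) -> "GeneSetEnrichment":
        """Build the model from a genes x samples DataFrame and label Series."""
        return cls(expression, labels, gene_sets, reference_level, **kwargs)

    def fit(self) -> "EnrichmentResults":
        """Run the pipeline: reference stats, binarization, set scoring."""
        stats = core.compute_reference_stats(self.data)
        binary = core.binarize(self.data, stats, which=self.score_samples)
        em = core.score_gene_sets(binary, self.gene_sets, denominator_mode=self.denominator)
        return EnrichmentResults(self, em, stats)


class EnrichmentResults:
    """Fitted enrichment scores plus diagnostics.

    Attributes
    ----------
    scores : pandas.DataFrame
        Gene sets x samples enrichment scores in [0, 1].
    reference_stats : ReferenceStats
        Per-gene mu/sigma over the reference samples (the thresholds are
        ``reference_stats.threshold``).
    genes_measured : pandas.Series
        Member genes of each kept set found in the expression matrix.
    dropped_sets : list
        Sets with no measured member gene.
    """

    def __init__(self, model: GeneSetEnrichment, em: EnrichmentMatrix, stats) -> None:
        self.model = model
        self.enrichment = em
        self.reference_stats = stats

    @property
    def scores(self) -> pd.DataFrame:
        return self.enrichment.scores

    @property
    def genes_measured(self) -> pd.Series:
        return self.enrichment.genes_measured

    @property
    def dropped_sets(self) -> list:
        return self.enrichment.dropped_sets

    def summary(self) -> str:
        """Per-set summary table: size, measured genes, mean/SD of scores."""
        full_sizes = self.model.gene_sets.sizes().reindex(self.scores.index)
        tab = pd.DataFrame(
            {
                "n_genes": full_sizes,
                "n_measured": self.genes_measured,
                "mean_es": self.scores.mean(axis=1),
                "sd_es": self.scores.std(axis=1, ddof=1),
                "min_es": self.scores.min(axis=1),
                "max_es": self.scores.max(axis=1),
            }
        )
        lines = [
            "Gene-set enrichment (binarized scoring)",
            f"  reference (C2) samples: {self.model.data.n_reference}",
            f"  scored samples:         {self.scores.shape[1]}",
            f"  denominator mode:       {self.enrichment.denominator_mode}",
            f"  dropped sets:           {len(self.dropped_sets)}",
            "",
            tab.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def min_max_scaled(self) -> pd.DataFrame:
        """Scores min-max scaled to [0, 1] across the whole matrix."""
        from .evaluation import min_max_scale

        flat = min_max_scale(self.scores.to_numpy().ravel())
        return pd.DataFrame(
            flat.reshape(self.scores.shape),
            index=self.scores.index,
            columns=self.scores.columns,
        )

    def permutation_test(
        self,
        n: int = 1000,
        seed: int | None = None,
        sets: Sequence[str] | None = None,
        statistic: str | Callable = "mean",
    ) -> pd.DataFrame:
        """Label-permutation p-values for each (or selected) gene set.

        Returns a DataFrame with the observed statistic, the exact p-value
        #{ES_perm >= ES_obs}/n and the corrected (count+1)/(n+1) variant.
        Per-set seeds are derived deterministically from ``seed``.
        """
        names = list(sets) if sets is not None else list(self.scores.index)
        ss = np.random.SeedSequence(seed)
        rows = []
        for name, child in zip(names, ss.spawn(len(names))):
            child_seed = int(child.generate_state(1)[0] % (2**31))
            res = significance.permutation_pvalue(
                self.model.data,
                self.model.gene_sets[name],
                n=n,
                statistic=statistic,
                seed=child_seed,
                denominator_mode=self.model.denominator,
                set_name=name,
            )
            rows.append(
                {
                    "gene_set": name,
                    "es_obs": res.es_obs,
                    "p_value": res.p_value,
                    "p_corrected": res.p_corrected,
                    "n": res.n,
                    "seed": child_seed,
                }
            )
        return pd.DataFrame(rows).set_index("gene_set")

    def plot_heatmap(self, ax=None, cmap: str = "viridis"):
        """Heatmap of the enrichment matrix (sets x samples)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(
                figsize=(max(4, 0.2 * self.scores.shape[1]), max(3, 0.25 * self.scores.shape[0]))
            )
        im = ax.imshow(self.scores.to_numpy(), aspect="auto", cmap=cmap, vmin=0, vmax=1)
        ax.set_yticks(range(self.scores.shape[0]), self.scores.index)
        ax.set_xlabel("samples")
        ax.figure.colorbar(im, ax=ax, label="enrichment score")
        return ax


class OneVsRestEnrichment:
    """One-vs-rest signature enrichment model for cell-type-labeled data.

    For each cell type with a signature set, all other cells form the
    reference condition; every cell is binarized against the complement's
    statistics and scored for that type's signature.
    """

    def __init__(
        self,
        expression: pd.DataFrame | ExpressionMatrix,
        cell_types: pd.Series | Mapping | None = None,
        signatures: GeneSetCollection | Mapping[str, Sequence[str]] | None = None,
        denominator: str = "measured",
    ) -> None:
        if isinstance(expression, ExpressionMatrix):
            self.data = expression
        else:
            if cell_types is None:
                raise ConfigurationError("cell_types are required with a plain matrix")
            self.data = ExpressionMatrix(expression, pd.Series(cell_types))
        if signatures is None:
            raise ConfigurationError("signatures are required")
        self.signatures = (
            signatures
            if isinstance(signatures, GeneSetCollection)
            else GeneSetCollection(signatures)
        )
        self.denominator = denominator

    def fit(self) -> "OneVsRestResults":
        em = core.one_vs_rest_scores(
            self.data, self.signatures, denominator_mode=self.denominator
        )
        return OneVsRestResults(self, em)


class OneVsRestResults:
    """Types x cells signature scores with in/out-of-type comparisons."""

    def __init__(self, model: OneVsRestEnrichment, em: EnrichmentMatrix) -> None:
        self.model = model
        self.enrichment = em

    @property
    def scores(self) -> pd.DataFrame:
        return self.enrichment.scores

    def fold_changes(self) -> pd.Series:
        """Per type: mean score of in-type cells over mean of all other cells."""
        labels = self.model.data.labels
        out = {}
        for t in self.scores.index:
            mask = (labels == t).to_numpy()
            out[t] = core.fold_change_of_means(self.scores.loc[t].to_numpy(), mask)
        return pd.Series(out, name="fold_change")

    def summary(self) -> str:
        labels = self.model.data.labels
        rows = {}
        for t in self.scores.index:
            mask = (labels == t).to_numpy()
            s = self.scores.loc[t].to_numpy()
            rows[t] = {
                "n_cells": int(mask.sum()),
                "mean_in": s[mask].mean(),
                "mean_out": s[~mask].mean(),
                "fold_change": core.fold_change_of_means(s, mask),
            }
        tab = pd.DataFrame(rows).T
        tab["n_cells"] = tab["n_cells"].astype(int)
        return (
            "One-vs-rest signature enrichment\n"
            f"  cell types scored: {self.scores.shape[0]}\n"
            f"  cells:             {self.scores.shape[1]}\n\n"
            + tab.to_string(float_format=lambda v: f"{v:.4f}")
        )
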