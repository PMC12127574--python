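"""The binarized enrichment scoring algorithm.

Two steps. First, each gene g is discretized against the reference
condition: with mu_g the mean and sigma_g the population standard deviation
of g's expression over the reference (C2) samples, an expression value
v(g, s) maps to 1 when v(g, s) > mu_g + sigma_g and to 0 otherwise (strict
inequality; ties at the threshold map to 0). Second, a gene set's enrichment
score in sample s is the fraction of its genes with binarized value 1 in s,
so scores lie on the grid {0, 1/G, ..., 1}.

Because the threshold is built from each gene's own reference statistics,
scores are invariant under per-gene affine rescaling (shift by a constant or
multiplication by a positive constant applied to all samples of that gene).

One-vs-rest mode repeats the procedure once per cell type, using all cells
NOT of that type as the reference condition and scoring that type's
signature set in every cell.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    BinaryMatrix,
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    ReferenceStats,
)
from .errors import AlignmentError, ConfigurationError, DataError

__all__ = [
    "compute_reference_stats",
    "binarize",
    "score_gene_sets",
    "enrich",
    "one_vs_rest_scores",
    "fold_change_of_means",
]


def compute_reference_stats(expr: ExpressionMatrix) -> ReferenceStats:
    """Per-gene mean and population SD over the reference (C2) samples.

    The population divisor (1/n_ref) is used, so a single reference sample
    yields sigma = 0 for every gene.
    """
    ref = expr.reference_samples
    if len(ref) == 0:
        raise ConfigurationError("no reference (C2) samples")
    vals = expr.values[ref].to_numpy(dtype=float)
    mu = vals.mean(axis=1)
    sigma = vals.std(axis=1, ddof=0)
    return ReferenceStats(
        mu=pd.Series(mu, index=expr.gene_ids, name="mu"),
        sigma=pd.Series(sigma, index=expr.gene_ids, name="sigma"),
        n_ref=len(ref),
    )


def binarize(
    expr: ExpressionMatrix, stats: ReferenceStats, which: str = "query"
) -> BinaryMatrix:
    """Discretize expression to 0/1 against per-gene thresholds mu + sigma.

    Parameters
    ----------
    which
        ``"query"`` scores only the query (C1) samples — the default
        two-condition workflow; ``"all"`` scores every sample, as needed for
        one-vs-rest comparisons where reference cells are scored too.
    """
    if which not in ("query", "all"):
        raise ConfigurationError(f"which must be 'query' or 'all', got {which!r}")
    if set(stats.gene_ids) != set(expr.gene_ids):
        raise AlignmentError(
            "gene identifiers of reference stats do not match the expression matrix"
        )
    thr = stats.threshold.reindex(expr.gene_ids).to_numpy()
    cols = expr.query_samples if which == "query" else expr.sample_ids
    vals = expr.values[cols].to_numpy(dtype=float)
    entries = (vals > thr[:, None]).astype(np.uint8)
    return BinaryMatrix(pd.DataFrame(entries, index=expr.gene_ids, columns=cols))


def score_gene_sets(
    binary: BinaryMatrix,
    sets: GeneSetCollection,
    denominator_mode: str = "measured",
) -> EnrichmentMatrix:
    """Score each gene set in each sample from a binarized matrix.

    score(set, s) = #{member genes measured and binarized 1 in s} / denominator,
    with denominator the number of measured member genes (mode ``"measured"``)
    or the full set size |GS| (mode ``"full"``). Sets with no measured member
    are dropped with a warning and listed in the result's ``dropped_sets``.
    """
    if denominator_mode not in ("measured", "full"):
        raise ConfigurationError(
            f"denominator_mode must be 'measured' or 'full', got {denominator_mode!r}"
        )
    gene_pos = {g: i for i, g in enumerate(binary.gene_ids)}
    entries = binary.entries.to_numpy()

    rows, measured, denoms, kept, dropped = [], [], [], [], []
    for name in sets:
        idx = [gene_pos[g] for g in sets[name] if g in gene_pos]
        if not idx:
            dropped.append(name)
            continue
        denom = len(idx) if denominator_mode == "measured" else len(sets[name])
        rows.append(entries[idx].sum(axis=0) / denom)
        measured.append(len(idx))
        denoms.append(denom)
        kept.append(name)

    if dropped:
        warnings.warn(
            f"{len(dropped)} gene set(s) had no measured genes and were dropped: "
            f"{dropped[:5]}"
        )
    if not kept:
        raise DataError("no gene set has any member measured in the matrix")

    scores = pd.DataFrame(np.vstack(rows), index=kept, columns=binary.sample_ids)
    return EnrichmentMatrix(
        scores=scores,
        genes_measured=pd.Series(measured, index=kept, name="genes_measured"),
        denominator_mode=denominator_mode,
        dropped_sets=dropped,
    )


def enrich(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    denominator_mode: str = "measured",
    which: str = "query",
) -> EnrichmentMatrix:
    """End-to-end pipeline: reference stats -> binarize -> score gene sets.

    Deterministic; output sample order preserves the input order of the
    scored samples.
    """
    stats = compute_reference_stats(expr)
    binary = binarize(expr, stats, which=which)
    return score_gene_sets(binary, sets, denominator_mode=denominator_mode)


def one_vs_rest_scores(
    expr: ExpressionMatrix,
    signatures: GeneSetCollection,
    denominator_mode: str = "measured",
) -> EnrichmentMatrix:
    """Score each cell type's signature in every cell, one type at a time.

    For each type t present in both the labels and the signature collection,
    the reference condition is "all cells not of type t"; reference stats are
    computed from that complement, ALL cells are binarized against them, and
    the signature set of t is scored in every cell. The per-type rows are
    stacked into one (types x cells) matrix, enabling in-type vs out-of-type
    mean comparisons.
    """
    levels = [str(x) for x in pd.unique(expr.labels)]
    if len(levels) < 2:
        raise ConfigurationError(
            "one-vs-rest scoring needs at least two cell types in the labels"
        )
    types = [t for t in signatures if t in levels]
    if not types:
        raise ConfigurationError(
            "no signature set name matches any cell-type label; "
            f"labels: {levels[:10]}, signatures: {signatures.set_names[:10]}"
        )

    rows, measured, dropped = [], [], []
    for t in types:
        rest = f"__not_{t}__"
        labels = expr.labels.where(expr.labels == t, rest)
        sub = expr.with_labels(labels, reference_level=rest)
        em = enrich(
            sub, signatures.subset([t]), denominator_mode=denominator_mode, which="all"
        )
        if t in em.dropped_sets:
            dropped.append(t)
            continue
        rows.append(em.scores.loc[t].reindex(expr.sample_ids))
        measured.append(int(em.genes_measured[t]))
    if not rows:
        raise DataError("no signature set has any member measured in the matrix")
    scores = pd.DataFrame(rows)
    kept = scores.index.tolist()
    return EnrichmentMatrix(
        scores=scores,
        genes_measured=pd.Series(measured, index=kept, name="genes_measured"),
        denominator_mode=denominator_mode,
        dropped_sets=dropped,
    )


def fold_change_of_means(
    scores: Sequence[float] | pd.Series,
    in_group: Sequence[bool] | np.ndarray,
) -> float:
    """Ratio of mean score in-group over mean score out-of-group.

    Conventions for degenerate denominators: returns ``inf`` when the
    out-group mean is 0 and the in-group mean is positive, and 1.0 when both
    means are 0.
    """
    s = np.asarray(scores, dtype=float)
    mask = np.asarray(in_group, dtype=bool)
    if mask.shape != s.shape:
        raise DataError("group mask length does not match scores")
    if not mask.any() or mask.all():
        raise DataError("both groups must be non-empty")
    m_in = s[mask].mean()
    m_out = s[~mask].mean()
    if m_out == 0:
        return 1.0 if m_in == 0 else math.inf
    return float(m_in / m_out)
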