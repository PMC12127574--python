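"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain Python loops and scalar arithmetic so
they share no code path with the vectorized implementation they check.
"""

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from bges import ExpressionMatrix, GeneSetCollection

DATA = Path(__file__).parent / "data"


# ---------------------------------------------------------------- oracles
def oracle_reference_stats(values: pd.DataFrame, ref_cols):
    """Scalar-loop mean and population SD per gene over reference columns."""
    mu, sd = {}, {}
    for g in values.index:
        vs = [float(values.loc[g, c]) for c in ref_cols]
        m = sum(vs) / len(vs)
        mu[g] = m
        sd[g] = (sum((v - m) ** 2 for v in vs) / len(vs)) ** 0.5
    return mu, sd


def oracle_scores(
    values: pd.DataFrame,
    labels: pd.Series,
    reference_level: str,
    sets: dict,
    denominator_mode: str = "measured",
    which: str = "query",
):
    """Naive triple-loop (gene x sample x set) scoring pipeline."""
    ref_cols = [s for s in values.columns if labels[s] == reference_level]
    if which == "query":
        scored = [s for s in values.columns if labels[s] != reference_level]
    else:
        scored = list(values.columns)
    mu, sd = oracle_reference_stats(values, ref_cols)

    out = {}
    for name, members in sets.items():
        measured = [g for g in dict.fromkeys(members) if g in values.index]
        if not measured:
            continue
        denom = len(measured) if denominator_mode == "measured" else len(set(members))
        row = {}
        for s in scored:
            k = 0
            for g in measured:
                if float(values.loc[g, s]) > mu[g] + sd[g]:
                    k += 1
            row[s] = k / denom
        out[name] = row
    return pd.DataFrame(out).T.reindex(columns=scored)


def oracle_binary(values: pd.DataFrame, labels, reference_level, which="query"):
    """Naive 0/1 discretization against mu + sigma of the reference columns."""
    ref_cols = [s for s in values.columns if labels[s] == reference_level]
    if which == "query":
        scored = [s for s in values.columns if labels[s] != reference_level]
    else:
        scored = list(values.columns)
    mu, sd = oracle_reference_stats(values, ref_cols)
    out = pd.DataFrame(0, index=values.index, columns=scored, dtype=int)
    for g in values.index:
        for s in scored:
            if float(values.loc[g, s]) > mu[g] + sd[g]:
                out.loc[g, s] = 1
    return out


def oracle_exhaustive_pvalue(values: pd.DataFrame, n_ref: int, members, es_obs):
    """Exact permutation p by enumerating all reference-subset assignments."""
    cols = list(values.columns)
    stats = []
    for ref_cols in combinations(cols, n_ref):
        mu, sd = oracle_reference_stats(values, ref_cols)
        query = [c for c in cols if c not in ref_cols]
        es = []
        for s in query:
            k = sum(1 for g in members if float(values.loc[g, s]) > mu[g] + sd[g])
            es.append(k / len(members))
        stats.append(sum(es) / len(es))
    return sum(1 for t in stats if t >= es_obs) / len(stats), stats


def oracle_ari(labels_a, labels_b) -> float:
    """Pair-counting adjusted Rand index over all item pairs."""
    n = len(labels_a)
    same_a = same_b = same_both = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            a = labels_a[i] == labels_a[j]
            b = labels_b[i] == labels_b[j]
            same_a += a
            same_b += b
            same_both += a and b
    expected = same_a * same_b / pairs
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (same_both - expected) / (max_index - expected)


def oracle_silhouette(points: np.ndarray, labels) -> float:
    """Per-point a(i)/b(i) silhouette with Euclidean distance, averaged."""
    labels = list(labels)
    n = len(labels)
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    svals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            svals.append(0.0)
            continue
        a = sum(dist[i, j] for j in own) / len(own)
        b = min(
            sum(dist[i, j] for j in range(n) if labels[j] == other)
            / sum(1 for j in range(n) if labels[j] == other)
            for other in set(labels)
            if other != labels[i]
        )
        svals.append((b - a) / max(a, b))
    return sum(svals) / n


def random_instance(rng, max_genes=30, max_samples=15, max_sets=5):
    """A random small labeled matrix + gene sets for oracle comparisons."""
    n_genes = rng.integers(3, max_genes + 1)
    n_samples = rng.integers(4, max_samples + 1)
    n_ref = rng.integers(2, n_samples - 1)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    values = pd.DataFrame(
        rng.gamma(2.0, 3.0, size=(n_genes, n_samples)), index=genes, columns=samples
    )
    lab = np.array(["C1"] * n_samples, dtype=object)
    lab[rng.choice(n_samples, n_ref, replace=False)] = "C2"
    labels = pd.Series(lab, index=samples)
    sets = {}
    for k in range(rng.integers(1, max_sets + 1)):
        size = rng.integers(1, n_genes + 1)
        members = list(rng.choice(genes, size=size, replace=False))
        if rng.random() < 0.3:  # sometimes include unmeasured genes
            members.append(f"missing{k}")
        sets[f"set{k}"] = members
    return values, labels, sets


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def toy_values() -> pd.DataFrame:
    return pd.DataFrame(
        [[1.0, 3.0, 4.0, 3.0, 1.0], [5.0, 5.0, 6.0, 5.0, 2.0], [2.0, 4.0, 10.0, 5.0, 0.0]],
        index=["g1", "g2", "g3"],
        columns=["n1", "n2", "t1", "t2", "t3"],
    )


@pytest.fixture(scope="session")
def toy_labels() -> pd.Series:
    return pd.Series(
        ["normal", "normal", "tumor", "tumor", "tumor"],
        index=["n1", "n2", "t1", "t2", "t3"],
    )


@pytest.fixture(scope="session")
def toy_sets() -> dict:
    return {"S1": ["g1", "g2"], "S2": ["g1", "g3", "gX"]}


@pytest.fixture
def toy_expr(toy_values, toy_labels) -> ExpressionMatrix:
    return ExpressionMatrix(toy_values, toy_labels, reference_level="normal")


@pytest.fixture
def toy_collection(toy_sets) -> GeneSetCollection:
    return GeneSetCollection(toy_sets)


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA
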