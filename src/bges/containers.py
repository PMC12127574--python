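"""Core data containers.

The package works on a genes x samples expression matrix with a categorical
label per sample. One label level is designated the *reference* condition
(C2 in the two-condition workflow: e.g. normal tissue, or "all other cell
types" in one-vs-rest mode); every other sample is a *query* (C1) sample.
Gene sets are named lists of gene identifiers, typically read from GMT files.

Containers validate their invariants on construction; they are light wrappers
around :class:`pandas.DataFrame` / :class:`pandas.Series` and expose the
underlying objects directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, DataError

__all__ = [
    "ExpressionMatrix",
    "ReferenceStats",
    "BinaryMatrix",
    "GeneSetCollection",
    "EnrichmentMatrix",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what} identifiers: {dupes[:10]}")


@dataclass
class ExpressionMatrix:
    """A labeled genes x samples expression matrix.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample (or cell)
        identifiers as columns. Entries must be finite. Values are consumed
        as provided — no internal log-transform or normalization is applied.
    labels
        Per-sample categorical label, indexed by sample identifier. Must
        cover every column of ``values`` exactly once.
    reference_level
        The label level whose samples form the reference condition (C2).
        ``None`` means no condition roles are assigned yet (e.g. cell-type
        labels used in one-vs-rest mode).
    """

    values: pd.DataFrame
    labels: pd.Series
    reference_level: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        self.labels = pd.Series(self.labels)
        missing = self.values.columns.difference(self.labels.index)
        if len(missing):
            raise DataError(f"samples without a label: {missing.tolist()[:10]}")
        # keep labels aligned to the matrix column order
        self.labels = self.labels.reindex(self.values.columns)
        if self.reference_level is not None:
            levels = set(self.labels.unique())
            if self.reference_level not in levels:
                raise ConfigurationError(
                    f"reference level {self.reference_level!r} not among "
                    f"label levels {sorted(map(str, levels))}"
                )
            if self.n_reference == 0 or self.n_query == 0:
                raise ConfigurationError(
                    "both reference (C2) and query (C1) conditions need at least one sample"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- condition roles ------------------------------------------------
    def _require_roles(self) -> None:
        if self.reference_level is None:
            raise ConfigurationError(
                "no reference level set; assign condition roles first"
            )

    @property
    def reference_mask(self) -> np.ndarray:
        self._require_roles()
        return (self.labels == self.reference_level).to_numpy()

    @property
    def reference_samples(self) -> pd.Index:
        return self.sample_ids[self.reference_mask]

    @property
    def query_samples(self) -> pd.Index:
        return self.sample_ids[~self.reference_mask]

    @property
    def n_reference(self) -> int:
        return int(self.reference_mask.sum())

    @property
    def n_query(self) -> int:
        return int((~self.reference_mask).sum())

    def with_labels(self, labels: pd.Series, reference_level: str | None) -> "ExpressionMatrix":
        """Return a copy with a different label assignment."""
        return ExpressionMatrix(self.values, labels, reference_level)


@dataclass
class ReferenceStats:
    """Per-gene mean and standard deviation over the reference condition.

    ``sigma`` uses the population divisor (1/n over the reference samples),
    not the n-1 sample estimator; with a single reference sample sigma is 0.
    """

    mu: pd.Series
    sigma: pd.Series
    n_ref: int

    def __post_init__(self) -> None:
        if len(self.mu) != len(self.sigma):
            raise AlignmentError("mu and sigma lengths differ")
        if self.n_ref < 1:
            raise ConfigurationError("need at least one reference sample")
        if (self.sigma.to_numpy() < 0).any():
            raise DataError("negative sigma")

    @property
    def gene_ids(self) -> pd.Index:
        return self.mu.index

    @property
    def threshold(self) -> pd.Series:
        """The per-gene binarization threshold mu + sigma."""
        return self.mu + self.sigma


@dataclass
class BinaryMatrix:
    """0/1 discretized expression over the scored samples."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.entries.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise DataError("binary matrix entries must be 0 or 1")
        self.entries = self.entries.astype(np.uint8)

    @property
    def gene_ids(self) -> pd.Index:
        return self.entries.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.entries.columns


class GeneSetCollection(Mapping[str, list]):
    """An ordered collection of named gene sets.

    Duplicate member genes within a set are collapsed (order preserved,
    warning emitted); duplicate set names are an error. Behaves as a mapping
    from set name to member list.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]] | Iterable[tuple[str, Sequence[str]]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
        self._sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, members in items:
            if name in self._sets:
                raise DataError(f"duplicate gene set name {name!r}")
            cleaned: list[str] = []
            seen: set[str] = set()
            for g in members:
                g = str(g).strip()
                if not g:
                    continue
                if g in seen:
                    continue
                seen.add(g)
                cleaned.append(g)
            if len(cleaned) < len([m for m in members if str(m).strip()]):
                warnings.warn(f"gene set {name!r}: duplicate members collapsed")
            if not cleaned:
                raise DataError(f"gene set {name!r} is empty")
            self._sets[name] = cleaned
            self.descriptions[name] = (descriptions or {}).get(name, "")

        if not self._sets:
            raise DataError("empty gene set collection")

    # Mapping interface
    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def set_names(self) -> list[str]:
        return list(self._sets)

    def sizes(self) -> pd.Series:
        """Full set sizes |GS| (including genes absent from any given matrix)."""
        return pd.Series({n: len(m) for n, m in self._sets.items()}, name="size")

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self._sets[n] for n in names},
            {n: self.descriptions[n] for n in names},
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"


@dataclass
class EnrichmentMatrix:
    """Gene sets x samples enrichment scores in [0, 1].

    Each score is the fraction of the set's genes binarized to 1 in that
    sample, so every entry is an exact multiple of 1/denominator where the
    denominator is either the number of the set's genes measured in the
    expression matrix (``denominator_mode='measured'``, default) or the full
    set size (``'full'``).
    """

    scores: pd.DataFrame
    genes_measured: pd.Series
    denominator_mode: str = "measured"
    dropped_sets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy()
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise DataError("enrichment scores must lie in [0, 1]")

    @property
    def set_names(self) -> pd.Index:
        return self.scores.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.columns
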