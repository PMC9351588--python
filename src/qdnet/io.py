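"""Reading, validating and aggregating abundance tables.

The central container is :class:`AbundanceMatrix`: a samples x taxa matrix of
non-negative abundances with string identifiers and optional per-sample
metadata (context / gut position / subject).  The row sum of a sample is its
*habitat index* — the total abundance the habitat carries — which downstream
modules use as the quasi-dynamic independent variable, so every retained
sample must have a strictly positive total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical rank order for taxonomy tables
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class AbundanceMatrix:
    """Samples x taxa non-negative abundance matrix with identifiers.

    Parameters
    ----------
    values
        ``(n_samples, n_taxa)`` array, all entries finite and ``>= 0``.
    sample_ids, taxon_ids
        Unique string identifiers matching the matrix dimensions.
    context, position, subject
        Optional per-sample categorical labels (length ``n_samples``).
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    context: np.ndarray | None = None
    position: np.ndarray | None = None
    subject: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("abundance values must be a 2-D matrix")
        n, m = self.values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(self.taxon_ids) != m:
            raise ValueError("taxon_ids length does not match matrix columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != m:
            raise ValueError("duplicate taxon ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundance matrix contains non-finite entries")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        for name in ("context", "position", "subject"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab, dtype=object)
                if lab.shape != (n,):
                    raise ValueError(f"{name} labels must have length {n}")
                setattr(self, name, lab)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def habitat_index(self) -> np.ndarray:
        """Per-sample habitat index ``H_i = sum_j y_ij`` (exact row sum)."""
        return self.values.sum(axis=1)

    def column(self, taxon: str) -> np.ndarray:
        return self.values[:, self.taxon_ids.index(taxon)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "AbundanceMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        sub = lambda lab: None if lab is None else lab[keep]  # noqa: E731
        return AbundanceMatrix(
            self.values[keep],
            [self.sample_ids[i] for i in keep],
            list(self.taxon_ids),
            context=sub(self.context),
            position=sub(self.position),
            subject=sub(self.subject),
        )

    def subset_taxa(self, taxa: Sequence[str]) -> "AbundanceMatrix":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return AbundanceMatrix(
            self.values[:, idx],
            list(self.sample_ids),
            [self.taxon_ids[i] for i in idx],
            context=self.context,
            position=self.position,
            subject=self.subject,
        )


@dataclass
class TaxonomyMap:
    """Maps taxon id to an ordered lineage (kingdom .. species)."""

    lineages: Mapping[str, Mapping[str, str]]

    def rank_of(self, taxon: str, level: str) -> str | None:
        lin = self.lineages.get(taxon)
        if lin is None:
            return None
        return lin.get(level)


def habitat_index(matrix: AbundanceMatrix) -> np.ndarray:
    """Habitat index of every sample: the exact row sum of the matrix."""
    return matrix.habitat_index()


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_abundance(
    path: str | Path,
    delimiter: str | None = None,
    orientation: str = "samples-rows",
    drop_zero_samples: bool = True,
) -> AbundanceMatrix:
    """Load a delimited abundance table into an :class:`AbundanceMatrix`.

    The canonical dialect has a header row of taxon ids and a first column of
    sample ids.  ``orientation="taxa-rows"`` transposes a table stored the
    other way round; loading a transposed file with that flag yields the same
    matrix as loading the untransposed file.

    Samples whose total abundance is zero cannot carry a habitat index and
    are dropped with a logged warning (unless ``drop_zero_samples=False``, in
    which case they raise).
    """
    path = Path(path)
    if orientation not in ("samples-rows", "taxa-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column ids in header: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if orientation == "taxa-rows":
        df = df.T
    body = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df.iloc[:, j]):
            try:
                body[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r} in {path}"
                ) from None
    if np.any(~np.isfinite(body)):
        i, j = np.argwhere(~np.isfinite(body))[0]
        raise ValueError(
            f"missing/non-finite cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    matrix = AbundanceMatrix(body, list(df.index), list(df.columns))
    totals = matrix.habitat_index()
    if np.any(totals <= 0):
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        if not drop_zero_samples:
            raise ValueError(f"samples with zero total abundance: {bad}")
        logger.warning("dropping %d zero-total sample(s): %s", len(bad), bad)
        matrix = matrix.subset_samples(totals > 0)
    return matrix


def write_abundance(matrix: AbundanceMatrix, path: str | Path, delimiter: str | None = None) -> None:
    """Write the canonical dialect (samples as rows, taxa as header)."""
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path, delimiter))


def load_metadata(matrix: AbundanceMatrix, path: str | Path, delimiter: str | None = None) -> AbundanceMatrix:
    """Attach per-sample ``context`` / ``position`` / ``subject`` labels.

    The metadata table is keyed by sample id in its first column; missing
    samples raise, extra rows are ignored.
    """
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0, dtype=str)
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing samples: {missing}")
    meta = meta.loc[matrix.sample_ids]
    kwargs = {}
    for name in ("context", "position", "subject"):
        if name in meta.columns:
            kwargs[name] = meta[name].to_numpy(dtype=object)
    return replace(matrix, **kwargs)


def load_taxonomy(path: str | Path, delimiter: str | None = None) -> TaxonomyMap:
    """Load a taxonomy table (first column taxon id, rank columns after)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0, dtype=str)
    ranks = [c.lower() for c in df.columns]
    lineages = {
        str(tid): {rank: str(val) for rank, val in zip(ranks, row)}
        for tid, row in zip(df.index, df.to_numpy())
    }
    return TaxonomyMap(lineages)


def aggregate(
    matrix: AbundanceMatrix,
    taxonomy: TaxonomyMap,
    level: str,
    top_k: int | None = None,
    other_label: str = "other",
    allow_missing: bool = True,
) -> AbundanceMatrix:
    """Sum taxon columns within each group at a taxonomic ``level``.

    Taxa absent from the taxonomy map fall into ``other_label`` when
    ``allow_missing`` (else they raise).  When ``top_k`` is set, groups are
    ranked by total abundance across samples (ties broken by lexicographic
    group name, for determinism) and ranks beyond ``top_k`` are merged into
    the "other" bin.  Per-sample totals — hence the habitat index — are
    conserved exactly.
    """
    level = level.lower()
    groups: dict[str, list[int]] = {}
    for j, taxon in enumerate(matrix.taxon_ids):
        name = taxonomy.rank_of(taxon, level)
        if name is None:
            if not allow_missing:
                raise ValueError(
                    f"taxon {taxon!r} missing from taxonomy and no 'other' policy"
                )
            name = other_label
        groups.setdefault(name, []).append(j)

    if top_k is not None and top_k < len(groups):
        totals = {g: matrix.values[:, idx].sum() for g, idx in groups.items()}
        ranked = sorted(groups, key=lambda g: (-totals[g], g))
        keep = set(ranked[:top_k])
        merged: dict[str, list[int]] = {}
        for g, idx in groups.items():
            target = g if g in keep else other_label
            merged.setdefault(target, []).extend(idx)
        groups = merged

    names = sorted(groups)
    values = np.column_stack([matrix.values[:, groups[g]].sum(axis=1) for g in names])
    return AbundanceMatrix(
        values,
        list(matrix.sample_ids),
        names,
        context=matrix.context,
        position=matrix.position,
        subject=matrix.subject,
    )
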