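"""Reading, writing and preprocessing of per-view omics matrices.

A *view* is one molecular layer (mRNA, miRNA, DNA methylation beta values,
protein abundance) measured on a shared set of samples and stored on disk as a
delimited features x samples matrix: first row sample IDs, first column
feature IDs.  Preprocessing follows the usual TCGA-style recipe:

1. drop features with more than a small fraction of missing values and set the
   surviving missing entries to zero;
2. log10-transform sequence-based expression views, with zeros mapped to one
   beforehand so they land at zero;
3. keep the most variable features;
4. restrict all views to the common, consistently ordered sample set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsView",
    "MultiOmicsDataset",
    "read_view",
    "write_view",
    "filter_missing",
    "log_transform",
    "variance_filter",
    "align_samples",
]

MODALITIES = ("sequence_expression", "methylation_beta", "protein", "other")


@dataclass
class OmicsView:
    """One omics view: a ``d_m x n`` (features x samples) real matrix.

    Missing entries are carried as NaN until :func:`filter_missing` resolves
    them; afterwards every entry is finite.
    """

    name: str
    X: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    modality: str = "other"
    is_logged: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D features x samples matrix")
        d, n = self.X.shape
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {d} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} columns")
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {kind} ID {dup!r}")

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class MultiOmicsDataset:
    """Sample-matched collection of views sharing one ordered sample list."""

    views: list[OmicsView]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("a dataset needs at least one view")
        if not self.sample_ids:
            self.sample_ids = list(self.views[0].sample_ids)
        if len(self.sample_ids) < 2:
            raise ValueError("a dataset needs at least two samples")
        for v in self.views:
            if v.sample_ids != self.sample_ids:
                raise ValueError(
                    f"view {v.name!r} has sample IDs inconsistent with the dataset"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


_MISSING = {"", "na", "nan", "n/a", "null"}


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_view(
    path: str | Path,
    name: str | None = None,
    modality: str = "other",
    delimiter: str | None = None,
) -> OmicsView:
    """Read a delimited features x samples matrix into an :class:`OmicsView`.

    Empty cells and ``NA``/``NaN`` markers (case-insensitive) are recorded as
    NaN; they are resolved later by :func:`filter_missing`.
    """
    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delim)
        sample_ids = [c.strip() for c in header[1:]]
        n = len(sample_ids)
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(delim)
            if len(cells) != n + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {n + 1} columns, found {len(cells)}"
                )
            feature_ids.append(cells[0].strip())
            rows.append([_parse_cell(c, path, lineno) for c in cells[1:]])
    X = np.asarray(rows, dtype=float) if rows else np.empty((0, n))
    return OmicsView(
        name=name or path.stem,
        X=X,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        modality=modality,
    )


def _parse_cell(cell: str, path: Path, lineno: int) -> float:
    s = cell.strip()
    if s.lower() in _MISSING:
        return math.nan
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: cannot parse cell {cell!r}") from exc


def write_view(view: OmicsView, path: str | Path, delimiter: str | None = None) -> None:
    """Write a view back as a delimited features x samples matrix."""
    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    view.to_frame().to_csv(path, sep=delim, index_label="")


def filter_missing(view: OmicsView, max_missing_frac: float = 0.05) -> OmicsView:
    """Drop features with too many missing values; zero-fill the rest.

    Features whose fraction of missing entries exceeds ``max_missing_frac``
    are removed; the remaining missing entries are replaced with 0.  The
    default threshold is 5%.
    """
    miss = np.isnan(view.X)
    frac = miss.mean(axis=1) if view.n_samples else np.zeros(view.n_features)
    keep = frac <= max_missing_frac
    if not keep.any():
        raise ValueError(f"view {view.name!r}: no features survive missing filter")
    X = view.X[keep].copy()
    X[np.isnan(X)] = 0.0
    return replace(
        view,
        X=X,
        feature_ids=[f for f, k in zip(view.feature_ids, keep) if k],
    )


def log_transform(view: OmicsView) -> OmicsView:
    """log10-transform a sequence-expression view, mapping 0 -> 1 -> 0 first.

    Zero counts are replaced with 1 before taking log10, so both 0 and 1
    collapse to 0 in the transformed view.
    """
    if view.modality != "sequence_expression":
        raise ValueError(
            f"view {view.name!r}: log transform applies to sequence_expression "
            f"views, not {view.modality!r}"
        )
    if view.is_logged:
        raise ValueError(f"view {view.name!r} is already log-transformed")
    if view.X.size and np.nanmin(view.X) < 0:
        raise ValueError(f"view {view.name!r} has negative entries")
    X = view.X.copy()
    X[X == 0] = 1.0
    with np.errstate(invalid="ignore"):
        X = np.log10(X)
    return replace(view, X=X, is_logged=True)


def variance_filter(view: OmicsView, top_n: int = 2000) -> OmicsView:
    """Keep the ``top_n`` most variable features (sample variance, ddof=1).

    Ties at the boundary and the retained set both preserve the original
    feature order.  The default of 2000 matches common practice for
    expression and methylation views.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if top_n >= view.n_features:
        return replace(view, X=view.X.copy())
    var = np.nanvar(view.X, axis=1, ddof=1)
    # stable sort on negated variance keeps original order among ties
    order = np.argsort(-var, kind="stable")[:top_n]
    keep = np.zeros(view.n_features, dtype=bool)
    keep[order] = True
    return replace(
        view,
        X=view.X[keep].copy(),
        feature_ids=[f for f, k in zip(view.feature_ids, keep) if k],
    )


def align_samples(views: Sequence[OmicsView]) -> MultiOmicsDataset:
    """Restrict every view to the shared samples, in first-view order."""
    if not views:
        raise ValueError("need at least one view")
    common = set(views[0].sample_ids)
    for v in views[1:]:
        common &= set(v.sample_ids)
    if not common:
        raise ValueError("sample ID intersection across views is empty")
    order = [s for s in views[0].sample_ids if s in common]
    aligned = []
    for v in views:
        idx = [v.sample_ids.index(s) for s in order]
        aligned.append(replace(v, X=v.X[:, idx].copy(), sample_ids=list(order)))
    return MultiOmicsDataset(views=aligned, sample_ids=list(order))


def preprocess_view(
    view: OmicsView,
    max_missing_frac: float = 0.05,
    top_n: int = 2000,
    log: bool | None = None,
) -> OmicsView:
    """Missing filter -> optional log transform -> variance filter.

    ``log=None`` applies the log transform exactly to sequence-expression
    views that are not yet logged.
    """
    out = filter_missing(view, max_missing_frac=max_missing_frac)
    do_log = (
        log
        if log is not None
        else (out.modality == "sequence_expression" and not out.is_logged)
    )
    if do_log:
        out = log_transform(out)
    return variance_filter(out, top_n=top_n)
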