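"""Transforms, alpha/beta diversity, ordination and trajectory distances.

Conventions follow QIIME 1: Shannon entropy in bits (log base 2), Faith's PD
includes the path to the root (PD_whole_tree), Bray-Curtis is computed on
relative abundances by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .io import DistanceMatrix, OtuTable, SampleMetadata

__all__ = [
    "TransformedTable",
    "OrdinationResult",
    "hellinger",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "distance_to_baseline",
]


@dataclass
class TransformedTable:
    """Hellinger-transformed abundances: ``A_ij = sqrt(n_ij / N_j)``.

    Each row has unit Euclidean norm; every value lies in [0, 1].
    """

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("values shape does not match ids")
        if np.any(self.values < 0):
            raise ValueError("transformed values must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class OrdinationResult:
    """Sample ordination: coordinates, eigenvalues and variance fractions."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # non-increasing
    proportion_explained: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.proportion_explained = np.asarray(self.proportion_explained, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        if self.proportion_explained.sum() > 1 + 1e-9:
            raise ValueError("proportion_explained sums above 1")


def hellinger(table: OtuTable) -> TransformedTable:
    """Hellinger transform: square root of relative abundance per sample."""
    props = table.proportions()
    return TransformedTable(list(table.sample_ids), list(table.otu_ids), np.sqrt(props))


def alpha_diversity(table: OtuTable, metric: str, tree=None) -> pd.Series:
    """Per-sample alpha diversity.

    ``observed_otus``: number of OTUs with nonzero count. ``shannon``:
    -sum(p*log2 p) over nonzero proportions. ``faith_pd``: total branch length
    of the minimal subtree connecting the observed OTUs, root included; needs
    ``tree`` with every observed OTU as a leaf.
    """
    counts = np.asarray(table.counts, dtype=float)
    if metric == "observed_otus":
        values = (counts > 0).sum(axis=1).astype(float)
    elif metric == "shannon":
        props = table.proportions()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(props > 0, props * np.log2(np.where(props > 0, props, 1.0)), 0.0)
        values = -terms.sum(axis=1)
    elif metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a tree")
        from skbio.diversity.alpha import faith_pd

        leaf_names = {t.name for t in tree.tips()}
        observed = {
            table.otu_ids[j]
            for j in range(counts.shape[1])
            if np.any(counts[:, j] > 0)
        }
        missing = sorted(observed - leaf_names)
        if missing:
            raise ValueError(f"tree is missing observed OTUs: {missing}")
        values = np.array(
            [faith_pd(row, table.otu_ids, tree) for row in counts], dtype=float
        )
    else:
        raise ValueError(f"unknown alpha metric {metric!r}")
    return pd.Series(values, index=table.sample_ids, name=metric)


def bray_curtis(table, use_proportions: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity ``1 - 2*sum(min)/(sum x + sum y)``.

    By default rows are normalised to proportions first (the metric is
    depth-sensitive on raw counts); pass ``use_proportions=False`` for the
    raw-count variant.
    """
    if isinstance(table, OtuTable):
        data = table.proportions() if use_proportions else table.counts.astype(float)
        ids = table.sample_ids
    else:  # TransformedTable-like carrying proportions
        data = np.asarray(table.values, dtype=float)
        ids = table.sample_ids
        if np.any(data.sum(axis=1) <= 0):
            raise ValueError("zero rows are not allowed")
    dm = squareform(pdist(data, metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(list(ids), dm)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling (principal coordinates analysis).

    Double-centres ``-0.5 * D**2``, eigendecomposes, and orders axes by
    decreasing eigenvalue. Negative eigenvalues are clamped to zero for the
    coordinates and excluded from the proportion-explained denominator.
    """
    n = len(dm.sample_ids)
    if n_axes is None:
        n_axes = n - 1
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    n_axes = min(n_axes, n - 1) if n > 1 else 1
    d2 = dm.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive_mass = eigvals[eigvals > 0].sum()
    clamped = np.clip(eigvals, 0.0, None)
    coords = eigvecs * np.sqrt(clamped)[None, :]
    prop = clamped / positive_mass if positive_mass > 0 else np.zeros_like(clamped)
    return OrdinationResult(
        list(dm.sample_ids),
        coords[:, :n_axes],
        clamped[:n_axes],
        prop[:n_axes],
        method="pcoa",
    )


def distance_to_baseline(
    table: OtuTable,
    meta: SampleMetadata,
    reference: str = "group_baseline_centroid",
) -> pd.DataFrame:
    """Bray-Curtis distance of each post-baseline sample to its baseline.

    Baseline samples are those with ``timepoint < 0``. The reference profile
    is the mean proportion vector over the baseline samples of the sample's
    group (``group_baseline_centroid``) or of its subject
    (``subject_baseline``).
    """
    if reference not in ("group_baseline_centroid", "subject_baseline"):
        raise ValueError(f"unknown reference mode {reference!r}")
    unit_col = "group" if reference == "group_baseline_centroid" else "subject"
    props = table.proportions()
    meta_df = meta.table.loc[table.sample_ids]
    baseline_mask = meta_df["timepoint"].to_numpy() < 0

    centroids: dict[str, np.ndarray] = {}
    units = meta_df[unit_col].astype(str).to_numpy()
    for unit in np.unique(units):
        sel = (units == unit) & baseline_mask
        if sel.any():
            centroids[unit] = props[sel].mean(axis=0)
    missing = sorted(set(units[~baseline_mask]) - set(centroids))
    if missing:
        raise ValueError(f"units with no baseline samples: {missing}")

    records = []
    for i, sid in enumerate(table.sample_ids):
        if baseline_mask[i]:
            continue
        c = centroids[units[i]]
        x = props[i]
        d = 1.0 - 2.0 * np.minimum(x, c).sum() / (x.sum() + c.sum())
        records.append(
            {
                "sample_id": sid,
                "group": meta_df["group"].iloc[i],
                "subject": meta_df["subject"].iloc[i],
                "timepoint": int(meta_df["timepoint"].iloc[i]),
                "distance": float(d),
            }
        )
    return pd.DataFrame.from_records(records)
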