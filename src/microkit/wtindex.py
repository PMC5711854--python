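"""Genotype-constrained RDA, key-OTU selection, the WT-index, and its
ROC/LOOCV/bootstrap validation.

The discriminant score for sample *j* over key-OTU sets *N* (reference-group
enriched) and *M* (contrast-group enriched) is

    I_j = (1/|N|) * sum_{i in N} A_ij  -  (1/|M|) * sum_{i in M} A_ij

with ``A`` the Hellinger-transformed abundance matrix, so ``I_j`` always lies
in [-1, 1]. Key OTUs are those whose Hellinger column has R-squared above a
threshold (default 0.10) against the binary group indicator — the per-species
goodness-of-fit of the single constrained RDA axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diversity import OrdinationResult, TransformedTable, hellinger
from .io import OtuTable, SampleMetadata

__all__ = [
    "KeyOtuSet",
    "WtIndexResult",
    "RocResult",
    "rda_two_group",
    "select_key_otus",
    "wt_index",
    "roc_auc",
    "bootstrap_auc_ci",
    "loocv_auc",
]


class KeySelectionError(ValueError):
    """Raised when key-OTU selection leaves N or M empty."""


@dataclass
class KeyOtuSet:
    """Discriminating OTU sets with per-OTU variance-explained fractions."""

    reference_enriched: list[str]  # N: higher mean Hellinger abundance in reference group
    contrast_enriched: list[str]  # M
    variance_explained: dict[str, float]
    threshold: float

    def __post_init__(self) -> None:
        overlap = set(self.reference_enriched) & set(self.contrast_enriched)
        if overlap:
            raise ValueError(f"OTUs in both sets: {sorted(overlap)}")
        for otu in list(self.reference_enriched) + list(self.contrast_enriched):
            if self.variance_explained[otu] <= self.threshold:
                raise ValueError(f"{otu} does not exceed threshold {self.threshold}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"otu_id": o, "set": s, "variance_explained": self.variance_explained[o]}
            for s, ids in (("N", self.reference_enriched), ("M", self.contrast_enriched))
            for o in ids
        ]
        return pd.DataFrame(rows)


@dataclass
class WtIndexResult:
    """Per-sample WT-index values with their N/M components."""

    sample_ids: list[str]
    index: np.ndarray  # I_j
    reference_component: np.ndarray  # I_jwt = sum over N
    contrast_component: np.ndarray  # I_jki = sum over M
    keys: KeyOtuSet

    def to_series(self) -> pd.Series:
        return pd.Series(self.index, index=self.sample_ids, name="wt_index")


@dataclass
class RocResult:
    """ROC validation record: ranked scores, AUC and bootstrap CI."""

    scores: np.ndarray
    labels: np.ndarray  # 1 = positive class
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0
    cv_mode: str = "none"
    failed_folds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (0 <= self.ci_low <= self.ci_high <= 1):
                raise ValueError("invalid CI bounds")

    def roc_points(self) -> pd.DataFrame:
        """FPR/TPR pairs of the empirical ROC curve (threshold sweep)."""
        order = np.argsort(-self.scores, kind="stable")
        labels = self.labels[order]
        tps = np.concatenate([[0], np.cumsum(labels)])
        fps = np.concatenate([[0], np.cumsum(1 - labels)])
        return pd.DataFrame(
            {"fpr": fps / max(fps[-1], 1), "tpr": tps / max(tps[-1], 1)}
        )


def _group_indicator(meta: SampleMetadata, sample_ids, group_pair) -> np.ndarray:
    ref, contrast = group_pair
    groups = np.array([meta.group_of(s) for s in sample_ids])
    unknown = sorted(set(groups) - {ref, contrast})
    if unknown:
        raise ValueError(f"samples outside group pair {group_pair}: {unknown}")
    return (groups == ref).astype(float)


def rda_two_group(
    a: TransformedTable, meta: SampleMetadata, group_pair: tuple[str, str]
) -> tuple[OrdinationResult, pd.Series]:
    """Redundancy analysis with a single binary (group) constraint.

    For one binary predictor the constrained subspace is one-dimensional: the
    fitted values of the column-centred Hellinger matrix are the per-group
    centroids, and the constrained axis is the centroid-difference direction.
    Returns the ordination (constrained axis scores first, eigenvalue =
    between-group sum of squares) and the per-OTU variance-explained vector
    (R-squared of each Hellinger column on the group indicator; constant
    columns get 0).
    """
    g = _group_indicator(meta, a.sample_ids, group_pair)
    n_ref, n_con = int(g.sum()), int((1 - g).sum())
    if n_ref < 2 or n_con < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {group_pair[0]}={n_ref}, {group_pair[1]}={n_con}"
        )
    y = a.values - a.values.mean(axis=0, keepdims=True)
    gc = (g - g.mean())[:, None]
    beta = (gc * y).sum(axis=0) / (gc**2).sum()
    fitted = gc @ beta[None, :]

    ss_between = (fitted**2).sum(axis=0)
    ss_total = (y**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    varexp = pd.Series(r2, index=a.otu_ids, name="variance_explained")

    # constrained axis: unit vector along the fitted (centroid-difference) direction
    norm = np.linalg.norm(beta)
    axis = beta / norm if norm > 0 else beta
    scores = y @ axis
    eig_constrained = ss_between.sum()
    total = ss_total.sum()
    ordination = OrdinationResult(
        list(a.sample_ids),
        scores[:, None],
        np.array([eig_constrained]),
        np.array([eig_constrained / total if total > 0 else 0.0]),
        method="rda",
    )
    return ordination, varexp


def select_key_otus(
    varexp: pd.Series,
    a: TransformedTable,
    meta: SampleMetadata,
    group_pair: tuple[str, str],
    threshold: float = 0.10,
) -> KeyOtuSet:
    """Select OTUs explaining more than ``threshold`` of sample variability.

    Membership in N versus M follows the sign of the mean Hellinger abundance
    difference (reference minus contrast); exact-zero differences are
    excluded. Raises :class:`KeySelectionError` if either set comes out empty.
    """
    if list(varexp.index) != list(a.otu_ids):
        varexp = varexp.reindex(a.otu_ids)
        if varexp.isna().any():
            raise ValueError("variance_explained is not aligned to the table's OTUs")
    g = _group_indicator(meta, a.sample_ids, group_pair).astype(bool)
    mean_ref = a.values[g].mean(axis=0)
    mean_con = a.values[~g].mean(axis=0)
    diff = mean_ref - mean_con
    passing = varexp.to_numpy() > threshold
    n_ids = [o for o, p, d in zip(a.otu_ids, passing, diff) if p and d > 0]
    m_ids = [o for o, p, d in zip(a.otu_ids, passing, diff) if p and d < 0]
    if not n_ids or not m_ids:
        raise KeySelectionError(
            f"selection at threshold {threshold} left |N|={len(n_ids)}, |M|={len(m_ids)}"
        )
    ve = {o: float(v) for o, v in varexp.items() if o in set(n_ids) | set(m_ids)}
    return KeyOtuSet(n_ids, m_ids, ve, threshold)


def wt_index(a: TransformedTable, keys: KeyOtuSet) -> WtIndexResult:
    """Compute the WT-index for every sample of a Hellinger table."""
    col = {o: j for j, o in enumerate(a.otu_ids)}
    missing = [o for o in keys.reference_enriched + keys.contrast_enriched if o not in col]
    if missing:
        raise ValueError(f"key OTUs absent from table: {missing}")
    idx_n = [col[o] for o in keys.reference_enriched]
    idx_m = [col[o] for o in keys.contrast_enriched]
    i_wt = a.values[:, idx_n].sum(axis=1)
    i_ki = a.values[:, idx_m].sum(axis=1)
    index = i_wt / len(idx_n) - i_ki / len(idx_m)
    return WtIndexResult(list(a.sample_ids), index, i_wt, i_ki, keys)


def roc_auc(scores, labels, positive_high=1) -> RocResult:
    """AUC via the midrank (tie-corrected) Mann-Whitney statistic.

    ``labels`` may be any pair of values; ``positive_high`` names the class
    expected to score high. AUC = U/(n1*n2) where U counts score pairs won by
    the positive class, ties contributing 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_high
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # midranks
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return RocResult(scores=scores, labels=pos.astype(int), auc=float(u / (n1 * n0)))


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Positives and negatives are resampled within class, so every replicate
    retains both classes; the interval is the percentile interval of the
    replicate AUCs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels != 1]
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos_scores, size=len(pos_scores), replace=True)
        ns = rng.choice(neg_scores, size=len(neg_scores), replace=True)
        ranks = rankdata(np.concatenate([ps, ns]))
        u = ranks[: len(ps)].sum() - len(ps) * (len(ps) + 1) / 2.0
        aucs[b] = u / (len(ps) * len(ns))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def loocv_auc(
    table: OtuTable,
    meta: SampleMetadata,
    group_pair: tuple[str, str],
    threshold: float = 0.10,
    seed: int = 0,
    n_boot: int = 1000,
) -> RocResult:
    """Honest leave-one-out validation of the WT-index classifier.

    For each sample, key-OTU selection (RDA variance explained + direction)
    is refit on the remaining samples and the held-out sample is scored with
    that fold's key set; all held-out (score, label) pairs are pooled into a
    single ROC with a stratified bootstrap CI. Folds where selection fails
    (empty N or M) contribute score 0 and are recorded in ``failed_folds``.

    The Hellinger transform is per-sample, so it is computed once; no
    information leaks across folds.
    """
    if len(table.sample_ids) < 3:
        raise ValueError("need at least 3 samples for leave-one-out validation")
    a = hellinger(table)
    labels = _group_indicator(meta, a.sample_ids, group_pair)
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    n = len(a.sample_ids)
    held_out = np.zeros(n)
    failed: list[str] = []
    for j in range(n):
        keep = [i for i in range(n) if i != j]
        a_train = TransformedTable(
            [a.sample_ids[i] for i in keep], list(a.otu_ids), a.values[keep]
        )
        try:
            _, varexp = rda_two_group(a_train, meta, group_pair)
            keys = select_key_otus(varexp, a_train, meta, group_pair, threshold)
        except (KeySelectionError, ValueError):
            failed.append(a.sample_ids[j])
            continue
        a_test = TransformedTable([a.sample_ids[j]], list(a.otu_ids), a.values[[j]])
        held_out[j] = wt_index(a_test, keys).index[0]
    roc = roc_auc(held_out, labels, positive_high=1.0)
    lo, hi = bootstrap_auc_ci(held_out, roc.labels, n_boot=n_boot, seed=seed)
    return RocResult(
        scores=held_out,
        labels=roc.labels,
        auc=roc.auc,
        ci_low=lo,
        ci_high=hi,
        n_bootstrap=n_boot,
        cv_mode="loocv",
        failed_folds=failed,
    )
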