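"""Group-difference statistics supporting the core analyses: Mann-Whitney
tests with BH-FDR control, MANOVA on principal coordinates, and per-taxon
differential abundance at a chosen taxonomic rank."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .diversity import pcoa
from .io import DistanceMatrix, OtuTable, SampleMetadata

__all__ = [
    "TestResult",
    "mann_whitney",
    "kruskal_wallis",
    "bh_fdr",
    "manova_on_pcs",
    "phylum_abundance_test",
]

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}
RANK_ORDER = list(RANK_PREFIXES)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    group_sizes: tuple[int, ...]
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p below raw p")


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Two-sided Mann-Whitney U with midranks.

    Exact p by enumeration when n1 + n2 <= 12 and the pooled values are
    tie-free; normal approximation with tie correction (and continuity
    correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann_whitney_{method}",
        group_sizes=(len(x), len(y)),
    )


def kruskal_wallis(*groups) -> TestResult:
    """Thin rank-based multi-group wrapper (chi-squared approximation)."""
    res = sps.kruskal(*groups)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(max(res.pvalue, np.nextafter(0, 1)), 1.0)),
        method="kruskal_wallis",
        group_sizes=tuple(len(g) for g in groups),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def manova_on_pcs(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    variance_target: float = 0.80,
    statistic: str = "pillai",
) -> TestResult:
    """One-way MANOVA across groups on leading principal coordinates.

    Runs PCoA on the distance matrix, retains the smallest number of axes
    whose cumulative proportion of (positive) eigenvalue mass reaches
    ``variance_target``, and tests group separation with Pillai's trace
    (``statistic='wilks'`` for Wilks' lambda) via the standard F
    approximation.
    """
    from statsmodels.multivariate.manova import MANOVA

    ord_res = pcoa(dm)
    cum = np.cumsum(ord_res.proportion_explained)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(cum))
    groups = np.array([meta.group_of(s) for s in dm.sample_ids])
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    n = len(groups)
    if k >= n - len(labels) + 1:
        raise ValueError(
            f"{k} retained PCs with {n} samples and {len(labels)} groups: "
            "within-group covariance singular"
        )
    pcs = ord_res.coordinates[:, :k]
    # exactly coincident group centroids (e.g. duplicated sample sets) make the
    # hypothesis SSCP zero and the F machinery degenerate: trace 0, p = 1
    ssb = 0.0
    for g in labels:
        sel = groups == g
        ssb += sel.sum() * ((pcs[sel].mean(axis=0) - pcs.mean(axis=0)) ** 2).sum()
    sst = ((pcs - pcs.mean(axis=0)) ** 2).sum()
    if sst <= 0 or ssb / sst < 1e-12:
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            method=f"manova_{statistic}_k{k}",
            group_sizes=tuple(int((groups == g).sum()) for g in labels),
        )
    if k == 1:
        # Pillai's trace with one response is eta-squared; its F approximation
        # is exactly the one-way ANOVA F on that coordinate
        pc = ord_res.coordinates[:, 0]
        res = sps.f_oneway(*(pc[groups == g] for g in labels))
        grand = pc.mean()
        ssb = sum(((pc[groups == g].mean() - grand) ** 2) * (groups == g).sum() for g in labels)
        sst = ((pc - grand) ** 2).sum()
        return TestResult(
            statistic=float(ssb / sst) if sst > 0 else 0.0,
            p_value=float(min(max(res.pvalue, np.nextafter(0, 1)), 1.0)),
            method=f"manova_{statistic}_k1",
            group_sizes=tuple(int((groups == g).sum()) for g in labels),
        )
    df = pd.DataFrame(
        ord_res.coordinates[:, :k], columns=[f"PC{i + 1}" for i in range(k)]
    )
    df["group"] = groups
    lhs = " + ".join(df.columns[:-1])
    mv = MANOVA.from_formula(f"{lhs} ~ C(group)", data=df)
    table = mv.mv_test().results["C(group)"]["stat"]
    row = "Pillai's trace" if statistic == "pillai" else "Wilks' lambda"
    return TestResult(
        statistic=float(table.loc[row, "Value"]),
        p_value=float(min(max(table.loc[row, "Pr > F"], np.nextafter(0, 1)), 1.0)),
        method=f"manova_{statistic}_k{k}",
        group_sizes=tuple(int((groups == g).sum()) for g in labels),
    )


def _rank_of(lineage: str, level: str) -> str:
    prefix = RANK_PREFIXES[level]
    parts = [p.strip() for p in str(lineage).split(";")]
    for part in parts:
        if part.lower().startswith(prefix):
            name = part[len(prefix):].strip()
            return name if name else "Unclassified"
    # plain semicolon-separated lineage without rank prefixes: use position
    pos = RANK_ORDER.index(level)
    if len(parts) > pos and parts[pos] and not any("__" in p for p in parts):
        return parts[pos]
    return "Unclassified"


def collapse_taxonomy(table: OtuTable, level: str = "phylum") -> pd.DataFrame:
    """Relative abundance per taxon at ``level`` (samples x taxa)."""
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    if level not in RANK_PREFIXES:
        raise ValueError(f"unknown rank {level!r}")
    taxa = [_rank_of(table.taxonomy.get(o, ""), level) for o in table.otu_ids]
    props = pd.DataFrame(table.proportions(), index=table.sample_ids, columns=taxa)
    return props.T.groupby(level=0).sum().T


def phylum_abundance_test(
    table: OtuTable,
    meta: SampleMetadata,
    group_pair: tuple[str, str],
    level: str = "phylum",
) -> pd.DataFrame:
    """Per-taxon Mann-Whitney tests on relative abundance with BH adjustment.

    Counts are collapsed to relative abundance at the requested rank; each
    taxon is compared between the two groups and the p-values are adjusted
    jointly over all tested taxa.
    """
    collapsed = collapse_taxonomy(table, level)
    ga, gb = group_pair
    in_a = np.array([meta.group_of(s) == ga for s in collapsed.index])
    in_b = np.array([meta.group_of(s) == gb for s in collapsed.index])
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError(f"empty group among {group_pair}")
    rows = []
    for taxon in collapsed.columns:
        vals = collapsed[taxon].to_numpy()
        res = mann_whitney(vals[in_a], vals[in_b])
        mean_a, mean_b = float(vals[in_a].mean()), float(vals[in_b].mean())
        rows.append(
            {
                "taxon": taxon,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "mean_" + ga: mean_a,
                "mean_" + gb: mean_b,
                "direction": "depleted_in_" + gb if mean_a > mean_b else "enriched_in_" + gb,
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values("adjusted_p", kind="stable").reset_index(drop=True)
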