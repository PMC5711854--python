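"""End-to-end pipeline: rarefaction, diversity, WT-index validation,
per-group SparCC networks, topology comparison, and group statistics.

``run_full`` is deterministic under the config's seed: re-running with an
identical config reproduces every output file bit-for-bit (no timestamps
are written)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import alpha_diversity, bray_curtis, distance_to_baseline, hellinger, pcoa
from .io import (
    OtuTable,
    SampleMetadata,
    read_metadata,
    read_otu_table,
    read_tree,
    rarefy,
    write_distance_matrix,
    write_network,
)
from .network import (
    build_network,
    compare_topologies,
    permutation_pvalues,
    prevalence_filter,
    sparcc,
    topology,
)
from .stats import manova_on_pcs, phylum_abundance_test
from .wtindex import loocv_auc, rda_two_group, roc_auc, select_key_otus, wt_index
from .wtindex import bootstrap_auc_ci

log = logging.getLogger("microkit")

__all__ = ["PipelineConfig", "run_full", "load_config"]


@dataclass
class PipelineConfig:
    """Flat configuration mirroring the CLI flags; validated on construction."""

    table: str
    metadata: str
    group_a: str  # reference (wild-type analogue)
    group_b: str
    out_dir: str = "results"
    tree: str | None = None
    table_dialect: str = "plain_tsv"
    rarefaction_depth: int = 9000
    rarefaction_perms: int = 1000
    key_otu_threshold: float = 0.10
    prevalence_min: float = 0.40
    p_max: float = 0.05
    r_min_abs: float = 0.7
    network_perms: int = 1000
    n_boot: int = 1000
    cv: str = "loocv"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("key_otu_threshold", 0.0, 1.0),
            ("prevalence_min", 0.0, 1.0),
            ("p_max", 0.0, 1.0),
            ("r_min_abs", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("rarefaction_depth", "rarefaction_perms", "network_perms", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cv not in ("none", "loocv"):
            raise ValueError(f"cv must be 'none' or 'loocv', got {self.cv!r}")
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")


def load_config(path, **overrides) -> PipelineConfig:
    """Read a flat TOML config file; keyword overrides win over file values."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _group_network(table, meta, group, cfg, seed):
    sub = table.select_samples(meta.samples_in_group(group))
    filtered = prevalence_filter(sub, cfg.prevalence_min)
    if filtered.shape[1] < 4:
        raise ValueError(
            f"group {group}: only {filtered.shape[1]} OTUs pass the prevalence filter"
        )
    r = sparcc(filtered, seed=seed)
    p = permutation_pvalues(filtered, r, n_perm=cfg.network_perms, seed=seed + 1)
    net = build_network(
        r,
        p,
        p_max=cfg.p_max,
        r_min_abs=cfg.r_min_abs,
        prevalence_min=cfg.prevalence_min,
        n_permutations=cfg.network_perms,
    )
    return net, topology(net)


def run_full(config: PipelineConfig) -> dict:
    """Execute every stage and write per-stage TSVs plus ``summary.json``.

    Returns the summary dict. Every stage logs its parameters and seed to
    the ``microkit`` logger; failures propagate with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = _stage("read_inputs")(read_otu_table)(config.table, config.table_dialect)
    meta = read_metadata(config.metadata)
    meta = meta.align_to([s for s in table.sample_ids if s in set(meta.sample_ids)])
    table = table.select_samples(meta.sample_ids)
    tree = read_tree(config.tree) if config.tree else None
    pair = (config.group_a, config.group_b)
    log.info("inputs: %d samples x %d OTUs, groups %s", *table.shape, pair)

    # --- rarefaction + diversity --------------------------------------------
    log.info("rarefy: depth=%d perms=%d seed=%d",
             config.rarefaction_depth, config.rarefaction_perms, config.seed)
    rare = _stage("rarefy")(rarefy)(
        table, config.rarefaction_depth, config.rarefaction_perms, config.seed
    )
    alpha = pd.DataFrame(
        {
            m: alpha_diversity(rare, m, tree)
            for m in (
                ("observed_otus", "shannon", "faith_pd") if tree else ("observed_otus", "shannon")
            )
        }
    )
    alpha.rename_axis("sample_id").to_csv(out / "alpha_diversity.tsv", sep="\t")
    dm = _stage("bray_curtis")(bray_curtis)(rare)
    write_distance_matrix(dm, out / "bray_curtis.tsv")
    ordn = pcoa(dm)
    coords = pd.DataFrame(
        ordn.coordinates,
        index=ordn.sample_ids,
        columns=[f"PC{i + 1}" for i in range(ordn.coordinates.shape[1])],
    )
    coords.rename_axis("sample_id").to_csv(out / "pcoa_coordinates.tsv", sep="\t")

    meta_rare = meta.align_to(rare.sample_ids)
    manova = None
    try:
        res = _stage("manova")(manova_on_pcs)(dm, meta_rare)
        manova = {"statistic": res.statistic, "p_value": res.p_value, "method": res.method}
    except ValueError as exc:
        log.warning("MANOVA skipped: %s", exc)

    # --- RDA / WT-index ------------------------------------------------------
    log.info("wt-index: threshold=%g cv=%s n_boot=%d seed=%d",
             config.key_otu_threshold, config.cv, config.n_boot, config.seed)
    a = hellinger(table)
    _, varexp = _stage("rda")(rda_two_group)(a, meta, pair)
    keys = _stage("select_key_otus")(select_key_otus)(
        varexp, a, meta, pair, config.key_otu_threshold
    )
    keys.to_dataframe().to_csv(out / "key_otus.tsv", sep="\t", index=False)
    wt = wt_index(a, keys)
    wt.to_series().rename_axis("sample_id").to_csv(out / "wt_index.tsv", sep="\t")
    labels = np.array([meta.group_of(s) == config.group_a for s in wt.sample_ids], int)

    if config.cv == "loocv":
        roc = _stage("loocv")(loocv_auc)(
            table, meta, pair, config.key_otu_threshold, config.seed, config.n_boot
        )
    else:
        roc = roc_auc(wt.index, labels)
        lo, hi = bootstrap_auc_ci(wt.index, labels, config.n_boot, seed=config.seed)
        roc.ci_low, roc.ci_high, roc.n_bootstrap = lo, hi, config.n_boot
    roc.roc_points().to_csv(out / "roc_points.tsv", sep="\t", index=False)

    # --- per-group networks ---------------------------------------------------
    log.info("networks: prevalence>%g, edges p<%g |R|>%g, %d perms",
             config.prevalence_min, config.p_max, config.r_min_abs, config.network_perms)
    topologies = {}
    for offset, group in enumerate(pair):
        net, topo = _stage(f"network[{group}]")(_group_network)(
            table, meta, group, config, config.seed + 100 * (offset + 1)
        )
        safe = group.replace("/", "_")
        write_network(net, out / f"network_{safe}.tsv", "edge_tsv")
        write_network(net, out / f"network_{safe}.graphml", "graphml")
        topologies[group] = topo
    comparison = compare_topologies(topologies[pair[0]], topologies[pair[1]])
    comparison["scalars"].rename_axis("metric").rename(
        columns={"a": pair[0], "b": pair[1]}
    ).to_csv(out / "topology_comparison.tsv", sep="\t")

    # --- taxon-level tests ----------------------------------------------------
    phylum = None
    if table.taxonomy:
        ph = _stage("phylum_tests")(phylum_abundance_test)(table, meta, pair)
        ph.to_csv(out / "phylum_tests.tsv", sep="\t", index=False)
        phylum = {
            "n_taxa": int(len(ph)),
            "significant": ph.loc[ph["adjusted_p"] < 0.05, "taxon"].tolist(),
        }

    summary = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "n_samples": len(table.sample_ids),
        "n_otus": len(table.otu_ids),
        "n_per_group": {g: len(meta.samples_in_group(g)) for g in pair},
        "auc": roc.auc,
        "auc_ci": [roc.ci_low, roc.ci_high],
        "cv_mode": roc.cv_mode,
        "n_key_otus": {
            "N": len(keys.reference_enriched),
            "M": len(keys.contrast_enriched),
        },
        "manova": manova,
        "phylum_tests": phylum,
        "topology": {g: t.scalars() for g, t in topologies.items()},
        "topology_ks": {
            k: comparison[k] for k in ("degree", "eigenvector_centrality")
        },
    }
    _write_json(summary, out / "summary.json")
    _write_json(
        {"config": dataclasses.asdict(config), "version": __version__},
        out / "run_manifest.json",
    )
    return summary
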