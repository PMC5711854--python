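"""Synthetic OTU tables with the statistical structure the analyses assume.

The generative model mirrors what SparCC and the discriminant index presume
about real 16S data: per-sample *basis* (absolute) log-abundances are
multivariate normal with optional within-block correlation, a binary group
effect shifts planted OTUs' log-means by ``effect_log2fc * log(2)``
(positive for reference-enriched, negative for contrast-enriched), the basis
is closed to proportions, and counts are drawn multinomially at a per-sample
sequencing depth. Everything is deterministic under the spec's seed.

Defaults mirror a mouse-cohort scale: 300 OTUs, 15 animals per group,
~9000 reads per sample, and a planted split of 20 reference-enriched and
30 contrast-enriched OTUs (the mutant community gains 30 and loses 20 taxa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OtuTable, SampleMetadata

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "generate_longitudinal"]


@dataclass
class SyntheticSpec:
    """Parameters of the two-group synthetic cohort.

    ``depth_sigma`` is the log-scale spread of a lognormal depth model
    (0 means every sample has exactly ``depth_mean`` reads).
    ``correlation_blocks`` is a list of ``(block_size, rho)`` pairs placed on
    consecutive OTUs after the planted sets. ``otu_mean_sd`` spreads per-OTU
    base log-abundances so the community is realistically uneven.
    """

    p_otus: int = 300
    n_per_group: int = 15
    depth_mean: int = 9000
    depth_sigma: float = 0.0
    n_ref_enriched: int = 20
    n_contrast_enriched: int = 30
    effect_log2fc: float = 2.0
    basis_log_mean: float = 0.0
    basis_log_sd: float = 1.0
    otu_mean_sd: float = 2.0
    correlation_blocks: list[tuple[int, float]] = field(default_factory=list)
    group_labels: tuple[str, str] = ("WT", "MUT")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ref_enriched + self.n_contrast_enriched > self.p_otus:
            raise ValueError("planted sets exceed p_otus")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        for size, rho in self.correlation_blocks:
            if not (-1 < rho < 1):
                raise ValueError(f"block correlation {rho} outside (-1, 1)")
        n_block = sum(s for s, _ in self.correlation_blocks)
        if self.n_ref_enriched + self.n_contrast_enriched + n_block > self.p_otus:
            raise ValueError("correlation blocks overlap planted sets or exceed p_otus")


@dataclass
class GroundTruth:
    """Planted structure of a generated table."""

    reference_enriched: list[str]
    contrast_enriched: list[str]
    basis_correlation: np.ndarray
    expected_proportions: dict[str, np.ndarray]  # group label -> length-p vector
    block_members: list[list[str]] = field(default_factory=list)


def _base_log_means(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """Per-OTU baseline log-abundances.

    Planted differential OTUs take mid-abundance baselines (median to 90th
    percentile of the community distribution): the enriched/depleted pattern
    being emulated consists of taxa observable at the cohort's sequencing
    depth but distinct from the dominant taxa, whose abundance is similar
    between groups. Planting effects below the detection floor would be
    invisible; planting them on community dominants would let the fold-change
    take over the composition and dilute everything else.
    """
    from scipy.special import ndtri

    z = rng.standard_normal(spec.p_otus)
    n_planted = spec.n_ref_enriched + spec.n_contrast_enriched
    z[:n_planted] = ndtri(rng.uniform(0.5, 0.9, size=n_planted))
    return spec.basis_log_mean + spec.otu_mean_sd * z


def _correlation_matrix(spec: SyntheticSpec) -> np.ndarray:
    corr = np.eye(spec.p_otus)
    start = spec.n_ref_enriched + spec.n_contrast_enriched
    for size, rho in spec.correlation_blocks:
        block = np.full((size, size), rho)
        np.fill_diagonal(block, 1.0)
        corr[start : start + size, start : start + size] = block
        start += size
    return corr


def _group_log_means(spec: SyntheticSpec, base: np.ndarray) -> dict[str, np.ndarray]:
    ref, contrast = spec.group_labels
    shift = spec.effect_log2fc * np.log(2.0)
    mu = {ref: base.copy(), contrast: base.copy()}
    mu[ref][: spec.n_ref_enriched] += shift
    sl = slice(spec.n_ref_enriched, spec.n_ref_enriched + spec.n_contrast_enriched)
    mu[contrast][sl] += shift
    return mu


def _expected_proportions(mu: np.ndarray, cov_diag: float) -> np.ndarray:
    # mean basis abundance of a lognormal, closed to composition
    e = np.exp(mu + cov_diag / 2.0)
    return e / e.sum()


def _draw_samples(
    rng: np.random.Generator,
    mu: np.ndarray,
    chol: np.ndarray,
    n: int,
    depths: np.ndarray,
) -> np.ndarray:
    z = rng.standard_normal((n, len(mu)))
    logs = mu[None, :] + z @ chol.T
    basis = np.exp(logs)
    props = basis / basis.sum(axis=1, keepdims=True)
    counts = np.empty((n, len(mu)), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(int(depths[i]), props[i])
    return counts


def _depths(rng: np.random.Generator, spec: SyntheticSpec, n: int) -> np.ndarray:
    if spec.depth_sigma == 0:
        return np.full(n, spec.depth_mean)
    # lognormal around depth_mean on the log scale
    return np.maximum(
        rng.lognormal(np.log(spec.depth_mean), spec.depth_sigma, size=n), 1
    ).astype(np.int64)


def generate(spec: SyntheticSpec) -> tuple[OtuTable, SampleMetadata, GroundTruth]:
    """Draw a two-group cross-sectional cohort.

    Returns the count table, metadata (groups only; subject = sample,
    timepoint 0, singly housed), and the planted ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    otu_ids = [f"OTU{i + 1}" for i in range(spec.p_otus)]
    base = _base_log_means(rng, spec)
    corr = _correlation_matrix(spec)
    cov = (spec.basis_log_sd**2) * corr
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(spec.p_otus))
    mu = _group_log_means(spec, base)

    counts, sample_ids, groups = [], [], []
    for label in spec.group_labels:
        depths = _depths(rng, spec, spec.n_per_group)
        counts.append(_draw_samples(rng, mu[label], chol, spec.n_per_group, depths))
        sample_ids += [f"{label}_{k + 1}" for k in range(spec.n_per_group)]
        groups += [label] * spec.n_per_group

    table = OtuTable(sample_ids, otu_ids, np.vstack(counts))
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "subject": sample_ids,
                "timepoint": 0,
                "housing": "sh",
            }
        ),
        groups=spec.group_labels,
    )
    start = spec.n_ref_enriched + spec.n_contrast_enriched
    blocks, at = [], start
    for size, _ in spec.correlation_blocks:
        blocks.append(otu_ids[at : at + size])
        at += size
    truth = GroundTruth(
        reference_enriched=otu_ids[: spec.n_ref_enriched],
        contrast_enriched=otu_ids[spec.n_ref_enriched : start],
        basis_correlation=corr,
        expected_proportions={
            label: _expected_proportions(mu[label], spec.basis_log_sd**2)
            for label in spec.group_labels
        },
        block_members=blocks,
    )
    return table, meta, truth


def generate_longitudinal(
    spec: SyntheticSpec,
    timepoints: tuple[int, ...] = (-20, -10, -3, 1, 2, 3, 8),
    drift_sd: dict[str, float] | None = None,
) -> tuple[OtuTable, SampleMetadata, GroundTruth]:
    """Longitudinal cohort: per-subject random walks on basis log-abundances.

    Each subject's log-abundance vector takes a Gaussian step of standard
    deviation ``drift_sd[group] * sqrt(day gap)`` between consecutive
    timepoints, so a group with larger drift shows larger expected
    Bray-Curtis deviation from its pre-treatment (timepoint < 0) baseline.
    """
    if len(timepoints) < 2:
        raise ValueError("need >= 2 timepoints")
    drift_sd = drift_sd or {g: 0.2 for g in spec.group_labels}
    for g, sd in drift_sd.items():
        if sd < 0:
            raise ValueError(f"negative drift sd for group {g}")
    rng = np.random.default_rng(spec.seed)
    otu_ids = [f"OTU{i + 1}" for i in range(spec.p_otus)]
    base = _base_log_means(rng, spec)
    corr = _correlation_matrix(spec)
    chol = np.linalg.cholesky(
        (spec.basis_log_sd**2) * corr + 1e-12 * np.eye(spec.p_otus)
    )
    mu = _group_log_means(spec, base)

    rows, records = [], []
    tps = sorted(timepoints)
    for label in spec.group_labels:
        sd = drift_sd.get(label, 0.0)
        for k in range(spec.n_per_group):
            subject = f"{label}_s{k + 1}"
            logs = mu[label] + chol @ rng.standard_normal(spec.p_otus)
            prev_t = tps[0]
            for t in tps:
                gap = max(t - prev_t, 0)
                if gap > 0 and sd > 0:
                    logs = logs + sd * np.sqrt(gap) * rng.standard_normal(spec.p_otus)
                prev_t = t
                basis = np.exp(logs)
                props = basis / basis.sum()
                depth = int(_depths(rng, spec, 1)[0])
                rows.append(rng.multinomial(depth, props))
                records.append(
                    {
                        "sample_id": f"{subject}_d{t}",
                        "group": label,
                        "subject": subject,
                        "timepoint": t,
                        "housing": "sh",
                    }
                )

    table = OtuTable([r["sample_id"] for r in records], otu_ids, np.vstack(rows))
    meta = SampleMetadata(pd.DataFrame(records), groups=spec.group_labels)
    start = spec.n_ref_enriched + spec.n_contrast_enriched
    truth = GroundTruth(
        reference_enriched=otu_ids[: spec.n_ref_enriched],
        contrast_enriched=otu_ids[spec.n_ref_enriched : start],
        basis_correlation=corr,
        expected_proportions={
            label: _expected_proportions(mu[label], spec.basis_log_sd**2)
            for label in spec.group_labels
        },
    )
    return table, meta, truth
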