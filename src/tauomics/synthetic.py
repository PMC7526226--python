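"""Synthetic paired transcriptome/proteome data with known ground truth.

Emulates the study design the downstream analyses expect: two (or more)
genotypes of an inducible tauopathy model crossed with an ordered series
of ages, a few replicates per cell, negative-binomial RNA-seq counts with
genotype and per-age-level effects, a paired label-free proteome whose
log-intensities track (or oppose) the transcript signal for a tunable
fraction of genes, intensity-dependent (MNAR) missingness near a
detection limit, a many-to-many cross-species homology table with
confidence scores, and a catalog of genetic-modifier evidence records.

Every generator is a pure function of its parameters and seed, so any
downstream result can be checked against the truth tables emitted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, StudyDesign

__all__ = [
    "SimParams",
    "ProteomeSimParams",
    "simulate_transcriptome",
    "simulate_proteome",
    "simulate_homology",
    "simulate_modifiers",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class SimParams:
    """Transcriptome simulation parameters.

    Defaults describe a bulk fly-head RNA-seq experiment of moderate
    depth: per-gene baselines log-normal around ~400 counts, per-gene NB
    dispersions log-normal around 0.05 (variance = mu + alpha*mu^2),
    10% of genes genotype-responsive with |log2FC| ~ N(1.5, 0.5), 30%
    age-responsive with per-level offsets, and ~20% CV in library depth.
    """

    n_genes: int = 2000
    baseline_mean_log_params: tuple = (np.log(400.0), 1.2)
    dispersion_log_params: tuple = (np.log(0.05), 0.5)
    frac_genotype_de: float = 0.1
    genotype_lfc_dist: tuple = (1.5, 0.5)
    frac_age_de: float = 0.3
    age_lfc_sd: float = 0.75
    library_size_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for frac in (self.frac_genotype_de, self.frac_age_de):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("DE fractions must be in [0, 1]")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be >= 0")


@dataclass(frozen=True)
class ProteomeSimParams:
    """Proteome simulation parameters.

    ``concordant_fraction`` of proteins track their transcript with
    positive slope on the log2 scale, ``discordant_fraction`` with
    negative slope; the remainder vary independently. Missingness has an
    MNAR component (logistic in latent log2 intensity, rising below the
    ``detection_limit_quantile`` of the intensity distribution) and an
    MCAR component applied uniformly. Intensities are exponentiated and
    scaled to ~1e6 to mimic raw LFQ magnitudes.
    """

    concordant_fraction: float = 0.6
    discordant_fraction: float = 0.25
    noise_sd: float = 0.5
    detection_limit_quantile: float = 0.15
    mnar_steepness: float = 1.5
    mcar_rate: float = 0.02
    intensity_scale: float = 1e6
    seed: int = 0

    def __post_init__(self):
        if self.concordant_fraction + self.discordant_fraction > 1.0 + 1e-12:
            raise ValueError("concordant + discordant fractions exceed 1")
        for rate in (
            self.concordant_fraction,
            self.discordant_fraction,
            self.mcar_rate,
            self.detection_limit_quantile,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.noise_sd < 0 or self.mnar_steepness < 0:
            raise ValueError("noise_sd and mnar_steepness must be >= 0")


def simulate_transcriptome(
    params: SimParams, design: StudyDesign
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate NB counts under a genotype x categorical-age design.

    Returns the count matrix and a truth table with one row per gene:
    ``is_genotype_de``, ``true_log2fc`` (non-control genotype effect),
    ``is_age_de``, per-age-level true log2 offsets, baseline mean and
    dispersion.

    Counts are drawn NB(mu * size_factor, alpha) with
    var = mu + alpha * mu^2; genotype effects apply only to flagged
    genes and age effects are level-specific offsets shared by both
    genotypes (no interaction is simulated).
    """
    rng = np.random.default_rng(params.seed)
    meta = design.metadata()
    n_genes, n_samples = params.n_genes, len(meta)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    loc, scale = params.baseline_mean_log_params
    baseline = rng.lognormal(loc, scale, size=n_genes)
    dloc, dscale = params.dispersion_log_params
    dispersion = rng.lognormal(dloc, dscale, size=n_genes)

    n_geno_de = int(round(params.frac_genotype_de * n_genes))
    n_age_de = int(round(params.frac_age_de * n_genes))
    geno_de_idx = rng.choice(n_genes, size=n_geno_de, replace=False)
    age_de_idx = rng.choice(n_genes, size=n_age_de, replace=False)

    lfc_mean, lfc_sd = params.genotype_lfc_dist
    true_lfc = np.zeros(n_genes)
    magnitudes = np.abs(rng.normal(lfc_mean, lfc_sd, size=n_geno_de))
    signs = rng.choice([-1.0, 1.0], size=n_geno_de)
    true_lfc[geno_de_idx] = signs * magnitudes

    # per-level log2 offsets, reference age = 0 by construction
    ages = list(design.ages)
    age_offsets = np.zeros((n_genes, len(ages)))
    age_offsets[age_de_idx, 1:] = rng.normal(
        0.0, params.age_lfc_sd, size=(n_age_de, len(ages) - 1)
    )

    if params.library_size_cv > 0:
        sigma = np.sqrt(np.log1p(params.library_size_cv**2))
        size_factors = rng.lognormal(-0.5 * sigma**2, sigma, size=n_samples)
    else:
        size_factors = np.ones(n_samples)

    is_tau = (meta["genotype"] != design.control).to_numpy(dtype=float)
    age_level = meta["age"].map({a: i for i, a in enumerate(ages)}).to_numpy()

    log2_mu = (
        np.log2(baseline)[:, None]
        + true_lfc[:, None] * is_tau[None, :]
        + age_offsets[:, age_level]
    )
    mu = 2.0**log2_mu * size_factors[None, :]

    alpha = dispersion[:, None]
    n_param = 1.0 / alpha
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param).astype(np.int64)

    values = pd.DataFrame(counts, index=gene_ids, columns=list(meta["sample_id"]))
    matrix = ExpressionMatrix(values, meta, modality="transcriptome")

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_genotype_de": np.isin(np.arange(n_genes), geno_de_idx),
            "true_log2fc": true_lfc,
            "is_age_de": np.isin(np.arange(n_genes), age_de_idx),
            "baseline_mean": baseline,
            "dispersion": dispersion,
        }
    ).set_index("gene_id")
    for i, a in enumerate(ages):
        truth[f"age_log2_offset_d{a}"] = age_offsets[:, i]
    return matrix, truth


def simulate_proteome(
    transcriptome: ExpressionMatrix,
    truth: pd.DataFrame,
    params: ProteomeSimParams,
    design: StudyDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a paired LFQ proteome from simulated transcript counts.

    Latent per-sample log2 intensity is ``slope * log2(count + 1)`` plus
    an offset and Gaussian noise, with slope +1 for concordant proteins,
    -1 for discordant, 0 (independent Gaussian profile) otherwise.
    Missingness combines a logistic-in-intensity MNAR component centered
    at the detection limit with uniform MCAR dropout; missing entries
    are NaN in the returned matrix.
    """
    if list(transcriptome.sample_ids) != list(design.metadata()["sample_id"]):
        raise ValueError("transcriptome samples do not match design")
    rng = np.random.default_rng(params.seed)
    counts = transcriptome.values.to_numpy(dtype=float)
    n_genes, n_samples = counts.shape
    gene_ids = transcriptome.feature_ids

    n_conc = int(round(params.concordant_fraction * n_genes))
    n_disc = int(round(params.discordant_fraction * n_genes))
    if n_conc + n_disc > n_genes:
        raise ValueError("concordant + discordant fractions exceed 1")
    order = rng.permutation(n_genes)
    conc_idx = order[:n_conc]
    disc_idx = order[n_conc : n_conc + n_disc]
    slope = np.zeros(n_genes)
    slope[conc_idx] = 1.0
    slope[disc_idx] = -1.0

    log2_counts = np.log2(counts + 1.0)
    centered = log2_counts - log2_counts.mean(axis=1, keepdims=True)
    base_level = rng.normal(12.0, 2.0, size=n_genes)
    latent = base_level[:, None] + slope[:, None] * centered
    indep = slope == 0
    latent[indep] = base_level[indep, None] + rng.normal(
        0.0, 1.0, size=(int(indep.sum()), n_samples)
    )
    latent = latent + rng.normal(0.0, params.noise_sd, size=latent.shape)

    # MNAR: missingness probability non-increasing in latent intensity
    p_miss = np.zeros_like(latent)
    if params.mnar_steepness > 0:
        limit = np.quantile(latent, params.detection_limit_quantile)
        p_miss = 1.0 / (1.0 + np.exp(params.mnar_steepness * (latent - limit)))
    mnar_missing = rng.random(latent.shape) < p_miss
    mcar_missing = rng.random(latent.shape) < params.mcar_rate
    missing = mnar_missing | mcar_missing

    # scale so the grand median sits near intensity_scale (raw LFQ range)
    intensities = 2.0 ** (latent - np.median(latent)) * params.intensity_scale
    intensities[missing] = np.nan

    values = pd.DataFrame(
        intensities, index=gene_ids, columns=transcriptome.sample_ids
    )
    matrix = ExpressionMatrix(values, transcriptome.metadata.copy(), "proteome")

    concordance_class = np.full(n_genes, "independent", dtype=object)
    concordance_class[conc_idx] = "concordant"
    concordance_class[disc_idx] = "discordant"
    prot_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "concordance_class": concordance_class,
            "n_missing": missing.sum(axis=1),
            "n_mnar_missing": mnar_missing.sum(axis=1),
            "n_mcar_only_missing": (mcar_missing & ~mnar_missing).sum(axis=1),
        }
    ).set_index("gene_id")
    return matrix, prot_truth


def simulate_homology(
    n_fly: int,
    n_human: int,
    mapped_fraction: float = 0.6,
    score_range: tuple = (1, 15),
    multi_map_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a many-to-many fly-human ortholog table with scores.

    Each of a Bernoulli(``mapped_fraction``) subset of human genes gets
    one fly partner; with probability ``multi_map_rate`` it gains extra
    partners (geometric count). Integer confidence scores are uniform on
    ``score_range``. Returns columns ``fly_id, human_id, score``.
    """
    if n_fly < 1 or n_human < 1:
        raise ValueError("gene counts must be positive")
    lo, hi = score_range
    if lo > hi:
        raise ValueError("score_range inverted")
    rng = np.random.default_rng(seed)
    fly_ids = np.array([f"fly{i:05d}" for i in range(n_fly)])
    records = []
    for h in range(n_human):
        if rng.random() >= mapped_fraction:
            continue
        n_partners = 1
        if multi_map_rate > 0 and rng.random() < multi_map_rate:
            n_partners += rng.geometric(0.5)
        partners = rng.choice(n_fly, size=min(n_partners, n_fly), replace=False)
        for f in partners:
            records.append(
                (fly_ids[f], f"HUM{h:05d}", int(rng.integers(lo, hi + 1)))
            )
    return pd.DataFrame(records, columns=["fly_id", "human_id", "score"])


def simulate_modifiers(
    gene_ids, n_records: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate genetic-modifier evidence records.

    Each record pairs a gene with a manipulation
    (``loss_of_function`` or ``overexpression``) and a screen outcome
    (``suppresses`` or ``enhances`` toxicity). Returns columns
    ``gene_id, manipulation, outcome, source``.
    """
    gene_ids = list(gene_ids)
    if n_records < 0:
        raise ValueError("n_records must be >= 0")
    if n_records > 4 * len(gene_ids):
        raise ValueError("n_records exceeds feasible combinations")
    rng = np.random.default_rng(seed)
    combos = [
        (g, m, o)
        for g in gene_ids
        for m in ("loss_of_function", "overexpression")
        for o in ("suppresses", "enhances")
    ]
    idx = rng.choice(len(combos), size=n_records, replace=False)
    rows = [
        combos[i] + (f"screen{int(rng.integers(1, 4))}",) for i in sorted(idx)
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "manipulation", "outcome", "source"]
    )
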