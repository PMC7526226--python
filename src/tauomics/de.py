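"""Differential expression for counts: filtering, normalization, NB GLM.

The model family is the negative binomial GLM with log link and
library-size offsets (var = mu + alpha * mu^2), tested per gene with a
Wald test on the coefficient of interest and Benjamini-Hochberg
adjustment within each analysis. Four designs are supported:

* ``genotype_stratified_by_age`` — expression ~ genotype within one age
* ``genotype_plus_age`` — expression ~ genotype + age (age categorical);
  the genotype coefficient is tested
* ``genotype_by_age_interaction`` — adds genotype:age terms, tested
  jointly with a chi-square Wald statistic
* ``age_contrast`` — expression ~ age for one genotype and an ordered
  pair of ages

Dispersion is estimated per gene by Cox-Reid adjusted profile maximum
likelihood with a method-of-moments initializer and a floor of 1e-8; no
empirical-Bayes shrinkage is applied. Wald statistics are referred to a
t distribution with residual degrees of freedom (F for joint tests),
which keeps the test calibrated at the small replicate numbers this
design uses. Fitting is IRLS vectorized across genes, which keeps
permutation re-fits cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import ExpressionMatrix

__all__ = [
    "DesignSpec",
    "default_designs",
    "filter_low_counts",
    "size_factors_median_of_ratios",
    "bh_adjust",
    "fit_nb_glm",
    "run_de_suite",
]

LN2 = np.log(2.0)
MIN_DISPERSION = 1e-8
MAX_DISPERSION = 50.0


@dataclass(frozen=True)
class DesignSpec:
    """One DE analysis: which samples, which model, which term is tested.

    ``stratum_age`` selects the age slice for cross-sectional analyses;
    ``stratum_genotype`` and ``contrast`` (an ordered age pair) define
    aging contrasts within one genotype.
    """

    formula_kind: str
    reference_genotype: str = "control"
    reference_age: object = None
    stratum_age: object = None
    stratum_genotype: object = None
    contrast: tuple | None = None
    label: str | None = None

    KINDS = (
        "genotype_stratified_by_age",
        "genotype_plus_age",
        "genotype_by_age_interaction",
        "age_contrast",
    )

    def __post_init__(self):
        if self.formula_kind not in self.KINDS:
            raise ValueError(f"unknown formula_kind {self.formula_kind!r}")
        if self.formula_kind == "genotype_stratified_by_age" and self.stratum_age is None:
            raise ValueError("stratified design needs stratum_age")
        if self.formula_kind == "age_contrast":
            if self.stratum_genotype is None or self.contrast is None:
                raise ValueError("age_contrast needs stratum_genotype and contrast")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.formula_kind == "genotype_stratified_by_age":
            return f"day{self.stratum_age}_crosssectional"
        if self.formula_kind == "genotype_plus_age":
            return "joint_genotype"
        if self.formula_kind == "genotype_by_age_interaction":
            return "genotype_age_interaction"
        a, b = self.contrast
        return f"{self.stratum_genotype}_age_{a}v{b}"


def default_designs(metadata: pd.DataFrame, reference_genotype: str = "control"):
    """The standard analysis suite: cross-sectional per age, the
    age-adjusted joint model, the genotype x age interaction, and all
    pairwise aging contrasts within each genotype."""
    ages = sorted(metadata["age"].unique())
    genotypes = list(pd.unique(metadata["genotype"]))
    designs = [
        DesignSpec("genotype_stratified_by_age", reference_genotype, ages[0], stratum_age=a)
        for a in ages
    ]
    designs.append(DesignSpec("genotype_plus_age", reference_genotype, ages[0]))
    designs.append(DesignSpec("genotype_by_age_interaction", reference_genotype, ages[0]))
    for g in genotypes:
        for i in range(len(ages)):
            for j in range(i + 1, len(ages)):
                designs.append(
                    DesignSpec(
                        "age_contrast",
                        reference_genotype,
                        stratum_genotype=g,
                        contrast=(ages[i], ages[j]),
                    )
                )
    return designs


# ---------------------------------------------------------------------------
# filtering and normalization


def filter_low_counts(matrix: ExpressionMatrix, min_avg: float = 50.0) -> ExpressionMatrix:
    """Drop features whose mean across all samples falls below ``min_avg``.

    The boundary is inclusive: a feature with mean exactly ``min_avg``
    is retained. Missing values are treated as absent (mean over all
    samples with NaN counted as 0), which only matters for proteome
    input upstream of imputation.
    """
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise ValueError("empty matrix")
    vals = matrix.values.to_numpy(dtype=float)
    means = np.nanmean(np.nan_to_num(vals), axis=1)
    keep = means >= min_avg
    return matrix.subset_features(np.asarray(matrix.feature_ids)[keep])


def size_factors_median_of_ratios(matrix: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth normalization.

    For each sample j, s_j is the median over reference genes of
    count_gj / geomean_g, where geomean_g is the geometric mean of gene
    g across samples and the reference set is the genes positive in
    every sample.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    arr = values.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts; cannot normalize")
    ref = arr[positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    sf = np.median(ref / geomean[:, None], axis=0)
    return pd.Series(sf, index=values.columns, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# NB GLM internals (vectorized across genes; design matrix shared)


def _nb_loglik(y, mu, alpha):
    """NB2 log-likelihood summed over samples; alpha per gene (G,)."""
    r = 1.0 / alpha[:, None]
    return np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu)),
        axis=1,
    )


def _cr_objective(y, mu, alpha, X):
    """Negative Cox-Reid adjusted profile log-likelihood in alpha.

    The adjustment (-1/2 log det X'WX) corrects the downward bias of
    plain ML dispersion when the mean model consumes a non-trivial
    share of the per-gene degrees of freedom (n=3 per cell here).
    """
    ll = _nb_loglik(y, mu, alpha)
    w = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("jp,gj,jq->gpq", X, w, X)
    _, logdet = np.linalg.slogdet(XtWX + np.eye(X.shape[1])[None] * 1e-12)
    return -(ll - 0.5 * logdet)


def _mle_dispersion(y, mu, X):
    """Per-gene dispersion maximizing the Cox-Reid adjusted profile
    likelihood given fitted means, by golden-section search on
    log(alpha) over [1e-8, 50]. The objective is unimodal in alpha for
    NB2, so the bracketed search converges."""
    lo = np.full(y.shape[0], np.log(MIN_DISPERSION))
    hi = np.full(y.shape[0], np.log(MAX_DISPERSION))
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc = _cr_objective(y, mu, np.exp(c), X)
    fd = _cr_objective(y, mu, np.exp(d), X)
    for _ in range(50):
        use_c = fc < fd
        hi = np.where(use_c, d, hi)
        lo = np.where(use_c, lo, c)
        c = hi - invphi * (hi - lo)
        d = lo + invphi * (hi - lo)
        fc = _cr_objective(y, mu, np.exp(c), X)
        fd = _cr_objective(y, mu, np.exp(d), X)
    return np.exp((lo + hi) / 2.0)


def _irls(y, X, offset, alpha, n_iter=60, tol=1e-9):
    """Weighted IRLS for the NB log-link GLM, vectorized across genes.

    y: (G, n); X: (n, p); offset: (n,); alpha: (G,).
    Returns beta (G, p), cov (G, p, p), converged (G,).
    """
    G, n = y.shape
    p = X.shape[1]
    eta = np.log(np.maximum(y, 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, eta.T, rcond=None)
    beta = beta.T
    converged = np.zeros(G, dtype=bool)
    for _ in range(n_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offset[None, :] + (y - mu) / mu
        XtWX = np.einsum("jp,gj,jq->gpq", X, w, X)
        XtWz = np.einsum("jp,gj,gj->gp", X, w, z)
        XtWX += np.eye(p)[None, :, :] * 1e-10
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.einsum(
                "gpq,gq->gp", np.linalg.pinv(XtWX), XtWz
            )
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        converged |= delta < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("jp,gj,jq->gpq", X, w, X) + np.eye(p)[None] * 1e-10
    cov = np.linalg.pinv(XtWX)
    return beta, cov, converged, mu


def _build_design(meta: pd.DataFrame, design: DesignSpec):
    """Design matrix with treatment coding and the tested column(s).

    Returns (X, test_cols, colnames, sample_mask). ``sample_mask``
    selects the rows of ``meta`` entering the analysis.
    """
    mask = np.ones(len(meta), dtype=bool)
    kind = design.formula_kind
    if kind == "genotype_stratified_by_age":
        mask &= (meta["age"] == design.stratum_age).to_numpy()
    elif kind == "age_contrast":
        a, b = design.contrast
        mask &= (meta["genotype"] == design.stratum_genotype).to_numpy()
        mask &= meta["age"].isin([a, b]).to_numpy()
    sub = meta.loc[mask]

    cols = [np.ones(len(sub))]
    names = ["intercept"]
    test_cols: list[int] = []

    if kind == "age_contrast":
        a, b = design.contrast
        ind = (sub["age"] == b).to_numpy(dtype=float)
        cols.append(ind)
        names.append(f"age[{b}]")
        test_cols.append(len(cols) - 1)
    else:
        ref_g = design.reference_genotype
        if ref_g not in set(sub["genotype"]):
            raise ValueError(f"reference genotype {ref_g!r} absent from stratum")
        others = [g for g in pd.unique(sub["genotype"]) if g != ref_g]
        if len(others) != 1:
            raise ValueError("exactly one non-reference genotype is required per fit")
        geno = (sub["genotype"] == others[0]).to_numpy(dtype=float)
        cols.append(geno)
        names.append(f"genotype[{others[0]}]")
        test_cols.append(len(cols) - 1)
        if kind in ("genotype_plus_age", "genotype_by_age_interaction"):
            ages = sorted(sub["age"].unique())
            ref_a = design.reference_age if design.reference_age is not None else ages[0]
            for a in ages:
                if a == ref_a:
                    continue
                ind = (sub["age"] == a).to_numpy(dtype=float)
                cols.append(ind)
                names.append(f"age[{a}]")
            if kind == "genotype_by_age_interaction":
                test_cols = []
                for a in ages:
                    if a == ref_a:
                        continue
                    ind = (sub["age"] == a).to_numpy(dtype=float)
                    cols.append(geno * ind)
                    names.append(f"genotype:age[{a}]")
                    test_cols.append(len(cols) - 1)
    X = np.column_stack(cols)
    return X, test_cols, names, mask


def fit_nb_glm(
    matrix: ExpressionMatrix,
    design: DesignSpec,
    size_factors: pd.Series | None = None,
    dispersion: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB GLM fit for one design.

    Returns a DataFrame with columns ``log2fc`` (tested coefficient on
    the log2 scale; NaN for the joint interaction test), ``se``,
    ``stat`` (Wald z, or chi-square for the interaction), ``df``,
    ``pvalue``, ``fdr`` and ``status``. All-zero genes are flagged
    ``all_zero`` and excluded from the BH denominator.

    ``dispersion`` fixes per-gene alpha (skips estimation), which the
    permutation machinery uses for speed when told to.
    """
    X, test_cols, names, mask = _build_design(matrix.metadata, design)
    sub = matrix.subset_samples(mask)
    genotype_like = design.formula_kind != "age_contrast"
    # require >= 2 samples per tested level
    if genotype_like:
        counts_per = sub.metadata.groupby("genotype").size()
    else:
        counts_per = sub.metadata.groupby("age").size()
    if (counts_per < 2).any() or len(counts_per) < 2:
        raise ValueError(f"design {design.name}: insufficient samples per level")

    y = sub.values.to_numpy(dtype=float)
    if not np.allclose(y, np.round(y), equal_nan=False):
        raise ValueError("count model requires integer-valued input")
    if size_factors is None:
        sf = size_factors_median_of_ratios(sub).to_numpy()
    else:
        sf = size_factors.loc[sub.sample_ids].to_numpy()
    offset = np.log(sf)

    ok = ~(y.sum(axis=1) == 0)
    results = pd.DataFrame(
        index=pd.Index(sub.feature_ids, name="feature_id"),
        columns=["log2fc", "se", "stat", "df", "pvalue", "fdr"],
        dtype=float,
    )
    results["status"] = "all_zero"
    results["analysis"] = design.name
    if ok.any():
        yk = y[ok]
        if dispersion is not None:
            alpha = np.asarray(dispersion, dtype=float)[ok]
        else:
            # moment initializer on depth-normalized counts, then two
            # rounds of (fit means | profile-ML alpha)
            norm = yk / sf[None, :]
            m = norm.mean(axis=1)
            v = norm.var(axis=1, ddof=1)
            alpha = np.clip((v - m) / np.maximum(m, 1e-12) ** 2, MIN_DISPERSION, MAX_DISPERSION)
            for _ in range(2):
                _, _, _, mu = _irls(yk, X, offset, alpha, n_iter=25)
                alpha = _mle_dispersion(yk, mu, X)
        beta, cov, converged, _ = _irls(yk, X, offset, alpha)

        idx = np.asarray(sub.feature_ids)[ok]
        # small-sample calibration: Wald statistic referred to t (or F
        # for joint tests) with residual df rather than the asymptotic
        # normal/chi-square, which is anti-conservative at n=3 per cell
        resid_df = max(X.shape[0] - X.shape[1], 1)
        if len(test_cols) == 1:
            t = test_cols[0]
            b = beta[:, t]
            se = np.sqrt(np.maximum(cov[:, t, t], 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(se > 0, b / se, 0.0)
            p = 2.0 * stats.t.sf(np.abs(z), resid_df)
            results.loc[idx, "log2fc"] = b / LN2
            results.loc[idx, "se"] = se / LN2
            results.loc[idx, "stat"] = z
            results.loc[idx, "df"] = 1.0
        else:
            tc = np.asarray(test_cols)
            b = beta[:, tc]
            covb = cov[:, tc[:, None], tc[None, :]]
            chi2 = np.einsum(
                "gp,gpq,gq->g", b, np.linalg.pinv(covb), b
            )
            df = len(tc)
            p = stats.f.sf(chi2 / df, df, resid_df)
            results.loc[idx, "stat"] = chi2
            results.loc[idx, "df"] = float(df)
        results.loc[idx, "pvalue"] = p
        results.loc[idx, "status"] = np.where(converged, "ok", "not_converged")
        fit_mask = results["pvalue"].notna()
        results.loc[fit_mask, "fdr"] = bh_adjust(results.loc[fit_mask, "pvalue"].to_numpy())
    return results.reset_index()


def run_de_suite(
    transcriptome: ExpressionMatrix | None,
    proteome: ExpressionMatrix | None,
    designs,
    alpha: float = 0.05,
    min_avg: float = 50.0,
    proteome_min_avg: float = 0.0,
) -> pd.DataFrame:
    """Run every design on each available modality and stack results.

    Per analysis: samples are subset per the design, low-abundance
    features are filtered on the comparison subset, size factors are
    recomputed, the NB GLM is fit, and BH is applied within that
    analysis. Proteome intensities are rounded half-to-even to integers
    before fitting, as the count model requires. A design whose levels
    are missing from a modality's metadata is skipped with a warning.
    Adds boolean ``significant`` at FDR < ``alpha``.
    """
    frames = []
    for modality, matrix, threshold in (
        ("transcriptome", transcriptome, min_avg),
        ("proteome", proteome, proteome_min_avg),
    ):
        if matrix is None:
            continue
        if modality == "proteome":
            vals = matrix.values.copy()
            if vals.isna().any().any():
                raise ValueError("proteome contains missing values; impute first")
            vals = np.round(vals.astype(float)).round().astype(np.int64)
            matrix = ExpressionMatrix(vals, matrix.metadata.copy(), "proteome")
        for design in designs:
            try:
                _, _, _, mask = _build_design(matrix.metadata, design)
                sub = matrix.subset_samples(mask)
                sub = filter_low_counts(sub, threshold)
                res = fit_nb_glm(sub, design)
            except ValueError as exc:
                warnings.warn(f"skipping {design.name} on {modality}: {exc}")
                continue
            res["modality"] = modality
            frames.append(res)
    if not frames:
        raise ValueError("no analysis could be run")
    table = pd.concat(frames, ignore_index=True)
    table["significant"] = table["fdr"] < alpha
    return table
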