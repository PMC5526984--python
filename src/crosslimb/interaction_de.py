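"""Precision-weighted linear modeling with empirical-Bayes moderated t-tests.

Counts are transformed to log2-CPM; observation-level precision weights are
derived from a lowess fit of residual standard deviations against average
log-count (the mean-variance trend of count data); per-gene weighted least
squares under a group-means design yields contrast estimates whose residual
variances are shrunk toward a pooled prior (d0, s0^2) before t-testing. For
the cross-species analysis the design has one indicator per group (EF, EH,
CF, CH = emu/chicken x forelimb/hindlimb) and the tested contrast is the
species-by-tissue interaction (EF - EH) - (CF - CH): the difference of
within-species fore/hind log-ratios. Species-level biases (assembly quality,
annotation completeness) enter both tissues of a species equally and cancel
from this contrast, which is why the two species' counts can be modeled
jointly even though direct cross-species contrasts (e.g. EF - CF) are not
interpretable.

Significant genes (Benjamini-Hochberg FDR < alpha) are ranked by
R_g = |log2FC fore/hind, species A| - |log2FC fore/hind, species B| in
descending order, putting genes whose fore/hind asymmetry is dominated by
species A (emu) on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

GROUP_LEVELS = ("EF", "EH", "CF", "CH")

#: Interaction contrast (EF - EH) - (CF - CH) on the group-means coefficients.
INTERACTION_CONTRAST = np.array([1.0, -1.0, -1.0, 1.0])

_SPECIES_CODE = {"emu": "E", "chicken": "C", "chick": "C", "E": "E", "C": "C"}
_TISSUE_CODE = {"fore": "F", "forelimb": "F", "hind": "H", "hindlimb": "H", "F": "F", "H": "H"}


class ModelError(ValueError):
    """Design or fitting problem (rank deficiency, no residual df, ...)."""


def make_group_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Group-means design matrix (no intercept) with columns EF, EH, CF, CH.

    ``samples`` needs ``sample``, ``species`` and ``tissue`` columns; each
    sample lands in exactly one group.
    """
    groups = []
    for _, row in samples.iterrows():
        sp = _SPECIES_CODE.get(str(row["species"]).lower(), None)
        ti = _TISSUE_CODE.get(str(row["tissue"]).lower(), None)
        if sp is None or ti is None:
            raise ModelError(
                f"sample {row['sample']!r}: unrecognized species/tissue "
                f"({row['species']!r}, {row['tissue']!r})"
            )
        groups.append(sp + ti)
    X = pd.DataFrame(0.0, index=list(samples["sample"]), columns=list(GROUP_LEVELS))
    for sample, g in zip(samples["sample"], groups):
        X.loc[sample, g] = 1.0
    return X


def log_cpm(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """log2 counts-per-million: y = log2((c + 0.5) / (L + 1) * 1e6).

    ``L`` is the per-sample column total. Returns ``(y, lib_sizes)``.
    """
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"all-zero sample columns: {bad}")
    y = np.log2((arr + 0.5) / (lib.to_numpy() + 1.0) * 1e6)
    return pd.DataFrame(y, index=counts.index, columns=counts.columns), lib.astype(float)


@dataclass
class WeightedExpression:
    """log2-CPM matrix with observation-level precision weights.

    ``trend_x``/``trend_y`` trace the fitted sqrt-residual-sd vs average
    log2-count curve the weights are read from.
    """

    y: pd.DataFrame
    weights: pd.DataFrame
    lib_sizes: pd.Series
    trend_x: np.ndarray
    trend_y: np.ndarray


def _ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    beta = y @ np.linalg.pinv(X).T
    fitted = beta @ X.T
    resid = y - fitted
    return beta, fitted, resid


def estimate_weights(
    y: pd.DataFrame,
    lib_sizes: pd.Series,
    design: pd.DataFrame,
    span: float = 0.5,
) -> WeightedExpression:
    """Derive precision weights from the empirical mean-variance trend.

    Per-gene OLS residual standard deviations (quarter-root scale) are
    smoothed by lowess against average log2 count; predicted trend values at
    each observation's fitted log-count, raised to the -4th power, become the
    weights. Predictions outside the trend's range are clamped to its
    endpoints, keeping every weight positive and finite.
    """
    X = design.to_numpy(dtype=float)
    G, n = y.shape
    p = np.linalg.matrix_rank(X)
    df_resid = n - p
    if df_resid <= 0:
        raise ModelError(f"no residual degrees of freedom (n={n}, rank={p})")
    if G < 10:
        raise ModelError("need >= 10 genes to fit the mean-variance trend")

    yarr = y.to_numpy()
    _, fitted, resid = _ols_fit(yarr, X)
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)

    lib = lib_sizes.to_numpy(dtype=float)
    # average log2 count per gene; the log2(1e6) offset undoes the CPM scale
    sx = yarr.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    delta = 0.01 * (sx.max() - sx.min())
    smooth = sm_lowess(sy, sx, frac=span, it=3, delta=delta, return_sorted=True)
    tx, ty = smooth[:, 0], smooth[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]
    if len(tx) < 2:
        raise ModelError("degenerate mean-variance trend (constant log-counts)")

    # predicted log2 count for every observation, from the fitted log2-CPM
    fitted_logcount = fitted + np.log2(lib + 1.0) - np.log2(1e6)
    pred = np.interp(fitted_logcount, tx, ty)  # np.interp clamps at the ends
    pred = np.clip(pred, max(ty.min(), 1e-10), None)
    w = pred**-4

    return WeightedExpression(
        y=y,
        weights=pd.DataFrame(w, index=y.index, columns=y.columns),
        lib_sizes=lib_sizes,
        trend_x=tx,
        trend_y=ty,
    )


@dataclass
class LinearFit:
    """Per-gene weighted least-squares fit under a shared design."""

    coefficients: pd.DataFrame  # genes x design columns
    sigma: np.ndarray  # residual sd per gene
    df_resid: int
    cov_unscaled: np.ndarray  # genes x p x p, (X' W_g X)^-1
    design: pd.DataFrame


def fit_weighted_lm(
    y: pd.DataFrame, weights: pd.DataFrame, design: pd.DataFrame
) -> LinearFit:
    """Gene-wise WLS: beta_g = (X' W_g X)^-1 X' W_g y_g, s_g^2 = wRSS/df."""
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("design matrix is rank deficient")
    df_resid = n - p
    if df_resid <= 0:
        raise ModelError(f"no residual degrees of freedom (n={n}, p={p})")

    yarr = y.to_numpy()
    w = weights.to_numpy()
    if not np.all(np.isfinite(w)) or (w <= 0).any():
        raise ValueError("weights must be positive and finite")

    xtwx = np.einsum("np,gn,nq->gpq", X, w, X)
    xtwy = np.einsum("np,gn->gp", X, w * yarr)
    cov_unscaled = np.linalg.inv(xtwx)
    beta = np.einsum("gpq,gq->gp", cov_unscaled, xtwy)
    resid = yarr - beta @ X.T
    s2 = (w * resid**2).sum(axis=1) / df_resid

    return LinearFit(
        coefficients=pd.DataFrame(beta, index=y.index, columns=design.columns),
        sigma=np.sqrt(s2),
        df_resid=df_resid,
        cov_unscaled=cov_unscaled,
        design=design,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on the log scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    observed residual variances via the distribution of log s^2.

    Genes with exactly zero residual variance are excluded from estimation.
    Returns ``(d0, s0_2)``; d0 = inf when the log-variances show no excess
    spread beyond sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise ModelError("too few genes with positive residual variance (need >= 10)")
    z = np.log(s2[ok])
    half_df = df_resid / 2.0
    e = z - special.digamma(half_df) + np.log(half_df)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, half_df))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def ebayes_moderate(
    fit: LinearFit,
    contrast: np.ndarray,
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Moderated t-test of a contrast with empirical-Bayes variance shrinkage.

    The shrunk variance is s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g) and
    the moderated t = L'beta_g / (s~_g * sqrt(L'(X'W_gX)^-1 L)) is referred
    to a t-distribution on d0 + d_g degrees of freedom (normal when d0 is
    infinite). ``d0``/``s0_2`` override the moment estimates — d0 = 0
    recovers the ordinary per-gene t-test, d0 = inf the fully pooled one.

    Returns a DataFrame (indexed like the fit) with columns ``estimate``,
    ``t``, ``p_value`` and attrs ``d0``, ``s0_2``, ``df_total``.
    """
    L = np.asarray(contrast, dtype=float)
    if L.shape != (fit.coefficients.shape[1],):
        raise ValueError(
            f"contrast length {L.shape} does not match design "
            f"({fit.coefficients.shape[1]} coefficients)"
        )
    s2 = fit.sigma**2
    if not np.any(s2 > 0):
        raise ModelError(
            "all residual variances are zero: data have no replication noise, "
            "moderated inference is undefined"
        )
    if d0 is None or s0_2 is None:
        d0_hat, s0_2_hat = fit_variance_prior(s2, fit.df_resid)
        d0 = d0_hat if d0 is None else d0
        s0_2 = s0_2_hat if s0_2 is None else s0_2

    est = fit.coefficients.to_numpy() @ L
    var_unscaled = np.einsum("p,gpq,q->g", L, fit.cov_unscaled, L)
    stdev_unscaled = np.sqrt(np.maximum(var_unscaled, 0.0))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + fit.df_resid * s2) / (d0 + fit.df_resid)
        df_total = d0 + fit.df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / (np.sqrt(s2_post) * stdev_unscaled)
    t = np.where(np.isnan(t) & (est == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)

    out = pd.DataFrame(
        {"estimate": est, "t": t, "p_value": p}, index=fit.coefficients.index
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s0_2"] = float(s0_2)
    out.attrs["df_total"] = float(df_total)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_candidates(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rank FDR-significant genes by R_g = |logFC_E| - |logFC_C|, descending.

    Ties break on smaller FDR, then gene ID. Returns a DataFrame with columns
    ``gene_id, score, logFC_E, logFC_C, fdr, rank`` (rank 1 = top candidate);
    empty when nothing is significant.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    sig = results[results["fdr"] < alpha].copy()
    sig["score"] = sig["logFC_E"].abs() - sig["logFC_C"].abs()
    sig = sig.rename_axis("gene_id").reset_index()
    sig = sig.sort_values(
        ["score", "fdr", "gene_id"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    sig["rank"] = np.arange(1, len(sig) + 1)
    return sig[["gene_id", "score", "logFC_E", "logFC_C", "fdr", "rank"]]


def run_interaction_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    span: float = 0.5,
    min_count: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full interaction analysis of a joined two-species count matrix.

    Returns ``(results, info)``. ``results`` has one row per gene with the
    within-species fore/hind log2 fold changes (``logFC_E``, ``logFC_C``),
    their difference (``interaction_logFC``), the moderated t, raw and
    BH-adjusted p-values, the ranking score for significant genes and the
    rank (NaN for non-significant genes). ``info`` records the prior
    hyperparameters and the gene counts at each stage.
    """
    samples = samples.set_index("sample").loc[list(counts.columns)].reset_index()
    if min_count:
        keep = (counts >= min_count).sum(axis=1) >= 2
        counts = counts[keep]
    design = make_group_design(samples)
    y, lib = log_cpm(counts)
    wx = estimate_weights(y, lib, design, span=span)
    fit = fit_weighted_lm(y, wx.weights, design)
    mod = ebayes_moderate(fit, INTERACTION_CONTRAST)

    coef = fit.coefficients
    results = pd.DataFrame(
        {
            "logFC_E": coef["EF"] - coef["EH"],
            "logFC_C": coef["CF"] - coef["CH"],
            "interaction_logFC": mod["estimate"],
            "t_moderated": mod["t"],
            "p_value": mod["p_value"],
        },
        index=counts.index,
    )
    results["fdr"] = bh_adjust(results["p_value"].to_numpy())
    ranked = rank_candidates(results, alpha=alpha)
    results["score"] = results["logFC_E"].abs() - results["logFC_C"].abs()
    results["rank"] = ranked.set_index("gene_id")["rank"].reindex(results.index)

    info = {
        "n_genes_tested": int(len(results)),
        "n_significant": int((results["fdr"] < alpha).sum()),
        "alpha": alpha,
        "d0": mod.attrs["d0"],
        "s0_2": mod.attrs["s0_2"],
    }
    return results, info
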