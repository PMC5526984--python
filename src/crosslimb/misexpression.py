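"""Analysis of the mis-expression experiment (treated vs control wing buds).

Genes are first filtered to those with at least ``min_count`` counts in at
least ``min_samples`` samples; embryo sex is inferred from the counts of a
female-specific marker gene (HINTW, a W-chromosome gene absent in males);
and a linear model with a treatment coefficient and a sex covariate is fit
with the same precision-weighting and moderated-t machinery as the
cross-species analysis, testing the treatment coefficient.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from crosslimb.interaction_de import (
    ModelError,
    bh_adjust,
    ebayes_moderate,
    estimate_weights,
    fit_weighted_lm,
    log_cpm,
)

DEFAULT_MARKER = "HINTW"


def filter_low_counts(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 2
) -> pd.DataFrame:
    """Keep genes with >= ``min_count`` counts in >= ``min_samples`` samples.

    Row order is preserved.
    """
    qualifying = (counts >= min_count).sum(axis=1)
    return counts[qualifying >= min_samples]


def infer_sex(
    counts: pd.DataFrame,
    marker_gene: str = DEFAULT_MARKER,
    cpm_threshold: float = 1.0,
) -> pd.Series:
    """Call each sample female iff the marker gene exceeds ``cpm_threshold``
    CPM (strictly), male otherwise.

    The call is library-size invariant because it is made on CPM. Raises if
    the marker row is absent — supply sexes explicitly in that case.
    """
    if marker_gene not in counts.index:
        raise KeyError(
            f"marker gene {marker_gene!r} not found in the count matrix; "
            "supply per-sample sexes explicitly in the sample sheet"
        )
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("all-zero sample columns; cannot compute CPM")
    cpm = counts.loc[marker_gene] / lib * 1e6
    sex = pd.Series(
        np.where(cpm > cpm_threshold, "female", "male"),
        index=counts.columns,
        name="sex",
    )
    return sex


def build_misexpression_design(
    samples: pd.DataFrame, sex: pd.Series | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (intercept, treatment, sex) and the treatment contrast.

    ``samples`` needs ``sample`` and ``treatment`` columns (levels 'control'
    and 'misexpression'). Sex comes from the ``sex`` argument, else the
    sample sheet; female is coded 1. A constant sex column is dropped with a
    warning rather than leaving the design singular.
    """
    names = list(samples["sample"])
    treat = samples["treatment"].astype(str).str.lower()
    levels = set(treat)
    if not levels <= {"control", "misexpression"}:
        raise ModelError(f"unknown treatment levels: {sorted(levels)}")
    if len(levels) < 2:
        raise ModelError("both treatment arms are required to estimate the effect")
    t_ind = (treat == "misexpression").astype(float).to_numpy()
    if t_ind.sum() < 2 or (1 - t_ind).sum() < 2:
        raise ModelError("need >= 2 samples in each treatment arm")

    X = pd.DataFrame({"intercept": 1.0, "treatment": t_ind}, index=names)
    if sex is None and "sex" in samples.columns:
        sex = samples.set_index("sample")["sex"]
    if sex is not None:
        s_ind = (sex.reindex(names).astype(str).str.lower() == "female").astype(float)
        if s_ind.nunique() < 2:
            warnings.warn(
                "sex does not vary across samples; dropping the sex coefficient",
                UserWarning,
                stacklevel=2,
            )
        elif np.array_equal(s_ind.to_numpy(), t_ind) or np.array_equal(
            s_ind.to_numpy(), 1 - t_ind
        ):
            warnings.warn(
                "sex is confounded with treatment; dropping the sex coefficient",
                UserWarning,
                stacklevel=2,
            )
        else:
            X["sex_female"] = s_ind.to_numpy()
    contrast = np.zeros(X.shape[1])
    contrast[list(X.columns).index("treatment")] = 1.0
    return X, contrast


def misexpression_fit(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    sex: pd.Series | None = None,
    alpha: float = 0.05,
    span: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Moderated-t test of the treatment coefficient, adjusting for sex.

    ``counts`` should already be low-count filtered. Returns ``(results,
    info)``; results hold ``logFC_treatment, t_moderated, p_value, fdr,
    rank`` with genes ranked by FDR then |logFC|.
    """
    samples = samples.set_index("sample").loc[list(counts.columns)].reset_index()
    X, contrast = build_misexpression_design(samples, sex=sex)
    y, lib = log_cpm(counts)
    wx = estimate_weights(y, lib, X, span=span)
    fit = fit_weighted_lm(y, wx.weights, X)
    mod = ebayes_moderate(fit, contrast)

    results = pd.DataFrame(
        {
            "logFC_treatment": mod["estimate"],
            "t_moderated": mod["t"],
            "p_value": mod["p_value"],
        },
        index=counts.index,
    )
    results["fdr"] = bh_adjust(results["p_value"].to_numpy())
    order = results.assign(_abs=results["logFC_treatment"].abs()).sort_values(
        ["fdr", "_abs"], ascending=[True, False], kind="stable"
    )
    results["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order.index
    ).reindex(results.index)

    info = {
        "n_genes_tested": int(len(results)),
        "n_significant": int((results["fdr"] < alpha).sum()),
        "alpha": alpha,
        "d0": mod.attrs["d0"],
        "s0_2": mod.attrs["s0_2"],
        "design_columns": list(X.columns),
    }
    return results, info
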