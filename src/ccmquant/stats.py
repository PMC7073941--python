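"""Downstream statistics: filtering, imputation, scaling, PCA, testing.

The conventions follow standard practice in metabolomics data analysis:
metabolites quantified in more than half of the biological groups are kept,
missing values are imputed with the metabolite's minimum measured value,
columns are auto-scaled (mean 0, unit variance) before PCA, group
differences are assessed with pooled-variance two-sample t-tests corrected
by the Benjamini–Hochberg step-up FDR, and effect sizes are reported as
log2 fold changes of group mean concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .panel import MetabolitePanel
from .quantify import FLAG_OK

__all__ = [
    "concentration_matrix",
    "group_means",
    "prevalence_filter",
    "impute_min",
    "autoscale",
    "PcaResult",
    "pca",
    "ttest_fdr",
    "log2_fold_change",
    "class_composition",
    "magnitude_heatmap",
]


def concentration_matrix(intracellular: pd.DataFrame) -> pd.DataFrame:
    """Wide samples x metabolites matrix of quantified intracellular molar
    concentrations; any non-``ok`` flag (missing, below LLOQ, rejected
    outlier, ...) becomes an absent cell.  Index is (group_id, sample_id)."""
    ok = intracellular.copy()
    ok.loc[ok["flag"] != FLAG_OK, "conc_intracellular_M"] = np.nan
    mat = (
        ok.set_index(["group_id", "sample_id", "metabolite_id"])["conc_intracellular_M"]
        .unstack("metabolite_id")
    )
    mat.columns.name = "metabolite_id"
    return mat


def group_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean over quantified replicates (groups x metabolites)."""
    return matrix.groupby(level="group_id").mean()


def prevalence_filter(
    matrix: pd.DataFrame, threshold: float = 0.5, unit: str = "groups"
) -> pd.DataFrame:
    """Keep metabolites quantified in strictly more than ``threshold`` of the
    biological groups (``unit="groups"``, a group counts as covered when at
    least one replicate is quantified) or of the samples (``unit="samples"``)."""
    if matrix.empty:
        raise ValidationError("empty concentration matrix")
    if unit == "groups":
        present = matrix.notna().groupby(level="group_id").any()
        frac = present.mean(axis=0)
    elif unit == "samples":
        frac = matrix.notna().mean(axis=0)
    else:
        raise ValidationError(f"unknown prevalence unit {unit!r}")
    return matrix.loc[:, frac > threshold]


def impute_min(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace absent cells by the metabolite's minimum measured value."""
    if matrix.isna().all(axis=0).any():
        cols = list(matrix.columns[matrix.isna().all(axis=0)])
        raise ValidationError(f"cannot impute fully-missing metabolite(s): {cols}")
    return matrix.fillna(matrix.min(axis=0))


def autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite mean-centering and division by the sample SD (n-1)."""
    if matrix.isna().any().any():
        raise ValidationError("autoscale requires a complete (imputed) matrix")
    sd = matrix.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValidationError(f"zero-variance metabolite column(s): {list(zero.index)}")
    return (matrix - matrix.mean(axis=0)) / sd


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components
    explained_variance_fraction: np.ndarray
    ellipses: pd.DataFrame  # per group: center/semi-axes/angle of the 95% region


def _group_ellipses(scores: pd.DataFrame, level: float, method: str) -> pd.DataFrame:
    """95% confidence ellipse of the first two score dimensions per group.

    ``chi2``: covariance ellipse scaled by the chi-square(2) quantile;
    ``hotelling``: small-sample Hotelling-T2 scaling with the F quantile.
    """
    rows = []
    for group_id, sub in scores.groupby(level="group_id"):
        pts = sub.iloc[:, :2].to_numpy()
        n = len(pts)
        if n < 3:
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        if method == "chi2":
            scale = sps.chi2.ppf(level, df=2)
        elif method == "hotelling":
            scale = 2 * (n - 1) / (n - 2) * sps.f.ppf(level, 2, n - 2)
        else:
            raise ValidationError(f"unknown ellipse method {method!r}")
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        rows.append(
            {
                "group_id": group_id,
                "center_pc1": center[0],
                "center_pc2": center[1],
                "semi_axis_major": float(np.sqrt(max(evals[0], 0.0) * scale)),
                "semi_axis_minor": float(np.sqrt(max(evals[1], 0.0) * scale)),
                "angle_rad": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def pca(
    matrix: pd.DataFrame,
    n_components: int = 2,
    *,
    ellipse_level: float = 0.95,
    ellipse_method: str = "chi2",
) -> PcaResult:
    """PCA of an auto-scaled matrix with per-group 95% score ellipses.

    Sign convention: the largest-magnitude loading of each component is
    positive, making scores/loadings reproducible across library versions.
    """
    n_samples, n_mets = matrix.shape
    if n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    max_comp = min(n_samples - 1, n_mets)
    if n_components > max_comp:
        raise ValidationError(f"n_components must be <= {max_comp}")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix.to_numpy())
    loadings = model.components_.T  # metabolites x components
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=comp_names)
    loadings_df = pd.DataFrame(loadings, index=matrix.columns, columns=comp_names)
    ellipses = (
        _group_ellipses(scores_df, ellipse_level, ellipse_method)
        if n_components >= 2 and "group_id" in (matrix.index.names or [])
        else pd.DataFrame()
    )
    return PcaResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
        ellipses=ellipses,
    )


def log2_fold_change(mean_a: float, mean_b: float) -> float:
    """log2(mean_a / mean_b); NaN when either mean is not positive."""
    if not (mean_a > 0 and mean_b > 0):
        return float("nan")
    return float(np.log2(mean_a / mean_b))


def ttest_fdr(
    matrix: pd.DataFrame, group_a: str, group_b: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-metabolite pooled-variance two-tailed t-test between two groups
    with Benjamini–Hochberg FDR adjustment.

    Returns a table with means, log2 fold change (a over b), t, p, q and the
    significance flag q <= alpha.
    """
    groups = matrix.index.get_level_values("group_id")
    a = matrix[groups == group_a]
    b = matrix[groups == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 replicates")
    res = sps.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0, equal_var=True)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": [log2_fold_change(x, y) for x, y in zip(mean_a, mean_b)],
            "t_statistic": res.statistic,
            "p_value": p,
            "q_value": q,
            "significant": q <= alpha,
        },
        index=matrix.columns,
    )
    out.index.name = "metabolite_id"
    return out


def class_composition(means: pd.DataFrame, panel: MetabolitePanel) -> pd.DataFrame:
    """Percent contribution of each metabolite class to the total measured
    pool, per group.  ``means`` is groups x metabolites (molar)."""
    class_of = panel.class_of()
    cls = means.columns.map(lambda m: class_of.get(m, "unknown"))
    totals = means.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"zero total measured pool for group(s): {bad}")
    rows = []
    for met_class in sorted(set(cls)):
        sub = means.loc[:, cls == met_class].sum(axis=1)
        for group_id, val in sub.items():
            rows.append(
                {
                    "group_id": group_id,
                    "met_class": met_class,
                    "percent": 100.0 * val / totals[group_id],
                }
            )
    return pd.DataFrame(rows)


def magnitude_heatmap(means: pd.DataFrame) -> pd.DataFrame:
    """Order of magnitude floor(log10(mean)) per (group, metabolite); decade
    boundaries belong to their own decade (1e-3 M -> -3).  Non-positive or
    absent means give absent cells (pandas NA)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.floor(np.log10(means.where(means > 0)))
    return vals.astype("Int64")
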