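"""Group association of epimutation burden scores, plus cohort diagnostics.

For every gene within one (region, direction) stratum the burden score is
regressed on the group indicator and available covariates with a quantile
regression at the median:

    wsems ~ group + age + stage + epithelial

The group coefficient is the covariate-adjusted shift of the median burden
in the positive group; its p-value comes from an exact-refit xy-pair
bootstrap (see :mod:`epiburden.quantreg`).  P-values are adjusted with the
Benjamini-Hochberg step-up within the stratum.

The model is deliberately oriented with the burden as the outcome and the
group as a regressor: that is the only orientation in which a median
quantile regression yields a coefficient interpretable as "how much higher
the typical epimutation burden is in the positive group", which is the
quantity the downstream enrichment consumes.

Also here: a contingency summary with Pearson chi-square for categorical
cohort characteristics, and a PCA check correlating the leading principal
components of the M-value matrix with the covariates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import M_SCALE, MethylationMatrix, ScaleError
from .quantreg import bootstrap_median_fit
from .regions import dense_scores
from .simulate import GROUP_NEGATIVE, GROUP_POSITIVE

log = logging.getLogger(__name__)

STAGE_SCORES = {"I": 1, "II": 2, "III": 3, "IV": 4}
OPTIONAL_COVARIATES = ("age", "stage", "epithelial")

RESULT_COLUMNS = [
    "gene", "region", "direction", "beta_group", "p", "q", "n_nonzero", "converged",
]


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + group indicator + whichever optional covariates exist."""
    if "group" not in covariates.columns:
        raise ValueError("covariates must contain a 'group' column")
    groups = set(covariates["group"].unique())
    if not groups <= {GROUP_POSITIVE, GROUP_NEGATIVE}:
        raise ValueError(f"unexpected group labels: {groups}")
    if len(groups) < 2:
        raise ValueError("degenerate design: only one group present")
    cols = [np.ones(len(covariates)), (covariates["group"] == GROUP_POSITIVE).to_numpy(float)]
    names = ["intercept", "group"]
    for cov in OPTIONAL_COVARIATES:
        if cov not in covariates.columns or covariates[cov].isna().all():
            continue
        if cov == "stage":
            vals = covariates["stage"].map(STAGE_SCORES)
            if vals.isna().any():
                raise ValueError("stage values must be I, II, III or IV")
            cols.append(vals.to_numpy(float))
        else:
            cols.append(covariates[cov].to_numpy(float))
        names.append(cov)
    return np.column_stack(cols), names


def quantile_regression_median(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    direction: str,
    region: str,
    n_boot: int = 500,
    seed: int = 0,
    q_family: bool = True,
    genes=None,
) -> pd.DataFrame:
    """Per-gene median regression of WSEMS on group + covariates.

    ``scores`` is the long score table; ``covariates`` is indexed by sample
    and must cover every scored sample.  Genes with all-zero scores across
    samples are untestable: they are reported with NaN statistics and
    excluded from the BH family.  Returns one row per gene with the group
    coefficient (positive = higher burden in the positive group), bootstrap
    p, BH q and the count of samples with a nonzero score.
    """
    samples = covariates.index
    scored_samples = set(scores["sample"].unique())
    if not scored_samples <= set(samples):
        raise ValueError("scores contain samples missing from the covariate table")
    X, names = _design_matrix(covariates)
    grid = dense_scores(scores, samples, direction, region)
    universe = list(grid.index) if genes is None else list(genes)
    rng_root = np.random.SeedSequence(seed)

    rows = []
    tested_idx = []
    for gene, seq in zip(universe, rng_root.spawn(len(universe))):
        if gene not in grid.index:
            rows.append((gene, region, direction, np.nan, np.nan, np.nan, 0, False))
            continue
        y = grid.loc[gene].to_numpy(float)
        n_nonzero = int((y > 0).sum())
        fit = bootstrap_median_fit(
            X, y, coef_index=1, n_boot=n_boot, rng=np.random.default_rng(seq)
        )
        tested_idx.append(len(rows))
        rows.append(
            (gene, region, direction, fit["coef"], fit["p"], np.nan, n_nonzero, fit["converged"])
        )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if q_family and tested_idx:
        out.loc[tested_idx, "q"] = bh_adjust(out.loc[tested_idx, "p"].to_numpy())
    out.attrs["design_columns"] = names
    out.attrs["n_boot"] = n_boot
    out.attrs["solver"] = "exact LAD linear program, warm-started dual simplex"
    n_untestable = int((out["n_nonzero"] == 0).sum())
    if n_untestable:
        log.info("%d genes untestable (all-zero scores) in %s/%s", n_untestable, region, direction)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def summarize_cohort(
    covariates: pd.DataFrame,
    factor: pd.Series,
    group_col: str = "group",
    correction: bool = False,
) -> dict:
    """Contingency summary of a categorical factor against the group label.

    Returns the count table (factor levels x groups), within-group column
    percentages, and the Pearson chi-square test over all cells.  The
    continuity-correction flag (applied by SciPy only to 2x2 tables) is
    recorded in the output so the exact variant used is reproducible.
    """
    joined = pd.DataFrame({group_col: covariates[group_col], "factor": factor.reindex(covariates.index)})
    counts = pd.crosstab(joined["factor"], joined[group_col])
    if counts.size == 0:
        raise ValueError("empty contingency table")
    percents = counts / counts.sum(axis=0) * 100
    chi2, p, dof, expected = stats.chi2_contingency(counts.to_numpy(), correction=correction)
    return {
        "counts": counts,
        "percents": percents,
        "chi2": float(chi2),
        "dof": int(dof),
        "p": float(p),
        "continuity_correction": correction,
        "cells": list(counts.index),
    }


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def pca_covariate_check(
    matrix: MethylationMatrix,
    covariates: pd.DataFrame,
    k: int = 5,
) -> pd.DataFrame:
    """Correlate the top-k sample-space principal components with covariates.

    PCA is run on the samples-by-probes matrix (probe-centred).  Numeric
    covariates use Pearson correlation; stage is integer-coded I-IV.
    Returns a long table (component, covariate, r, p, stars).
    """
    if matrix.scale != M_SCALE:
        raise ScaleError("pca_covariate_check requires an M-scale matrix")
    if k > min(matrix.n_samples, matrix.n_probes):
        raise ValueError("k exceeds the matrix rank bound")
    from sklearn.decomposition import PCA

    data = matrix.values.to_numpy(float).T  # samples x probes
    pcs = PCA(n_components=k, svd_solver="full").fit_transform(data - data.mean(axis=0))
    cov = covariates.reindex(matrix.samples)

    rows = []
    for name in OPTIONAL_COVARIATES:
        if name not in cov.columns or cov[name].isna().all():
            continue
        v = cov[name].map(STAGE_SCORES) if name == "stage" else cov[name]
        v = v.to_numpy(float)
        for j in range(k):
            r, p = stats.pearsonr(pcs[:, j], v)
            rows.append({"component": f"PC{j + 1}", "covariate": name,
                         "r": float(r), "p": float(p), "stars": _stars(p)})
    return pd.DataFrame(rows)
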