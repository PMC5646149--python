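"""Imputation accuracy metrics.

Accuracy is primarily the genotype concordance (rate of correctly imputed
genotypes over all study individuals and all imputed variants); the
imputation quality score (IQS) additionally corrects for agreement
expected by chance given the minor allele frequency, in the form of a
Cohen's kappa on the per-variant 3x3 truth-vs-imputed contingency table.
Variants are stratified as rare (MAF <= 0.01), low-frequency
(0.01 < MAF <= 0.05) and common (MAF > 0.05); monomorphic variants are
excluded from analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "genotype_concordance",
    "iqs",
    "iqs_per_variant",
    "maf_category",
    "summarize_replicates",
    "compare_methods",
    "MAF_CATEGORIES",
]

MAF_CATEGORIES = ("rare", "low-frequency", "common")


def _check_matrices(truth, imputed):
    truth = np.asarray(truth)
    imputed = np.asarray(imputed)
    if truth.shape != imputed.shape:
        raise ValueError(
            f"truth {truth.shape} and imputed {imputed.shape} dimensions differ"
        )
    return truth, imputed


def genotype_concordance(truth, best_guess, site_keep=None) -> float:
    """Fraction of correctly imputed genotypes over all individuals and
    (optionally filtered) variants.

    ``site_keep`` is a boolean column filter, typically excluding
    monomorphic variants.
    """
    truth, best_guess = _check_matrices(truth, best_guess)
    if site_keep is not None:
        truth = truth[:, site_keep]
        best_guess = best_guess[:, site_keep]
    if truth.size == 0:
        return np.nan
    return float(np.mean(truth == best_guess))


def iqs_per_variant(truth, best_guess) -> np.ndarray:
    """IQS of each variant (column): kappa of the 3x3 contingency table.

    ``P_o`` is the observed agreement, ``P_e = sum_g row_g * col_g / n^2``
    the marginal chance agreement; IQS = (P_o - P_e) / (1 - P_e), NaN when
    ``P_e`` = 1 (both margins degenerate on the same genotype).
    """
    truth, best_guess = _check_matrices(truth, best_guess)
    n = truth.shape[0]
    out = np.empty(truth.shape[1])
    for j in range(truth.shape[1]):
        table = np.zeros((3, 3))
        np.add.at(table, (truth[:, j], best_guess[:, j]), 1)
        p_o = np.trace(table) / n
        p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
        out[j] = np.nan if p_e >= 1.0 - 1e-12 else (p_o - p_e) / (1.0 - p_e)
    return out


def iqs(truth, best_guess, site_keep=None) -> float:
    """Mean per-variant IQS over the (filtered) variants, skipping
    variants where chance agreement is exactly 1."""
    truth, best_guess = _check_matrices(truth, best_guess)
    if site_keep is not None:
        truth = truth[:, site_keep]
        best_guess = best_guess[:, site_keep]
    per = iqs_per_variant(truth, best_guess)
    if np.all(np.isnan(per)):
        return np.nan
    return float(np.nanmean(per))


def maf_category(maf: float) -> str:
    """Boundary-inclusive MAF stratum: ``monomorphic`` (0), ``rare``
    (<= 0.01), ``low-frequency`` (<= 0.05) or ``common``."""
    if not 0 <= maf <= 0.5:
        raise ValueError(f"minor allele frequency must lie in [0, 0.5], got {maf}")
    if maf == 0:
        return "monomorphic"
    if maf <= 0.01:
        return "rare"
    if maf <= 0.05:
        return "low-frequency"
    return "common"


def summarize_replicates(values) -> tuple[float, tuple[float, float]]:
    """Mean and normal-approximation 95% CI (mean +/- 1.96 * sd/sqrt(n))
    across replicates.  With fewer than two values the CI is (nan, nan)."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return np.nan, (np.nan, np.nan)
    mean = float(values.mean())
    if values.size < 2:
        return mean, (np.nan, np.nan)
    half = 1.96 * values.std(ddof=1) / np.sqrt(values.size)
    return mean, (mean - half, mean + half)


def compare_methods(values_a, values_b) -> dict:
    """Two-sample comparison of per-replicate accuracies: t-test on the
    means and F-test on the variances (both two-sided).

    Zero-variance degenerate inputs yield p = 1 when the samples are
    identical in mean/variance and p = 0 otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicate values per method")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        t_p = 1.0 if a.mean() == b.mean() else 0.0
        f_p = 1.0
        t_stat = 0.0 if a.mean() == b.mean() else np.inf
        f_stat = 1.0
    else:
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
        if va == 0 or vb == 0:
            f_stat, f_p = np.inf, 0.0
        else:
            f_stat = va / vb
            dfa, dfb = a.size - 1, b.size - 1
            cdf = stats.f.cdf(f_stat, dfa, dfb)
            f_p = 2.0 * min(cdf, 1.0 - cdf)
    return {
        "t_stat": float(t_stat),
        "t_pvalue": float(t_p),
        "f_stat": float(f_stat),
        "f_pvalue": float(f_p),
    }


# ----------------------------------------------------------------------
def evaluate_imputation(cohort, posterior) -> pd.DataFrame:
    """Per-stratum accuracy of one imputation run.

    MAF is computed from the true allele frequencies over the full
    simulated sample (study plus reference), the only source available
    identically to both imputation methods; variants monomorphic in the
    pooled truth are excluded.  Returns one row per stratum plus an
    ``all`` row with columns ``n_variants``, ``concordance`` and ``iqs``.
    """
    truth = cohort.study_truth()
    best = posterior.best_guess
    if not np.array_equal(posterior.masked_idx, cohort.masked_idx):
        raise ValueError("posterior covers different masked sites than the cohort")
    maf = cohort.haps.minor_allele_freq()[cohort.masked_idx]
    cats = np.array([maf_category(m) for m in maf])
    keep = cats != "monomorphic"
    per_iqs = iqs_per_variant(truth, best)
    rows = []
    for cat in ("all",) + MAF_CATEGORIES:
        sel = keep if cat == "all" else (cats == cat)
        n_var = int(sel.sum())
        conc = genotype_concordance(truth, best, sel) if n_var else np.nan
        iqs_val = (
            float(np.nanmean(per_iqs[sel]))
            if n_var and not np.all(np.isnan(per_iqs[sel]))
            else np.nan
        )
        rows.append({
            "maf_category": cat,
            "n_variants": n_var,
            "concordance": conc,
            "iqs": iqs_val,
        })
    return pd.DataFrame(rows)
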