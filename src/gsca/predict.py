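"""Predicted vs observed allele frequency change, thinning, FDR, cross-validation.

Selection estimates are converted into the common currency of predicted
per-generation allele frequency change:

    male selection:      dp = (p_M - p_A) / 2
    viability selection: dp = (1 - alpha) (p_A - p_L)

where alpha is the fraction of seedlings surviving to reproduce (0.7 in the
target field system, from 700 of 1000 surveyed seedlings).  The observed
change is p_Z (pooled zygote frequency of the next year) minus p_A.

Split-half cross-validation guards against the winner's-curse / shared-
parameter artifacts: families are split into odd and even halves, models are
fitted per half, and each significant SNP yields an "Ascertained" contrast
(the significant half's prediction against the other half's observation)
and a complementary "Paired" contrast.  Under neutrality the Paired
correlation is zero even though the un-partitioned observed-vs-predicted
covariance is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_ALPHA",
    "survival_fraction",
    "viability_coefficient",
    "predicted_dp",
    "observed_dp",
    "best_snp_per_gene",
    "bh_fdr",
    "fisher_combined",
    "crossval_contrasts",
    "PredictionSummary",
    "prediction_summary",
]

DEFAULT_ALPHA = 0.7


def survival_fraction(n_survived: int, n_total: int) -> float:
    """Fraction of marked seedlings that survived to flower."""
    if not 0 <= n_survived <= n_total or n_total == 0:
        raise ValueError("need 0 <= n_survived <= n_total, n_total > 0")
    return n_survived / n_total


def viability_coefficient(alpha: float = DEFAULT_ALPHA) -> float:
    """Coefficient of (p_A - p_L) in the viability prediction: 1 - alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - alpha


def predicted_dp(test: str, estimates: dict[str, float], alpha: float = DEFAULT_ALPHA) -> float:
    """Predicted per-generation frequency change for one selection component."""
    if test == "male":
        return (estimates["p_M"] - estimates["p_A"]) / 2.0
    if test == "viability":
        return viability_coefficient(alpha) * (estimates["p_A"] - estimates["p_L"])
    raise ValueError(f"unknown test {test!r}")


def observed_dp(p_Z_next: float, p_A: float) -> float:
    """Observed change: next year's pooled zygote frequency minus adult frequency."""
    return p_Z_next - p_A


def best_snp_per_gene(
    results: pd.DataFrame, threshold: float = 1e-5, p_col: str = "p_value"
) -> pd.DataFrame:
    """At most one SNP per gene set: the minimum p, reported only below threshold.

    Ties are broken by genomic position (5'-most wins).
    """
    df = results.sort_values([p_col, "pos"], kind="stable")
    best = df.groupby("set_id", sort=False).head(1)
    return best[best[p_col] < threshold].reset_index(drop=True)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combined(p1: float, p2: float) -> tuple[float, float]:
    """Fisher's combined statistic over two tests: X = -2(ln p1 + ln p2) ~ chi2(4)."""
    p1 = max(float(p1), 1e-300)
    p2 = max(float(p2), 1e-300)
    X = -2.0 * (np.log(p1) + np.log(p2))
    return X, float(stats.chi2.sf(X, 4))


def crossval_contrasts(
    half_results: pd.DataFrame,
    threshold: float = 1e-5,
    reverse: bool = False,
) -> pd.DataFrame:
    """Build Ascertained/Paired contrast pairs from per-half fits.

    ``half_results`` has one row per SNP with columns ``snp_id``,
    ``p_odd``, ``p_even``, ``pred_odd``, ``pred_even``, ``obs_odd``,
    ``obs_even``.  For a SNP significant in exactly one half, the
    Ascertained contrast matches the significant half's predicted dp to the
    other half's observed dp and the Paired contrast is the complement.
    ``reverse=True`` flips the assignment — appropriate for the allele
    frequency change test, whose ascertainment acts on the observed dp.  A
    SNP significant in both halves yields two Ascertained contrasts and no
    Paired one.
    """
    rows = []
    for rec in half_results.itertuples(index=False):
        sig_odd = rec.p_odd < threshold
        sig_even = rec.p_even < threshold
        if not (sig_odd or sig_even):
            continue

        def pair(sig_half: str, kind: str):
            other = "even" if sig_half == "odd" else "odd"
            if not reverse:
                pred_half, obs_half = sig_half, other
            else:
                pred_half, obs_half = other, sig_half
            rows.append(
                {
                    "snp_id": rec.snp_id,
                    "kind": kind,
                    "predicted_half": pred_half,
                    "observed_half": obs_half,
                    "predicted": getattr(rec, f"pred_{pred_half}"),
                    "observed": getattr(rec, f"obs_{obs_half}"),
                }
            )

        if sig_odd and sig_even:
            pair("odd", "Ascertained")
            pair("even", "Ascertained")
        elif sig_odd:
            pair("odd", "Ascertained")
            pair("even", "Paired")
        else:
            pair("even", "Ascertained")
            pair("odd", "Paired")
    return pd.DataFrame(rows, columns=["snp_id", "kind", "predicted_half", "observed_half", "predicted", "observed"])


def parity_split(data) -> tuple:
    """Split a per-SNP family dataset into odd/even halves by family index.

    The family index is its position in the dataset's stable family order,
    mirroring a split on odd/even family numbers.
    """
    idx = np.arange(data.n_families)
    return data.subset(idx % 2 == 1), data.subset(idx % 2 == 0)


def male_selection_fit(data_y1, data_y2) -> dict[str, float]:
    """Male-selection test on one data (half): p-value, predicted and observed dp.

    Fits the year-1 adult/male-gamete contrast (free p_A, p_M vs a single
    shared p) and the year-2 pooled zygote frequency p_Z; predicted dp is
    (p_M - p_A)/2 and observed dp is p_Z - p_A.
    """
    from .models import MODELS_2013, MODELS_2014, fit_model, lrt

    f0 = fit_model(data_y1, MODELS_2013["H0"])
    f1 = fit_model(data_y1, MODELS_2013["H1"])
    if f1.lnL < f0.lnL:
        f1 = fit_model(data_y1, MODELS_2013["H1"],
                       start={"p_A": f0.estimates["p"], "p_M": f0.estimates["p"]})
    t = lrt(f1, f0)
    fz = fit_model(data_y2, MODELS_2014["H0"])
    return {
        "p_value": t.p_value,
        "statistic": t.statistic,
        "predicted": predicted_dp("male", f1.estimates),
        "observed": observed_dp(fz.estimates["p"], f1.estimates["p_A"]),
        "p_A": f1.estimates["p_A"],
        "p_M": f1.estimates["p_M"],
        "p_Z": fz.estimates["p"],
    }


def male_selection_half_results(snp_id: str, data_y1, data_y2) -> dict[str, float]:
    """Full/odd/even male-selection fits for one SNP, as a crossval input row."""
    odd1, even1 = parity_split(data_y1)
    odd2, even2 = parity_split(data_y2)
    full = male_selection_fit(data_y1, data_y2)
    odd = male_selection_fit(odd1, odd2)
    even = male_selection_fit(even1, even2)
    return {
        "snp_id": snp_id,
        "p_full": full["p_value"], "pred_full": full["predicted"], "obs_full": full["observed"],
        "p_odd": odd["p_value"], "pred_odd": odd["predicted"], "obs_odd": odd["observed"],
        "p_even": even["p_value"], "pred_even": even["predicted"], "obs_even": even["observed"],
    }


@dataclass
class PredictionSummary:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def prediction_summary(predicted, observed) -> PredictionSummary:
    """OLS of observed on predicted plus Pearson correlation."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 contrast pairs")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in predictor; summary undefined")
    fit = stats.linregress(x, y)
    return PredictionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )
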