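"""Performance evaluation of angle estimates.

Implements the error metrics (RMSE, mean and median absolute error),
nonparametric bootstrap confidence intervals with the bias-corrected
percentile method (5000 resamples by default), Spearman rank correlation,
Bland-Altman agreement with limits at the median bias +/- 1.45 * iqr of the
signed differences, and per-5-degree-bin error profiles with an
underrepresentation flag for bins backed by fewer than 200 training records.

Quartiles use linear interpolation of order statistics (the common "type 7"
convention).  Reported strata: the whole set, NORM, and pooled cardiac
disease (MI, CD, STTC, HYP, LOWM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "UNDERREPRESENTED_TRAIN_COUNT",
    "bland_altman",
    "bootstrap_estimate",
    "error_metrics",
    "evaluate",
    "ks_normality_diagnostic",
    "per_bin_profile",
    "plot_report",
    "spearman",
]

#: Angle bins with fewer training records than this are flagged.
UNDERREPRESENTED_TRAIN_COUNT = 200

#: Half-width multiplier of the Bland-Altman limits of agreement.
LOA_IQR_FACTOR = 1.45

DISEASE_CLASSES = ("MI", "CD", "STTC", "HYP", "LOWM")


def error_metrics(alpha: np.ndarray, alpha_hat: np.ndarray) -> tuple[float, float, float]:
    """(RMSE, mean absolute error, median absolute error), all in degrees."""
    alpha = np.asarray(alpha, dtype=float)
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    if alpha.shape != alpha_hat.shape or alpha.size == 0:
        raise ValueError("need nonempty, equal-length angle arrays")
    err = np.abs(alpha_hat - alpha)
    rmse = float(np.sqrt(np.mean((alpha_hat - alpha) ** 2)))
    return rmse, float(err.mean()), float(np.median(err))


def bootstrap_estimate(
    errors: np.ndarray,
    statistic: str = "mean",
    B: int = 5000,
    seed: int = 0,
    confidence: float = 0.95,
) -> tuple[float, float, float]:
    """Bootstrap point estimate and bias-corrected percentile CI.

    Resamples with replacement ``B`` times; the point estimate is the
    statistic of the full sample.  The bias correction shifts the percentile
    bounds by the normal quantile of the fraction of bootstrap replicates
    below the point estimate.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("errors must be nonempty")
    if B < 1:
        raise ValueError("B must be >= 1")
    stat = {"mean": np.mean, "median": np.median}[statistic]
    point = float(stat(errors))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, errors.size, size=(B, errors.size))
    boots = stat(errors[idx], axis=1)

    if np.allclose(boots, point):
        return point, point, point
    # bias-corrected percentile: z0 from the fraction of replicates < point
    frac = np.mean(boots < point)
    frac = min(max(frac, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = stats.norm.ppf(frac)
    z_alpha = stats.norm.ppf((1.0 - confidence) / 2.0)
    lo_p = stats.norm.cdf(2 * z0 + z_alpha)
    hi_p = stats.norm.cdf(2 * z0 - z_alpha)
    lo, hi = np.percentile(boots, [100 * lo_p, 100 * hi_p])
    return point, float(lo), float(hi)


def spearman(alpha: np.ndarray, alpha_hat: np.ndarray) -> float:
    """Spearman rank correlation between target and estimated angles."""
    alpha = np.asarray(alpha, dtype=float)
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    if alpha.size == 0 or alpha.shape != alpha_hat.shape:
        raise ValueError("need nonempty, equal-length angle arrays")
    if np.all(alpha == alpha[0]) or np.all(alpha_hat == alpha_hat[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, _ = stats.spearmanr(alpha, alpha_hat)
    return float(rho)


def bland_altman(alpha: np.ndarray, alpha_hat: np.ndarray) -> tuple[float, float, float]:
    """Bland-Altman bias and limits of agreement on signed differences.

    Differences are ``alpha_hat - alpha``; the bias is their median and the
    limits are ``bias +/- 1.45 * iqr`` with type-7 quartiles.
    """
    d = np.asarray(alpha_hat, dtype=float) - np.asarray(alpha, dtype=float)
    if d.size == 0:
        raise ValueError("need nonempty angle arrays")
    bias = float(np.median(d))
    q25, q75 = np.percentile(d, [25, 75])  # linear interpolation = type 7
    half = LOA_IQR_FACTOR * (q75 - q25)
    return bias, bias - half, bias + half


def ks_normality_diagnostic(errors: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of the error distribution against a fitted
    normal; purely diagnostic (the bootstrap is used regardless)."""
    errors = np.asarray(errors, dtype=float)
    mu, sd = errors.mean(), errors.std(ddof=1)
    if sd == 0:
        return float("nan"), 0.0
    res = stats.kstest(errors, "norm", args=(mu, sd))
    return float(res.statistic), float(res.pvalue)


def per_bin_profile(
    alpha: np.ndarray,
    alpha_hat: np.ndarray,
    train_counts: np.ndarray | None = None,
    bin_width: float = 5.0,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean absolute error per 5-degree bin of the target angle.

    Returns one row per bin over [0, 180): bin bounds, record count, mean
    absolute error with bootstrap CI (NaN for empty bins), and an
    ``underrepresented`` flag where the training count is below 200.
    """
    alpha = np.asarray(alpha, dtype=float)
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    n_bins = int(180.0 // bin_width)
    bins = np.minimum((alpha // bin_width).astype(int), n_bins - 1)
    err = np.abs(alpha_hat - alpha)
    if train_counts is None:
        train_counts = np.zeros(n_bins, dtype=int)
    rows = []
    for b in range(n_bins):
        sel = bins == b
        n = int(sel.sum())
        if n:
            point, lo, hi = bootstrap_estimate(err[sel], "mean", B=B, seed=seed + b)
        else:
            point = lo = hi = float("nan")
        rows.append(
            {
                "bin_low": b * bin_width,
                "bin_high": (b + 1) * bin_width,
                "n": n,
                "mean_abs_err": point,
                "ci_low": lo,
                "ci_high": hi,
                "train_count": int(train_counts[b]),
                "underrepresented": bool(train_counts[b] < UNDERREPRESENTED_TRAIN_COUNT),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Full evaluation of one stratum of validation records."""

    stratum: str
    n: int
    rmse: float
    mean_abs_err: float
    mean_abs_err_ci: tuple[float, float]
    median_abs_err: float
    median_abs_err_ci: tuple[float, float]
    spearman_rho: float
    bland_altman_bias: float
    bland_altman_limits: tuple[float, float]
    ks_statistic: float
    ks_pvalue: float
    per_bin: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = {
            "stratum": self.stratum,
            "n": self.n,
            "rmse": self.rmse,
            "mean_abs_err": self.mean_abs_err,
            "mean_abs_err_ci": list(self.mean_abs_err_ci),
            "median_abs_err": self.median_abs_err,
            "median_abs_err_ci": list(self.median_abs_err_ci),
            "spearman_rho": self.spearman_rho,
            "bland_altman_bias": self.bland_altman_bias,
            "bland_altman_limits": list(self.bland_altman_limits),
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
        }
        return d


def evaluate(
    alpha: np.ndarray,
    alpha_hat: np.ndarray,
    morph_class: np.ndarray | None = None,
    train_counts: np.ndarray | None = None,
    B: int = 5000,
    seed: int = 0,
) -> dict[str, EvaluationReport]:
    """Evaluate estimates for the strata all / NORM / cardiac disease.

    ``morph_class`` enables the NORM vs. pooled-disease strata; without it
    only the "all" stratum is produced.  ``train_counts`` (length-36 array of
    per-bin training counts) drives the underrepresentation flags.
    """
    alpha = np.asarray(alpha, dtype=float)
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    strata: dict[str, np.ndarray] = {"all": np.ones(alpha.size, dtype=bool)}
    if morph_class is not None:
        morph_class = np.asarray(morph_class)
        strata["NORM"] = morph_class == "NORM"
        strata["cardiac_disease"] = np.isin(morph_class, DISEASE_CLASSES)

    reports = {}
    for name, sel in strata.items():
        if not sel.any():
            continue
        a, ah = alpha[sel], alpha_hat[sel]
        err = np.abs(ah - a)
        rmse, mean_err, med_err = error_metrics(a, ah)
        _, mean_lo, mean_hi = bootstrap_estimate(err, "mean", B=B, seed=seed)
        _, med_lo, med_hi = bootstrap_estimate(err, "median", B=B, seed=seed + 1)
        try:
            rho = spearman(a, ah)
        except ValueError:
            rho = float("nan")
        bias, lo, hi = bland_altman(a, ah)
        ks_stat, ks_p = ks_normality_diagnostic(err)
        reports[name] = EvaluationReport(
            stratum=name,
            n=int(sel.sum()),
            rmse=rmse,
            mean_abs_err=mean_err,
            mean_abs_err_ci=(mean_lo, mean_hi),
            median_abs_err=med_err,
            median_abs_err_ci=(med_lo, med_hi),
            spearman_rho=rho,
            bland_altman_bias=bias,
            bland_altman_limits=(lo, hi),
            ks_statistic=ks_stat,
            ks_pvalue=ks_p,
            per_bin=per_bin_profile(a, ah, train_counts, B=min(B, 1000), seed=seed + 2),
        )
    return reports


def plot_report(
    alpha: np.ndarray,
    alpha_hat: np.ndarray,
    report: EvaluationReport,
    save_path=None,
):
    """Diagnostic figure: estimate-vs-target scatter, Bland-Altman, per-bin errors.

    Returns the matplotlib figure; saves it when ``save_path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    alpha = np.asarray(alpha, dtype=float)
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))

    ax = axes[0]
    ax.scatter(alpha, alpha_hat, s=6, alpha=0.5)
    ax.plot([0, 180], [0, 180], "k--", lw=1)
    ax.set_xlabel("target angle (deg)")
    ax.set_ylabel("estimated angle (deg)")
    ax.set_title(f"{report.stratum}: rho={report.spearman_rho:.2f}")

    ax = axes[1]
    d = alpha_hat - alpha
    mean_pair = (alpha_hat + alpha) / 2.0
    ax.scatter(mean_pair, d, s=6, alpha=0.5)
    for y, style in ((report.bland_altman_bias, "k-"),
                     (report.bland_altman_limits[0], "k--"),
                     (report.bland_altman_limits[1], "k--")):
        ax.axhline(y, ls=style[1:], color="k", lw=1)
    ax.set_xlabel("mean of target and estimate (deg)")
    ax.set_ylabel("estimate - target (deg)")
    ax.set_title("Bland-Altman (limits = bias ± 1.45 iqr)")

    ax = axes[2]
    table = report.per_bin
    populated = table[table["n"] > 0]
    centers = (populated["bin_low"] + populated["bin_high"]) / 2.0
    yerr = np.vstack([
        populated["mean_abs_err"] - populated["ci_low"],
        populated["ci_high"] - populated["mean_abs_err"],
    ])
    ax.errorbar(centers, populated["mean_abs_err"], yerr=np.abs(yerr), fmt="o", ms=3)
    under = populated[populated["underrepresented"]]
    if len(under):
        ax.scatter((under["bin_low"] + under["bin_high"]) / 2.0,
                   under["mean_abs_err"], marker="x", color="r", zorder=3,
                   label="< 200 training records")
        ax.legend(fontsize=8)
    ax.set_xlabel("target angle bin (deg)")
    ax.set_ylabel("mean absolute error (deg)")
    ax.set_title("per-bin error")

    fig.tight_layout()
    if save_path is not None:
        fig.savefig(save_path, dpi=120)
    return fig
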