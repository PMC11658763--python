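"""Per-feature differential transcript-length testing.

Given a per-read length table and a two-condition library design, each
gene/transcript is tested for a shift in read length between
conditions under one of three models:

``lmm``
    Random-intercept linear mixed model ``Y = b0 + b_cond*cond + lib + e``
    with the library as the random effect, so replicate-level length
    shifts are absorbed and deep libraries cannot dominate. The Wald
    statistic ``b_cond / SE`` is referred by default to a t
    distribution with Satterthwaite degrees of freedom, which keeps
    the test calibrated with the handful of libraries typical of
    nanopore designs.
``ttest``
    Ordinary least squares of length on condition (+ optional
    covariates); equivalent to the pooled-variance two-sample t-test
    when no covariates are given. Ignores the library structure.
``wilcoxon``
    Two-sided Mann-Whitney rank-sum test; condition only, no
    covariates.

Estimates follow one sign convention throughout: negative = shorter in
the treated condition. With ``logscale`` lengths are log2-transformed
before fitting, so the estimate is directly a log2 fold-change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lmm import fit_random_intercept
from .tables import DesignTable, LengthTable

__all__ = [
    "TestConfig",
    "LengthTestResult",
    "InsufficientDataError",
    "fit_ttest",
    "fit_wilcoxon",
    "fit_lmm",
    "adjust_pvalues",
    "run_differential_length",
    "results_to_frame",
]

log = logging.getLogger(__name__)

MODELS = ("lmm", "ttest", "wilcoxon")


class InsufficientDataError(ValueError):
    """A condition has too few observations for the requested model."""


@dataclass
class TestConfig:
    """Configuration of one differential-length run."""

    model: str = "lmm"
    logscale: bool = False
    alpha: float = 0.05
    min_reads: int = 5
    covariates: tuple[str, ...] = ()
    adjust_method: str = "fdr_bh"  # or "bonferroni"
    reml: bool = True
    df_method: str = "satterthwaite"  # or "between_within" / "normal"
    wilcoxon_exact_threshold: int = 8

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.covariates = tuple(self.covariates)
        if self.model == "wilcoxon" and self.covariates:
            raise ValueError("the Wilcoxon model tests the condition only and cannot take covariates")


@dataclass
class LengthTestResult:
    """One feature's differential-length test result."""

    feature_id: str
    n_control: int
    n_condition: int
    estimate: float
    se: float
    statistic: float
    p_value: float
    adj_p_value: float = float("nan")
    status: str = "ok"
    variance_components: tuple[float, float] | None = None  # (sigma2_lib, sigma2_resid)


def _design_matrix(cond: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(cond, dtype=float), cond.astype(float)]
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(cond):
            cov = cov.T
        cols.extend(cov.T)
    return np.column_stack(cols)


def fit_ttest(
    lengths: np.ndarray,
    condition: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """OLS of length on intercept + condition (+ covariates).

    Returns ``(estimate, se, t, p)`` where the two-sided p-value uses
    the t distribution with residual degrees of freedom. Without
    covariates this is exactly the pooled-variance two-sample t-test.
    """
    y = np.asarray(lengths, dtype=float)
    cond = np.asarray(condition)
    for level in (0, 1):
        if np.sum(cond == level) < 2:
            raise InsufficientDataError(
                f"t-test requires >= 2 observations per condition (condition {level} has {np.sum(cond == level)})"
            )
    X = _design_matrix(cond, covariates)
    n, p = X.shape
    beta, rss_arr, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - rank
    if df <= 0 or rss <= 1e-12 * max(1.0, float(y @ y)):
        raise InsufficientDataError("zero residual variance: t statistic undefined")
    s2 = rss / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[1, 1]))
    est = float(beta[1])
    t = est / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return est, se, t, p


def fit_wilcoxon(
    lengths: np.ndarray,
    condition: np.ndarray,
    exact_threshold: int = 8,
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney rank-sum test of length by condition.

    Uses the exact null distribution when both groups are small
    (``min(n, m) <= exact_threshold``) and the data are tie-free;
    otherwise the normal approximation with tie and continuity
    correction. Returns ``(estimate, U, p)`` where the estimate is the
    treated-minus-control difference of group medians (descriptive
    only — the test itself is rank-based).
    """
    y = np.asarray(lengths, dtype=float)
    cond = np.asarray(condition)
    ctrl, trt = y[cond == 0], y[cond == 1]
    if len(ctrl) == 0 or len(trt) == 0:
        raise InsufficientDataError("Wilcoxon requires >= 1 observation per condition")
    has_ties = len(np.unique(y)) < len(y)
    if not has_ties and min(len(ctrl), len(trt)) <= exact_threshold:
        method = "exact"
    else:
        method = "asymptotic"
    if np.all(ctrl[0] == y):  # constant data: U is its null mean, p = 1
        return 0.0, len(ctrl) * len(trt) / 2.0, 1.0
    res = sps.mannwhitneyu(trt, ctrl, alternative="two-sided", method=method)
    estimate = float(np.median(trt) - np.median(ctrl))
    return estimate, float(res.statistic), float(min(res.pvalue, 1.0))


def fit_lmm(
    lengths: np.ndarray,
    condition: np.ndarray,
    library_ids: np.ndarray,
    covariates: np.ndarray | None = None,
    reml: bool = True,
    df_method: str = "satterthwaite",
) -> tuple[float, float, float, float, tuple[float, float], str]:
    """Random-intercept LMM of length on condition with library as the group.

    Returns ``(estimate, se, statistic, p, (sigma2_lib, sigma2_resid),
    status)``. ``status`` is ``"ok"``, ``"boundary"`` when the library
    variance was estimated at zero (the fit then coincides with OLS),
    or ``"fallback_ols"`` when the mixed fit failed outright and a
    fixed-effects refit was used.

    The Wald statistic is referred to a t distribution whose degrees of
    freedom are, by default, the Satterthwaite approximation for the
    condition coefficient — with a handful of libraries the library
    variance carries few df and a normal reference is badly
    anticonservative. ``df_method="between_within"`` uses the simpler
    ``n_libraries - n_fixed_params``; ``df_method="normal"`` the
    standard normal.
    """
    y = np.asarray(lengths, dtype=float)
    cond = np.asarray(condition)
    libs = np.asarray(library_ids)
    X = _design_matrix(cond, covariates)
    n_libs = len(np.unique(libs))
    if n_libs < 2:
        raise InsufficientDataError("LMM requires >= 2 libraries")
    per_cond_libs = [len(np.unique(libs[cond == lv])) for lv in (0, 1)]
    if min(per_cond_libs) < 2:
        warnings.warn(
            "only one library in a condition: condition and library are confounded",
            UserWarning,
            stacklevel=2,
        )
    status = "ok"
    df = float("nan")
    try:
        fit = fit_random_intercept(y, X, libs, reml=reml, compute_df=df_method == "satterthwaite")
        est, se = float(fit.beta[1]), float(fit.se[1])
        vc = (float(fit.tau2), float(fit.sigma2))
        if fit.boundary:
            status = "boundary"
        if fit.df_satterthwaite is not None:
            df = float(fit.df_satterthwaite[1])
    except (ValueError, np.linalg.LinAlgError):
        est, se, _, _ = fit_ttest(y, cond, covariates)
        vc = (0.0, float("nan"))
        status = "fallback_ols"
        df = float(len(y) - X.shape[1])
    stat = est / se
    if df_method == "between_within":
        df = float(max(n_libs - X.shape[1], 1))
    if df_method == "normal" or not np.isfinite(df):
        p = float(2.0 * sps.norm.sf(abs(stat)))
    else:
        p = float(2.0 * sps.t.sf(abs(stat), df))
    return est, se, stat, p, vc, status


def adjust_pvalues(p: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment across features.

    ``fdr_bh`` (default) applies the Benjamini-Hochberg step-up
    procedure; ``bonferroni`` multiplies by the number of tests. Output
    is clipped to [0, 1] and is never smaller than the input p-value.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "fdr_bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_differential_length(
    table: LengthTable,
    design: DesignTable,
    config: TestConfig | None = None,
) -> list[LengthTestResult]:
    """Test every feature in the table for differential read length.

    Lengths are log2-transformed first when ``config.logscale``. The
    multiple-testing adjustment is computed across all features whose
    fit produced a p-value; features whose fit failed carry a flagged
    status and NaN statistics rather than being dropped. Results are
    sorted by p-value.
    """
    config = config or TestConfig()
    if len(table) == 0:
        warnings.warn("no features to test after filtering", UserWarning, stacklevel=2)
        return []

    lib_to_cond = dict(zip(design.df["library_id"], design.condition_indicator()))
    missing = set(table.df["library_id"]) - set(lib_to_cond)
    if missing:
        raise ValueError(f"library {sorted(missing)[0]!r} missing from design table")
    cov_names = [c for c in config.covariates if c]
    for c in cov_names:
        if c not in design.df.columns:
            raise ValueError(f"covariate {c!r} not in design table")
    lib_cov = design.df.set_index("library_id")[cov_names] if cov_names else None

    results: list[LengthTestResult] = []
    for fid, sub in table.df.groupby("feature_id", sort=False):
        y = sub["length"].to_numpy(dtype=float)
        if config.logscale:
            y = np.log2(y)
        cond = sub["library_id"].map(lib_to_cond).to_numpy()
        n_ctrl = int(np.sum(cond == 0))
        n_trt = int(np.sum(cond == 1))
        cov = lib_cov.loc[sub["library_id"]].to_numpy(dtype=float) if cov_names else None
        est = se = stat = p = float("nan")
        vc = None
        status = "ok"
        try:
            if config.model == "ttest":
                est, se, stat, p = fit_ttest(y, cond, cov)
            elif config.model == "wilcoxon":
                est, stat, p = fit_wilcoxon(y, cond, config.wilcoxon_exact_threshold)
                se = float("nan")
            else:
                libs = sub["library_id"].to_numpy()
                est, se, stat, p, vc, status = fit_lmm(
                    y, cond, libs, cov, reml=config.reml, df_method=config.df_method
                )
        except (InsufficientDataError, ValueError) as exc:
            status = f"failed: {exc}"
        results.append(
            LengthTestResult(
                feature_id=str(fid),
                n_control=n_ctrl,
                n_condition=n_trt,
                estimate=est,
                se=se,
                statistic=stat,
                p_value=p,
                status=status,
                variance_components=vc,
            )
        )

    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        adj = adjust_pvalues([r.p_value for r in tested], config.adjust_method)
        for r, a in zip(tested, adj):
            r.adj_p_value = float(a)
    results.sort(key=lambda r: (not np.isfinite(r.p_value), r.p_value))
    return results


def results_to_frame(results: Sequence[LengthTestResult]) -> pd.DataFrame:
    """Tidy results table (one row per feature, sorted as given)."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "n_control": [r.n_control for r in results],
            "n_condition": [r.n_condition for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p_value": [r.adj_p_value for r in results],
            "status": [r.status for r in results],
        }
    )
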