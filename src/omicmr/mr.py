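"""Two-sample Mendelian randomization estimators and sensitivity cascade.

Estimation uses the Wald ratio for a single instrument and inverse-variance
weighting (IVW, weighted regression through the origin with outcome-variance
weights) for two or more.  Heterogeneity across instruments is measured by
Cochran's Q; when Q is significant a multiplicative random-effects IVW
(standard-error inflation by sqrt(Q/df), floored at 1) replaces the fixed
model.  The sensitivity cascade comprises Steiger directionality filtering,
MR-PRESSO outlier detection by parametric bootstrap, and MR-Egger regression,
whose intercept tests for directional horizontal pleiotropy; exposures with a
significant Egger intercept are excluded from results.  Benjamini-Hochberg
FDR control is applied across the exposures of one omic layer and outcome.

Outcome effects are log-odds for case-control traits, so exp(theta) is an
odds ratio per unit exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("omicmr.mr")


class MRInputError(ValueError):
    """Raised when an estimator's instrument-count precondition is violated."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds (theta) and odds-ratio scales."""

    method: str            # wald | ivw_fixed | ivw_random | egger_slope
    theta: float
    se: float
    pvalue: float
    k: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.theta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.theta - 1.959963984540054 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.theta + 1.959963984540054 * self.se))


@dataclass(frozen=True)
class HeterogeneityReport:
    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class EggerReport:
    intercept: float
    intercept_se: float
    intercept_p: float
    slope: float
    slope_se: float


@dataclass(frozen=True)
class PressoReport:
    global_rss_obs: float
    global_p: float
    outlier_p: dict[str, float]
    removed_ids: list[str]
    n_sim: int
    seed: int


@dataclass
class SteigerReport:
    """Per-SNP directionality assessment; ``removed_ids`` failed the direction test."""

    table: pd.DataFrame  # snp_id, r2_exposure, r2_outcome, direction_ok, steiger_p
    removed_ids: list[str]
    skipped_ids: list[str]


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-instrument Wald ratio, first-order delta-method standard error."""
    if beta_x == 0:
        raise MRInputError("undefined_wald: exposure effect is zero")
    theta = beta_y / beta_x
    se = se_y / abs(beta_x)
    return MREstimate("wald", float(theta), float(se), _two_sided_p(theta / se), 1)


def _ivw_fixed_core(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    s_xy = float(np.sum(w * bx * by))
    s_xx = float(np.sum(w * bx * bx))
    return s_xy / s_xx, s_xx ** -0.5


def ivw(instr: pd.DataFrame, effects_model: str = "auto",
        het_alpha: float = 0.05) -> MREstimate:
    """Inverse-variance-weighted estimate over k >= 2 instruments.

    ``fixed``: weighted regression of beta_out on beta_exp through the origin,
    weights 1/se_out².  ``random``: same point estimate with the SE inflated
    by sqrt(max(1, Q/(k-1))).  ``auto``: fixed when the Q test p >= het_alpha,
    random otherwise.
    """
    k = len(instr)
    if k < 2:
        raise MRInputError("use_wald: IVW needs at least two instruments")
    bx = instr["beta_exp"].to_numpy(float)
    by = instr["beta_out"].to_numpy(float)
    w = instr["se_out"].to_numpy(float) ** -2.0
    theta, se = _ivw_fixed_core(bx, by, w)
    het = cochran_q(instr, theta)
    if effects_model == "auto":
        effects_model = "fixed" if het.pvalue >= het_alpha else "random"
    if effects_model == "random":
        se *= max(1.0, het.q / het.df) ** 0.5
        method = "ivw_random"
    elif effects_model == "fixed":
        method = "ivw_fixed"
    else:
        raise ValueError(f"unknown effects_model {effects_model!r}")
    return MREstimate(method, float(theta), float(se), _two_sided_p(theta / se), k)


def cochran_q(instr: pd.DataFrame, theta: float) -> HeterogeneityReport:
    """Cochran's Q of per-instrument outcome residuals around theta·beta_exp."""
    k = len(instr)
    if k < 2:
        raise MRInputError("cochran_q needs at least two instruments")
    bx = instr["beta_exp"].to_numpy(float)
    by = instr["beta_out"].to_numpy(float)
    w = instr["se_out"].to_numpy(float) ** -2.0
    q = float(np.sum(w * (by - theta * bx) ** 2))
    df = k - 1
    return HeterogeneityReport(q, df, float(stats.chi2.sf(q, df)))


def egger(instr: pd.DataFrame) -> EggerReport:
    """MR-Egger weighted regression with intercept (directional-pleiotropy test).

    Instruments are oriented so every exposure effect is non-negative (both
    betas flipped together), then beta_out is regressed on beta_exp with
    weights 1/se_out².  Standard errors use the weighted-LS covariance with
    the residual standard deviation floored at 1 (multiplicative
    random-effects convention); p-values use a t reference with k-2 df.
    """
    k = len(instr)
    if k < 3:
        raise MRInputError("egger_skipped: MR-Egger needs at least three instruments")
    bx = instr["beta_exp"].to_numpy(float).copy()
    by = instr["beta_out"].to_numpy(float).copy()
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    w = instr["se_out"].to_numpy(float) ** -2.0
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    s2 = float(np.sum(w * resid ** 2) / (k - 2))
    cov = max(s2, 1.0) * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_int = coef[0] / se[0] if se[0] > 0 else (0.0 if coef[0] == 0 else np.inf)
    p_int = float(2.0 * stats.t.sf(abs(t_int), k - 2)) if np.isfinite(t_int) else 0.0
    if t_int == 0.0:
        p_int = 1.0
    return EggerReport(float(coef[0]), float(se[0]), p_int, float(coef[1]), float(se[1]))


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW estimates, one per instrument."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(instr: pd.DataFrame, n_sim: int = 1000, seed: int = 0,
              outlier_p_threshold: float = 0.05) -> PressoReport:
    """Pleiotropy-outlier detection by parametric-bootstrap residual comparison.

    The observed global statistic is the weighted residual sum of squares
    RSS = Σ_j w_j (beta_out_j − θ₋ⱼ·beta_exp_j)² with θ₋ⱼ the leave-one-out
    IVW estimate.  The null distribution is simulated by redrawing
    beta_exp* ~ N(beta_exp, se_exp²) and beta_out* ~ N(θ₋ⱼ·beta_exp_j, se_out²)
    and recomputing RSS (including its leave-one-out estimates) on each
    replicate.  ``global_p`` is the fraction of simulated RSS at or above the
    observed one; per-SNP outlier p-values compare each SNP's observed RSS
    contribution with its simulated distribution.  Per-SNP outliers (p below
    the threshold) are reported as removed only when the global test itself
    is significant.
    """
    k = len(instr)
    if k < 4:
        raise MRInputError("presso_skipped: MR-PRESSO needs at least four instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    ids = instr["snp_id"].astype(str).to_list()
    bx = instr["beta_exp"].to_numpy(float)
    by = instr["beta_out"].to_numpy(float)
    sx = instr["se_exp"].to_numpy(float)
    sy = instr["se_out"].to_numpy(float)
    w = sy ** -2.0

    t_loo = _loo_thetas(bx, by, w)
    rss_j = w * (by - t_loo * bx) ** 2
    rss_obs = float(np.sum(rss_j))

    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(t_loo * bx, sy, size=(n_sim, k))
    s_xy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_sim * bx_sim, axis=1, keepdims=True)
    t_loo_sim = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim * bx_sim)
    rss_j_sim = w * (by_sim - t_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(rss_j_sim, axis=1)

    global_p = float(np.mean(rss_sim >= rss_obs))
    outlier_p = {ids[j]: float(np.mean(rss_j_sim[:, j] >= rss_j[j])) for j in range(k)}
    removed = [s for s, p in outlier_p.items() if p < outlier_p_threshold] \
        if global_p < outlier_p_threshold else []
    return PressoReport(rss_obs, global_p, outlier_p, removed, n_sim, seed)


# ---------------------------------------------------------------------------
# Steiger directionality
# ---------------------------------------------------------------------------

def _r_from_beta(beta: np.ndarray, eaf: np.ndarray,
                 case_fraction: float | None) -> np.ndarray:
    """Per-SNP trait correlation implied by a marginal effect.

    For a standardized quantitative trait r = beta·sqrt(2·eaf·(1−eaf)); for a
    case-control trait the log-odds beta is first mapped to an observed-scale
    (0/1) slope via the case-fraction variance v(1−v), giving
    r = beta·sqrt(v·(1−v)·2·eaf·(1−eaf)).
    """
    var_g = 2.0 * eaf * (1.0 - eaf)
    if case_fraction is None:
        r = beta * np.sqrt(var_g)
    else:
        v = case_fraction
        r = beta * np.sqrt(v * (1.0 - v) * var_g)
    return np.clip(np.abs(r), 0.0, 1.0 - 1e-12)


def steiger_filter(instr: pd.DataFrame, n_exp: float, n_out: float,
                   case_fraction: float | None = None,
                   alpha: float = 0.05) -> tuple[SteigerReport, pd.DataFrame]:
    """Remove instruments whose variance explained points from outcome to exposure.

    Per SNP the variance explained in the exposure (quantitative, SD units)
    and in the outcome (case-control on the observed scale when
    ``case_fraction`` is given) are compared with a Fisher-z two-correlation
    test on independent samples of sizes ``n_exp`` and ``n_out``.  SNPs with
    r²_outcome > r²_exposure and Steiger p < alpha are removed; SNPs without
    an exposure EAF are exempted (``steiger_skipped``).
    """
    rows, removed, skipped = [], [], []
    for rec in instr.itertuples():
        eaf = rec.eaf_exp
        if pd.isna(eaf) or eaf <= 0 or eaf >= 1:
            skipped.append(str(rec.snp_id))
            rows.append({"snp_id": rec.snp_id, "r2_exposure": np.nan,
                         "r2_outcome": np.nan, "direction_ok": True,
                         "steiger_p": np.nan})
            continue
        eaf_out = rec.eaf_out if pd.notna(rec.eaf_out) else eaf
        r_x = _r_from_beta(np.array(rec.beta_exp), np.array(eaf), None)
        r_y = _r_from_beta(np.array(rec.beta_out), np.array(eaf_out), case_fraction)
        z = (np.arctanh(r_x) - np.arctanh(r_y)) / \
            np.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0))
        p = _two_sided_p(float(z))
        ok = bool(r_y ** 2 <= r_x ** 2)
        rows.append({"snp_id": rec.snp_id, "r2_exposure": float(r_x ** 2),
                     "r2_outcome": float(r_y ** 2), "direction_ok": ok,
                     "steiger_p": p})
        if not ok and p < alpha:
            removed.append(str(rec.snp_id))
    report = SteigerReport(pd.DataFrame(rows), removed, skipped)
    kept = instr[~instr["snp_id"].astype(str).isin(removed)].reset_index(drop=True)
    return report, kept


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-exposure cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Sample sizes, trait scale and sensitivity-cascade settings for one analysis."""

    n_exposure: float
    n_outcome: float
    case_fraction: float | None = None   # None => quantitative outcome
    presso_n_sim: int = 1000
    presso_seed: int = 0
    het_alpha: float = 0.05
    egger_alpha: float = 0.05
    steiger_alpha: float = 0.05
    outlier_p: float = 0.05


@dataclass
class ExposureAnalysis:
    """Bundle of the estimate and sensitivity reports for one exposure/outcome pair."""

    estimate: MREstimate | None
    heterogeneity: HeterogeneityReport | None
    egger: EggerReport | None
    presso: PressoReport | None
    steiger: SteigerReport | None
    qc_verdict: str                      # pass | excluded_pleiotropy | no_instruments
    n_removed_steiger: int = 0
    n_removed_presso: int = 0
    notes: list[str] = field(default_factory=list)


def analyze_exposure(instr: pd.DataFrame, config: AnalysisConfig) -> ExposureAnalysis:
    """Run the full estimation and sensitivity cascade for one exposure.

    Order: Steiger filter → MR-PRESSO outlier removal (k ≥ 4) → Cochran's Q →
    fixed/random model choice → IVW (or Wald at k = 1) → MR-Egger intercept
    verdict.  An exposure with a significant Egger intercept gets
    ``qc_verdict = "excluded_pleiotropy"``; one with no surviving instruments
    is skipped with a notice.
    """
    notes: list[str] = []
    if len(instr) == 0:
        logger.info("no instruments; exposure skipped")
        return ExposureAnalysis(None, None, None, None, None,
                                "no_instruments", notes=["empty instrument set"])

    steiger, instr = steiger_filter(instr, config.n_exposure, config.n_outcome,
                                    config.case_fraction, config.steiger_alpha)
    n_steiger = len(steiger.removed_ids)
    if len(instr) == 0:
        return ExposureAnalysis(None, None, None, None, steiger, "no_instruments",
                                n_removed_steiger=n_steiger,
                                notes=["all instruments removed by Steiger filter"])

    presso = None
    n_presso = 0
    if len(instr) >= 4:
        presso = mr_presso(instr, config.presso_n_sim, config.presso_seed,
                           config.outlier_p)
        if presso.removed_ids:
            instr = instr[~instr["snp_id"].astype(str).isin(presso.removed_ids)]
            instr = instr.reset_index(drop=True)
            n_presso = len(presso.removed_ids)
    else:
        notes.append("presso_skipped")

    het = None
    if len(instr) == 1:
        r = instr.iloc[0]
        est = wald_ratio(r["beta_exp"], r["se_exp"], r["beta_out"], r["se_out"])
    else:
        est = ivw(instr, "auto", config.het_alpha)
        theta_fixed, _ = _ivw_fixed_core(instr["beta_exp"].to_numpy(float),
                                         instr["beta_out"].to_numpy(float),
                                         instr["se_out"].to_numpy(float) ** -2.0)
        het = cochran_q(instr, theta_fixed)

    egger_rep = None
    verdict = "pass"
    if len(instr) >= 3:
        egger_rep = egger(instr)
        if egger_rep.intercept_p < config.egger_alpha:
            verdict = "excluded_pleiotropy"
    else:
        notes.append("egger_skipped")

    return ExposureAnalysis(est, het, egger_rep, presso, steiger, verdict,
                            n_removed_steiger=n_steiger,
                            n_removed_presso=n_presso, notes=notes)
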