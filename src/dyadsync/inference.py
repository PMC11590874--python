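"""Dyad-level statistical inference.

Three estimators link the dyad-level measures (cooperativeness X,
smiling-with-gaze M1, inter-brain synchrony M2, cooperative behavior Y):

* simple OLS regression with the classical t-test on the slope;
* linear mediation estimated by nested OLS — ``a`` from ``m ~ x``,
  ``b`` and the direct effect ``c'`` from ``y ~ x + m``, the total
  effect ``c`` from ``y ~ x`` — with the indirect effect (ACME)
  ``a * b``, the direct effect (ADE) ``c'``, and case-resampling
  bootstrap confidence intervals (bias-corrected by default);
* recursive path analysis: equation-wise coefficients are the maximum
  likelihood estimates for a recursive model, the model-implied
  covariance is compared to the sample covariance through the normal
  ML discrepancy ``F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p``, and
  global fit is summarized by T = (N-1) F against chi-square, CFI
  (against the independence baseline) and SRMR.

For the linear estimators the decomposition total = ADE + ACME is an
algebraic identity of the nested OLS fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MediationResult",
    "PathFit",
    "ols_regress",
    "mediate_bootstrap",
    "fit_path_model",
    "DEFAULT_PATHS",
]

#: Hypothesized structural model: cooperativeness drives both candidate
#: mediators and behavior directly; both mediators may drive behavior.
DEFAULT_PATHS: "tuple[tuple[str, str], ...]" = (
    ("smile_gaze", "cooperativeness"),
    ("ibs", "cooperativeness"),
    ("coop_behavior", "cooperativeness"),
    ("coop_behavior", "smile_gaze"),
    ("coop_behavior", "ibs"),
)


def ols_regress(y: np.ndarray, x: np.ndarray) -> dict:
    """Simple linear regression of y on x with the classical slope test.

    Returns a dict with ``slope``, ``intercept``, ``t``, ``df`` (n - 2),
    ``p`` (two-sided) and ``r_squared``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be equal-length vectors")
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    df = n - 2
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "t": float(t),
        "df": df,
        "p": float(res.pvalue),
        "r_squared": float(res.rvalue**2),
    }


def _mediation_effects(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(total, direct, indirect, proportion) from the three nested OLS fits.

    Computed in covariance algebra (equivalent to OLS with intercepts).
    When m is exactly collinear with x the two-predictor fit is not
    identified; the vanishing-noise limit attributes the effect through
    the mediator, which keeps total = direct + indirect.
    """
    xc, mc, yc = x - x.mean(), m - m.mean(), y - y.mean()
    n = len(x)
    v_x, v_m = xc @ xc / n, mc @ mc / n
    c_xm, c_xy, c_my = xc @ mc / n, xc @ yc / n, mc @ yc / n
    a = c_xm / v_x
    c = c_xy / v_x
    det = v_x * v_m - c_xm**2
    if det > 1e-12 * v_x * v_m:
        c_prime = (v_m * c_xy - c_xm * c_my) / det
        b = (v_x * c_my - c_xm * c_xy) / det
    else:  # mediator collinear with treatment
        b = c_my / v_m
        c_prime = c - a * b
    acme = a * b
    prop = acme / c if c != 0 else np.nan
    return np.array([c, c_prime, acme, prop])


_EFFECT_NAMES = ("total", "direct", "indirect", "proportion_mediated")


@dataclass(frozen=True)
class MediationResult:
    """Mediation effects with bootstrap confidence intervals.

    ``effects`` maps each of total / direct (ADE) / indirect (ACME) /
    proportion_mediated to ``(estimate, ci_low, ci_high, p)``.
    """

    effects: "dict[str, tuple[float, float, float, float]]"
    n_boot: int
    seed: int
    ci_method: str
    n_redrawn: int = 0

    @property
    def total_effect(self) -> float:
        return self.effects["total"][0]

    @property
    def direct_effect(self) -> float:
        return self.effects["direct"][0]

    @property
    def indirect_effect(self) -> float:
        return self.effects["indirect"][0]

    @property
    def proportion_mediated(self) -> float:
        return self.effects["proportion_mediated"][0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(effect=name, estimate=est, ci_low=lo, ci_high=hi, p=p)
            for name, (est, lo, hi, p) in self.effects.items()
        ]
        return pd.DataFrame(rows)


def mediate_bootstrap(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci: str = "bias_corrected",
    conf_level: float = 0.95,
) -> MediationResult:
    """Linear mediation with case-resampling bootstrap intervals.

    Point estimates come from the full-sample nested OLS fits; each
    bootstrap replicate resamples dyads with replacement and
    re-estimates all four effects.  ``ci`` is ``bias_corrected``
    (default; the BC interval, acceleration not applied) or
    ``percentile``.  Two-sided bootstrap p-values are
    ``2 * min(P(boot <= 0), P(boot >= 0))``.  Degenerate resamples (a
    constant x or m) are redrawn and counted.
    """
    x, m, y = (np.asarray(v, dtype=float) for v in (x, m, y))
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("x, m, y must be equal-length vectors")
    if np.isnan(x).any() or np.isnan(m).any() or np.isnan(y).any():
        raise ValueError("mediation requires complete data (drop missing dyads first)")
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 complete dyads, got {n}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be unstable")
    if ci not in ("bias_corrected", "percentile"):
        raise ValueError(f"unknown ci method {ci!r}")
    point = _mediation_effects(x, m, y)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 4))
    n_redrawn = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.ptp(x[idx]) > 0 and np.ptp(m[idx]) > 0:
                break
            n_redrawn += 1
        boots[i] = _mediation_effects(x[idx], m[idx], y[idx])
    alpha = 1.0 - conf_level
    effects: dict = {}
    for k, name in enumerate(_EFFECT_NAMES):
        draws = boots[:, k]
        draws = draws[np.isfinite(draws)]
        if ci == "bias_corrected":
            prop_below = np.clip(np.mean(draws < point[k]), 1e-9, 1 - 1e-9)
            z0 = stats.norm.ppf(prop_below)
            z_lo, z_hi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
            lo_q = stats.norm.cdf(2 * z0 + z_lo)
            hi_q = stats.norm.cdf(2 * z0 + z_hi)
        else:
            lo_q, hi_q = alpha / 2, 1 - alpha / 2
        lo, hi = np.quantile(draws, [lo_q, hi_q])
        pval = min(1.0, 2.0 * min(np.mean(draws <= 0), np.mean(draws >= 0)))
        effects[name] = (float(point[k]), float(lo), float(hi), float(pval))
    return MediationResult(
        effects=effects, n_boot=n_boot, seed=seed, ci_method=ci, n_redrawn=n_redrawn
    )


@dataclass(frozen=True)
class PathFit:
    """Recursive path-model estimates and global fit.

    ``paths`` has one row per directed path: outcome, predictor,
    unstandardized estimate, SE, z, p, standardized beta.
    ``r_squared`` is the squared multiple correlation of each
    endogenous variable's equation.
    """

    paths: pd.DataFrame
    r_squared: "dict[str, float]"
    chi2: float
    df: int
    p_fit: float
    cfi: float
    srmr: float
    n: int

    def good_fit(self, srmr_max: float = 0.08, cfi_min: float = 0.95, alpha: float = 0.05) -> bool:
        """Conventional joint criterion: nonsignificant chi-square, SRMR <= 0.08, CFI >= 0.95."""
        chi_ok = True if self.df == 0 else self.p_fit > alpha
        return chi_ok and self.srmr <= srmr_max and self.cfi >= cfi_min


def _assert_recursive(paths: "list[tuple[str, str]]") -> "list[str]":
    """Topological order of variables; raises on a cyclic path diagram."""
    nodes = sorted({v for p in paths for v in p})
    succ = {v: set() for v in nodes}
    indeg = {v: 0 for v in nodes}
    for outcome, predictor in paths:
        if outcome not in succ[predictor]:
            succ[predictor].add(outcome)
            indeg[outcome] += 1
    order, ready = [], sorted(v for v in nodes if indeg[v] == 0)
    while ready:
        v = ready.pop(0)
        order.append(v)
        for w in sorted(succ[v]):
            indeg[w] -= 1
            if indeg[w] == 0:
                ready.append(w)
    if len(order) != len(nodes):
        cyclic = sorted(v for v in nodes if v not in order)
        raise ValueError(f"path specification is cyclic through {cyclic}")
    return order


def _fml(S: np.ndarray, sigma: np.ndarray) -> float:
    p = len(S)
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("implied covariance not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)


def fit_path_model(
    data: pd.DataFrame,
    paths: "tuple[tuple[str, str], ...]" = DEFAULT_PATHS,
) -> PathFit:
    """Fit a recursive path model by covariance-algebra ML.

    ``data`` holds one row per dyad with a column per model variable;
    rows with missing values on any model variable are dropped
    (complete-case analysis).  ``paths`` lists directed
    ``(outcome, predictor)`` edges; residuals are independent across
    equations and exogenous variables covary freely.

    For recursive models with independent residuals the ML estimates
    coincide with equation-wise OLS, computed here directly from the
    sample covariance.  Fit: T = (N-1) F_ML referred to chi-square with
    df = #unique moments - #free parameters; CFI against the
    independence (diagonal-covariance) baseline; SRMR as the root mean
    square of correlation-metric residual moments.  Standard errors use
    the expected information (OLS formula with ML residual variance);
    standardized betas rescale by the variables' standard deviations.
    """
    variables = _assert_recursive(list(paths))
    missing_cols = [v for v in variables if v not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks model variables {missing_cols}")
    frame = data[variables].dropna()
    n = len(frame)
    if n <= len(variables) + 1:
        raise ValueError(f"too few complete cases ({n}) for {len(variables)} variables")
    X = frame.to_numpy(dtype=float)
    S = np.cov(X, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(S)
    if eigvals[0] <= 1e-12:
        raise ValueError(
            f"sample covariance is not positive definite (min eigenvalue {eigvals[0]:.3g})"
        )
    p = len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    sd = np.sqrt(np.diag(S))

    outcomes = sorted({o for o, _ in paths})
    exogenous = [v for v in variables if v not in outcomes]

    B = np.zeros((p, p))
    psi = np.zeros((p, p))
    for e in exogenous:  # free exogenous (co)variances
        for f in exogenous:
            psi[idx[e], idx[f]] = S[idx[e], idx[f]]
    rows = []
    r_squared: dict = {}
    for outcome in outcomes:
        preds = [pr for o, pr in paths if o == outcome]
        pi = [idx[v] for v in preds]
        oi = idx[outcome]
        Spp = S[np.ix_(pi, pi)]
        spy = S[pi, oi]
        b = np.linalg.solve(Spp, spy)
        resid_var = float(S[oi, oi] - b @ spy)
        B[oi, pi] = b
        psi[oi, oi] = resid_var
        r_squared[outcome] = 1.0 - resid_var / S[oi, oi]
        # expected-information SEs: ML residual variance over n
        cov_b = (resid_var * (n - 1) / n) * np.linalg.inv(Spp * (n - 1) / n) / n
        se = np.sqrt(np.diag(cov_b))
        for j, pred in enumerate(preds):
            z = b[j] / se[j] if se[j] > 0 else np.inf
            rows.append(
                dict(
                    outcome=outcome,
                    predictor=pred,
                    estimate=float(b[j]),
                    se=float(se[j]),
                    z=float(z),
                    p=float(2 * stats.norm.sf(abs(z))),
                    beta_std=float(b[j] * sd[idx[pred]] / sd[oi]),
                )
            )

    IB = np.linalg.inv(np.eye(p) - B)
    sigma = IB @ psi @ IB.T
    n_moments = p * (p + 1) // 2
    n_exog = len(exogenous)
    n_free = len(paths) + len(outcomes) + n_exog * (n_exog + 1) // 2
    df = n_moments - n_free
    T = (n - 1) * _fml(S, sigma)
    p_fit = 1.0 if df == 0 else float(stats.chi2.sf(T, df))

    sigma_b = np.diag(np.diag(S))
    T_b = (n - 1) * _fml(S, sigma_b)
    df_b = n_moments - p
    denom = max(T - df, T_b - df_b, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(T - df, 0.0) / denom

    std_resid = (S - sigma) / np.outer(sd, sd)
    tri = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(std_resid[tri] ** 2)))

    return PathFit(
        paths=pd.DataFrame(rows),
        r_squared=r_squared,
        chi2=float(T),
        df=int(df),
        p_fit=p_fit,
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        srmr=srmr,
        n=n,
    )
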