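"""Exponential decay fitting for normalized pulse-chase trajectories.

One-phase model:  y(t) = plateau + (y0 - plateau) * exp(-k t)
Two-phase model:  y(t) = plateau + (y0 - plateau) *
                         [f_fast exp(-k_fast t) + (1 - f_fast) exp(-k_slow t)]

with t in days since the pulse and y the control-normalized GFP/RFP ratio.
Fits are unweighted least squares with every replicate as an individual
point; the plateau is normally constrained to the measured autofluorescence
background on the normalized scale. Parameter 95% intervals are asymptotic
Wald intervals with t critical values (df = n - p); half-life intervals are
obtained by transforming the rate interval. A rate below ``INF_RATE_TOL``
is reported as an essentially infinite half-life (unresolvable within a
chase of a few days).

Also provided: the extra sum-of-squares F test for the nested one- vs
two-phase comparison, and ROUT outlier elimination (robust Lorentzian-loss
regression, robust SD of residuals from the 68.27th percentile, and a
false-discovery-rate step at rate Q) followed by an ordinary fit on the
inliers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "DecayFit",
    "HalfLife",
    "fit_one_phase",
    "fit_two_phase",
    "extra_ss_f_test",
    "rout_outliers",
    "profile_ci_rate",
    "INF_RATE_TOL",
]

#: Rates below this (per day) are reported as "essentially infinite" half-life.
INF_RATE_TOL = 1e-3

_RATE_MAX = 50.0


@dataclass
class HalfLife:
    """A half-life (days) with its 95% confidence interval."""

    value: float
    ci95: tuple[float, float]

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.value)


@dataclass
class DecayFit:
    """A fitted decay model with uncertainty and goodness-of-fit."""

    model: str  # "one_phase" | "two_phase"
    params: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    plateau_constrained: bool
    plateau_value: float
    half_lives: dict[str, HalfLife]
    ss_residual: float
    df: int
    n_points: int
    r_squared: float
    t: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    outlier_mask: np.ndarray | None = field(default=None, repr=False)
    q_used: float | None = None
    degenerate: str | None = None

    @property
    def n_free_params(self) -> int:
        return self.n_points - self.df

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        b = self.plateau_value
        p = self.params
        if self.model == "one_phase":
            return b + (p["y0"] - b) * np.exp(-p["k"] * t)
        return b + (p["y0"] - b) * (
            p["f_fast"] * np.exp(-p["k_fast"] * t)
            + (1.0 - p["f_fast"]) * np.exp(-p["k_slow"] * t)
        )

    def report(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "model": self.model,
            "params": self.params,
            "se": self.se,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "plateau_constrained": self.plateau_constrained,
            "plateau_value": self.plateau_value,
            "half_lives": {
                k: {"value": h.value, "ci95": list(h.ci95)}
                for k, h in self.half_lives.items()
            },
            "ss_residual": self.ss_residual,
            "df": self.df,
            "n_points": self.n_points,
            "r_squared": self.r_squared,
            "q_used": self.q_used,
            "n_outliers": int(self.outlier_mask.size - self.outlier_mask.sum())
            if self.outlier_mask is not None
            else 0,
            "degenerate": self.degenerate,
        }


def _half_life_from_rate(k: float, ci: tuple[float, float]) -> HalfLife:
    """Transform a rate and its CI to a half-life; sub-tolerance rates -> inf."""
    ln2 = math.log(2.0)
    value = math.inf if k < INF_RATE_TOL else ln2 / k
    k_lo, k_hi = ci
    hl_lo = ln2 / k_hi if k_hi >= INF_RATE_TOL else math.inf
    hl_hi = ln2 / k_lo if k_lo >= INF_RATE_TOL else math.inf
    return HalfLife(value=value, ci95=(hl_lo, hl_hi))


def _wald(res, names, n, y, plateau, plateau_constrained, t, model):
    """Assemble a DecayFit from a converged least_squares result."""
    p = len(res.x)
    dof = n - p
    ss = float(2.0 * res.cost)
    # covariance from the Jacobian at the solution; guard rank deficiency
    J = res.jac
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cov = np.linalg.inv(J.T @ J) * (ss / dof if dof > 0 else np.nan)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tcrit = sps.t.ppf(0.975, dof) if dof > 0 else np.nan
    params = dict(zip(names, (float(v) for v in res.x)))
    se_d = dict(zip(names, (float(v) for v in se)))
    ci = {
        k: (params[k] - tcrit * se_d[k], params[k] + tcrit * se_d[k]) for k in names
    }
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss / sst if sst > 0 else 1.0
    if model == "one_phase":
        half = {"half_life": _half_life_from_rate(params["k"], ci["k"])}
    else:
        half = {
            "fast": _half_life_from_rate(params["k_fast"], ci["k_fast"]),
            "slow": _half_life_from_rate(params["k_slow"], ci["k_slow"]),
        }
    return DecayFit(
        model=model,
        params=params,
        se=se_d,
        ci95=ci,
        plateau_constrained=plateau_constrained,
        plateau_value=float(params.get("plateau", plateau)),
        half_lives=half,
        ss_residual=ss,
        df=dof,
        n_points=n,
        r_squared=r2,
        t=t,
        y=y,
    )


def _initial_rate(t: np.ndarray, y: np.ndarray, plateau: float) -> float:
    """Rate guess from log-linear regression of (y - plateau) on t."""
    z = y - plateau
    ok = z > 1e-9
    if ok.sum() >= 2 and np.ptp(t[ok]) > 0:
        slope = np.polyfit(t[ok], np.log(z[ok]), 1)[0]
        k0 = max(-slope, 1e-4)
    else:
        k0 = 1.0
    return min(k0, _RATE_MAX)


def _check_inputs(t, y, min_n):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if t.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {t.size}")
    if np.any(t < 0):
        raise ValueError("chase times must be >= 0")
    return t, y


def fit_one_phase(t, y, plateau: float | None = None) -> DecayFit:
    """Fit y = plateau + (y0 - plateau) exp(-k t) by unweighted least squares.

    ``plateau``: fix the asymptote to this value (the measured background on
    the normalized scale); ``None`` leaves it free. Multi-start over rate
    scalings guards against local minima.
    """
    free_plateau = plateau is None
    t, y = _check_inputs(t, y, 4 if free_plateau else 3)
    b0 = float(np.percentile(y, 5)) if free_plateau else float(plateau)
    k0 = _initial_rate(t, y, min(b0, y.min() - 1e-6) if free_plateau else b0)
    y0_guess = float(y[np.argmin(t)])

    def residual_fixed(x):
        y0, k = x
        return plateau + (y0 - plateau) * np.exp(-k * t) - y

    def residual_free(x):
        y0, k, b = x
        return b + (y0 - b) * np.exp(-k * t) - y

    best = None
    errors = []
    for scale in (1.0, 0.25, 4.0):
        k_start = min(max(k0 * scale, 1e-4), _RATE_MAX)
        try:
            if free_plateau:
                res = optimize.least_squares(
                    residual_free,
                    x0=[y0_guess, k_start, b0],
                    bounds=([-np.inf, 0.0, -np.inf], [np.inf, _RATE_MAX, np.inf]),
                )
            else:
                res = optimize.least_squares(
                    residual_fixed,
                    x0=[y0_guess, k_start],
                    bounds=([-np.inf, 0.0], [np.inf, _RATE_MAX]),
                )
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(str(exc))
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(f"one-phase fit failed to converge: {errors}")
    names = ["y0", "k", "plateau"] if free_plateau else ["y0", "k"]
    return _wald(best, names, t.size, y, plateau, not free_plateau, t, "one_phase")


def fit_two_phase(t, y, plateau: float | None = None) -> DecayFit:
    """Fit the two-pool model
    y = plateau + (y0 - plateau) [f exp(-k_fast t) + (1-f) exp(-k_slow t)].

    Rates are ordered k_fast >= k_slow >= 0 (enforced by relabelling).
    Degenerate solutions are flagged on the returned fit rather than raised:
    ``rates_collapsed`` when the two rates are indistinguishable (the model
    reduces to one phase) and ``boundary_fraction`` when f_fast sticks at 0
    or 1.
    """
    free_plateau = plateau is None
    t, y = _check_inputs(t, y, 6 if free_plateau else 5)
    b0 = float(np.percentile(y, 5)) if free_plateau else float(plateau)
    k0 = _initial_rate(t, y, b0 if not free_plateau else min(b0, y.min() - 1e-6))
    y0_guess = float(y[np.argmin(t)])

    def model(x):
        if free_plateau:
            y0, f, kf, ks, b = x
        else:
            y0, f, kf, ks = x
            b = plateau
        return b + (y0 - b) * (f * np.exp(-kf * t) + (1 - f) * np.exp(-ks * t))

    def residual(x):
        return model(x) - y

    # warm-start from the nested one-phase solution (rate splitting): with
    # k_fast = k_slow = k_hat the two-phase SS equals the one-phase SS, so
    # the refined fit can never be worse than the simpler model
    try:
        one = fit_one_phase(t, y, plateau)
        k_hat, y0_hat = one.params["k"], one.params["y0"]
    except Exception:
        k_hat, y0_hat = k0, y0_guess
    y0_guess = y0_hat
    starts = [
        (0.5, max(k_hat, 1e-4), max(k_hat, 1e-4)),
        (0.5, 2.0 * k_hat, 0.5 * k_hat),
        (0.4, 4.0 * k_hat, 0.0),
        (0.7, 2.0 * k_hat, 0.0),
        (0.2, 10.0 * k_hat, 0.8 * k_hat),
        (0.8, 1.5 * k_hat, 0.1 * k_hat),
        (0.1, 25.0 * k_hat, max(k_hat, 1e-4)),
        (0.3, 8.0 * k0, 0.25 * k0),
    ]
    best = None
    for f_s, kf_s, ks_s in starts:
        kf_s = min(max(kf_s, 1e-4), _RATE_MAX)
        ks_s = min(max(ks_s, 0.0), _RATE_MAX)
        x0 = [y0_guess, f_s, kf_s, ks_s] + ([b0] if free_plateau else [])
        lb = [-np.inf, 0.0, 0.0, 0.0] + ([-np.inf] if free_plateau else [])
        ub = [np.inf, 1.0, _RATE_MAX, _RATE_MAX] + ([np.inf] if free_plateau else [])
        try:
            res = optimize.least_squares(residual, x0=x0, bounds=(lb, ub))
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("two-phase fit failed to converge from all starts")
    if best.x[2] < best.x[3]:  # relabel so k_fast >= k_slow, refresh Jacobian
        x = best.x.copy()
        x[2], x[3] = x[3], x[2]
        x[1] = 1.0 - x[1]
        lb = [-np.inf, 0.0, 0.0, 0.0] + ([-np.inf] if free_plateau else [])
        ub = [np.inf, 1.0, _RATE_MAX, _RATE_MAX] + ([np.inf] if free_plateau else [])
        best = optimize.least_squares(residual, x0=x, bounds=(lb, ub))
    names = ["y0", "f_fast", "k_fast", "k_slow"] + (
        ["plateau"] if free_plateau else []
    )
    fit = _wald(best, names, t.size, y, plateau, not free_plateau, t, "two_phase")
    if abs(fit.params["k_fast"] - fit.params["k_slow"]) < 1e-4:
        fit.degenerate = "rates_collapsed"
    elif fit.params["f_fast"] < 1e-6 or fit.params["f_fast"] > 1 - 1e-6:
        fit.degenerate = "boundary_fraction"
    return fit


def extra_ss_f_test(fit_null: DecayFit, fit_alt: DecayFit) -> tuple[float, float]:
    """Extra sum-of-squares F test for nested decay models.

    F = [(SS_null - SS_alt) / (df_null - df_alt)] / (SS_alt / df_alt), with p
    from F(df_null - df_alt, df_alt). The null must be the simpler model
    fitted to the same data.
    """
    nested = fit_null.model == "one_phase" and fit_alt.model == "two_phase"
    if not nested or fit_null.n_points != fit_alt.n_points:
        raise ValueError("models must be nested fits of the same data")
    if fit_null.df <= fit_alt.df:
        raise ValueError("null model must have more residual df than alternative")
    d_df = fit_null.df - fit_alt.df
    d_ss = fit_null.ss_residual - fit_alt.ss_residual
    if d_ss <= 1e-12 * max(fit_null.ss_residual, 1e-12):
        if d_ss < -1e-9 * max(fit_null.ss_residual, 1e-12):
            warnings.warn(
                "alternative fit has larger SS than null (numerical); F clamped to 0"
            )
        return 0.0, 1.0
    if fit_alt.ss_residual == 0:
        return math.inf, 0.0
    F = (d_ss / d_df) / (fit_alt.ss_residual / fit_alt.df)
    p = float(sps.f.sf(F, d_df, fit_alt.df))
    return float(F), p


def _robust_fit_residuals(t, y, model_spec, plateau):
    """Residuals from a robust (Lorentzian-loss) fit of the given model."""
    # start from the ordinary fit, then reweight with Cauchy/Lorentzian loss
    if model_spec == "one_phase":
        ols = fit_one_phase(t, y, plateau)
        names = list(ols.params)

        def resid(x):
            y0, k = x[0], x[1]
            b = x[2] if len(x) == 3 else plateau
            return b + (y0 - b) * np.exp(-k * t) - y

        x0 = [ols.params[n] for n in names]
        lb = [-np.inf, 0.0] + ([-np.inf] if len(names) == 3 else [])
        ub = [np.inf, _RATE_MAX] + ([np.inf] if len(names) == 3 else [])
    elif model_spec == "two_phase":
        ols = fit_two_phase(t, y, plateau)
        names = list(ols.params)

        def resid(x):
            y0, f, kf, ks = x[:4]
            b = x[4] if len(x) == 5 else plateau
            return b + (y0 - b) * (
                f * np.exp(-kf * t) + (1 - f) * np.exp(-ks * t)
            ) - y

        x0 = [ols.params[n] for n in names]
        lb = [-np.inf, 0.0, 0.0, 0.0] + ([-np.inf] if len(names) == 5 else [])
        ub = [np.inf, 1.0, _RATE_MAX, _RATE_MAX] + ([np.inf] if len(names) == 5 else [])
    else:
        raise ValueError(f"unknown model_spec {model_spec!r}")
    r0 = resid(np.asarray(x0))
    scale = 1.4826 * np.median(np.abs(r0 - np.median(r0)))
    scale = max(scale, 1e-6 * max(1.0, float(np.abs(y).max())))
    res = optimize.least_squares(
        resid, x0=x0, bounds=(lb, ub), loss="cauchy", f_scale=scale
    )
    return resid(res.x), len(x0)


def rout_outliers(
    t, y, model_spec: str = "one_phase", Q: float = 0.05, plateau: float | None = None
) -> tuple[np.ndarray, DecayFit]:
    """ROUT outlier elimination, then an ordinary fit on the inliers.

    Procedure: robust regression with a Lorentzian merit function; robust
    standard deviation of residuals (RSDR) from the 68.27th percentile of
    absolute residuals with the small-sample correction n/(n-p); each
    residual's two-sided t p-value (df = n-p) passed through a
    false-discovery-rate step at rate ``Q``. Points surviving are refit by
    unweighted least squares. Outliers are removed once (no re-iteration).

    Returns (inlier_mask, cleaned_fit).
    """
    if not 0.0 < Q <= 0.1:
        raise ValueError("Q must lie in (0, 0.1]")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    resid, p = _robust_fit_residuals(t, y, model_spec, plateau)
    n = t.size
    if n < 2 * p:
        raise ValueError(f"need at least {2 * p} points for outlier detection")
    dof = n - p
    rsdr = float(np.percentile(np.abs(resid), 68.27)) * n / dof
    rsdr = max(rsdr, 1e-12)
    pvals = 2.0 * sps.t.sf(np.abs(resid) / rsdr, dof)
    # Benjamini-Hochberg step at rate Q: flag the largest set {p_(1..j)} with
    # p_(j) <= Q * j / n
    order = np.argsort(pvals)
    thresh = Q * (np.arange(1, n + 1)) / n
    passed = pvals[order] <= thresh
    n_flag = int(np.max(np.nonzero(passed)[0]) + 1) if passed.any() else 0
    mask = np.ones(n, dtype=bool)
    mask[order[:n_flag]] = False
    if not mask.any():
        raise ValueError("degenerate outlier removal: all points flagged")
    fitfun = fit_one_phase if model_spec == "one_phase" else fit_two_phase
    fit = fitfun(t[mask], y[mask], plateau)
    fit.outlier_mask = mask
    fit.q_used = Q
    return mask, fit


def profile_ci_rate(fit: DecayFit, rate: str = "k", n_grid: int = 60) -> tuple[float, float]:
    """Profile-likelihood 95% CI on a rate parameter of a one-phase fit.

    Useful at parameter boundaries where the Wald interval degenerates
    (e.g. very slow decays whose upper half-life limit is unbounded).
    Returns (lo, hi); ``hi`` may be inf when the profile never crosses the
    threshold within the searched range.
    """
    if fit.model != "one_phase" or rate != "k":
        raise NotImplementedError("profile CI implemented for one-phase k")
    t, y = fit.t, fit.y
    b = fit.plateau_value
    constrained = fit.plateau_constrained
    ss_min = fit.ss_residual
    crit = ss_min * (1.0 + sps.f.ppf(0.95, 1, fit.df) / fit.df)

    def ss_at(k_fixed: float) -> float:
        def resid(x):
            y0 = x[0]
            bb = x[1] if not constrained else b
            return bb + (y0 - bb) * np.exp(-k_fixed * t) - y

        x0 = [fit.params["y0"]] + ([b] if not constrained else [])
        res = optimize.least_squares(resid, x0=x0)
        return float(2.0 * res.cost)

    k_hat = fit.params["k"]
    lo = 0.0
    for kk in np.linspace(k_hat, max(k_hat * 1e-3, 1e-6), n_grid):
        if ss_at(kk) > crit:
            lo = kk
            break
    hi = math.inf
    for kk in np.linspace(k_hat if k_hat > 0 else 1e-4, max(k_hat * 20, 1.0), n_grid):
        if kk > k_hat and ss_at(kk) > crit:
            hi = kk
            break
    return lo, hi
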