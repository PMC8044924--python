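"""Numerical- and functional-response models for protist grazers.

The numerical response (NR) relates predator per-capita growth rate to
prey biomass with a Michaelis-Menten-type hyperbola shifted to cross zero
at a positive prey threshold P'::

    mu(P) = mu_max * (P - P') / (k2 + P - P')

mu_max is the asymptotic maximum growth rate (d^-1), P' the threshold
prey concentration at which growth balances mortality (mg C/liter), and
k2 a shape constant (mg C/liter) that is *not* the classical Michaelis
half-saturation constant.  The initial slope alpha = mu_max/k2 measures
predator-prey affinity at low food.

The functional response (FR) relates per-predator ingestion to prey
biomass, either as a Holling type II saturating hyperbola::

    I(P) = I_max * P / (k + P)

or — when no saturation occurs within the observed food range — as a
zero-intercept line I(P) = slope * P.  Fitting tries both and selects by
AICc, with an independent divergence check that mirrors the common field
practice of reporting "infinite" Holling parameters for unsaturated data.

Both models follow the Model -> fit() -> Results idiom: construct from
arrays (or a rates DataFrame), call ``fit()``, and read estimates,
standard errors, Wald p-values, confidence bands and ``summary()`` off
the Results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "evaluate_nr",
    "evaluate_fr",
    "initial_slope",
    "gross_growth_efficiency",
    "GGEResult",
    "NumericalResponse",
    "NumericalResponseResults",
    "FunctionalResponse",
    "FunctionalResponseResults",
    "FitError",
]


class FitError(ValueError):
    """Raised when a response fit cannot be attempted or is rejected."""


# ---------------------------------------------------------------------------
# model curves


def evaluate_nr(params, p):
    """Threshold numerical response mu = mu_max*(P-P')/(k2+P-P').

    ``params`` is (mu_max, p_prime, k2) or an NR results object; ``p`` is
    prey biomass in mg C/liter.  Below the threshold the (negative) model
    value is returned, not zero.
    """
    if isinstance(params, NumericalResponseResults):
        mu_max, p_prime, k2 = params.params
    else:
        mu_max, p_prime, k2 = params
    p = np.asarray(p, dtype=float)
    shifted = p - p_prime
    return mu_max * shifted / (k2 + shifted)


def evaluate_fr(params, p):
    """Functional response evaluation.

    ``params`` is (I_max, k) for Holling II, a scalar slope for the linear
    model, or a FR results object (its selected model is used).
    """
    if isinstance(params, FunctionalResponseResults):
        return params.predict(p)
    p = np.asarray(p, dtype=float)
    if np.isscalar(params) or np.ndim(params) == 0:
        return float(params) * p
    imax, k = params
    return imax * p / (k + p)


def initial_slope(mu_max, k2, cov: Optional[np.ndarray] = None):
    """Initial slope alpha = mu_max/k2, optionally with a delta-method SE.

    ``cov`` is the 2x2 covariance of (mu_max, k2); returns alpha or
    (alpha, se).
    """
    if k2 <= 0:
        raise ValueError("initial_slope requires k2 > 0")
    alpha = mu_max / k2
    if cov is None:
        return alpha
    grad = np.array([1.0 / k2, -mu_max / k2**2])
    var = float(grad @ np.asarray(cov) @ grad)
    return alpha, np.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class GGEResult:
    """Gross growth efficiency GGE = mu*M/I at one food level."""

    gge: float  # dimensionless fraction
    food_level_mg_l: float
    temperature_c: Optional[float]
    mu: float  # d^-1
    cell_biomass_ng: float  # M, ng C/cell
    ingestion_ng_per_cell_d: float  # I

    @property
    def percent(self) -> float:
        return 100.0 * self.gge


def gross_growth_efficiency(
    mu: float,
    cell_biomass_ng: float,
    ingestion_ng_per_cell_d: float,
    food_level_mg_l: float = 0.5,
    temperature_c: Optional[float] = None,
) -> GGEResult:
    """Fraction of ingested prey carbon converted into predator carbon.

    Undefined (error) for non-positive ingestion; values outside [0, 1]
    are physically suspect and draw a warning, not an error.
    """
    if ingestion_ng_per_cell_d <= 0:
        raise FitError("GGE undefined for ingestion <= 0")
    gge = mu * cell_biomass_ng / ingestion_ng_per_cell_d
    if not (0.0 <= gge <= 1.0):
        warnings.warn(f"GGE = {gge:.3f} outside [0, 1]", stacklevel=2)
    return GGEResult(gge, food_level_mg_l, temperature_c, mu, cell_biomass_ng, ingestion_ng_per_cell_d)


# ---------------------------------------------------------------------------
# shared fitting machinery


def _wald(params, cov, dof):
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = params / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=max(dof, 1))
    return se, tvals, pvals


def _aicc(rss: float, n: int, n_params: int) -> float:
    # Gaussian log-likelihood with the error variance counted as a parameter
    k = n_params + 1
    if n <= k + 1:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _covariance(res, n: int, n_params: int):
    """Parameter covariance from the least-squares Jacobian (Wald)."""
    dof = n - n_params
    if dof <= 0:
        return None
    _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
    threshold = np.finfo(float).eps * max(res.jac.shape) * s[0] if s[0] > 0 else 0.0
    if s[-1] <= threshold:
        return None  # singular information matrix
    cov_unscaled = (vt.T / s**2) @ vt
    sigma2 = 2.0 * res.cost / dof  # cost = 0.5 * rss
    return cov_unscaled * sigma2


# ---------------------------------------------------------------------------
# numerical response


class NumericalResponse:
    """Threshold numerical-response model for (P, mu) observations.

    Parameters
    ----------
    mu : array-like
        Per-capita predator growth rates (d^-1); negative values are
        legitimate and constrain the threshold.
    prey : array-like
        Geometric-mean prey biomass (mg C/liter).

    Notes
    -----
    Fitting is bounded nonlinear least squares (Levenberg-Marquardt-type
    trust region) started from several deterministic heuristic initial
    points; the best converged start wins on residual sum of squares.
    """

    #: parameter names in order
    param_names = ("mu_max", "p_prime", "k2")

    def __init__(self, mu, prey):
        mu = np.asarray(mu, dtype=float)
        prey = np.asarray(prey, dtype=float)
        mask = np.isfinite(mu) & np.isfinite(prey)
        self.endog = mu[mask]
        self.exog = prey[mask]
        n = self.endog.size
        if n < 4:
            raise FitError(f"numerical response needs >= 4 points, got {n}")
        if np.all(self.endog <= 0):
            raise FitError("no positive growth rates: numerical response unconstrained")
        if np.any(self.exog < 0):
            raise FitError("prey biomass must be >= 0")
        span = self.exog.max() / max(self.exog.min(), 1e-12)
        if n < 6 or span < 5:
            warnings.warn(
                f"weakly designed NR fit: n={n}, prey span {span:.1f}-fold "
                "(recommended >= 6 points over >= 5-fold range)",
                stacklevel=2,
            )

    @classmethod
    def from_rates(cls, rates, species=None, temperature=None) -> "NumericalResponse":
        """Build from a rates-table DataFrame, dropping extinct wells."""
        df = _select(rates, species, temperature)
        df = df[df["mu_per_d"].notna()]
        return cls(df["mu_per_d"].to_numpy(), df["p_mean_mgC_per_liter"].to_numpy())

    def _starts(self):
        p, mu = self.exog, self.endog
        p_range = p.max() - p.min()
        mu_max0 = max(mu.max(), 0.05)
        nonpos = p[mu <= 0]
        pp0 = nonpos.max() if nonpos.size else p.min() / 2.0
        pp0 = min(pp0, 0.95 * p.max())
        starts = [(mu_max0, pp0, f * p_range) for f in (0.25, 0.5, 1.0)]
        starts.append((mu_max0, 0.0, 0.5 * p_range))
        starts.append((1.5 * mu_max0, pp0, 0.1 * p_range))
        return starts

    def fit(self) -> "NumericalResponseResults":
        p, mu = self.exog, self.endog
        lo = np.array([1e-8, 0.0, 1e-8])
        hi = np.array([20.0, p.max(), 100.0])

        def resid(theta):
            return evaluate_nr(theta, p) - mu

        best = None
        for x0 in self._starts():
            x0 = np.clip(x0, lo + 1e-10, hi - 1e-10)
            try:
                res = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitError("numerical-response optimizer failed from every start")

        flags = []
        est = best.x
        at_bound = (np.isclose(est, hi, rtol=1e-6) | (est <= lo + 1e-9)).tolist()
        # P' = 0 is an admissible interior value of the science, not a failure
        if at_bound[0] or at_bound[2] or np.isclose(est[1], hi[1], rtol=1e-6):
            flags.append("at_bound")
        cov = _covariance(best, p.size, 3)
        if cov is None:
            flags.append("singular_covariance")
            cov = np.full((3, 3), np.nan)
        se, tvals, pvals = _wald(est, cov, p.size - 3)
        if np.any(se[[0, 2]] > np.abs(est[[0, 2]])):
            flags.append("non_identifiable")
        # a flat response is fit equally well by k2 -> 0 (step) or k2 -> inf
        # (rescaled line); either degenerate limit means no hyperbolic signal
        p_scale = p.max() - p.min()
        if p_scale > 0 and (est[2] < 1e-4 * p_scale or est[2] > 0.99 * hi[2]):
            if "non_identifiable" not in flags:
                flags.append("non_identifiable")
        rss = 2.0 * best.cost
        return NumericalResponseResults(
            model=self,
            params=est,
            cov_params=cov,
            bse=se,
            tvalues=tvals,
            pvalues=pvals,
            rss=rss,
            nobs=p.size,
            flags=flags,
        )


@dataclass
class NumericalResponseResults:
    """Fitted threshold numerical response."""

    model: NumericalResponse
    params: np.ndarray  # (mu_max, p_prime, k2)
    cov_params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    rss: float
    nobs: int
    flags: list = field(default_factory=list)

    param_names = NumericalResponse.param_names

    @property
    def mu_max(self) -> float:
        return float(self.params[0])

    @property
    def p_prime(self) -> float:
        return float(self.params[1])

    @property
    def k2(self) -> float:
        return float(self.params[2])

    @property
    def converged(self) -> bool:
        return not ({"at_bound", "singular_covariance"} & set(self.flags))

    @property
    def alpha(self) -> float:
        """Initial slope mu_max/k2 from the unrounded estimates."""
        return initial_slope(self.mu_max, self.k2)

    @property
    def alpha_se(self) -> float:
        sub = self.cov_params[np.ix_([0, 2], [0, 2])]
        return initial_slope(self.mu_max, self.k2, sub)[1]

    @property
    def aicc(self) -> float:
        return _aicc(self.rss, self.nobs, 3)

    def predict(self, p):
        return evaluate_nr(self.params, p)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald confidence intervals, one (lo, hi) row per parameter.

        mu_max and k2 are strictly positive scale parameters whose sampling
        distributions are right-skewed at realistic design sizes; their
        intervals are therefore Wald intervals on the log scale mapped back
        (the standard construction for positivity-constrained parameters).
        P' may legitimately be 0, so its interval stays on the natural scale.
        """
        q = stats.t.ppf(1 - alpha / 2.0, df=max(self.nobs - 3, 1))
        out = np.empty((3, 2))
        for j, name in enumerate(self.param_names):
            est, se = self.params[j], self.bse[j]
            if name in ("mu_max", "k2") and est > 0 and np.isfinite(se) and se > 0:
                s_log = se / est  # delta method on log(theta)
                out[j] = est * np.exp(-q * s_log), est * np.exp(q * s_log)
            else:
                out[j] = est - q * se, est + q * se
        return out

    def _gradient(self, p):
        mu_max, pp, k2 = self.params
        s = np.asarray(p, dtype=float) - pp
        denom = (k2 + s) ** 2
        return np.stack(
            [s / (k2 + s), -mu_max * k2 / denom, -mu_max * s / denom], axis=-1
        )

    def conf_band(self, p, alpha: float = 0.05, method: str = "delta", n_boot: int = 1000, seed: int = 0):
        """Pointwise confidence band for the fitted curve over prey levels ``p``.

        ``delta`` propagates the Wald covariance through the curve's
        gradient; ``bootstrap`` resamples parameters from the asymptotic
        normal (parametric, seeded).
        """
        p = np.asarray(p, dtype=float)
        fit = self.predict(p)
        if method == "delta":
            grad = self._gradient(p)
            var = np.einsum("...i,ij,...j->...", grad, self.cov_params, grad)
            half = stats.t.ppf(1 - alpha / 2.0, df=max(self.nobs - 3, 1)) * np.sqrt(
                np.clip(var, 0.0, np.inf)
            )
            return fit - half, fit + half
        if method == "bootstrap":
            rng = np.random.default_rng(seed)
            draws = rng.multivariate_normal(self.params, self.cov_params, size=n_boot)
            draws = np.clip(draws, [1e-8, 0.0, 1e-8], None)
            curves = np.stack([evaluate_nr(d, p) for d in draws])
            lo, hi = np.quantile(curves, [alpha / 2.0, 1 - alpha / 2.0], axis=0)
            return lo, hi
        raise ValueError("method must be 'delta' or 'bootstrap'")

    def summary(self) -> str:
        lines = [
            "Threshold numerical response: mu = mu_max*(P-P')/(k2+P-P')",
            f"n = {self.nobs}, RSS = {self.rss:.5g}, AICc = {self.aicc:.2f}",
            f"{'param':>8} {'estimate':>10} {'SE':>10} {'t':>8} {'p':>10}",
        ]
        units = {"mu_max": "d^-1", "p_prime": "mg C/L", "k2": "mg C/L"}
        for name, est, se, t, pv in zip(
            self.param_names, self.params, self.bse, self.tvalues, self.pvalues
        ):
            lines.append(f"{name:>8} {est:>10.4f} {se:>10.4f} {t:>8.2f} {pv:>10.2g}  [{units[name]}]")
        lines.append(f"   alpha {self.alpha:>10.4f} {self.alpha_se:>10.4f}  [per (mg C/L) per d]")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def plot(self, ax=None, data=True, band=True, p_grid=None):
        """Fitted NR curve with optional 95% band and data overlay."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if p_grid is None:
            p_grid = np.linspace(0, self.model.exog.max() * 1.05, 200)
        ax.plot(p_grid, self.predict(p_grid), color="C0", label="fit")
        if band:
            lo, hi = self.conf_band(p_grid)
            ax.fill_between(p_grid, lo, hi, alpha=0.2, color="C0", label="95% CI")
        if data:
            ax.plot(self.model.exog, self.model.endog, "ko", ms=4, label="data")
        ax.axhline(0.0, ls=":", color="grey", lw=0.8)
        ax.set_xlabel("prey biomass (mg C/liter)")
        ax.set_ylabel("growth rate (d$^{-1}$)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional response


class FunctionalResponse:
    """Holling-II vs linear functional response for (P, I) observations.

    ``fit()`` estimates both the saturating hyperbola I = I_max*P/(k+P)
    and the zero-intercept line I = slope*P, selects between them by
    AICc, and independently flags the Holling fit as divergent when its
    parameters run to the bounds or their standard errors exceed the
    estimates — the signature of data with no saturation in range.
    """

    def __init__(self, ingestion, prey):
        ingestion = np.asarray(ingestion, dtype=float)
        prey = np.asarray(prey, dtype=float)
        mask = np.isfinite(ingestion) & np.isfinite(prey)
        self.endog = ingestion[mask]
        self.exog = prey[mask]
        n = self.endog.size
        if n < 4:
            raise FitError(f"functional response needs >= 4 points, got {n}")
        if np.any(self.endog < 0):
            raise FitError("ingestion rates must be >= 0 (clip negatives upstream)")
        if n < 6:
            warnings.warn(f"weakly designed FR fit: n={n} (< 6 points)", stacklevel=2)

    @classmethod
    def from_rates(cls, rates, species=None, temperature=None) -> "FunctionalResponse":
        df = _select(rates, species, temperature)
        df = df[df["ingestion_ngC_per_cell_d"].notna()]
        df = df[df["ingestion_ngC_per_cell_d"] >= 0]
        return cls(df["ingestion_ngC_per_cell_d"].to_numpy(), df["p_mean_mgC_per_liter"].to_numpy())

    def fit(self) -> "FunctionalResponseResults":
        p, y = self.exog, self.endog
        n = p.size

        # --- Holling II by bounded least squares, multi-start on k
        imax_hi = max(1e3 * y.max(), 1.0)
        k_hi = 1e3 * p.max()
        lo = np.array([1e-10, 1e-10])
        hi = np.array([imax_hi, k_hi])

        def resid(theta):
            return evaluate_fr(theta, p) - y

        p_range = p.max() - p.min()
        best = None
        for kf in (0.1, 0.25, 0.5, 1.0, 2.0):
            x0 = np.clip([max(y.max(), 1e-3), kf * max(p_range, 1e-6)], lo + 1e-12, hi - 1e-9)
            try:
                res = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res

        holling = None
        holling_flags: list = []
        if best is not None:
            est = best.x
            cov = _covariance(best, n, 2)
            if cov is None:
                holling_flags.append("singular_covariance")
                cov = np.full((2, 2), np.nan)
            se, tvals, pvals = _wald(est, cov, n - 2)
            rss = 2.0 * best.cost
            if np.any(np.isclose(est, hi, rtol=1e-3)):
                holling_flags.append("at_bound")
            with np.errstate(invalid="ignore"):
                if np.any(~np.isfinite(se)) or np.any(se > np.abs(est)):
                    holling_flags.append("se_exceeds_estimate")
            holling = {
                "params": est,
                "cov": cov,
                "bse": se,
                "tvalues": tvals,
                "pvalues": pvals,
                "rss": rss,
                "aicc": _aicc(rss, n, 2),
            }
        else:
            holling_flags.append("optimizer_failed")

        # --- zero-intercept line, closed form
        sxx = float(np.sum(p * p))
        if sxx <= 0:
            raise FitError("functional response needs positive prey levels")
        slope = float(np.sum(p * y) / sxx)
        lin_resid = y - slope * p
        lin_rss = float(np.sum(lin_resid**2))
        lin_dof = n - 1
        slope_var = lin_rss / lin_dof / sxx if lin_dof > 0 else np.nan
        slope_se = float(np.sqrt(slope_var))
        lin_t = slope / slope_se if slope_se > 0 else np.inf
        lin_p = 2.0 * stats.t.sf(abs(lin_t), df=max(lin_dof, 1))
        lin_aicc = _aicc(lin_rss, n, 1)

        divergent = bool({"at_bound", "se_exceeds_estimate", "optimizer_failed"} & set(holling_flags))
        if divergent:
            selected = "linear"
        else:
            selected = "holling_II" if holling["aicc"] <= lin_aicc else "linear"

        return FunctionalResponseResults(
            model=self,
            selected=selected,
            holling=holling,
            holling_flags=holling_flags,
            linear={
                "slope": slope,
                "bse": slope_se,
                "tvalue": lin_t,
                "pvalue": lin_p,
                "rss": lin_rss,
                "aicc": lin_aicc,
            },
            nobs=n,
        )


@dataclass
class FunctionalResponseResults:
    """Fitted functional response with model-selection verdict."""

    model: FunctionalResponse
    selected: str  # "holling_II" or "linear"
    holling: Optional[dict]
    holling_flags: list
    linear: dict
    nobs: int

    @property
    def holling_divergent(self) -> bool:
        """True when the saturating fit ran away (no saturation in range)."""
        return bool(
            {"at_bound", "se_exceeds_estimate", "optimizer_failed"} & set(self.holling_flags)
        )

    @property
    def i_max(self) -> float:
        if self.holling is None:
            return np.nan
        return float(self.holling["params"][0])

    @property
    def k(self) -> float:
        if self.holling is None:
            return np.nan
        return float(self.holling["params"][1])

    @property
    def slope(self) -> float:
        return float(self.linear["slope"])

    def predict(self, p, which: Optional[str] = None):
        which = which or self.selected
        p = np.asarray(p, dtype=float)
        if which == "linear":
            return self.slope * p
        if self.holling is None:
            raise FitError("Holling fit unavailable")
        return evaluate_fr(self.holling["params"], p)

    def summary(self) -> str:
        lines = [
            "Functional response: Holling II (I = I_max*P/(k+P)) vs linear (I = slope*P)",
            f"n = {self.nobs}; selected model: {self.selected}"
            + ("  [Holling divergent: unsaturated data]" if self.holling_divergent else ""),
        ]
        if self.holling is not None:
            h = self.holling
            lines.append(
                f"  Holling II: I_max = {h['params'][0]:.4g} ± {h['bse'][0]:.3g} ng C/cell/d, "
                f"k = {h['params'][1]:.4g} ± {h['bse'][1]:.3g} mg C/L, AICc = {h['aicc']:.2f}"
            )
            if self.holling_flags:
                lines.append("    flags: " + ", ".join(self.holling_flags))
        lin = self.linear
        lines.append(
            f"  linear: slope = {lin['slope']:.4g} ± {lin['bse']:.3g} (ng C/cell/d)/(mg C/L), "
            f"AICc = {lin['aicc']:.2f}"
        )
        return "\n".join(lines)

    def plot(self, ax=None, data=True, p_grid=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if p_grid is None:
            p_grid = np.linspace(0, self.model.exog.max() * 1.05, 200)
        ax.plot(p_grid, self.predict(p_grid), color="C1", label=f"fit ({self.selected})")
        if data:
            ax.plot(self.model.exog, self.model.endog, "ko", ms=4, label="data")
        ax.set_xlabel("prey biomass (mg C/liter)")
        ax.set_ylabel("ingestion (ng C cell$^{-1}$ d$^{-1}$)")
        ax.legend()
        return ax


def _select(rates, species, temperature):
    df = rates
    if species is not None:
        df = df[df["species"] == species]
    if temperature is not None:
        df = df[np.isclose(df["temperature_C"], temperature)]
    return df
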