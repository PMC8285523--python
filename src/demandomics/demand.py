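"""Exponential demand-curve analysis of operant self-administration data.

The model is the exponential demand equation of behavioral economics
(Hursh & Silberberg form)::

    log10 Q(C) = log10 Q0 + k * (exp(-alpha * Q0 * C) - 1)

where ``C`` is unit price (responses per unit of reinforcer), ``Q`` is
consumption at that price, ``Q0`` is consumption at a minimally constraining
price, ``alpha`` is the rate of decline of consumption with price (units
1/(C*Q)) and ``k`` is a fixed constant giving the log10-unit range of the
consumption decline (2 throughout this package unless overridden).

Derived indices:

* ``Pmax`` — the price at which demand becomes elastic, i.e. where the
  log-log slope of the curve equals -1 and expenditure ``E(C) = C * Q(C)``
  peaks.  Substituting ``u = alpha*Q0*C`` the unit-slope condition reads
  ``k*ln(10) * u * exp(-u) = 1``; the expenditure maximum is the smaller of
  its two roots, available in closed form through the principal branch of
  the Lambert W function: ``u* = -W0(-1/(k ln 10))`` and
  ``Pmax = u*/(alpha*Q0)``.
* ``standardized Pmax = Pmax * Q0`` — an intake-controlled motivation index
  (``u*/alpha`` up to the constant), comparable across groups.
* ``Omax = Pmax * Q(Pmax)`` — predicted peak expenditure.

The model object / results object pair follows the statsmodels convention:
``ExponentialDemand(price, consumption).fit()`` returns
:class:`ExponentialDemandResults` with estimates, standard errors, derived
indices and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import lambertw

__all__ = [
    "DemandError",
    "DemandDerived",
    "ExponentialDemand",
    "ExponentialDemandResults",
    "predict_consumption",
    "fit_demand",
    "solve_pmax",
    "bins_to_demand_points",
    "doses_to_demand_points",
    "pr_breakpoint",
    "consumption_change_summary",
    "THRESHOLD_FR_SCHEDULE",
    "PR_RATIO_LADDER",
]

#: escalating fixed-ratio requirements of the within-session threshold procedure
THRESHOLD_FR_SCHEDULE = (1, 2, 3, 5, 8, 10, 14, 18, 25, 31, 48)

#: progressive-ratio response-requirement ladder used for breakpoint testing
PR_RATIO_LADDER = (1, 3, 5, 6, 8, 10, 14, 18, 25, 31, 38, 45, 55, 85, 110, 140, 200)

LN10 = math.log(10.0)


class DemandError(ValueError):
    """Raised for unusable demand data or degenerate model configurations."""


def predict_consumption(q0: float, alpha: float, price, k: float = 2.0):
    """Predicted consumption Q at unit price(s) ``price``.

    Strictly decreasing in price; Q(0) = q0 and Q(inf) = q0 * 10**(-k).
    """
    if q0 <= 0 or alpha <= 0 or k <= 0:
        raise DemandError("q0, alpha and k must be positive")
    price = np.asarray(price, dtype=float)
    log10q = math.log10(q0) + k * (np.exp(-alpha * q0 * price) - 1.0)
    out = 10.0**log10q
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DemandDerived:
    """Price indices derived from a fitted demand curve."""

    pmax: float
    standardized_pmax: float
    omax: float


def solve_pmax(fit, k: float | None = None) -> DemandDerived:
    """Pmax (expenditure-maximizing price), standardized Pmax and Omax.

    Accepts any object exposing ``q0``, ``alpha`` and (unless ``k`` is given)
    ``k``.  Uses the closed-form Lambert-W solution of the unit-elasticity
    condition; the smaller root is the inelastic-to-elastic crossing where
    response output peaks.
    """
    q0 = float(fit.q0)
    alpha = float(fit.alpha)
    k = float(fit.k if k is None else k)
    if q0 <= 0 or alpha <= 0:
        raise DemandError("q0 and alpha must be positive")
    c = 1.0 / (k * LN10)
    if c >= math.exp(-1.0):
        # u*exp(-u) has maximum 1/e: no unit-slope crossing exists
        raise DemandError(
            f"degenerate demand model: k*ln(10) = {k * LN10:.4f} <= e; no Pmax"
        )
    u_star = float(-lambertw(-c, 0).real)
    pmax = u_star / (alpha * q0)
    omax = pmax * predict_consumption(q0, alpha, pmax, k=k)
    return DemandDerived(pmax=pmax, standardized_pmax=pmax * q0, omax=omax)


class ExponentialDemand:
    """Exponential demand model for (price, consumption) observations.

    Parameters
    ----------
    price : array-like
        Unit prices C (> 0), e.g. responses per pellet or per mg.
    consumption : array-like
        Consumption Q (>= 0) at each price.  Zero-consumption points are
        dropped from the log-space fit (log10 undefined) and counted in the
        results diagnostics.
    k : float
        Fixed log10-range constant, held constant during fitting (default 2).
    """

    def __init__(self, price, consumption, k: float = 2.0):
        price = np.asarray(price, dtype=float)
        consumption = np.asarray(consumption, dtype=float)
        if price.shape != consumption.shape or price.ndim != 1:
            raise DemandError("price and consumption must be 1-D arrays of equal length")
        if (price <= 0).any():
            raise DemandError("all prices must be > 0")
        if (consumption < 0).any():
            raise DemandError("consumption must be >= 0")
        if k <= 0:
            raise DemandError("k must be > 0")
        self.price = price
        self.consumption = consumption
        self.k = float(k)

    @classmethod
    def from_points(cls, points: pd.DataFrame, k: float = 2.0) -> "ExponentialDemand":
        """Build from a demand-point table with columns ``unit_price``/``consumption``."""
        return cls(points["unit_price"].to_numpy(), points["consumption"].to_numpy(), k=k)

    def fit(
        self,
        method: str = "ls",
        weights: str = "none",
        irls_rounds: int = 3,
        cap: int | None = None,
    ) -> "ExponentialDemandResults":
        """Fit (q0, alpha); k is held fixed.

        ``method='ls'`` (default) minimizes the sum of squared log10-consumption
        residuals over the points with Q > 0 (zero-consumption points are
        dropped — log10 undefined — and counted in the diagnostics).  With
        ``weights='poisson'`` the residuals are iteratively reweighted by the
        predicted consumption (delta-method inverse variance of the log of a
        count), which removes most of the small-count bias when consumption is
        a noisy integer tally.

        ``method='mle'`` maximizes the Poisson likelihood of the observed
        counts instead, using every point including zeros; ``cap`` declares a
        per-observation ceiling (e.g. a 20-pellet bin cap), handled as right
        censoring.  This is the recommended estimator for count consumption
        data: the zero bins at high prices carry most of the information about
        the decay rate.

        Starts are deterministic: q0 at the maximum observed consumption and
        alpha from a log-spaced grid scan.
        """
        if method == "ls":
            return self._fit_ls(weights=weights, irls_rounds=irls_rounds)
        if method == "mle":
            return self._fit_mle(cap=cap)
        raise DemandError(f"unknown fit method {method!r}")

    # deterministic alpha starting grid shared by both estimators
    _ALPHA_GRID = np.geomspace(1e-6, 10.0, 20)

    def _check_identifiable(self, C):
        if len(C) < 3:
            raise DemandError(f"need >= 3 usable points, got {len(C)}")
        if np.unique(C).size < 2:
            raise DemandError("all prices identical: demand curve unidentifiable")

    def _fit_ls(self, weights: str, irls_rounds: int) -> "ExponentialDemandResults":
        keep = self.consumption > 0
        n_dropped = int((~keep).sum())
        C = self.price[keep]
        y = np.log10(self.consumption[keep])
        self._check_identifiable(C)
        k = self.k
        qmax = float(self.consumption.max())

        def solve(w):
            sw = np.sqrt(w)

            def resid(theta):
                q0, alpha = theta
                return sw * (math.log10(q0) + k * (np.exp(-alpha * q0 * C) - 1.0) - y)

            sses = [float(np.sum(resid((qmax, a)) ** 2)) for a in self._ALPHA_GRID]
            a0 = float(self._ALPHA_GRID[int(np.argmin(sses))])
            return optimize.least_squares(
                resid,
                x0=(qmax, a0),
                bounds=((1e-12, 1e-12), (10.0 * qmax, 10.0)),
                method="trf",
                xtol=1e-13,
                ftol=1e-13,
                gtol=1e-13,
            )

        res = solve(np.ones_like(y))
        if weights == "poisson":
            for _ in range(irls_rounds):
                lam = predict_consumption(*res.x, C, k=k)
                res = solve(np.maximum(lam, 1e-9))
        elif weights != "none":
            raise DemandError(f"unknown weights {weights!r}")
        q0_hat, alpha_hat = (float(v) for v in res.x)
        sse = float(np.sum(res.fun**2))
        dof = len(C) - 2
        bse = np.full(2, np.nan)
        if dof > 0 and res.jac is not None:
            jtj = res.jac.T @ res.jac
            try:
                cov = sse / dof * np.linalg.inv(jtj)
                bse = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                pass
        return ExponentialDemandResults(
            model=self,
            q0=q0_hat,
            alpha=alpha_hat,
            k=k,
            sse=sse,
            n_points=int(len(C)),
            n_dropped_zero=n_dropped,
            converged=bool(res.success),
            bse_q0=float(bse[0]),
            bse_alpha=float(bse[1]),
            optimizer_message=str(res.message),
        )

    def _fit_mle(self, cap: int | None) -> "ExponentialDemandResults":
        from scipy import stats as sps

        C = self.price
        q = self.consumption
        self._check_identifiable(C)
        if not np.allclose(q, np.round(q)):
            raise DemandError("method='mle' requires integer consumption counts")
        k = self.k
        counts = np.round(q).astype(np.int64)

        def nll(log_theta):
            q0, alpha = np.exp(log_theta)
            lam = np.maximum(q0 * 10.0 ** (k * (np.exp(-alpha * q0 * C) - 1.0)), 1e-12)
            ll = sps.poisson.logpmf(counts, lam)
            if cap is not None:
                at_cap = counts >= cap
                if at_cap.any():
                    ll = np.where(
                        at_cap,
                        np.log(np.maximum(sps.poisson.sf(cap - 1, lam), 1e-300)),
                        ll,
                    )
            return -float(ll.sum())

        q0_start = math.log(max(float(q.max()), 1.0))
        best = None
        for a0 in self._ALPHA_GRID[::4]:
            res = optimize.minimize(
                nll,
                x0=(q0_start, math.log(a0)),
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        q0_hat, alpha_hat = (float(v) for v in np.exp(best.x))
        pos = counts > 0
        log_resid = np.log10(counts[pos]) - np.log10(
            predict_consumption(q0_hat, alpha_hat, C[pos], k=k)
        )
        return ExponentialDemandResults(
            model=self,
            q0=q0_hat,
            alpha=alpha_hat,
            k=k,
            sse=float(np.sum(log_resid**2)),
            n_points=int(len(C)),
            n_dropped_zero=0,
            converged=bool(best.success),
            bse_q0=float("nan"),
            bse_alpha=float("nan"),
            optimizer_message=str(best.message),
        )


@dataclass
class ExponentialDemandResults:
    """Fitted demand parameters, uncertainties, and derived price indices."""

    model: ExponentialDemand
    q0: float
    alpha: float
    k: float
    sse: float
    n_points: int
    n_dropped_zero: int
    converged: bool
    bse_q0: float
    bse_alpha: float
    optimizer_message: str = ""

    @property
    def params(self) -> pd.Series:
        return pd.Series({"q0": self.q0, "alpha": self.alpha})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({"q0": self.bse_q0, "alpha": self.bse_alpha})

    @property
    def derived(self) -> DemandDerived:
        return solve_pmax(self)

    @property
    def pmax(self) -> float:
        return self.derived.pmax

    @property
    def standardized_pmax(self) -> float:
        return self.derived.standardized_pmax

    @property
    def omax(self) -> float:
        return self.derived.omax

    def predict(self, price):
        """Predicted consumption at the given price(s)."""
        return predict_consumption(self.q0, self.alpha, price, k=self.k)

    def expenditure(self, price):
        """Predicted expenditure (responses emitted) C * Q(C)."""
        price = np.asarray(price, dtype=float)
        return price * self.predict(price)

    def summary(self) -> str:
        d = self.derived
        lines = [
            "Exponential demand model (log10 Q = log10 Q0 + k(exp(-a Q0 C) - 1))",
            "-" * 68,
            f"{'n points (Q>0)':<24}{self.n_points:>10d}"
            f"    {'dropped (Q=0)':<16}{self.n_dropped_zero:>6d}",
            f"{'k (fixed)':<24}{self.k:>10.4g}    {'converged':<16}{str(self.converged):>6}",
            f"{'SSE (log10 space)':<24}{self.sse:>10.4g}",
            "-" * 68,
            f"{'param':<12}{'estimate':>14}{'std err':>14}",
            f"{'Q0':<12}{self.q0:>14.6g}{self.bse_q0:>14.4g}",
            f"{'alpha':<12}{self.alpha:>14.6g}{self.bse_alpha:>14.4g}",
            "-" * 68,
            f"{'Pmax':<12}{d.pmax:>14.6g}",
            f"{'std Pmax':<12}{d.standardized_pmax:>14.6g}",
            f"{'Omax':<12}{d.omax:>14.6g}",
        ]
        return "\n".join(lines)


def fit_demand(points, k: float = 2.0, **fit_kwargs) -> ExponentialDemandResults:
    """Fit the exponential demand model to a demand-point table or (C, Q) arrays.

    ``points`` may be a DataFrame with ``unit_price``/``consumption`` columns or
    a (price, consumption) pair of sequences.  Keyword arguments are forwarded
    to :meth:`ExponentialDemand.fit` (``method``, ``weights``, ``cap``).
    """
    if isinstance(points, pd.DataFrame):
        return ExponentialDemand.from_points(points, k=k).fit(**fit_kwargs)
    price, consumption = points
    return ExponentialDemand(price, consumption, k=k).fit(**fit_kwargs)


def bins_to_demand_points(
    bins: pd.DataFrame,
    reinforcer_magnitude: float,
    body_weight_g: float | None = None,
) -> pd.DataFrame:
    """Convert threshold-procedure bins to (price, consumption) demand points.

    One point per bin: price C = fr_value / reinforcer_magnitude (responses per
    unit of reinforcer) and consumption Q = reinforcers_earned *
    reinforcer_magnitude, optionally divided by body weight (grams) when
    normalization is requested.  Zero-consumption bins are kept and flagged;
    the fitter drops them from the log-space fit.
    """
    if len(bins) == 0:
        raise DemandError("empty bin collection")
    if reinforcer_magnitude <= 0:
        raise DemandError("reinforcer_magnitude must be > 0")
    fr = bins["fr_value"].to_numpy(dtype=float)
    earned = bins["reinforcers_earned"].to_numpy(dtype=float)
    q = earned * reinforcer_magnitude
    if body_weight_g is not None:
        if body_weight_g <= 0:
            raise DemandError("body_weight_g must be > 0")
        q = q / body_weight_g
    return pd.DataFrame(
        {
            "unit_price": fr / reinforcer_magnitude,
            "consumption": q,
            "zero_consumption": earned == 0,
        }
    )


def doses_to_demand_points(
    injections,
    doses_mg_per_kg,
    body_weight_g: float,
    fr_value: int = 1,
) -> pd.DataFrame:
    """Convert per-dose injection counts from a dose-response test to demand points.

    Under a fixed ratio, each injection of dose d (mg/kg) to an animal of body
    weight w grams delivers d * w/1000 mg of drug, so the unit price is
    C = fr_value / (d * w/1000) responses per mg — price falls as dose rises.
    Consumption is expressed in mg/kg: Q = injections * d.
    """
    injections = np.asarray(injections, dtype=float)
    doses = np.asarray(doses_mg_per_kg, dtype=float)
    if injections.shape != doses.shape:
        raise DemandError("need one injection count per dose")
    if (doses <= 0).any():
        raise DemandError("doses must be > 0")
    if body_weight_g <= 0 or fr_value < 1:
        raise DemandError("body_weight_g must be > 0 and fr_value >= 1")
    mg_per_injection = doses * body_weight_g / 1000.0
    return pd.DataFrame(
        {
            "unit_price": fr_value / mg_per_injection,
            "consumption": injections * doses,
            "zero_consumption": injections == 0,
        }
    )


def pr_breakpoint(completed_ratios, ratio_ladder=PR_RATIO_LADDER) -> int:
    """Largest progressive-ratio requirement completed (0 if none).

    Every completed ratio must lie on the declared ladder.
    """
    ladder = list(ratio_ladder)
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise DemandError("ratio_ladder must be strictly increasing")
    completed = list(completed_ratios)
    off = sorted(set(completed) - set(ladder))
    if off:
        raise DemandError(f"completed ratios not on ladder: {off}")
    return max(completed) if completed else 0


def consumption_change_summary(
    session_totals: dict,
    body_weight_g: float,
    schedule_a: str = "VR3",
    schedule_b: str = "VR5",
) -> float:
    """Body-weight-normalized change in mean consumption between two schedules.

    Returns (mean under ``schedule_b`` - mean under ``schedule_a``) /
    body_weight_g — e.g. the mg/g shift in sucrose intake from VR3 to VR5.
    """
    for s in (schedule_a, schedule_b):
        if s not in session_totals or len(np.atleast_1d(session_totals[s])) == 0:
            raise DemandError(f"missing consumption totals for schedule {s!r}")
    if body_weight_g <= 0:
        raise DemandError("body_weight_g must be > 0")
    mean_a = float(np.mean(session_totals[schedule_a]))
    mean_b = float(np.mean(session_totals[schedule_b]))
    return (mean_b - mean_a) / body_weight_g
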