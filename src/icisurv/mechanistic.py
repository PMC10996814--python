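"""Mechanistic tumor-burden model and mathematical biomarkers.

The master equation for normalized tumor burden rho(t) under immune
checkpoint inhibitor therapy is the logistic-form ODE

    d(rho)/dt = rho * (alpha0 - mu + Lambda*mu) + rho**2 * (-Lambda*mu),

where alpha0 is the intrinsic (pre-treatment) growth rate [1/day], mu is the
tumor kill rate due to therapy [1/day] and Lambda is the dimensionless
anti-tumor immune state.  Burden is normalized so rho(0) = 1.  Writing
a = alpha0 - mu + Lambda*mu and b = Lambda*mu the equation is
d(rho)/dt = a*rho - b*rho**2 with the closed-form solution

    rho(t) = a * exp(a t) / (a + b * (exp(a t) - 1))     (a != 0)
    rho(t) = 1 / (1 + b t)                               (a == 0)

The per-patient "mathematical biomarkers" are mu, Lambda and alpha1, the
effective growth rate between treatment start and first restaging,
alpha1 = ln(rho(t1)) / t1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "TumorBurdenSeries",
    "MechanisticParams",
    "BlowUpError",
    "InsufficientDataError",
    "FitFailureError",
    "ALPHA1_THRESHOLD",
    "solve_tumor_burden",
    "fit_mechanistic_params",
    "compute_alpha1",
    "classify_alpha1",
]

#: Prognostic threshold on alpha1 [1/day]: favorable iff alpha1 <= 0.002.
ALPHA1_THRESHOLD = 0.002


class BlowUpError(ValueError):
    """The closed-form solution diverges before the largest requested time."""


class InsufficientDataError(ValueError):
    """Too few post-baseline observations to fit the model."""


class FitFailureError(RuntimeError):
    """No optimizer start converged to a finite optimum."""


@dataclass(frozen=True)
class TumorBurdenSeries:
    """Longitudinal normalized tumor burden for one patient.

    ``times`` are days since treatment start (first element 0, strictly
    increasing); ``burdens`` are tumor burden divided by burden at t=0,
    so ``burdens[0] == 1``.
    """

    patient_id: str
    times: np.ndarray
    burdens: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.burdens, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "burdens", y)
        if t.ndim != 1 or y.shape != t.shape or t.size < 2:
            raise ValueError("need matched 1-d times/burdens of length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("first observation must be at t = 0")
        if abs(y[0] - 1.0) > 1e-9:
            raise ValueError("burden at t = 0 must be 1 (normalized)")
        if not np.all(y > 0):
            raise ValueError("burdens must be positive")


@dataclass(frozen=True)
class MechanisticParams:
    """Mathematical biomarkers for one patient.

    Negative mu and Lambda are permitted: they arise when the tumor grows
    faster after treatment than before.
    """

    alpha0: float
    mu: float
    Lambda: float
    alpha1: float = np.nan

    @property
    def a(self) -> float:
        """Linear growth coefficient alpha0 - mu + Lambda*mu."""
        return self.alpha0 - self.mu + self.Lambda * self.mu

    @property
    def b(self) -> float:
        """Quadratic (saturation) coefficient Lambda*mu."""
        return self.Lambda * self.mu


def _solve_ab(a: float, b: float, times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(times)) or np.any(times < 0):
        raise ValueError("times must be finite and non-negative")
    tmax = times.max(initial=0.0)
    t_star = _blowup_time(a, b)
    if t_star is not None and tmax >= t_star:
        raise BlowUpError(
            f"solution diverges at t = {t_star:.6g} d, before requested t = {tmax:.6g} d"
        )
    if a == 0.0:
        return 1.0 / (1.0 + b * times)
    # Equivalent to a*e^{at} / (a + b*(e^{at}-1)); this form is
    # cancellation-free for tiny |a t| and exact at the a == b equilibrium.
    with np.errstate(over="ignore"):
        return a / ((a - b) * np.exp(-a * times) + b)


def _blowup_time(a: float, b: float) -> float | None:
    """Smallest t > 0 where the closed-form denominator vanishes, if any."""
    if a == 0.0:
        return -1.0 / b if b < 0 else None
    # a + b*(e^{at}-1) = 0  =>  e^{at} = 1 - a/b
    if b == 0.0:
        return None
    ratio = 1.0 - a / b
    if ratio <= 0:
        return None
    t = np.log(ratio) / a
    return t if t > 0 else None


def solve_tumor_burden(params: MechanisticParams, times: np.ndarray) -> np.ndarray:
    """Closed-form normalized burden rho(t) of the master equation.

    Raises :class:`BlowUpError` if the solution diverges in finite time
    before the largest requested time (possible when Lambda*mu < 0).
    """
    return _solve_ab(params.a, params.b, times)


def compute_alpha1(burden_at_t1: float, t1: float) -> float:
    """Growth rate at first restaging, alpha1 = ln(rho(t1)) / t1 [1/day]."""
    if not (burden_at_t1 > 0):
        raise ValueError("burden at first restaging must be positive")
    if not (t1 > 0):
        raise ValueError("first-restaging time must be positive")
    return float(np.log(burden_at_t1) / t1)


def classify_alpha1(alpha1: float) -> str:
    """Prognostic group from alpha1: 'favorable' iff alpha1 <= 0.002 / day."""
    if not np.isfinite(alpha1):
        raise ValueError("alpha1 must be finite")
    return "favorable" if alpha1 <= ALPHA1_THRESHOLD else "unfavorable"


def _canonical_mu_lambda(alpha0: float, a: float, b: float) -> tuple[float, float]:
    # (mu, Lambda) are only jointly identified given alpha0; the canonical
    # representative inverts a = alpha0 - mu + b, i.e. mu = alpha0 - a + b.
    mu = alpha0 - a + b
    if mu == 0.0:
        return 0.0, 0.0
    return mu, b / mu


def fit_mechanistic_params(
    series: TumorBurdenSeries,
    alpha0: float,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[MechanisticParams, float]:
    """Estimate (mu, Lambda) from a burden series with alpha0 fixed.

    Minimizes the sum of squared residuals between log observed burden and
    log model burden (a multiplicative error model, natural for volumes)
    over the identifiable pair (a, b), by Nelder-Mead from ``n_starts``
    deterministic random starts, then maps back to the canonical
    (mu, Lambda).  Returns ``(params, rss)``; ``params.alpha1`` is computed
    from the first post-baseline observation.
    """
    t = series.times
    logy = np.log(series.burdens)
    if t.size - 1 < 2:
        raise InsufficientDataError("need at least 2 post-baseline observations")

    def objective(ab: np.ndarray) -> float:
        a, b = ab
        try:
            model = _solve_ab(a, b, t)
        except BlowUpError:
            return np.inf
        if np.any(model <= 0) or not np.all(np.isfinite(model)):
            return np.inf
        r = logy - np.log(model)
        return float(r @ r)

    rng = np.random.default_rng(seed)
    # crude slope-based start plus random perturbations
    slope = (logy[-1] - logy[0]) / (t[-1] - t[0])
    starts = [np.array([slope, 0.0])]
    for _ in range(n_starts - 1):
        starts.append(np.array([slope + rng.normal(0, 0.02), rng.normal(0, 0.02)]))

    best: optimize.OptimizeResult | None = None
    for x0 in starts:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # inf objective values in blow-up regions trip harmless
            # RuntimeWarnings inside the simplex bookkeeping
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
            )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError("all optimizer starts diverged")

    a, b = best.x
    # canonicalize the degenerate flat case to exactly (0, 0)
    if abs(a) < 1e-10 and abs(b) < 1e-10 and np.allclose(logy, 0.0, atol=1e-12):
        a, b = 0.0, 0.0
    mu, Lambda = _canonical_mu_lambda(alpha0, a, b)
    alpha1 = compute_alpha1(series.burdens[1], series.times[1])
    return MechanisticParams(alpha0=alpha0, mu=mu, Lambda=Lambda, alpha1=alpha1), float(best.fun)


def fit_biomarker_table(burden, alpha0_by_patient=None, seed: int = 0):
    """Fit biomarkers for every patient in a long-form burden table.

    ``burden`` is a DataFrame with columns ``patient_id, time_days,
    normalized_burden``.  ``alpha0_by_patient`` maps patient id to alpha0;
    missing patients default to 0 with a warning.  Returns a DataFrame with
    columns ``patient_id, alpha0, mu, Lambda, alpha1, rss, prognostic_group``.
    """
    import pandas as pd

    rows = []
    for pid, grp in burden.groupby("patient_id", sort=False):
        grp = grp.sort_values("time_days")
        series = TumorBurdenSeries(
            patient_id=str(pid),
            times=grp["time_days"].to_numpy(float),
            burdens=grp["normalized_burden"].to_numpy(float),
        )
        if alpha0_by_patient is None or pid not in alpha0_by_patient:
            warnings.warn(f"no alpha0 supplied for patient {pid}; defaulting to 0")
            alpha0 = 0.0
        else:
            alpha0 = float(alpha0_by_patient[pid])
        params, rss = fit_mechanistic_params(series, alpha0, seed=seed)
        rows.append(
            {
                "patient_id": pid,
                "alpha0": params.alpha0,
                "mu": params.mu,
                "Lambda": params.Lambda,
                "alpha1": params.alpha1,
                "rss": rss,
                "prognostic_group": classify_alpha1(params.alpha1),
            }
        )
    return pd.DataFrame(rows)
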