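"""Adsorption-trace analysis: ΔΠ extraction, biexponential kinetics fits,
and maximum-insertion-pressure (MIP) extrapolation.

An adsorption run records surface pressure Π(t) after injecting polymer
under a lipid monolayer held at initial pressure Π_ini.  The pressure rise
ΔΠ = Π_max − Π_ini shrinks as Π_ini grows; the x-intercept of a straight
line through (Π_ini, ΔΠ) points is the MIP (exclusion pressure): the
initial pressure at which the polymer can no longer insert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import KineticsFitError, NoExclusionError


@dataclass(frozen=True)
class AdsorptionTrace:
    """Π(t) record at fixed initial pressure.

    times in s (strictly increasing), pressures in mN/m.  The first sample
    must sit within 1 mN/m of ``pi_ini`` (the film is equilibrated before
    injection).
    """

    times: np.ndarray
    pressures: np.ndarray
    pi_ini: float
    polymer_concentration_nM: float | None = None
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pressures", p)
        if t.size != p.size or t.size == 0:
            raise ValueError("times and pressures must be equal-length, non-empty")
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if self.pi_ini < 0:
            raise ValueError("pi_ini must be non-negative")
        if abs(p[0] - self.pi_ini) > 1.0:
            raise ValueError(
                f"first sampled pressure {p[0]:g} is more than 1 mN/m from "
                f"pi_ini={self.pi_ini:g}"
            )


@dataclass(frozen=True)
class KineticsFit:
    """Result of fitting Π(t) = Π_eq − Σᵢ aᵢ·exp(−t/τᵢ).

    ``order`` is 1 or 2; amplitudes are non-negative; time constants are
    sorted so τ_fast < τ_slow.  ``aicc`` is the small-sample-corrected
    information criterion used for order selection.
    """

    order: int
    pi_eq: float
    amplitudes: tuple[float, ...]
    time_constants: tuple[float, ...]
    aicc: float
    residual_rms: float

    def __post_init__(self):
        if self.order not in (1, 2) or len(self.amplitudes) != self.order:
            raise ValueError("order must be 1 or 2 and match component count")
        if len(self.time_constants) != self.order:
            raise ValueError("time constant count must match order")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if any(tau <= 0 for tau in self.time_constants):
            raise ValueError("time constants must be positive")
        if self.order == 2 and not self.time_constants[0] < self.time_constants[1]:
            raise ValueError("time constants must satisfy tau_fast < tau_slow")

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.pi_eq)
        for a, tau in zip(self.amplitudes, self.time_constants):
            out = out - a * np.exp(-t / tau)
        return out


@dataclass(frozen=True)
class MIPResult:
    """Least-squares line through (Π_ini, ΔΠ) and its x-intercept."""

    slope: float
    intercept: float
    mip: float
    mip_stderr: float
    n_points: int

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError("a meaningful extrapolation needs slope < 0")


def delta_pi(
    trace: AdsorptionTrace,
    mode: str = "max",
    fit: KineticsFit | None = None,
) -> float:
    """Pressure rise ΔΠ of one trace.

    mode ``"max"``: max observed pressure minus Π_ini, floored at 0 (the
    conventional definition).  mode ``"fitted_eq"``: fitted equilibrium
    pressure minus Π_ini, for traces that have not fully equilibrated; a
    fit is run if one is not supplied.
    """
    if mode == "max":
        return max(0.0, float(trace.pressures.max()) - trace.pi_ini)
    if mode == "fitted_eq":
        if fit is None:
            fit = fit_adsorption_kinetics(trace)
        return fit.pi_eq - trace.pi_ini
    raise ValueError(f"unknown mode {mode!r}")


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, n * 1e-30)  # guard log(0) on exact fits
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def _fit_order(t, p, order: int):
    """Best bounded least-squares fit of the given order over deterministic
    log-spaced time-constant starts.  Returns (params, rss) or None."""
    span = max(t[-1] - t[0], 1e-6)
    dt = max(np.min(np.diff(t)), span / (10 * t.size)) if t.size > 1 else span
    pi_eq0 = float(p[-1])
    amp0 = max(float(pi_eq0 - p[0]), 1e-3)
    tau_grid = np.geomspace(max(2 * dt, span / 300), 2 * span, 6)

    if order == 1:
        def model(tt, pi_eq, a, tau):
            return pi_eq - a * np.exp(-tt / tau)

        lower = [-np.inf, 0.0, 1e-9]
        upper = [np.inf, np.inf, np.inf]
        starts = [(pi_eq0, amp0, tau) for tau in tau_grid]
    else:
        def model(tt, pi_eq, a1, tau1, a2, tau2):
            return pi_eq - a1 * np.exp(-tt / tau1) - a2 * np.exp(-tt / tau2)

        lower = [-np.inf, 0.0, 1e-9, 0.0, 1e-9]
        upper = [np.inf, np.inf, np.inf, np.inf, np.inf]
        starts = [
            (pi_eq0, amp0 / 2, tau1, amp0 / 2, tau2)
            for i, tau1 in enumerate(tau_grid)
            for tau2 in tau_grid[i + 1 :]
        ]

    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                model, t, p, p0=p0, bounds=(lower, upper), maxfev=5000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(t, *popt) - p) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    return best


#: Identifiability guards for accepting the 2-component model: each
#: amplitude must carry at least this fraction of the total, and the time
#: constants must be separated by at least this ratio.  Sums of two
#: exponentials with closer time constants are numerically
#: indistinguishable from a single exponential at realistic noise levels,
#: so such fits report order 1.
MIN_AMPLITUDE_SHARE = 0.05
MIN_TAU_RATIO = 3.0


def fit_adsorption_kinetics(trace: AdsorptionTrace) -> KineticsFit:
    """Fit one- and two-exponential approach-to-equilibrium models.

    Both orders are fitted by bounded least squares from deterministic
    log-spaced time-constant starts (reproducible without seeds), and the
    order with the lower AICc is returned; ties (ΔAICc < 2) favor order 1,
    as does a 2-component fit whose components are not identifiable
    (amplitude share below 5% or τ ratio below 2).
    """
    t = trace.times
    p = trace.pressures
    n = t.size
    if n < 10:
        raise KineticsFitError(f"need at least 10 samples, have {n}")

    fit1 = _fit_order(t, p, 1)
    fit2 = _fit_order(t, p, 2)
    if fit1 is None and fit2 is None:
        raise KineticsFitError(
            "neither model order converged",
            diagnostics={"n": n, "span_s": float(t[-1] - t[0])},
        )

    results: dict[int, KineticsFit] = {}
    if fit1 is not None:
        popt, rss = fit1
        results[1] = KineticsFit(
            order=1,
            pi_eq=float(popt[0]),
            amplitudes=(float(popt[1]),),
            time_constants=(float(popt[2]),),
            aicc=_aicc(rss, n, 3),
            residual_rms=float(np.sqrt(rss / n)),
        )
    if fit2 is not None:
        popt, rss = fit2
        comps = sorted([(popt[2], popt[1]), (popt[4], popt[3])])
        (tau_f, a_f), (tau_s, a_s) = comps
        if tau_f == tau_s:
            tau_s = np.nextafter(tau_s, np.inf)
        results[2] = KineticsFit(
            order=2,
            pi_eq=float(popt[0]),
            amplitudes=(float(a_f), float(a_s)),
            time_constants=(float(tau_f), float(tau_s)),
            aicc=_aicc(rss, n, 5),
            residual_rms=float(np.sqrt(rss / n)),
        )

    chosen = _select_order(results)
    tau_slow = chosen.time_constants[-1]
    if t[-1] - t[0] < 3 * tau_slow:
        warnings.warn(
            f"trace spans {t[-1] - t[0]:g} s, less than 3x the fitted slow "
            f"time constant ({tau_slow:g} s); equilibrium values are "
            "extrapolated",
            stacklevel=2,
        )
    return chosen


def _select_order(results: dict[int, "KineticsFit"]) -> "KineticsFit":
    if 2 not in results:
        return results[1]
    if 1 not in results:
        return results[2]
    f2 = results[2]
    total = sum(f2.amplitudes)
    identifiable = (
        total > 0
        and min(f2.amplitudes) / total >= MIN_AMPLITUDE_SHARE
        and f2.time_constants[1] / f2.time_constants[0] >= MIN_TAU_RATIO
    )
    if identifiable and results[1].aicc - f2.aicc >= 2.0:
        return f2
    return results[1]


def mip_from_series(points) -> MIPResult:
    """Ordinary least-squares MIP extrapolation from (Π_ini, ΔΠ) points.

    Points with ΔΠ <= 0 are excluded (the polymer did not insert there);
    at least 3 points with distinct Π_ini must remain.  The MIP is the
    x-intercept −intercept/slope, with a first-order (delta-method)
    standard error propagated from the slope/intercept covariance.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (pi_ini, delta_pi) pairs")
    pts = pts[pts[:, 1] > 0]
    x, y = pts[:, 0], pts[:, 1]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points with positive delta_pi")
    if np.ptp(x) == 0:
        raise ValueError("pi_ini values must not all be equal")

    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    if slope >= 0:
        raise NoExclusionError(
            "delta_pi does not decrease with pi_ini: no exclusion pressure "
            "in the sampled range"
        )

    resid = y - (intercept + slope * x)
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    var_slope = s2 / sxx
    var_int = s2 * (1.0 / n + xbar**2 / sxx)
    cov_sb = -s2 * xbar / sxx

    mip = -intercept / slope
    # delta method: d(mip)/d(intercept) = -1/slope, d(mip)/d(slope) = intercept/slope^2
    gi = -1.0 / slope
    gs = intercept / slope**2
    var_mip = gi * gi * var_int + gs * gs * var_slope + 2 * gi * gs * cov_sb
    mip_stderr = float(np.sqrt(max(var_mip, 0.0)))

    return MIPResult(
        slope=slope,
        intercept=intercept,
        mip=float(mip),
        mip_stderr=mip_stderr,
        n_points=int(n),
    )
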