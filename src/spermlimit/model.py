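"""Sperm–oocyte negative-feedback dynamics of *C. elegans* egg laying.

A hermaphrodite makes a fixed pool of ``S_0`` self-sperm before switching its
germline to oogenesis. Oocytes are produced at a constant rate ``k_o`` and the
fertilization flux is proportional to the product of available oocytes and
remaining sperm (the sperm-secreted MSP hormone stimulates oocyte maturation
and ovulation in a dose-dependent way). With E = cumulative fertilized eggs,
O = mature oocytes and S = remaining sperm::

    E' = k_f * O * S
    O' = k_o - E'
    S' = -E'

with initial condition (S, O, E)(0) = (S_0, 0, 0). Each fertilization consumes
one sperm and one oocyte, so E + S = S_0 and O + E = k_o * t at all times.

The module provides an adaptive Runge-Kutta (Dormand-Prince) numeric solution,
an overflow-safe closed-form solution, and derived quantities used by the
fitting and quantitative-genetics layers: the instantaneous egg-laying rate,
eggs laid in an assay window, genotype effect-size curves, remaining sperm,
and the mated (sperm top-up) scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import erfcx

__all__ = [
    "EggLayingParams",
    "ReproductiveState",
    "Trajectory",
    "AnalyticOverflowError",
    "IntegrationError",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "simulate_numeric",
    "analytic_state",
    "analytic_trajectory",
    "egg_rate",
    "window_eggs",
    "effect_size",
    "effect_size_crossings",
    "sperm_remaining",
    "simulate_with_mating",
]

#: default integration tolerances; conservation must be testable at 1e-6
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class AnalyticOverflowError(ArithmeticError):
    """Closed-form evaluation left the floating-point range even in scaled form."""


class IntegrationError(RuntimeError):
    """The adaptive ODE solver failed (e.g. step-size underflow)."""


@dataclass(frozen=True)
class EggLayingParams:
    """Model parameters for one strain / genotype class.

    Attributes
    ----------
    k_o : float
        Oocyte generation rate, oocytes / animal / hour.
    k_f : float
        Fertilization rate constant, 1 / (sperm * hour).
    s_0 : float
        Initial self-sperm count, cells / animal. Equals lifetime
        self-fecundity, since every fertilization consumes one sperm.
    """

    k_o: float
    k_f: float
    s_0: float

    def __post_init__(self) -> None:
        for name in ("k_o", "k_f", "s_0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"{name} must be a positive finite scalar, got {v!r}"
                )

    def replace(self, **kw) -> "EggLayingParams":
        d = {"k_o": self.k_o, "k_f": self.k_f, "s_0": self.s_0}
        d.update(kw)
        return EggLayingParams(**d)


@dataclass(frozen=True)
class ReproductiveState:
    """State (t, S, O, E) of one animal at time t hours post-L4."""

    t: float
    S: float
    O: float
    E: float


@dataclass
class Trajectory:
    """States at strictly increasing times, with solution provenance."""

    times: np.ndarray
    S: np.ndarray
    O: np.ndarray
    E: np.ndarray
    provenance: str = "numeric"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.O = np.asarray(self.O, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> ReproductiveState:
        return ReproductiveState(
            float(self.times[i]), float(self.S[i]), float(self.O[i]), float(self.E[i])
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "S": self.S, "O": self.O, "E": self.E}
        )


def _check_times(times: Sequence[float]) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[0] < 0:
        raise ValueError("times must be non-negative")
    return t


def _rhs(params: EggLayingParams):
    k_o, k_f = params.k_o, params.k_f

    def f(t, y):
        S, O, E = y
        flux = k_f * O * S
        return (-flux, k_o - flux, flux)

    return f


def simulate_numeric(
    params: EggLayingParams,
    times: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the feedback ODEs with an adaptive Dormand-Prince RK pair.

    Returns states at the requested (strictly increasing, non-negative) times,
    always starting the integration from (S_0, 0, 0) at t = 0.
    """
    t = _check_times(times)
    y = np.empty((3, t.size))
    y0 = (params.s_0, 0.0, 0.0)
    zero_mask = t == 0.0
    y[:, zero_mask] = np.array(y0)[:, None]
    t_pos = t[~zero_mask]
    if t_pos.size:
        sol = solve_ivp(
            _rhs(params),
            (0.0, float(t_pos[-1])),
            y0,
            method="RK45",  # explicit Dormand-Prince 5(4) embedded pair
            t_eval=t_pos,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed for params {params}: {sol.message}"
            )
        y[:, ~zero_mask] = sol.y
    S, O, E = np.maximum(y, 0.0)
    return Trajectory(t, S, O, E, provenance="numeric")


def _analytic_soe(params: EggLayingParams, t: np.ndarray):
    """Closed-form (S, O, E) arrays; overflow-safe via erfcx branches.

    Using the conservation relations, S obeys the Riccati-type equation
    S' = -k_f * S * (S + k_o t - S_0); the substitution u = 1/S linearizes it
    and the integrating factor produces an erf integral. Rearranged so that
    every exponential argument is non-positive:

        x = sqrt(k_f / 2 k_o) * (k_o t - S_0),   b = sqrt(k_f / 2 k_o) * S_0
        c = sqrt(pi k_f / 2 k_o)

        x <= 0:  1/S = exp(x^2 - b^2) * (1/S_0 - c*erfcx(b)) + c*erfcx(-x)
        x  > 0:  S = exp(-x^2) / (exp(-b^2)/S_0
                                  + c*(2 - exp(-x^2) erfcx(x) - exp(-b^2) erfcx(b)))

    Naive evaluation of the textbook erf form overflows once
    k_f S_0^2 / (2 k_o) exceeds ~709; here x^2 <= b^2 whenever x <= 0, so all
    exponentials are bounded by 1 on the branch where cancellation matters.
    """
    k_o, k_f, s_0 = params.k_o, params.k_f, params.s_0
    kk = math.sqrt(k_f / (2.0 * k_o))
    b = kk * s_0
    c = math.sqrt(math.pi * k_f / (2.0 * k_o))
    with np.errstate(over="ignore", invalid="ignore"):
        d = 1.0 / s_0 - c * erfcx(b)  # > 0 analytically; ~ 1/(2 S_0 b^2)
    if not np.isfinite(d) or d <= 0.0:
        raise AnalyticOverflowError(
            f"scaled closed form degenerate for params {params}; "
            "use simulate_numeric"
        )
    x = kk * (k_o * t - s_0)
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        inv_s_neg = np.exp(x * x - b * b) * d + c * erfcx(-x)
        s_neg = 1.0 / inv_s_neg
        f_pos = 2.0 - np.exp(-x * x) * erfcx(np.abs(x)) - np.exp(-b * b) * erfcx(b)
        denom_pos = np.exp(-b * b) / s_0 + c * f_pos
        s_pos = np.exp(-x * x) / denom_pos
    S = np.where(x <= 0.0, s_neg, s_pos)
    if not np.all(np.isfinite(S)):
        raise AnalyticOverflowError(
            f"closed-form sperm count not finite for params {params}"
        )
    S = np.minimum(S, s_0)
    E = s_0 - S
    O = np.maximum(k_o * t - E, 0.0)
    return S, O, E


def analytic_trajectory(params: EggLayingParams, times: Sequence[float]) -> Trajectory:
    """Closed-form solution evaluated at the requested times."""
    t = _check_times(times)
    S, O, E = _analytic_soe(params, t)
    return Trajectory(t, S, O, E, provenance="analytic")


def analytic_state(params: EggLayingParams, t: float) -> ReproductiveState:
    """Closed-form state at a single time t >= 0 hours post-L4."""
    if t < 0:
        raise ValueError("t must be non-negative")
    S, O, E = _analytic_soe(params, np.asarray([float(t)]))
    return ReproductiveState(float(t), float(S[0]), float(O[0]), float(E[0]))


def _soe(params: EggLayingParams, t: np.ndarray):
    """Closed form with automatic fall-back to the numeric solver."""
    try:
        return _analytic_soe(params, t)
    except AnalyticOverflowError:
        order = np.argsort(t, kind="stable")
        ts = np.unique(t[order])
        traj = simulate_numeric(params, ts if ts[0] > 0 else ts)
        idx = np.searchsorted(ts, t)
        return traj.S[idx], traj.O[idx], traj.E[idx]


def egg_rate(params: EggLayingParams, t) -> np.ndarray | float:
    """Instantaneous egg-laying rate k_f * O(t) * S(t), eggs/animal/hour."""
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(arr < 0):
        raise ValueError("t must be non-negative")
    S, O, _ = _soe(params, arr)
    rate = params.k_f * O * S
    return rate if np.ndim(t) else float(rate[0])


def window_eggs(params: EggLayingParams, t0: float, t1: float) -> float:
    """Eggs laid per animal in the window [t0, t1]: E(t1) - E(t0)."""
    if t1 < t0 or t0 < 0:
        raise ValueError("require 0 <= t0 <= t1")
    if t1 == t0:
        return 0.0
    _, _, E = _soe(params, np.asarray([float(t0), float(t1)]))
    return float(max(E[1] - E[0], 0.0))


def effect_size(
    params_a: EggLayingParams,
    params_b: EggLayingParams,
    times,
    mode: str = "rate",
) -> np.ndarray:
    """Effect-size curve between two genotype classes.

    mode="rate": egg_rate(a, t) - egg_rate(b, t) at each time in `times`.
    mode="window": `times` is a sequence of (start, end) assay windows; the
    difference of per-animal window eggs divided by window length (i.e. mean
    rate difference over each window), matching how the assays compare strains.
    """
    if mode == "rate":
        t = np.atleast_1d(np.asarray(times, dtype=float))
        return np.asarray(egg_rate(params_a, t)) - np.asarray(egg_rate(params_b, t))
    if mode == "window":
        out = []
        for t0, t1 in times:
            width = t1 - t0
            if width <= 0:
                raise ValueError("windows must have positive length")
            out.append(
                (window_eggs(params_a, t0, t1) - window_eggs(params_b, t0, t1)) / width
            )
        return np.asarray(out)
    raise ValueError(f"unknown mode {mode!r}")


def effect_size_crossings(
    params_a: EggLayingParams,
    params_b: EggLayingParams,
    t_max: float | None = None,
    n_grid: int = 2001,
    xtol: float = 1e-6,
) -> list[float]:
    """Zero crossings of the rate effect-size curve on (0, t_max].

    Bracketing on a dense grid followed by bisection (Brent) to `xtol` hours.
    Default horizon: ten times the slower class's sperm-exhaustion scale.
    """
    if t_max is None:
        t_max = 10.0 * max(params_a.s_0 / params_a.k_o, params_b.s_0 / params_b.k_o)
    grid = np.linspace(0.0, t_max, n_grid)[1:]

    def diff(t):
        return float(
            egg_rate(params_a, float(t)) - egg_rate(params_b, float(t))
        )

    vals = effect_size(params_a, params_b, grid, mode="rate")
    crossings: list[float] = []
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        crossings.append(brentq(diff, grid[i], grid[i + 1], xtol=xtol))
    # grid points that are exact zeros between opposite signs
    for i in np.nonzero(sign == 0)[0]:
        if 0 < i < sign.size - 1 and sign[i - 1] * sign[i + 1] < 0:
            crossings.append(float(grid[i]))
    return sorted(crossings)


def sperm_remaining(params: EggLayingParams, t) -> np.ndarray | float:
    """Remaining self-sperm S(t); strictly decreasing while S > 0."""
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(arr < 0):
        raise ValueError("t must be non-negative")
    S, _, _ = _soe(params, arr)
    return S if np.ndim(t) else float(S[0])


def simulate_with_mating(
    params: EggLayingParams,
    t_mate: float,
    sperm_added: float,
    times: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate with a sperm top-up S(t_mate+) = S(t_mate-) + sperm_added.

    Mating transfers male sperm into the spermatheca (~1000 per successful
    mating); after t_mate the conservation relation becomes
    E + S = S_0 + sperm_added.
    """
    if t_mate < 0:
        raise ValueError("t_mate must be non-negative")
    if sperm_added < 0:
        raise ValueError("sperm_added must be non-negative")
    t = _check_times(times)
    if sperm_added == 0:
        return simulate_numeric(params, t, rtol=rtol, atol=atol)

    pre_mask = t <= t_mate
    y = np.empty((3, t.size))

    pre = simulate_numeric(params, np.append(t[pre_mask], t_mate)
                           if (not pre_mask.any() or t[pre_mask][-1] < t_mate)
                           else t[pre_mask],
                           rtol=rtol, atol=atol)
    if pre_mask.any():
        n_pre = int(pre_mask.sum())
        y[0, :n_pre] = pre.S[:n_pre]
        y[1, :n_pre] = pre.O[:n_pre]
        y[2, :n_pre] = pre.E[:n_pre]
    state_at_mate = (pre.S[-1], pre.O[-1], pre.E[-1])

    post_t = t[~pre_mask]
    if post_t.size:
        y0 = (state_at_mate[0] + sperm_added, state_at_mate[1], state_at_mate[2])
        sol = solve_ivp(
            _rhs(params),
            (float(t_mate), float(post_t[-1])),
            y0,
            method="RK45",
            t_eval=post_t,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"post-mating integration failed for params {params}: {sol.message}"
            )
        y[:, ~pre_mask] = sol.y
    S, O, E = np.maximum(y, 0.0)
    return Trajectory(t, S, O, E, provenance="numeric-mating")
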