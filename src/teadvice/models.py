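"""Dynamical systems supplying targets and experts.

Two chaotic benchmark maps (Henon, Ikeda) generate scalar series via the
observable x + y, and a piecewise-linear model of prostate-cancer cell
populations under intermittent androgen suppression (IAS) generates PSA
trajectories.

The IAS model tracks three cell compartments: androgen-dependent cells x1,
reversibly androgen-independent cells x2, and irreversibly independent cells
x3.  On treatment, x1 may convert to x2 or x3 (six rate coefficients
d1..d6); off treatment, x2 may revert to x1 while x3 cannot revert (four
coefficients e1..e4).  PSA is modeled as x1 + x2 + x3.  Each treatment piece
is a linear ODE x' = A x solved exactly with the matrix exponential; time is
continuous in days and measurement times are arbitrary reals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .core import TimeSeries

__all__ = [
    "IASParams", "CellState", "henon_series", "ikeda_series", "ias_simulate",
]


@dataclass(frozen=True)
class IASParams:
    """Rate coefficients of the piecewise-linear IAS model (per day).

    On treatment:  x1' = d1*x1;  x2' = d2*x1 + d3*x2;  x3' = d4*x1 + d5*x2 + d6*x3.
    Off treatment: x1' = e1*x1 + e2*x2;  x2' = e3*x2;  x3' = e4*x3.
    """

    on_rates: Tuple[float, ...] = (0.0,) * 6
    off_rates: Tuple[float, ...] = (0.0,) * 4
    id: str = ""

    def __post_init__(self) -> None:
        on = tuple(float(v) for v in self.on_rates)
        off = tuple(float(v) for v in self.off_rates)
        if len(on) != 6 or len(off) != 4:
            raise ValueError("need 6 on-treatment and 4 off-treatment rates")
        if not all(math.isfinite(v) for v in on + off):
            raise ValueError("rates must be finite")
        object.__setattr__(self, "on_rates", on)
        object.__setattr__(self, "off_rates", off)

    def on_matrix(self) -> np.ndarray:
        d1, d2, d3, d4, d5, d6 = self.on_rates
        return np.array([[d1, 0.0, 0.0], [d2, d3, 0.0], [d4, d5, d6]])

    def off_matrix(self) -> np.ndarray:
        e1, e2, e3, e4 = self.off_rates
        return np.array([[e1, e2, 0.0], [0.0, e3, 0.0], [0.0, 0.0, e4]])


@dataclass(frozen=True)
class CellState:
    """Cell-population burdens (PSA-equivalent units); physical states are
    componentwise nonnegative."""

    x1: float
    x2: float
    x3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], dtype=float)

    @property
    def psa(self) -> float:
        return self.x1 + self.x2 + self.x3


def _iterate_map(step, x0: float, y0: float, n: int, transient: int) -> TimeSeries:
    if n < 1:
        raise ValueError("n must be >= 1")
    if transient < 0:
        raise ValueError("transient must be >= 0")
    x, y = float(x0), float(y0)
    for _ in range(transient):
        x, y = step(x, y)
    out = np.empty(n)
    for k in range(n):
        out[k] = x + y
        x, y = step(x, y)
    if not np.all(np.isfinite(out)) or abs(out).max() > 1e12:
        raise OverflowError("map orbit diverged to non-finite values")
    return TimeSeries.from_values(out)


def henon_series(a: float = 1.35, b: float = 0.15, x0: float = 0.0,
                 y0: float = 0.0, n: int = 100, transient: int = 1000) -> TimeSeries:
    """Observable x + y of the Henon map x' = 1 - a*x**2 + y, y' = b*x.

    The default (a, b) = (1.35, 0.15) lies in a chaotic regime; the
    ``transient`` iterations are discarded so the recorded orbit sits on the
    attractor.
    """
    return _iterate_map(lambda x, y: (1.0 - a * x * x + y, b * x), x0, y0, n, transient)


def ikeda_series(u: float = 0.9, x0: float = 0.0, y0: float = 0.0,
                 n: int = 100, transient: int = 1000) -> TimeSeries:
    """Observable x + y of the Ikeda map with phase tau = 0.4 - 6/(1+x**2+y**2):

    x' = 1 + u*(x*cos(tau) - y*sin(tau)),  y' = u*(x*sin(tau) + y*cos(tau)).
    """

    def step(x: float, y: float):
        tau = 0.4 - 6.0 / (1.0 + x * x + y * y)
        c, s = math.cos(tau), math.sin(tau)
        return 1.0 + u * (x * c - y * s), u * (x * s + y * c)

    return _iterate_map(step, x0, y0, n, transient)


def ias_simulate(
    params: IASParams,
    initial: CellState,
    schedule: Sequence[Tuple[float, str]],
    eval_times: Sequence[float],
) -> Tuple[np.ndarray, TimeSeries]:
    """Integrate the piecewise-linear IAS model over a treatment schedule.

    ``schedule`` is a list of (duration_days, "on"|"off") pieces starting at
    time 0.  Returns the 3-component states at ``eval_times`` and the PSA
    series x1 + x2 + x3.  Each linear piece is solved exactly with the matrix
    exponential, so composition over pieces introduces no integration error.
    """
    eval_times = np.asarray(eval_times, dtype=float)
    if eval_times.ndim != 1 or len(eval_times) == 0:
        raise ValueError("eval_times must be a nonempty 1-D sequence")
    if np.any(np.diff(eval_times) <= 0):
        raise ValueError("eval_times must be strictly increasing")
    total = sum(d for d, _ in schedule)
    if eval_times[0] < 0 or eval_times[-1] > total + 1e-9:
        raise ValueError(
            f"eval_times must lie within the schedule span [0, {total}]"
        )
    matrices = {"on": params.on_matrix(), "off": params.off_matrix()}

    states = np.empty((len(eval_times), 3))
    state = initial.as_array()
    piece_start = 0.0
    idx = 0
    for duration, phase in schedule:
        if duration < 0:
            raise ValueError("schedule durations must be nonnegative")
        if phase not in matrices:
            raise ValueError(f"unknown treatment phase {phase!r}")
        piece_end = piece_start + duration
        A = matrices[phase]
        while idx < len(eval_times) and eval_times[idx] <= piece_end + 1e-9:
            states[idx] = expm(A * (eval_times[idx] - piece_start)) @ state
            idx += 1
        state = expm(A * duration) @ state
        piece_start = piece_end
    if idx < len(eval_times):  # pragma: no cover - guarded by span check
        raise ValueError("schedule ended before all eval_times were reached")
    if not np.all(np.isfinite(states)):
        raise OverflowError("IAS trajectory overflowed to non-finite values")
    psa = states.sum(axis=1)
    return states, TimeSeries(eval_times, psa)


def off_propagators(params: IASParams, dts: Sequence[float]) -> List[np.ndarray]:
    """Matrix exponentials expm(A_off * dt) for each elapsed time in ``dts``.

    Precomputing these turns repeated off-treatment trajectory evaluations
    (e.g. inside an initial-state fit) into plain matrix-vector products.
    """
    A = params.off_matrix()
    return [expm(A * float(dt)) for dt in dts]
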