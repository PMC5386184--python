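"""Expert-panel construction.

Two routes supply the advice matrix:

* sliding windows — every contiguous length-P window of every series in a
  database becomes one expert, so a pool of J series of length L yields
  J*(L-P+1) experts whose advice at step k is the window's k-th point;
* mechanistic model — for each candidate rate-parameter set of the
  piecewise-linear IAS model, the initial cell state is fitted to the first
  K observations of the target patient and the model is then run forward;
  each simulated PSA trajectory is one expert.

The initial-state fit minimizes the summed absolute discrepancy between
observed PSA and model output x1+x2+x3 at the observation times, plus a
huge penalty 1e15*(1-x) for every negative state component at every
evaluated time, which makes nonnegativity an effectively hard constraint.
The optimizer is a derivative-free simplex search from multiple random
starts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import ExpertPanel, TimeSeries
from .models import CellState, IASParams, off_propagators

__all__ = [
    "SeriesDatabase", "FitResult", "windowed_experts", "fit_initial_state",
    "model_experts", "nonnegativity_penalty",
]

PENALTY_SCALE = 1e15


@dataclass(frozen=True)
class SeriesDatabase:
    """A pool of scalar series x_{j,l}; lengths may differ across series."""

    series: Tuple[np.ndarray, ...]
    ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        series = tuple(np.asarray(s, dtype=float) for s in self.series)
        if len(series) < 1:
            raise ValueError("database must contain at least one series")
        for s in series:
            if s.ndim != 1 or len(s) < 1 or not np.all(np.isfinite(s)):
                raise ValueError("each series must be a finite 1-D sequence")
        object.__setattr__(self, "series", series)
        ids = tuple(self.ids) if self.ids else tuple(
            f"series{j + 1}" for j in range(len(series))
        )
        if len(ids) != len(series):
            raise ValueError("ids must match the number of series")
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.series)


def windowed_experts(db: SeriesDatabase, P: int) -> ExpertPanel:
    """Every length-P contiguous window of every series, as one expert each.

    Window i of series j (both 1-based) becomes expert (L_j-P+1)*(j-1)+i in
    order, with advice at step k equal to the window's k-th point and horizon
    P.
    """
    if P < 1:
        raise ValueError("window length P must be >= 1")
    rows: List[np.ndarray] = []
    ids: List[str] = []
    for j, s in enumerate(db.series):
        L = len(s)
        if P > L:
            raise ValueError(
                f"window length {P} exceeds series {db.ids[j]!r} length {L}"
            )
        for i in range(L - P + 1):
            rows.append(s[i : i + P])
            ids.append(f"{db.ids[j]}:w{i + 1}")
    return ExpertPanel(advice=np.vstack(rows), ids=tuple(ids))


def nonnegativity_penalty(x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Barrier h(x) = 1e15*(1-x) for x < 0 and 0 for x >= 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, PENALTY_SCALE * (1.0 - x), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FitResult:
    """Fitted initial cell state for one rate-parameter set."""

    initial_state: CellState
    cost: float
    params_id: str


def fit_initial_state(
    params: IASParams,
    observations: TimeSeries,
    n_starts: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> FitResult:
    """Fit (x1, x2, x3) at the first observation time to K >= 3 PSA points.

    Off-treatment dynamics are used (the fitted segment is follow-up data).
    The trajectory from a candidate initial state is a matrix-vector product
    with precomputed propagators, so each cost evaluation is cheap; the
    simplex search is restarted from ``n_starts`` random points in
    [0, y_1]**3 and the best local optimum is returned.
    """
    K = len(observations)
    if K < 3:
        raise ValueError(
            f"need at least 3 observation points (model dimension), got {K}"
        )
    rng = np.random.default_rng(rng)
    times = observations.times - observations.times[0]
    y = observations.values
    props = np.stack(off_propagators(params, times))  # K x 3 x 3

    def cost(x0: np.ndarray) -> float:
        states = props @ x0  # K x 3
        fit = np.abs(states.sum(axis=1) - y).sum()
        return fit + nonnegativity_penalty(states).sum()

    hi = max(float(y[0]), 1e-6)
    starts = list(rng.uniform(0.0, hi, size=(n_starts, 3)))
    # Linear-algebra start: PSA is linear in the initial state, so the
    # least-squares solution of sum_s(Phi_k x0)_s = y_k is the exact optimum
    # whenever a perfect (nonnegative) fit exists, at any data magnitude.
    design = props.sum(axis=1)  # K x 3 rows of column sums
    ls, *_ = np.linalg.lstsq(design, y, rcond=None)
    starts.append(np.maximum(ls, 0.0))
    best_x, best_c = None, np.inf
    for x0 in starts:
        res = minimize(
            cost, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
        )
        if np.isfinite(res.fun) and res.fun < best_c:
            best_x, best_c = res.x, float(res.fun)
    if best_x is None or best_c >= PENALTY_SCALE:
        raise RuntimeError(
            f"initial-state fit failed for parameter set {params.id!r}: "
            "no start reached a penalty-free optimum"
        )
    best_x = np.maximum(best_x, 0.0)  # clip optimizer dust at the boundary
    return FitResult(
        initial_state=CellState(*best_x), cost=best_c, params_id=params.id,
    )


def model_experts(
    param_table: Union[Sequence[IASParams], pd.DataFrame],
    observations: TimeSeries,
    K: int,
    horizon_times: Sequence[float],
    n_starts: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ExpertPanel, List[FitResult]]:
    """One expert per rate-parameter set: fit the initial state to the first
    K observations, then simulate PSA at ``horizon_times``.

    Parameter sets whose fit fails are skipped with a warning, shrinking the
    panel instead of aborting.
    """
    if isinstance(param_table, pd.DataFrame):
        param_table = params_from_table(param_table)
    if len(param_table) == 0:
        raise ValueError("parameter table is empty")
    if K < 3 or K > len(observations):
        raise ValueError(f"K must lie in [3, {len(observations)}], got {K}")
    rng = np.random.default_rng(rng)
    horizon_times = np.asarray(horizon_times, dtype=float)
    learning = TimeSeries(observations.times[:K], observations.values[:K])
    t0 = learning.times[0]

    rows, ids, fits = [], [], []
    for params in param_table:
        try:
            fit = fit_initial_state(params, learning, n_starts=n_starts, rng=rng)
        except RuntimeError as err:
            warnings.warn(str(err), RuntimeWarning, stacklevel=2)
            continue
        props = off_propagators(params, horizon_times - t0)
        traj = np.array([p @ fit.initial_state.as_array() for p in props])
        rows.append(traj.sum(axis=1))
        ids.append(params.id or f"set{len(ids) + 1}")
        fits.append(fit)
    if not rows:
        raise RuntimeError("every parameter set failed to fit")
    return ExpertPanel(advice=np.vstack(rows), ids=tuple(ids)), fits


def params_from_table(table: pd.DataFrame) -> List[IASParams]:
    """Rows of an ``id,d1..d6,e1..e4`` table as IASParams records."""
    d_cols = [f"d{i}" for i in range(1, 7)]
    e_cols = [f"e{i}" for i in range(1, 5)]
    missing = [c for c in d_cols + e_cols if c not in table.columns]
    if missing:
        raise ValueError(f"parameter table missing columns: {missing}")
    out = []
    for _, row in table.iterrows():
        out.append(
            IASParams(
                on_rates=tuple(row[c] for c in d_cols),
                off_rates=tuple(row[c] for c in e_cols),
                id=str(row["id"]) if "id" in table.columns else "",
            )
        )
    return out
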