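"""Seeded synthetic-data generators.

Two generators stand in for data that cannot ship with the package:

* ``toy_database`` — a chaotic-map expert database: M parameter sets drawn
  uniformly from a range (defaults: Henon a in [1.3, 1.4], b in [0.1, 0.2]),
  S random initial conditions per set drawn from [-0.02, 0.02]^2, each orbit
  iterated past a 1000-step transient; the recorded x+y series are used
  directly as experts.  Defaults M=100, S=1000 match the toy-experiment
  conditions; tests and examples scale S down.
* ``synthetic_cohort`` — a PSA cohort: per patient, off-treatment rates
  e1..e4 are sampled (self-rates in [-0.1, 0.1]/day with at least one
  positive growth mode, the reversion coupling e2 in [0, 0.1]/day so cell
  burdens stay nonnegative), a nonnegative initial state is drawn, the
  piecewise-linear IAS model is run at irregularly spaced measurement times
  (clinical follow-up cadence, 20-60 days apart), and Gaussian observation
  noise clipped at zero is added.

Everything is bit-reproducible under a fixed seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import ExpertPanel, TimeSeries
from .experts import SeriesDatabase
from .models import CellState, IASParams, henon_series, ias_simulate, ikeda_series

__all__ = [
    "ToyDatabaseSpec", "CohortSpec", "PatientRecord", "toy_database",
    "toy_target", "synthetic_cohort",
]


@dataclass(frozen=True)
class ToyDatabaseSpec:
    """Conditions for a chaotic-map expert database."""

    map_kind: str = "henon"
    m_param_sets: int = 100
    s_initial: int = 1000
    a_range: Tuple[float, float] = (1.3, 1.4)
    b_range: Tuple[float, float] = (0.1, 0.2)
    u_range: Tuple[float, float] = (0.7, 0.9)
    init_range: Tuple[float, float] = (-0.02, 0.02)
    transient: int = 1000
    length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.map_kind not in ("henon", "ikeda"):
            raise ValueError(f"unknown map kind {self.map_kind!r}")
        if self.m_param_sets < 1 or self.s_initial < 1:
            raise ValueError("M and S must be >= 1")
        if self.length < 1 or self.transient < 0:
            raise ValueError("invalid length or transient")
        for lo, hi in (self.a_range, self.b_range, self.u_range, self.init_range):
            if not lo < hi:
                raise ValueError("ranges must satisfy lo < hi")


def _generate_orbit(spec: ToyDatabaseSpec, params, rng, max_tries: int = 50):
    """One recorded orbit; diverging draws are discarded and redrawn."""
    for _ in range(max_tries):
        x0, y0 = rng.uniform(*spec.init_range, size=2)
        try:
            if spec.map_kind == "henon":
                a, b = params
                return henon_series(a, b, x0, y0, spec.length, spec.transient)
            (u,) = params
            return ikeda_series(u, x0, y0, spec.length, spec.transient)
        except OverflowError:
            warnings.warn(
                "diverging orbit discarded and redrawn", RuntimeWarning,
                stacklevel=2,
            )
    raise RuntimeError("could not generate a bounded orbit; check parameter ranges")


def toy_database(spec: ToyDatabaseSpec) -> Tuple[SeriesDatabase, ExpertPanel]:
    """M uniform parameter draws x S random initials, each a full-horizon
    expert; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    series: List[np.ndarray] = []
    ids: List[str] = []
    for m in range(spec.m_param_sets):
        if spec.map_kind == "henon":
            params = (rng.uniform(*spec.a_range), rng.uniform(*spec.b_range))
        else:
            params = (rng.uniform(*spec.u_range),)
        for s in range(spec.s_initial):
            orbit = _generate_orbit(spec, params, rng)
            series.append(orbit.values)
            ids.append(f"m{m + 1}s{s + 1}")
    db = SeriesDatabase(series=tuple(series), ids=tuple(ids))
    panel = ExpertPanel(advice=np.vstack(series), ids=tuple(ids))
    return db, panel


def toy_target(
    spec: ToyDatabaseSpec,
    a: float = 1.35,
    b: float = 0.15,
    u: float = 0.9,
    seed: Optional[int] = None,
) -> TimeSeries:
    """A target orbit at fixed parameters outside the database draw (Henon
    default a=1.35, b=0.15, a chaotic regime), initial condition drawn from
    the same range as the experts'."""
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    params = (a, b) if spec.map_kind == "henon" else (u,)
    return _generate_orbit(spec, params, rng)


@dataclass(frozen=True)
class CohortSpec:
    """Conditions for a synthetic off-treatment PSA cohort."""

    n_patients: int = 72
    self_rate_range: Tuple[float, float] = (-0.1, 0.1)
    coupling_range: Tuple[float, float] = (0.0, 0.1)
    initial_range: Tuple[float, float] = (0.1, 5.0)
    n_points: int = 8
    spacing_range: Tuple[float, float] = (20.0, 60.0)
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        for lo, hi in (self.self_rate_range, self.coupling_range,
                       self.initial_range, self.spacing_range):
            if not lo < hi:
                raise ValueError("ranges must satisfy lo < hi")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: generating parameters, true trajectory, and
    noisy observations at irregular measurement times."""

    id: str
    params: IASParams
    initial: CellState
    truth: TimeSeries
    observed: TimeSeries


def _sample_params(spec: CohortSpec, rng, pid: str) -> IASParams:
    for _ in range(1000):
        e1, e3, e4 = rng.uniform(*spec.self_rate_range, size=3)
        e2 = rng.uniform(*spec.coupling_range)
        if max(e1, e3, e4) > 0:  # at least one growing mode: rising PSA arm
            return IASParams(off_rates=(e1, e2, e3, e4), id=pid)
    raise RuntimeError("could not sample a parameter set with a growth mode")


def synthetic_cohort(spec: CohortSpec) -> Tuple[pd.DataFrame, List[PatientRecord]]:
    """Sampled rate-parameter table plus per-patient short PSA series.

    Returns the ``id,d1..d6,e1..e4`` parameter table (on-treatment rates are
    zero: only the follow-up, off-treatment period is emulated) and patient
    records holding both the noise-free trajectory and the clipped noisy
    observations.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    patients: List[PatientRecord] = []
    for i in range(spec.n_patients):
        pid = f"p{i + 1:03d}"
        params = _sample_params(spec, rng, pid)
        initial = CellState(*rng.uniform(*spec.initial_range, size=3))
        spacings = rng.uniform(*spec.spacing_range, size=spec.n_points - 1)
        times = np.concatenate([[0.0], np.cumsum(spacings)])
        _, truth = ias_simulate(
            params, initial, [(float(times[-1]), "off")], times
        )
        noisy = truth.values + rng.normal(0.0, spec.noise, size=len(times)) \
            if spec.noise > 0 else truth.values.copy()
        observed = TimeSeries(times, np.maximum(noisy, 0.0))
        rows.append(
            {"id": pid, **{f"d{j}": 0.0 for j in range(1, 7)},
             **{f"e{j}": params.off_rates[j - 1] for j in range(1, 5)}}
        )
        patients.append(
            PatientRecord(id=pid, params=params, initial=initial,
                          truth=truth, observed=observed)
        )
    return pd.DataFrame(rows), patients
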