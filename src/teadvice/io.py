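"""CSV / config file dialects.

* TimeSeries CSV: header ``time,value``; ``#`` starts a comment line.
* ExpertPanel CSV: first column ``expert_id``, then ``t1..tT``; cells beyond
  an expert's horizon are empty.
* IAS parameter table CSV: columns ``id,d1..d6,e1..e4``.
* Scheme config: JSON or YAML mapping with keys
  ``variant, lambda, tea_exponent, rho, eta`` (eta may be ``"auto"``).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd
import yaml

from .core import ExpertPanel, TimeSeries, WeightScheme
from .experts import params_from_table
from .models import IASParams

__all__ = [
    "read_timeseries", "write_timeseries", "read_expert_panel",
    "write_expert_panel", "read_params_table", "write_params_table",
    "read_scheme_config",
]

PathLike = Union[str, Path]


class MalformedFileError(ValueError):
    """A data file failed validation; the message names the offending line."""


def _read_csv(path: PathLike, required: List[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as err:  # pandas raises several parser error types
        raise MalformedFileError(f"{path}: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedFileError(f"{path}: missing columns {missing}")
    return df


def _first_bad_line(path: PathLike, df: pd.DataFrame, bad_mask: np.ndarray) -> int:
    """1-based physical line number of the first offending data row."""
    row = int(np.flatnonzero(bad_mask)[0])
    # account for the header and any leading comment lines
    n_comments = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.lstrip().startswith("#"):
                n_comments += 1
            elif i - n_comments > row:
                break
    return row + 2 + n_comments


def read_timeseries(path: PathLike) -> TimeSeries:
    df = _read_csv(path, ["time", "value"])
    t = pd.to_numeric(df["time"], errors="coerce")
    v = pd.to_numeric(df["value"], errors="coerce")
    bad = t.isna() | v.isna()
    if bad.any():
        line = _first_bad_line(path, df, bad.to_numpy())
        raise MalformedFileError(f"{path}: non-numeric time/value at line {line}")
    try:
        return TimeSeries(t.to_numpy(), v.to_numpy())
    except ValueError as err:
        raise MalformedFileError(f"{path}: {err}") from err


def write_timeseries(series: TimeSeries, path: PathLike) -> None:
    pd.DataFrame({"time": series.times, "value": series.values}).to_csv(
        path, index=False
    )


def read_expert_panel(path: PathLike) -> ExpertPanel:
    df = _read_csv(path, ["expert_id"])
    t_cols = [c for c in df.columns if c != "expert_id"]
    if not t_cols:
        raise MalformedFileError(f"{path}: no advice columns t1..tT")
    advice = df[t_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
    horizons = np.zeros(len(df), dtype=int)
    for i in range(len(df)):
        finite = np.isfinite(advice[i])
        horizons[i] = int(finite.sum())
        if horizons[i] == 0 or finite[: horizons[i]].sum() != horizons[i]:
            raise MalformedFileError(
                f"{path}: expert {df['expert_id'].iloc[i]!r} (line {i + 2}) has "
                "empty or non-contiguous advice"
            )
    try:
        return ExpertPanel(
            advice=advice, horizons=horizons, ids=tuple(df["expert_id"].astype(str))
        )
    except ValueError as err:
        raise MalformedFileError(f"{path}: {err}") from err


def write_expert_panel(panel: ExpertPanel, path: PathLike) -> None:
    cols = {"expert_id": panel.ids or [f"e{i + 1}" for i in range(panel.n_experts)]}
    for t in range(panel.n_steps):
        col = panel.advice[:, t].astype(object)
        col[panel.horizons < t + 1] = ""
        cols[f"t{t + 1}"] = col
    pd.DataFrame(cols).to_csv(path, index=False)


def read_params_table(path: PathLike) -> List[IASParams]:
    df = _read_csv(path, [f"d{i}" for i in range(1, 7)] + [f"e{i}" for i in range(1, 5)])
    try:
        return params_from_table(df)
    except (ValueError, TypeError) as err:
        raise MalformedFileError(f"{path}: {err}") from err


def write_params_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False)


def read_scheme_config(path: PathLike) -> WeightScheme:
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise MalformedFileError(f"{path}: scheme config must be a mapping")
    known = {"variant", "lambda", "tea_exponent", "rho", "eta"}
    unknown = set(cfg) - known
    if unknown:
        raise MalformedFileError(f"{path}: unknown scheme keys {sorted(unknown)}")
    kwargs = {
        "variant": cfg.get("variant", "tea"),
        "lambda_": cfg.get("lambda"),
        "rho": cfg.get("rho"),
        "eta": cfg.get("eta", "auto"),
    }
    if "tea_exponent" in cfg:
        kwargs["tea_exponent"] = cfg["tea_exponent"]
    try:
        return WeightScheme(**kwargs)
    except ValueError as err:
        raise MalformedFileError(f"{path}: {err}") from err
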