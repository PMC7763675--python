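"""Release-curve CSV I/O and JSON fit reports.

The on-disk curve format is a two-column CSV with header
``time_days,release_percent``; lines starting with ``#`` are comments.
Time is fixed to days in files to prevent silent unit bugs (unit
conversions happen only through the explicit conversion operations).

A fit report is a JSON document that echoes its inputs and options, so
every number in it can be recomputed from the report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .curves import ReleaseCurve, SphericalCarrier
from .errors import ValidationError
from .fitting import FitOptions, FitResult, ModelComparison
from .models import BimodalParams, SeriesParams, SingleTermParams

__all__ = [
    "read_release_csv",
    "write_release_csv",
    "FitReport",
    "report_from_comparison",
    "write_fit_report",
    "read_fit_report",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("time_days", "release_percent")


def read_release_csv(path) -> ReleaseCurve:
    """Read and validate a release curve from CSV.

    Duplicate or backwards-going times are reported as errors rather
    than silently sorted; release values above 100 % (up to the 110 %
    ceiling) are accepted with a warning.
    """
    path = Path(path)
    try:
        # round_trip parser: the default fast parser can be 1 ulp off,
        # breaking exact write->read identity
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except FileNotFoundError:
        raise ValidationError(f"release CSV not found: {path}") from None
    except Exception as exc:
        raise ValidationError(f"could not parse {path} as CSV: {exc}") from exc

    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    for col in _REQUIRED_COLUMNS:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            bad = frame.loc[numeric.isna(), col].iloc[0]
            raise ValidationError(f"{path}: non-numeric value {bad!r} in column {col}")
        frame[col] = numeric

    times = frame["time_days"].to_numpy(float)
    if np.any(np.diff(times) == 0):
        raise ValidationError(f"{path}: duplicate time values")
    if np.any(np.diff(times) < 0):
        raise ValidationError(f"{path}: time values go backwards (input is not sorted)")

    release = frame["release_percent"].to_numpy(float)
    if np.any(release > 100.0):
        logger.warning(
            "%s: %d release value(s) exceed 100 %% (accepted, ceiling 110 %%)",
            path,
            int(np.sum(release > 100.0)),
        )
    return ReleaseCurve(times=times, release=release)


def write_release_csv(curve: ReleaseCurve, path) -> None:
    """Write a release curve; full float precision so read-back is exact."""
    frame = pd.DataFrame(
        {"time_days": curve.times, "release_percent": curve.release}
    )
    # no float_format: pandas' default shortest-repr output round-trips
    # doubles exactly, a fixed %.17g-style format does not
    frame.to_csv(path, index=False)


def _params_to_dict(params) -> dict:
    return dataclasses.asdict(params)


def _params_from_dict(model_id: str, data: dict):
    cls = {
        "bimodal": BimodalParams,
        "single_term": SingleTermParams,
        "series": SeriesParams,
    }[model_id]
    return cls(**data)


@dataclass(frozen=True)
class FitReport:
    """Self-contained record of a model-comparison run."""

    input_description: str
    input_times: list
    input_release: list
    filter_threshold: float
    n_points: int
    radius_nm: Optional[float]
    models: dict  # model_id -> {params, s_value, n_points, n_starts, converged}
    ranking: list
    diffusivities: dict
    failures: dict
    options: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def input_curve(self) -> ReleaseCurve:
        return ReleaseCurve(
            times=np.asarray(self.input_times), release=np.asarray(self.input_release)
        )

    def fit_options(self) -> FitOptions:
        return FitOptions(**self.options)


def report_from_comparison(
    comparison: ModelComparison,
    *,
    input_curve: ReleaseCurve,
    options: FitOptions,
    input_description: str = "",
    radius_nm: Optional[float] = None,
) -> FitReport:
    """Assemble a JSON-serialisable report from a model comparison."""
    models = {
        model_id: {
            "params": _params_to_dict(res.params),
            "s_value": res.s_value,
            "n_points": res.n_points,
            "n_starts": res.n_starts,
            "converged": res.converged,
        }
        for model_id, res in comparison.results.items()
    }
    return FitReport(
        input_description=input_description,
        input_times=[float(t) for t in input_curve.times],
        input_release=[float(r) for r in input_curve.release],
        filter_threshold=options.filter_threshold,
        n_points=len(comparison.curve),
        radius_nm=radius_nm,
        models=models,
        ranking=list(comparison.ranking),
        diffusivities=comparison.diffusivities,
        failures=dict(comparison.failures),
        options=dataclasses.asdict(options),
    )


def write_fit_report(report: FitReport, path) -> None:
    """Serialise a report to JSON (floats at full precision)."""
    with open(path, "w") as handle:
        json.dump(report.to_dict(), handle, indent=2)
        handle.write("\n")


def read_fit_report(path) -> FitReport:
    """Load a report written by :func:`write_fit_report`."""
    with open(path) as handle:
        data = json.load(handle)
    return FitReport(**data)
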