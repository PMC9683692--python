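"""Measurement data model and the calibration objective.

Each scalar measurement carries an uncertainty given either directly as a
standard deviation sigma or as a coefficient of variation
CV = sigma / zhat (equivalently CV = RC% / 2.77 in terms of the
repeatability coefficient).  The calibration objective is the
standard-deviation-weighted sum of squared residuals

    cost(theta) = sum_i ((f_i(theta) - zhat_i) / sigma_i)^2

over whichever observables the patient actually has — missing
measurements are simply absent and contribute nothing.  The MCMC
log-likelihood is -0.5 times this cost (independent Gaussian noise);
a failed forward solve maps to infinite cost / -inf log-likelihood,
which rejects the candidate in both the genetic algorithm and MCMC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelOutputs

__all__ = [
    "Measurement",
    "MeasurementSet",
    "cv_to_sigma",
    "rc_percent_to_cv",
    "cost",
    "log_likelihood",
    "standardized_errors",
]

#: Repeatability coefficient (percent of the measurement) per unit CV.
RC_PERCENT_PER_CV = 2.77


def cv_to_sigma(cv: float, value: float) -> float:
    """sigma = CV * |zhat| (CV as a dimensionless fraction)."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if value == 0:
        raise ValueError("sigma undefined: CV given for a zero-valued measurement")
    return cv * abs(value)


def rc_percent_to_cv(rc_percent: float) -> float:
    """Convert a repeatability coefficient to a CV, unit-preserving
    (percent in, percent out): the RC of a test-retest protocol covers
    95% of paired differences, RC = 1.96 sqrt(2) sigma = 2.77 sigma."""
    return rc_percent / RC_PERCENT_PER_CV


@dataclass(frozen=True)
class Measurement:
    """One named scalar observable with value zhat and uncertainty sigma.

    Exactly one of ``cv`` (fraction) or ``sigma`` is given at
    construction; the other is derived.
    """

    name: str
    value: float
    cv: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"{self.name}: non-finite measurement value")
        if (self.cv is None) == (self.sigma is None):
            raise ValueError(f"{self.name}: give exactly one of cv or sigma")
        if self.sigma is None:
            object.__setattr__(self, "sigma", cv_to_sigma(self.cv, self.value))
        else:
            if self.sigma <= 0:
                raise ValueError(f"{self.name}: sigma must be positive")
            if self.value != 0:
                object.__setattr__(self, "cv", self.sigma / abs(self.value))
        if self.sigma <= 0:
            raise ValueError(f"{self.name}: derived sigma must be positive")


class MeasurementSet:
    """A patient's named measurements (uniquely named, n_z >= 1)."""

    def __init__(self, measurements: list[Measurement], patient_id: str = "patient"):
        if not measurements:
            raise ValueError("measurement set must contain at least one entry")
        names = [m.name for m in measurements]
        if len(set(names)) != len(names):
            raise ValueError("duplicate measurement names")
        self.patient_id = patient_id
        self.measurements = list(measurements)

    @property
    def n_z(self) -> int:
        return len(self.measurements)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.measurements]

    @property
    def values(self) -> np.ndarray:
        return np.array([m.value for m in self.measurements])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([m.sigma for m in self.measurements])

    def drop(self, names: list[str]) -> "MeasurementSet":
        kept = [m for m in self.measurements if m.name not in set(names)]
        return MeasurementSet(kept, patient_id=self.patient_id)

    def __iter__(self):
        return iter(self.measurements)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MeasurementSet({self.patient_id!r}, n_z={self.n_z})"

    # -- IO ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, patient_id: str | None = None
                 ) -> "MeasurementSet":
        """Read ``patient_id,name,value,cv_percent,sigma`` (one of the last
        two non-empty per row)."""
        df = pd.read_csv(path)
        if patient_id is not None:
            df = df[df["patient_id"] == patient_id]
            if df.empty:
                raise ValueError(f"no rows for patient {patient_id!r}")
        ids = df["patient_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"measurement CSV holds several patients {list(ids)}; "
                             "pass patient_id")
        ms = []
        for _, r in df.iterrows():
            has_cv = "cv_percent" in r and pd.notna(r["cv_percent"])
            has_sig = "sigma" in r and pd.notna(r["sigma"])
            if has_cv == has_sig:
                raise ValueError(f"{r['name']}: exactly one of cv_percent/sigma "
                                 "must be set")
            ms.append(Measurement(
                name=str(r["name"]),
                value=float(r["value"]),
                cv=float(r["cv_percent"]) / 100.0 if has_cv else None,
                sigma=float(r["sigma"]) if has_sig else None,
            ))
        return cls(ms, patient_id=str(ids[0]))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "patient_id": self.patient_id,
                    "name": m.name,
                    "value": m.value,
                    "cv_percent": m.cv * 100.0 if m.cv is not None else np.nan,
                    "sigma": m.sigma if m.cv is None else np.nan,
                }
                for m in self.measurements
            ]
        ).to_csv(path, index=False)


def _residuals(outputs: ModelOutputs, data: MeasurementSet) -> np.ndarray:
    if not outputs.solver_ok or outputs.summaries is None:
        raise ValueError("outputs carry no summaries (solver failed)")
    missing = [m.name for m in data if m.name not in outputs.summaries]
    if missing:
        raise KeyError(f"measurements absent from model outputs: {missing}")
    f = np.array([outputs.summaries[m.name] for m in data])
    return (f - data.values) / data.sigmas


def cost(outputs: ModelOutputs, data: MeasurementSet) -> float:
    """Weighted sum of squared residuals; +inf when the solver failed."""
    if not outputs.solver_ok:
        return math.inf
    r = _residuals(outputs, data)
    return float(r @ r)


def log_likelihood(outputs: ModelOutputs, data: MeasurementSet) -> float:
    """-0.5 x cost; -inf on solver failure (candidate rejection)."""
    c = cost(outputs, data)
    return -0.5 * c


def standardized_errors(outputs: ModelOutputs, data: MeasurementSet
                        ) -> dict[str, dict[str, float | None]]:
    """Per-measurement residuals normalized by sigma and by zhat.

    Returns name -> {"standardized": (f-zhat)/sigma,
    "percent": 100 (f-zhat)/zhat or None when zhat = 0}.
    """
    std = _residuals(outputs, data)
    out: dict[str, dict[str, float | None]] = {}
    for m, s in zip(data, std):
        f = outputs.summaries[m.name]
        pct = 100.0 * (f - m.value) / m.value if m.value != 0 else None
        out[m.name] = {"standardized": float(s), "percent": pct}
    return out
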