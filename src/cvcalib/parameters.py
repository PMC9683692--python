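"""Parameter tables for the lumped-parameter cardiovascular model.

A :class:`ParameterSet` holds every model parameter — the 12 candidate
calibration parameters (stressed blood volume, ventricular maximum
elastances, pulmonary resistance, the seven terminal-bed resistances and
the venous compliance) together with all fixed physiological plumbing
(valve resistances, segment R/C values, chamber baseline elastances,
activation timing, heart period).  Each entry carries units, a nominal
value, physiological bounds and a free/fixed status flag.

The on-disk format is a CSV with header ``name,units,value,min,max,status``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Parameter", "ParameterSet", "default_parameters"]

_STATUSES = ("free", "fixed")


@dataclass(frozen=True)
class Parameter:
    name: str
    units: str
    value: float
    lower: float
    upper: float
    status: str = "fixed"

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"status must be one of {_STATUSES}, got {self.status!r}")
        if not np.isfinite(self.value):
            raise ValueError(f"parameter {self.name!r}: non-finite value")
        if self.value < 0:
            raise ValueError(f"parameter {self.name!r}: negative value {self.value}")
        if not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"parameter {self.name!r}: value {self.value} outside "
                f"[{self.lower}, {self.upper}]"
            )


class ParameterSet:
    """Ordered collection of named parameters with box bounds.

    The free subset (``status == 'free'``) is the calibration vector theta;
    the full set is the search space Theta restricted to the physiological
    box.
    """

    def __init__(self, entries: list[Parameter]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self._entries: dict[str, Parameter] = {e.name: e for e in entries}

    # -- basic access ----------------------------------------------------
    def __getitem__(self, name: str) -> Parameter:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    @property
    def free_names(self) -> list[str]:
        return [n for n, e in self._entries.items() if e.status == "free"]

    @property
    def fixed_names(self) -> list[str]:
        return [n for n, e in self._entries.items() if e.status == "fixed"]

    def value(self, name: str) -> float:
        return self._entries[name].value

    def values(self, names: list[str] | None = None) -> np.ndarray:
        names = self.names if names is None else names
        return np.array([self._entries[n].value for n in names], dtype=float)

    @property
    def free_values(self) -> np.ndarray:
        return self.values(self.free_names)

    @property
    def free_bounds(self) -> np.ndarray:
        """(n_free, 2) array of [lower, upper] for the free parameters."""
        return np.array(
            [[self._entries[n].lower, self._entries[n].upper] for n in self.free_names]
        )

    # -- functional updates ----------------------------------------------
    def with_values(self, updates: dict[str, float]) -> "ParameterSet":
        entries = []
        for name, e in self._entries.items():
            if name in updates:
                e = replace(e, value=float(updates[name]))
            entries.append(e)
        return ParameterSet(entries)

    def with_free_values(self, theta: np.ndarray) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        free = self.free_names
        if theta.shape != (len(free),):
            raise ValueError(f"expected {len(free)} free values, got {theta.shape}")
        return self.with_values(dict(zip(free, theta)))

    def fix(self, name: str, value: float | None = None) -> "ParameterSet":
        """Return a copy with ``name`` held fixed (optionally at ``value``)."""
        if name not in self._entries:
            raise KeyError(name)
        entries = []
        for x in self._entries.values():
            if x.name == name:
                changes = {"status": "fixed"}
                if value is not None:
                    changes["value"] = float(value)
                x = replace(x, **changes)
            entries.append(x)
        return ParameterSet(entries)

    def in_bounds(self, theta: np.ndarray) -> bool:
        b = self.free_bounds
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= b[:, 0]) and np.all(theta <= b[:, 1]))

    # -- IO ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterSet":
        df = pd.read_csv(path)
        required = {"name", "units", "value", "min", "max", "status"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parameter CSV missing columns: {sorted(missing)}")
        entries = [
            Parameter(
                name=str(r["name"]),
                units=str(r["units"]),
                value=float(r["value"]),
                lower=float(r["min"]),
                upper=float(r["max"]),
                status=str(r["status"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                {
                    "name": e.name,
                    "units": e.units,
                    "value": e.value,
                    "min": e.lower,
                    "max": e.upper,
                    "status": e.status,
                }
                for e in self._entries.values()
            ]
        )
        df.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ParameterSet({len(self)} parameters, "
            f"{len(self.free_names)} free: {self.free_names})"
        )


def default_parameters() -> ParameterSet:
    """Load the packaged parameter table (12 free candidates + fixed set)."""
    ref = importlib.resources.files("cvcalib.data").joinpath("parameters.csv")
    with importlib.resources.as_file(ref) as p:
        return ParameterSet.from_csv(p)
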