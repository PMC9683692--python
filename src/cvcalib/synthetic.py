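"""Synthetic patients with known ground truth.

Generates measurement sets that emulate the clinical protocol the
calibration pipeline targets: echocardiographic chamber-volume extrema,
brachial cuff pressures, and mean terminal flows, each with the
inter-observer coefficient of variation reported for that modality.
A patient is the forward model evaluated at a known true parameter
vector with multiplicative Gaussian noise (sigma = CV x true value)
applied per observable, plus an optional missingness pattern that drops
named observables — mirroring the fact that real patients routinely lack
some measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .measurements import Measurement, MeasurementSet
from .model import DEFAULT_OBSERVABLES, ModelOutputs, SimulationConfig, simulate
from .parameters import ParameterSet

__all__ = [
    "SyntheticPatient",
    "generate_patient",
    "default_cv_table",
    "preset_missing_patterns",
]

def default_cv_table() -> dict[str, float]:
    """CV (percent) per observable.

    Chamber volumes carry echocardiographic inter-observer CVs, cuff
    pressures 24-h repeat CVs, cerebral terminal flows the 8% of
    transcranial flow measurement, and the non-crucial leg/brachial/trunk
    flows deliberately large CVs (30-50%) so they only weakly constrain
    the fit.  The mean-brachial-pressure CV (2.25%) is the estimate its
    source derived from the max/min cuff-pressure repeatabilities.
    """
    return {
        "max(q_la)": 21.3,
        "min(q_la)": 23.5,
        "max(q_lv)": 12.6,
        "min(q_lv)": 19.4,
        "max(q_ra)": 10.0,
        "max(p_BR)": 1.5,
        "min(p_BR)": 4.0,
        "mean(p_BR)": 2.25,
        "mean(v_LE_T)": 30.0,
        "mean(v_BR_T)": 30.0,
        "mean(v_PC_T)": 8.0,
        "mean(v_EC_T)": 8.0,
        "mean(v_MC_T)": 8.0,
        "mean(v_AC_T)": 8.0,
        "mean(v_TR_T)": 50.0,
    }


def preset_missing_patterns() -> dict[str, list[str]]:
    """Three missingness presets: a full set, a missing atrial minimum,
    and missing ventricular volumes (per-patient data availability
    varies in practice)."""
    return {
        "patient_full": [],
        "patient_no_qla_min": ["min(q_la)"],
        "patient_no_qlv": ["max(q_lv)", "min(q_lv)"],
    }


@dataclass
class SyntheticPatient:
    """Ground-truthed synthetic patient."""

    patient_id: str
    theta_true: dict[str, float]
    data: MeasurementSet
    missing: list[str]
    seed: int
    truth: ModelOutputs = field(repr=False, default=None)

    def save(self, directory: str | Path) -> None:
        """Emit the measurement CSV plus a ground-truth JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(directory / f"{self.patient_id}_measurements.csv")
        sidecar = {
            "patient_id": self.patient_id,
            "theta_true": self.theta_true,
            "missing": self.missing,
            "seed": self.seed,
            "true_summaries": self.truth.summaries if self.truth else None,
        }
        with open(directory / f"{self.patient_id}_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def generate_patient(
    theta_true: ParameterSet,
    cv_table: dict[str, float] | None = None,
    missing: list[str] | None = None,
    seed: int = 0,
    patient_id: str = "synthetic",
    sim_config: SimulationConfig | None = None,
    noise_scale: float = 1.0,
) -> SyntheticPatient:
    """Simulate at ``theta_true`` and apply multiplicative Gaussian noise.

    Each retained observable becomes zhat = f_true (1 + s CV xi) with
    xi ~ N(0, 1) and s = ``noise_scale``, redrawn (not clipped) if the
    noisy value would be non-positive, so measured volumes/pressures/
    flows stay positive.  CVs are percentages, as printed in
    measurement-repeatability tables; they define the sigma weighting of
    the measurements regardless of ``noise_scale``, so a noise-free
    patient (``noise_scale=0``) keeps realistic uncertainties while its
    values equal the ground truth exactly.
    """
    cv_table = default_cv_table() if cv_table is None else cv_table
    missing = list(missing or [])
    truth = simulate(theta_true, sim_config)
    if not truth.solver_ok:
        raise RuntimeError("forward model failed at theta_true")
    rng = np.random.default_rng(seed)

    ms = []
    for name in DEFAULT_OBSERVABLES:
        if name in missing:
            continue
        if name not in cv_table:
            raise KeyError(f"no CV entry for observable {name!r}")
        cv = cv_table[name] / 100.0
        f_true = truth.summaries[name]
        s = noise_scale * cv
        noisy = f_true * (1.0 + s * rng.standard_normal())
        while noisy <= 0.0 and s > 0.0:
            noisy = f_true * (1.0 + s * rng.standard_normal())
        if cv > 0.0:
            ms.append(Measurement(name=name, value=float(noisy), cv=cv))
        else:
            ms.append(Measurement(name=name, value=float(noisy),
                                  sigma=abs(f_true) if f_true else 1.0))
    data = MeasurementSet(ms, patient_id=patient_id)
    return SyntheticPatient(
        patient_id=patient_id,
        theta_true={n: float(v) for n, v in
                    zip(theta_true.free_names, theta_true.free_values)},
        data=data,
        missing=missing,
        seed=seed,
        truth=truth,
    )
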