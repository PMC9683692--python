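"""Forward simulator of the closed-loop lumped-parameter circulation.

Exposes :func:`simulate`, which integrates the compartment ODEs over
repeated cardiac cycles until the cycle-start state is periodic, then
reports

* the 15 named scalar observables used for calibration (chamber volume
  extrema, brachial pressure extrema/mean, mean terminal flows), and
* the middle cerebral artery pressure waveform ``p_MC`` — the core
  prediction whose uncertainty the calibration pipeline quantifies.

Internal units follow the parameter table: volumes in m^3, pressures in
MPa, time in s, flows in m^3/s.  Reported pressures are in kPa.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from . import _core
from .parameters import ParameterSet

__all__ = [
    "SimulationConfig",
    "ModelOutputs",
    "simulate",
    "chamber_elastance",
    "extract_observables",
    "DEFAULT_OBSERVABLES",
    "CORE_PREDICTIONS",
    "KPA_PER_MMHG",
    "PACK_ORDER",
]

#: kPa per mmHg conversion factor.
KPA_PER_MMHG = 0.133322

#: The 15 calibration observables (volume in m^3, pressure kPa, flow m^3/s).
DEFAULT_OBSERVABLES = [
    "max(q_la)", "min(q_la)",
    "max(q_lv)", "min(q_lv)",
    "max(q_ra)",
    "max(p_BR)", "min(p_BR)", "mean(p_BR)",
    "mean(v_LE_T)", "mean(v_BR_T)",
    "mean(v_PC_T)", "mean(v_EC_T)", "mean(v_MC_T)", "mean(v_AC_T)",
    "mean(v_TR_T)",
]

#: Scalar summaries of the core prediction (middle cerebral artery pressure).
CORE_PREDICTIONS = ["max(p_MC)", "min(p_MC)", "mean(p_MC)"]

#: Packed parameter vector order; must match the index layout in _core.
PACK_ORDER = [
    "q_sbv", "E_LVa", "E_RVa", "R_par",
    "R_LE_T", "R_BR_T", "R_AC_T", "R_EC_T", "R_MC_T", "R_PC_T", "R_TR_T",
    "C_V", "T", "t_sys", "t_atr", "atr_onset",
    "E_RAb", "E_RAa", "E_RVb", "E_LAb", "E_LAa", "E_LVb",
    "R_trv", "R_puv", "R_miv", "R_aov", "p_smooth",
    "C_par", "C_pvn", "R_pvn",
    "C_aor", "C_ubr", "C_cer", "C_mca", "C_bra", "C_dao",
    "R_aor_ubr", "R_aor_dao", "R_ubr_cer", "R_ubr_bra", "R_cer_mca",
    "C_LE_T", "C_BR_T", "C_AC_T", "C_EC_T", "C_MC_T", "C_PC_T", "C_TR_T",
    "R_LE_ven", "R_BR_ven", "R_AC_ven", "R_EC_ven", "R_MC_ven", "R_PC_ven",
    "R_TR_ven",
    "f_vub", "R_svc", "R_ivc",
    "q0_ra", "q0_rv", "q0_la", "q0_lv",
]

assert len(PACK_ORDER) == _core.N_PARAMS


@dataclass(frozen=True)
class SimulationConfig:
    """Solver settings.

    dt : fixed RK4 step [s]; max_cycles : cap on simulated heart beats;
    periodicity_tol : relative L-inf change of the cycle-start state below
    which the run is declared periodic (<= 0 forces exactly ``max_cycles``
    beats — used for deterministic finite-difference sensitivities);
    output_fs : final-cycle sampling rate [Hz]; rel_tol/abs_tol : scales
    for the volume-conservation check.
    """

    dt: float = 5.0e-4
    max_cycles: int = 60
    periodicity_tol: float = 1.0e-6
    output_fs: float = 500.0
    rel_tol: float = 1.0e-8
    abs_tol: float = 1.0e-12

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.output_fs <= 0:
            raise ValueError("dt and output_fs must be positive")
        if self.max_cycles < 2:
            raise ValueError("max_cycles must be >= 2")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")

    def exact_cycles(self, n: int) -> "SimulationConfig":
        """A copy that runs exactly ``n`` cycles (no periodicity stop)."""
        return replace(self, max_cycles=n, periodicity_tol=0.0)


@dataclass
class ModelOutputs:
    """Result of one forward run.

    ``summaries`` maps observable names to scalars over the final
    (periodic) cycle; ``waveforms`` holds time series over that cycle
    (all states plus derived pressures/flows); both are None when the
    solver failed (``solver_ok`` False), which callers treat as candidate
    rejection rather than an error.
    """

    solver_ok: bool
    converged: bool = False
    n_cycles: int = 0
    summaries: dict[str, float] | None = None
    waveforms: dict[str, np.ndarray] | None = None
    volume_drift: float = field(default=np.nan)
    final_state: np.ndarray | None = field(default=None, repr=False)


def pack_parameters(params: ParameterSet) -> np.ndarray:
    vec = np.array([params.value(n) for n in PACK_ORDER], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [n for n, v in zip(PACK_ORDER, vec) if not np.isfinite(v)]
        raise ValueError(f"non-finite parameter values: {bad}")
    if np.any(vec < 0):
        bad = [n for n, v in zip(PACK_ORDER, vec) if v < 0]
        raise ValueError(f"negative parameter values: {bad}")
    return vec


# Reference filling pressures [MPa] used only to shape the initial volume
# distribution: compliance x reference pressure, rescaled to q_sbv.  Starting
# near typical operating pressures shortens the run-in to the periodic cycle;
# the converged cycle itself does not depend on this distribution.
_P_REF_ART = 0.013
_P_REF_VEN = 0.0009
_P_REF_PVN = 0.0014
_P_REF_PAR = 0.0018
_P_REF_TERM = 0.002


def initial_state(p: np.ndarray) -> np.ndarray:
    """Distribute the stressed blood volume q_sbv across compartments.

    Weights are compartment compliance (chambers: baseline diastolic
    1/E_B; veins share C_V) times a fixed reference filling pressure, so
    the loop starts near its operating point.  The closed loop then
    redistributes volume during the run-in cycles; total stressed volume
    equals q_sbv exactly throughout.
    """
    w = np.empty(_core.N_STATES)
    w[_core.X_RA] = _P_REF_VEN / p[_core.I_E_RAB]
    w[_core.X_RV] = _P_REF_VEN / p[_core.I_E_RVB]
    w[_core.X_LA] = _P_REF_PVN / p[_core.I_E_LAB]
    w[_core.X_LV] = _P_REF_PVN / p[_core.I_E_LVB]
    w[_core.X_PAR] = p[_core.I_C_PAR] * _P_REF_PAR
    w[_core.X_PVN] = p[_core.I_C_PVN] * _P_REF_PVN
    for xi, ci in [
        (_core.X_AOR, _core.I_C_AOR), (_core.X_UBR, _core.I_C_UBR),
        (_core.X_CER, _core.I_C_CER), (_core.X_MCA, _core.I_C_MCA),
        (_core.X_BRA, _core.I_C_BRA), (_core.X_DAO, _core.I_C_DAO),
    ]:
        w[xi] = p[ci] * _P_REF_ART
    for xi, ci in [
        (_core.X_LE, _core.I_C_LE), (_core.X_BR, _core.I_C_BR),
        (_core.X_AC, _core.I_C_AC), (_core.X_EC, _core.I_C_EC),
        (_core.X_MC, _core.I_C_MC), (_core.X_PC, _core.I_C_PC),
        (_core.X_TR, _core.I_C_TR),
    ]:
        w[xi] = p[ci] * _P_REF_TERM
    w[_core.X_VUB] = p[_core.I_F_VUB] * p[_core.I_C_V] * _P_REF_VEN
    w[_core.X_VLB] = (1.0 - p[_core.I_F_VUB]) * p[_core.I_C_V] * _P_REF_VEN
    return p[_core.I_Q_SBV] * w / w.sum()


def chamber_elastance(t, e_min: float, e_max: float, onset: float,
                      duration: float, period: float):
    """Time-varying chamber elastance E(t) = (E_A - E_B) e(t) + E_B [MPa/m^3].

    The activation e(t) is a raised cosine in [0, 1] of width ``duration``
    starting at ``onset`` (periodic with ``period``); e = 1 at the
    activation peak gives E = E_A (maximum elastance), e = 0 in diastole
    gives the baseline E_B.
    """
    if e_min < 0 or e_max < 0:
        raise ValueError("elastances must be non-negative")
    if duration <= 0 or period <= 0:
        raise ValueError("activation duration and period must be positive")
    t = np.asarray(t, dtype=float)
    tau = np.mod(t - onset, period)
    e = np.where(tau < duration, 0.5 * (1.0 - np.cos(2.0 * np.pi * tau
                                                     / duration)), 0.0)
    return (e_max - e_min) * e + e_min


_OBS_RE = re.compile(r"^(max|min|mean)\((\w+)\)$")


def extract_observables(waveforms: dict[str, np.ndarray],
                        names: list[str]) -> dict[str, float]:
    """Apply max/min/mean over exactly one period of the named series.

    Means are trapezoidal time-averages over the cycle (the sampled cycle
    includes both the start and end points of the period).
    """
    t = waveforms["time"]
    period = t[-1] - t[0]
    out: dict[str, float] = {}
    for name in names:
        m = _OBS_RE.match(name)
        if not m or m.group(2) not in waveforms:
            valid = sorted(k for k in waveforms if k != "time")
            raise KeyError(
                f"unknown observable {name!r}; expected op(series) with op in "
                f"max/min/mean and series in {valid}"
            )
        op, key = m.groups()
        y = waveforms[key]
        if op == "max":
            out[name] = float(np.max(y))
        elif op == "min":
            out[name] = float(np.min(y))
        else:
            out[name] = float(np.trapezoid(y, t) / period)
    return out


def _build_waveforms(traj: np.ndarray, p: np.ndarray,
                     fs: float) -> dict[str, np.ndarray]:
    c = _core
    n = traj.shape[0]
    t = np.arange(n) / fs
    w: dict[str, np.ndarray] = {"time": t}

    # chamber volumes reported with their unstressed offsets (m^3)
    w["q_ra"] = traj[:, c.X_RA] + p[c.I_Q0_RA]
    w["q_rv"] = traj[:, c.X_RV] + p[c.I_Q0_RV]
    w["q_la"] = traj[:, c.X_LA] + p[c.I_Q0_LA]
    w["q_lv"] = traj[:, c.X_LV] + p[c.I_Q0_LV]

    # chamber pressures need the elastances (kPa)
    period = p[c.I_T]
    e_v = chamber_elastance(t, p[c.I_E_RVB], p[c.I_E_RVA], 0.0,
                            p[c.I_T_SYS], period)
    w["p_RV"] = e_v * traj[:, c.X_RV] * 1e3
    e_lv = chamber_elastance(t, p[c.I_E_LVB], p[c.I_E_LVA], 0.0,
                             p[c.I_T_SYS], period)
    w["p_LV"] = e_lv * traj[:, c.X_LV] * 1e3
    e_ra = chamber_elastance(t, p[c.I_E_RAB], p[c.I_E_RAA],
                             p[c.I_ATR_ONSET], p[c.I_T_ATR], period)
    w["p_RA"] = e_ra * traj[:, c.X_RA] * 1e3
    e_la = chamber_elastance(t, p[c.I_E_LAB], p[c.I_E_LAA],
                             p[c.I_ATR_ONSET], p[c.I_T_ATR], period)
    w["p_LA"] = e_la * traj[:, c.X_LA] * 1e3

    # vessel pressures (kPa)
    p_mpa = {
        "p_par": traj[:, c.X_PAR] / p[c.I_C_PAR],
        "p_pvn": traj[:, c.X_PVN] / p[c.I_C_PVN],
        "p_aor": traj[:, c.X_AOR] / p[c.I_C_AOR],
        "p_ubr": traj[:, c.X_UBR] / p[c.I_C_UBR],
        "p_cer": traj[:, c.X_CER] / p[c.I_C_CER],
        "p_MC": traj[:, c.X_MCA] / p[c.I_C_MCA],
        "p_BR": traj[:, c.X_BRA] / p[c.I_C_BRA],
        "p_dao": traj[:, c.X_DAO] / p[c.I_C_DAO],
        "p_vub": traj[:, c.X_VUB] / (p[c.I_F_VUB] * p[c.I_C_V]),
        "p_vlb": traj[:, c.X_VLB] / ((1.0 - p[c.I_F_VUB]) * p[c.I_C_V]),
    }
    for k, v in p_mpa.items():
        w[k] = v * 1e3

    # terminal-bed pressures (MPa, internal) and inflows (m^3/s)
    terms = [
        ("LE", c.X_LE, c.I_C_LE, c.I_R_LE_T, "p_dao"),
        ("BR", c.X_BR, c.I_C_BR, c.I_R_BR_T, "p_BR"),
        ("AC", c.X_AC, c.I_C_AC, c.I_R_AC_T, "p_cer"),
        ("EC", c.X_EC, c.I_C_EC, c.I_R_EC_T, "p_cer"),
        ("MC", c.X_MC, c.I_C_MC, c.I_R_MC_T, "p_MC"),
        ("PC", c.X_PC, c.I_C_PC, c.I_R_PC_T, "p_cer"),
        ("TR", c.X_TR, c.I_C_TR, c.I_R_TR_T, "p_dao"),
    ]
    for name, xi, ci, ri, upstream in terms:
        p_t = traj[:, xi] / p[ci]
        w[f"v_{name}_T"] = (p_mpa[upstream] - p_t) / p[ri]

    # valve flows (m^3/s), from the same smoothed-diode law as the RHS
    ps2 = p[c.I_P_SMOOTH] ** 2

    def diode(dp_kpa, r):
        dp = dp_kpa * 1e-3
        return 0.5 * (dp + np.sqrt(dp * dp + ps2)) / r

    w["v_trv"] = diode(w["p_RA"] - w["p_RV"], p[c.I_R_TRV])
    w["v_puv"] = diode(w["p_RV"] - w["p_par"], p[c.I_R_PUV])
    w["v_miv"] = diode(w["p_LA"] - w["p_LV"], p[c.I_R_MIV])
    w["v_aov"] = diode(w["p_LV"] - w["p_aor"], p[c.I_R_AOV])

    w["total_volume"] = traj.sum(axis=1)
    return w


def simulate(params: ParameterSet, config: SimulationConfig | None = None,
             observables: list[str] | None = None,
             x0: np.ndarray | None = None) -> ModelOutputs:
    """Run the closed-loop model to a periodic cycle and summarize it.

    Integrator failure (non-finite or runaway states) yields
    ``solver_ok=False`` with no summaries — the rejection signal used by
    the genetic algorithm and the MCMC sampler — rather than an
    exception.  Non-finite parameters raise.

    ``x0`` optionally warm-starts the run-in from a previous run's
    ``final_state`` (rescaled so total stressed volume equals q_sbv);
    the periodicity stop criterion makes the converged cycle independent
    of the start to within the periodicity tolerance.
    """
    cfg = config or SimulationConfig()
    p = pack_parameters(params)
    return simulate_packed(p, cfg, observables=observables, x0=x0)


def simulate_packed(p: np.ndarray, cfg: SimulationConfig,
                    observables: list[str] | None = None,
                    x0: np.ndarray | None = None) -> ModelOutputs:
    """Fast path of :func:`simulate` on an already-packed parameter
    vector (see ``PACK_ORDER``); used by the calibration loops, which
    evaluate the model tens of thousands of times and cannot afford
    rebuilding a validated :class:`ParameterSet` per call."""
    period = p[_core.I_T]
    spc = max(2, int(round(period / cfg.dt)))
    dt = period / spc
    out_every = max(1, int(round(1.0 / (cfg.output_fs * dt))))
    while spc % out_every:
        out_every -= 1

    if x0 is not None and np.all(np.isfinite(x0)) and x0.sum() > 0:
        x0 = np.asarray(x0, dtype=float) * (p[_core.I_Q_SBV] / x0.sum())
    else:
        x0 = initial_state(p)
    traj, n_cycles, converged, ok = _core.integrate(
        x0, p, dt, spc, cfg.max_cycles, cfg.periodicity_tol, out_every
    )
    if not ok or not np.all(np.isfinite(traj)):
        return ModelOutputs(solver_ok=False, n_cycles=int(n_cycles))

    fs = 1.0 / (out_every * dt)
    waveforms = _build_waveforms(traj, p, fs)
    drift = float(np.max(np.abs(waveforms["total_volume"] - p[_core.I_Q_SBV])))
    names = observables if observables is not None else (
        DEFAULT_OBSERVABLES + CORE_PREDICTIONS
    )
    summaries = extract_observables(waveforms, names)
    return ModelOutputs(
        solver_ok=True,
        converged=bool(converged),
        n_cycles=int(n_cycles),
        summaries=summaries,
        waveforms=waveforms,
        volume_drift=drift,
        final_state=traj[-1].copy(),
    )


def write_waveforms(outputs: ModelOutputs, path) -> None:
    """Write the final-cycle waveforms as CSV (time + named columns)."""
    import pandas as pd

    if outputs.waveforms is None:
        raise ValueError("no waveforms: solver failed")
    pd.DataFrame(outputs.waveforms).to_csv(path, index=False)
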