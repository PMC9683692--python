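"""Local structural identifiability: sensitivities, importance, collinearity.

The reduction loop repeatedly (i) fits the free parameters, (ii)
linearizes the model at the fit by first-order finite differences,
(iii) ranks parameters by importance

    delta_l = sqrt( (1/n_z) sum_k S_kl^2 ),
    S_kl    = d f_k / d theta_l  *  theta*_l / sigma_k,

and measures pairwise collinearity: with columns of S normalized to unit
Euclidean norm (divide by delta_l sqrt(n_z)), the 2x2 Gram matrix N of a
column pair has smallest eigenvalue mu, and

    gamma_ij = 1 / sqrt(mu)  =  1 / sqrt(1 - |cos angle(S_i, S_j)|).

A pair with gamma above the collinearity threshold t_c means the two
parameters can compensate each other near the fit: the lower-importance
member is fixed at its nominal physiological value.  Parameters with
importance below t_i are likewise fixed.  Before fixing, the same
quantities computed against the core predictions (delta^p, gamma^p,
normalized by the prediction values since predictions carry no
measurement sigma) must show the candidate is safe to fix — it either
barely moves the predictions or is prediction-collinear with a retained
parameter.  The loop stops when no parameter violates the thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .measurements import MeasurementSet
from .model import CORE_PREDICTIONS, DEFAULT_OBSERVABLES, SimulationConfig, simulate
from .parameters import ParameterSet

__all__ = [
    "ReductionConfig",
    "SensitivityResult",
    "ReductionReport",
    "sensitivity_matrix",
    "parameter_importance",
    "collinearity",
    "collinearity_matrix",
    "prediction_sensitivities",
    "reduce_parameters",
]

#: Sentinel for infinite collinearity (proportional columns), serializable.
GAMMA_CAP = 1.0e12


@dataclass(frozen=True)
class ReductionConfig:
    """Thresholds and numerics of the reduction loop.

    t_i : importance threshold (parameters below are candidates to fix);
    t_c : collinearity threshold (pairs above are candidates);
    t_u : optional prediction-uncertainty bound, reported only — whether
    the final uncertainty is acceptable is a user decision, not a gate;
    fd_rel_step : relative forward-difference step; sens_cycles : exact
    cycle count used during sensitivity runs so finite differences see a
    deterministic solver.
    """

    t_i: float = 0.1
    t_c: float = 10.0
    t_u: float | None = None
    fd_rel_step: float = 1.0e-3
    max_iterations: int = 12
    sens_cycles: int = 45

    def __post_init__(self) -> None:
        if self.t_i < 0:
            raise ValueError("t_i must be >= 0")
        if self.t_c <= 1:
            raise ValueError("t_c must be > 1 (gamma >= 1 always)")
        if self.fd_rel_step <= 0:
            raise ValueError("fd_rel_step must be positive")


@dataclass
class SensitivityResult:
    """Normalized sensitivities at an expansion point theta*."""

    parameter_names: list[str]
    output_names: list[str]
    theta_star: np.ndarray
    S: np.ndarray
    delta: np.ndarray = field(init=False)
    gamma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.delta = parameter_importance(self.S)
        self.gamma = collinearity_matrix(self.S, self.delta)

    @property
    def S_tilde(self) -> np.ndarray:
        """Importance-normalized matrix: columns have unit norm where
        delta > 0."""
        n_z = self.S.shape[0]
        denom = self.delta * math.sqrt(n_z)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, self.S / denom, 0.0)


def parameter_importance(S: np.ndarray) -> np.ndarray:
    """Root-mean-square of each normalized sensitivity column."""
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("sensitivity matrix contains non-finite entries")
    n_z = S.shape[0]
    return np.sqrt((S ** 2).sum(axis=0) / n_z)


def collinearity(S: np.ndarray, delta: np.ndarray, i: int, j: int) -> float:
    """Pairwise collinearity via the smallest-eigenvalue path.

    Returns NaN when either column has zero importance (the importance
    rule handles those parameters); infinite collinearity (proportional
    columns) is capped at a large sentinel for serializability.
    """
    if delta[i] <= 0 or delta[j] <= 0:
        return math.nan
    n_z = S.shape[0]
    u = S[:, i] / (delta[i] * math.sqrt(n_z))
    v = S[:, j] / (delta[j] * math.sqrt(n_z))
    n_hat = np.array([[u @ u, u @ v], [v @ u, v @ v]])
    mu = float(np.linalg.eigvalsh(n_hat)[0])
    if mu <= 1.0 / GAMMA_CAP ** 2:
        return GAMMA_CAP
    return min(1.0 / math.sqrt(mu), GAMMA_CAP)


def collinearity_matrix(S: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise collinearities (diagonal = 1)."""
    n = S.shape[1]
    g = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            g[i, j] = g[j, i] = collinearity(S, delta, i, j)
    return g


# ---------------------------------------------------------------------------
# finite differences against the forward model
# ---------------------------------------------------------------------------

Forward = Callable[[ParameterSet], dict[str, float] | None]


def _default_forward(sim_config: SimulationConfig,
                     output_names: list[str]) -> Forward:
    def forward(ps: ParameterSet) -> dict[str, float] | None:
        out = simulate(ps, sim_config, observables=output_names)
        return out.summaries if out.solver_ok else None
    return forward


def _fd_matrix(
    params: ParameterSet,
    output_names: list[str],
    forward: Forward,
    fd_rel_step: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference Jacobian of the named outputs w.r.t. free
    parameters, scaled by theta*_l (not yet by sigma).

    Returns (f0, J_scaled) with J_scaled[k, l] = df_k/dtheta_l * theta*_l.
    Solver failure at a perturbed point retries with a halved step before
    giving up.
    """
    theta = params.free_values
    if np.any(theta == 0):
        bad = [n for n, v in zip(params.free_names, theta) if v == 0]
        raise ValueError(f"cannot normalize sensitivities at zero-valued "
                         f"parameters: {bad}")
    base = forward(params)
    if base is None:
        raise RuntimeError("forward model failed at the expansion point")
    f0 = np.array([base[k] for k in output_names])
    jac = np.empty((len(output_names), theta.size))
    for l, name in enumerate(params.free_names):
        h = fd_rel_step * theta[l]
        # step backwards when the forward step would leave the box
        if theta[l] + h > params[name].upper:
            h = -h
        fh = None
        for _ in range(3):
            pert = forward(params.with_values({name: theta[l] + h}))
            if pert is not None:
                fh = np.array([pert[k] for k in output_names])
                break
            h *= 0.5
        if fh is None:
            raise RuntimeError(
                f"forward model failed at perturbations of {name!r}")
        jac[:, l] = (fh - f0) / h * theta[l]
    return f0, jac


def sensitivity_matrix(
    params: ParameterSet,
    data: MeasurementSet,
    cfg: ReductionConfig,
    sim_config: SimulationConfig | None = None,
    forward: Forward | None = None,
) -> SensitivityResult:
    """Sensitivities of the measured observables, normalized by sigma."""
    base_cfg = sim_config or SimulationConfig()
    if forward is None:
        forward = _default_forward(base_cfg.exact_cycles(cfg.sens_cycles),
                                   data.names)
    _, jac = _fd_matrix(params, data.names, forward, cfg.fd_rel_step)
    S = jac / data.sigmas[:, None]
    return SensitivityResult(
        parameter_names=params.free_names,
        output_names=data.names,
        theta_star=params.free_values,
        S=S,
    )


def prediction_sensitivities(
    params: ParameterSet,
    cfg: ReductionConfig,
    sim_config: SimulationConfig | None = None,
    prediction_names: list[str] | None = None,
    forward: Forward | None = None,
) -> SensitivityResult:
    """Sensitivities of the core predictions.

    Predictions have no measurement sigma; columns are normalized by the
    prediction magnitudes |f_k(theta*)| instead, making S a matrix of
    relative (log-log) sensitivities.
    """
    names = prediction_names if prediction_names is not None else CORE_PREDICTIONS
    base_cfg = sim_config or SimulationConfig()
    if forward is None:
        forward = _default_forward(base_cfg.exact_cycles(cfg.sens_cycles), names)
    f0, jac = _fd_matrix(params, names, forward, cfg.fd_rel_step)
    scale = np.where(np.abs(f0) > 0, np.abs(f0), 1.0)
    S = jac / scale[:, None]
    return SensitivityResult(
        parameter_names=params.free_names,
        output_names=names,
        theta_star=params.free_values,
        S=S,
    )


# ---------------------------------------------------------------------------
# the reduction loop
# ---------------------------------------------------------------------------

@dataclass
class ReductionReport:
    """Per-iteration record of the reduction loop and its outcome."""

    iterations: list[dict]
    final_free: list[str]
    final_fixed: dict[str, float]
    final_theta_star: dict[str, float]
    converged: bool
    warning: str | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=_jsonify)

    @classmethod
    def from_json(cls, path: str | Path) -> "ReductionReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def gamma_csv(self, path: str | Path, iteration: int = -1) -> None:
        """Write the iteration's collinearity matrix as a labelled table."""
        import pandas as pd

        it = self.iterations[iteration]
        pd.DataFrame(it["gamma"], index=it["free"], columns=it["free"]
                     ).to_csv(path)


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _pick_lower_importance(names: list[str], delta: np.ndarray,
                           i: int, j: int) -> tuple[int, int]:
    """The member of a collinear pair to fix: lower importance; ties break
    to the name that sorts later (deterministic)."""
    if delta[i] < delta[j]:
        return i, j
    if delta[j] < delta[i]:
        return j, i
    return (i, j) if names[i] > names[j] else (j, i)


def _is_safe_to_fix(cand: int, free: list[str],
                    pred: SensitivityResult | None,
                    cfg: ReductionConfig) -> tuple[bool, str]:
    """Prediction-space safety: fixing must not suppress real prediction
    uncertainty — the candidate either barely moves the predictions
    (delta^p < t_i) or is prediction-collinear with a retained parameter
    (some gamma^p >= t_c), whose freedom then covers the candidate's."""
    if pred is None:
        return True, "no core predictions defined"
    if pred.delta[cand] < cfg.t_i:
        return True, f"delta_pred={pred.delta[cand]:.4g} < t_i"
    for other in range(len(free)):
        if other == cand:
            continue
        g = pred.gamma[cand, other]
        if np.isfinite(g) and g >= cfg.t_c:
            return True, (f"gamma_pred({free[cand]},{free[other]})="
                          f"{g:.4g} >= t_c")
    return False, "prediction-relevant and not covered by a retained parameter"


def reduce_parameters(
    initial: ParameterSet,
    data: MeasurementSet,
    cfg: ReductionConfig,
    optimizer: Callable[[Callable[[np.ndarray], float], np.ndarray], "object"],
    sim_config: SimulationConfig | None = None,
    forward: Forward | None = None,
    prediction_names: list[str] | None = None,
    logger: Callable[[str], None] | None = None,
) -> ReductionReport:
    """Iterative sensitivity-based reduction to a structurally
    identifiable free set.

    Per iteration: refit the free parameters with ``optimizer`` (a
    ``(objective, bounds) -> FitResult`` callable), linearize, then fix at
    most one parameter — the lower-importance member of the worst
    above-threshold collinear pair, or failing that the least important
    below-threshold parameter — provided the prediction-space safety
    check passes.  Fixed parameters are held at their nominal values from
    ``initial`` (their approximate physiological values).  Terminates
    when an iteration fixes nothing.
    """
    if len(initial.free_names) < 2:
        raise ValueError("reduction needs at least 2 free parameters")
    pred_names = (prediction_names if prediction_names is not None
                  else CORE_PREDICTIONS)
    base_cfg = sim_config or SimulationConfig()
    log = logger or (lambda msg: None)

    # separate forward closures: a periodicity-stopping one for the fit,
    # an exact-cycle one for deterministic finite differences
    if forward is None:
        all_names = list(dict.fromkeys(data.names + pred_names))
        fwd_fit = _default_forward(base_cfg, data.names)
        fwd_fd = _default_forward(base_cfg.exact_cycles(cfg.sens_cycles),
                                  all_names)
    else:
        fwd_fit = fwd_fd = forward

    zhat = data.values
    sig = data.sigmas

    params = initial
    iterations: list[dict] = []
    converged = False
    warning = None
    theta_star_named: dict[str, float] = {}

    for it in range(cfg.max_iterations):
        free = params.free_names

        if forward is None:
            # packed fast path: the GA evaluates this thousands of times
            from .model import PACK_ORDER, pack_parameters, simulate_packed

            p_base = pack_parameters(params)
            free_idx = np.array([PACK_ORDER.index(n) for n in free])

            def objective(theta: np.ndarray,
                          _p=p_base, _idx=free_idx) -> float:
                p = _p.copy()
                p[_idx] = theta
                out = simulate_packed(p, base_cfg, observables=data.names)
                if not out.solver_ok:
                    return math.inf
                f = np.array([out.summaries[k] for k in data.names])
                r = (f - zhat) / sig
                return float(r @ r)
        else:
            def objective(theta: np.ndarray) -> float:
                s = fwd_fit(params.with_free_values(theta))
                if s is None:
                    return math.inf
                f = np.array([s[k] for k in data.names])
                r = (f - zhat) / sig
                return float(r @ r)

        fit = optimizer(objective, params.free_bounds)
        theta_star = np.asarray(fit.theta_star, dtype=float)
        params_star = params.with_free_values(theta_star)
        theta_star_named = dict(zip(free, theta_star))
        log(f"iteration {it}: refit cost={fit.best_cost:.4g} over {free}")

        sens = sensitivity_matrix(params_star, data, cfg, forward=fwd_fd,
                                  sim_config=base_cfg)
        pred = (prediction_sensitivities(params_star, cfg, forward=fwd_fd,
                                         sim_config=base_cfg,
                                         prediction_names=pred_names)
                if pred_names else None)

        record = {
            "free": free,
            "theta_star": theta_star_named,
            "cost": float(fit.best_cost),
            "delta": dict(zip(free, sens.delta)),
            "gamma": sens.gamma,
            "delta_pred": dict(zip(free, pred.delta)) if pred else None,
            "gamma_pred": pred.gamma if pred else None,
            "fixed": None,
            "reason": None,
            "safety": None,
        }

        fixed_name = None
        # worst collinear pair first
        pairs = [
            (sens.gamma[i, j], i, j)
            for i in range(len(free)) for j in range(i + 1, len(free))
            if np.isfinite(sens.gamma[i, j]) and sens.gamma[i, j] > cfg.t_c
        ]
        for g, i, j in sorted(pairs, reverse=True):
            cand, other = _pick_lower_importance(free, sens.delta, i, j)
            safe, why = _is_safe_to_fix(cand, free, pred, cfg)
            if safe:
                fixed_name = free[cand]
                record["fixed"] = fixed_name
                record["reason"] = f"collinear-with:{free[other]} (gamma={g:.4g})"
                record["safety"] = why
                break
            log(f"  candidate {free[cand]} (gamma={g:.4g}) not safe: {why}")

        # then low importance
        if fixed_name is None:
            low = [l for l in np.argsort(sens.delta) if sens.delta[l] < cfg.t_i]
            for cand in low:
                safe, why = _is_safe_to_fix(cand, free, pred, cfg)
                if safe:
                    fixed_name = free[cand]
                    record["fixed"] = fixed_name
                    record["reason"] = (f"low-importance "
                                        f"(delta={sens.delta[cand]:.4g})")
                    record["safety"] = why
                    break
                log(f"  candidate {free[cand]} (low delta) not safe: {why}")

        iterations.append(record)
        if fixed_name is None:
            converged = True
            log(f"iteration {it}: no parameter violates thresholds; done")
            break

        log(f"iteration {it}: fixing {fixed_name} ({record['reason']}; "
            f"thresholds t_i={cfg.t_i}, t_c={cfg.t_c}; "
            f"safety: {record['safety']})")
        params = params.fix(fixed_name, value=initial[fixed_name].value)
        if len(params.free_names) < 2:
            warning = "reduction stopped with fewer than 2 free parameters"
            break

    if not converged and warning is None:
        warning = f"no convergence within {cfg.max_iterations} iterations"

    final_free = params.free_names
    final_fixed = {
        n: params.value(n) for n in initial.free_names if n not in final_free
    }
    return ReductionReport(
        iterations=iterations,
        final_free=final_free,
        final_fixed=final_fixed,
        final_theta_star={n: theta_star_named[n] for n in final_free
                          if n in theta_star_named},
        converged=converged,
        warning=warning,
    )
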