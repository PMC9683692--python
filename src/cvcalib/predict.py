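"""Core-prediction uncertainty from posterior samples.

Draws parameter vectors from the post-burn-in posterior, reruns the
forward model for each, and summarizes the resulting middle cerebral
artery pressure waveforms: pointwise mean/SD/95% band over the cycle,
and per-sample scalar summaries (max, min, mean pressure) with their
medians and equal-tailed 95% percentile intervals.  The interval
half-width — reported in both kPa and mmHg — is the quantity a clinician
would compare against a task-specific acceptability bound t_u; the
pipeline reports it but never gates on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .mcmc import ChainSet
from .model import KPA_PER_MMHG

__all__ = [
    "PredictionDistribution",
    "sample_predictions",
    "summarize_ci",
    "ci_halfwidth_report",
]

#: Scalar summaries taken from each sampled waveform (kPa).
SUMMARY_NAMES = ("max(p_MC)", "min(p_MC)", "mean(p_MC)")


def summarize_ci(samples: np.ndarray, level: float = 0.95
                 ) -> tuple[float, float, float]:
    """Median and equal-tailed percentile interval (linear interpolation).

    Returns (median, lower, upper) at the given level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples for an interval")
    tail = 100.0 * (1.0 - level) / 2.0
    lower, med, upper = np.percentile(samples, [tail, 50.0, 100.0 - tail])
    return float(med), float(lower), float(upper)


@dataclass
class PredictionDistribution:
    """Sampled core-prediction waveforms and their summaries."""

    time: np.ndarray
    waveforms: np.ndarray  # (n_samples, n_time), kPa
    summaries: dict[str, np.ndarray]  # per-sample scalars
    n_redrawn: int = 0
    level: float = 0.95
    pointwise: dict[str, np.ndarray] = field(init=False)
    intervals: dict[str, dict[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        w = self.waveforms
        tail = 100.0 * (1.0 - self.level) / 2.0
        lo, hi = np.percentile(w, [tail, 100.0 - tail], axis=0)
        self.pointwise = {
            "mean": w.mean(axis=0),
            "sd": w.std(axis=0, ddof=1) if w.shape[0] > 1
                  else np.zeros(w.shape[1]),
            "lower": lo,
            "upper": hi,
            "median": np.percentile(w, 50.0, axis=0),
        }
        self.intervals = {}
        for name, vals in self.summaries.items():
            if vals.size >= 2:
                med, lo_s, up_s = summarize_ci(vals, self.level)
            else:
                med = lo_s = up_s = float(vals[0])
            self.intervals[name] = {
                "median": med, "ci_lower": lo_s, "ci_upper": up_s,
                "units": "kPa",
            }

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[0]

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_samples": self.n_samples,
                    "n_redrawn": self.n_redrawn,
                    "level": self.level,
                    "intervals": self.intervals,
                    "per_sample_summaries": {k: v.tolist() for k, v in
                                             self.summaries.items()},
                },
                fh, indent=1,
            )

    def band_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time": self.time,
                "mean": self.pointwise["mean"],
                "sd": self.pointwise["sd"],
                "lower": self.pointwise["lower"],
                "upper": self.pointwise["upper"],
            }
        ).to_csv(path, index=False)


def sample_predictions(
    chains: ChainSet,
    forward_waveform: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray] | None],
    n: int = 100,
    seed: int = 0,
    level: float = 0.95,
) -> PredictionDistribution:
    """Simulate ``n`` posterior draws and collect p_MC waveforms.

    ``forward_waveform(theta)`` returns (time, p_MC in kPa) over one
    cycle, or None on solver failure; failed draws are replaced by fresh
    ones (counted in ``n_redrawn``).  Draws are uniform without
    replacement from the flattened post-burn-in samples; waveforms are
    aligned at cycle start by construction.
    """
    flat = chains.flat()
    if flat.shape[0] == 0:
        raise ValueError("no post-burn-in samples to draw from")
    rng = np.random.default_rng(seed)
    order = rng.permutation(flat.shape[0])

    waveforms = []
    summaries: dict[str, list[float]] = {k: [] for k in SUMMARY_NAMES}
    time = None
    n_redrawn = 0
    used = 0
    for idx in order:
        if len(waveforms) == n:
            break
        used += 1
        res = forward_waveform(flat[idx])
        if res is None:
            n_redrawn += 1
            if n_redrawn > max(10, used // 2):
                raise RuntimeError(
                    "more than half of posterior draws fail the forward "
                    "solve; the posterior concentrates on a failure region")
            continue
        t, wave = res
        if time is None:
            time = np.asarray(t, dtype=float)
        waveforms.append(np.asarray(wave, dtype=float))
        summaries["max(p_MC)"].append(float(np.max(wave)))
        summaries["min(p_MC)"].append(float(np.min(wave)))
        summaries["mean(p_MC)"].append(
            float(np.trapezoid(wave, t) / (t[-1] - t[0])))
    if len(waveforms) < n:
        raise RuntimeError(
            f"could only simulate {len(waveforms)} of {n} requested draws")

    return PredictionDistribution(
        time=time,
        waveforms=np.vstack(waveforms),
        summaries={k: np.asarray(v) for k, v in summaries.items()},
        n_redrawn=n_redrawn,
        level=level,
    )


def ci_halfwidth_report(dist: PredictionDistribution,
                        t_u: float | None = None) -> dict:
    """Interval half-widths per summary, in kPa and mmHg.

    If a prediction-uncertainty threshold ``t_u`` (kPa) is supplied the
    report records pass/fail per summary without raising: the
    acceptability judgement belongs to the user, not the pipeline.
    """
    report: dict = {"level": dist.level, "t_u_kpa": t_u, "summaries": {}}
    for name, iv in dist.intervals.items():
        half_kpa = 0.5 * (iv["ci_upper"] - iv["ci_lower"])
        entry = {
            "median_kpa": iv["median"],
            "ci_lower_kpa": iv["ci_lower"],
            "ci_upper_kpa": iv["ci_upper"],
            "halfwidth_kpa": half_kpa,
            "halfwidth_mmhg": half_kpa / KPA_PER_MMHG,
        }
        if t_u is not None:
            entry["within_t_u"] = bool(half_kpa <= t_u)
        report["summaries"][name] = entry
    return report
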