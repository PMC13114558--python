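"""Seeded Monte Carlo evaluation of CUSUM-type detectors.

Provides average-run-length (ARL) estimation under the pre-change law,
threshold calibration to a target ARL by bisection with common random
numbers, worst-case delay estimation under a change at time zero (the
worst case for CUSUM-type rules), and the two tradeoff sweeps: delay
versus privacy level at matched ARL, and delay versus ARL along a
threshold grid.

Every estimate is a pure function of (configuration, seed): replication
i of a given evaluation derives its generator from the seed sequence
``(seed, context, i)``, so calibration re-uses identical streams and
noise draws across bisection iterations (making the estimated ARL
monotone in the threshold path-by-path), while the final reported ARL
uses an independent context to avoid optimization bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .detection import simulate_stopping_time

__all__ = [
    "MCConfig",
    "CalibrationResult",
    "TradeoffCurve",
    "estimate_arl",
    "calibrate_threshold",
    "estimate_wadd",
    "delay_privacy_curve",
    "delay_arl_curve",
]

# seed-sequence contexts keeping calibration, reporting and delay
# estimation statistically independent
_CTX_CALIBRATE = 0
_CTX_REPORT = 1
_CTX_DELAY = 2


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings.

    ``target_arl`` is the false-alarm budget gamma; ``cap`` censors any
    single run (default 50x gamma, generous enough that censoring under
    the post-change law is negligible at calibrated thresholds).
    """

    replications: int = 1000
    seed: int = 0
    target_arl: float = 1000.0
    cap: Optional[int] = None
    chunk: int = 2048

    def __post_init__(self):
        if self.replications < 100:
            raise ValueError("at least 100 replications are required")
        if self.target_arl <= 1:
            raise ValueError("target ARL must exceed 1")
        cap = self.cap
        if cap is None:
            cap = int(round(50 * self.target_arl))
            object.__setattr__(self, "cap", cap)
        if cap < 10 * self.target_arl:
            raise ValueError("cap must be at least 10x the target ARL")


def _rep_rng(seed: int, context: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, context, i)))


def _stopping_times(
    detector, b: float, cfg: MCConfig, context: int, post_change: bool
) -> tuple[np.ndarray, np.ndarray]:
    times = np.empty(cfg.replications)
    crossed = np.empty(cfg.replications, dtype=bool)
    for i in range(cfg.replications):
        rng = _rep_rng(cfg.seed, context, i)
        t, c = simulate_stopping_time(
            detector, b, cfg.cap, rng, post_change=post_change, chunk=cfg.chunk
        )
        times[i] = t
        crossed[i] = c
    return times, crossed


def estimate_arl(
    detector, b: float, cfg: MCConfig, context: int = _CTX_REPORT
) -> tuple[float, float, int]:
    """Mean time to false alarm under pure-f0 streams.

    Censored runs are included at the cap value, biasing the estimate
    downward -- conservative when checking an ARL >= gamma guarantee.
    Returns ``(estimate, stderr, censored_count)``.
    """
    times, crossed = _stopping_times(detector, b, cfg, context, post_change=False)
    censored = int(np.sum(~crossed))
    if censored == cfg.replications:
        raise RuntimeError("all ARL runs censored at cap; threshold too high")
    est = float(np.mean(times))
    se = float(np.std(times, ddof=1) / math.sqrt(len(times)))
    return est, se, censored


def estimate_wadd(
    detector, b: float, cfg: MCConfig, context: int = _CTX_DELAY
) -> tuple[float, float]:
    """Worst-case average detection delay: mean stopping time under pure-f1
    streams started at S_0 = 0 (the worst case for CUSUM-type detectors)."""
    times, crossed = _stopping_times(detector, b, cfg, context, post_change=True)
    n_censored = int(np.sum(~crossed))
    if n_censored > 0.01 * cfg.replications:
        raise RuntimeError(
            f"{n_censored}/{cfg.replications} delay runs censored; threshold "
            "too high for the post-change drift"
        )
    est = float(np.mean(times))
    se = float(np.std(times, ddof=1) / math.sqrt(len(times)))
    return est, se


@dataclass(frozen=True)
class CalibrationResult:
    """Bisection-calibrated threshold with an independently re-estimated ARL."""

    threshold: float
    arl_estimate: float
    arl_stderr: float
    censored: int
    config: MCConfig


def calibrate_threshold(
    detector,
    cfg: MCConfig,
    tolerance: float = 0.05,
    max_iter: int = 40,
) -> CalibrationResult:
    """Find b with ARL(b) ~= gamma by bisection under common random numbers.

    The bracket starts at log(gamma) +/- 3 and expands automatically when
    the detector's increments are too noisy for the first-order guess
    (e.g. heavily privatized baselines).  The returned ARL is
    re-estimated at the final threshold with an independent seed
    context.
    """
    gamma = cfg.target_arl
    b_lo = max(1e-3, math.log(gamma) - 3.0)
    b_hi = math.log(gamma) + 3.0

    def arl(b: float) -> float:
        est, _, _ = estimate_arl(detector, b, cfg, context=_CTX_CALIBRATE)
        return est

    a_lo = arl(b_lo)
    while a_lo > gamma and b_lo > 1e-3:
        b_lo = max(1e-3, b_lo / 2.0 if b_lo < 3.0 else b_lo - 3.0)
        a_lo = arl(b_lo)
    a_hi = arl(b_hi)
    expansions = 0
    while a_hi < gamma:
        expansions += 1
        if expansions > 60:
            raise RuntimeError("calibration bracket failed to expand")
        b_lo, a_lo = b_hi, a_hi
        b_hi += 3.0
        a_hi = arl(b_hi)

    b = b_hi
    a = a_hi
    for _ in range(max_iter):
        if abs(a - gamma) / gamma <= tolerance:
            break
        mid = 0.5 * (b_lo + b_hi)
        a = arl(mid)
        if a < gamma:
            b_lo = mid
        else:
            b_hi = mid
        b = mid

    est, se, censored = estimate_arl(detector, b, cfg, context=_CTX_REPORT)
    return CalibrationResult(b, est, se, censored, cfg)


class CurvePoint(NamedTuple):
    axis_value: float
    delay: float
    delay_se: float
    arl: float
    arl_se: float
    threshold: float


@dataclass(frozen=True)
class TradeoffCurve:
    """A (privacy or threshold) sweep for one detector."""

    axis: str  # "alpha" or "threshold"
    label: str
    points: tuple[CurvePoint, ...]
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([p._asdict() for p in self.points])
        df.insert(0, "detector", self.label)
        df.insert(1, "axis", self.axis)
        df["seed"] = self.seed
        return df


def curves_to_frame(curves: Iterable[TradeoffCurve]) -> pd.DataFrame:
    return pd.concat([c.to_dataframe() for c in curves], ignore_index=True)


def delay_privacy_curve(
    model,
    detector_factories: Sequence[tuple[str, Callable[[float], object]]],
    alpha_grid: Sequence[float],
    cfg: MCConfig,
    tolerance: float = 0.05,
) -> list[TradeoffCurve]:
    """Matched-ARL delay-versus-privacy curves.

    ``detector_factories`` maps a privacy level alpha to a detector (an
    alpha-independent detector such as the exact CUSUM may ignore its
    argument).  For each alpha and factory the threshold is calibrated
    to the target ARL and the worst-case delay is then estimated at
    that threshold.
    """
    alphas = sorted(alpha_grid)
    if not alphas or min(alphas) <= 0:
        raise ValueError("alpha grid must be nonempty and positive")
    curves = []
    for label, factory in detector_factories:
        pts = []
        for a in alphas:
            det = factory(a)
            cal = calibrate_threshold(det, cfg, tolerance=tolerance)
            delay, delay_se = estimate_wadd(det, cal.threshold, cfg)
            pts.append(
                CurvePoint(
                    a, delay, delay_se, cal.arl_estimate, cal.arl_stderr,
                    cal.threshold,
                )
            )
        curves.append(TradeoffCurve("alpha", label, tuple(pts), cfg.seed))
    return curves


def delay_arl_curve(
    model,
    detectors: Sequence,
    b_grid: Sequence[float],
    cfg: MCConfig,
) -> list[TradeoffCurve]:
    """Delay-versus-ARL tradeoff along a grid of thresholds, per detector."""
    b_grid = sorted(b_grid)
    if not b_grid:
        raise ValueError("threshold grid must be nonempty")
    if min(b_grid) <= 0:
        raise ValueError("thresholds must be positive")
    curves = []
    for det in detectors:
        pts = []
        for b in b_grid:
            arl, arl_se, _ = estimate_arl(det, b, cfg)
            delay, delay_se = estimate_wadd(det, b, cfg)
            pts.append(CurvePoint(b, delay, delay_se, arl, arl_se, b))
        curves.append(TradeoffCurve("threshold", det.label, tuple(pts), cfg.seed))
    return curves
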