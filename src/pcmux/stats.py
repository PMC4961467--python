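"""Statistical scaffolding: normality gating, empirical p-values from control
ensembles, and resampling-based power estimation.

A test result is only declared significant when its p-value clears the level
AND its bootstrap power exceeds 0.8, so marginal effects with unstable
resampling behavior are not reported as findings.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

POWER_THRESHOLD = 0.8


@dataclass
class TestResult:
    statistic: float
    p: float
    power: float
    level: float
    method: str

    @property
    def significant(self) -> bool:
        return (self.p < self.level) and (self.power > POWER_THRESHOLD)


def normality_gate(sample: np.ndarray, level: float = 0.05) -> dict:
    """D'Agostino's K^2 omnibus normality test (skew + kurtosis)."""
    x = np.asarray(sample, float)
    if len(x) < 20:
        raise ValueError("need at least 20 samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample (all values identical)")
    k2, p = sstats.normaltest(x)
    return {"k2": float(k2), "p": float(p), "normal": bool(p >= level)}


def empirical_p(observed: float, controls: np.ndarray) -> float:
    """One-sided empirical p with the plus-one convention:
    p = (1 + #{controls >= observed}) / (1 + n). Never returns 0."""
    c = np.asarray(controls, float)
    if len(c) == 0:
        raise ValueError("empty controls")
    return float((1.0 + np.sum(c >= observed)) / (1.0 + len(c)))


def power_by_resampling(
    test,
    data: np.ndarray,
    level: float = 0.05,
    n_resamples: int = 400,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap power: fraction of with-replacement resamples on which
    ``test(resample)`` returns a p-value below ``level``. Resamples on which
    the test raises are dropped (and counted out of the denominator)."""
    if not 1 <= n_resamples:
        raise ValueError("n_resamples must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.asarray(data)
    n_pass = n_ok = 0
    for _ in range(n_resamples):
        res = data[rng.integers(0, len(data), len(data))]
        try:
            p = test(res)
        except Exception:
            continue
        n_ok += 1
        if p < level:
            n_pass += 1
    if n_ok == 0:
        raise ValueError("test failed on every resample")
    return n_pass / n_ok


def gated_test(
    statistic: float,
    p: float,
    power: float,
    level: float = 0.05,
    method: str = "",
) -> TestResult:
    """Bundle a test outcome with its power gate."""
    return TestResult(statistic=statistic, p=p, power=power, level=level, method=method)
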