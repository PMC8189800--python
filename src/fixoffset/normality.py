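"""Simulation-based normality screen for offset distributions.

Formal normality tests reject trivially at fixation-sized samples
(n ~ 500), so normality is screened against Monte-Carlo acceptance
bands instead: 10,000 standard-normal samples of the fixation length are
drawn, the moment-based sample skewness and kurtosis (non-excess,
normal = 3) are computed for each, and the 5th/95th empirical
percentiles of the two statistics form the acceptance limits.  A
distribution whose skewness and kurtosis both fall inside the limits is
considered normal for reporting purposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["NormalityLimits", "simulate_limits", "is_normal",
           "sample_skewness", "sample_kurtosis"]


def sample_skewness(x: np.ndarray) -> float:
    """Moment-based sample skewness g1 (biased form)."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0:
        raise ValueError("zero variance: skewness undefined")
    m3 = ((x - m) ** 3).mean()
    return float(m3 / m2**1.5)


def sample_kurtosis(x: np.ndarray) -> float:
    """Moment-based sample kurtosis (non-excess; normal = 3)."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0:
        raise ValueError("zero variance: kurtosis undefined")
    m4 = ((x - m) ** 4).mean()
    return float(m4 / m2**2)


@dataclass
class NormalityLimits:
    """Monte-Carlo acceptance bands for skewness and kurtosis at fixed n."""

    n: int
    reps: int
    seed: int
    skew_lo: float
    skew_hi: float
    kurt_lo: float
    kurt_hi: float
    lower_pct: float = 5.0
    upper_pct: float = 95.0

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path) -> "NormalityLimits":
        return cls(**json.loads(Path(path).read_text()))


def simulate_limits(
    n: int = 500,
    reps: int = 10_000,
    seed: int = 0,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> NormalityLimits:
    """Acceptance bands from ``reps`` standard-normal samples of size ``n``.

    The stated "95% confidence limits" are the 5th and 95th empirical
    percentiles of each statistic (per-statistic one-sided 5% tails);
    this convention matches the asymptotic +-1.645 * sqrt(6/n) skewness
    half-width, which the test suite verifies.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    rng = np.random.default_rng(seed)
    skews = np.empty(reps)
    kurts = np.empty(reps)
    # chunked to bound memory at large reps * n
    chunk = max(1, int(2_000_000 // n))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        x = rng.standard_normal((m, n))
        mu = x.mean(axis=1, keepdims=True)
        d = x - mu
        m2 = (d**2).mean(axis=1)
        skews[done:done + m] = (d**3).mean(axis=1) / m2**1.5
        kurts[done:done + m] = (d**4).mean(axis=1) / m2**2
        done += m
    return NormalityLimits(
        n=n, reps=reps, seed=seed,
        skew_lo=float(np.percentile(skews, lower_pct)),
        skew_hi=float(np.percentile(skews, upper_pct)),
        kurt_lo=float(np.percentile(kurts, lower_pct)),
        kurt_hi=float(np.percentile(kurts, upper_pct)),
        lower_pct=lower_pct, upper_pct=upper_pct,
    )


def is_normal(offsets, limits: NormalityLimits) -> bool:
    """True iff sample skewness and kurtosis both fall inside the bands.

    Samples whose length differs from ``limits.n`` are still screened
    against the same bands (the bands are built at the plurality fixation
    length).
    """
    x = np.asarray(offsets, dtype=float)
    x = x[np.isfinite(x)]
    s = sample_skewness(x)
    k = sample_kurtosis(x)
    return bool(limits.skew_lo <= s <= limits.skew_hi
                and limits.kurt_lo <= k <= limits.kurt_hi)
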