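"""Independent brute-force reference for sudden-gain detection.

Deliberately written without the package's detection code paths: plain
Python arithmetic, and a Student-t quantile obtained by root-finding on
the regularised-incomplete-beta form of the t CDF rather than calling a
quantile function.  Used to cross-check the detector interval by
interval on randomised trajectories.
"""

from __future__ import annotations

import math
from functools import lru_cache

from scipy.optimize import brentq
from scipy.special import betainc


@lru_cache(maxsize=None)
def t_quantile(p: float, df: int) -> float:
    """Upper-tail Student-t quantile via the incomplete-beta CDF."""

    def cdf(x: float) -> float:
        if x == 0:
            return 0.5
        ib = betainc(df / 2.0, 0.5, df / (df + x * x))
        return 1.0 - 0.5 * ib if x > 0 else 0.5 * ib

    return brentq(lambda x: cdf(x) - p, 0.0, 1e3, xtol=1e-12)


def brute_force_gains(series: dict[int, float], n_weeks: int | None = None,
                      cutoff: float = 12.0, pct: float = 0.25,
                      alpha: float = 0.05, min_window: int = 2) -> list[int]:
    """Every pre-gain week n whose interval (n, n+1) meets all criteria."""
    if not series:
        return []
    if n_weeks is None:
        n_weeks = max(series)
    hits = []
    for n in range(1, n_weeks):
        if n not in series or (n + 1) not in series:
            continue
        pre = [series[w] for w in (n - 2, n - 1, n) if w >= 1 and w in series]
        post = [series[w] for w in (n + 1, n + 2, n + 3)
                if w <= n_weeks and w in series]
        if len(pre) < min_window or len(post) < min_window:
            continue
        drop = series[n] - series[n + 1]
        if drop < cutoff:
            continue
        if series[n] <= 0 or drop < pct * series[n]:
            continue
        m_pre = sum(pre) / len(pre)
        m_post = sum(post) / len(post)
        v_pre = sum((x - m_pre) ** 2 for x in pre) / (len(pre) - 1)
        v_post = sum((x - m_post) ** 2 for x in post) / (len(post) - 1)
        crit = t_quantile(1.0 - alpha / 2.0, len(pre) + len(post) - 2)
        if (m_pre - m_post) > crit * math.sqrt((v_pre + v_post) / 2.0):
            hits.append(n)
    return hits


def random_short_trajectory(rng, max_len: int = 12, grid_step: int = 6,
                            max_missing: int = 2) -> dict[int, float]:
    """A random trajectory on a coarse score grid with a few missing weeks."""
    length = int(rng.integers(4, max_len + 1))
    values = rng.integers(0, 145 // grid_step + 1, size=length) * grid_step
    series = {w + 1: float(v) for w, v in enumerate(values)}
    n_missing = int(rng.integers(0, max_missing + 1))
    for w in rng.choice(length, size=min(n_missing, length), replace=False):
        series.pop(int(w) + 1, None)
    return series
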