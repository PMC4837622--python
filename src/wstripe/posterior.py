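"""Posterior summaries and diagnostics for threshold-model chains.

Per-draw heritabilities h² = σ²_g/(σ²_g + σ²_e) (optionally adding the
maternal-environment variance σ²_c to the denominator, the convention used
for body weight) and genetic correlations r_g = σ_g12/√(σ²_g1·σ²_g2); the
posterior mean and SD over the retained draws are reported as the estimate
and its standard error, with 95% equal-tail intervals deciding "significant"
(interval excluding 0).  Includes the Dempster–Lerner liability→observed
scale conversion for binary incidence and a Heidelberger–Welch convergence
test (Cramér–von Mises stationarity with an AR-estimated spectral density at
frequency zero, plus the relative-halfwidth check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.regression.linear_model import yule_walker

__all__ = [
    "h2_per_draw",
    "rg_per_draw",
    "summarize",
    "dempster_lerner",
    "heidelberger_welch",
    "HeidelbergerWelchResult",
    "trace_and_running_mean",
]


def h2_per_draw(sigma2_g, sigma2_e, sigma2_c=0.0, include_maternal: bool = False):
    """Heritability of one draw: σ²_g/(σ²_g + σ²_e), maternal variance in the
    denominator when ``include_maternal`` (body-weight convention)."""
    sigma2_g = np.asarray(sigma2_g, dtype=float)
    den = sigma2_g + np.asarray(sigma2_e, dtype=float)
    if include_maternal:
        den = den + np.asarray(sigma2_c, dtype=float)
    return sigma2_g / den


def rg_per_draw(sigma_g12, sigma2_g1, sigma2_g2):
    """Genetic correlation of one draw: σ_g12/√(σ²_g1·σ²_g2)."""
    g1 = np.asarray(sigma2_g1, dtype=float)
    g2 = np.asarray(sigma2_g2, dtype=float)
    if np.any(g1 <= 0) or np.any(g2 <= 0):
        raise ValueError("degenerate genetic variance in draw")
    return np.asarray(sigma_g12, dtype=float) / np.sqrt(g1 * g2)


def summarize(chain, level: float = 0.95, hdi: bool = False) -> pd.DataFrame:
    """Posterior mean, SD ("standard error of the estimate"), interval and
    significance flag per parameter of a chain.

    ``chain`` is a ChainStore or a draws DataFrame; the ``iter`` column is
    ignored.  Significance means the equal-tail (or HDI) interval excludes 0.
    """
    draws = getattr(chain, "draws", chain)
    alpha = 1.0 - level
    rows = []
    for col in draws.columns:
        if col == "iter":
            continue
        x = draws[col].to_numpy(dtype=float)
        if hdi:
            lo, hi = _hdi(x, level)
        else:
            lo, hi = np.quantile(x, [alpha / 2.0, 1.0 - alpha / 2.0])
        m = float(x.mean())
        rows.append(
            {
                "parameter": col,
                "mean": m,
                "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                "lower": float(min(lo, m)),
                "upper": float(max(hi, m)),
                "n_draws": len(x),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


def _hdi(x: np.ndarray, level: float) -> tuple[float, float]:
    xs = np.sort(x)
    n = len(xs)
    k = max(int(np.floor(level * n)), 1)
    widths = xs[k:] - xs[: n - k]
    j = int(np.argmin(widths)) if len(widths) else 0
    return float(xs[j]), float(xs[min(j + k, n - 1)])


def dempster_lerner(h2_liability: float, incidence: float) -> float:
    """Liability-scale → observed-scale heritability for a binary trait.

    h²_obs = h²_lia · z²/(p·(1−p)) with p the incidence and z the standard
    normal density at the threshold Φ⁻¹(1−p).  The conversion factor is
    symmetric in p ↔ 1−p and peaks at p = 0.5, where it equals 2/π.
    """
    if not 0.0 <= h2_liability <= 1.0:
        raise ValueError("liability heritability must be in [0, 1]")
    if not 0.0 < incidence < 1.0:
        raise ValueError("incidence must be strictly inside (0, 1)")
    z = stats.norm.pdf(stats.norm.ppf(1.0 - incidence))
    return h2_liability * z * z / (incidence * (1.0 - incidence))


# --------------------------------------------------------------------------
# Heidelberger–Welch
# --------------------------------------------------------------------------


@dataclass
class HeidelbergerWelchResult:
    stationarity_passed: bool
    start_index: int  # first retained draw after discarding
    cvm_statistic: float
    cvm_pvalue: float
    halfwidth_passed: bool
    mean: float
    halfwidth: float


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit."""
    n = len(x)
    v0 = float(np.var(x, ddof=1)) if n > 1 else 0.0
    if v0 <= 0:
        return 0.0
    max_order = min(int(10.0 * math.log10(n)), n - 2, 30)
    best = (n * math.log(v0), v0)  # order 0
    for p in range(1, max_order + 1):
        try:
            rho, sigma = yule_walker(x, order=p, method="mle")
        except Exception:
            break
        v = float(sigma) ** 2
        if not np.isfinite(v) or v <= 0:
            continue
        aic = n * math.log(v) + 2.0 * p
        if aic < best[0]:
            denom = (1.0 - float(np.sum(rho))) ** 2
            if denom > 1e-12:
                best = (aic, v / denom)
    return best[1]


def _pcramer(q: float, eps: float = 1e-5) -> float:
    """CDF of the asymptotic Cramér–von Mises distribution (Csörgő–Faraway
    four-term Bessel series, as used by the boa/coda implementations)."""
    if q <= 0:
        return 0.0
    total = 0.0
    for k in range(4):
        u = (4 * k + 1) ** 2 / (16.0 * q)
        if u > -math.log(eps):
            continue
        z = (
            math.gamma(k + 0.5)
            * math.sqrt(4 * k + 1)
            / (math.gamma(k + 1.0) * math.pi ** 1.5 * math.sqrt(q))
        )
        total += z * math.exp(-u) * float(special.kv(0.25, u))
    return min(max(total, 0.0), 1.0)


def heidelberger_welch(
    chain, alpha: float = 0.05, halfwidth_tol: float = 0.1
) -> HeidelbergerWelchResult:
    """Stationarity + halfwidth verdicts for a single-parameter chain.

    The stationarity stage applies the Cramér–von Mises test to the Brownian
    bridge of cumulative sums, discarding the initial 10% increments (up to
    50%) until the test passes at ``alpha``; the spectral density at zero is
    estimated by an AR fit on the second half of the chain.  The halfwidth
    stage compares the 95% asymptotic-SE halfwidth of the retained mean to
    ``halfwidth_tol`` times its absolute value.
    """
    x = np.asarray(chain, dtype=float).ravel()
    n = len(x)
    if n < 100:
        raise ValueError("chain too short for the Heidelberger-Welch test (need >= 100)")
    if np.ptp(x) == 0.0:
        return HeidelbergerWelchResult(True, 0, 0.0, 1.0, True, float(x[0]), 0.0)

    s0 = _spectrum0_ar(x[n // 2 :])
    if s0 <= 0:
        return HeidelbergerWelchResult(True, 0, 0.0, 1.0, True, float(x.mean()), 0.0)

    passed = False
    start = 0
    stat, pval = np.nan, np.nan
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        start = int(frac * n)
        xs = x[start:]
        m = len(xs)
        csum = np.cumsum(xs)
        idx = np.arange(1, m + 1)
        bridge = csum - idx * xs.mean()
        stat = float(np.sum(bridge[: m - 1] ** 2) / (m * m * s0))
        pval = 1.0 - _pcramer(stat)
        if pval > alpha:
            passed = True
            break
    if not passed:
        start = n  # nothing retained
        return HeidelbergerWelchResult(False, start, stat, pval, False, float("nan"), float("nan"))

    xs = x[start:]
    s0_kept = _spectrum0_ar(xs)
    halfwidth = 1.96 * math.sqrt(max(s0_kept, 0.0) / len(xs))
    mean = float(xs.mean())
    hw_pass = bool(halfwidth <= halfwidth_tol * abs(mean)) if mean != 0 else halfwidth == 0.0
    return HeidelbergerWelchResult(True, start, stat, pval, hw_pass, mean, halfwidth)


def trace_and_running_mean(chain, param: str):
    """(iteration, value) and (iteration, cumulative mean) series for plotting."""
    draws = getattr(chain, "draws", chain)
    if param not in draws.columns:
        raise KeyError(
            f"unknown parameter {param!r}; available: "
            f"{[c for c in draws.columns if c != 'iter']}"
        )
    vals = draws[param].to_numpy(dtype=float)
    iters = (
        draws["iter"].to_numpy()
        if "iter" in draws.columns
        else np.arange(1, len(vals) + 1)
    )
    running = np.cumsum(vals) / np.arange(1, len(vals) + 1)
    return (iters, vals), (iters, running)
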