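"""Goodness-of-fit battery for the background model.

Per distance bin, a discrete Kolmogorov-Smirnov statistic compares the
observed count distribution with the null NB(s1 * s2 * f(d), r), where the
biases s1, s2 are drawn from their estimated empirical distributions and d
is uniform over the bin.  Because the null is a mixture with no tractable
CDF, significance is assessed by Monte Carlo simulation with the standard
(1 + #exceedances) / (1 + n_sim) p-value estimator, followed by a
bin-wise Bonferroni correction.  The module also carries the
technical-noise trend diagnostic (pool medians and variances should rise
across pools).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import DistanceBinning, NullModel

__all__ = [
    "KSResult",
    "ks_statistic_discrete",
    "simulate_null_bin",
    "ks_monte_carlo",
    "bonferroni_ks",
    "lambda_trend_diagnostic",
]


@dataclass
class KSResult:
    bin: int
    label: str
    d_statistic: float
    mc_p: float
    n_sim: int
    n_pairs_per_sim: int
    n_observed: int
    significant_after_bonferroni: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_statistic <= 1.0):
            raise ValueError("D statistic must lie in [0, 1]")
        if self.mc_p < 1.0 / (self.n_sim + 1) - 1e-12:
            raise ValueError("Monte-Carlo p-value below its estimator floor")


def ks_statistic_discrete(observed_counts, model_cdf) -> float:
    """Discrete KS statistic: max |ECDF - model CDF| over observed atoms.

    ``model_cdf`` maps integer counts to cumulative probabilities (a dict
    or a callable); it must be non-decreasing and bounded by 1.
    """
    obs = np.asarray(observed_counts)
    if obs.size == 0:
        raise ValueError("empty observation set")
    atoms, counts = np.unique(obs, return_counts=True)
    ecdf = np.cumsum(counts) / obs.size
    if callable(model_cdf):
        f = np.asarray(model_cdf(atoms), dtype=float)
    else:
        f = np.array([model_cdf[a] for a in atoms], dtype=float)
    if np.any(np.diff(f) < -1e-12) or np.any(f > 1 + 1e-12):
        raise ValueError("model CDF must be non-decreasing and bounded by 1")
    return float(np.max(np.abs(ecdf - f)))


def _ecdf_function(sample: np.ndarray):
    srt = np.sort(sample)

    def cdf(x):
        return np.searchsorted(srt, np.asarray(x), side="right") / srt.size

    return cdf


def simulate_null_bin(model: NullModel, binning: DistanceBinning, bin_idx: int,
                      n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n null counts for one distance bin.

    Biases are resampled from the estimated bait and pooled other-end
    empirical distributions and the distance is uniform across the bin;
    the technical-noise component is omitted, per the small-distance
    approximation under which the NB null is tested.
    """
    lo = bin_idx * binning.width_bp
    hi = lo + binning.width_bp
    d = rng.uniform(lo if lo > 0 else 1.0, hi, size=n)
    s1 = rng.choice(model.bait_bias_values(), size=n)
    s2 = rng.choice(model.pooled_other_end_values(), size=n)
    mu = s1 * s2 * model.distance_fit.f(d)
    r = model.dispersion_r
    return rng.negative_binomial(r, r / (r + mu))


def ks_monte_carlo(observed_counts, model: NullModel, binning: DistanceBinning,
                   bin_idx: int, n_sim: int = 5000, n_pairs: int = 5000,
                   seed: int = 0) -> KSResult:
    """Monte-Carlo KS test of one distance bin against the null.

    Two independent pools of ``n_sim * n_pairs`` null draws are used: the
    first, pooled, supplies the reference model CDF; the second is split
    into ``n_sim`` replicates whose D statistics form the null D
    distribution.  The reported p-value is
    (1 + #{D_sim >= D_obs}) / (1 + n_sim), which is floored at
    1 / (n_sim + 1).
    """
    obs = np.asarray(observed_counts)
    if obs.size == 0:
        raise ValueError(f"no observed pairs in bin {bin_idx}")
    if n_sim < 100:
        warnings.warn(
            f"n_sim={n_sim} gives an unstable Monte-Carlo p-value floor "
            f"of {1 / (n_sim + 1):.3g}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    pool = simulate_null_bin(model, binning, bin_idx, n_sim * n_pairs, rng)
    cdf = _ecdf_function(pool)
    d_obs = ks_statistic_discrete(obs, cdf)
    sims = simulate_null_bin(model, binning, bin_idx, n_sim * n_pairs, rng)
    sims = sims.reshape(n_sim, n_pairs)
    d_sim = np.empty(n_sim)
    for i in range(n_sim):
        d_sim[i] = ks_statistic_discrete(sims[i], cdf)
    mc_p = (1 + int(np.sum(d_sim >= d_obs))) / (1 + n_sim)
    return KSResult(
        bin=bin_idx,
        label=binning.label(bin_idx),
        d_statistic=d_obs,
        mc_p=mc_p,
        n_sim=n_sim,
        n_pairs_per_sim=n_pairs,
        n_observed=int(obs.size),
    )


def bonferroni_ks(results: list[KSResult], alpha: float = 0.05) -> list[KSResult]:
    """Flag bins significant under a bin-wise Bonferroni correction."""
    if not results:
        raise ValueError("no KS results to correct")
    cutoff = alpha / len(results)
    for res in results:
        res.significant_after_bonferroni = bool(res.mc_p < cutoff)
    return results


def lambda_trend_diagnostic(pool_values: list) -> tuple[pd.DataFrame, bool]:
    """Summarise technical-noise pools and check the expected trend.

    Returns per-pool median, quartiles and variance, plus a flag that is
    true iff both the medians and the variances are non-decreasing (ties
    allowed) from the first pool to the last - the pattern expected when
    pooling tracks fragment visibility.
    """
    if len(pool_values) < 2:
        raise ValueError("need at least 2 pools for a trend diagnostic")
    rows = []
    for k, vals in enumerate(pool_values):
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            rows.append({"pool": k, "n": 0, "median": np.nan, "q1": np.nan,
                         "q3": np.nan, "variance": np.nan})
            continue
        rows.append(
            {
                "pool": k,
                "n": int(v.size),
                "median": float(np.median(v)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
                "variance": float(np.var(v)),
            }
        )
    summary = pd.DataFrame(rows)
    med = summary["median"].dropna().to_numpy()
    var = summary["variance"].dropna().to_numpy()
    trend = bool(
        np.all(np.diff(med) >= -1e-15) and np.all(np.diff(var) >= -1e-15)
    )
    return summary, trend
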