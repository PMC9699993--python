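"""The background model for capture Hi-C read counts, and its estimators.

The null for a bait/other-end pair at genomic distance d is a Delaporte
distribution: the convolution of a negative binomial NB(mu, r) describing
Brownian-collision background, with mean mu = s_i * s_j * f(d) (fragment
biases times a distance-decay function), and a Poisson(lambda) component
describing distance-independent technical noise.  Below ~1.5 Mb the
Poisson contribution is small and the model is well approximated by the
NB component alone; the full convolution is still available for p-values.

This module provides the probability machinery (pmf, upper-tail log
p-values), the distance-function estimator (per-bin geometric means of
non-zero counts, fitted on log-log scale as cubic / linear / theoretical
d^-1 curves with a curvature summary), simplified bias / dispersion /
technical-noise estimators, the prior-probability weight curve, and the
score statistic ``score = max(0, -log p + log w(d))`` used to rank
interactions.

All probability work happens in natural-log space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy.integrate import quad
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson

__all__ = [
    "DistanceBinning",
    "DistanceFit",
    "NullModel",
    "WeightCurve",
    "nb_pmf",
    "nb_logpmf",
    "delaporte_pmf",
    "delaporte_logpmf",
    "upper_tail_log_p",
    "upper_tail_log_p_vec",
    "enumerate_cis_pairs",
    "estimate_distance_function",
    "fit_distance_curves",
    "curvature_integral",
    "curvature_K",
    "estimate_dispersion",
    "estimate_biases",
    "estimate_lambda",
    "fit_weight_curve",
    "compute_scores",
    "DISPERSION_CAP",
]

DISPERSION_CAP = 1e6

# Distance range (bp) over which the decay curve is fitted; outside it the
# log-log curve is extrapolated linearly.
FIT_RANGE_BP = (1.0e4, 1.5e6)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceBinning:
    """Half-open distance bins (lower, upper] tiling (0, upper_bp].

    Defaults give 75 bins of 20 kb up to 1.5 Mb, the range over which the
    NB approximation to the Delaporte null is used.
    """

    width_bp: int = 20_000
    upper_bp: int = 1_500_000

    def __post_init__(self) -> None:
        if self.width_bp <= 0 or self.upper_bp <= 0:
            raise ValueError("bin width and upper bound must be positive")
        if self.upper_bp % self.width_bp != 0:
            raise ValueError("upper_bp must be a multiple of width_bp")

    @property
    def n_bins(self) -> int:
        return self.upper_bp // self.width_bp

    @property
    def edges(self) -> np.ndarray:
        return np.arange(0, self.upper_bp + self.width_bp, self.width_bp, dtype=float)

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + self.width_bp / 2.0

    def bin_index(self, distance_bp) -> np.ndarray:
        """Index of the bin containing each distance; -1 outside (0, upper]."""
        d = np.asarray(distance_bp, dtype=float)
        idx = np.ceil(d / self.width_bp).astype(int) - 1
        with np.errstate(invalid="ignore"):
            bad = ~((d > 0) & (d <= self.upper_bp))
        return np.where(bad, -1, idx)

    def label(self, b: int) -> str:
        lo, hi = b * self.width_bp, (b + 1) * self.width_bp
        return f"({lo:g},{hi:g}]"


# ---------------------------------------------------------------------------
# pmfs and tail probabilities
# ---------------------------------------------------------------------------

def _check_nb_params(mu, r) -> None:
    if np.any(np.asarray(mu) <= 0):
        raise ValueError("mu must be positive")
    if np.any(np.asarray(r) <= 0):
        raise ValueError("r must be positive")


def nb_logpmf(k, mu, r):
    """log NB pmf with mean ``mu`` and size (dispersion) ``r``.

    P(X=k) = Gamma(r+k)/(k! Gamma(r)) * (mu/(r+mu))^k * (r/(r+mu))^r.
    """
    _check_nb_params(mu, r)
    return nbinom.logpmf(k, r, r / (r + np.asarray(mu, dtype=float)))


def nb_pmf(k, mu, r):
    return np.exp(nb_logpmf(k, mu, r))


def delaporte_logpmf(k: int, mu: float, r: float, lam: float) -> float:
    """log pmf of NB(mu, r) + Poisson(lam), by exact finite convolution."""
    _check_nb_params(mu, r)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if lam == 0:
        return float(nb_logpmf(k, mu, r))
    j = np.arange(0, k + 1)
    return float(logsumexp(poisson.logpmf(j, lam) + nb_logpmf(k - j, mu, r)))


def delaporte_pmf(k: int, mu: float, r: float, lam: float) -> float:
    return float(np.exp(delaporte_logpmf(k, mu, r, lam)))


def upper_tail_log_p(count: int, mu: float, r: float, lam: float = 0.0) -> float:
    """log P(X >= count) under the Delaporte null; 0 at count 0.

    With X = NB + Pois the survival function decomposes exactly as
    P(X >= c) = sum_{j<c} Pois(j) P(NB >= c-j) + P(Pois >= c),
    a finite sum computed in log space.
    """
    _check_nb_params(mu, r)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if count <= 0:
        return 0.0
    p = r / (r + mu)
    if lam == 0:
        return float(nbinom.logsf(count - 1, r, p))
    j = np.arange(0, count)
    terms = poisson.logpmf(j, lam) + nbinom.logsf(count - 1 - j, r, p)
    out = logsumexp(np.append(terms, poisson.logsf(count - 1, lam)))
    return float(min(out, 0.0))


def upper_tail_log_p_vec(counts, mus, r: float, lams) -> np.ndarray:
    """Vectorised ``upper_tail_log_p`` over pairs sharing the dispersion r.

    The Poisson convolution is truncated where its pmf falls below 1e-16
    of the total mass, which is exact to double precision for the small
    technical-noise rates that occur in practice.
    """
    counts = np.asarray(counts, dtype=int)
    mus = np.asarray(mus, dtype=float)
    lams = np.broadcast_to(np.asarray(lams, dtype=float), counts.shape).copy()
    _check_nb_params(mus, r)
    if np.any(lams < 0):
        raise ValueError("lam must be nonnegative")
    p = r / (r + mus)
    out = np.zeros(counts.shape, dtype=float)
    pos = counts > 0
    if not pos.any():
        return out
    nolam = pos & (lams == 0)
    out[nolam] = nbinom.logsf(counts[nolam] - 1, r, p[nolam])
    conv = pos & (lams > 0)
    if conv.any():
        c = counts[conv]
        lam = lams[conv]
        pc = p[conv]
        jmax = int(min(c.max() - 1, np.max(poisson.isf(1e-16, lam.max())) + 1))
        terms = [poisson.logsf(c - 1, lam)]
        for j in range(jmax + 1):
            ok = j <= c - 1
            t = np.full(c.shape, -np.inf)
            t[ok] = poisson.logpmf(j, lam[ok]) + nbinom.logsf(c[ok] - 1 - j, r, pc[ok])
            terms.append(t)
        out[conv] = np.minimum(logsumexp(np.stack(terms, axis=0), axis=0), 0.0)
    return out


# ---------------------------------------------------------------------------
# distance function
# ---------------------------------------------------------------------------

@dataclass
class DistanceFit:
    """A log-log fit of the distance-decay function f(d).

    ``coeffs`` are polynomial coefficients of log f in log d, lowest order
    first: cubic (a0..a3), linear (b0, b1), theoretical (c0, -1).  Outside
    ``fit_range_bp`` the curve is extrapolated linearly on the log-log
    scale, so its curvature there is zero by construction.
    """

    kind: str
    coeffs: np.ndarray
    rss: float = 0.0
    fit_range_bp: tuple = FIT_RANGE_BP

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.kind not in {"cubic", "linear", "theoretical"}:
            raise ValueError(f"unknown fit kind {self.kind!r}")

    def log_f(self, d) -> np.ndarray:
        x = np.log(np.asarray(d, dtype=float))
        lo, hi = np.log(self.fit_range_bp[0]), np.log(self.fit_range_bp[1])
        xc = np.clip(x, lo, hi)
        y = npoly.polyval(xc, self.coeffs)
        slope = npoly.polyval(xc, npoly.polyder(self.coeffs))
        return y + slope * (x - xc)

    def f(self, d) -> np.ndarray:
        return np.exp(self.log_f(d))

    @property
    def curvature(self) -> float:
        return curvature_K(self)


def estimate_distance_function(interactions, binning: DistanceBinning) -> pd.DataFrame:
    """Per-bin geometric mean of the non-zero read counts.

    ``interactions`` is a DataFrame with ``distance_bp`` and ``count``
    columns restricted to cis pairs.  Returns one row per bin with the
    geometric mean over strictly positive counts; bins without any
    positive count are flagged ``empty`` (not zero).
    """
    if hasattr(interactions, "records"):
        interactions = interactions.cis
    if len(interactions) == 0:
        raise ValueError("empty interaction table")
    d = interactions["distance_bp"].to_numpy(dtype=float)
    n = interactions["count"].to_numpy(dtype=float)
    idx = binning.bin_index(d)
    keep = (idx >= 0) & (n > 0)
    frame = pd.DataFrame({"bin": idx[keep], "logn": np.log(n[keep])})
    agg = frame.groupby("bin")["logn"].agg(["mean", "size"])
    out = pd.DataFrame(
        {
            "bin": np.arange(binning.n_bins),
            "center_bp": binning.centers,
            "geo_mean": np.nan,
            "n_nonzero": 0,
            "empty": True,
        }
    )
    out.loc[agg.index, "geo_mean"] = np.exp(agg["mean"].to_numpy())
    out.loc[agg.index, "n_nonzero"] = agg["size"].to_numpy()
    out.loc[agg.index, "empty"] = False
    return out


def fit_distance_curves(bin_estimates: pd.DataFrame, binning: DistanceBinning,
                        ) -> dict[str, DistanceFit]:
    """Least-squares cubic, linear and theoretical (slope -1) log-log fits.

    Fits use bins that are non-empty and whose centers fall inside the
    canonical fit range.  Requires at least 5 usable bins.
    """
    usable = bin_estimates[
        (~bin_estimates["empty"])
        & (bin_estimates["center_bp"] >= FIT_RANGE_BP[0])
        & (bin_estimates["center_bp"] <= FIT_RANGE_BP[1])
    ]
    if len(usable) < 5:
        raise ValueError(
            f"only {len(usable)} usable distance bins; need at least 5 to fit"
        )
    x = np.log(usable["center_bp"].to_numpy())
    y = np.log(usable["geo_mean"].to_numpy())
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all bins at one distance")

    fits = {}
    for kind, deg in (("cubic", 3), ("linear", 1)):
        coeffs = npoly.polyfit(x, y, deg)
        resid = y - npoly.polyval(x, coeffs)
        fits[kind] = DistanceFit(kind=kind, coeffs=coeffs, rss=float(resid @ resid))
    c0 = float(np.mean(y + x))  # least squares with slope fixed at -1
    resid = y - (c0 - x)
    fits["theoretical"] = DistanceFit(
        kind="theoretical", coeffs=np.array([c0, -1.0]), rss=float(resid @ resid)
    )
    return fits


def curvature_integral(ycoeffs, x0: float, x1: float) -> float:
    """Integral of the curvature |y''| / (1 + y'^2)^(3/2) of a polynomial."""
    ycoeffs = np.asarray(ycoeffs, dtype=float)
    d1 = npoly.polyder(ycoeffs)
    d2 = npoly.polyder(ycoeffs, 2)
    if d2.size == 0 or np.allclose(d2, 0):
        return 0.0

    def kappa(x):
        return np.abs(npoly.polyval(x, d2)) / (1 + npoly.polyval(x, d1) ** 2) ** 1.5

    val, _ = quad(kappa, x0, x1, limit=200)
    return float(val)


def curvature_K(fit: DistanceFit) -> float:
    """Deviation of a log-log fit from a power law: integrated curvature.

    A straight line on the log-log scale (linear or theoretical fit) has
    K = 0 exactly.
    """
    x0, x1 = np.log(fit.fit_range_bp[0]), np.log(fit.fit_range_bp[1])
    return curvature_integral(fit.coeffs, x0, x1)


# ---------------------------------------------------------------------------
# pair enumeration (map geometry)
# ---------------------------------------------------------------------------

def enumerate_cis_pairs(fmap, max_distance_bp: float) -> pd.DataFrame:
    """All testable directed cis pairs (bait -> other fragment) on the map.

    Bait-bait pairs appear once, keyed with the smaller id in the bait
    role; ``compute_scores`` re-emits both directions.  Columns:
    ``bait_id``, ``other_id``, ``distance_bp``, ``bait_bait``.
    """
    frags = fmap.fragments
    mids = (frags["start"].to_numpy() + frags["end"].to_numpy()) / 2.0
    ids = frags["id"].to_numpy()
    chroms = frags["chrom"].to_numpy()
    is_bait = np.isin(ids, list(fmap.bait_ids))
    rows = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        cid, cmid, cbait = ids[sel], mids[sel], is_bait[sel]
        order = np.argsort(cmid, kind="stable")
        cid, cmid, cbait = cid[order], cmid[order], cbait[order]
        for i in np.flatnonzero(cbait):
            d = np.abs(cmid - cmid[i])
            ok = (d > 0) & (d <= max_distance_bp)
            # avoid double-listing bait-bait pairs
            ok &= ~(cbait & (cid < cid[i]))
            rows.append(
                pd.DataFrame(
                    {
                        "bait_id": cid[i],
                        "other_id": cid[ok],
                        "distance_bp": d[ok],
                        "bait_bait": cbait[ok],
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["bait_id", "other_id", "distance_bp", "bait_bait"])
    return pd.concat(rows, ignore_index=True)


def _attach_counts(pairs: pd.DataFrame, table) -> pd.DataFrame:
    """Left-join observed counts onto enumerated pairs (0 where unobserved)."""
    rec = table.cis if hasattr(table, "records") else table
    rec = rec[["bait_id", "other_id", "count"]]
    # bait-bait rows may be stored in either orientation
    lo = np.minimum(pairs["bait_id"], pairs["other_id"])
    hi = np.maximum(pairs["bait_id"], pairs["other_id"])
    key = pd.MultiIndex.from_arrays([lo, hi])
    rlo = np.minimum(rec["bait_id"], rec["other_id"])
    rhi = np.maximum(rec["bait_id"], rec["other_id"])
    counts = pd.Series(rec["count"].to_numpy(),
                       index=pd.MultiIndex.from_arrays([rlo, rhi]))
    counts = counts.groupby(level=[0, 1]).sum()
    out = pairs.copy()
    out["count"] = counts.reindex(key).fillna(0).to_numpy(dtype=int)
    return out


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Everything needed to score a pair under the background model.

    Bait biases are fixed per-bait multipliers; other-end biases are
    treated as draws from pooled empirical distributions (fragments
    stratified into quantile pools), the structural asymmetry that makes
    bait-bait scores direction-dependent.  ``lambda_pools`` carries the
    per-pool technical-noise rates.
    """

    distance_fit: DistanceFit
    dispersion_r: float
    bait_bias: dict = field(default_factory=dict)
    other_end_bias: dict = field(default_factory=dict)     # per-fragment values
    other_end_pool_of: dict = field(default_factory=dict)  # fragment -> pool
    other_end_pool_values: list = field(default_factory=list)
    lambda_pools: np.ndarray = field(default_factory=lambda: np.zeros(1))
    unestimable_baits: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.dispersion_r <= 0:
            raise ValueError("dispersion_r must be positive")
        self.lambda_pools = np.asarray(self.lambda_pools, dtype=float)
        if np.any(self.lambda_pools < 0):
            raise ValueError("lambda values must be nonnegative")

    @property
    def other_end_pool_means(self) -> np.ndarray:
        return np.array(
            [np.mean(v) if len(v) else 1.0 for v in self.other_end_pool_values]
        )

    def other_role_bias(self, ids) -> np.ndarray:
        """Expected bias of a fragment acting in the other-end role."""
        means = self.other_end_pool_means
        return np.array(
            [means[self.other_end_pool_of.get(i, 0)] if len(means) else 1.0
             for i in np.asarray(ids)]
        )

    def lam(self, ids) -> np.ndarray:
        if self.lambda_pools.size == 0:
            return np.zeros(len(np.asarray(ids)))
        return np.array(
            [self.lambda_pools[self.other_end_pool_of.get(i, 0)]
             for i in np.asarray(ids)]
        )

    def bait_bias_values(self) -> np.ndarray:
        return np.array(sorted(self.bait_bias.values()))

    def pooled_other_end_values(self) -> np.ndarray:
        if not self.other_end_pool_values:
            return np.array([1.0])
        return np.concatenate([np.asarray(v) for v in self.other_end_pool_values])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def estimate_dispersion(counts, mus, cap: float = DISPERSION_CAP) -> float:
    """Profile maximum-likelihood NB dispersion r with fixed per-pair means.

    One-dimensional optimisation on log r (bounded Brent, tolerance 1e-6).
    Under-dispersed data (sample variance <= mean of the Pearson scale)
    returns the cap with a warning, since r is then unidentifiable.
    """
    counts = np.asarray(counts, dtype=float)
    mus = np.asarray(mus, dtype=float)
    if counts.size == 0:
        raise ValueError("no counts to estimate dispersion from")
    _check_nb_params(mus, 1.0)

    # no evidence of overdispersion (2 SEs of the Poisson-null Pearson stat)
    pearson = np.sum((counts - mus) ** 2 / mus) / counts.size
    if pearson <= 1.0 + 2.0 * np.sqrt(2.0 / counts.size):
        warnings.warn(
            "data not overdispersed relative to the NB model; "
            f"dispersion capped at {cap:g}",
            stacklevel=2,
        )
        return cap

    def nll(logr):
        r = np.exp(logr)
        return -np.sum(nb_logpmf(counts, mus, r))

    res = minimize_scalar(nll, bounds=(np.log(1e-3), np.log(cap)),
                          method="bounded", options={"xatol": 1e-6})
    r_hat = float(np.exp(res.x))
    if r_hat >= cap * 0.99:
        warnings.warn(
            "data not overdispersed relative to the NB model; "
            f"dispersion capped at {cap:g}",
            stacklevel=2,
        )
        return cap
    return r_hat


@dataclass
class BiasEstimate:
    bait_bias: dict
    unestimable_baits: frozenset
    other_end_bias: dict
    pool_of: dict
    pool_values: list


def _geometric_normalise(values: dict) -> dict:
    g = np.exp(np.mean(np.log(np.array(list(values.values())))))
    return {k: v / g for k, v in values.items()}


def estimate_biases(table, fmap, distance_fit: DistanceFit,
                    binning: DistanceBinning, n_pools: int = 5) -> BiasEstimate:
    """Two-pass weighted ratio estimator for fragment-level biases.

    Pass 1 regresses each bait's observed counts on the expected counts
    under f(d) with unit biases; the slope is the bait bias s_i.  The
    regression is inverse-variance weighted under a working NB variance
    mu + mu^2/r0 (r0 from a method-of-moments fit), so hypervariable
    high-mean pairs cannot dominate.  Biases are normalised to geometric
    mean 1 across baits.  Pass 2 repeats the regression per other end
    given the bait biases; other ends are stratified into ``n_pools``
    quantile pools by marginal count, each pool summarised as an
    empirical distribution of (positive) ratios, jointly normalised to
    geometric mean 1.  Baits or other ends with no usable signal are
    flagged unestimable rather than given a bias of zero.

    This is deliberately a simplified estimator: it preserves the
    fixed-bait / random-other-end asymmetry of the full caller without
    its iterative machinery.  Pairs closer than the lower edge of the
    distance-fit range are excluded: there f(d) is an extrapolation and
    the counts are hypervariable, so they would dominate the ratio's
    variance without informing the bias.
    """
    pairs = enumerate_cis_pairs(fmap, binning.upper_bp)
    pairs = pairs[
        pairs["distance_bp"] >= distance_fit.fit_range_bp[0]
    ].reset_index(drop=True)
    pairs = _attach_counts(pairs, table)
    f_d = distance_fit.f(pairs["distance_bp"].to_numpy())
    pairs = pairs.assign(f_d=f_d)

    # working dispersion for the variance weights (method of moments)
    k = pairs["count"].to_numpy(dtype=float)
    excess = np.sum((k - f_d) ** 2) - f_d.sum()
    r0 = float(np.clip(np.sum(f_d**2) / max(excess, 1e-12), 0.1, DISPERSION_CAP))

    def _wls_slope(grp):
        mu = grp["f_d"].to_numpy()
        kk = grp["count"].to_numpy(dtype=float)
        w = 1.0 / (mu + mu**2 / r0)
        denom = np.sum(w * mu**2)
        return np.sum(w * mu * kk) / denom if denom > 0 else np.nan

    # pass 1: baits (bait-bait pairs contribute to both baits' totals)
    fwd = pairs[["bait_id", "count", "f_d"]]
    rev = pairs.loc[pairs["bait_bait"], ["other_id", "count", "f_d"]].rename(
        columns={"other_id": "bait_id"}
    )
    both = pd.concat([fwd, rev])
    bait_bias = {}
    unestimable = []
    for bid, grp in both.groupby("bait_id"):
        s = _wls_slope(grp)
        if not np.isfinite(s) or s <= 0:
            unestimable.append(bid)
        else:
            bait_bias[bid] = s
    for bid in fmap.bait_ids:
        if bid not in bait_bias and bid not in unestimable:
            unestimable.append(bid)
    if not bait_bias:
        raise ValueError("no bait bias estimable from the data")
    bait_bias = _geometric_normalise(bait_bias)

    # pass 2: other ends, given bait biases
    s_bait = pairs["bait_id"].map(bait_bias)
    ok = s_bait.notna()
    oe = pairs[ok].assign(f_d=s_bait[ok] * pairs.loc[ok, "f_d"])
    ratio = oe.groupby("other_id")[["f_d", "count"]].apply(_wls_slope)
    per_oe = oe.groupby("other_id")[["count"]].sum()
    positive = ratio[ratio > 0]
    if len(positive) == 0:
        raise ValueError("no other-end bias estimable from the data")
    g = np.exp(np.mean(np.log(positive.to_numpy())))
    other_end_bias = dict(positive / g)

    # quantile pools by marginal count
    marg = per_oe.loc[positive.index, "count"]
    qs = np.quantile(marg, np.linspace(0, 1, n_pools + 1))
    pool_idx = np.clip(np.searchsorted(qs[1:-1], marg, side="right"), 0, n_pools - 1)
    pool_of = dict(zip(positive.index, pool_idx.astype(int)))
    pool_values = [
        np.sort([other_end_bias[i] for i, p in pool_of.items() if p == k])
        for k in range(n_pools)
    ]
    return BiasEstimate(
        bait_bias=bait_bias,
        unestimable_baits=frozenset(unestimable),
        other_end_bias=other_end_bias,
        pool_of=pool_of,
        pool_values=pool_values,
    )


@dataclass
class LambdaEstimate:
    lambda_pools: np.ndarray
    pool_of: dict
    pool_values: list           # per-fragment rate estimates, by pool
    mean_trans_pairs_per_bait: float


def estimate_lambda(table, fmap, n_pools: int = 5) -> LambdaEstimate:
    """Technical-noise rates from trans-chromosomal pairs.

    Every observed read between fragments on different chromosomes is
    attributed to noise.  Fragments are stratified into ``n_pools``
    quantile pools by marginal trans count; the pool rate is total trans
    reads divided by the number of possible trans pairs for fragments in
    the pool.  Also reports the mean number of observed trans pairs per
    bait, the companion diagnostic.
    """
    if hasattr(table, "records"):
        trans = table.trans
    else:
        trans = table[table["trans"]] if len(table) else table
    frags = fmap.fragments
    chroms = frags["chrom"].to_numpy()
    ids = frags["id"].to_numpy()
    bait_chrom = {b: c for b, c in zip(ids, chroms) if b in fmap.bait_ids}
    # possible trans partners per fragment = baits on a different chromosome
    n_baits_by_chrom = pd.Series(list(bait_chrom.values())).value_counts()
    n_baits = len(bait_chrom)
    possible = pd.Series(
        [n_baits - int(n_baits_by_chrom.get(c, 0)) for c in chroms], index=ids
    )
    eligible = possible[possible > 0]
    if len(eligible) == 0 or len(trans) == 0:
        warnings.warn("no trans pairs present; all lambda estimates are 0",
                      stacklevel=2)
        return LambdaEstimate(
            lambda_pools=np.zeros(n_pools),
            pool_of={int(i): 0 for i in eligible.index},
            pool_values=[np.array([])] * n_pools,
            mean_trans_pairs_per_bait=0.0,
        )
    marg = (
        trans.groupby("other_id")["count"].sum().reindex(eligible.index).fillna(0)
    )
    qs = np.quantile(marg, np.linspace(0, 1, n_pools + 1))
    pool_idx = np.clip(np.searchsorted(qs[1:-1], marg, side="right"), 0, n_pools - 1)
    pool_of = dict(zip(eligible.index, pool_idx.astype(int)))
    lam = np.zeros(n_pools)
    pool_values = []
    rate = marg / eligible
    for k in range(n_pools):
        members = marg.index[pool_idx == k]
        tot_possible = eligible.loc[members].sum()
        tot_counts = marg.loc[members].sum()
        lam[k] = tot_counts / tot_possible if tot_possible > 0 else 0.0
        pool_values.append(np.sort(rate.loc[members].to_numpy()))
    mean_trans = len(trans[trans["count"] > 0]) / max(n_baits, 1)
    return LambdaEstimate(
        lambda_pools=lam,
        pool_of={int(k): int(v) for k, v in pool_of.items()},
        pool_values=pool_values,
        mean_trans_pairs_per_bait=float(mean_trans),
    )


# ---------------------------------------------------------------------------
# weight curve
# ---------------------------------------------------------------------------

@dataclass
class WeightCurve:
    """Four-parameter bounded logistic prior-probability-vs-distance curve.

    ``params`` = (lower asymptote, upper asymptote, midpoint on the
    log-distance axis, slope >= 0):

        w(d) = lower + (upper - lower) / (1 + exp(slope * (log d - mid)))

    which is monotone non-increasing in log distance with values in
    [lower, upper] subset of [0, 1].
    """

    params: tuple
    rss: float = 0.0
    n_zero_bins: int = 0

    def __post_init__(self) -> None:
        lower, upper, mid, slope = self.params
        if not (0 <= lower <= upper <= 1):
            raise ValueError("asymptotes must satisfy 0 <= lower <= upper <= 1")
        if slope < 0:
            raise ValueError("slope must be nonnegative (non-increasing curve)")

    def weight(self, d) -> np.ndarray:
        lower, upper, mid, slope = self.params
        x = np.log(np.asarray(d, dtype=float))
        return lower + (upper - lower) / (1.0 + np.exp(slope * (x - mid)))

    def log_weight(self, d) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.weight(d))


def _logistic4(x, lower, delta, mid, slope):
    return lower + delta / (1.0 + np.exp(slope * (x - mid)))


def fit_weight_curve(observed_prior: pd.DataFrame, binning: DistanceBinning,
                     ) -> WeightCurve:
    """Bounded least-squares fit of the logistic prior curve.

    ``observed_prior`` has per-bin columns ``prior`` and ``empty``; bins
    with no observed interactions are excluded from the objective (their
    count is reported as ``n_zero_bins``).  Three deterministic starting
    points guard against local minima; monotonicity is enforced through a
    nonnegative slope bound.
    """
    contributing = observed_prior[~observed_prior["empty"].astype(bool)]
    n_zero = int(len(observed_prior) - len(contributing))
    if len(contributing) < 4:
        raise ValueError(
            f"only {len(contributing)} distance bins with observed interactions; "
            "need at least 4 to fit the weight curve"
        )
    x = np.log(binning.centers[contributing["bin"].to_numpy(dtype=int)])
    yobs = contributing["prior"].to_numpy(dtype=float)

    lo = np.array([0.0, 0.0, x.min() - 5.0, 0.0])
    hi = np.array([1.0, 1.0, x.max() + 5.0, 50.0])
    y0, y1 = float(yobs[-1]), float(yobs[0])
    starts = [
        np.array([max(y0, 1e-4), max(y1 - y0, 1e-4), np.median(x), s])
        for s in (0.5, 2.0, 5.0)
    ]

    def resid(p):
        return _logistic4(x, *p) - yobs

    best = None
    for p0 in starts:
        sol = least_squares(resid, np.clip(p0, lo, hi), bounds=(lo, hi))
        if best is None or sol.cost < best.cost:
            best = sol
    lower, delta, mid, slope = best.x
    upper = min(lower + delta, 1.0)
    r = resid(best.x)
    return WeightCurve(
        params=(float(lower), float(upper), float(mid), float(slope)),
        rss=float(r @ r),
        n_zero_bins=n_zero,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def compute_scores(table, fmap, model: NullModel, weights: WeightCurve,
                   binning: DistanceBinning | None = None,
                   symmetrized: bool = False) -> pd.DataFrame:
    """Score every directed cis pair under the null model.

    For a pair with bait i and other end j at distance d the upper-tail
    log p-value is computed under Delaporte(s_i * s_j * f(d), r, lambda)
    and combined with the prior weight as

        score = max(0, -log p + log w(d)).

    The bait-role fragment always uses its fixed bait bias; the
    other-role fragment is represented by its pool's expected bias, so
    bait-bait pairs (emitted in both directions) generally receive
    direction-dependent scores.  ``symmetrized=True`` makes both roles of
    a bait-bait pair use the fixed bait biases, which restores exact
    symmetry.  Pairs involving a bait with no estimable bias are dropped
    (with a logged count).  Zero-count pairs score 0 by construction.
    """
    binning = binning or DistanceBinning()
    pairs = enumerate_cis_pairs(fmap, binning.upper_bp)
    pairs = _attach_counts(pairs, table)

    rows = [pairs]
    bb = pairs[pairs["bait_bait"]]
    if len(bb):
        rows.append(
            bb.rename(columns={"bait_id": "other_id", "other_id": "bait_id"})
        )
    directed = pd.concat(rows, ignore_index=True)

    s_bait = directed["bait_id"].map(model.bait_bias)
    keep = s_bait.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logging.getLogger(__name__).warning(
            "dropped %d directed pairs with unestimable bait bias", n_dropped
        )
    directed = directed[keep].reset_index(drop=True)
    s_bait = s_bait[keep].to_numpy(dtype=float)

    other_ids = directed["other_id"].to_numpy()
    if symmetrized:
        s_other = np.where(
            directed["bait_bait"],
            directed["other_id"].map(model.bait_bias).fillna(1.0),
            model.other_role_bias(other_ids),
        )
    else:
        s_other = model.other_role_bias(other_ids)

    d = directed["distance_bp"].to_numpy(dtype=float)
    mu = s_bait * s_other * model.distance_fit.f(d)
    lam = model.lam(other_ids)
    counts = directed["count"].to_numpy(dtype=int)
    log_p = upper_tail_log_p_vec(counts, mu, model.dispersion_r, lam)
    w = np.clip(weights.weight(d), 1e-300, 1.0)
    score = np.maximum(0.0, -log_p + np.log(w))
    return pd.DataFrame(
        {
            "bait_id": directed["bait_id"].to_numpy(),
            "other_id": other_ids,
            "distance_bp": d,
            "count": counts,
            "log_p": log_p,
            "weight": w,
            "score": score,
            "bait_bait": directed["bait_bait"].to_numpy(),
        }
    )
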