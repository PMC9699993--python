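"""Audit of the interaction score statistic and its thresholds.

The caller's score combines an upper-tail p-value with a distance-based
prior weight, and interactions are declared at score > 5 (the "normal
score threshold", NST).  This module measures how well that convention
behaves: bait-bait score symmetry and the fraction of "reversible"
bait-bait calls; the false-negative-rate function

    g(rho) = |{pairs: score < t and log p < rho}| / |{pairs: log p < rho}|

whose value at rho = -10 is an FNR for robust interactions; a replicate
reproducibility FDR proxy (1 - Jaccard index of significant sets); a
family-wise Bonferroni score threshold anchored on the smallest distance
bin; and alternative "suggested score thresholds" (SSTs) found by fixing
the FNR or numerically minimising the FDR proxy with either a bounded
quasi-Newton method (L-BFGS-B) or the Nelder-Mead simplex - two
optimisers that can disagree markedly on this piecewise-constant
objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "SymmetryResult",
    "ThresholdReport",
    "jaccard",
    "pair_directed_scores",
    "score_symmetry",
    "percent_reversible",
    "fnr_g",
    "solve_rho",
    "replicate_fdr",
    "fwer_score_threshold",
    "significant_set",
    "sst_for_fnr",
    "sst_minimising_fdr",
]

NST = 5.0  # the advocated score threshold for declaring an interaction


def jaccard(*sets) -> float:
    """|intersection| / |union| of two or more finite sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    sets = [set(s) for s in sets]
    union = set.union(*sets)
    if not union:
        raise ValueError("Jaccard index undefined: all sets empty")
    inter = set.intersection(*sets)
    return len(inter) / len(union)


# ---------------------------------------------------------------------------
# bait-bait symmetry
# ---------------------------------------------------------------------------

def pair_directed_scores(scored: pd.DataFrame) -> pd.DataFrame:
    """Match the two directions of each bait-bait pair.

    Returns one row per undirected pair (keyed by sorted ids) with the
    forward score (smaller id in the bait role) and the reverse score.
    """
    bb = scored[scored["bait_bait"]]
    if bb.empty:
        return pd.DataFrame(columns=["id_a", "id_b", "score_fwd", "score_rev"])
    lo = np.minimum(bb["bait_id"], bb["other_id"])
    hi = np.maximum(bb["bait_id"], bb["other_id"])
    fwd = bb["bait_id"].to_numpy() == lo.to_numpy()
    df = pd.DataFrame(
        {"id_a": lo.to_numpy(), "id_b": hi.to_numpy(),
         "score": bb["score"].to_numpy(), "fwd": fwd}
    )
    piv = df.pivot_table(index=["id_a", "id_b"], columns="fwd", values="score")
    piv = piv.dropna()
    out = piv.reset_index()
    out.columns = ["id_a", "id_b", "score_rev", "score_fwd"]
    return out[["id_a", "id_b", "score_fwd", "score_rev"]]


@dataclass
class SymmetryResult:
    correlation: float | None
    n_used: int
    top_deviations: pd.DataFrame


def score_symmetry(scored: pd.DataFrame) -> SymmetryResult:
    """Pearson correlation between bait-bait scores and their reverses.

    Pairs where both directions score zero are excluded, so the many
    non-interacting pairs cannot inflate the correlation.  Also reports
    the 5 pairs with the largest squared score difference.
    """
    pairs = pair_directed_scores(scored)
    nz = pairs[(pairs["score_fwd"] > 0) | (pairs["score_rev"] > 0)].copy()
    nz["sq_dev"] = (nz["score_fwd"] - nz["score_rev"]) ** 2
    top = nz.nlargest(5, "sq_dev")
    if len(nz) < 3:
        warnings.warn(
            f"only {len(nz)} bait-bait pairs with a non-zero score; "
            "symmetry correlation not computed",
            stacklevel=2,
        )
        return SymmetryResult(correlation=None, n_used=len(nz), top_deviations=top)
    x = nz["score_fwd"].to_numpy()
    y = nz["score_rev"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        corr = 1.0 if np.allclose(x, y) else None
    else:
        corr = float(np.corrcoef(x, y)[0, 1])
    return SymmetryResult(correlation=corr, n_used=len(nz), top_deviations=top)


def percent_reversible(scored: pd.DataFrame, threshold: float = NST) -> float | None:
    """Fraction of bait-bait pairs significant in both directions.

    Computed as the Jaccard index of {pairs with forward score > t} and
    {pairs with reverse score > t}; None (with a warning) when neither
    direction has a significant pair.
    """
    pairs = pair_directed_scores(scored)
    a = set(map(tuple, pairs.loc[pairs["score_fwd"] > threshold,
                                 ["id_a", "id_b"]].to_numpy()))
    b = set(map(tuple, pairs.loc[pairs["score_rev"] > threshold,
                                 ["id_a", "id_b"]].to_numpy()))
    if not a and not b:
        warnings.warn("no bait-bait pair significant in either direction",
                      stacklevel=2)
        return None
    return jaccard(a, b)


# ---------------------------------------------------------------------------
# FNR function g(rho)
# ---------------------------------------------------------------------------

def fnr_g(scored: pd.DataFrame, rho: float, threshold: float = NST) -> float:
    """Fraction of robust pairs (log p < rho) failing the score threshold."""
    robust = scored[scored["log_p"] < rho]
    if robust.empty:
        raise ValueError(f"no pairs with log p below rho={rho}")
    return float(np.mean(robust["score"].to_numpy() < threshold))


def solve_rho(scored: pd.DataFrame, target: float = 0.05,
              threshold: float = NST, grid=(-50.0, -1.0), step: float = 0.1,
              ) -> float | None:
    """The rho at which g(rho) crosses ``target``, if it exists.

    Scans rho over ``grid`` at ``step`` resolution, then bisects between
    the bracketing grid points.  Returns None (with a warning) when g
    never crosses the target on the grid.
    """
    log_p = scored["log_p"].to_numpy()
    score = scored["score"].to_numpy()

    def g(rho):
        mask = log_p < rho
        if not mask.any():
            return None
        return float(np.mean(score[mask] < threshold))

    rhos = np.arange(grid[0], grid[1] + step / 2, step)
    vals = [g(r) for r in rhos]
    best = None
    for r, v in zip(rhos, vals):
        if v is not None and (best is None or abs(v - target) < abs(best[1] - target)):
            best = (float(r), v)
    bracket = None
    for (r1, v1), (r2, v2) in zip(zip(rhos, vals), zip(rhos[1:], vals[1:])):
        if v1 is None or v2 is None:
            continue
        if v1 == target:
            return float(r1)
        if (v1 - target) * (v2 - target) < 0:
            bracket = (float(r1), float(r2))
            break
    if bracket is None:
        if best is not None and best[1] == target:
            return best[0]
        warnings.warn(
            f"g(rho) never crosses {target} on [{grid[0]}, {grid[1]}]",
            stacklevel=2,
        )
        return None
    lo, hi = bracket
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        v = g(mid)
        if v is None:
            lo = mid
            continue
        if abs(v - target) < abs(best[1] - target):
            best = (mid, v)
        if (g(lo) - target) * (v - target) <= 0:
            hi = mid
        else:
            lo = mid
    return float(best[0])


# ---------------------------------------------------------------------------
# replicate reproducibility and thresholds
# ---------------------------------------------------------------------------

def replicate_fdr(significant_sets: list) -> float:
    """FDR proxy: 1 - Jaccard index of per-replicate significant sets.

    Under the idealisation that true interactions are significant in all
    replicates and false ones in none, the non-reproduced fraction is the
    false-discovery rate.
    """
    if len(significant_sets) < 2:
        raise ValueError("need at least two replicates")
    return 1.0 - jaccard(*significant_sets)


def fwer_score_threshold(n_pairs_smallest_bin: int, alpha: float = 0.05) -> float:
    """Bonferroni score threshold anchored on the smallest distance bin.

    Thresholding at score alpha demands more evidence than a proximal
    pair with p-value e^-alpha, so controlling the family-wise error rate
    over the n pairs of the first bin gives -log(alpha / n) = log(n / alpha).
    """
    if n_pairs_smallest_bin < 1:
        raise ValueError("smallest bin must contain at least one pair")
    return float(np.log(n_pairs_smallest_bin / alpha))


def significant_set(scored: pd.DataFrame, threshold: float) -> set:
    """Directed pairs with score strictly above the threshold."""
    sig = scored[scored["score"] > threshold]
    return set(zip(sig["bait_id"].astype(int), sig["other_id"].astype(int)))


def sst_for_fnr(scored: pd.DataFrame, target_fnr: float = 0.2,
                rho: float = -10.0, t_max: int = 100) -> int:
    """Integer score threshold whose FNR is closest to the target.

    FNR(t) is the fraction of robust pairs (log p < rho) with score < t;
    the scan covers t = 0..t_max and ties break toward the smaller
    threshold (favouring sensitivity).
    """
    robust = scored[scored["log_p"] < rho]
    if robust.empty:
        raise ValueError(f"no robust pairs at rho={rho}")
    s = robust["score"].to_numpy()
    ts = np.arange(0, t_max + 1)
    gap = np.array([abs(np.mean(s < t) - target_fnr) for t in ts])
    # smallest threshold among (numerically) tied minima
    return int(ts[gap <= gap.min() + 1e-9][0])


def sst_minimising_fdr(replicate_scored: list, optimiser: str = "quasi_newton",
                       init: float = NST, bounds: tuple = (0.0, 1e4),
                       ) -> tuple[int, float]:
    """Score threshold minimising the replicate-Jaccard FDR proxy.

    The objective t -> 1 - Jaccard(significant sets at t) is piecewise
    constant, so the outcome depends on the optimiser: ``quasi_newton``
    runs bound-constrained L-BFGS-B with forward-difference gradients
    (step 0.5), ``simplex`` runs Nelder-Mead.  The threshold is rounded
    to the nearest integer and the achieved FDR is re-evaluated there.
    """
    if len(replicate_scored) < 2:
        raise ValueError("need at least two replicates")
    score_arrays = [
        (df[["bait_id", "other_id"]].to_numpy(dtype=int), df["score"].to_numpy())
        for df in replicate_scored
    ]

    def objective(t):
        t = float(np.atleast_1d(t)[0])
        sets = [
            set(map(tuple, ids[s > t])) for (ids, s) in score_arrays
        ]
        if not any(sets):
            return 1.0
        return replicate_fdr(sets)

    if optimiser == "quasi_newton":
        res = minimize(
            objective, x0=[init], method="L-BFGS-B", bounds=[bounds],
            options={"eps": 0.5, "maxiter": 200},
        )
    elif optimiser == "simplex":
        res = minimize(objective, x0=[init], method="Nelder-Mead",
                       options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-9})
    else:
        raise ValueError(f"unknown optimiser {optimiser!r}")
    if not np.isfinite(res.x[0]):
        raise RuntimeError(f"optimiser failed: {res.message}")
    t_int = int(round(float(np.clip(res.x[0], *bounds))))
    return t_int, float(objective(t_int))


@dataclass
class ThresholdReport:
    """The battery of suggested score thresholds and quality statistics."""

    nst: float
    sst_fnr: int
    sst_fdr_quasi_newton: int
    fdr_at_sst_quasi_newton: float
    sst_fdr_simplex: int
    fdr_at_sst_simplex: float
    sst_fwer: int
    fwer_threshold_exact: float
    fdr_at_nst: float | None
    fnr_at_nst: float | None
    rho_star: float | None
    n_significant_at_nst: int
    n_significant_at_sst_fwer: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])
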