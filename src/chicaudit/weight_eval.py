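"""Audit of the p-value weighting procedure.

The caller corrects p-values by the prior probability of interaction at
each distance, fitted as a monotone-decreasing logistic in log distance
from the fraction of pairs reproducibly significant (log p < rho in all
replicates) per distance bin.  This module quantifies how well that model
matches data: a lack-of-monotonicity statistic of the observed per-bin
priors (0 for a monotone sequence, approaching 1 for maximal
oscillation), the fit RSS with zero-observation bins excluded (and their
count reported, since excluding them deflates the RSS), and the effect of
re-estimating the weights at an alternative reproducibility threshold -
captured as the Jaccard concordance between significant calls under
default and re-estimated weights, together with the induced change in the
headline quality statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import DistanceBinning, WeightCurve, fit_weight_curve
from .score_eval import (
    NST,
    fnr_g,
    jaccard,
    percent_reversible,
    replicate_fdr,
    score_symmetry,
    significant_set,
)

__all__ = [
    "WeightEvalReport",
    "lack_of_monotonicity",
    "observed_prior",
    "weight_fit_rss",
    "rescore_with_weights",
    "reweight_and_compare",
]


def lack_of_monotonicity(v) -> float:
    """LOM(v) = 1 - |v_n - v_1| / sum |v_{i+1} - v_i|, in [0, 1].

    Zero iff the sequence is (non-strictly) monotone.  A constant
    sequence has an undefined ratio and is monotone by convention, so it
    returns 0 with a warning.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    steps = np.abs(np.diff(v))
    denom = steps.sum()
    if denom == 0:
        warnings.warn("constant sequence: LOM defined as 0 by convention",
                      stacklevel=2)
        return 0.0
    return float(1.0 - abs(v[-1] - v[0]) / denom)


def observed_prior(scored_tables: list, binning: DistanceBinning,
                   rho: float = -10.0) -> pd.DataFrame:
    """Per-bin fraction of tested pairs reproducibly significant.

    A pair counts toward the prior when log p < rho in every replicate;
    pairs absent from any replicate are non-reproducible.  The
    denominator is the union of pairs tested in the bin.  Bins with no
    reproducible interaction are flagged ``empty``.
    """
    if not scored_tables:
        raise ValueError("no scored tables")
    keyed = []
    for df in scored_tables:
        k = pd.DataFrame(
            {
                "key": list(zip(df["bait_id"].astype(int),
                                df["other_id"].astype(int))),
                "distance_bp": df["distance_bp"].to_numpy(),
                "robust": (df["log_p"] < rho).to_numpy(),
            }
        ).set_index("key")
        keyed.append(k)
    union = keyed[0][["distance_bp"]]
    for k in keyed[1:]:
        union = union.combine_first(k[["distance_bp"]])
    robust_all = pd.Series(True, index=union.index)
    for k in keyed:
        robust_all &= k["robust"].reindex(union.index, fill_value=False).astype(bool)
    bins = binning.bin_index(union["distance_bp"].to_numpy())
    frame = pd.DataFrame({"bin": bins, "robust": robust_all.to_numpy()})
    frame = frame[frame["bin"] >= 0]
    agg = frame.groupby("bin")["robust"].agg(["mean", "sum", "size"])
    out = pd.DataFrame(
        {
            "bin": np.arange(binning.n_bins),
            "prior": 0.0,
            "n_tested": 0,
            "n_reproducible": 0,
        }
    )
    out.loc[agg.index, "prior"] = agg["mean"].to_numpy()
    out.loc[agg.index, "n_tested"] = agg["size"].to_numpy()
    out.loc[agg.index, "n_reproducible"] = agg["sum"].to_numpy(dtype=int)
    out["empty"] = out["n_reproducible"] == 0
    return out


def weight_fit_rss(curve: WeightCurve, observed: pd.DataFrame,
                   binning: DistanceBinning) -> tuple[float, int]:
    """RSS of a weight curve over non-empty bins, on the prior scale.

    Empty bins contribute nothing to the RSS (their implied prior of 0
    would make the weighted log p infinite) but their count is returned
    alongside, making the artificial-deflation caveat visible.
    """
    contributing = observed[~observed["empty"].astype(bool)]
    n_zero = int(len(observed) - len(contributing))
    if contributing.empty:
        raise ValueError("all distance bins are empty")
    centers = binning.centers[contributing["bin"].to_numpy(dtype=int)]
    resid = contributing["prior"].to_numpy(dtype=float) - curve.weight(centers)
    return float(resid @ resid), n_zero


def rescore_with_weights(scored: pd.DataFrame, curve: WeightCurve) -> pd.DataFrame:
    """Recompute scores from stored log p-values under a new weight curve."""
    w = np.clip(curve.weight(scored["distance_bp"].to_numpy()), 1e-300, 1.0)
    out = scored.copy()
    out["weight"] = w
    out["score"] = np.maximum(0.0, -out["log_p"].to_numpy() + np.log(w))
    return out


@dataclass
class WeightEvalReport:
    lom: float
    rss: float
    n_zero_bins: int
    rho_used: float
    curve: WeightCurve
    reweight_jaccard: float | None
    delta_score_correlation: float | None
    delta_percent_reversible: float | None
    delta_fdr_at_nst: float | None
    delta_fnr: float | None
    notes: list


def _battery(scored_tables: list, threshold: float, rho: float) -> dict:
    """Headline quality statistics for a set of replicate scored tables."""
    first = scored_tables[0]
    sym = score_symmetry(first)
    rev = percent_reversible(first, threshold)
    try:
        fnr = fnr_g(first, rho, threshold)
    except ValueError:
        fnr = None
    fdr = None
    if len(scored_tables) >= 2:
        sets = [significant_set(df, threshold) for df in scored_tables]
        if any(sets):
            fdr = replicate_fdr(sets)
    return {"correlation": sym.correlation, "reversible": rev,
            "fnr": fnr, "fdr": fdr}


def _delta(a, b):
    if a is None or b is None:
        return None
    return a - b


def reweight_and_compare(scored_tables: list, default_curve: WeightCurve,
                         binning: DistanceBinning,
                         rho_candidates: tuple = (-10.0,),
                         threshold: float = NST) -> WeightEvalReport:
    """Re-estimate the weight curve from the data and measure the impact.

    Weight curves are fitted from the observed priors at each candidate
    reproducibility threshold rho; the fit with the lower RSS is kept,
    all replicates are rescored under it, and the report carries the
    Jaccard concordance of significant calls (default vs re-estimated
    weights, averaged over replicates) together with the change
    (custom - default) in score correlation, % reversible, FDR at the
    NST, and FNR.  The LOM of the observed priors at the first candidate
    rho is included as the monotonicity diagnostic.
    """
    notes = []
    candidates = [r for r in rho_candidates if r is not None]
    if not candidates:
        candidates = [-10.0]
        notes.append("no usable rho candidate; fell back to -10")

    fits = []
    for rho in candidates:
        obs = observed_prior(scored_tables, binning, rho)
        try:
            curve = fit_weight_curve(obs, binning)
        except ValueError as exc:
            notes.append(f"weight fit at rho={rho} failed: {exc}")
            continue
        rss, n_zero = weight_fit_rss(curve, obs, binning)
        fits.append((rss, rho, curve, n_zero, obs))
    if not fits:
        raise ValueError("weight curve could not be fitted at any candidate rho")
    fits.sort(key=lambda t: t[0])
    rss, rho_used, curve, n_zero, obs = fits[0]
    lom = lack_of_monotonicity(
        obs.loc[~obs["empty"].astype(bool), "prior"].to_numpy()
    )

    rescored = [rescore_with_weights(df, curve) for df in scored_tables]
    jaccards = []
    for before, after in zip(scored_tables, rescored):
        a = significant_set(before, threshold)
        b = significant_set(after, threshold)
        if a or b:
            jaccards.append(jaccard(a, b))
    reweight_jac = float(np.mean(jaccards)) if jaccards else None
    if reweight_jac is None:
        notes.append("no significant calls under either weighting")

    base = _battery(scored_tables, threshold, rho_used)
    custom = _battery(rescored, threshold, rho_used)
    return WeightEvalReport(
        lom=lom,
        rss=rss,
        n_zero_bins=n_zero,
        rho_used=float(rho_used),
        curve=curve,
        reweight_jaccard=reweight_jac,
        delta_score_correlation=_delta(custom["correlation"], base["correlation"]),
        delta_percent_reversible=_delta(custom["reversible"], base["reversible"]),
        delta_fdr_at_nst=_delta(custom["fdr"], base["fdr"]),
        delta_fnr=_delta(custom["fnr"], base["fnr"]),
        notes=notes,
    )
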