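"""Synthetic capture Hi-C data with known ground truth.

The generator emulates the statistical structure the caller assumes: a
restriction digest of one synthetic chromosome (HindIII-like fragment
lengths, ~4 kb) with a designated bait subset, background counts
NB(s_i * s_j * f(d), r) with a power-law-like distance decay
f(d) = exp(c0) / d, log-normal fragment biases, Poisson technical noise
whose rate rises across fragment pools, spiked true interactions whose
prior probability decays with distance, and replicates that share the
truth but draw independent noise.  Optional perturbations emulate copy
number variation and translocation-style breakpoint fusions seen in
cancer genomes.

Everything is deterministic given the seed: the same
(parameters, seed) pair regenerates each dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    DistanceFit,
    NullModel,
    WeightCurve,
    enumerate_cis_pairs,
)
from .io_formats import FragmentMap, InteractionTable

__all__ = [
    "TruthSet",
    "generate_fragment_map",
    "default_null_model",
    "sample_truth",
    "simulate_counts",
    "apply_perturbations",
]

# Default decay level: f(d) = exp(C0_DEFAULT)/d gives ~15 reads per pair at
# 20 kb falling to ~0.2 at 1.5 Mb, a realistic per-replicate depth.
C0_DEFAULT = float(np.log(3.0e5))


@dataclass
class TruthSet:
    """Ground-truth interactions spiked into a simulation.

    ``true_pairs`` maps (bait_id, other_id) -> effect multiplier (> 1);
    ``prior_curve`` is the generating prior-probability-vs-distance
    logistic; ``generator_params`` records everything needed (with the
    seed) to regenerate the dataset exactly.
    """

    true_pairs: dict
    prior_curve: WeightCurve
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(m <= 1 for m in self.true_pairs.values()):
            raise ValueError("true-pair effect multipliers must exceed 1")


def generate_fragment_map(n_fragments: int, mean_len_bp: float = 4000.0,
                          bait_fraction: float = 0.1, seed: int = 0,
                          n_decoy_fragments: int = 0) -> FragmentMap:
    """One synthetic chromosome tiled by contiguous restriction fragments.

    Fragment lengths are gamma-distributed around ``mean_len_bp`` (floored
    at 150 bp); an evenly spaced, deterministic subset of fragments is
    designated baits.  ``n_decoy_fragments`` adds an unbaited second
    chromosome whose only role is to furnish trans pairs for
    technical-noise estimation.
    """
    if n_fragments < 10:
        raise ValueError("need at least 10 fragments")
    n_baits = int(round(n_fragments * bait_fraction))
    if n_baits < 1:
        raise ValueError(
            f"bait_fraction {bait_fraction} yields 0 baits for {n_fragments} fragments"
        )
    rng = np.random.default_rng(seed)

    def tile(chrom: str, n: int, id0: int) -> pd.DataFrame:
        lengths = np.maximum(
            rng.gamma(shape=4.0, scale=mean_len_bp / 4.0, size=n), 150.0
        ).astype(np.int64)
        ends = np.cumsum(lengths)
        starts = np.concatenate([[1], ends[:-1] + 1])
        return pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends,
             "id": np.arange(id0, id0 + n, dtype=np.int64)}
        )

    main = tile("chrS", n_fragments, 1)
    frames = [main]
    if n_decoy_fragments > 0:
        frames.append(tile("chrD", n_decoy_fragments, n_fragments + 1))
    fragments = pd.concat(frames, ignore_index=True)

    bait_pos = np.unique(
        np.round(np.linspace(0, n_fragments - 1, n_baits)).astype(int)
    )
    bait_ids = main["id"].to_numpy()[bait_pos]
    return FragmentMap(
        fragments=fragments,
        bait_ids=frozenset(int(b) for b in bait_ids),
        bait_names={int(b): f"bait_{b}" for b in bait_ids},
    )


def default_null_model(fmap: FragmentMap, seed: int = 0, c0: float = C0_DEFAULT,
                       dispersion_r: float = 2.0, bait_bias_sd: float = 0.25,
                       other_end_bias_sd: float = 0.5,
                       lambda_range: tuple = (0.001, 0.01),
                       n_pools: int = 5) -> NullModel:
    """Ground-truth background model for a fragment map.

    Distance decay is the theoretical power law f(d) = exp(c0)/d.  Bait
    biases are log-normal(0, bait_bias_sd^2); other-end biases
    log-normal(0, other_end_bias_sd^2), the wider spread reflecting the
    greater heterogeneity of uncaptured fragments.  Fragments are split
    into ``n_pools`` quantile pools by their other-end bias, with
    technical-noise rates increasing linearly across pools over
    ``lambda_range`` (so the standard "median and variance trend upwards"
    diagnostic has something to detect).
    """
    rng = np.random.default_rng(seed)
    ids = fmap.fragments["id"].to_numpy()
    bait_ids = np.array(sorted(fmap.bait_ids))
    bait_bias = dict(
        zip(
            (int(i) for i in bait_ids),
            np.exp(rng.normal(0.0, bait_bias_sd, size=len(bait_ids))),
        )
    )
    oe_bias = np.exp(rng.normal(0.0, other_end_bias_sd, size=len(ids)))
    other_end_bias = {int(i): float(b) for i, b in zip(ids, oe_bias)}

    qs = np.quantile(oe_bias, np.linspace(0, 1, n_pools + 1))
    pool_idx = np.clip(np.searchsorted(qs[1:-1], oe_bias, side="right"), 0, n_pools - 1)
    pool_of = {int(i): int(p) for i, p in zip(ids, pool_idx)}
    pool_values = [np.sort(oe_bias[pool_idx == k]) for k in range(n_pools)]
    lam = np.linspace(lambda_range[0], lambda_range[1], n_pools)
    return NullModel(
        distance_fit=DistanceFit(kind="theoretical", coeffs=np.array([c0, -1.0])),
        dispersion_r=dispersion_r,
        bait_bias=bait_bias,
        other_end_bias=other_end_bias,
        other_end_pool_of=pool_of,
        other_end_pool_values=pool_values,
        lambda_pools=lam,
    )


def sample_truth(fmap: FragmentMap, prior_params: tuple = (0.01, 0.3, 12.0, 2.0),
                 effect_range: tuple = (3.0, 10.0), seed: int = 0,
                 max_distance_bp: float = 1.5e6) -> TruthSet:
    """Spike true interactions with a distance-decaying prior probability.

    Each cis bait/other-end pair within range is true independently with
    probability given by the four-parameter logistic prior; true pairs
    receive an effect multiplier drawn uniformly from ``effect_range``.
    """
    prior = WeightCurve(params=tuple(float(p) for p in prior_params))
    rng = np.random.default_rng(seed)
    pairs = enumerate_cis_pairs(fmap, max_distance_bp)
    p = prior.weight(pairs["distance_bp"].to_numpy())
    hit = rng.random(len(pairs)) < p
    mult = rng.uniform(effect_range[0], effect_range[1], size=len(pairs))
    true_pairs = {
        (int(b), int(o)): float(m)
        for b, o, m in zip(
            pairs["bait_id"][hit], pairs["other_id"][hit], mult[hit]
        )
    }
    return TruthSet(
        true_pairs=true_pairs,
        prior_curve=prior,
        generator_params={
            "prior_params": tuple(prior_params),
            "effect_range": tuple(effect_range),
            "seed": int(seed),
            "max_distance_bp": float(max_distance_bp),
        },
    )


def _draw_counts(rng, means, r):
    means = np.asarray(means, dtype=float)
    return rng.negative_binomial(r, r / (r + means))


def simulate_counts(fmap: FragmentMap, model: NullModel, truth: TruthSet,
                    n_replicates: int = 2, seed: int = 0,
                    max_distance_bp: float = 1.5e6) -> list[InteractionTable]:
    """Replicate count tables sharing the truth, with independent noise.

    Cis pairs draw NB(multiplier * s_i * s_j * f(d), r) plus
    Poisson(lambda_pool); trans pairs (bait against every fragment on
    another chromosome) draw Poisson(lambda_pool) only.  Only pairs with
    at least one read are recorded, as in real count tables; absent pairs
    are implicitly zero and recoverable from the map.
    """
    pairs = enumerate_cis_pairs(fmap, max_distance_bp)
    d = pairs["distance_bp"].to_numpy()
    s_i = pairs["bait_id"].map(model.bait_bias).to_numpy(dtype=float)
    s_j = pairs["other_id"].map(model.other_end_bias).to_numpy(dtype=float)
    mult = np.array(
        [
            truth.true_pairs.get((int(b), int(o)), 1.0)
            for b, o in zip(pairs["bait_id"], pairs["other_id"])
        ]
    )
    means = mult * s_i * s_j * model.distance_fit.f(d)
    lam_cis = model.lam(pairs["other_id"].to_numpy())

    # trans universe: every (bait, fragment-on-another-chromosome) pair
    frags = fmap.fragments
    ids = frags["id"].to_numpy()
    chroms = frags["chrom"].to_numpy()
    bait_ids = np.array(sorted(fmap.bait_ids))
    bait_chrom = {int(i): c for i, c in zip(ids, chroms)}
    t_bait, t_other = [], []
    for b in bait_ids:
        sel = chroms != bait_chrom[int(b)]
        t_bait.append(np.full(sel.sum(), b))
        t_other.append(ids[sel])
    t_bait = np.concatenate(t_bait) if t_bait else np.array([], dtype=int)
    t_other = np.concatenate(t_other) if t_other else np.array([], dtype=int)
    lam_trans = model.lam(t_other) if len(t_other) else np.array([])

    tables = []
    for rep, ss in enumerate(np.random.SeedSequence(seed).spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        counts = _draw_counts(rng, means, model.dispersion_r)
        counts = counts + rng.poisson(lam_cis)
        pos = counts > 0
        cis_rec = pd.DataFrame(
            {
                "bait_id": pairs["bait_id"].to_numpy()[pos],
                "other_id": pairs["other_id"].to_numpy()[pos],
                "count": counts[pos],
                "distance_bp": d[pos],
                "trans": False,
            }
        )
        recs = [cis_rec]
        if len(t_other):
            t_counts = rng.poisson(lam_trans)
            tpos = t_counts > 0
            recs.append(
                pd.DataFrame(
                    {
                        "bait_id": t_bait[tpos],
                        "other_id": t_other[tpos],
                        "count": t_counts[tpos],
                        "distance_bp": np.nan,
                        "trans": True,
                    }
                )
            )
        tables.append(
            InteractionTable(
                replicate_id=f"rep{rep + 1}",
                records=pd.concat(recs, ignore_index=True),
            )
        )
    return tables


def apply_perturbations(fmap: FragmentMap, table: InteractionTable,
                        cnv_regions: list | None = None,
                        breakpoint: tuple | None = None,
                        model: NullModel | None = None,
                        seed: int = 0,
                        max_distance_bp: float = 1.5e6,
                        min_effective_bp: float = 1.0e4) -> InteractionTable:
    """Impose copy-number and translocation-style distortions on counts.

    ``cnv_regions`` is a list of ((chrom, start, end), multiplier)
    entries; counts of pairs with an anchor midpoint inside a region are
    binomially thinned (multiplier < 1) or Poisson-amplified
    (multiplier > 1), preserving integer counts with the right mean.
    Regions may not overlap.

    ``breakpoint`` = (chrom, pos_a, pos_b) fuses the loci at pos_a and
    pos_b: every cis pair spanning the interval has the intervening
    segment effectively excised, so its count is resampled from the null
    at the shortened distance d - (pos_b - pos_a), floored at
    ``min_effective_bp`` (a fusion junction still separates loci by a
    junction-scale gap).  This requires the generating ``model``.  The map-reported distances are left untouched
    (the analyst does not know about the rearrangement), which is exactly
    the distortion such events inflict on distance-decay estimates.
    """
    rng = np.random.default_rng(seed)
    records = table.records.copy().reset_index(drop=True)

    if cnv_regions:
        ivs = sorted(
            [(c, float(s), float(e), float(m)) for (c, s, e), m in cnv_regions]
        )
        for (c1, s1, e1, _), (c2, s2, e2, _) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 <= e1:
                raise ValueError("overlapping CNV regions")
        mid_b = fmap.midpoint(records["bait_id"].to_numpy())
        mid_o = fmap.midpoint(records["other_id"].to_numpy())
        chr_b = fmap.chrom(records["bait_id"].to_numpy())
        chr_o = fmap.chrom(records["other_id"].to_numpy())
        for (chrom, start, end), m in cnv_regions:
            if m <= 0:
                raise ValueError("CNV multiplier must be positive")
            hit = ((chr_b == chrom) & (mid_b >= start) & (mid_b <= end)) | (
                (chr_o == chrom) & (mid_o >= start) & (mid_o <= end)
            )
            if m == 1 or not hit.any():
                continue
            cnt = records.loc[hit, "count"].to_numpy()
            if m < 1:
                records.loc[hit, "count"] = rng.binomial(cnt, m)
            else:
                records.loc[hit, "count"] = cnt + rng.poisson((m - 1) * cnt)
        records = records[records["count"] > 0].reset_index(drop=True)

    if breakpoint is not None:
        if model is None:
            raise ValueError("breakpoint resampling requires the generating model")
        chrom, pos_a, pos_b = breakpoint
        if pos_b <= pos_a:
            raise ValueError("breakpoint positions must satisfy pos_a < pos_b")
        span = pos_b - pos_a
        pairs = enumerate_cis_pairs(fmap, max_distance_bp)
        mid_b = fmap.midpoint(pairs["bait_id"].to_numpy())
        mid_o = fmap.midpoint(pairs["other_id"].to_numpy())
        on_chrom = fmap.chrom(pairs["bait_id"].to_numpy()) == chrom
        lo = np.minimum(mid_b, mid_o)
        hi = np.maximum(mid_b, mid_o)
        spanning = on_chrom & (lo <= pos_a) & (hi >= pos_b)
        aff = pairs[spanning]
        if len(aff):
            d_eff = np.maximum(aff["distance_bp"].to_numpy() - span,
                               min_effective_bp)
            s_i = aff["bait_id"].map(model.bait_bias).fillna(1.0).to_numpy()
            s_j = aff["other_id"].map(model.other_end_bias).fillna(1.0).to_numpy()
            means = s_i * s_j * model.distance_fit.f(d_eff)
            new_counts = _draw_counts(rng, means, model.dispersion_r)
            new_counts = new_counts + rng.poisson(model.lam(aff["other_id"].to_numpy()))
            # replace any existing rows for affected pairs with the resample
            key = set(zip(aff["bait_id"], aff["other_id"]))
            old_key = list(zip(records["bait_id"], records["other_id"]))
            drop = np.array([k in key for k in old_key])
            kept = records[~drop]
            pos = new_counts > 0
            new_rec = pd.DataFrame(
                {
                    "bait_id": aff["bait_id"].to_numpy()[pos],
                    "other_id": aff["other_id"].to_numpy()[pos],
                    "count": new_counts[pos],
                    "distance_bp": aff["distance_bp"].to_numpy()[pos],
                    "trans": False,
                }
            )
            records = pd.concat([kept, new_rec], ignore_index=True)

    return InteractionTable(replicate_id=table.replicate_id, records=records)
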