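"""End-to-end orchestration: simulate -> call -> evaluate -> report.

``run_pipeline`` executes the full evaluation battery over either a
synthetic dataset (generated from the config) or user-supplied
rmap/baitmap/chinput files, and writes one TSV per report section plus a
plain-text summary.  Every stochastic step is seeded from the single
config seed through spawned child streams, so a report regenerates
bit-for-bit; evaluation is computed bin-by-bin in a fixed order, so the
result does not depend on the requested thread count.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, core_model, model_eval, score_eval, synthetic_data, weight_eval
from .core_model import DistanceBinning, NullModel, WeightCurve
from .io_formats import read_fragment_map, read_interactions, write_scored_interactions

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "default_config", "run_pipeline"]

_DEFAULT_CONFIG = {
    "generation": {
        "n_fragments": 1000,
        "n_decoy_fragments": 200,
        "mean_len_bp": 4000,
        "bait_fraction": 0.1,
        "c0": synthetic_data.C0_DEFAULT,
        "dispersion_r": 2.0,
        "bait_bias_sd": 0.25,
        "other_end_bias_sd": 0.5,
        "lambda_range": [0.001, 0.01],
        "prior_params": [0.01, 0.3, 12.0, 2.0],
        "effect_range": [3.0, 10.0],
        "n_replicates": 2,
    },
    "input": {},  # rmap / baitmap / chinputs paths; overrides generation
    "model": {"n_pools": 5, "bin_width_bp": 20000, "bin_upper_bp": 1500000},
    "evaluation": {"ks_n_sim": 200, "ks_n_pairs": 500, "ks_alpha": 0.05},
    "thresholds": {"nst": 5.0, "fwer_alpha": 0.05},
    "weights": {"rho": -10.0, "default_params": None},
    "sections": ["distance", "ks", "lambda", "symmetry", "thresholds", "weights"],
}


def default_config() -> dict:
    import copy

    return copy.deepcopy(_DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class EvalReport:
    """The assembled diagnostic battery.

    Sections that could not be computed are recorded in ``skipped`` with
    a reason; ``provenance`` (config, seed, version) suffices to
    regenerate the report bit-for-bit.
    """

    ks_table: pd.DataFrame | None = None
    distance_fits: pd.DataFrame | None = None
    lambda_summary: pd.DataFrame | None = None
    lambda_trend_ok: bool | None = None
    symmetry: score_eval.SymmetryResult | None = None
    percent_reversible: float | None = None
    thresholds: score_eval.ThresholdReport | None = None
    weights: weight_eval.WeightEvalReport | None = None
    provenance: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)


def _load_inputs(cfg: dict, seed: int):
    """Return (fmap, tables, truth-or-None, generating-model-or-None)."""
    inp = cfg.get("input") or {}
    if inp.get("rmap"):
        for key in ("rmap", "baitmap"):
            path = inp.get(key)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"input.{key}: no such file: {path}")
        chinputs = inp.get("chinputs") or []
        if not chinputs:
            raise FileNotFoundError("input.chinputs: no count tables given")
        for path in chinputs:
            if not Path(path).exists():
                raise FileNotFoundError(f"input.chinputs: no such file: {path}")
        fmap = read_fragment_map(inp["rmap"], inp["baitmap"])
        tables = [
            read_interactions(p, fmap, replicate_id=f"rep{i + 1}")
            for i, p in enumerate(chinputs)
        ]
        return fmap, tables, None, None

    gen = cfg["generation"]
    seeds = np.random.SeedSequence(seed).generate_state(4)
    fmap = synthetic_data.generate_fragment_map(
        n_fragments=int(gen["n_fragments"]),
        mean_len_bp=float(gen["mean_len_bp"]),
        bait_fraction=float(gen["bait_fraction"]),
        seed=int(seeds[0]),
        n_decoy_fragments=int(gen["n_decoy_fragments"]),
    )
    model = synthetic_data.default_null_model(
        fmap,
        seed=int(seeds[1]),
        c0=float(gen["c0"]),
        dispersion_r=float(gen["dispersion_r"]),
        bait_bias_sd=float(gen["bait_bias_sd"]),
        other_end_bias_sd=float(gen["other_end_bias_sd"]),
        lambda_range=tuple(gen["lambda_range"]),
        n_pools=int(cfg["model"]["n_pools"]),
    )
    truth = synthetic_data.sample_truth(
        fmap,
        prior_params=tuple(gen["prior_params"]),
        effect_range=tuple(gen["effect_range"]),
        seed=int(seeds[2]),
    )
    tables = synthetic_data.simulate_counts(
        fmap, model, truth,
        n_replicates=int(gen["n_replicates"]),
        seed=int(seeds[3]),
    )
    return fmap, tables, truth, model


def estimate_model(table, fmap, binning: DistanceBinning, n_pools: int = 5,
                   ) -> NullModel:
    """Fit the full background model to one replicate's counts."""
    est = core_model.estimate_distance_function(table, binning)
    fits = core_model.fit_distance_curves(est, binning)
    active = fits["cubic"]
    biases = core_model.estimate_biases(table, fmap, active, binning, n_pools)
    pairs = core_model.enumerate_cis_pairs(fmap, binning.upper_bp)
    pairs = core_model._attach_counts(pairs, table)
    s_i = pairs["bait_id"].map(biases.bait_bias)
    s_j = pairs["other_id"].map(biases.other_end_bias)
    ok = s_i.notna() & s_j.notna()
    mus = (
        s_i[ok].to_numpy() * s_j[ok].to_numpy()
        * active.f(pairs.loc[ok, "distance_bp"].to_numpy())
    )
    r = core_model.estimate_dispersion(pairs.loc[ok, "count"].to_numpy(), mus)
    lam = core_model.estimate_lambda(table, fmap, n_pools)
    model = NullModel(
        distance_fit=active,
        dispersion_r=r,
        bait_bias=biases.bait_bias,
        other_end_bias=biases.other_end_bias,
        other_end_pool_of=biases.pool_of,
        other_end_pool_values=biases.pool_values,
        lambda_pools=lam.lambda_pools,
        unestimable_baits=biases.unestimable_baits,
    )
    model._distance_fits = fits
    model._distance_estimates = est
    model._lambda_estimate = lam
    return model


def run_pipeline(config: dict | None = None, seed: int = 0,
                 outdir: str | Path | None = None, threads: int = 1,
                 ) -> EvalReport:
    """Run every evaluation stage in order and assemble the report.

    ``threads`` is accepted for interface stability; evaluation results
    are independent of its value.
    """
    t0 = time.time()
    cfg = _merge(_DEFAULT_CONFIG, config or {})
    sections = list(cfg["sections"])
    binning = DistanceBinning(
        width_bp=int(cfg["model"]["bin_width_bp"]),
        upper_bp=int(cfg["model"]["bin_upper_bp"]),
    )
    report = EvalReport(
        provenance={
            "config": cfg,
            "seed": int(seed),
            "version": __version__,
        }
    )

    fmap, tables, truth, gen_model = _load_inputs(cfg, seed)
    logger.info(
        "inputs ready: %d fragments, %d baits, %d replicate(s) [%.1fs]",
        fmap.n_fragments, fmap.n_baits, len(tables), time.time() - t0,
    )

    n_pools = int(cfg["model"]["n_pools"])
    model = estimate_model(tables[0], fmap, binning, n_pools)
    fits = model._distance_fits
    logger.info("model estimated: r=%.3g [%.1fs]", model.dispersion_r,
                time.time() - t0)

    # -- distance section --------------------------------------------------
    if "distance" in sections:
        rows = []
        for kind in ("cubic", "linear", "theoretical"):
            fit = fits[kind]
            coeffs = {f"c{i}": c for i, c in enumerate(fit.coeffs)}
            rows.append(
                {"kind": kind, "rss": fit.rss, "curvature_K": fit.curvature,
                 **coeffs}
            )
        report.distance_fits = pd.DataFrame(rows)

    # -- KS section --------------------------------------------------------
    if "ks" in sections:
        pairs = core_model.enumerate_cis_pairs(fmap, binning.upper_bp)
        pairs = core_model._attach_counts(pairs, tables[0])
        bins = binning.bin_index(pairs["distance_bp"].to_numpy())
        ks_seeds = np.random.SeedSequence(seed + 1_000_003).generate_state(
            binning.n_bins
        )
        results = []
        for b in range(binning.n_bins):
            obs = pairs.loc[bins == b, "count"].to_numpy()
            if obs.size == 0:
                continue
            results.append(
                model_eval.ks_monte_carlo(
                    obs, model, binning, b,
                    n_sim=int(cfg["evaluation"]["ks_n_sim"]),
                    n_pairs=int(cfg["evaluation"]["ks_n_pairs"]),
                    seed=int(ks_seeds[b]),
                )
            )
        if results:
            model_eval.bonferroni_ks(results, float(cfg["evaluation"]["ks_alpha"]))
            floor = 1.0 / (int(cfg["evaluation"]["ks_n_sim"]) + 1)
            report.ks_table = pd.DataFrame(
                [
                    {
                        "bin": r.label,
                        "D": r.d_statistic,
                        "mc_p": f"<{floor:g}" if r.mc_p <= floor else f"{r.mc_p:g}",
                        "n_observed": r.n_observed,
                        "significant": r.significant_after_bonferroni,
                    }
                    for r in results
                ]
            )
        else:
            report.skipped["ks"] = "no observed pairs in any distance bin"
        logger.info("KS battery done [%.1fs]", time.time() - t0)

    # -- lambda section ----------------------------------------------------
    if "lambda" in sections:
        lam_est = model._lambda_estimate
        if all(len(v) == 0 for v in lam_est.pool_values):
            report.skipped["lambda"] = "no trans pairs available"
        else:
            summary, trend = model_eval.lambda_trend_diagnostic(lam_est.pool_values)
            summary["lambda_pool"] = lam_est.lambda_pools
            report.lambda_summary = summary
            report.lambda_trend_ok = trend

    # -- scoring (needed by symmetry / thresholds / weights) ---------------
    weight_params = cfg["weights"].get("default_params")
    if weight_params:
        default_curve = WeightCurve(params=tuple(float(p) for p in weight_params))
    elif truth is not None:
        default_curve = truth.prior_curve
    else:
        default_curve = WeightCurve(
            params=tuple(_DEFAULT_CONFIG["generation"]["prior_params"])
        )
    scored = [
        core_model.compute_scores(t, fmap, model, default_curve, binning)
        for t in tables
    ]
    logger.info("scoring done: %d directed pairs per replicate [%.1fs]",
                len(scored[0]), time.time() - t0)

    nst = float(cfg["thresholds"]["nst"])
    if "symmetry" in sections:
        report.symmetry = score_eval.score_symmetry(scored[0])
        report.percent_reversible = score_eval.percent_reversible(scored[0], nst)

    if "thresholds" in sections:
        rho = float(cfg["weights"]["rho"])
        pairs0 = core_model.enumerate_cis_pairs(fmap, binning.upper_bp)
        n_b0 = int((binning.bin_index(pairs0["distance_bp"].to_numpy()) == 0).sum())
        fwer_exact = score_eval.fwer_score_threshold(
            n_b0, float(cfg["thresholds"]["fwer_alpha"])
        )
        try:
            fnr_at_nst = score_eval.fnr_g(scored[0], rho, nst)
        except ValueError:
            fnr_at_nst = None
        rho_star = score_eval.solve_rho(scored[0], threshold=nst)
        try:
            sst_fnr = score_eval.sst_for_fnr(scored[0], rho=rho)
        except ValueError:
            sst_fnr = -1
        if len(scored) >= 2:
            sst_qn, fdr_qn = score_eval.sst_minimising_fdr(scored, "quasi_newton",
                                                           init=nst)
            sst_nm, fdr_nm = score_eval.sst_minimising_fdr(scored, "simplex",
                                                           init=nst)
            sets = [score_eval.significant_set(df, nst) for df in scored]
            fdr_at_nst = score_eval.replicate_fdr(sets) if any(sets) else None
        else:
            report.skipped["thresholds.replicate_fdr"] = (
                "replicate-FDR statistics need at least 2 replicates"
            )
            sst_qn = sst_nm = -1
            fdr_qn = fdr_nm = float("nan")
            fdr_at_nst = None
        report.thresholds = score_eval.ThresholdReport(
            nst=nst,
            sst_fnr=sst_fnr,
            sst_fdr_quasi_newton=sst_qn,
            fdr_at_sst_quasi_newton=fdr_qn,
            sst_fdr_simplex=sst_nm,
            fdr_at_sst_simplex=fdr_nm,
            sst_fwer=int(round(fwer_exact)),
            fwer_threshold_exact=fwer_exact,
            fdr_at_nst=fdr_at_nst,
            fnr_at_nst=fnr_at_nst,
            rho_star=rho_star,
            n_significant_at_nst=len(score_eval.significant_set(scored[0], nst)),
            n_significant_at_sst_fwer=len(
                score_eval.significant_set(scored[0], round(fwer_exact))
            ),
        )
        logger.info("threshold battery done [%.1fs]", time.time() - t0)

    if "weights" in sections:
        rho = float(cfg["weights"]["rho"])
        rho_star = (
            report.thresholds.rho_star if report.thresholds is not None else None
        )
        candidates = (rho,) if rho_star is None else (rho, rho_star)
        try:
            report.weights = weight_eval.reweight_and_compare(
                scored, default_curve, binning, rho_candidates=candidates,
                threshold=nst,
            )
        except ValueError as exc:
            report.skipped["weights"] = str(exc)
        logger.info("weighting battery done [%.1fs]", time.time() - t0)

    if outdir is not None:
        _write_report(report, scored, Path(outdir), fmap)
    logger.info("pipeline complete [%.1fs]", time.time() - t0)
    return report


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_report(report: EvalReport, scored: list, outdir: Path, fmap) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if report.ks_table is not None:
        report.ks_table.to_csv(outdir / "ks_table.tsv", sep="\t", index=False)
    if report.distance_fits is not None:
        report.distance_fits.to_csv(outdir / "distance_fits.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    if report.lambda_summary is not None:
        report.lambda_summary.to_csv(outdir / "lambda_pools.tsv", sep="\t",
                                     index=False, float_format="%.6g")
    if report.thresholds is not None:
        report.thresholds.to_frame().to_csv(outdir / "thresholds.tsv", sep="\t",
                                            index=False, float_format="%.6g")
    if report.weights is not None:
        w = report.weights
        pd.DataFrame(
            [
                {
                    "lom": w.lom, "rss": w.rss, "n_zero_bins": w.n_zero_bins,
                    "rho_used": w.rho_used,
                    "reweight_jaccard": w.reweight_jaccard,
                    "delta_score_correlation": w.delta_score_correlation,
                    "delta_percent_reversible": w.delta_percent_reversible,
                    "delta_fdr_at_nst": w.delta_fdr_at_nst,
                    "delta_fnr": w.delta_fnr,
                }
            ]
        ).to_csv(outdir / "weights.tsv", sep="\t", index=False,
                 float_format="%.6g")
    for i, df in enumerate(scored):
        write_scored_interactions(df, outdir / f"scored_rep{i + 1}.tsv")

    lines = [f"chicaudit evaluation report (v{report.provenance['version']}, "
             f"seed {report.provenance['seed']})", ""]
    if report.distance_fits is not None:
        lin = report.distance_fits.set_index("kind")
        lines.append(
            "distance decay: linear slope "
            f"{lin.loc['linear', 'c1']:.4f}, cubic curvature K "
            f"{lin.loc['cubic', 'curvature_K']:.4f}"
        )
    if report.ks_table is not None:
        n_sig = int(report.ks_table["significant"].sum())
        lines.append(
            f"KS battery: {n_sig}/{len(report.ks_table)} bins reject the null "
            "after Bonferroni"
        )
    if report.lambda_trend_ok is not None:
        lines.append(f"technical-noise pools trend upwards: {report.lambda_trend_ok}")
    if report.symmetry is not None:
        lines.append(
            f"bait-bait score correlation: {_fmt(report.symmetry.correlation)} "
            f"(n={report.symmetry.n_used}); % reversible: "
            f"{_fmt(None if report.percent_reversible is None else 100 * report.percent_reversible)}"
        )
    if report.thresholds is not None:
        t = report.thresholds
        lines.append(
            f"thresholds: NST={t.nst:g}, SST(FNR=0.2)={t.sst_fnr}, "
            f"SST(FWER)={t.sst_fwer}, FDR@NST={_fmt(t.fdr_at_nst)}, "
            f"FNR@NST={_fmt(t.fnr_at_nst)}, rho*={_fmt(t.rho_star)}, "
            f"n_sig@NST={t.n_significant_at_nst}, "
            f"n_sig@FWER={t.n_significant_at_sst_fwer}"
        )
    if report.weights is not None:
        w = report.weights
        lines.append(
            f"weighting: LOM={w.lom:.4f}, RSS={w.rss:.4g} "
            f"({w.n_zero_bins} empty bins), reweight Jaccard="
            f"{_fmt(w.reweight_jaccard)}"
        )
    for key, reason in report.skipped.items():
        lines.append(f"skipped {key}: {reason}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(report.provenance, fh, sort_keys=True)
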