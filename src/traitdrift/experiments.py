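"""Replicate orchestration for the demographic sweeps and thresholding experiments.

Every replicate is an independent (genealogy, trait) realization: a fresh
genotype simulation, fresh effect sizes and a fresh environmental-variance
calibration.  Per-replicate seeds are derived from a master seed with
``numpy.random.SeedSequence`` spawn keys ``(stream, index)``, so runs are
reproducible and streams (sweep values, calibration vs evaluation batches)
never collide.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .heritability import HeritabilityResult, evaluate_trait
from .scenario_sim import DemographyConfig, EmptyTraitError, simulate_genotypes
from .stats import (
    BootstrapCI,
    bootstrap_variance_ci,
    correlation_with_fisher_se,
    regression_coefficient,
)
from .thresholding import (
    ThresholdMode,
    ThresholdSpec,
    calibrate_threshold,
    gwas_pvalues,
    thresholded_heritability,
    variance_explained,
)
from .trait_model import build_architecture, genetic_values, simulate_phenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "SweepResult",
    "replicate_seed",
    "run_replicates",
    "summarize_records",
    "sweep",
    "calibrate_power_threshold",
    "threshold_experiment",
]

_CONFIG_ECHO = ("N0", "N", "T", "m", "g", "genome_length_morgans",
                "genome_length_bp", "causal_mutation_rate",
                "n_sample_ref", "n_sample_bot")


def replicate_seed(master_seed: int, stream: int, index: int) -> tuple[int, np.random.Generator]:
    """Deterministic (simulation seed, trait rng) for replicate ``index`` of ``stream``."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(stream, index))
    sim_ss, trait_ss = ss.spawn(2)
    return int(sim_ss.generate_state(1, dtype=np.uint64)[0] >> 1), np.random.default_rng(trait_ss)


def _one_replicate(config: DemographyConfig, s: float, h2_target: float,
                   trait_rng: np.random.Generator):
    dataset = simulate_genotypes(config)
    arch = build_architecture(dataset, s=s, h2_target=h2_target, seed=trait_rng)
    return dataset, arch, evaluate_trait(dataset, arch)


def run_replicates(
    config: DemographyConfig,
    R: int,
    master_seed: int,
    s: float = -1.0,
    h2_target: float = 0.5,
    stream: int = 0,
) -> pd.DataFrame:
    """Run ``R`` independent (genealogy, trait) realizations of one scenario.

    Returns one row per replicate with the heritability record and a full
    config echo; a replicate that fails (e.g. an empty trait) is logged and
    recorded with NaN heritabilities rather than aborting the run.
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    rows = []
    for i in range(R):
        sim_seed, trait_rng = replicate_seed(master_seed, stream, i)
        cfg = config.replace(seed=sim_seed)
        row: dict = {"replicate": i, "seed": sim_seed, "s": s, "h2_target": h2_target}
        row.update({k: getattr(cfg, k) for k in _CONFIG_ECHO})
        try:
            dataset, arch, res = _one_replicate(cfg, s, h2_target, trait_rng)
            row.update(
                L=dataset.L, Vg_ref=res.Vg_ref, Vg_bot=res.Vg_bot,
                Ve=res.Ve, h2_ref=res.h2_ref, h2_bot=res.h2_bot,
            )
        except EmptyTraitError as exc:
            logger.warning("replicate %d failed: %s", i, exc)
            row.update(L=0, Vg_ref=np.nan, Vg_bot=np.nan, Ve=np.nan,
                       h2_ref=np.nan, h2_bot=np.nan)
        rows.append(row)
        if (i + 1) % 50 == 0:
            logger.info("completed %d/%d replicates", i + 1, R)
    return pd.DataFrame(rows)


def summarize_records(records: pd.DataFrame, column: str = "h2_bot") -> dict:
    """Mean, SE of the mean, and variance of one column over non-missing replicates."""
    vals = records[column].dropna().to_numpy()
    if vals.size == 0:
        return {"n": 0, "mean": np.nan, "se_mean": np.nan, "variance": np.nan}
    return {
        "n": int(vals.size),
        "mean": float(vals.mean()),
        "se_mean": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan,
        "variance": float(vals.var(ddof=1)) if vals.size > 1 else np.nan,
    }


@dataclasses.dataclass
class SweepResult:
    """Replicate records plus summaries for one value of the swept parameter."""

    parameter: str
    value: float
    R: int
    records: pd.DataFrame
    summary: dict
    variance_ci: BootstrapCI | None = None


_SWEEPABLE = {"N", "T", "m", "g"}


def sweep(
    parameter: str,
    values: Sequence[float],
    R: int,
    base_config: DemographyConfig,
    master_seed: int,
    s: float = -1.0,
    h2_target: float = 0.5,
    bootstrap_B: int = 1000,
) -> list[SweepResult]:
    """Run ``run_replicates`` for each value of one demographic parameter.

    Each sweep value gets its own seed stream.  A bootstrap CI for the
    variance of ``h2_bot`` is attached whenever at least two replicates
    succeeded (used for the bottleneck-time sweep).
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {sorted(_SWEEPABLE)}, got {parameter!r}")
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    results = []
    for vi, value in enumerate(values):
        cast = int(value) if parameter == "N" else float(value)
        cfg = base_config.replace(**{parameter: cast})
        records = run_replicates(cfg, R, master_seed, s=s, h2_target=h2_target, stream=vi)
        summary = summarize_records(records)
        h2 = records["h2_bot"].dropna().to_numpy()
        ci = None
        if h2.size >= 2 and np.var(h2) > 0:
            ci = bootstrap_variance_ci(h2, B=bootstrap_B, alpha=0.05, seed=master_seed + vi)
        logger.info("sweep %s=%s: mean h2_bot=%.4f (n=%d)",
                    parameter, value, summary["mean"], summary["n"])
        results.append(SweepResult(parameter=parameter, value=float(value), R=R,
                                   records=records, summary=summary, variance_ci=ci))
    return results


def calibrate_power_threshold(
    config: DemographyConfig,
    spec: ThresholdSpec,
    master_seed: int,
    s: float = -1.0,
    h2_target: float = 0.5,
    stream: int = 1,
) -> tuple[ThresholdSpec, np.ndarray]:
    """Calibrate the power threshold from ``spec.n_calibration`` independent traits.

    All per-SNP scores from the calibration traits (computed in the
    bottleneck population) are pooled with equal weight and the cutoff for
    the top ``1/2**n`` is taken from the combined distribution.  Returns the
    calibrated spec and the per-trait fraction of SNPs that survive it.
    """
    per_trait_scores: list[np.ndarray] = []
    for i in range(spec.n_calibration):
        sim_seed, trait_rng = replicate_seed(master_seed, stream, i)
        cfg = config.replace(seed=sim_seed)
        try:
            dataset, arch, _ = _one_replicate(cfg, s, h2_target, trait_rng)
        except EmptyTraitError as exc:
            logger.warning("calibration trait %d skipped: %s", i, exc)
            continue
        if spec.mode is ThresholdMode.variance_explained:
            scores = variance_explained(dataset.f_bot, arch.betas)
        else:
            y_bot = simulate_phenotypes(
                genetic_values(dataset.X_bot, arch.betas), arch.Ve, trait_rng
            )
            scores = gwas_pvalues(dataset.X_bot, y_bot)
        per_trait_scores.append(scores)
    if not per_trait_scores:
        raise EmptyTraitError("all calibration traits were empty")
    pooled = np.concatenate(per_trait_scores)
    calibrated = calibrate_threshold(pooled, spec)
    if calibrated.mode is ThresholdMode.variance_explained:
        fractions = np.array(
            [np.mean(sc >= calibrated.threshold_value) for sc in per_trait_scores]
        )
    else:
        fractions = np.array(
            [np.mean(sc <= calibrated.threshold_value) for sc in per_trait_scores]
        )
    logger.info(
        "calibrated %s threshold at n=%d: %.4g (mean per-trait retention %.3f%%)",
        calibrated.mode.value, calibrated.n, calibrated.threshold_value,
        100 * fractions.mean(),
    )
    return calibrated, fractions


def threshold_experiment(
    base_config: DemographyConfig,
    n_values: Iterable[int],
    R: int,
    mode: ThresholdMode | str,
    master_seed: int,
    n_calibration: int = 200,
    s: float = -1.0,
    h2_target: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired (simulated, thresholded) heritabilities across quantile exponents.

    For each ``n``, a threshold is calibrated on an independent batch of
    ``n_calibration`` traits and then evaluated on ``R`` fresh replicates.
    Returns the per-replicate pair table and a per-n summary with the Pearson
    correlation (Fisher-z SE) and the OLS slope of thresholded on simulated
    heritability.
    """
    mode = ThresholdMode(mode)
    pair_rows, summary_rows = [], []
    for ni, n in enumerate(n_values):
        spec = ThresholdSpec(mode=mode, n=int(n), n_calibration=n_calibration)
        calibrated, fractions = calibrate_power_threshold(
            base_config, spec, master_seed, s=s, h2_target=h2_target,
            stream=1000 + ni,
        )
        sims, thrs = [], []
        for i in range(R):
            sim_seed, trait_rng = replicate_seed(master_seed, 2000 + ni, i)
            cfg = base_config.replace(seed=sim_seed)
            try:
                dataset, arch, _ = _one_replicate(cfg, s, h2_target, trait_rng)
            except EmptyTraitError as exc:
                logger.warning("evaluation replicate %d skipped: %s", i, exc)
                continue
            res = thresholded_heritability(dataset, arch, calibrated, seed=trait_rng)
            sims.append(res.h2_simulated)
            thrs.append(res.h2_thresholded)
            pair_rows.append({
                "n": int(n), "mode": mode.value,
                "threshold_value": calibrated.threshold_value,
                "replicate": i, "seed": sim_seed,
                "n_snps_total": res.n_snps_total,
                "n_snps_retained": res.n_snps_retained,
                "h2_simulated": res.h2_simulated,
                "h2_thresholded": res.h2_thresholded,
            })
        sims_a, thrs_a = np.asarray(sims), np.asarray(thrs)
        r, se_r = correlation_with_fisher_se(sims_a, thrs_a)
        slope = regression_coefficient(sims_a, thrs_a)
        summary_rows.append({
            "n": int(n), "mode": mode.value,
            "threshold_value": calibrated.threshold_value,
            "mean_calibration_retention": float(fractions.mean()),
            "R": len(sims), "r": r, "se_r": se_r, "slope": slope,
        })
    return pd.DataFrame(pair_rows), pd.DataFrame(summary_rows)
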