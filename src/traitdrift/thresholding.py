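"""GWAS-detectability thresholding of causal SNPs in the bottlenecked population.

SNPs are scored in the bottleneck sample either by variance explained,
``v = f(1-f) * beta**2``, or by a marginal per-SNP association p-value.  A
power threshold retaining the top ``1/2**n`` of scores is calibrated from a
pool of scores across many independent trait simulations sharing one
demography; heritability is then recomputed from the SNPs that survive.
"""

from __future__ import annotations

import dataclasses
from enum import Enum

import numpy as np
from scipy import stats as sps

from .heritability import heritability_from_variances
from .scenario_sim import GenotypeDataset
from .trait_model import TraitArchitecture, genetic_values, simulate_phenotypes

__all__ = [
    "ThresholdMode",
    "ThresholdSpec",
    "EmptyRetentionError",
    "variance_explained",
    "gwas_pvalues",
    "calibrate_threshold",
    "retained_mask",
    "ThresholdedHeritability",
    "thresholded_heritability",
]


class ThresholdMode(str, Enum):
    variance_explained = "variance_explained"
    p_value = "p_value"


class EmptyRetentionError(RuntimeError):
    """Quantile exponent so strict that no pooled score survives."""


@dataclasses.dataclass(frozen=True)
class ThresholdSpec:
    """Thresholding mode, quantile exponent n (retain top 1/2**n) and cutoff."""

    mode: ThresholdMode = ThresholdMode.variance_explained
    n: int = 5
    n_calibration: int = 200
    threshold_value: float | None = None

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be an integer >= 1, got {self.n}")
        if self.n_calibration < 2:
            raise ValueError(f"n_calibration must be >= 2, got {self.n_calibration}")
        object.__setattr__(self, "mode", ThresholdMode(self.mode))
        if self.threshold_value is not None:
            if not np.isfinite(self.threshold_value):
                raise ValueError("threshold_value must be finite")
            if self.mode is ThresholdMode.p_value and not 0 <= self.threshold_value <= 1:
                raise ValueError("p-value threshold must be in [0, 1]")

    @property
    def retained_fraction(self) -> float:
        return 1.0 / 2.0**self.n

    @property
    def calibrated(self) -> bool:
        return self.threshold_value is not None


def variance_explained(f, beta):
    """Phenotypic variance explained by a SNP: ``f * (1 - f) * beta**2``.

    Zero at f in {0, 1} (a lost or fixed SNP explains nothing).  Accepts
    scalars or arrays.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    out = f * (1.0 - f) * np.asarray(beta, dtype=float) ** 2
    return out if out.ndim else float(out)


def gwas_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Marginal per-SNP p-values from OLS of phenotype on allele count.

    One simple linear regression per SNP; two-sided t-test on the slope.
    Monomorphic SNPs get p = 1 by convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match the phenotype vector length")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 individuals, got {n}")
    yc = y - y.mean()
    sy = float(yc @ yc)
    if sy == 0:
        raise ValueError("phenotype vector is constant")
    Xc = X - X.mean(axis=0)
    sx = np.einsum("ij,ij->j", Xc, Xc)
    poly = sx > 0
    p = np.ones(X.shape[1])
    if poly.any():
        sxy = yc @ Xc[:, poly]
        r = sxy / np.sqrt(sx[poly] * sy)
        r = np.clip(r, -1.0, 1.0)
        denom = np.maximum(1.0 - r**2, np.finfo(float).tiny)
        with np.errstate(over="ignore"):  # r = +/-1 gives t = inf, p = 0
            t = r * np.sqrt((n - 2) / denom)
        p[poly] = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return p


def calibrate_threshold(pooled_scores: np.ndarray, spec: ThresholdSpec) -> ThresholdSpec:
    """Set the cutoff so the top 1/2**n of the pooled score distribution survives.

    For variance-explained scores the threshold is the k-th largest pooled
    value with ``k = floor(len(pool) / 2**n)`` and retention is ``score >=
    threshold``; for p-values it is the k-th smallest with retention
    ``score <= threshold``.  Raises :class:`EmptyRetentionError` when k = 0.
    """
    scores = np.asarray(pooled_scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("pooled_scores must be a non-empty 1-d vector")
    k = int(scores.size * spec.retained_fraction)
    if k < 1:
        raise EmptyRetentionError(
            f"n={spec.n} retains fewer than one of {scores.size} pooled scores"
        )
    ordered = np.sort(scores)
    if spec.mode is ThresholdMode.variance_explained:
        cutoff = float(ordered[-k])
    else:
        cutoff = float(ordered[k - 1])
    return dataclasses.replace(spec, threshold_value=cutoff)


def retained_mask(
    dataset: GenotypeDataset,
    arch: TraitArchitecture,
    spec: ThresholdSpec,
    y_bot: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of SNPs surpassing the calibrated threshold in the bottleneck sample."""
    if not spec.calibrated:
        raise ValueError("spec must be calibrated (threshold_value is unset)")
    if dataset.L != arch.L:
        raise ValueError("dataset and architecture disagree on the SNP set")
    if spec.mode is ThresholdMode.variance_explained:
        scores = variance_explained(dataset.f_bot, arch.betas)
        return scores >= spec.threshold_value
    if y_bot is None:
        raise ValueError("p-value mode requires the bottleneck phenotype vector")
    return gwas_pvalues(dataset.X_bot, y_bot) <= spec.threshold_value


@dataclasses.dataclass(frozen=True)
class ThresholdedHeritability:
    """Bottleneck heritability before and after discarding undetectable SNPs."""

    h2_simulated: float
    h2_thresholded: float
    n_snps_total: int
    n_snps_retained: int

    def __iter__(self):
        # allow `h2_sim, h2_thr = thresholded_heritability(...)`
        return iter((self.h2_simulated, self.h2_thresholded))


def thresholded_heritability(
    dataset: GenotypeDataset,
    arch: TraitArchitecture,
    spec: ThresholdSpec,
    y_bot: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> ThresholdedHeritability:
    """Recompute bottleneck heritability using only SNPs above the power threshold.

    ``h2_simulated`` uses all SNPs; ``h2_thresholded`` recomputes Vg_bot from
    the retained columns with the same Ve.  An empty retained set yields
    ``h2_thresholded = 0`` (reported, not an error).  In p-value mode a
    bottleneck phenotype vector is simulated from ``arch.Ve`` and ``seed``
    unless ``y_bot`` is supplied.
    """
    if spec.mode is ThresholdMode.p_value and y_bot is None:
        y_bot = simulate_phenotypes(genetic_values(dataset.X_bot, arch.betas), arch.Ve, seed)
    mask = retained_mask(dataset, arch, spec, y_bot=y_bot)
    Vg_all = float(np.var(genetic_values(dataset.X_bot, arch.betas)))
    h2_sim = heritability_from_variances(Vg_all, arch.Ve)
    if mask.all():
        h2_thr = h2_sim  # exact identity when nothing is filtered
    elif mask.any():
        Vg_kept = float(np.var(genetic_values(dataset.X_bot[:, mask], arch.betas[mask])))
        h2_thr = heritability_from_variances(Vg_kept, arch.Ve)
    else:
        h2_thr = 0.0
    return ThresholdedHeritability(
        h2_simulated=h2_sim,
        h2_thresholded=h2_thr,
        n_snps_total=int(dataset.L),
        n_snps_retained=int(mask.sum()),
    )
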