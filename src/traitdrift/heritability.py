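"""Genetic variance and heritability in both populations for a fixed trait."""

from __future__ import annotations

import dataclasses

import numpy as np

from .scenario_sim import GenotypeDataset
from .trait_model import TraitArchitecture, genetic_values

__all__ = ["HeritabilityResult", "heritability_from_variances", "evaluate_trait"]


def heritability_from_variances(Vg: float, Ve: float) -> float:
    """h2 = Vg / (Vg + Ve)."""
    if Vg < 0 or Ve < 0:
        raise ValueError(f"variances must be >= 0, got Vg={Vg}, Ve={Ve}")
    if Vg + Ve == 0:
        raise ValueError("Vg and Ve cannot both be zero")
    return Vg / (Vg + Ve)


@dataclasses.dataclass(frozen=True)
class HeritabilityResult:
    """Genetic variances and heritabilities for one trait realization.

    The same environmental variance ``Ve`` (calibrated in the Reference
    population) is used on both sides.
    """

    Vg_ref: float
    Vg_bot: float
    h2_ref: float
    h2_bot: float
    Ve: float

    def __post_init__(self) -> None:
        for name in ("h2_ref", "h2_bot"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def evaluate_trait(dataset: GenotypeDataset, arch: TraitArchitecture) -> HeritabilityResult:
    """Compute Vg and h2 in the Reference and Bottlenecked samples.

    Uses the shared effect sizes and the single Reference-calibrated Ve;
    variances are empirical over the sampled individuals (ddof=0).  When Ve
    was calibrated on this dataset, ``h2_ref`` equals the calibration target
    up to floating point.
    """
    if dataset.L != arch.L:
        raise ValueError(
            f"SNP-set mismatch: dataset has {dataset.L} SNPs, architecture has {arch.L}"
        )
    Vg_ref = float(np.var(genetic_values(dataset.X_ref, arch.betas)))
    Vg_bot = float(np.var(genetic_values(dataset.X_bot, arch.betas)))
    return HeritabilityResult(
        Vg_ref=Vg_ref,
        Vg_bot=Vg_bot,
        h2_ref=heritability_from_variances(Vg_ref, arch.Ve),
        h2_bot=heritability_from_variances(Vg_bot, arch.Ve),
        Ve=arch.Ve,
    )
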