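"""Polygenic trait architecture on top of a genotype dataset.

Effect sizes are drawn per SNP from a zero-mean Gaussian whose variance is
coupled to the Reference-sample allele frequency, ``[f(1-f)]**s``.  With the
default ``s = -1`` rare alleles carry large effects, mimicking a trait whose
variance has been selected against.  Environmental variance is calibrated
once, in the Reference population, to hit a target heritability and is then
held constant for the bottlenecked population.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Any

import numpy as np

from .scenario_sim import GenotypeDataset

__all__ = [
    "TraitArchitecture",
    "effect_size_variance",
    "draw_effect_sizes",
    "genetic_values",
    "calibrate_Ve",
    "simulate_phenotypes",
    "build_architecture",
]


@dataclasses.dataclass(frozen=True)
class TraitArchitecture:
    """Per-SNP effect sizes plus the calibrated environmental variance."""

    betas: np.ndarray
    s: float = -1.0
    Ve: float = float("nan")
    h2_target: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError(f"h2_target must be in (0, 1), got {self.h2_target}")
        if np.isfinite(self.Ve) and self.Ve < 0:
            raise ValueError(f"Ve must be >= 0, got {self.Ve}")

    @property
    def L(self) -> int:
        return len(self.betas)

    def to_csv(
        self,
        csv_path: str | pathlib.Path,
        dataset: GenotypeDataset | None = None,
        sidecar: dict[str, Any] | None = None,
    ) -> None:
        """Write (position, f_ref, beta) rows plus a JSON sidecar of scalars."""
        csv_path = pathlib.Path(csv_path)
        with csv_path.open("w") as fh:
            fh.write("position,f_ref,beta\n")
            for j in range(self.L):
                pos = dataset.positions[j] if dataset is not None else float("nan")
                f = dataset.f_ref[j] if dataset is not None else float("nan")
                fh.write(f"{pos},{f},{self.betas[j]}\n")
        meta = {"s": self.s, "Ve": self.Ve, "h2_target": self.h2_target}
        if sidecar:
            meta.update(sidecar)
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def effect_size_variance(f, s: float):
    """Variance of the effect-size distribution at frequency ``f``: ``[f(1-f)]**s``.

    ``f`` may be a scalar or array; every entry must lie strictly in (0, 1)
    (the expression is undefined at 0 and 1 for negative ``s``).
    """
    f = np.asarray(f, dtype=float)
    bad = np.nonzero(~((np.atleast_1d(f) > 0) & (np.atleast_1d(f) < 1)))[0]
    if bad.size:
        raise ValueError(
            f"frequencies must be strictly in (0, 1); offending index {bad[0]} "
            f"with value {f.flat[bad[0]]}"
        )
    out = (f * (1.0 - f)) ** s
    return out if out.ndim else float(out)


def draw_effect_sizes(
    f_ref: np.ndarray,
    s: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw independent N(0, [f(1-f)]**s) effect sizes, one per SNP."""
    rng = np.random.default_rng(seed)
    sd = np.sqrt(effect_size_variance(f_ref, s))
    return rng.normal(0.0, 1.0, size=len(sd)) * sd


def genetic_values(X: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Per-individual genetic value: the matrix-vector product ``X @ betas``."""
    X = np.asarray(X)
    betas = np.asarray(betas, dtype=float)
    if X.ndim != 2 or betas.ndim != 1 or X.shape[1] != betas.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"betas has length {betas.shape[0] if betas.ndim == 1 else '?'}"
        )
    return X.astype(float) @ betas


def calibrate_Ve(Vg_ref: float, h2_target: float) -> float:
    """Environmental variance pinning Reference heritability at ``h2_target``.

    Inverts h2 = Vg / (Vg + Ve): returns ``Vg_ref * (1 - h2_target) / h2_target``.
    """
    if not 0.0 < h2_target < 1.0:
        raise ValueError(f"h2_target must be in (0, 1), got {h2_target}")
    if Vg_ref <= 0:
        raise ValueError(
            f"cannot calibrate a trait with no genetic variance (Vg_ref={Vg_ref})"
        )
    return Vg_ref * (1.0 - h2_target) / h2_target


def simulate_phenotypes(
    genetic_values: np.ndarray,
    Ve: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Add i.i.d. N(0, Ve) environmental noise to the genetic values."""
    if Ve < 0:
        raise ValueError(f"Ve must be >= 0, got {Ve}")
    rng = np.random.default_rng(seed)
    gv = np.asarray(genetic_values, dtype=float)
    return gv + rng.normal(0.0, np.sqrt(Ve), size=gv.shape)


def build_architecture(
    dataset: GenotypeDataset,
    s: float = -1.0,
    h2_target: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> TraitArchitecture:
    """Draw effect sizes for ``dataset`` and calibrate Ve in the Reference sample.

    Vg_ref is the empirical (population-convention, ddof=0) variance of
    Reference genetic values, so covariance between linked SNPs is included.
    """
    betas = draw_effect_sizes(dataset.f_ref, s, seed)
    Vg_ref = float(np.var(genetic_values(dataset.X_ref, betas)))
    Ve = calibrate_Ve(Vg_ref, h2_target)
    return TraitArchitecture(betas=betas, s=s, Ve=Ve, h2_target=h2_target)
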