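"""Two-population split demography and genotype simulation.

A single ancestral population of size ``N0`` splits ``T`` generations ago
into a Reference population (constant size ``N0``) and a Bottlenecked
population founded with ``N`` diploid individuals.  The bottlenecked
population may grow exponentially at per-generation rate ``g`` (so its
present-day size is ``N * exp(g*T)``) and may receive migrants from the
Reference population at per-generation fraction ``m``.

Genealogies are simulated with :mod:`msprime`; mutations are superimposed
under the infinite-sites model (continuous positions, binary alleles) with
no restriction on when they may occur.  The causal SNP universe is the set
of sites segregating in the *Reference sample*.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Any, Mapping

import msprime
import numpy as np
import tskit

__all__ = [
    "DemographyConfig",
    "GenotypeDataset",
    "EmptyTraitError",
    "growth_factor",
    "build_demography",
    "simulate_tree_sequence",
    "dataset_from_tree_sequence",
    "simulate_genotypes",
    "allele_frequencies",
    "write_vcf",
]


class EmptyTraitError(RuntimeError):
    """No causal SNPs segregate in the Reference sample."""


def growth_factor(g: float, T: float) -> float:
    """Fold change of a population growing exponentially at rate ``g`` for ``T`` generations.

    Returns ``exp(g * T)``.
    """
    if g < 0:
        raise ValueError(f"g must be >= 0, got {g}")
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    return math.exp(g * T)


@dataclasses.dataclass(frozen=True)
class DemographyConfig:
    """All demographic and genomic parameters of one scenario.

    Sizes are counts of diploid individuals.  ``m`` is the forward-time
    per-generation migration fraction from the Reference population into the
    Bottlenecked population.  ``causal_mutation_rate`` is the per-bp
    per-generation rate of causal mutations (an already-scaled rate: the
    fraction of mutations that are causal is folded into it).
    """

    N0: int = 10_000
    N: int = 1_000
    T: float = 200.0
    m: float = 0.0
    g: float = 0.0
    genome_length_morgans: float = 0.1
    genome_length_bp: int = 10_000_000
    causal_mutation_rate: float = 4e-10
    n_sample_ref: int = 500
    n_sample_bot: int = 500
    seed: int = 1

    def __post_init__(self) -> None:
        if self.N0 < 1:
            raise ValueError(f"N0 must be >= 1, got {self.N0}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.T < 0:
            raise ValueError(f"T must be >= 0, got {self.T}")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must be in [0, 1], got {self.m}")
        if self.g < 0:
            raise ValueError(f"g must be >= 0, got {self.g}")
        if self.genome_length_morgans <= 0:
            raise ValueError(
                f"genome_length_morgans must be > 0, got {self.genome_length_morgans}"
            )
        if self.genome_length_bp <= 0:
            raise ValueError(f"genome_length_bp must be > 0, got {self.genome_length_bp}")
        if self.causal_mutation_rate < 0:
            raise ValueError(
                f"causal_mutation_rate must be >= 0, got {self.causal_mutation_rate}"
            )
        if self.n_sample_ref < 1 or self.n_sample_ref > self.N0:
            raise ValueError(
                f"n_sample_ref must be in [1, N0={self.N0}], got {self.n_sample_ref}"
            )
        present = self.bottleneck_size_now
        if self.n_sample_bot < 1 or self.n_sample_bot > present:
            raise ValueError(
                f"n_sample_bot must be in [1, N*exp(g*T)={present:.1f}], "
                f"got {self.n_sample_bot}"
            )
        if self.seed < 0:
            raise ValueError(f"seed must be >= 0, got {self.seed}")

    @property
    def bottleneck_size_now(self) -> float:
        """Present-day size of the bottlenecked population, ``N * exp(g*T)``."""
        return self.N * growth_factor(self.g, self.T)

    @property
    def recombination_rate(self) -> float:
        """Uniform per-bp per-generation recombination rate."""
        return self.genome_length_morgans / self.genome_length_bp

    def replace(self, **changes: Any) -> "DemographyConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DemographyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**dict(d))


def build_demography(config: DemographyConfig) -> msprime.Demography:
    """Build the two-population split demography for ``config``.

    Three populations: ``ref`` (constant size ``N0``) and ``bot`` are both
    sampled at present day and merge into the ancestral ``anc`` (size ``N0``)
    at the split time ``T``.  Backward in time the bottlenecked population
    has present-day size ``N * exp(g*T)`` shrinking at rate ``g`` back to
    ``N`` at founding.  The forward-time migration ``m`` from Reference into
    Bottlenecked corresponds to lineage movement from ``bot`` to ``ref`` in
    the coalescent.

    The degenerate case ``T = 0`` (both samples drawn from one panmictic
    population at present day) is modelled as a single population of size
    ``N0``.
    """
    demography = msprime.Demography()
    if config.T == 0:
        demography.add_population(name="anc", initial_size=config.N0)
        return demography
    demography.add_population(name="ref", initial_size=config.N0)
    demography.add_population(
        name="bot",
        initial_size=config.bottleneck_size_now,
        growth_rate=config.g,
    )
    demography.add_population(name="anc", initial_size=config.N0)
    demography.add_population_split(time=config.T, derived=["ref", "bot"], ancestral="anc")
    if config.m > 0:
        # backward-time convention: lineages now in "bot" trace back to "ref"
        demography.set_migration_rate(source="bot", dest="ref", rate=config.m)
    return demography


def _msprime_seeds(seed: int) -> tuple[int, int]:
    # msprime requires seeds in [1, 2**32 - 1]
    state = np.random.SeedSequence(seed).generate_state(2, dtype=np.uint64)
    return tuple(int(s) % (2**32 - 1) + 1 for s in state)


def simulate_tree_sequence(config: DemographyConfig) -> tskit.TreeSequence:
    """Simulate genealogies and superimpose infinite-sites mutations."""
    ancestry_seed, mutation_seed = _msprime_seeds(config.seed)
    if config.T == 0:
        samples = {"anc": config.n_sample_ref + config.n_sample_bot}
    else:
        samples = {"ref": config.n_sample_ref, "bot": config.n_sample_bot}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=build_demography(config),
        sequence_length=config.genome_length_bp,
        recombination_rate=config.recombination_rate,
        ploidy=2,
        random_seed=ancestry_seed,
    )
    return msprime.sim_mutations(
        ts,
        rate=config.causal_mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,  # infinite sites: unique float positions
        random_seed=mutation_seed,
    )


@dataclasses.dataclass(frozen=True)
class GenotypeDataset:
    """Sampled diploid genotypes for both populations at the causal SNP set.

    ``X_ref`` and ``X_bot`` are derived-allele count matrices (individuals x
    SNPs, entries in {0, 1, 2}) over the same column order; only SNPs
    segregating in the Reference sample are kept, so ``0 < f_ref < 1``
    columnwise while ``f_bot`` may hit 0 (lost) or 1 (fixed).
    """

    X_ref: np.ndarray
    X_bot: np.ndarray
    f_ref: np.ndarray
    f_bot: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        if self.X_ref.ndim != 2 or self.X_bot.ndim != 2:
            raise ValueError("genotype matrices must be 2-dimensional")
        if self.X_ref.shape[1] != self.X_bot.shape[1]:
            raise ValueError("X_ref and X_bot must share the SNP (column) dimension")
        L = self.X_ref.shape[1]
        for name, vec in (
            ("f_ref", self.f_ref),
            ("f_bot", self.f_bot),
            ("positions", self.positions),
        ):
            if vec.shape != (L,):
                raise ValueError(f"{name} must have length {L}, got {vec.shape}")
        if L and not (np.all(self.f_ref > 0) and np.all(self.f_ref < 1)):
            raise ValueError("f_ref entries must be strictly in (0, 1)")
        if L and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def L(self) -> int:
        """Number of causal SNPs (segregating in the Reference sample)."""
        return self.X_ref.shape[1]

    @property
    def n_ref(self) -> int:
        return self.X_ref.shape[0]

    @property
    def n_bot(self) -> int:
        return self.X_bot.shape[0]

    def to_csv(self, directory: str | pathlib.Path, config: DemographyConfig | None = None) -> None:
        """Write genotype matrices as CSV plus a JSON sidecar of frequencies/config."""
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = ",".join(f"snp{i}" for i in range(self.L))
        np.savetxt(directory / "X_ref.csv", self.X_ref, fmt="%d", delimiter=",", header=header, comments="")
        np.savetxt(directory / "X_bot.csv", self.X_bot, fmt="%d", delimiter=",", header=header, comments="")
        sidecar = {
            "L": self.L,
            "positions": self.positions.tolist(),
            "f_ref": self.f_ref.tolist(),
            "f_bot": self.f_bot.tolist(),
        }
        if config is not None:
            sidecar["config"] = config.to_dict()
        (directory / "dataset.json").write_text(json.dumps(sidecar, indent=2))


def allele_frequencies(X: np.ndarray) -> np.ndarray:
    """Per-SNP derived-allele frequency of a diploid count matrix.

    Column mean divided by 2.  Rejects empty input and entries outside {0,1,2}.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("genotype matrix must be non-empty and 2-dimensional")
    if not np.isin(X, (0, 1, 2)).all():
        raise ValueError("genotype entries must be in {0, 1, 2}")
    return X.mean(axis=0) / 2.0


def _diploid_matrices(ts: tskit.TreeSequence, n_ref: int) -> tuple[np.ndarray, np.ndarray]:
    """(Reference, Bottleneck) individuals x sites derived-allele count matrices.

    Individuals are assigned by the population of their nodes ("ref" = 0,
    "bot" = 1).  For a single-population tree sequence (the ``T = 0`` case)
    the first ``n_ref`` sampled individuals form the Reference sample.
    """
    node_population = ts.tables.nodes.population
    first_nodes, second_nodes, populations = [], [], []
    for ind in ts.individuals():
        nodes = ind.nodes
        if len(nodes) != 2:
            raise ValueError("expected diploid individuals")
        first_nodes.append(nodes[0])
        second_nodes.append(nodes[1])
        populations.append(node_population[nodes[0]])
    G = ts.genotype_matrix()  # sites x sample nodes, derived-allele indicator
    X = (G[:, first_nodes] + G[:, second_nodes]).T.astype(np.int8)
    populations = np.asarray(populations)
    if len(set(populations.tolist())) > 1:
        return X[populations == 0], X[populations == 1]
    return X[:n_ref], X[n_ref:]


def dataset_from_tree_sequence(ts: tskit.TreeSequence, n_ref: int | None = None) -> GenotypeDataset:
    """Extract the causal-SNP genotype dataset from a simulated tree sequence.

    Restricts to sites segregating in the Reference sample.  Raises
    :class:`EmptyTraitError` if no such site exists.
    """
    if ts.num_sites == 0:
        raise EmptyTraitError("no mutations were generated on the genealogy")
    X_ref_all, X_bot_all = _diploid_matrices(
        ts, n_ref if n_ref is not None else ts.num_individuals
    )
    f_ref_all = X_ref_all.mean(axis=0) / 2.0
    keep = (f_ref_all > 0) & (f_ref_all < 1)
    if not keep.any():
        raise EmptyTraitError("no SNP segregates in the Reference sample")
    positions = ts.tables.sites.position[keep]
    X_ref = np.ascontiguousarray(X_ref_all[:, keep])
    X_bot = np.ascontiguousarray(X_bot_all[:, keep])
    return GenotypeDataset(
        X_ref=X_ref,
        X_bot=X_bot,
        f_ref=f_ref_all[keep],
        f_bot=X_bot.mean(axis=0) / 2.0,
        positions=positions,
    )


def simulate_genotypes(config: DemographyConfig) -> GenotypeDataset:
    """Simulate one scenario and return the causal-SNP genotype dataset.

    Deterministic given ``config`` (including its seed).  Raises
    :class:`EmptyTraitError` when no SNP segregates in the Reference sample.
    """
    return dataset_from_tree_sequence(
        simulate_tree_sequence(config), n_ref=config.n_sample_ref
    )


def write_vcf(dataset: GenotypeDataset, path: str | pathlib.Path) -> None:
    """Export both samples as a single diploid VCF (derived allele as ALT).

    Infinite-sites float positions are rounded up to unique 1-based integer
    coordinates; Reference individuals come first.
    """
    path = pathlib.Path(path)
    n_ref, n_bot = dataset.n_ref, dataset.n_bot
    names = [f"ref{i}" for i in range(n_ref)] + [f"bot{i}" for i in range(n_bot)]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names),
    ]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    last_pos = 0
    for j in range(dataset.L):
        pos = max(int(math.floor(dataset.positions[j])) + 1, last_pos + 1)
        last_pos = pos
        calls = [gt[int(c)] for c in dataset.X_ref[:, j]]
        calls += [gt[int(c)] for c in dataset.X_bot[:, j]]
        lines.append(f"1\t{pos}\tsnp{j}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls))
    path.write_text("\n".join(lines) + "\n")
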