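"""Desk-scale synthetic genomes with plantable editing-context signal.

The signal model is deliberately simple: positives are copies of a fixed
adenine-centered consensus with independent per-position mutations,
planted on either strand of an i.i.d. background genome. This creates a
learnable similarity structure without imitating real ADAR preferences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contexts import ContextSequence, GenomicSite, extract_context, sample_negative_sites
from .exceptions import ParameterError
from .io import revcomp, write_fasta, write_sites

_BASES = "ACGT"


@dataclass(frozen=True)
class MotifModel:
    """Mutated-consensus motif; the central adenine is always preserved."""

    consensus: str
    per_position_mutation_prob: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "consensus", self.consensus.upper())
        if len(self.consensus) % 2 == 0:
            raise ParameterError("consensus length must be odd")
        if self.consensus[len(self.consensus) // 2] != "A":
            raise ParameterError("consensus center must be 'A'")
        if not 0.0 <= self.per_position_mutation_prob < 1.0:
            raise ParameterError("per_position_mutation_prob must be in [0, 1)")

    @property
    def length(self) -> int:
        return len(self.consensus)

    def sample(self, rng: np.random.Generator) -> str:
        """One motif instance: each non-center base mutated with prob p."""
        center = self.length // 2
        chars = list(self.consensus)
        flips = rng.random(self.length) < self.per_position_mutation_prob
        for i in np.flatnonzero(flips):
            if i == center:
                continue
            choices = [b for b in _BASES if b != chars[i]]
            chars[i] = choices[rng.integers(3)]
        return "".join(chars)


def random_consensus(length: int, seed: int) -> str:
    """A random odd-length consensus with 'A' at the center."""
    if length % 2 == 0:
        raise ParameterError("length must be odd")
    rng = np.random.default_rng(seed)
    chars = [_BASES[i] for i in rng.integers(4, size=length)]
    chars[length // 2] = "A"
    return "".join(chars)


def generate_genome(length: int, base_composition=(0.25, 0.25, 0.25, 0.25),
                    seed: int = 0, n_contigs: int = 1,
                    name_prefix: str = "chr") -> dict[str, str]:
    """i.i.d. genome of ``n_contigs`` contigs of ``length`` nt each."""
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
        raise ParameterError(
            "base_composition must be 4 non-negative probabilities summing to 1"
        )
    if length < 1 or n_contigs < 1:
        raise ParameterError("length and n_contigs must be >= 1")
    rng = np.random.default_rng(seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for c in range(n_contigs):
        idx = rng.choice(4, size=length, p=comp)
        genome[f"{name_prefix}{c + 1}"] = lut[idx].tobytes().decode("ascii")
    return genome


def plant_sites(genome: dict[str, str], motif: MotifModel, n_sites: int,
                seed: int = 0) -> tuple[dict[str, str], list[GenomicSite]]:
    """Plant non-overlapping motif instances on random strands.

    Minus-strand instances appear reverse-complemented on the forward
    strand (their center becomes a forward 'T'). Returns the modified
    genome and the truth sites in genomic order.
    """
    if n_sites < 1:
        raise ParameterError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    L = motif.length
    flank = L // 2
    contigs = list(genome)
    capacity = sum(max(0, len(genome[c]) - L + 1) for c in contigs)
    if capacity < n_sites * L:
        raise ParameterError(
            f"genome too small to place {n_sites} non-overlapping {L}-mers"
        )
    arrays = {c: bytearray(genome[c].encode("ascii")) for c in contigs}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    weights = np.array([len(genome[c]) for c in contigs], dtype=float)
    weights /= weights.sum()
    sites: list[GenomicSite] = []
    attempts = 0
    while len(sites) < n_sites:
        attempts += 1
        if attempts > 1000 * n_sites:
            raise ParameterError("failed to place non-overlapping sites; genome too small")
        chrom = contigs[rng.choice(len(contigs), p=weights)]
        n = len(genome[chrom])
        if n < L:
            continue
        start = int(rng.integers(n - L + 1))
        if any(start < e and start + L > s for s, e in occupied[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        instance = motif.sample(rng)
        placed = instance if strand == "+" else revcomp(instance)
        arrays[chrom][start : start + L] = placed.encode("ascii")
        occupied[chrom].append((start, start + L))
        sites.append(GenomicSite(chrom, start + flank + 1, strand))
    new_genome = {c: arrays[c].decode("ascii") for c in contigs}
    order = {c: i for i, c in enumerate(contigs)}
    sites.sort(key=lambda s: (order[s.chrom], s.pos))
    return new_genome, sites


@dataclass(frozen=True)
class BenchmarkConfig:
    genome_length: int = 120_000
    n_contigs: int = 1
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    consensus: str | None = None  # derived from seed when None
    context_length: int = 41
    mutation_prob: float = 0.05
    n_sites: int = 200
    negative_rate: float = 2e-3
    seed: int = 0

    @property
    def flank(self) -> int:
        return self.context_length // 2


@dataclass
class Benchmark:
    config: BenchmarkConfig
    genome: dict[str, str]
    motif: MotifModel
    pos_sites: list[GenomicSite]
    pos_contexts: list[ContextSequence]
    neg_contexts: list[ContextSequence]

    @property
    def neg_sites(self) -> list[GenomicSite]:
        return [c.origin for c in self.neg_contexts]

    def write(self, outdir) -> dict[str, Path]:
        """Write genome.fa, positives.tsv, negatives.tsv under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "positives": outdir / "positives.tsv",
            "negatives": outdir / "negatives.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_sites(self.pos_sites, paths["positives"],
                    labels=["positive"] * len(self.pos_sites))
        write_sites(self.neg_sites, paths["negatives"],
                    labels=["negative"] * len(self.neg_contexts))
        return paths


def make_benchmark(config: BenchmarkConfig = BenchmarkConfig()) -> Benchmark:
    """Compose genome generation, planting, extraction and negative sampling.

    Fully deterministic given ``config`` (a single top-level seed fans
    out to the component seeds).
    """
    consensus = config.consensus or random_consensus(
        config.context_length, config.seed + 10_000
    )
    motif = MotifModel(consensus, config.mutation_prob)
    genome = generate_genome(config.genome_length, config.base_composition,
                             seed=config.seed, n_contigs=config.n_contigs)
    genome, pos_sites = plant_sites(genome, motif, config.n_sites,
                                    seed=config.seed + 1)
    pos_contexts = [
        extract_context(genome, s, config.flank, label="positive")
        for s in pos_sites
    ]
    neg_contexts = sample_negative_sites(
        genome, config.negative_rate, seed=config.seed + 2,
        exclude=pos_contexts, flank=config.flank,
    )
    return Benchmark(config=config, genome=genome, motif=motif,
                     pos_sites=pos_sites, pos_contexts=pos_contexts,
                     neg_contexts=neg_contexts)
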