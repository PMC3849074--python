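"""Two-class synthetic metagenome generator.

The generator emulates the study design used throughout this package's
benchmarks: random background genomes (i.i.d. bases), class-specific short
motifs ("seeds") overwritten into each genome at a controlled density, and
error-free short reads sampled uniformly from both strands at a fixed fold
coverage.  Seed density is defined as ``l * n_insertions / n`` for seed
length ``l`` and genome length ``n``, so the number of insertion events per
seed is ``round(density * n / l)`` (half away from zero).

Everything is driven by a single seeded :class:`numpy.random.Generator`, so
a dataset is fully reproducible from its :class:`SimulationConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dna import BASES, decode, encode, reverse_complement

__all__ = [
    "SeedSpec",
    "SimulationConfig",
    "ReadSet",
    "InsertionEvent",
    "SampleTruth",
    "generate_background_genome",
    "insert_seeds",
    "sample_reads",
    "generate_dataset",
    "random_seed_specs",
]

UNIFORM_BASE_PROBS = (0.25, 0.25, 0.25, 0.25)


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SeedSpec:
    """A motif to insert plus the target density l*#insertions/n."""

    sequence: str
    density: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("seed sequence must be non-empty")
        if set(self.sequence) - set(BASES):
            raise ValueError(f"seed sequence must be over ACGT: {self.sequence!r}")
        if not self.density > 0:
            raise ValueError("seed density must be positive")

    def n_insertions(self, genome_length: int) -> int:
        """Insertion events needed to reach the target density."""
        count = _round_half_away(self.density * genome_length / len(self.sequence))
        if count < 1:
            raise ValueError(
                f"density {self.density} gives no insertions for genome length "
                f"{genome_length} and seed length {len(self.sequence)}"
            )
        return count


@dataclass
class ReadSet:
    """One sample's reads plus its identifier and optional class label."""

    sample_id: str
    reads: list[str]
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (-1, 1):
            raise ValueError(f"label must be -1 or +1, got {self.label}")


@dataclass(frozen=True)
class InsertionEvent:
    seed: str
    position: int  # 0-based start in the genome


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample: genome and insertion events."""

    sample_id: str
    genome: str
    events: list[InsertionEvent]


@dataclass
class SimulationConfig:
    """Parameters of a two-class simulation.

    Defaults are the benchmark conditions used throughout: 25 genomes per
    class, genome length 10,000, uniform base composition, 50 bp error-free
    reads at 10x coverage.
    """

    n_per_class: int = 25
    genome_length: int = 10_000
    base_probs: tuple[float, float, float, float] = UNIFORM_BASE_PROBS
    seeds_class1: Sequence[SeedSpec] = field(default_factory=tuple)
    seeds_class2: Sequence[SeedSpec] = field(default_factory=tuple)
    read_length: int = 50
    coverage: float = 10.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        probs = np.asarray(self.base_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any():
            raise ValueError("base_probs must be 4 non-negative numbers")
        if abs(float(probs.sum()) - 1.0) > 1e-12:
            raise ValueError("base_probs must sum to 1")
        if self.genome_length < self.read_length:
            raise ValueError("genome_length must be >= read_length")
        if not self.coverage > 0:
            raise ValueError("coverage must be positive")
        for seed in (*self.seeds_class1, *self.seeds_class2):
            if len(seed.sequence) > self.genome_length:
                raise ValueError("seed longer than genome")
            seed.n_insertions(self.genome_length)  # raises if density too low


def generate_background_genome(
    genome_length: int, base_probs: Sequence[float], rng: np.random.Generator
) -> str:
    """Draw a genome of i.i.d. bases from ``base_probs`` (A, C, G, T)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    probs = np.asarray(base_probs, dtype=float)
    if probs.shape != (4,) or (probs < 0).any() or abs(float(probs.sum()) - 1.0) > 1e-12:
        raise ValueError("base_probs must be 4 non-negative numbers summing to 1")
    codes = rng.choice(4, size=genome_length, p=probs)
    return decode(codes)


def insert_seeds(
    genome: str, seeds: Sequence[SeedSpec], rng: np.random.Generator
) -> tuple[str, list[InsertionEvent]]:
    """Overwrite seed motifs into a genome at random positions.

    Each seed is inserted ``round(density * n / l)`` times at positions drawn
    independently and uniformly from the legal range; later insertions may
    overwrite earlier ones, so the number of *surviving* copies can be lower.
    Genome length is conserved.  Returns the new genome and the insertion
    events (seed, 0-based position) for ground-truth bookkeeping.
    """
    n = len(genome)
    arr = bytearray(genome, "ascii")
    events: list[InsertionEvent] = []
    for seed in seeds:
        l = len(seed.sequence)
        if l > n:
            raise ValueError(f"seed {seed.sequence!r} longer than genome (n={n})")
        seq = seed.sequence.encode("ascii")
        for _ in range(seed.n_insertions(n)):
            pos = int(rng.integers(0, n - l + 1))
            arr[pos : pos + l] = seq
            events.append(InsertionEvent(seed.sequence, pos))
    return arr.decode("ascii"), events


def sample_reads(
    genome: str,
    read_length: int,
    coverage: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
    label: Optional[int] = None,
) -> ReadSet:
    """Sample error-free reads uniformly from both strands of a genome.

    The read count is ``round(coverage * n / read_length)``; each read starts
    uniformly in the legal range and comes from either strand with equal
    probability (reverse-complemented when from the minus strand).  Start
    positions are drawn with replacement.
    """
    n = len(genome)
    if read_length > n:
        raise ValueError(f"read_length {read_length} exceeds genome length {n}")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    n_reads = _round_half_away(coverage * n / read_length)
    starts = rng.integers(0, n - read_length + 1, size=n_reads)
    minus = rng.random(n_reads) < 0.5
    reads = []
    for start, is_minus in zip(starts, minus):
        fragment = genome[start : start + read_length]
        reads.append(reverse_complement(fragment) if is_minus else fragment)
    return ReadSet(sample_id=sample_id, reads=reads, label=label)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[ReadSet], list[SampleTruth]]:
    """Generate a full labelled two-class dataset.

    Class 1 genomes (label +1) receive ``seeds_class1``, class 2 genomes
    (label -1) receive ``seeds_class2``.  Fully reproducible from
    ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    samples: list[ReadSet] = []
    truths: list[SampleTruth] = []
    width = max(2, len(str(config.n_per_class)))
    for class_no, (seeds, label) in enumerate(
        [(config.seeds_class1, +1), (config.seeds_class2, -1)], start=1
    ):
        for i in range(config.n_per_class):
            sample_id = f"class{class_no}_{i + 1:0{width}d}"
            genome = generate_background_genome(
                config.genome_length, config.base_probs, rng
            )
            genome, events = insert_seeds(genome, seeds, rng)
            read_set = sample_reads(
                genome,
                config.read_length,
                config.coverage,
                rng,
                sample_id=sample_id,
                label=label,
            )
            samples.append(read_set)
            truths.append(SampleTruth(sample_id, genome, events))
    return samples, truths


def random_seed_specs(
    n_seeds: int,
    length: int,
    density: float,
    rng: np.random.Generator,
    exclude: Sequence[str] = (),
) -> list[SeedSpec]:
    """Draw distinct random seed motifs of a given length.

    Motifs are drawn uniformly; a candidate is rejected if it, or its reverse
    complement, collides with an already-drawn or excluded motif, so that two
    classes given disjoint seed sets carry genuinely distinct signatures even
    on reads from both strands.
    """
    taken = set()
    for s in exclude:
        taken.add(s)
        taken.add(reverse_complement(s))
    specs: list[SeedSpec] = []
    while len(specs) < n_seeds:
        seq = decode(rng.integers(0, 4, size=length))
        if seq in taken or reverse_complement(seq) in taken:
            continue
        taken.add(seq)
        taken.add(reverse_complement(seq))
        specs.append(SeedSpec(sequence=seq, density=density))
    return specs
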