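"""Synthetic satellite-DNA libraries, species pools, tandem arrays and reads.

The generator embodies the satDNA "library" model of concerted evolution:
related species inherit a common pool of monomer variants from their ancestor
and amplify them differentially. An :class:`AncestralLibrary` holds the shared
variant pool; a :class:`SpeciesProfile` states how strongly each variant is
amplified in one species, and how much post-amplification mutation (per-site
substitutions, occasional short indels) the copies accumulate. Amplified
copies are laid down as a tandem array from which paired-end reads are
sampled, so the whole downstream analysis can be exercised against known
ground truth.

All randomness flows through explicit integer seeds; identical seed and
configuration give byte-identical output (including FASTQ files).
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._align import revcomp
from .errors import ParameterError
from .readprep import ReadPair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_UNIT = 177


def _to_idx(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ParameterError("sequence contains symbols outside {A,C,G,T}")
    return arr


def _to_seq(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode()


@dataclass(frozen=True)
class AncestralLibrary:
    """A shared pool of related monomer haplotypes (the satDNA 'library').

    ``divergence`` is the expected per-site substitution proportion between
    the root haplotype and each derived haplotype.
    """

    haplotypes: tuple[tuple[str, str], ...]
    divergence: float

    def __post_init__(self):
        if not self.haplotypes:
            raise ParameterError("library must contain at least one haplotype")
        ids = [h[0] for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            raise ParameterError("haplotype ids must be unique")
        for _, seq in self.haplotypes:
            if not seq or set(seq) - set("ACGT"):
                raise ParameterError("haplotype sequences must be non-empty over {A,C,G,T}")

    @property
    def ids(self) -> list[str]:
        return [h[0] for h in self.haplotypes]

    @property
    def sequences(self) -> list[str]:
        return [h[1] for h in self.haplotypes]

    def __len__(self) -> int:
        return len(self.haplotypes)


@dataclass
class SpeciesProfile:
    """Per-species amplification of the ancestral library.

    ``amplification_weights`` (normalized internally) give the probability
    that a new copy derives from each ancestral haplotype. With
    ``exact_proportions`` the copy numbers are the largest-remainder rounding
    of weights x total_copies instead of a multinomial draw — useful when an
    experiment needs exact haplotype counts.
    """

    species: str
    amplification_weights: Sequence[float]
    total_copies: int
    mutation_rate: float = 0.0
    indel_rate: float = 0.0
    max_indel: int = 9
    exact_proportions: bool = False

    def __post_init__(self):
        w = np.asarray(self.amplification_weights, dtype=float)
        if w.size == 0 or (w < 0).any() or not (w > 0).any():
            raise ParameterError("at least one amplification weight must be positive")
        for name in ("mutation_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.total_copies < 0:
            raise ParameterError("total_copies must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        w = np.asarray(self.amplification_weights, dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class SimMonomer:
    """One amplified monomer copy with its true ancestral origin."""

    sequence: str
    ancestral_id: str
    species: str


@dataclass(frozen=True)
class TandemArray:
    """A tandem array plus per-monomer ground truth (offset of each unit)."""

    sequence: str
    monomers: tuple[SimMonomer, ...]
    offsets: tuple[int, ...]

    def ground_truth_rows(self):
        for i, (m, off) in enumerate(zip(self.monomers, self.offsets)):
            yield (f"unit{i:05d}", m.ancestral_id, m.species, off, len(m.sequence))


@dataclass(frozen=True)
class SimReadSet:
    """Simulated paired-end reads with constant-quality Phred strings."""

    pairs: tuple[ReadPair, ...]
    read_length: int
    frag_mean: int
    frag_sd: float
    error_rate: float
    seed: int

    def write_fastq(self, path1, path2, compress: bool = False) -> None:
        opener = (lambda p: gzip.open(p, "wt")) if compress else (lambda p: open(p, "w"))
        with opener(path1) as h1, opener(path2) as h2:
            for p in self.pairs:
                h1.write(f"@{p.id}/1\n{p.mate1}\n+\n{p.qual1}\n")
                h2.write(f"@{p.id}/2\n{p.mate2}\n+\n{p.qual2}\n")


def simulate_library(n_haplotypes: int, unit_length: int = _DEFAULT_UNIT,
                     divergence: float = 0.0, seed: int = 0) -> AncestralLibrary:
    """Draw a root monomer and derive related haplotypes from it.

    The root is uniform over {A,C,G,T}^L; each other haplotype substitutes
    every site independently with probability ``divergence`` (always to a
    different base, so the realized root distance is Binomial(L, divergence)).
    """
    if n_haplotypes < 1:
        raise ParameterError("n_haplotypes must be >= 1")
    if unit_length < 10:
        raise ParameterError("unit_length must be >= 10")
    if not 0.0 <= divergence <= 0.5:
        raise ParameterError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, unit_length, dtype=np.uint8)
    haps = [("hap001", _to_seq(root))]
    for i in range(1, n_haplotypes):
        derived = root.copy()
        mask = rng.random(unit_length) < divergence
        shift = rng.integers(1, 4, unit_length, dtype=np.uint8)
        derived[mask] = (derived[mask] + shift[mask]) % 4
        haps.append((f"hap{i + 1:03d}", _to_seq(derived)))
    return AncestralLibrary(tuple(haps), divergence)


def _exact_counts(weights: np.ndarray, total: int) -> np.ndarray:
    raw = weights * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def amplify_species(library: AncestralLibrary, profile: SpeciesProfile,
                    seed: int = 0) -> list[SimMonomer]:
    """Draw ``total_copies`` monomers from the library and mutate them.

    Copies are sampled according to the profile's amplification weights, then
    each copy independently receives per-site substitutions at
    ``mutation_rate`` and, with probability ``indel_rate``, one 1-9 nt
    insertion or deletion. Labels retain the true ancestral haplotype.
    """
    if len(profile.weights) != len(library):
        raise ParameterError("profile weights length must equal library size")
    rng = np.random.default_rng(seed)
    total = profile.total_copies
    if total == 0:
        return []
    if profile.exact_proportions:
        counts = _exact_counts(profile.weights, total)
    else:
        counts = rng.multinomial(total, profile.weights)

    hap_arrays = [_to_idx(seq) for seq in library.sequences]
    pool: list[SimMonomer] = []
    for hap_i, c in enumerate(counts):
        if c == 0:
            continue
        L = hap_arrays[hap_i].size
        block = np.tile(hap_arrays[hap_i], (c, 1))
        if profile.mutation_rate > 0:
            mask = rng.random(block.shape) < profile.mutation_rate
            shift = rng.integers(1, 4, block.shape, dtype=np.uint8)
            block[mask] = (block[mask] + shift[mask]) % 4
        for row in block:
            seq = _to_seq(row)
            if profile.indel_rate > 0 and rng.random() < profile.indel_rate:
                size = int(rng.integers(1, profile.max_indel + 1))
                pos = int(rng.integers(0, len(seq) + 1))
                if rng.random() < 0.5:
                    ins = _to_seq(rng.integers(0, 4, size, dtype=np.uint8))
                    seq = seq[:pos] + ins + seq[pos:]
                elif len(seq) > size:
                    seq = seq[:pos] + seq[pos + size:]
            pool.append(SimMonomer(seq, library.ids[hap_i], profile.species))
    # interleave deterministically so pool order does not group haplotypes
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


def build_tandem_array(pool: Sequence[SimMonomer], seed: int = 0,
                       shuffle: bool = True) -> TandemArray:
    """Concatenate all pool monomers in a (seeded) shuffled order."""
    if not pool:
        raise ParameterError("monomer pool is empty")
    order = np.arange(len(pool))
    if shuffle:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(pool))
    monomers = tuple(pool[i] for i in order)
    offsets = []
    pos = 0
    for m in monomers:
        offsets.append(pos)
        pos += len(m.sequence)
    return TandemArray("".join(m.sequence for m in monomers), monomers, tuple(offsets))


def generate_reads(array: str, n_pairs: int, read_length: int = 101,
                   frag_mean: int = 180, frag_sd: float = 20.0,
                   error_rate: float = 0.0, seed: int = 0,
                   id_prefix: str = "sim", quality_char: str = "F") -> SimReadSet:
    """Sample paired-end reads from a circularized tandem array.

    Fragment start positions are uniform along the array with wrap-around (a
    real array is far longer than the simulated one, so there are no edge
    effects); mate1 is the fragment prefix and mate2 the reverse complement of
    the fragment suffix. Sequencing errors are i.i.d. substitutions at
    ``error_rate``; qualities are constant (default Q37, Phred+33 'F').
    """
    if read_length < 1 or n_pairs < 0:
        raise ParameterError("read_length must be >= 1 and n_pairs >= 0")
    if frag_mean < read_length:
        raise ParameterError("frag_mean must be >= read_length")
    if len(array) < frag_mean:
        raise ParameterError("array shorter than frag_mean")
    rng = np.random.default_rng(seed)
    L = len(array)
    doubled = array + array
    qual = quality_char * read_length
    pairs = []
    starts = rng.integers(0, L, n_pairs)
    lengths = np.clip(np.rint(rng.normal(frag_mean, frag_sd, n_pairs)).astype(int),
                      read_length, L)
    for i in range(n_pairs):
        frag = doubled[starts[i]: starts[i] + lengths[i]]
        m1 = frag[:read_length]
        m2 = revcomp(frag[-read_length:])
        if error_rate > 0:
            m1 = _apply_errors(m1, error_rate, rng)
            m2 = _apply_errors(m2, error_rate, rng)
        pairs.append(ReadPair(f"{id_prefix}{i:07d}", m1, m2, qual, qual))
    return SimReadSet(tuple(pairs), read_length, frag_mean, frag_sd, error_rate, seed)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = _to_idx(seq)
    mask = rng.random(arr.size) < rate
    if mask.any():
        shift = rng.integers(1, 4, arr.size, dtype=np.uint8)
        arr[mask] = (arr[mask] + shift[mask]) % 4
    return _to_seq(arr)


def write_ground_truth_tsv(array: TandemArray, path) -> None:
    """Ground-truth table: monomer id, true ancestral id, species, array offset."""
    with open(path, "w") as out:
        out.write("monomer_id\tancestral_id\tspecies\tarray_offset\tlength\n")
        for row in array.ground_truth_rows():
            out.write("\t".join(str(x) for x in row) + "\n")
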