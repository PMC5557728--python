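"""Population-level diversity statistics for satellite monomers.

Implements the classic estimators on a table of haplotypes with counts:

* haplotype (gene) diversity, unbiased form Hd = n/(n-1) * (1 - sum p_i^2);
* nucleotide diversity pi, the average per-site pairwise difference, with two
  indel policies ("considering indels" counts each maximal indel run as one
  difference; complete deletion drops gapped columns before comparing);
* per-column sequence-logo information content R = 2 - H (bits).

A lightweight anchored star alignment is provided for aligning monomers that
all descend from one consensus; removing the gaps always recovers the inputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from ._align import parse_cigar
from .errors import DataError, ParameterError

_GAP = ord("-")
_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class HapRow:
    haplotype_id: str
    sequence: str
    count: int
    species: str = ""
    origin: str = "illumina"


class HaplotypeTable:
    """Rows of (haplotype, sequence, count, species, origin).

    Sequences are unique within each (species, origin) group; the sample size
    n is the sum of counts and haplotype frequencies are count/n.
    """

    def __init__(self, rows: Sequence[HapRow]):
        rows = list(rows)
        seen = set()
        for r in rows:
            if r.count < 1:
                raise ParameterError("haplotype counts must be >= 1")
            key = (r.species, r.origin, r.sequence)
            if key in seen:
                raise ParameterError("duplicate sequence within a (species, origin) group")
            seen.add(key)
        self.rows = rows

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n(self) -> int:
        return sum(r.count for r in self.rows)

    def counts(self) -> list[int]:
        return [r.count for r in self.rows]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.rows]

    def subset(self, species: str | None = None, origin: str | None = None) -> "HaplotypeTable":
        rows = [r for r in self.rows
                if (species is None or r.species == species)
                and (origin is None or r.origin == origin)]
        return HaplotypeTable(rows)

    def groups(self) -> list[tuple[str, str]]:
        out = []
        for r in self.rows:
            key = (r.species, r.origin)
            if key not in out:
                out.append(key)
        return out

    def merged_with(self, other: "HaplotypeTable") -> "HaplotypeTable":
        return HaplotypeTable(self.rows + other.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.haplotype_id, r.sequence, r.count, r.species, r.origin) for r in self.rows],
            columns=["haplotype_id", "sequence", "count", "species", "origin"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t")
        return cls([HapRow(str(r.haplotype_id), str(r.sequence), int(r.count),
                           str(r.species), str(r.origin))
                    for r in df.itertuples()])


@dataclass(frozen=True)
class DiversityStats:
    """One Table row: N, size range, haplotype count, Hd, pi."""

    species: str
    origin: str
    n: int
    size_min: int
    size_max: int
    hap: int
    hd: float
    pi: float


def align_monomers(sequences: Sequence[str], reference: str | None = None) -> list[str]:
    """Anchored star alignment: every sequence is pairwise-aligned to a common
    anchor (the consensus when given, else the longest input) and the pairwise
    gap patterns are merged into one set of columns.

    All output rows have equal length and removing gaps recovers the inputs
    exactly. This is not a full progressive MSA; it is adequate for monomers
    that are all small perturbations of one repeat consensus.
    """
    sequences = list(sequences)
    if not sequences:
        raise ParameterError("align_monomers requires at least one sequence")
    if len(sequences) == 1 and reference is None:
        return [sequences[0]]
    anchor = reference if reference is not None else max(sequences, key=len)
    La = len(anchor)

    # For each sequence: ins[j] = query chars inserted before anchor column j
    # (j in 0..La), cell[j] = aligned char or '-' at anchor column j.
    profiles = []
    for seq in sequences:
        res = edlib.align(seq, anchor, mode="NW", task="path")
        ins = [""] * (La + 1)
        cell = ["-"] * La
        q = t = 0
        for length, op in parse_cigar(res["cigar"]):
            if op in ("=", "X", "M"):
                for _ in range(length):
                    cell[t] = seq[q]
                    q += 1
                    t += 1
            elif op == "I":
                ins[t] += seq[q: q + length]
                q += length
            elif op == "D":
                t += length
        profiles.append((ins, cell))

    master_ins = [max(len(p[0][j]) for p in profiles) for j in range(La + 1)]
    rows = []
    for ins, cell in profiles:
        parts = []
        for j in range(La):
            parts.append(ins[j] + "-" * (master_ins[j] - len(ins[j])))
            parts.append(cell[j])
        parts.append(ins[La] + "-" * (master_ins[La] - len(ins[La])))
        rows.append("".join(parts))
    return rows


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Nei's unbiased haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    counts = list(counts)
    if not counts or any(c < 1 for c in counts):
        raise ParameterError("all haplotype counts must be >= 1")
    n = sum(counts)
    if n < 2:
        raise ParameterError("haplotype diversity undefined for n < 2")
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1.0 - sum_p2)


def _rows_to_matrix(alignment: Sequence[str]) -> np.ndarray:
    lengths = {len(r) for r in alignment}
    if len(lengths) != 1:
        raise ParameterError("alignment rows must have equal length")
    return np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in alignment])


def _count_runs(mask: np.ndarray) -> int:
    if mask.size == 0:
        return 0
    return int(mask[0]) + int(np.count_nonzero(mask[1:] & ~mask[:-1]))


def pair_differences(row_a: np.ndarray, row_b: np.ndarray) -> tuple[int, int, int]:
    """(substitution differences, indel events, compared sites) for two rows.

    Substitutions are counted where both symbols are in {A,C,G,T}; each
    maximal run of columns gapped in exactly one of the two rows is one indel
    event. Compared sites = both-ACGT columns (Ns are treated as missing).
    """
    ga = row_a == _GAP
    gb = row_b == _GAP
    valid = np.isin(row_a, _ACGT_CODES) & np.isin(row_b, _ACGT_CODES)
    d_sub = int(np.count_nonzero((row_a != row_b) & valid))
    events = _count_runs(ga & ~gb) + _count_runs(gb & ~ga)
    return d_sub, events, int(np.count_nonzero(valid))


def nucleotide_diversity(alignment: Sequence[str], counts: Sequence[int],
                         indel_policy: str = "gap_as_event") -> float:
    """Nucleotide diversity pi over a gapped alignment with haplotype counts.

    pi = sum_{i<j} n_i n_j (d_ij / L_ij) / C(n, 2), i.e. the average per-site
    difference over all C(n,2) sequence pairs with duplicates materialized.
    Under ``complete_deletion`` every column containing a gap is dropped and
    d is the substitution count; under ``gap_as_event`` (the default,
    "considering indels") each maximal single-row gap run adds one difference
    and one compared site.
    """
    if indel_policy not in ("gap_as_event", "complete_deletion"):
        raise ParameterError(f"unknown indel_policy {indel_policy!r}")
    counts = list(counts)
    if len(alignment) != len(counts):
        raise ParameterError("alignment rows and counts must be parallel")
    if any(c < 1 for c in counts):
        raise ParameterError("counts must be >= 1")
    mat = _rows_to_matrix(list(alignment))
    if indel_policy == "complete_deletion":
        keep = ~(mat == _GAP).any(axis=0)
        if not keep.any():
            raise DataError("complete deletion removed every column")
        mat = mat[:, keep]
    n = sum(counts)
    if n < 2:
        return 0.0
    num = 0.0
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            d_sub, events, L_valid = pair_differences(mat[i], mat[j])
            if indel_policy == "gap_as_event":
                d = d_sub + events
                L = L_valid + events
            else:
                d = d_sub
                L = L_valid
            if L == 0:
                raise DataError("a sequence pair shares no comparable sites")
            num += counts[i] * counts[j] * (d / L)
    return num / (n * (n - 1) / 2)


def logo_matrix(alignment: Sequence[str], counts: Sequence[int] | None = None) -> pd.DataFrame:
    """Count-weighted per-column base frequencies and information content.

    Columns: fA fC fG fT fgap H_bits R_bits. H is the Shannon entropy of the
    non-gap base distribution and R = 2 - H; an all-gap column has no defined
    information content and is emitted as NaN. Ns are ignored entirely.
    """
    if not alignment:
        raise ParameterError("logo_matrix requires a non-empty alignment")
    if counts is None:
        counts = [1] * len(alignment)
    mat = _rows_to_matrix(list(alignment))
    w = np.asarray(list(counts), dtype=float)
    records = []
    for col in range(mat.shape[1]):
        column = mat[:, col]
        tot = {}
        for sym, code in (("A", ord("A")), ("C", ord("C")), ("G", ord("G")),
                          ("T", ord("T")), ("-", _GAP)):
            tot[sym] = float(w[column == code].sum())
        denom = sum(tot.values())
        freqs = {s: (tot[s] / denom if denom else np.nan) for s in tot}
        base_total = sum(tot[s] for s in "ACGT")
        if base_total > 0:
            probs = [tot[s] / base_total for s in "ACGT" if tot[s] > 0]
            H = -sum(p * math.log2(p) for p in probs)
            R = 2.0 - H
        else:
            H = np.nan
            R = np.nan
        records.append((col, freqs["A"], freqs["C"], freqs["G"], freqs["T"],
                        freqs["-"], H, R))
    return pd.DataFrame(records,
                        columns=["column", "fA", "fC", "fG", "fT", "fgap",
                                 "H_bits", "R_bits"])


def summarize(table: HaplotypeTable, alignment: Sequence[str] | None = None,
              reference: str | None = None,
              indel_policy: str = "gap_as_event") -> DiversityStats:
    """Produce one diversity-summary row for a (species, origin) table."""
    if len(table) == 0:
        raise DataError("cannot summarize an empty haplotype table")
    groups = table.groups()
    species = groups[0][0] if len({g[0] for g in groups}) == 1 else "pooled"
    origin = groups[0][1] if len({g[1] for g in groups}) == 1 else "mixed"
    seqs = table.sequences()
    counts = table.counts()
    if alignment is None:
        alignment = align_monomers(seqs, reference=reference)
    sizes = [len(s) for s in seqs]
    n = table.n
    hd = 0.0 if len(seqs) == 1 else haplotype_diversity(counts)
    pi = nucleotide_diversity(alignment, counts, indel_policy=indel_policy)
    return DiversityStats(species, origin, n, min(sizes), max(sizes),
                          len(seqs), hd, pi)


def stats_frame(stats: Sequence[DiversityStats]) -> pd.DataFrame:
    """TSV-ready frame mirroring the N / Size / Hap / Hd / pi table layout."""
    return pd.DataFrame(
        [(s.species, s.origin, s.n, s.size_min, s.size_max, s.hap,
          round(s.hd, 4), round(s.pi, 4)) for s in stats],
        columns=["species", "origin", "N", "size_min", "size_max", "Hap", "Hd", "pi"])
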