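"""Monomer extraction against a satellite consensus, plus in-silico PCR.

Tandem-repeat co-ordinates are circular: a merged read may start anywhere
within a repeat unit, so all alignment here is done against a consensus
repeated enough times to cover the read (the "doubled consensus" idea), and
every extracted unit is rotated to a canonical phase before counting.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import SeqIO

from ._align import edit_distance, parse_cigar, revcomp
from .errors import DataError, ParameterError

DEFAULT_EXTRACT_IDENTITY = 0.60
DEFAULT_LENGTH_TOL = 0.10

_IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGTN"),
}


@dataclass(frozen=True)
class SatConsensus:
    """A named satellite family consensus (e.g. MsaSat01-177, 177 nt unit)."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ParameterError("consensus sequence must be non-empty")

    @property
    def unit_length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path) -> "SatConsensus":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise DataError(f"no sequences in consensus FASTA {path}")
        return cls(records[0].id, str(records[0].seq).upper())

    def to_fasta(self, path) -> None:
        with open(path, "w") as out:
            out.write(f">{self.name}\n{self.sequence}\n")


@dataclass(frozen=True)
class Monomer:
    """One full-length repeat unit in canonical rotation."""

    sequence: str
    source_id: str
    species: str = ""
    origin: str = "illumina"  # or "pcr"

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """Degenerate PCR primer pair (IUPAC symbols allowed)."""

    forward: str
    reverse: str
    max_mismatches: int = 0

    def __post_init__(self):
        for primer in (self.forward, self.reverse):
            if not primer:
                raise ParameterError("primers must be non-empty")
            bad = set(primer.upper()) - set(_IUPAC)
            if bad:
                raise ParameterError(f"malformed IUPAC symbols in primer: {sorted(bad)}")


def canonical_rotation(monomer: str, consensus: SatConsensus) -> str:
    """Rotate a monomer to the phase that best matches the consensus.

    All rotations are scored by global edit distance to the consensus; the
    minimum wins, with ties broken by the lexicographically smallest rotation
    string (which makes the result invariant to the input's rotation and the
    operation idempotent).
    """
    if not monomer:
        raise ParameterError("monomer must be non-empty")
    doubled = monomer + monomer
    L = len(monomer)
    best_key = None
    best = monomer
    for k in range(L):
        rot = doubled[k: k + L]
        d = edlib.align(rot, consensus.sequence, mode="NW")["editDistance"]
        key = (d, rot)
        if best_key is None or key < best_key:
            best_key = key
            best = rot
    return best


def _gapless_phase(read: str, consensus: SatConsensus) -> tuple[int, int]:
    """(cost, phase) of the best gapless tiling of the read onto the consensus.

    Phase r means read position i sits at consensus position (r + i) mod unit;
    the cost is the Hamming distance to that tiling. Ties resolve to the
    smallest phase.
    """
    unit = consensus.unit_length
    L = len(read)
    reps = consensus.sequence * (L // unit + 2)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    ref = np.frombuffer(reps.encode(), dtype=np.uint8)
    best_cost, best_r = L + 1, 0
    for r in range(unit):
        cost = int(np.count_nonzero(read_arr != ref[r: r + L]))
        if cost < best_cost:
            best_cost, best_r = cost, r
    return best_cost, best_r


def _origin_positions_gapped(read: str, consensus: SatConsensus) -> list[int] | None:
    """Map consensus unit origins onto read co-ordinates via edlib alignment.

    The read is aligned (semi-globally) against enough consensus copies to
    cover it; returns the read positions that correspond to consensus position
    0 (mod unit length), in increasing order, or None if no alignment exists.
    """
    unit = consensus.unit_length
    n_copies = len(read) // unit + 3
    reference = consensus.sequence * n_copies
    res = edlib.align(read, reference, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    t = res["locations"][0][0]
    q = 0
    origins = []

    def check(tpos, qpos):
        if tpos % unit == 0:
            origins.append(qpos)

    check(t, q)
    for length, op in parse_cigar(res["cigar"]):
        if op in ("=", "X", "M"):
            for _ in range(length):
                q += 1
                t += 1
                check(t, q)
        elif op == "I":  # read base with no consensus partner
            q += length
        elif op == "D":  # consensus base skipped in read
            for _ in range(length):
                t += 1
                check(t, q)
    return origins


def _origin_positions(read: str, consensus: SatConsensus,
                      gapped_distance: int) -> list[int] | None:
    """Read positions of consensus unit origins, preferring a gapless phasing.

    Tandem-repeat boundaries are phase-consistent along an indel-free read, so
    the best gapless tiling is used whenever its cost is close to the optimal
    (gapped) edit distance; a minimum-edit path is only trusted for origin
    placement when the read genuinely contains indels (where gapless tiling
    becomes much more expensive than the gapped alignment).
    """
    unit = consensus.unit_length
    L = len(read)
    cost, phase = _gapless_phase(read, consensus)
    if cost - gapped_distance <= max(4, int(0.02 * L)):
        first = (unit - phase % unit) % unit
        return list(range(first, L + 1, unit))
    return _origin_positions_gapped(read, consensus)


def extract_monomers(merged_seq: str, consensus: SatConsensus,
                     min_identity: float = DEFAULT_EXTRACT_IDENTITY,
                     length_tol: float = DEFAULT_LENGTH_TOL,
                     source_id: str = "", species: str = "",
                     origin: str = "illumina",
                     check_reverse: bool = True) -> list[Monomer]:
    """Cut full repeat units out of a merged read.

    The read is aligned against tandem copies of the consensus; segments
    between consecutive consensus origins are excised, rotated to canonical
    phase, and kept when their length is within ``length_tol`` of the unit
    length and their identity to the consensus (1 - edit distance / unit
    scale) reaches ``min_identity``. Reads spanning less than one full unit
    yield an empty list.
    """
    if not merged_seq:
        return []
    unit = consensus.unit_length
    candidates = [merged_seq]
    if check_reverse:
        candidates.append(revcomp(merged_seq))
    best_seq, best_d = None, None
    for seq in candidates:
        n_copies = len(seq) // unit + 3
        d = edlib.align(seq, consensus.sequence * n_copies, mode="HW")["editDistance"]
        if d >= 0 and (best_d is None or d < best_d):
            best_seq, best_d = seq, d
    if best_seq is None:
        return []

    origins = _origin_positions(best_seq, consensus, best_d)
    if origins is None or len(origins) < 2:
        return []
    lo = unit * (1 - length_tol)
    hi = unit * (1 + length_tol)
    out = []
    for q0, q1 in zip(origins, origins[1:]):
        seg = best_seq[q0:q1]
        if not lo <= len(seg) <= hi:
            continue
        canon = canonical_rotation(seg, consensus)
        ident = 1.0 - edit_distance(canon, consensus.sequence) / max(len(canon), unit)
        if ident >= min_identity:
            out.append(Monomer(canon, source_id, species, origin))
    return out


def tally_and_filter_singletons(monomers: Sequence[Monomer],
                                apply_filter: bool = True):
    """Collapse identical monomer sequences into a haplotype table.

    With ``apply_filter``, haplotypes observed exactly once are discarded —
    but only for Illumina-derived monomers; PCR clones are kept regardless
    (most sequenced clones are legitimately unique).
    """
    from .popstats import HaplotypeTable, HapRow

    counts: Counter = Counter()
    for m in monomers:
        counts[(m.species, m.origin, m.sequence)] += 1
    rows = []
    per_group_index: Counter = Counter()
    for (species, origin, seq), c in sorted(
            counts.items(), key=lambda kv: (kv[0][0], kv[0][1], -kv[1], kv[0][2])):
        if apply_filter and origin == "illumina" and c == 1:
            continue
        per_group_index[(species, origin)] += 1
        i = per_group_index[(species, origin)]
        hap_id = f"{species or 'sample'}|{origin}|h{i:04d}"
        rows.append(HapRow(hap_id, seq, c, species, origin))
    return HaplotypeTable(rows)


def _primer_sites(template: str, primer: str, max_mm: int) -> list[int]:
    primer = primer.upper()
    lp = len(primer)
    sets = [_IUPAC[c] for c in primer]
    sites = []
    for i in range(len(template) - lp + 1):
        mism = 0
        for c, allowed in zip(template[i: i + lp], sets):
            if c not in allowed:
                mism += 1
                if mism > max_mm:
                    break
        if mism <= max_mm:
            sites.append(i)
    return sites


def in_silico_pcr(template: str, primers: PrimerPair,
                  product_range: tuple[int, int] = (40, 3000)) -> list[tuple[int, int, int]]:
    """Predict PCR products on a template with degenerate primers.

    Forward sites are matched on the plus strand, reverse sites as the reverse
    complement of the reverse primer on the plus strand, both allowing up to
    ``max_mismatches`` under IUPAC semantics (R = A/G, Y = C/T, N = any).
    Returns (start, end, length) for every product whose length falls within
    ``product_range``; on a tandem array this forms the ladder pattern of
    monomer, dimer, trimer ... products.
    """
    template = template.upper()
    lo, hi = product_range
    fwd_sites = _primer_sites(template, primers.forward, primers.max_mismatches)
    rc_rev = revcomp(primers.reverse.upper())
    rev_sites = _primer_sites(template, rc_rev, primers.max_mismatches)
    lr = len(primers.reverse)
    products = []
    for i in fwd_sites:
        for j in rev_sites:
            end = j + lr
            length = end - i
            if lo <= length <= hi:
                products.append((i, end, length))
    return sorted(products)


def read_pcr_clones_fasta(path, consensus: SatConsensus, species: str = "") -> list[Monomer]:
    """Load Sanger-sequenced PCR clone monomers and canonicalize their rotation."""
    monomers = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        monomers.append(Monomer(canonical_rotation(seq, consensus), rec.id,
                                species, origin="pcr"))
    return monomers


def write_monomers_fasta(monomers: Iterable[Monomer], path) -> None:
    with open(path, "w") as out:
        for i, m in enumerate(monomers):
            out.write(f">{m.source_id or f'monomer{i:05d}'}|{m.species}|{m.origin}\n"
                      f"{m.sequence}\n")
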