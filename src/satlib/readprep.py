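"""Read preparation: FASTQ ingestion, subsampling, pair merging, homology selection.

This is the front end of the monomer-mining pipeline: paired-end WGS reads are
(optionally) randomly subsampled, overlapping mates are merged into a single
fragment sequence, and merged reads are screened for homology against the
satellite consensus by local alignment on both strands. Only merged reads
hitting the consensus proceed to monomer extraction.
"""
from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from ._align import best_local_identity, local_aligner, revcomp
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH_FRAC = 0.10
DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_ALIGNED = 50
MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read with Phred(+33) quality strings."""

    id: str
    mate1: str
    mate2: str
    qual1: str
    qual2: str

    def __post_init__(self):
        if len(self.mate1) != len(self.qual1) or len(self.mate2) != len(self.qual2):
            raise ParameterError(f"read {self.id}: sequence/quality length mismatch")

    def n_fraction(self) -> float:
        total = len(self.mate1) + len(self.mate2)
        if total == 0:
            return 0.0
        return (self.mate1.count("N") + self.mate2.count("N")) / total


@dataclass(frozen=True)
class MergedRead:
    """A pair merged through its overlap; mate2 was reverse-complemented."""

    id: str
    sequence: str
    overlap: int
    mismatches: int


@dataclass(frozen=True)
class HomologyHit:
    """Best local-alignment hit of a query against the consensus."""

    query_id: str
    identity: float
    aligned_length: int
    strand: str  # '+' or '-'


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files, in order."""
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        it1 = SeqIO.parse(h1, "fastq")
        it2 = SeqIO.parse(h2, "fastq")
        for rec1, rec2 in zip(it1, it2):
            q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
            q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
            yield ReadPair(rec1.id, str(rec1.seq).upper(), str(rec2.seq).upper(), q1, q2)
        if next(it1, None) is not None or next(it2, None) is not None:
            raise DataError("mate FASTQ files have different numbers of records")


def subsample_pairs(pairs: Iterable[ReadPair], n: int, seed: int) -> list[ReadPair]:
    """Uniform sample of ``n`` pairs without replacement (reservoir algorithm).

    Returns all pairs when ``n`` is at least the stream length; the sample is
    emitted in original stream order and is deterministic under ``seed``.
    """
    if n < 0:
        raise ParameterError("subsample size must be non-negative")
    rng = np.random.default_rng(seed)
    reservoir: list[tuple[int, ReadPair]] = []
    for t, pair in enumerate(pairs):
        if t < n:
            reservoir.append((t, pair))
        else:
            j = int(rng.random() * (t + 1))
            if j < n:
                reservoir[j] = (t, pair)
    reservoir.sort(key=lambda item: item[0])
    return [pair for _, pair in reservoir]


def merge_pair(pair: ReadPair, min_overlap: int = DEFAULT_MIN_OVERLAP,
               max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC) -> MergedRead | None:
    """Merge mates through their best overlap, or return None when irreconcilable.

    Mate2 is reverse-complemented; every overlap length >= ``min_overlap`` is
    scored and the one minimising the mismatch fraction wins (ties go to the
    longest overlap). The merge is rejected when the best mismatch fraction
    exceeds ``max_mismatch_frac``, or when the pair carries more than 10% Ns.
    Mismatched overlap bases resolve to the higher-quality base (ties: mate1).
    An ``N`` never counts as agreeing with anything.
    """
    if min_overlap < 1:
        raise ParameterError("min_overlap must be >= 1")
    if not pair.mate1 or not pair.mate2:
        raise ParameterError(f"read {pair.id}: empty mate sequence")
    if pair.n_fraction() > MAX_N_FRACTION:
        return None

    m1 = pair.mate1
    m2 = revcomp(pair.mate2)
    q1 = pair.qual1
    q2 = pair.qual2[::-1]

    a = np.frombuffer(m1.encode(), dtype=np.uint8)
    b = np.frombuffer(m2.encode(), dtype=np.uint8)
    n_code = ord("N")
    max_o = min(len(m1), len(m2))
    if max_o < min_overlap:
        return None

    best = None  # (mismatch_frac, -overlap, mismatches)
    for o in range(min_overlap, max_o + 1):
        sa = a[len(a) - o:]
        sb = b[:o]
        mism = int(np.count_nonzero((sa != sb) | (sa == n_code) | (sb == n_code)))
        key = (mism / o, -o)
        if best is None or key < best[:2]:
            best = (mism / o, -o, mism)
    frac, neg_o, mismatches = best
    if frac > max_mismatch_frac:
        return None
    o = -neg_o

    head = m1[: len(m1) - o]
    tail = m2[o:]
    ov1 = m1[len(m1) - o:]
    ov2 = m2[:o]
    qo1 = q1[len(m1) - o:]
    qo2 = q2[:o]
    resolved = [
        c1 if c1 == c2 or qo1[i] >= qo2[i] else c2
        for i, (c1, c2) in enumerate(zip(ov1, ov2))
    ]
    merged = head + "".join(resolved) + tail
    return MergedRead(pair.id, merged, o, mismatches)


def select_homologous(queries: Sequence[tuple[str, str]], consensus,
                      min_identity: float = DEFAULT_MIN_IDENTITY,
                      min_aligned: int = DEFAULT_MIN_ALIGNED) -> list[HomologyHit]:
    """Screen (id, sequence) queries against the satellite consensus.

    Each query is locally aligned against the doubled consensus (circular
    tandem co-ordinates) on both strands; a hit requires identity >=
    ``min_identity`` over >= ``min_aligned`` alignment columns. Queries shorter
    than ``min_aligned`` are skipped with a warning.
    """
    if not consensus.sequence:
        raise ParameterError("consensus sequence is empty")
    target = consensus.sequence * 2
    aligner = local_aligner()
    hits = []
    for qid, seq in queries:
        if len(seq) < min_aligned:
            warnings.warn(f"query {qid} shorter than min_aligned={min_aligned}; skipped")
            continue
        best_hit = None
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            identity, cols = best_local_identity(q, target, aligner)
            if cols >= min_aligned and identity >= min_identity:
                if best_hit is None or identity > best_hit.identity:
                    best_hit = HomologyHit(qid, identity, cols, strand)
        if best_hit is not None:
            hits.append(best_hit)
    return hits


def write_merged_fasta(merged: Iterable[MergedRead], path) -> None:
    with open(path, "w") as out:
        for m in merged:
            out.write(f">{m.id} overlap={m.overlap} mismatches={m.mismatches}\n{m.sequence}\n")


def write_hits_tsv(hits: Iterable[HomologyHit], path) -> None:
    with open(path, "w") as out:
        out.write("id\tidentity\tstrand\taligned_length\n")
        for h in hits:
            out.write(f"{h.query_id}\t{h.identity:.4f}\t{h.strand}\t{h.aligned_length}\n")
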