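"""Shared pairwise-alignment helpers.

Two backends are used deliberately:

* :class:`Bio.Align.PairwiseAligner` for scored alignments where the scoring
  scheme matters (local homology search: match +1, mismatch -1, gap open -2,
  gap extend -1; global identity for clustering), and
* ``edlib`` for unit-cost (Levenshtein) alignments where only the edit
  distance and the co-ordinate mapping matter (rotation search, monomer
  extraction, star-MSA pairwise step) — it is orders of magnitude faster.

Identity is always matches / alignment columns, where gap columns count and
``N`` never counts as a match.
"""
from __future__ import annotations

import re

import edlib
import numpy as np
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

_ACGT = frozenset(b"ACGT")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def local_aligner() -> Align.PairwiseAligner:
    """Local aligner with the package's standard scoring (+1/-1, gaps -2/-1)."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -1.0
    return a


def global_aligner() -> Align.PairwiseAligner:
    """Global aligner with the same scoring; used for cluster identities."""
    a = local_aligner()
    a.mode = "global"
    return a


def _identity_from_rows(row_a: str, row_b: str) -> tuple[float, int]:
    """(identity, columns) from two gapped alignment rows.

    Matches require equal symbols that are both in {A,C,G,T}; gaps and Ns
    count as columns but never as matches.
    """
    a = np.frombuffer(row_a.encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.encode(), dtype=np.uint8)
    cols = a.size
    if cols == 0:
        return 0.0, 0
    is_acgt = np.isin(a, list(_ACGT)) & np.isin(b, list(_ACGT))
    matches = int(np.count_nonzero((a == b) & is_acgt))
    return matches / cols, cols


def best_local_identity(query: str, target: str,
                        aligner: Align.PairwiseAligner) -> tuple[float, int]:
    """Identity and column count of the best-scoring local alignment.

    Returns (0.0, 0) when no alignment with positive score exists.
    """
    if not query or not target:
        return 0.0, 0
    alns = aligner.align(query, target)
    if alns.score <= 0:
        return 0.0, 0
    aln = alns[0]
    return _identity_from_rows(aln[0], aln[1])


def global_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    """Identity (matches / columns) of a global pairwise alignment."""
    if a == b:
        return 1.0
    aln = aligner.align(a, b)[0]
    return _identity_from_rows(aln[0], aln[1])[0]


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (edlib, global mode)."""
    return edlib.align(a, b, mode="NW")["editDistance"]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse an edlib extended CIGAR into (length, op) pairs.

    Ops: '=' match, 'X' substitution, 'I' consumes query only,
    'D' consumes target only (edlib convention: query is the first argument).
    """
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
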