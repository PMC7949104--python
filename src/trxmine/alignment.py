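"""Global pairwise protein alignment helpers.

A single PairwiseAligner configuration is shared by the redundancy filter
and the tree-building distance matrix: match = 1, mismatch = 0, linear gap
penalty of -0.5 per gap position.  With this scoring the optimal global
alignment maximises the number of identical aligned residues minus a small
gap cost, which is the quantity the downstream identity and p-distance
definitions need.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -0.5
_aligner.extend_gap_score = -0.5


@lru_cache(maxsize=65536)
def align_stats(a: str, b: str) -> tuple[int, int]:
    """Return (identical aligned positions, alignment length) for two sequences."""
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities, aln.length


def fraction_identity(a: str, b: str) -> float:
    """Identity as exact matches over the length of the shorter sequence.

    This is the CD-HIT-style denominator used by the redundancy filter.
    """
    ident, _ = align_stats(a, b)
    return ident / min(len(a), len(b))


def p_distance(a: str, b: str) -> float:
    """1 - (identical aligned positions / aligned length), gaps included."""
    ident, length = align_stats(a, b)
    return 1.0 - ident / length
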