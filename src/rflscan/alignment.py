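"""Pairwise protein alignment utilities shared across modules.

Thin wrappers around Biopython's PairwiseAligner providing the two identity
notions the pipeline needs: global identity (panel assignment) and
CD-HIT-style local identity with coverage of the shorter sequence
(orthogroup clustering, ``-G 0 -aS`` semantics). Identity is identical
columns divided by alignment columns (gap columns included).
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def _identity_from_alignment(aln) -> tuple[float, int]:
    counts = aln.counts()
    ncols = aln.length
    return (counts.identities / ncols if ncols else 0.0), ncols


def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the best global alignment."""
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner("global").align(a, b)[0]
    ident, _ = _identity_from_alignment(aln)
    return ident


def local_identity_coverage(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage_of_shorter) of the best local alignment.

    Identity: identical columns / local alignment columns. Coverage: span
    of the alignment on the shorter sequence / shorter sequence length.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner("local").align(a, b)[0]
    ident, _ = _identity_from_alignment(aln)
    coords = aln.coordinates
    span_a = coords[0, -1] - coords[0, 0]
    span_b = coords[1, -1] - coords[1, 0]
    short_len = min(len(a), len(b))
    span_short = span_a if len(a) <= len(b) else span_b
    return ident, span_short / short_len
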