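"""Progressive protein alignment and codon back-translation.

The aligner is a deterministic progressive profile-profile aligner: a
UPGMA guide tree on k-mer distances, then affine-gap Needleman-Wunsch
between column profiles scored with expected BLOSUM62. It targets the
highly similar orthogroup members this pipeline aligns, not remote
homology. Back-translation expands each aligned residue to its source
codon; columns containing a gap or an ambiguous codon are excluded from
model fitting (their count is kept so downstream site indices can be
mapped back to alignment columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from ..genome_scan import translate_dna
from .codon import encode_codon

__all__ = ["CodonAlignment", "progressive_msa", "backtranslate"]

_B62 = substitution_matrices.load("BLOSUM62")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(_AA20)}
_SCORE = np.zeros((20, 20))
for _i, _a in enumerate(_AA20):
    for _j, _b in enumerate(_AA20):
        _SCORE[_i, _j] = _B62[_a, _b]

_GAP_OPEN = 10.0
_GAP_EXTEND = 0.5


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile(rows: list[str]) -> np.ndarray:
    """(ncols, 20) normalised residue frequencies; gaps excluded."""
    ncols = len(rows[0])
    counts = np.zeros((ncols, 20))
    for r in rows:
        for i, ch in enumerate(r):
            j = _AA_IDX.get(ch)
            if j is not None:
                counts[i, j] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return counts / totals


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global affine alignment of two alignments; returns the two row sets
    with gap columns inserted. Deterministic tie-break: diagonal, then gap
    in B, then gap in A."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    sub = pa @ _SCORE @ pb.T  # (na, nb) expected column score
    na, nb = sub.shape
    neg = -1e30
    m = np.full((na + 1, nb + 1), neg)
    ix = np.full((na + 1, nb + 1), neg)  # gap in B (consume A)
    iy = np.full((na + 1, nb + 1), neg)  # gap in A (consume B)
    m[0, 0] = 0.0
    for i in range(1, na + 1):
        ix[i, 0] = -_GAP_OPEN - (i - 1) * _GAP_EXTEND
    for j in range(1, nb + 1):
        iy[0, j] = -_GAP_OPEN - (j - 1) * _GAP_EXTEND
    for i in range(1, na + 1):
        srow = sub[i - 1]
        for j in range(1, nb + 1):
            best = max(m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1])
            m[i, j] = best + srow[j - 1]
            ix[i, j] = max(m[i - 1, j] - _GAP_OPEN, ix[i - 1, j] - _GAP_EXTEND)
            iy[i, j] = max(m[i, j - 1] - _GAP_OPEN, iy[i, j - 1] - _GAP_EXTEND)
    # traceback
    i, j = na, nb
    state = int(np.argmax([m[i, j], ix[i, j], iy[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("M")
            prev = [m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1]]
            target = m[i, j] - sub[i - 1, j - 1]
            state = int(np.argmax(np.isclose(prev, target, atol=1e-9)))
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("X")
            state = 0 if np.isclose(ix[i, j], m[i - 1, j] - _GAP_OPEN, atol=1e-9) else 1
            i -= 1
        else:
            ops.append("Y")
            state = 0 if np.isclose(iy[i, j], m[i, j - 1] - _GAP_OPEN, atol=1e-9) else 2
            j -= 1
        if i == 0 and state == 1:
            state = 1 if j == 0 else state
        if i == 0 and j > 0 and state == 0:
            state = 2
        if j == 0 and i > 0 and state == 0:
            state = 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ai = bi = 0
    for op in ops:
        if op in "MX":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ai]
            ai += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
        if op in "MY":
            for r, row in enumerate(rows_b):
                out_b[r] += row[bi]
            bi += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += "-"
    return out_a, out_b


def progressive_msa(proteins: dict[str, str]) -> dict[str, str]:
    """Deterministic progressive multiple alignment.

    A single sequence aligns to itself; two or more are merged following a
    UPGMA guide tree built from 3-mer distances.
    """
    if not proteins:
        raise ValueError("no sequences to align")
    ids = list(proteins)
    seqs = [proteins[i].upper() for i in ids]
    if any(not s for s in seqs):
        raise ValueError("empty sequence in alignment input")
    if len(ids) == 1:
        return {ids[0]: seqs[0]}
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i], seqs[j])
    z = linkage(squareform(d, checks=False), method="average")
    root, nodes = to_tree(z, rd=True)

    def merge(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            return [node.id], [seqs[node.id]]
        il, rl = merge(node.left)
        ir, rr = merge(node.right)
        al, ar = _align_profiles(rl, rr)
        return il + ir, al + ar

    order, rows = merge(root)
    return {ids[k]: row for k, row in zip(order, rows)}


@dataclass
class CodonAlignment:
    """Codon-level alignment with bookkeeping for column cleaning.

    ``columns`` holds every aligned codon column (triplet strings, '---'
    for protein gaps); ``kept`` flags the columns retained for model
    fitting (no gaps, no stops, no ambiguity). Integer codon codes for the
    kept columns are exposed via :meth:`codes`.
    """

    taxa: list[str]
    columns: list[tuple[str, ...]]  # per column: one triplet per taxon
    protein_alignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.kept = np.array(
            [all(encode_codon(c) >= 0 for c in col) for col in self.columns],
            dtype=bool,
        )

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_codons(self) -> int:
        """Number of codon columns retained for fitting."""
        return int(self.kept.sum())

    @property
    def n_removed(self) -> int:
        return self.n_columns - self.n_codons

    @property
    def kept_columns(self) -> np.ndarray:
        return np.flatnonzero(self.kept)

    def codes(self) -> np.ndarray:
        """(n_taxa, n_codons) sense-codon indices of the kept columns."""
        cols = self.kept_columns
        out = np.empty((len(self.taxa), len(cols)), dtype=int)
        for t in range(len(self.taxa)):
            out[t] = [encode_codon(self.columns[c][t]) for c in cols]
        return out

    def sequences(self, include_removed: bool = True) -> dict[str, str]:
        cols = range(self.n_columns) if include_removed else self.kept_columns
        return {
            taxon: "".join(self.columns[c][t] for c in cols)
            for t, taxon in enumerate(self.taxa)
        }


def backtranslate(msa: dict[str, str], cds_by_taxon: dict[str, str]) -> CodonAlignment:
    """Expand a protein alignment to codons using each taxon's CDS.

    Every CDS must translate exactly to its ungapped protein row (standard
    code); mismatches raise with the taxon and residue position named.
    """
    taxa = list(msa)
    missing = [t for t in taxa if t not in cds_by_taxon]
    if missing:
        raise ValueError(f"no CDS for taxa: {missing}")
    ncols = len(next(iter(msa.values())))
    codon_rows: dict[str, list[str]] = {}
    for t in taxa:
        row = msa[t].upper()
        if len(row) != ncols:
            raise ValueError("protein alignment rows differ in length")
        protein = row.replace("-", "")
        cds = cds_by_taxon[t].upper()
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"CDS length for {t!r} is {len(cds)} nt, expected {3 * len(protein)}"
            )
        trans = translate_dna(cds)
        for pos, (x, y) in enumerate(zip(trans, protein), start=1):
            if x == "*":
                raise ValueError(f"internal stop codon in CDS of {t!r} at residue {pos}")
            if x != y and x != "X" and y != "X":
                raise ValueError(
                    f"CDS/protein mismatch for {t!r} at residue {pos}: {x} vs {y}"
                )
        codons = [cds[3 * k : 3 * k + 3] for k in range(len(protein))]
        out, k = [], 0
        for ch in row:
            if ch == "-":
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        codon_rows[t] = out
    columns = [tuple(codon_rows[t][c] for t in taxa) for c in range(ncols)]
    return CodonAlignment(taxa, columns, dict(msa))
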