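"""POG eligibility filtering and motif-position selection profiles.

The per-motif profile answers the question the site models alone cannot:
*where inside the 35-aa repeat* does diversifying selection act. Each
analysed codon column is mapped onto a residue of a reference member (the
longest full-length sequence), that residue onto its 1-35 offset within an
annotated motif, and positive-selection posteriors are averaged per offset,
separately for genes organised in genomic clusters and for singlets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..motif_model import MotifHit
from .msa import CodonAlignment

__all__ = [
    "filter_pogs_for_selection",
    "map_sites_to_reference",
    "motif_position_profile",
    "MOTIF_LENGTH",
]

MOTIF_LENGTH = 35

MIN_ACCESSIONS = 4  # strictly more than this many accessions required
MIN_LENGTH_AA = 400  # strictly longer than this many residues required


def filter_pogs_for_selection(
    pogs,
    seq_lengths: dict[str, int],
    *,
    min_accessions: int = MIN_ACCESSIONS,
    min_length_aa: int = MIN_LENGTH_AA,
):
    """Orthogroups eligible for codon-model analysis.

    Keeps POGs with members from strictly more than ``min_accessions``
    accessions; within each, keeps member sequences strictly longer than
    ``min_length_aa`` residues. Returns (pog, retained member ids) pairs.
    """
    eligible = []
    for pog in pogs:
        accessions = {acc for acc, _ in pog.members}
        if len(accessions) <= min_accessions:
            continue
        kept = [
            seq_id
            for _, seq_id in pog.members
            if seq_lengths.get(seq_id, 0) > min_length_aa
        ]
        if len(kept) >= 2:
            eligible.append((pog, kept))
    return eligible


def map_sites_to_reference(aln: CodonAlignment, reference: str) -> np.ndarray:
    """Residue position (1-based) of the reference member for every codon
    column retained in fitting; 0 where the reference has a gap."""
    if reference not in aln.taxa:
        raise ValueError(f"reference {reference!r} not in alignment")
    t = aln.taxa.index(reference)
    residue = 0
    by_column = np.zeros(aln.n_columns, dtype=int)
    for c in range(aln.n_columns):
        codon = aln.columns[c][t]
        if codon != "---":
            residue += 1
            by_column[c] = residue
    return by_column[aln.kept_columns]


@dataclass
class GeneSelectionTrack:
    """Inputs to the motif-position profile for one gene/POG."""

    gene_id: str
    p_positive: np.ndarray  # per retained codon column
    aln: CodonAlignment
    reference: str
    motif_hits: list[MotifHit]  # on the reference protein
    group: str  # "clustered" or "singlet"


def motif_position_profile(
    tracks: list[GeneSelectionTrack],
    motif_length: int = MOTIF_LENGTH,
) -> pd.DataFrame:
    """Mean positive-selection probability at each motif offset (1..35).

    Residues outside annotated motifs are ignored; motifs longer than
    ``motif_length`` contribute only their first ``motif_length`` offsets.
    Genes without motif annotations are skipped with a warning; if none
    remain the profile is undefined and an error is raised.
    Returns a DataFrame indexed by position with one column per group.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    used = 0
    for track in tracks:
        if not track.motif_hits:
            warnings.warn(
                f"gene {track.gene_id!r} has no annotated motifs; skipped",
                stacklevel=2,
            )
            continue
        used += 1
        ref_pos = map_sites_to_reference(track.aln, track.reference)
        if len(ref_pos) != len(track.p_positive):
            raise ValueError(
                f"gene {track.gene_id!r}: posterior length does not match "
                "retained codon columns"
            )
        g = track.group
        if g not in sums:
            sums[g] = np.zeros(motif_length)
            counts[g] = np.zeros(motif_length)
        for pos, p in zip(ref_pos, track.p_positive):
            if pos == 0:
                continue
            for hit in track.motif_hits:
                if hit.start_aa <= pos <= hit.end_aa:
                    offset = pos - hit.start_aa + 1
                    if offset <= motif_length:
                        sums[g][offset - 1] += p
                        counts[g][offset - 1] += 1
                    break
    if used == 0:
        raise ValueError("no genes with annotated motifs")
    data = {}
    for g in sorted(sums):
        with np.errstate(invalid="ignore"):
            data[g] = np.where(counts[g] > 0, sums[g] / np.maximum(counts[g], 1), np.nan)
    return pd.DataFrame(data, index=pd.RangeIndex(1, motif_length + 1, name="position"))
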