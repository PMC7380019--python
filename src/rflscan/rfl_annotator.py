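"""RFL classification and genomic architecture annotation.

A P-class PPR gene model is called restorer-of-fertility-like (RFL) when
two independent tests agree: its nearest neighbour in a labelled reference
panel is an RFL at high enough global identity, and a neighbor-joining
placement of the query into the panel tree falls inside the RFL clade.
Annotated genes are then organised along chromosomes: tandem arrays
(single-linkage with a configurable maximum inter-gene gap) versus
singlets, per-window gene density, and pseudogene flags (no predicted
mitochondrial targeting peptide, or a motif truncated by the ORF
boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import global_identity
from .genome_scan import GenomicInterval
from .motif_model import PprGeneModel

__all__ = [
    "PanelSequence",
    "RflGene",
    "GeneCluster",
    "assign_rfl",
    "predict_mtp",
    "flag_pseudogene",
    "genomic_clusters",
    "gene_density",
    "annotation_table",
    "DEFAULT_MAX_GAP",
    "DEFAULT_IDENTITY_FLOOR",
    "FULL_LENGTH_MIN_MOTIFS",
]

#: clusters in reference genomes span ~2 Mb while singlets sit >=10 Mb
#: apart; 3 Mb separates the two regimes
DEFAULT_MAX_GAP = 3_000_000

#: minimum global identity to the nearest RFL panel member
DEFAULT_IDENTITY_FLOOR = 0.60

#: full-length RFL proteins carry at least this many PPR motifs
FULL_LENGTH_MIN_MOTIFS = 10


@dataclass(frozen=True)
class PanelSequence:
    id: str
    protein: str
    is_rfl: bool


@dataclass
class RflGene:
    """An RFL-classified gene model with its genomic annotation."""

    gene_id: str
    model: PprGeneModel
    interval: GenomicInterval
    protein: str
    is_rfl: bool
    rfl_support: float  # nearest-panel identity (fraction)
    mtp_predicted: str = "unknown"  # {"yes", "no", "unknown"}
    mtp_predictor: str = ""
    pseudogene: bool = False
    cluster_id: str | None = None
    cluster_kind: str | None = None  # {"cluster", "singlet"}

    @property
    def full_length(self) -> bool:
        return self.model.n_motifs >= FULL_LENGTH_MIN_MOTIFS


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[RflGene]
    span: GenomicInterval
    kind: str  # {"cluster", "singlet"}


def predict_mtp(protein: str, n_term: int = 60, threshold: float = 0.15) -> tuple[str, float]:
    """Naive N-terminal mitochondrial targeting peptide heuristic.

    Scores arginine+serine enrichment minus acidic (D/E) content over the
    first ``n_term`` residues. This is a built-in stand-in; calls from a
    dedicated targeting predictor can be supplied instead wherever an
    ``mtp_call`` is accepted.
    """
    head = protein[:n_term].upper()
    if not head:
        return "no", 0.0
    n = len(head)
    score = (head.count("R") + head.count("S")) / n - (
        head.count("D") + head.count("E")
    ) / n
    return ("yes" if score >= threshold else "no"), score


def assign_rfl(
    model_protein: str,
    panel: Sequence[PanelSequence],
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    *,
    check_clade: bool = True,
) -> tuple[bool, float]:
    """RFL call for a P-class protein against a labelled reference panel.

    Two tests must both pass: the nearest panel sequence (by global
    identity) is RFL-labelled with identity >= ``identity_floor``, and an
    NJ placement of the query among the panel sequences falls inside the
    clade spanned by the RFL-labelled leaves. Returns (is_rfl, nearest
    identity).
    """
    if not panel:
        raise ValueError("empty reference panel")
    if not any(p.is_rfl for p in panel):
        raise ValueError("panel contains no RFL-labelled sequences")
    idents = [(global_identity(model_protein, p.protein), p) for p in panel]
    best_ident, best_seq = max(idents, key=lambda x: (x[0], x[1].id))
    if not best_seq.is_rfl or best_ident < identity_floor:
        return False, best_ident
    non_rfl = [p for p in panel if not p.is_rfl]
    if check_clade and non_rfl and len(panel) >= 3:
        if not _query_in_rfl_clade(model_protein, panel):
            return False, best_ident
    return True, best_ident


_PANEL_MSA_CACHE: dict[tuple, dict[str, str]] = {}


def _panel_msa(panel: Sequence[PanelSequence]) -> dict[str, str]:
    from .selection.msa import progressive_msa

    key = tuple((p.id, hash(p.protein)) for p in panel)
    if key not in _PANEL_MSA_CACHE:
        _PANEL_MSA_CACHE[key] = progressive_msa({p.id: p.protein for p in panel})
        if len(_PANEL_MSA_CACHE) > 8:
            _PANEL_MSA_CACHE.pop(next(iter(_PANEL_MSA_CACHE)))
    return _PANEL_MSA_CACHE[key]


def _query_in_rfl_clade(query: str, panel: Sequence[PanelSequence]) -> bool:
    """NJ tree over panel + query; is the query inside the minimal clade
    containing every RFL-labelled panel leaf (rooted at the first non-RFL
    panel sequence)? The panel alignment is cached; the query is merged
    into it by one profile alignment."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    from .selection.msa import _align_profiles
    from .selection.trees import jtt_distance_matrix

    base = _panel_msa(panel)
    ids_panel = list(base)
    rows_panel, rows_query = _align_profiles([base[i] for i in ids_panel], [query])
    msa = {i: r for i, r in zip(ids_panel, rows_panel)}
    msa["__query__"] = rows_query[0]
    ids, d = jtt_distance_matrix(msa)
    tree = nj(DistanceMatrix(d, ids))
    outgroup_id = sorted(p.id for p in panel if not p.is_rfl)[0]
    rooted = tree.root_at(tree.find(outgroup_id).parent)
    rfl_ids = [p.id for p in panel if p.is_rfl]
    non_rfl = {p.id for p in panel if not p.is_rfl}
    # inside the RFL clade == the RFL leaves plus the query still form a
    # group containing no non-RFL leaf
    mrca = rooted.lca(rfl_ids + ["__query__"])
    under = {t.name for t in mrca.tips()}
    return not (under & non_rfl)


def flag_pseudogene(
    model: PprGeneModel,
    mtp_call: str,
    nominal_motif_lengths: dict[str, int] | None = None,
) -> bool:
    """Pseudogene rule: no predicted targeting peptide, or a motif
    truncated by the ORF boundary (a hit shorter than its nominal motif
    length abutting either protein terminus)."""
    if mtp_call == "no":
        return True
    nominal = nominal_motif_lengths or {"P": 35, "L": 36, "S": 31}
    for h in model.hits:
        nom = nominal.get(h.class_label, 35)
        if h.span < nom and (h.end_aa == model.protein_length or h.start_aa == 1):
            return True
    return False


def genomic_clusters(genes: Sequence[RflGene], max_gap: int = DEFAULT_MAX_GAP) -> list[GeneCluster]:
    """Single-linkage grouping of genes along each sequence.

    Consecutive genes whose inter-gene gap is <= ``max_gap`` share a
    cluster; one-member groups are singlets. Ids are deterministic by
    position. Members' ``cluster_id``/``cluster_kind`` fields are set.
    """
    by_seq: dict[str, list[RflGene]] = {}
    for g in genes:
        by_seq.setdefault(g.interval.seq_id, []).append(g)
    out: list[GeneCluster] = []
    for seq_id in sorted(by_seq):
        ordered = sorted(by_seq[seq_id], key=lambda g: (g.interval.start, g.interval.end))
        groups: list[list[RflGene]] = [[ordered[0]]]
        for g in ordered[1:]:
            gap = g.interval.start - groups[-1][-1].interval.end - 1
            if gap <= max_gap:
                groups[-1].append(g)
            else:
                groups.append([g])
        for k, members in enumerate(groups, start=1):
            kind = "cluster" if len(members) > 1 else "singlet"
            cid = f"{seq_id}_{'C' if kind == 'cluster' else 'S'}{k}"
            span = GenomicInterval(
                seq_id,
                members[0].interval.start,
                members[-1].interval.end,
                "+",
            )
            for m in members:
                m.cluster_id = cid
                m.cluster_kind = kind
            out.append(GeneCluster(cid, members, span, kind))
    return out


def gene_density(
    genes: Sequence[RflGene],
    window: int = 2_000_000,
    seq_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Gene-midpoint counts per half-open tiling window along each
    sequence (the 2-Mb density track)."""
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    by_seq: dict[str, list[int]] = {}
    for g in genes:
        mid = (g.interval.start + g.interval.end) // 2
        by_seq.setdefault(g.interval.seq_id, []).append(mid)
    seq_ids = sorted(set(by_seq) | set(seq_lengths or {}))
    for seq_id in seq_ids:
        mids = by_seq.get(seq_id, [])
        length = (seq_lengths or {}).get(seq_id, max(mids, default=0))
        n_windows = max(1, -(-length // window)) if length else 1
        counts = np.zeros(n_windows, dtype=int)
        for m in mids:
            counts[min((m - 1) // window, n_windows - 1)] += 1
        for w, c in enumerate(counts):
            rows.append(
                {
                    "seq_id": seq_id,
                    "window_start": w * window + 1,
                    "window_end": (w + 1) * window,
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows, columns=["seq_id", "window_start", "window_end", "count"])


def write_rfl_gff3(genes: Sequence[RflGene], path: str | Path) -> None:
    """GFF3 of RFL genes with their motif hits as genomic child features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = (
                f"ID={g.gene_id};n_motifs={g.model.n_motifs};"
                f"full_length={str(g.full_length).lower()};"
                f"pseudogene={str(g.pseudogene).lower()}"
            )
            fh.write(
                f"{iv.seq_id}\trflscan\tgene\t{iv.start}\t{iv.end}\t"
                f"{g.model.protein_score:.1f}\t{iv.strand}\t.\t{attrs}\n"
            )
            for k, h in enumerate(sorted(g.model.hits), start=1):
                # protein coordinates -> genomic, strand-aware
                if iv.strand == "+":
                    s = iv.start + 3 * (h.start_aa - 1)
                    e = iv.start + 3 * h.end_aa - 1
                else:
                    e = iv.end - 3 * (h.start_aa - 1)
                    s = iv.end - 3 * h.end_aa + 1
                fh.write(
                    f"{iv.seq_id}\trflscan\tppr_motif\t{s}\t{e}\t"
                    f"{h.score:.1f}\t{iv.strand}\t.\t"
                    f"ID={g.gene_id}.m{k};Parent={g.gene_id};"
                    f"class={h.class_label}\n"
                )


def annotation_table(genes: Sequence[RflGene]) -> pd.DataFrame:
    """Gene-table-style TSV frame: id, location, cluster/singlet, printed
    span (reverse strand high->low), length, motif structure, mTP call and
    pseudogene flag."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "seq_id": g.interval.seq_id,
                "cluster": g.cluster_id or "",
                "kind": g.cluster_kind or "",
                "physical_position": g.interval.render_span(),
                "gene_length_bp": g.interval.length,
                "n_motifs": g.model.n_motifs,
                "motif_structure": g.model.structure_string,
                "full_length": g.full_length,
                "mtp": g.mtp_predicted,
                "pseudogene": g.pseudogene,
                "rfl_support": round(g.rfl_support, 4),
            }
        )
    return pd.DataFrame(rows)
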