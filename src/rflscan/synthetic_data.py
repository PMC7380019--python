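"""Synthetic fixtures: genomes with planted RFL architecture, accession
sequence sets with controlled identity, and codon alignments simulated
under known site-class omega mixtures.

Every simulator is seed-deterministic and emits a machine-readable truth
table so pipeline outputs are always compared against ground truth, never
against captured output. Proteins are sampled from the packaged motif
profiles rather than copied from any organism, so the repository carries
no genomic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_scan import GenomeSequence
from .motif_model import AA_ALPHABET, MotifProfile, load_packaged_profiles
from .rfl_annotator import PanelSequence
from .selection.codon import (
    N_CODONS,
    SENSE_CODONS,
    CODON_AA,
    CodonTransition,
    f3x4_frequencies,
    mean_rate,
)
from .selection.msa import CodonAlignment
from .selection.trees import PhyloTree

__all__ = [
    "GenomeSimConfig",
    "CodonSimConfig",
    "simulate_genome",
    "mutate_family",
    "simulate_codon_alignment",
    "synthetic_rfl_panel",
    "sample_motif_protein",
]

_AA = AA_ALPHABET
# mitochondrial targeting peptides are arginine/serine-rich and acid-poor
_MTP_ALPHABET = "RRRRRSSSSSSLLAATPVGK"


@dataclass
class GenomeSimConfig:
    """Planted-architecture genome simulation.

    ``clusters`` lists (n_genes, intra_gap_nt) tandem arrays per
    chromosome; ``n_singlets`` genes are placed with >= ``singlet_gap``
    spacing from everything else. ``pseudogene_fraction`` of genes are
    made pseudogenes (alternating mTP-less and mid-motif truncated).
    """

    n_chromosomes: int = 1
    chromosome_length: int = 600_000
    clusters: Sequence[tuple[int, int]] = ((3, 10_000),)
    n_singlets: int = 1
    intercluster_gap: int = 150_000
    singlet_gap: int = 150_000
    pseudogene_fraction: float = 0.0
    motif_range: tuple[int, int] = (11, 19)
    mutation_rate: float = 0.05
    seed: int = 0

    @property
    def suggested_max_gap(self) -> int:
        """A cluster gap threshold separating the intra-cluster from the
        inter-feature regime of this layout (annotate with this)."""
        intra = max((g for _, g in self.clusters), default=10_000)
        inter = min(self.intercluster_gap, self.singlet_gap)
        if inter <= 2 * intra:
            raise ValueError("layout gaps do not separate cluster regimes")
        return (2 * intra + inter) // 3


@dataclass
class CodonSimConfig:
    """Codon alignment simulation under a site-class omega mixture."""

    tree: PhyloTree
    kappa: float = 2.0
    site_classes: Sequence[tuple[float, float]] = ((1.0, 0.3),)  # (prop, omega)
    n_codons: int = 300
    position_nt_freqs: np.ndarray | None = None  # 3x4; uniform if None
    seed: int = 0
    site_omega: np.ndarray | None = None  # explicit per-site omega override

    def __post_init__(self):
        if self.site_omega is None:
            total = sum(p for p, _ in self.site_classes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("site class proportions must sum to 1")


def _sample_from_profile(profile: MotifProfile, rng: np.random.Generator,
                         mutation_rate: float) -> str:
    """One motif instance: profile consensus with substitutions drawn from
    the background at the given per-position rate."""
    cons = profile.consensus
    out = list(cons)
    for i in range(len(out)):
        if rng.random() < mutation_rate:
            out[i] = _AA[rng.choice(20, p=profile.background)]
    return "".join(out)


def sample_motif_protein(
    n_motifs: int,
    rng: np.random.Generator,
    *,
    profiles: dict[str, MotifProfile] | None = None,
    mutation_rate: float = 0.05,
    with_mtp: bool = True,
    nterm_len: int = 20,
    cterm_len: int = 10,
    truncate_last_motif_by: int = 0,
) -> tuple[str, int]:
    """A P-class-like protein: optional mTP, linker, tandem P motifs, tail.

    Returns (protein, index of first motif residue, 1-based).
    ``truncate_last_motif_by`` clips the final motif (and drops the tail),
    emulating a gene truncated mid-motif.
    """
    profiles = profiles or load_packaged_profiles()
    p = profiles["P"]
    parts = []
    if with_mtp:
        parts.append("M" + "".join(rng.choice(list(_MTP_ALPHABET), size=39)))
    else:
        parts.append("M")
    # linker kept acidic so the mTP heuristic stays quiet without the mTP
    linker = "".join(rng.choice(list("DEGNQTAVLI"), size=nterm_len))
    parts.append(linker)
    first_motif = sum(len(x) for x in parts) + 1
    for k in range(n_motifs):
        motif = _sample_from_profile(p, rng, mutation_rate)
        if k == n_motifs - 1 and truncate_last_motif_by > 0:
            motif = motif[: len(motif) - truncate_last_motif_by]
        parts.append(motif)
    if truncate_last_motif_by == 0:
        parts.append("".join(rng.choice(list("DEGNQTAVLI"), size=cterm_len)))
    return "".join(parts), first_motif


_SYNONYMOUS: dict[str, list[str]] = {}


def _codons_for(aa: str) -> list[str]:
    if not _SYNONYMOUS:
        for c, a in zip(SENSE_CODONS, CODON_AA):
            _SYNONYMOUS.setdefault(a, []).append(c)
    return _SYNONYMOUS[aa]


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein, synonymous codons drawn uniformly."""
    out = []
    for a in protein.upper():
        choices = _codons_for(a)
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_genome(
    config: GenomeSimConfig,
) -> tuple[list[GenomeSequence], pd.DataFrame]:
    """Chromosomes with planted RFL genes arranged per the cluster/singlet
    spec. Returns (genome sequences, truth table).

    The truth table carries one row per planted gene: chromosome, 1-based
    interval, strand, motif count, planted cluster label, pseudogene flag
    and pseudogene mechanism.
    """
    rng = np.random.default_rng(config.seed)
    profiles = load_packaged_profiles()
    genomes: list[GenomeSequence] = []
    truth_rows: list[dict] = []
    gene_counter = 0
    for chrom_i in range(config.n_chromosomes):
        chrom_id = f"chr{chrom_i + 1}S"
        pos_plan: list[dict] = []

        def plan_gene(cluster_label: str, kind: str):
            nonlocal gene_counter
            gene_counter += 1
            n_motifs = int(rng.integers(config.motif_range[0], config.motif_range[1] + 1))
            is_pseudo = rng.random() < config.pseudogene_fraction
            mech = ""
            trunc = 0
            with_mtp = True
            if is_pseudo:
                mech = "no_mtp" if gene_counter % 2 == 0 else "truncated"
                if mech == "no_mtp":
                    with_mtp = False
                else:
                    trunc = 3
            protein, first_motif = sample_motif_protein(
                n_motifs,
                rng,
                profiles=profiles,
                mutation_rate=config.mutation_rate,
                with_mtp=with_mtp,
                truncate_last_motif_by=trunc,
            )
            cds = reverse_translate(protein, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            return {
                "gene_id": f"SG{gene_counter:03d}",
                "cds": cds,
                "protein": protein,
                "strand": strand,
                "n_motifs": n_motifs,
                "cluster_label": cluster_label,
                "kind": kind,
                "pseudogene": bool(is_pseudo),
                "pseudogene_mechanism": mech,
            }

        for c_i, (n_genes, intra_gap) in enumerate(config.clusters, start=1):
            for g_i in range(n_genes):
                pos_plan.append(
                    {
                        "gene": plan_gene(f"cluster{c_i}", "cluster"),
                        "gap_before": config.intercluster_gap if g_i == 0 else intra_gap,
                    }
                )
        for s_i in range(config.n_singlets):
            pos_plan.append(
                {
                    "gene": plan_gene(f"singlet{s_i + 1}", "singlet"),
                    "gap_before": config.singlet_gap,
                }
            )

        # lay the genes down left to right
        cursor = 0
        dna_parts: list[str] = []
        for item in pos_plan:
            gap = item["gap_before"]
            dna_parts.append(_random_dna(gap, rng))
            cursor += gap
            gene = item["gene"]
            cds = gene["cds"]
            # bracket the CDS with in-frame stop codons on its own strand so
            # the recovered ORF matches the planted interval exactly
            if gene["strand"] == "+":
                insert = "TAA" + cds + "TAA"
                start = cursor + 3 + 1  # 1-based first CDS base
                end = cursor + 3 + len(cds)
            else:
                rc = _revcomp(cds)
                insert = "TTA" + rc + "TTA"
                start = cursor + 3 + 1
                end = cursor + 3 + len(rc)
            dna_parts.append(insert)
            truth_rows.append(
                {
                    "gene_id": gene["gene_id"],
                    "seq_id": chrom_id,
                    "start": start,
                    "end": end,
                    "strand": gene["strand"],
                    "n_motifs": gene["n_motifs"],
                    "cluster_label": gene["cluster_label"],
                    "kind": gene["kind"],
                    "pseudogene": gene["pseudogene"],
                    "pseudogene_mechanism": gene["pseudogene_mechanism"],
                    "protein": gene["protein"],
                }
            )
            cursor += len(insert)
        if cursor + config.singlet_gap > config.chromosome_length:
            raise ValueError(
                "infeasible packing: planted genes exceed chromosome_length"
            )
        dna_parts.append(_random_dna(config.chromosome_length - cursor, rng))
        genomes.append(GenomeSequence(chrom_id, "".join(dna_parts), "synthetic"))
    truth = pd.DataFrame(truth_rows)
    return genomes, truth


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def mutate_family(
    base_protein: str,
    identity_targets: Sequence[float],
    n_per_level: int,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Per-accession variant sets at controlled identity to a base protein.

    For each target t, ``n_per_level`` accessions each receive one variant
    with exactly round((1-t)*L) substituted positions (uniform positions,
    uniform non-identical residues), so realised identity is within 1/L of
    the target. Returns {accession: [(seq_id, protein)]}.
    """
    rng = np.random.default_rng(seed)
    L = len(base_protein)
    out: dict[str, list[tuple[str, str]]] = {}
    import warnings

    for t in identity_targets:
        if not 0 < t <= 1:
            raise ValueError("identity targets must be in (0, 1]")
        if t < 0.5:
            warnings.warn(
                f"identity target {t} below 0.5: alignment-based identity "
                "is unreliable this far out",
                stacklevel=2,
            )
        n_sub = int(round((1.0 - t) * L))
        for k in range(n_per_level):
            s = list(base_protein)
            pos = rng.choice(L, size=n_sub, replace=False)
            for p in pos:
                choices = [a for a in _AA if a != s[p]]
                s[p] = choices[rng.integers(len(choices))]
            acc = f"acc_t{int(round(t * 100)):03d}_{k + 1}"
            out[acc] = [(f"{acc}_seq", "".join(s))]
    return out


def synthetic_rfl_panel(seed: int = 0, n_rfl: int = 4, n_other: int = 3) -> list[PanelSequence]:
    """A labelled reference panel: RFL-like tandem-P proteins plus
    unrelated non-RFL proteins (synthetic stand-ins for a published
    panel)."""
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_rfl):
        protein, _ = sample_motif_protein(14, rng, mutation_rate=0.04)
        panel.append(PanelSequence(f"panelRFL{i + 1:02d}", protein, True))
    for i in range(n_other):
        # editing-factor-like decoys: same length scale, shuffled content
        length = int(rng.integers(400, 600))
        protein = "M" + "".join(np.array(list(_AA))[rng.integers(0, 20, size=length)])
        panel.append(PanelSequence(f"panelOTH{i + 1:02d}", protein, False))
    return panel


def simulate_codon_alignment(
    config: CodonSimConfig,
) -> tuple[CodonAlignment, pd.DataFrame]:
    """Evolve codons down a tree under a GY94 site-class mixture.

    Per site, a class omega is drawn (or taken from ``site_omega``); the
    root codon is drawn from the F3x4 stationary distribution and evolved
    with transition matrices exp(Q(omega) t). Stop codons cannot arise (the
    generator excludes them). Returns (alignment, per-site truth).
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    f = (
        np.full((3, 4), 0.25)
        if config.position_nt_freqs is None
        else np.asarray(config.position_nt_freqs, float)
    )
    pi = f3x4_frequencies(f)
    if config.site_omega is not None:
        site_omega = np.asarray(config.site_omega, float)
        n_sites = len(site_omega)
        site_class = np.full(n_sites, -1)
        omegas = np.unique(site_omega)
        props = np.array([np.mean(site_omega == w) for w in omegas])
    else:
        n_sites = config.n_codons
        props = np.array([p for p, _ in config.site_classes])
        omegas = np.array([w for _, w in config.site_classes])
        site_class = rng.choice(len(omegas), size=n_sites, p=props)
        site_omega = omegas[site_class]
    scale = float(sum(p * mean_rate(config.kappa, w, pi) for p, w in zip(props, omegas)))
    # transition matrices per distinct omega per branch
    trans = {float(w): CodonTransition(config.kappa, float(w), pi, scale) for w in omegas}
    pmats = {
        (float(w), i): trans[float(w)].probability_matrix(tree.blen[i])
        for w in omegas
        for i in range(1, tree.n_nodes)
    }
    states = np.empty((tree.n_nodes, n_sites), dtype=int)
    states[0] = rng.choice(N_CODONS, size=n_sites, p=pi)
    order = tree.postorder()[::-1]  # preorder: parents before children
    for node in order:
        if node == 0:
            continue
        parent_states = states[tree.parent[node]]
        out = np.empty(n_sites, dtype=int)
        for w in omegas:
            sel = site_omega == w
            if not sel.any():
                continue
            p = pmats[(float(w), node)]
            # vectorised categorical draw per site via inverse CDF
            cdf = np.cumsum(p[parent_states[sel]], axis=1)
            u = rng.random(sel.sum())
            out[sel] = np.minimum((u[:, None] > cdf).sum(axis=1), N_CODONS - 1)
        states[node] = out
    leaves = tree.leaves
    taxa = [tree.names[i] for i in leaves]
    columns = [
        tuple(SENSE_CODONS[states[i, h]] for i in leaves) for h in range(n_sites)
    ]
    aln = CodonAlignment(taxa, columns)
    truth = pd.DataFrame(
        {
            "site": np.arange(1, n_sites + 1),
            "omega": site_omega,
            "class_index": site_class,
            "positively_selected": site_omega > 1.0,
        }
    )
    return aln, truth
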