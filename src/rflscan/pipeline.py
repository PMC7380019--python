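"""End-to-end orchestration: scan -> annotate -> orthogroups -> selection.

Every printed threshold of the discovery procedure lives in
:class:`PipelineConfig` (minimum ORF length 93 aa, P/PLS protein-score
thresholds 100/240, >=10 motifs for full-length RFLs, 3-Mb cluster gap,
98/96/93% HCA identity thresholds, >4 accessions and >400 aa for the
selection stage); stage logic never hard-codes them. The config is
serialised alongside every run for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import rfl_annotator
from .genome_scan import GenomeSequence, six_frame_orfs
from .motif_model import (
    DEFAULT_HIT_THRESHOLD,
    MotifProfile,
    chain_and_classify,
    load_packaged_profiles,
    scan_protein,
)
from .pog_cluster import (
    DEFAULT_THRESHOLDS,
    ClusterParams,
    Orthogroup,
    iterative_hca,
    presence_matrix,
)
from .rfl_annotator import (
    DEFAULT_IDENTITY_FLOOR,
    DEFAULT_MAX_GAP,
    FULL_LENGTH_MIN_MOTIFS,
    PanelSequence,
    RflGene,
    annotation_table,
    assign_rfl,
    flag_pseudogene,
    gene_density,
    genomic_clusters,
    predict_mtp,
)

logger = logging.getLogger("rflscan")

__all__ = ["PipelineConfig", "scan_genome", "run_scan_report", "annotate_genome", "run_full"]


@dataclass
class PipelineConfig:
    min_orf_aa: int = 93
    p_score: float = 100.0
    pls_score: float = 240.0
    hit_threshold: float = DEFAULT_HIT_THRESHOLD
    min_motifs: int = FULL_LENGTH_MIN_MOTIFS
    max_gap: int = DEFAULT_MAX_GAP
    rfl_identity_floor: float = DEFAULT_IDENTITY_FLOOR
    hca_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    min_accessions: int = 4  # strictly more than this
    min_len_aa: int = 400  # strictly longer than this
    models: tuple[str, ...] = ("M0", "M1a", "M2a", "M7", "M8")
    run_beb: bool = True
    density_window: int = 2_000_000
    seed: int = 0
    max_pog_members_for_selection: int = 10

    def __post_init__(self):
        for name in (
            "min_orf_aa",
            "p_score",
            "pls_score",
            "min_motifs",
            "max_gap",
            "density_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["hca_thresholds"] = list(d["hca_thresholds"])
        d["models"] = list(d["models"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "hca_thresholds" in d:
            d["hca_thresholds"] = tuple(d["hca_thresholds"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def scan_genome(
    genome: GenomeSequence,
    profiles: dict[str, MotifProfile] | None = None,
    config: PipelineConfig | None = None,
):
    """ORFs and classified PPR gene models for one sequence.

    Returns (orfs, models) with one model per ORF carrying >= 1 motif hit.
    """
    config = config or PipelineConfig()
    profiles = profiles or load_packaged_profiles()
    orfs = six_frame_orfs(genome, config.min_orf_aa)
    thresholds = {"P": config.p_score, "PLS": config.pls_score}
    models = []
    for orf in orfs:
        hits = scan_protein(orf.aa_seq, profiles.values(), config.hit_threshold)
        model = chain_and_classify(
            hits, orf.orf_id, len(orf.aa_seq), thresholds
        )
        if model.hits:
            models.append((orf, model))
    return orfs, models


def run_scan_report(
    genomes: Sequence[GenomeSequence],
    config: PipelineConfig | None = None,
    profiles: dict[str, MotifProfile] | None = None,
    panel: Sequence[PanelSequence] | None = None,
) -> pd.DataFrame:
    """Summary-table counts per genome: total ORFs, ORFs with PPR
    repeats, PLS-class (score > 240), P-class (score > 100), and
    full-length RFLs (>= 10 motifs; RFL-assigned when a panel is given,
    otherwise all full-length P-class models are counted)."""
    config = config or PipelineConfig()
    profiles = profiles or load_packaged_profiles()
    rows = []
    for genome in genomes:
        orfs, models = scan_genome(genome, profiles, config)
        n_pls = sum(1 for _, m in models if m.family_class == "PLS")
        n_p = sum(1 for _, m in models if m.family_class == "P")
        rfl_candidates = [
            (o, m)
            for o, m in models
            if m.family_class == "P" and m.n_motifs >= config.min_motifs
        ]
        if panel:
            n_rfl = 0
            for o, m in rfl_candidates:
                is_rfl, _ = assign_rfl(o.aa_seq, panel, config.rfl_identity_floor)
                n_rfl += int(is_rfl)
        else:
            n_rfl = len(rfl_candidates)
        rows.append(
            {
                "genome": genome.id,
                "n_orfs": len(orfs),
                "n_orfs_with_ppr": len(models),
                f"n_pls_class_gt{config.pls_score:g}": n_pls,
                f"n_p_class_gt{config.p_score:g}": n_p,
                f"n_rfl_ge{config.min_motifs}_motifs": n_rfl,
            }
        )
    return pd.DataFrame(rows)


def orf_length_histogram(
    genomes: Sequence[GenomeSequence],
    config: PipelineConfig | None = None,
    bins: Sequence[int] = (93, 200, 400, 600, 800, 1000, 10_000),
) -> pd.DataFrame:
    """ORF length distribution (histogram bins, aa)."""
    config = config or PipelineConfig()
    lengths = []
    for genome in genomes:
        lengths.extend(len(o.aa_seq) for o in six_frame_orfs(genome, config.min_orf_aa))
    counts, edges = np.histogram(lengths, bins=list(bins))
    return pd.DataFrame(
        {
            "bin_lo_aa": edges[:-1].astype(int),
            "bin_hi_aa": edges[1:].astype(int),
            "count": counts,
        }
    )


def annotate_genome(
    genomes: Sequence[GenomeSequence],
    panel: Sequence[PanelSequence],
    config: PipelineConfig | None = None,
    profiles: dict[str, MotifProfile] | None = None,
    mtp_calls: dict[str, str] | None = None,
    collect_models: list | None = None,
) -> tuple[list[RflGene], list]:
    """Full RFL annotation of a genome set.

    ``mtp_calls`` may supply external targeting predictions keyed by gene
    id; genes not covered fall back to the built-in N-terminal heuristic
    (a warning notes this once). ``collect_models`` (if a list) receives
    every scanned (orf, model) pair. Returns (RFL genes, clusters).
    """
    config = config or PipelineConfig()
    profiles = profiles or load_packaged_profiles()
    genes: list[RflGene] = []
    used_naive = False
    counter = 0
    for genome in genomes:
        _, models = scan_genome(genome, profiles, config)
        if collect_models is not None:
            collect_models.extend(models)
        for orf, model in models:
            if model.family_class != "P":
                continue
            is_rfl, support = assign_rfl(
                orf.aa_seq, panel, config.rfl_identity_floor
            )
            if not is_rfl:
                continue
            counter += 1
            gene_id = f"RFL{counter:03d}"
            if mtp_calls and gene_id in mtp_calls:
                mtp, predictor = mtp_calls[gene_id], "external"
            else:
                mtp, _score = predict_mtp(orf.aa_seq)
                predictor = "nterm-rs-heuristic"
                used_naive = True
            gene = RflGene(
                gene_id=gene_id,
                model=model,
                interval=orf.interval,
                protein=orf.aa_seq,
                is_rfl=True,
                rfl_support=support,
                mtp_predicted=mtp,
                mtp_predictor=predictor,
            )
            gene.pseudogene = flag_pseudogene(model, mtp)
            genes.append(gene)
    if used_naive:
        logger.warning(
            "mitochondrial-targeting calls use the built-in N-terminal "
            "heuristic, not a dedicated predictor"
        )
    clusters = genomic_clusters(genes, config.max_gap)
    return genes, clusters


def run_full(
    out_dir: str | Path,
    genomes: Sequence[GenomeSequence],
    accession_seqs: dict[str, list[tuple[str, str]]],
    accession_cds: dict[str, str] | None = None,
    panel: Sequence[PanelSequence] | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage and write the output bundle.

    Stages: motif scan + RFL annotation of the genomes; HCA orthogrouping
    of the per-accession sequences (reference RFLs included); codon-model
    selection on eligible POGs when CDS sequences are supplied; motif
    position profiles grouped by cluster/singlet architecture.
    Returns a manifest dict (also written as JSON).
    """
    from .selection import (
        GeneSelectionTrack,
        backtranslate,
        beb_site_probs,
        filter_pogs_for_selection,
        fit_model_series,
        lrt,
        motif_position_profile,
        nj_tree,
        progressive_msa,
    )

    t0 = time.time()
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    panel = panel or []
    timings = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.time()

    stage("annotate")
    all_models: list = []
    genes, clusters = annotate_genome(
        genomes, panel, config, collect_models=all_models
    )
    with open(out / "ppr_models.tsv", "w") as fh:
        fh.write("orf_id\tclass\tprotein_score\tn_motifs\tstructure_string\n")
        for _, model in all_models:
            fh.write(
                f"{model.orf_id}\t{model.family_class}\t"
                f"{model.protein_score:.2f}\t{model.n_motifs}\t"
                f"{model.structure_string}\n"
            )
    annotation_table(genes).to_csv(out / "rfl_genes.tsv", sep="\t", index=False)
    rfl_annotator.write_rfl_gff3(genes, out / "rfl_genes.gff3")
    gene_density(genes, config.density_window).to_csv(
        out / "gene_density.tsv", sep="\t", index=False
    )
    with open(out / "clusters.bed", "w") as fh:
        for cl in clusters:
            fh.write(
                f"{cl.span.seq_id}\t{cl.span.start - 1}\t{cl.span.end}\t"
                f"{cl.cluster_id}\t{len(cl.members)}\t.\n"
            )
    timings["annotate"] = time.time() - timings["annotate"]

    stage("pogs")
    seqs_by_acc = dict(accession_seqs)
    if genes:
        seqs_by_acc["reference"] = [(g.gene_id, g.protein) for g in genes]
    pogs = iterative_hca(seqs_by_acc, config.hca_thresholds)
    acc_list = sorted(seqs_by_acc)
    pm = presence_matrix(pogs, acc_list)
    pm.to_csv(out / "pog_presence.tsv", sep="\t")
    with open(out / "pog_members.tsv", "w") as fh:
        fh.write("pog_id\taccession\tseq_id\tidentity_to_rep\n")
        for pog in pogs:
            for acc, sid in pog.members:
                fh.write(
                    f"{pog.pog_id}\t{acc}\t{sid}\t"
                    f"{pog.member_identities.get(sid, 1.0):.4f}\n"
                )
    with open(out / "pog_representatives.fa", "w") as fh:
        for pog in pogs:
            fh.write(f">{pog.pog_id} {pog.representative.id}\n{pog.representative.seq}\n")
    timings["pogs"] = time.time() - timings["pogs"]

    selection_summary = []
    if accession_cds is not None:
        stage("selection")
        all_seqs = {
            sid: seq for pairs in seqs_by_acc.values() for sid, seq in pairs
        }
        lengths = {sid: len(s) for sid, s in all_seqs.items()}
        gene_by_id = {g.gene_id: g for g in genes}
        eligible = filter_pogs_for_selection(
            pogs,
            lengths,
            min_accessions=config.min_accessions,
            min_length_aa=config.min_len_aa,
        )
        for pog, kept in eligible:
            kept = sorted(kept, key=lambda s: -lengths[s])[
                : config.max_pog_members_for_selection
            ]
            cds = {s: accession_cds[s] for s in kept if s in accession_cds}
            if len(cds) < 3:
                continue
            proteins = {s: all_seqs[s] for s in cds}
            msa = progressive_msa(proteins)
            aln = backtranslate(msa, cds)
            if aln.n_codons < 30:
                continue
            tree = nj_tree(msa)
            fits = fit_model_series(aln, tree, config.models)
            row = {"pog_id": pog.pog_id, "n_seqs": len(cds), "n_codons": aln.n_codons}
            if "M0" in fits:
                row["m0_omega"] = fits["M0"].omega
            pog_dir = out / "selection" / pog.pog_id
            pog_dir.mkdir(parents=True, exist_ok=True)
            work_tree = fits["M0"].tree if "M0" in fits else tree
            (pog_dir / "tree.nwk").write_text(work_tree.to_newick() + "\n")
            with open(pog_dir / "fits.tsv", "w") as fh:
                fh.write("model\tlnL\tkappa\tclasses\tconverged\n")
                for name, f in fits.items():
                    classes = ";".join(
                        f"{p:.4f}:{w:.4f}" for p, w in f.omega_classes
                    )
                    fh.write(
                        f"{name}\t{f.lnL:.6f}\t{f.kappa:.4f}\t{classes}\t"
                        f"{f.converged}\n"
                    )
            lrt_rows = []
            for null, alt in (("M1a", "M2a"), ("M7", "M8")):
                if null in fits and alt in fits:
                    r = lrt(fits[null], fits[alt])
                    row[f"lrt_{null}_{alt}_p"] = r.p_value
                    row[f"lrt_{null}_{alt}_stars"] = r.stars()
                    lrt_rows.append(r)
            with open(pog_dir / "lrt.tsv", "w") as fh:
                fh.write("null\talt\tstatistic\tdf\tp_value\tstars\n")
                for r in lrt_rows:
                    fh.write(
                        f"{r.null_model}\t{r.alt_model}\t{r.statistic:.4f}\t"
                        f"{r.df}\t{r.p_value:.6g}\t{r.stars()}\n"
                    )
            if config.run_beb and "M2a" in fits:
                post = beb_site_probs(fits["M2a"], aln)
                with open(pog_dir / "site_posteriors.tsv", "w") as fh:
                    fh.write("site\tp_positive\n")
                    for k, p in enumerate(post.p_positive, start=1):
                        fh.write(f"{k}\t{p:.6f}\n")
            # architecture group via reference members, if any
            ref_ids = [s for _, s in pog.members if s in gene_by_id]
            if ref_ids:
                kinds = {gene_by_id[r].cluster_kind for r in ref_ids}
                row["group"] = "clustered" if "cluster" in kinds else "singlet"
            selection_summary.append(row)
        pd.DataFrame(selection_summary).to_csv(
            out / "selection_summary.tsv", sep="\t", index=False
        )
        timings["selection"] = time.time() - timings["selection"]

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_genomes": len(genomes),
        "n_rfl_genes": len(genes),
        "n_clusters": sum(1 for c in clusters if c.kind == "cluster"),
        "n_singlets": sum(1 for c in clusters if c.kind == "singlet"),
        "n_pogs": len(pogs),
        "n_pogs_selection": len(selection_summary),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
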