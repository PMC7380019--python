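"""RFL annotation: panel assignment, clusters vs singlets, pseudogenes.

Simulates a chromosome with the reference-genome-style layout (three
sub-clusters of 2/8/4 genes plus one singlet, some pseudogenes), then
re-annotates it from raw sequence: ORF scan, motif classification, RFL
assignment against a labelled panel, cluster/singlet architecture and
pseudogene flags.
"""

from rflscan.pipeline import PipelineConfig, annotate_genome
from rflscan.rfl_annotator import annotation_table, gene_density
from rflscan.synthetic_data import GenomeSimConfig, simulate_genome, synthetic_rfl_panel

cfg = GenomeSimConfig(
    seed=5,
    clusters=((2, 10_000), (8, 10_000), (4, 10_000)),
    n_singlets=1,
    chromosome_length=1_000_000,
    pseudogene_fraction=0.2,
)
genomes, truth = simulate_genome(cfg)
panel = synthetic_rfl_panel(seed=5)

genes, clusters = annotate_genome(
    genomes, panel, PipelineConfig(max_gap=cfg.suggested_max_gap)
)
print(f"planted {len(truth)} genes; recovered {len(genes)} RFL genes")
for c in clusters:
    print(f"  {c.cluster_id}: {c.kind} with {len(c.members)} gene(s)")
table = annotation_table(genes)
print(table[["gene_id", "kind", "n_motifs", "motif_structure", "mtp", "pseudogene"]]
      .head(4).to_string(index=False))
density = gene_density(genes, window=100_000)
busy = density[density["count"] > 0]
print(f"windows with genes: {len(busy)} (peak {density['count'].max()} per 100 kb)")
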