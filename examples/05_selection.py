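"""Codon site models, LRT and BEB positive-selection sites.

Simulates a codon alignment on an 8-taxon tree where 10% of sites evolve
under diversifying selection (omega = 4), fits the M0/M1a/M2a site
models, runs the M1a-vs-M2a likelihood ratio test and computes Bayes
Empirical Bayes posterior probabilities that each site belongs to the
omega > 1 class.
"""

import numpy as np

from rflscan.selection import PhyloTree, beb_site_probs, lrt
from rflscan.selection.sitemodels import fit_model_series
from rflscan.synthetic_data import CodonSimConfig, simulate_codon_alignment

tree = PhyloTree.from_newick(
    "(((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05):0.05,"
    "(E:0.1,F:0.1):0.05,(G:0.1,H:0.1):0.05);"
)
config = CodonSimConfig(
    tree=tree,
    kappa=2.0,
    site_classes=((0.6, 0.2), (0.3, 1.0), (0.1, 4.0)),  # (proportion, omega)
    n_codons=400,
    seed=7,
)
aln, truth = simulate_codon_alignment(config)
print(f"simulated {aln.n_codons} codons for {len(aln.taxa)} taxa")

fits = fit_model_series(aln, tree, ("M0", "M1a", "M2a"))
for name, fit in fits.items():
    classes = ", ".join(f"p={p:.2f} w={w:.2f}" for p, w in fit.omega_classes)
    print(f"{name}: lnL={fit.lnL:.2f} kappa={fit.kappa:.2f}  [{classes}]")

result = lrt(fits["M1a"], fits["M2a"])
print(
    f"M1a vs M2a: 2dlnL={result.statistic:.2f}, df={result.df}, "
    f"p={result.p_value:.3g} ({result.stars()})"
)

post = beb_site_probs(fits["M2a"], aln)
sel = truth["positively_selected"].to_numpy()
print(
    f"mean BEB P(omega>1): {post.p_positive[sel].mean():.3f} at truly "
    f"selected sites vs {post.p_positive[~sel].mean():.3f} elsewhere"
)
top = np.argsort(post.p_positive)[-5:][::-1]
print("top sites:", ", ".join(f"{s+1} (p={post.p_positive[s]:.2f})" for s in top))
# M0's single averaged omega hides the selected class; M2a recovers it
# and the LRT rejects the nearly-neutral null.
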