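"""Bayes Empirical Bayes posterior probabilities of positive selection.

Instead of plugging in the MLEs of the site-class mixture (naive empirical
Bayes), the class-proportion and omega hyperparameters are integrated over
a uniform grid: each grid point contributes site posteriors weighted by its
data likelihood. Branch lengths, kappa and the codon frequencies stay fixed
at their MLEs, and each class generator is scaled by the MLE mixture rate so
branch lengths keep their fitted meaning across grid points.

Supported models: M2a (grid over p0, p1, omega0 in (0,1), omega2 in (1,11))
and M8 (grid over p0, beta p and q in (0,2), omega_s in (1,11)). The
default grid has 10 points per dimension; smaller grids are accepted for
quick exploratory runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .msa import CodonAlignment
from .sitemodels import (
    CodonPruner,
    SiteModelFit,
    _beta_category_omegas,
    _class_log_likelihood_table,
)

__all__ = ["SitePosterior", "beb_site_probs"]


@dataclass
class SitePosterior:
    """Per-site class posteriors for a positive-selection model fit."""

    model: str
    class_posteriors: np.ndarray  # (n_sites, n_classes) grid-averaged
    p_positive: np.ndarray  # posterior mass of the omega>1 class per site

    @property
    def n_sites(self) -> int:
        return len(self.p_positive)


def _grid(n: int) -> np.ndarray:
    """Midpoints of n equal bins on (0,1)."""
    return (np.arange(n) + 0.5) / n


def beb_site_probs(
    fit: SiteModelFit,
    aln: CodonAlignment,
    tree=None,
    grid_size: int = 10,
) -> SitePosterior:
    """BEB site posteriors for a fitted M2a or M8 model.

    ``tree`` defaults to the tree carried by the fit (fixed branch
    lengths).
    """
    if fit.model not in ("M2a", "M8"):
        raise ValueError("BEB requires a fitted M2a or M8 model")
    tree = tree if tree is not None else fit.tree
    codes = aln.codes()
    pruner = CodonPruner(codes, aln.taxa, tree)
    pi = fit.codon_freqs
    kappa = fit.kappa
    scale = fit.scale
    blen = tree.blen
    u = _grid(grid_size)

    if fit.model == "M2a":
        omega0_grid = u  # (0,1)
        omega_pos_grid = 1.0 + 10.0 * u  # (1,11)
        # distinct omegas: omega0 grid, 1.0, positive grid
        omegas = np.concatenate([omega0_grid, [1.0], omega_pos_grid])
        table = _class_log_likelihood_table(pruner, kappa, omegas, pi, scale, blen)
        log_f0 = table[:grid_size]  # (g0, sites)
        log_f1 = table[grid_size]  # (sites,)
        log_f2 = table[grid_size + 1 :]  # (g2, sites)
        # proportion grid: p0, p1 midpoints with p0 + p1 <= 1
        prop_pairs = [
            (p0, p1)
            for p0 in u
            for p1 in u
            if p0 + p1 < 1.0
        ]
        n_sites = pruner.n_sites
        num = np.zeros((n_sites, 3))
        log_weights = []
        posts = []
        for p0, p1 in prop_pairs:
            p2 = 1.0 - p0 - p1
            for i0 in range(grid_size):
                for i2 in range(grid_size):
                    stack = np.stack(
                        [
                            np.log(p0) + log_f0[i0],
                            np.log(p1) + log_f1,
                            np.log(p2) + log_f2[i2],
                        ]
                    )  # (3, sites)
                    site_log_mix = logsumexp(stack, axis=0)
                    log_weights.append(site_log_mix.sum())
                    posts.append(np.exp(stack - site_log_mix[None, :]).T)
        log_weights = np.array(log_weights)
        w = np.exp(log_weights - logsumexp(log_weights))
        for wi, post in zip(w, posts):
            num += wi * post
        return SitePosterior("M2a", num, num[:, 2].copy())

    # M8
    p0_grid = u
    pq_grid = 2.0 * u  # beta parameters on (0,2), the published default range
    omega_s_grid = 1.0 + 10.0 * u
    # site likelihood table for every beta category of every (p,q) pair
    cat_tables = {}
    for p in pq_grid:
        for q in pq_grid:
            cats = _beta_category_omegas(p, q)
            cat_tables[(p, q)] = _class_log_likelihood_table(
                pruner, kappa, cats, pi, scale, blen
            )
    pos_table = _class_log_likelihood_table(
        pruner, kappa, omega_s_grid, pi, scale, blen
    )
    n_sites = pruner.n_sites
    num = np.zeros((n_sites, 2))  # (beta bulk, positive class)
    log_weights = []
    posts = []
    for p in pq_grid:
        for q in pq_grid:
            tab = cat_tables[(p, q)]
            k = tab.shape[0]
            log_beta_mean = logsumexp(tab, axis=0) - np.log(k)  # (sites,)
            for p0 in p0_grid:
                for i_s, _ in enumerate(omega_s_grid):
                    stack = np.stack(
                        [
                            np.log(p0) + log_beta_mean,
                            np.log(1.0 - p0) + pos_table[i_s],
                        ]
                    )
                    site_log_mix = logsumexp(stack, axis=0)
                    log_weights.append(site_log_mix.sum())
                    posts.append(np.exp(stack - site_log_mix[None, :]).T)
    log_weights = np.array(log_weights)
    w = np.exp(log_weights - logsumexp(log_weights))
    for wi, post in zip(w, posts):
        num += wi * post
    return SitePosterior("M8", num, num[:, 1].copy())
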