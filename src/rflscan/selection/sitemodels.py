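"""Codon site-model fitting (M0, M1a, M2a, M7, M8), likelihood ratio tests.

All models share the GY94 rate matrix with F3x4 codon frequencies taken
empirically from the data. Site likelihoods are computed by Felsenstein
pruning with per-node scaling; mixture models sum site likelihoods over
omega classes. The beta models discretise beta(p,q) into K=10
equal-probability categories represented by their medians; M8 adds a
point mass omega_s >= 1.

Branch lengths are optimised under M0 and then held fixed for the site
models (re-optimisation is configurable), the standard practice that
stabilises the boundary-heavy mixture optimisations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .codon import (
    N_CODONS,
    CodonTransition,
    f3x4_from_codon_matrix,
    mean_rate,
)
from .msa import CodonAlignment
from .trees import PhyloTree

__all__ = ["SiteModelFit", "LrtResult", "fit_site_model", "fit_model_series", "lrt"]

MODELS = ("M0", "M1a", "M2a", "M7", "M8")

_KAPPA_BOUNDS = (0.1, 20.0)
_OMEGA_BOUNDS = (1e-4, 50.0)
_POS_OMEGA_BOUNDS = (1.0, 50.0)
_BETA_BOUNDS = (0.005, 99.0)
_PROP_BOUNDS = (1e-6, 1.0 - 1e-6)
_BLEN_BOUNDS = (1e-8, 25.0)
_N_BETA_CATEGORIES = 10


@dataclass
class SiteModelFit:
    """A fitted codon site model."""

    model: str
    lnL: float
    kappa: float
    omega_classes: list[tuple[float, float]]  # (proportion, omega)
    codon_freqs: np.ndarray
    tree: PhyloTree
    beta_params: tuple[float, float] | None = None
    positive_omega: float | None = None  # omega_s (M8) / omega_2 (M2a)
    converged: bool = True
    n_codons: int = 0
    taxa: tuple[str, ...] = ()

    @property
    def omega(self) -> float:
        """Mixture-average omega (equals the single omega under M0)."""
        return float(sum(p * w for p, w in self.omega_classes))

    @property
    def scale(self) -> float:
        return sum(
            p * mean_rate(self.kappa, w, self.codon_freqs)
            for p, w in self.omega_classes
        )


@dataclass
class LrtResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float
    flagged: bool = False

    def stars(self) -> str:
        """Significance band string (no multiple-testing correction)."""
        p = self.p_value
        if p < 1e-20:
            return "****"
        if p < 1e-10:
            return "***"
        if p < 1e-5:
            return "**"
        if p < 0.1:
            return "*"
        return "ns"


class CodonPruner:
    """Felsenstein pruning over an integer codon matrix.

    Leaves observe sense-codon indices (negative = gap/unknown, treated as
    fully ambiguous). Per-site scaling keeps partial likelihoods in range.
    """

    def __init__(self, codes: np.ndarray, taxa: list[str], tree: PhyloTree):
        leaf_nodes = tree.leaves
        name_to_node = {tree.names[i]: i for i in leaf_nodes}
        missing = [t for t in taxa if t not in name_to_node]
        if missing:
            raise ValueError(f"taxa missing from tree: {missing}")
        if len(leaf_nodes) != len(taxa):
            raise ValueError("tree and alignment taxa differ")
        self.tree = tree
        self.codes_by_node = {name_to_node[t]: codes[i] for i, t in enumerate(taxa)}
        self.n_sites = codes.shape[1]
        self.postorder = tree.postorder()
        self.children = tree.children()

    def site_log_likelihoods(
        self, trans: CodonTransition, blen: np.ndarray
    ) -> np.ndarray:
        """log f(x_h) per site under one omega class."""
        n_sites = self.n_sites
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_sites)
        pmats = {
            i: trans.probability_matrix(blen[i]) for i in range(1, self.tree.n_nodes)
        }
        for node in self.postorder:
            kids = self.children[node]
            if not kids:
                continue
            acc = np.ones((n_sites, N_CODONS))
            for c in kids:
                p = pmats[c]
                if not self.children[c]:  # leaf child
                    obs = self.codes_by_node[c]
                    contrib = np.ones((n_sites, N_CODONS))
                    known = obs >= 0
                    contrib[known] = p[:, obs[known]].T
                else:
                    contrib = partial.pop(c) @ p.T
                acc *= contrib
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            acc /= mx[:, None]
            logscale += np.log(mx)
            partial[node] = acc
        root = self.postorder[-1]
        like = partial[root] @ trans.pi
        return np.log(np.clip(like, 1e-300, None)) + logscale


def _class_log_likelihood_table(
    pruner: CodonPruner,
    kappa: float,
    omegas: np.ndarray,
    pi: np.ndarray,
    scale: float,
    blen: np.ndarray,
) -> np.ndarray:
    """(n_classes, n_sites) table of per-class site log-likelihoods."""
    out = np.empty((len(omegas), pruner.n_sites))
    cache: dict[float, np.ndarray] = {}
    for k, w in enumerate(omegas):
        key = round(float(w), 12)
        if key in cache:
            out[k] = cache[key]
        else:
            trans = CodonTransition(kappa, float(w), pi, scale)
            out[k] = cache[key] = pruner.site_log_likelihoods(trans, blen)
    return out


def mixture_lnl(
    pruner: CodonPruner,
    kappa: float,
    props: np.ndarray,
    omegas: np.ndarray,
    pi: np.ndarray,
    blen: np.ndarray,
) -> float:
    scale = float(
        sum(p * mean_rate(kappa, w, pi) for p, w in zip(props, omegas))
    )
    table = _class_log_likelihood_table(pruner, kappa, omegas, pi, scale, blen)
    site_lnl = logsumexp(table, axis=0, b=props[:, None])
    return float(site_lnl.sum())


def _beta_category_omegas(p: float, q: float, k: int = _N_BETA_CATEGORIES) -> np.ndarray:
    quantiles = (np.arange(k) + 0.5) / k
    return beta_dist.ppf(quantiles, p, q)


def _model_classes(model: str, theta: dict) -> tuple[np.ndarray, np.ndarray]:
    """(proportions, omegas) for a parameter dictionary."""
    if model == "M0":
        return np.array([1.0]), np.array([theta["omega"]])
    if model == "M1a":
        p0 = theta["p0"]
        return np.array([p0, 1.0 - p0]), np.array([theta["omega0"], 1.0])
    if model == "M2a":
        p0, p1 = theta["p0"], theta["p1"]
        return (
            np.array([p0, p1, 1.0 - p0 - p1]),
            np.array([theta["omega0"], 1.0, theta["omega2"]]),
        )
    if model == "M7":
        w = _beta_category_omegas(theta["p"], theta["q"])
        k = len(w)
        return np.full(k, 1.0 / k), w
    if model == "M8":
        w = _beta_category_omegas(theta["p"], theta["q"])
        k = len(w)
        p0 = theta["p0"]
        return (
            np.concatenate([np.full(k, p0 / k), [1.0 - p0]]),
            np.concatenate([w, [theta["omega_s"]]]),
        )
    raise ValueError(f"unknown model {model!r}")


# -- parameter packing -------------------------------------------------------

def _spec(model: str):
    """Free parameters (name, bounds) per model; proportions use
    stick-breaking fractions bounded away from 0/1."""
    common = [("kappa", _KAPPA_BOUNDS)]
    if model == "M0":
        return common + [("omega", _OMEGA_BOUNDS)]
    if model == "M1a":
        return common + [("p0", _PROP_BOUNDS), ("omega0", (1e-4, 1.0))]
    if model == "M2a":
        return common + [
            ("p0", _PROP_BOUNDS),
            ("s1", _PROP_BOUNDS),  # p1 = (1-p0)*s1
            ("omega0", (1e-4, 1.0)),
            ("omega2", _POS_OMEGA_BOUNDS),
        ]
    if model == "M7":
        return common + [("p", _BETA_BOUNDS), ("q", _BETA_BOUNDS)]
    if model == "M8":
        return common + [
            ("p0", _PROP_BOUNDS),
            ("p", _BETA_BOUNDS),
            ("q", _BETA_BOUNDS),
            ("omega_s", _POS_OMEGA_BOUNDS),
        ]
    raise ValueError(f"unknown model {model!r}")


def _theta_from_vector(model: str, x: np.ndarray) -> dict:
    names = [n for n, _ in _spec(model)]
    theta = dict(zip(names, x))
    if model == "M2a":
        theta["p1"] = (1.0 - theta["p0"]) * theta.pop("s1")
    return theta


_STARTS = {
    "M0": [(2.0, 0.4)],
    "M1a": [(2.0, 0.7, 0.2), (2.0, 0.5, 0.05), (2.0, 0.9, 0.5)],
    "M2a": [
        (2.0, 0.7, 0.67, 0.2, 3.0),
        (2.0, 0.6, 0.75, 0.1, 5.0),
        (2.0, 0.85, 0.67, 0.3, 1.5),
    ],
    "M7": [(2.0, 0.5, 1.5), (2.0, 1.0, 1.0), (2.0, 0.2, 2.0)],
    "M8": [
        (2.0, 0.9, 0.5, 1.5, 3.0),
        (2.0, 0.8, 1.0, 1.0, 5.0),
        (2.0, 0.95, 0.3, 2.0, 1.5),
    ],
}


def fit_site_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: str,
    *,
    optimize_branch_lengths: bool | None = None,
    starts: list[tuple[float, ...]] | None = None,
    pi: np.ndarray | None = None,
    maxiter: int = 500,
) -> SiteModelFit:
    """Maximum-likelihood fit of one codon site model.

    Branch lengths are optimised only under M0 by default; other models
    inherit the lengths carried by ``tree`` (pass a tree from an M0 fit).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    codes = aln.codes()
    if codes.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    if codes.shape[1] < 1:
        raise ValueError("no usable codon columns")
    if pi is None:
        pi = f3x4_from_codon_matrix(codes)
    pruner = CodonPruner(codes, aln.taxa, tree)
    if optimize_branch_lengths is None:
        optimize_branch_lengths = model == "M0"
    spec = _spec(model)
    base_blen = tree.blen.copy()
    if optimize_branch_lengths and np.all(base_blen[1:] <= 1e-8):
        base_blen[1:] = 0.1  # neutral starting lengths
    n_theta = len(spec)
    bounds = [b for _, b in spec]
    if optimize_branch_lengths:
        bounds = bounds + [_BLEN_BOUNDS] * (tree.n_nodes - 1)

    def neg_lnl(x: np.ndarray) -> float:
        theta = _theta_from_vector(model, x[:n_theta])
        props, omegas = _model_classes(model, theta)
        blen = base_blen
        if optimize_branch_lengths:
            blen = np.concatenate([[0.0], x[n_theta:]])
        val = mixture_lnl(pruner, theta["kappa"], props, omegas, pi, blen)
        if not np.isfinite(val):
            return 1e12
        return -val

    start_list = starts if starts is not None else _STARTS[model]
    best = None
    for s in start_list:
        x0 = np.array(list(s), dtype=float)
        if optimize_branch_lengths:
            x0 = np.concatenate([x0, np.clip(base_blen[1:], *_BLEN_BOUNDS)])
        res = minimize(
            neg_lnl,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter * len(x0)},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(f"non-finite likelihood fitting {model}")
    theta = _theta_from_vector(model, best.x[:n_theta])
    props, omegas = _model_classes(model, theta)
    fitted_tree = tree
    if optimize_branch_lengths:
        fitted_tree = tree.with_branch_lengths(
            np.concatenate([[0.0], best.x[n_theta:]])
        )
    beta_params = (theta["p"], theta["q"]) if model in ("M7", "M8") else None
    pos = {"M2a": "omega2", "M8": "omega_s"}.get(model)
    return SiteModelFit(
        model=model,
        lnL=-float(best.fun),
        kappa=float(theta["kappa"]),
        omega_classes=list(zip(props.tolist(), omegas.tolist())),
        codon_freqs=pi,
        tree=fitted_tree,
        beta_params=beta_params,
        positive_omega=float(theta[pos]) if pos else None,
        converged=bool(best.success),
        n_codons=codes.shape[1],
        taxa=tuple(aln.taxa),
    )


def fit_model_series(
    aln: CodonAlignment,
    tree: PhyloTree,
    models: tuple[str, ...] = MODELS,
    **kwargs,
) -> dict[str, SiteModelFit]:
    """Fit several models, optimising branch lengths under M0 (fitted
    first when requested) and holding them fixed elsewhere."""
    fits: dict[str, SiteModelFit] = {}
    work_tree = tree
    if "M0" in models:
        fits["M0"] = fit_site_model(aln, tree, "M0", **kwargs)
        work_tree = fits["M0"].tree
    for m in models:
        if m == "M0":
            continue
        fits[m] = fit_site_model(aln, work_tree, m, **kwargs)
    return fits


_NESTED = {("M1a", "M2a"), ("M7", "M8"), ("M0", "M1a"), ("M0", "M2a")}


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit, df: int = 2) -> LrtResult:
    """Likelihood ratio test of a nested model pair (df=2 for M1a-M2a and
    M7-M8). The statistic is clamped at zero; a negative raw statistic
    beyond tolerance flags the fit (optimizer failure on nested models)."""
    if (null_fit.model, alt_fit.model) not in _NESTED:
        raise ValueError(
            f"{null_fit.model} vs {alt_fit.model} is not a supported nested pair"
        )
    if null_fit.n_codons != alt_fit.n_codons or null_fit.taxa != alt_fit.taxa:
        raise ValueError("fits are not on the same data")
    raw = 2.0 * (alt_fit.lnL - null_fit.lnL)
    flagged = raw < -1e-6
    stat = max(0.0, raw)
    return LrtResult(
        null_model=null_fit.model,
        alt_model=alt_fit.model,
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
        flagged=flagged,
    )
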