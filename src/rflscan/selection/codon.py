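"""GY94-style codon substitution machinery.

The 61 sense codons of the standard genetic code (alphabetical order),
the F3x4 stationary distribution, and the Goldman-Yang rate matrix
parameterised by the transition/transversion ratio kappa and the
nonsynonymous/synonymous rate ratio omega:

    q_ij = 0                 more than one codon position differs
         = pi_j              synonymous transversion
         = kappa pi_j        synonymous transition
         = omega pi_j        nonsynonymous transversion
         = omega kappa pi_j  nonsynonymous transition

Rates are reported per expected substitution per codon: under a site-class
mixture the generator is divided by the mixture-average rate so branch
lengths keep that meaning across models.
"""

from __future__ import annotations

from itertools import product

import numpy as np

NUCLEOTIDES = "ACGT"
_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_STOPS = {"TAA", "TAG", "TGA"}

_CODON_AA = {}


def _standard_code() -> dict[str, str]:
    if not _CODON_AA:
        from ..genome_scan import translate_dna

        for c in ("".join(p) for p in product(NUCLEOTIDES, repeat=3)):
            _CODON_AA[c] = translate_dna(c)
    return _CODON_AA


SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in product(NUCLEOTIDES, repeat=3))
    if c not in _STOPS
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

CODON_AA = tuple(_standard_code()[c] for c in SENSE_CODONS)

# codon -> nucleotide index at each of the three positions
CODON_NT = np.array(
    [[_NT_INDEX[c[k]] for k in range(3)] for c in SENSE_CODONS], dtype=int
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _pair_structure():
    """Single-nucleotide-difference codon pairs with their change type."""
    pairs = []
    for i in range(N_CODONS):
        for j in range(N_CODONS):
            if i == j:
                continue
            ci, cj = SENSE_CODONS[i], SENSE_CODONS[j]
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            is_ts = (ci[k], cj[k]) in _TRANSITIONS
            is_nonsyn = CODON_AA[i] != CODON_AA[j]
            pairs.append((i, j, is_ts, is_nonsyn))
    arr = np.array(pairs, dtype=int)
    return arr[:, 0], arr[:, 1], arr[:, 2].astype(bool), arr[:, 3].astype(bool)


_PI_I, _PI_J, _IS_TS, _IS_NONSYN = _pair_structure()


def f3x4_frequencies(position_nt_freqs: np.ndarray) -> np.ndarray:
    """Sense-codon stationary distribution from per-codon-position
    nucleotide frequencies (3x4 array, rows sum to 1)."""
    f = np.asarray(position_nt_freqs, dtype=float)
    if f.shape != (3, 4):
        raise ValueError("position_nt_freqs must be 3x4")
    pi = f[0, CODON_NT[:, 0]] * f[1, CODON_NT[:, 1]] * f[2, CODON_NT[:, 2]]
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate nucleotide frequencies")
    return pi / total


def f3x4_from_codon_matrix(codes: np.ndarray) -> np.ndarray:
    """Empirical F3x4 frequencies from an integer codon matrix
    (gap/unknown coded as negative)."""
    counts = np.zeros((3, 4))
    obs = codes[codes >= 0]
    if obs.size == 0:
        raise ValueError("no observed codons")
    for k in range(3):
        counts[k] = np.bincount(CODON_NT[obs, k], minlength=4)
    counts += 0.5  # avoid zero frequencies on tiny alignments
    return f3x4_frequencies(counts / counts.sum(axis=1, keepdims=True))


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled GY94 generator (rows sum to zero)."""
    q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[_PI_J].copy()
    rates[_IS_TS] *= kappa
    rates[_IS_NONSYN] *= omega
    q[_PI_I, _PI_J] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def mean_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Expected substitution rate at stationarity for an unscaled Q."""
    rates = pi[_PI_I] * pi[_PI_J]
    rates[_IS_TS] *= kappa
    rates[_IS_NONSYN] *= omega
    return float(rates.sum())


class CodonTransition:
    """Cached spectral decomposition of one scaled GY94 generator.

    The generator is reversible w.r.t. pi, so it is symmetrised with
    diag(sqrt(pi)) and decomposed once; P(t) then costs two small matrix
    products per branch.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray, scale: float):
        q = gy94_rate_matrix(kappa, omega, pi) / scale
        half = np.sqrt(pi)
        b = (q * half[:, None]) / half[None, :]
        b = (b + b.T) / 2.0
        w, u = np.linalg.eigh(b)
        self._w = w
        self._right = u / half[:, None]
        self._left = u.T * half[None, :]
        self.pi = pi
        self.q = q

    def probability_matrix(self, t: float) -> np.ndarray:
        p = (self._right * np.exp(self._w * t)[None, :]) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def encode_codon(codon: str) -> int:
    """Sense-codon index; -1 for gaps, stops or ambiguous codons."""
    return CODON_INDEX.get(codon.upper(), -1)
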