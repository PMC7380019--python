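"""PPR motif scoring, chaining and P/PLS classification.

A PPR protein is a tandem array of degenerate 31-36 aa repeats. Each motif
class (P: 35 aa canonical, L: long, S: short) is modelled as a position
specific log-odds profile. Proteins are scanned with a glocal alignment
(whole motif, local in the protein); overlapping hits are reduced to the
best-scoring non-overlapping chain by weighted interval scheduling, and
the chained model is classified with the family score thresholds:
P-class needs a summed score above 100 with no L/S motifs, PLS-class a
summed score above 240 with at least one L and one S motif (both strict
inequalities).

The protein score used here is the sum of per-motif bit scores, which
approximates (but is not identical to) a full-sequence hmmsearch score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._jtt import JTT_FREQS, AA_ORDER as _JTT_AA

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical, 20 canonical residues
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# JTT equilibrium frequencies reordered to the alphabetical alphabet: a
# reasonable default background for log-odds scoring.
DEFAULT_BACKGROUND = np.array([JTT_FREQS[_JTT_AA.index(a)] for a in AA_ALPHABET])
DEFAULT_BACKGROUND = DEFAULT_BACKGROUND / DEFAULT_BACKGROUND.sum()

#: tolerated deviation of a hit's span from the nominal motif length,
#: accommodating the 31-36 aa range of natural PPR motifs
LENGTH_TOLERANCE = 4

DEFAULT_HIT_THRESHOLD = 8.0  # bits per motif

PROTEIN_SCORE_THRESHOLDS = {"P": 100.0, "PLS": 240.0}

__all__ = [
    "MotifProfile",
    "MotifHit",
    "PprGeneModel",
    "build_profile",
    "scan_protein",
    "chain_and_classify",
    "render_motif_structure",
    "read_profile",
    "write_profile",
    "read_hmm_profile",
    "load_packaged_profiles",
    "max_weight_chain",
    "DEFAULT_HIT_THRESHOLD",
    "PROTEIN_SCORE_THRESHOLDS",
]


@dataclass
class MotifProfile:
    """Position-specific log-odds model of one motif class."""

    class_label: str
    match_scores: np.ndarray  # (length, 20) bits
    gap_open: float = 11.0
    gap_extend: float = 1.0
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())

    def __post_init__(self):
        self.match_scores = np.asarray(self.match_scores, dtype=float)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 20:
            raise ValueError("match_scores must be (length, 20)")
        if self.length < 31:
            raise ValueError("PPR motif profiles are at least 31 aa long")

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[j] for j in self.match_scores.argmax(axis=1))

    def position_scores(self, protein: str) -> np.ndarray:
        """(length, n) matrix of per-position scores against a protein.

        Unknown residues (X etc.) score 0 everywhere: indistinguishable
        from background.
        """
        n = len(protein)
        idx = np.array([_AA_INDEX.get(a, -1) for a in protein])
        ps = np.zeros((self.length, n))
        known = idx >= 0
        ps[:, known] = self.match_scores[:, idx[known]]
        return ps


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence, 1-based inclusive protein coordinates."""

    start_aa: int
    end_aa: int
    class_label: str
    score: float

    @property
    def span(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass
class PprGeneModel:
    """An ORF together with its chained motif hits and family class."""

    orf_id: str
    protein_length: int
    hits: list[MotifHit]
    family_class: str  # "P", "PLS" or "none"
    protein_score: float

    @property
    def n_motifs(self) -> int:
        return len(self.hits)

    @property
    def structure_string(self) -> str:
        return render_motif_structure(self)


def build_profile(
    seed_alignment: Sequence[str],
    class_label: str,
    *,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MotifProfile:
    """Profile from an aligned set of motif instances.

    Per-column Laplace-smoothed frequencies against the background, in bits.
    Gap characters in a column are ignored (the pseudocount keeps every
    emission positive).
    """
    rows = [r.upper() for r in seed_alignment]
    if not rows:
        raise ValueError("empty seed alignment")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("seed alignment rows have unequal lengths")
    bg = DEFAULT_BACKGROUND if background is None else np.asarray(background, float)
    counts = np.zeros((length, 20))
    for r in rows:
        for i, a in enumerate(r):
            j = _AA_INDEX.get(a)
            if j is not None:
                counts[i, j] += 1.0
    freqs = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 20.0 * pseudocount
    )
    scores = np.log2(freqs / bg[None, :])
    return MotifProfile(class_label, scores, gap_open, gap_extend, bg)


def _fit_best_scores(profile: MotifProfile, ps: np.ndarray) -> np.ndarray:
    """Best glocal (full profile, free start) alignment score ending at
    each protein position, width-unconstrained.

    This upper-bounds every fixed-width window score ending at or after
    that position (a window's extra leading/trailing gaps only subtract),
    so it prunes the exact window enumeration without ever dropping a
    hit.
    """
    L = ps.shape[0]
    n = ps.shape[1]
    go, ge = profile.gap_open, profile.gap_extend
    neg = -1e30
    m = np.full(L + 1, neg)
    ix = np.full(L + 1, neg)
    iy = np.full(L + 1, neg)
    m[0] = 0.0
    # column j=0: leading profile deletions
    iy[1:] = -go - np.arange(L) * ge
    best = np.full(n, neg)
    idx = np.arange(L)
    for j in range(n):
        new_m = np.full(L + 1, neg)
        prev_best = np.maximum(m, np.maximum(ix, iy))
        new_m[1:] = ps[:, j] + prev_best[:-1]
        new_m[0] = 0.0
        new_ix = np.maximum(m - go, ix - ge)
        new_ix[0] = neg
        # iy[i] = max_{k<i} new_m[k] - go - (i-1-k)*ge  (prefix max trick)
        shifted = np.maximum.accumulate(new_m[:-1] + idx * ge)
        new_iy = np.full(L + 1, neg)
        new_iy[1:] = shifted - go - idx * ge
        m, ix, iy = new_m, new_ix, new_iy
        best[j] = max(m[L], iy[L])
    return best


def _window_scores(
    profile: MotifProfile, protein: str, width: int, starts: np.ndarray,
    ps: np.ndarray | None = None,
) -> np.ndarray:
    """Global affine-gap alignment score of the full profile against the
    ``width``-long windows beginning at ``starts``, vectorised."""
    n = len(protein)
    k = len(starts)
    if k == 0:
        return np.full(0, -np.inf)
    if ps is None:
        ps = profile.position_scores(protein)  # (L, n)
    L = profile.length
    go, ge = profile.gap_open, profile.gap_extend
    neg = -1e30
    # DP over (profile position i, window offset j), vectors over starts.
    m_prev = np.full((width + 1, k), neg)
    ix_prev = np.full((width + 1, k), neg)  # gap in profile (protein consumed)
    iy_prev = np.full((width + 1, k), neg)  # gap in protein (profile consumed)
    m_prev[0, :] = 0.0
    for j in range(1, width + 1):
        ix_prev[j, :] = -go - (j - 1) * ge
    for i in range(1, L + 1):
        m_cur = np.full((width + 1, k), neg)
        ix_cur = np.full((width + 1, k), neg)
        iy_cur = np.full((width + 1, k), neg)
        iy_cur[0, :] = -go - (i - 1) * ge
        for j in range(1, width + 1):
            emit = ps[i - 1, starts + j - 1]
            m_cur[j] = emit + np.maximum(
                m_prev[j - 1], np.maximum(ix_prev[j - 1], iy_prev[j - 1])
            )
            ix_cur[j] = np.maximum(m_cur[j - 1] - go, ix_cur[j - 1] - ge)
            iy_cur[j] = np.maximum(m_prev[j] - go, iy_prev[j] - ge)
        m_prev, ix_prev, iy_prev = m_cur, ix_cur, iy_cur
    return np.maximum(m_prev[width], np.maximum(ix_prev[width], iy_prev[width]))


def _candidate_hits(
    profile: MotifProfile, protein: str, hit_threshold: float
) -> list[MotifHit]:
    """Best-scoring candidate per end position, over all window widths
    within the length tolerance. Ties prefer the smaller start."""
    n = len(protein)
    L = profile.length
    if n < L - LENGTH_TOLERANCE:
        return []
    ps = profile.position_scores(protein)
    fit_best = _fit_best_scores(profile, ps)
    # flag ends worth enumerating: a window ending at e either ends its
    # alignment at e (bounded by fit_best[e]) or pads with >= 1 trailing
    # gap costing > gap_open (bounded by a recent fit_best - gap_open)
    w_max = min(n, L + LENGTH_TOLERANCE)
    flagged = fit_best > hit_threshold
    padded = np.concatenate([np.full(w_max - 1, -1e30), fit_best[:-1]])
    recent = np.lib.stride_tricks.sliding_window_view(padded, w_max - 1).max(axis=1)
    flagged |= (recent - profile.gap_open) > hit_threshold
    ends = np.flatnonzero(flagged)
    if len(ends) == 0:
        return []
    best: dict[int, tuple[float, int]] = {}  # end (0-based) -> (score, start)
    for width in range(max(1, L - LENGTH_TOLERANCE), w_max + 1):
        starts = ends - width + 1
        keep = (starts >= 0) & (ends < n)
        starts = starts[keep]
        scores = _window_scores(profile, protein, width, starts, ps)
        for s, sc in zip(starts, scores):
            if sc <= hit_threshold:
                continue
            e = s + width - 1
            cur = best.get(e)
            if cur is None or sc > cur[0] or (sc == cur[0] and s < cur[1]):
                best[e] = (float(sc), s)
    return [
        MotifHit(int(s) + 1, int(e) + 1, profile.class_label, sc)
        for e, (sc, s) in sorted(best.items())
    ]


def max_weight_chain(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Maximum-total-score set of non-overlapping hits (weighted interval
    scheduling). On equal totals the chain including the leftmost-starting
    hit is preferred."""
    if not hits:
        return []
    order = sorted(hits, key=lambda h: (h.end_aa, h.start_aa))
    ends = [h.end_aa for h in order]
    import bisect

    n = len(order)
    # dp[i] = (best score using first i hits, chosen hits tuple)
    dp_score = [0.0] * (n + 1)
    dp_take: list[bool] = [False] * (n + 1)
    pred = [0] * (n + 1)
    for i in range(1, n + 1):
        h = order[i - 1]
        p = bisect.bisect_left(ends, h.start_aa, 0, i - 1)
        take = dp_score[p] + h.score
        skip = dp_score[i - 1]
        pred[i] = p
        if take >= skip - 1e-12:
            dp_score[i] = take
            dp_take[i] = True
        else:
            dp_score[i] = skip
            dp_take[i] = False
    chosen: list[MotifHit] = []
    i = n
    while i > 0:
        if dp_take[i]:
            chosen.append(order[i - 1])
            i = pred[i]
        else:
            i -= 1
    chosen.reverse()
    return chosen


def scan_protein(
    protein: str,
    profiles: Iterable[MotifProfile],
    hit_threshold: float = DEFAULT_HIT_THRESHOLD,
) -> list[MotifHit]:
    """Motif hits along a protein, reduced to a best-scoring
    non-overlapping set across all profile classes."""
    protein = protein.upper()
    candidates: list[MotifHit] = []
    for prof in profiles:
        candidates.extend(_candidate_hits(prof, protein, hit_threshold))
    return max_weight_chain(candidates)


def chain_and_classify(
    hits: Sequence[MotifHit],
    orf_id: str = "",
    protein_length: int = 0,
    protein_score_thresholds: dict[str, float] | None = None,
) -> PprGeneModel:
    """Chain hits and classify the protein as P-class, PLS-class or none.

    Thresholds are strict: a summed score of exactly 100 (240) does not
    qualify.
    """
    th = protein_score_thresholds or PROTEIN_SCORE_THRESHOLDS
    chained = max_weight_chain(hits)
    total = float(sum(h.score for h in chained))
    labels = {h.class_label for h in chained}
    has_l, has_s = "L" in labels, "S" in labels
    eps = 1e-9  # strict thresholds, insensitive to float dust
    if has_l and has_s and total > th["PLS"] + eps:
        family = "PLS"
    elif not has_l and not has_s and total > th["P"] + eps and chained:
        family = "P"
    else:
        family = "none"
    return PprGeneModel(orf_id, protein_length, chained, family, total)


def render_motif_structure(model: PprGeneModel) -> str:
    """Hyphen-joined token string: inter-motif/terminal segment lengths in
    aa, class letters for motifs; zero-length segments omitted.
    """
    if not model.hits:
        return ""
    tokens: list[str] = []
    prev_end = 0
    for h in sorted(model.hits):
        gap = h.start_aa - prev_end - 1
        if gap > 0:
            tokens.append(str(gap))
        tokens.append(h.class_label)
        prev_end = h.end_aa
    tail = model.protein_length - prev_end
    if tail > 0:
        tokens.append(str(tail))
    return "-".join(tokens)


# ---------------------------------------------------------------------------
# profile text format: header lines then a (length x 20) log-odds table

def write_profile(profile: MotifProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rflscan motif profile\nclass\t{profile.class_label}\n")
        fh.write(f"gap_open\t{profile.gap_open}\ngap_extend\t{profile.gap_extend}\n")
        fh.write("background\t" + "\t".join(f"{b:.6f}" for b in profile.background) + "\n")
        fh.write("alphabet\t" + "\t".join(AA_ALPHABET) + "\n")
        for row in profile.match_scores:
            fh.write("\t".join(f"{v:.4f}" for v in row) + "\n")


def read_profile(path: str | Path) -> MotifProfile:
    label, go, ge, bg = None, 11.0, 1.0, None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "class":
                label = parts[1]
            elif parts[0] == "gap_open":
                go = float(parts[1])
            elif parts[0] == "gap_extend":
                ge = float(parts[1])
            elif parts[0] == "background":
                bg = np.array([float(x) for x in parts[1:]])
            elif parts[0] == "alphabet":
                if "".join(parts[1:]) != AA_ALPHABET:
                    raise ValueError("unsupported profile alphabet")
            else:
                rows.append([float(x) for x in parts])
    if label is None or not rows:
        raise ValueError(f"malformed profile file {path}")
    return MotifProfile(label, np.array(rows), go, ge, bg if bg is not None else DEFAULT_BACKGROUND.copy())


def read_hmm_profile(
    path: str | Path,
    class_label: str | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MotifProfile:
    """Import a HMMER3 profile HMM as a motif profile.

    Only the match-state emissions are used (converted to log-odds in
    bits against this package's background); insert/delete transition
    structure is replaced by the scanner's affine gap penalties.
    """
    import pyhmmer

    with pyhmmer.plan7.HMMFile(str(path)) as fh:
        hmm = fh.read()
    symbols = hmm.alphabet.symbols[:20]
    order = [symbols.index(a) for a in AA_ALPHABET]
    probs = np.asarray(hmm.match_emissions)[1:, :20][:, order]
    probs = np.clip(probs, 1e-6, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    scores = np.log2(probs / DEFAULT_BACKGROUND[None, :])
    label = class_label or (hmm.name.decode() if hmm.name else "P")
    return MotifProfile(label, scores, gap_open, gap_extend)


def load_packaged_profiles() -> dict[str, MotifProfile]:
    """The P/L/S fixture profiles built from the packaged seed alignments.

    These seeds are synthetic stand-ins written for this package (built
    around a canonical P-motif consensus), sufficient for testing and for
    synthetic genomes; reproducing published annotations requires the
    originally published motif models as an input artifact.
    """
    from importlib.resources import files

    out: dict[str, MotifProfile] = {}
    data = files("rflscan.data")
    for label, fname in (
        ("P", "synthetic_p_motif_seed.afa"),
        ("L", "synthetic_l_motif_seed.afa"),
        ("S", "synthetic_s_motif_seed.afa"),
    ):
        rows = []
        for line in (data / fname).read_text().splitlines():
            if line and not line.startswith((">", ";")):
                rows.append(line.strip())
        out[label] = build_profile(rows, label)
    return out
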