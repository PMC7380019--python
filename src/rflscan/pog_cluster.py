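"""Greedy identity clustering of RFL sequences into putative orthogroups.

Reproduces the semantics of iterated CD-HIT runs: sequences sorted by
decreasing length; each sequence joins the best-identity existing cluster
representative that meets the identity threshold (``-c``) and the
coverage-of-shorter-sequence constraint (``-aS``), computed on a local
alignment (``-G 0``), otherwise it founds a new cluster (``-g 1`` = best
assignment). Three iterated rounds at 98/96/93% identity re-cluster the
representatives, and the union through the hierarchy defines the POGs.

The k-mer prefilter is purely an admissible shortcut: it only skips pairs
whose identity is provably below the threshold, so disabling it never
changes the result.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment import local_identity_coverage

__all__ = [
    "ClusterParams",
    "SeqRecord",
    "Cluster",
    "Orthogroup",
    "greedy_cluster",
    "iterative_hca",
    "presence_matrix",
    "read_accession_dir",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.98, 0.96, 0.93)


@dataclass(frozen=True)
class ClusterParams:
    """CD-HIT-style clustering parameters (defaults mirror
    ``-c 0.98 -n 5 -g 1 -G 0 -aS 0.99 -d 0``)."""

    identity_c: float = 0.98
    word_n: int = 5
    coverage_aS: float = 0.99
    assign_mode_g: str = "best"  # {"first", "best"}
    identity_mode_G: str = "local"
    use_prefilter: bool = True

    def __post_init__(self):
        if not 0 < self.identity_c <= 1:
            raise ValueError("identity_c must be in (0, 1]")
        if not 0 < self.coverage_aS <= 1:
            raise ValueError("coverage_aS must be in (0, 1]")
        if self.assign_mode_g not in ("first", "best"):
            raise ValueError("assign_mode_g must be 'first' or 'best'")
        if self.identity_mode_G != "local":
            raise ValueError("only local (-G 0) identity is supported")


@dataclass(frozen=True)
class SeqRecord:
    id: str
    seq: str
    accession: str = ""


@dataclass
class Cluster:
    representative: SeqRecord
    members: list[tuple[SeqRecord, float]]  # (record, identity to representative)

    @property
    def ids(self) -> list[str]:
        return [self.representative.id] + [m.id for m, _ in self.members]

    @property
    def size(self) -> int:
        return 1 + len(self.members)


@dataclass
class Orthogroup:
    """A putative orthogroup: RFL sequences grouped across accessions."""

    pog_id: str
    representative: SeqRecord
    members: list[tuple[str, str]]  # (accession, sequence id)
    member_identities: dict[str, float]  # id -> identity along the merge chain

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def accessions(self) -> set[str]:
        return {a for a, _ in self.members}


def _kmers(seq: str, n: int) -> Counter:
    """k-mer multiset: repeat proteins are highly repetitive, so shared
    k-mers must be counted with multiplicity for the skip bound to hold."""
    return Counter(seq[i : i + n] for i in range(len(seq) - n + 1))


def _shared_kmers(a: Counter, b: Counter) -> int:
    return sum(min(c, b[k]) for k, c in a.items() if k in b)


def _prefilter_may_skip(
    short_len: int, shared_kmers: int, params: ClusterParams
) -> bool:
    """True when the shared k-mer count proves identity < identity_c.

    With identity = identical columns / alignment columns and identical
    columns <= short_len, an alignment at identity c has at most
    short_len*(1-c)/c non-identical columns, each destroying at most
    word_n of the shorter sequence's k-mers.
    """
    n = params.word_n
    if short_len < n:
        return False
    max_bad = int(short_len * (1.0 - params.identity_c) / params.identity_c)
    lower_bound = (short_len - n + 1) - n * max_bad
    return shared_kmers < lower_bound


def greedy_cluster(
    seqs: Sequence[SeqRecord], params: ClusterParams = ClusterParams()
) -> list[Cluster]:
    """One greedy incremental clustering pass.

    Deterministic: input sorted by decreasing length (stable, so
    equal-length order follows the input); best-assignment ties go to the
    longer representative, then the lexicographically smaller id.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    order = sorted(range(len(seqs)), key=lambda i: -len(seqs[i].seq))
    clusters: list[Cluster] = []
    rep_kmers: list[Counter] = []
    for idx in order:
        rec = seqs[idx]
        km = _kmers(rec.seq, params.word_n)
        best: tuple[float, int] | None = None  # (identity, cluster index)
        for ci, cl in enumerate(clusters):
            rep = cl.representative
            short_len = min(len(rec.seq), len(rep.seq))
            if params.use_prefilter and short_len >= params.word_n:
                shared = _shared_kmers(km, rep_kmers[ci])
                if _prefilter_may_skip(short_len, shared, params):
                    continue
            ident, cov = local_identity_coverage(rec.seq, rep.seq)
            if ident < params.identity_c or cov < params.coverage_aS:
                continue
            if params.assign_mode_g == "first":
                best = (ident, ci)
                break
            if best is None or _better_assignment(ident, ci, best, clusters):
                best = (ident, ci)
        if best is None:
            clusters.append(Cluster(rec, []))
            rep_kmers.append(km)
        else:
            clusters[best[1]].members.append((rec, best[0]))
    return clusters


def _better_assignment(
    ident: float, ci: int, best: tuple[float, int], clusters: list[Cluster]
) -> bool:
    if ident > best[0] + 1e-12:
        return True
    if ident < best[0] - 1e-12:
        return False
    cand, cur = clusters[ci].representative, clusters[best[1]].representative
    if len(cand.seq) != len(cur.seq):
        return len(cand.seq) > len(cur.seq)
    return cand.id < cur.id


def iterative_hca(
    seqs_by_accession: dict[str, Sequence[tuple[str, str]]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    params: ClusterParams = ClusterParams(),
) -> list[Orthogroup]:
    """Hierarchical cluster analysis: iterated greedy clustering at
    decreasing identity thresholds, re-clustering representatives each
    round; the union of members through the hierarchy defines each POG.

    POG ids are ordered by decreasing membership, then representative id.
    """
    if not seqs_by_accession:
        raise ValueError("no accessions")
    ths = list(thresholds)
    if any(b >= a for a, b in zip(ths, ths[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    records = [
        SeqRecord(sid, seq, acc)
        for acc, pairs in seqs_by_accession.items()
        for sid, seq in pairs
    ]
    if not records:
        raise ValueError("no sequences")
    # members_of[rep_id]: accumulated (record, chain identity) at any level
    members_of: dict[str, list[tuple[SeqRecord, float]]] = {
        r.id: [(r, 1.0)] for r in records
    }
    current = records
    for th in ths:
        p = ClusterParams(
            identity_c=th,
            word_n=params.word_n,
            coverage_aS=params.coverage_aS,
            assign_mode_g=params.assign_mode_g,
            identity_mode_G=params.identity_mode_G,
            use_prefilter=params.use_prefilter,
        )
        level = greedy_cluster(current, p)
        next_reps: list[SeqRecord] = []
        new_members: dict[str, list[tuple[SeqRecord, float]]] = {}
        for cl in level:
            rep = cl.representative
            pooled = list(members_of[rep.id])
            for rec, ident in cl.members:
                pooled.extend(
                    (r, min(i, ident)) for r, i in members_of[rec.id]
                )
            new_members[rep.id] = pooled
            next_reps.append(rep)
        members_of = new_members
        current = next_reps
    groups = []
    for rep in current:
        pooled = members_of[rep.id]
        groups.append((rep, pooled))
    groups.sort(key=lambda g: (-len(g[1]), g[0].id))
    out = []
    width = max(2, len(str(len(groups))))
    for k, (rep, pooled) in enumerate(groups, start=1):
        out.append(
            Orthogroup(
                pog_id=f"POG{k:0{width}d}",
                representative=rep,
                members=sorted((r.accession, r.id) for r, _ in pooled),
                member_identities={r.id: i for r, i in pooled},
            )
        )
    return out


def presence_matrix(
    pogs: Sequence[Orthogroup], accessions: Sequence[str]
) -> pd.DataFrame:
    """Binary POG x accession presence matrix with per-POG frequency,
    rows sorted by frequency descending (then POG id)."""
    if not list(accessions):
        raise ValueError("empty accession list")
    acc = list(accessions)
    rows = {}
    for pog in pogs:
        present = pog.accessions
        rows[pog.pog_id] = [a in present for a in acc]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=acc)
    df["frequency"] = df[acc].mean(axis=1)
    df = df.sort_values(["frequency"], ascending=False, kind="stable")
    df = df.loc[
        sorted(df.index, key=lambda i: (-df.loc[i, "frequency"], i))
    ]
    return df


def read_accession_dir(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Load one protein FASTA per accession from a directory."""
    from Bio import SeqIO

    path = Path(path)
    out: dict[str, list[tuple[str, str]]] = {}
    for fa in sorted(path.glob("*.fa")) + sorted(path.glob("*.fasta")):
        acc = fa.stem
        out[acc] = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fa), "fasta")]
    if not out:
        raise ValueError(f"no FASTA files in {path}")
    return out
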