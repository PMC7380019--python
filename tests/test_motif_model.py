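"""Motif profile construction, scanning, chaining and classification."""

import numpy as np
import pytest

from rflscan.motif_model import (
    AA_ALPHABET,
    DEFAULT_BACKGROUND,
    LENGTH_TOLERANCE,
    MotifHit,
    PprGeneModel,
    build_profile,
    chain_and_classify,
    max_weight_chain,
    read_profile,
    render_motif_structure,
    scan_protein,
    write_profile,
)

from conftest import random_protein


class TestBuildProfile:
    def test_single_sequence_pseudocounted_indicators(self):
        seed = ["A" * 31]
        prof = build_profile(seed, "P")
        a = AA_ALPHABET.index("A")
        # column frequency for the observed residue: (1+1)/(1+20)
        expected_obs = np.log2((2 / 21) / DEFAULT_BACKGROUND[a])
        expected_other = np.log2((1 / 21) / DEFAULT_BACKGROUND)
        assert np.allclose(prof.match_scores[:, a], expected_obs)
        mask = np.ones(20, bool)
        mask[a] = False
        assert np.allclose(prof.match_scores[0, mask], expected_other[mask])

    def test_two_sequence_column_tally(self):
        rows = ["A" * 31, "C" + "A" * 30]
        prof = build_profile(rows, "P")
        a, c = AA_ALPHABET.index("A"), AA_ALPHABET.index("C")
        # column 0: one A, one C -> (1+1)/22 each
        assert np.isclose(
            prof.match_scores[0, a], np.log2((2 / 22) / DEFAULT_BACKGROUND[a])
        )
        assert np.isclose(
            prof.match_scores[0, c], np.log2((2 / 22) / DEFAULT_BACKGROUND[c])
        )
        # column 1: two As -> (2+1)/22
        assert np.isclose(
            prof.match_scores[1, a], np.log2((3 / 22) / DEFAULT_BACKGROUND[a])
        )

    def test_ragged_rows_error(self):
        with pytest.raises(ValueError, match="unequal"):
            build_profile(["A" * 31, "A" * 30], "P")

    def test_empty_error(self):
        with pytest.raises(ValueError):
            build_profile([], "P")

    def test_emission_rows_normalise(self, p_profile):
        freqs = p_profile.background[None, :] * np.exp2(p_profile.match_scores)
        assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_hmmer_profile_import(self, tmp_path, profiles):
        """A HMMER3 HMM built from the packaged seed alignment imports as
        a working profile: the consensus still produces a strong hit."""
        import pyhmmer

        from rflscan.motif_model import read_hmm_profile

        from importlib.resources import files

        rows = [
            line
            for line in (files("rflscan.data") / "synthetic_p_motif_seed.afa")
            .read_text()
            .splitlines()
            if line and not line.startswith((">", ";"))
        ]
        alphabet = pyhmmer.easel.Alphabet.amino()
        msa = pyhmmer.easel.TextMSA(
            name=b"P",
            sequences=[
                pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=r)
                for i, r in enumerate(rows)
            ],
        )
        builder = pyhmmer.plan7.Builder(alphabet)
        hmm, _, _ = builder.build_msa(
            msa.digitize(alphabet), pyhmmer.plan7.Background(alphabet)
        )
        path = tmp_path / "p.hmm"
        with open(path, "wb") as fh:
            hmm.write(fh)
        prof = read_hmm_profile(path, "P")
        assert prof.length == 35
        consensus = profiles["P"].consensus
        hits = scan_protein("G" * 10 + consensus + "G" * 10, [prof])
        assert len(hits) == 1 and hits[0].score > 30

    def test_round_trip_text_format(self, tmp_path, p_profile):
        path = tmp_path / "p.prof"
        write_profile(p_profile, path)
        back = read_profile(path)
        assert back.class_label == "P"
        assert np.allclose(back.match_scores, p_profile.match_scores, atol=1e-4)


def oracle_window_dp(prof, protein, s, w):
    """Plain-python global affine alignment of the profile vs one window."""
    L = prof.length
    go, ge = prof.gap_open, prof.gap_extend
    NEG = -1e30
    ps = prof.position_scores(protein)
    M = [[NEG] * (w + 1) for _ in range(L + 1)]
    Ix = [[NEG] * (w + 1) for _ in range(L + 1)]
    Iy = [[NEG] * (w + 1) for _ in range(L + 1)]
    M[0][0] = 0.0
    for j in range(1, w + 1):
        Ix[0][j] = -go - (j - 1) * ge
    for i in range(1, L + 1):
        Iy[i][0] = -go - (i - 1) * ge
    for i in range(1, L + 1):
        for j in range(1, w + 1):
            M[i][j] = ps[i - 1, s + j - 1] + max(
                M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]
            )
            Ix[i][j] = max(M[i][j - 1] - go, Ix[i][j - 1] - ge)
            Iy[i][j] = max(M[i - 1][j] - go, Iy[i - 1][j] - ge)
    return max(M[L][w], Ix[L][w], Iy[L][w])


def oracle_scan(protein, profiles, thr=8.0):
    """Exhaustive all-windows scoring followed by the same chaining rule."""
    cands = []
    for prof in profiles:
        L = prof.length
        best = {}
        for w in range(max(1, L - LENGTH_TOLERANCE), L + LENGTH_TOLERANCE + 1):
            for s in range(0, len(protein) - w + 1):
                sc = oracle_window_dp(prof, protein, s, w)
                if sc > thr:
                    e = s + w - 1
                    cur = best.get(e)
                    if cur is None or sc > cur[0] or (sc == cur[0] and s < cur[1]):
                        best[e] = (sc, s)
        cands.extend(
            MotifHit(s + 1, e + 1, prof.class_label, float(sc))
            for e, (sc, s) in best.items()
        )
    return max_weight_chain(cands)


def as_tuples(hits):
    return [(h.start_aa, h.end_aa, h.class_label, round(h.score, 6)) for h in hits]


class TestScanProtein:
    def test_three_planted_consensus_copies(self, profiles, p_profile):
        cons = p_profile.consensus
        protein = "G" * 10 + cons + "A" * 10 + cons + "W" * 10 + cons + "K" * 10
        hits = scan_protein(protein, profiles.values())
        assert [(h.start_aa, h.end_aa, h.class_label) for h in hits] == [
            (11, 45, "P"),
            (56, 90, "P"),
            (101, 135, "P"),
        ]

    def test_shorter_than_profile_empty(self, profiles):
        assert scan_protein("ACDEF", profiles.values()) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_window_oracle(self, seed, profiles):
        rng = np.random.default_rng(seed)
        # random protein with one noisy planted motif so hits exist
        label = ["P", "L", "S"][seed % 3]
        motif = list(profiles[label].consensus)
        for p in rng.choice(len(motif), 6, replace=False):
            motif[p] = AA_ALPHABET[rng.integers(20)]
        protein = (
            random_protein(rng, 30) + "".join(motif) + random_protein(rng, 30)
        )
        fast = scan_protein(protein, profiles.values())
        slow = oracle_scan(protein, profiles.values())
        assert as_tuples(fast) == as_tuples(slow)

    def test_planted_motif_recovery_perfect(self, profiles, p_profile):
        """Recall and precision of hits are 1.0 for motifs planted at
        substitution rate <= 0.1."""
        rng = np.random.default_rng(42)
        cons = p_profile.consensus
        for _ in range(100):
            k = int(rng.integers(3, 7))
            linkers = [random_protein(rng, int(rng.integers(5, 30))) for _ in range(k + 1)]
            truth = []
            parts = [linkers[0]]
            pos = len(linkers[0])
            for i in range(k):
                motif = list(cons)
                for p in rng.choice(35, int(rng.integers(0, 4)), replace=False):
                    motif[p] = AA_ALPHABET[rng.integers(20)]
                parts.append("".join(motif))
                truth.append((pos + 1, pos + 35))
                pos += 35
                parts.append(linkers[i + 1])
                pos += len(linkers[i + 1])
            protein = "".join(parts)
            hits = scan_protein(protein, [p_profile])
            got = [(h.start_aa, h.end_aa) for h in hits]
            assert got == truth


class TestChainAndClassify:
    def _mk(self, n, score_each, label="P"):
        return [
            MotifHit(1 + 40 * i, 35 + 40 * i, label, score_each) for i in range(n)
        ]

    def test_p_class_above_100(self):
        model = chain_and_classify(self._mk(15, 101 / 15), "o", 600)
        assert model.family_class == "P"

    def test_score_exactly_100_is_not_p(self):
        model = chain_and_classify(self._mk(15, 100 / 15), "o", 600)
        assert model.family_class == "none"

    def test_pls_needs_l_and_s_and_240(self):
        hits = self._mk(4, 70, "P") + [
            MotifHit(500, 535, "L", 50),
            MotifHit(600, 630, "S", 50),
        ]
        assert chain_and_classify(hits, "o", 700).family_class == "PLS"
        # same score but no S motif: neither class
        hits2 = self._mk(4, 70, "P") + [MotifHit(500, 535, "L", 100)]
        assert chain_and_classify(hits2, "o", 700).family_class == "none"

    def test_empty_hits(self):
        model = chain_and_classify([], "o", 100)
        assert model.family_class == "none"
        assert model.structure_string == ""

    def test_score_additivity(self, profiles, p_profile):
        rng = np.random.default_rng(0)
        cons = p_profile.consensus
        protein = random_protein(rng, 20) + cons + "AG" + cons + random_protein(rng, 20)
        hits = scan_protein(protein, profiles.values())
        model = chain_and_classify(hits, "o", len(protein))
        assert model.protein_score == pytest.approx(sum(h.score for h in model.hits), abs=1e-12)

    def test_chain_matches_exhaustive_subset_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            hits = []
            for _ in range(n):
                s = int(rng.integers(1, 160))
                e = s + int(rng.integers(30, 40))
                hits.append(MotifHit(s, e, "P", float(rng.integers(9, 60))))
            best_total = 0.0
            for r in range(1, n + 1):
                for combo in combinations(hits, r):
                    ordered = sorted(combo)
                    if any(
                        b.start_aa <= a.end_aa
                        for a, b in zip(ordered, ordered[1:])
                    ):
                        continue
                    best_total = max(best_total, sum(h.score for h in combo))
            got = max_weight_chain(hits)
            assert sum(h.score for h in got) == pytest.approx(best_total)
            ordered = sorted(got)
            assert all(b.start_aa > a.end_aa for a, b in zip(ordered, ordered[1:]))


class TestStructureStringProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        data=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=60),  # gap before motif
                st.integers(min_value=31, max_value=39),  # motif span
            ),
            min_size=1,
            max_size=12,
        ),
        tail=st.integers(min_value=0, max_value=80),
    )
    @settings(max_examples=150, deadline=None)
    def test_tokens_reconstruct_protein_length(self, data, tail):
        """Segment tokens plus motif spans always sum to the protein
        length, and the token count reflects the motif count."""
        hits = []
        pos = 0
        for gap, span in data:
            start = pos + gap + 1
            hits.append(MotifHit(start, start + span - 1, "P", 10.0))
            pos = start + span - 1
        plen = pos + tail
        model = PprGeneModel("o", plen, hits, "P", 10.0 * len(hits))
        s = render_motif_structure(model)
        tokens = s.split("-") if s else []
        total = sum(int(t) for t in tokens if t.isdigit())
        spans = sum(h.span for h in hits)
        assert total + spans == plen
        assert sum(1 for t in tokens if t == "P") == len(hits)


class TestMotifStructure:
    def _model(self, hits, plen):
        return PprGeneModel("o", plen, sorted(hits), "P", sum(h.score for h in hits))

    def test_adjacent_motifs(self):
        m = self._model(
            [MotifHit(11, 45, "P", 50), MotifHit(46, 80, "P", 50)], 90
        )
        assert render_motif_structure(m) == "10-P-P-10"

    def test_interior_gap(self):
        m = self._model(
            [MotifHit(5, 39, "P", 50), MotifHit(75, 109, "P", 50)], 120
        )
        assert render_motif_structure(m) == "4-P-35-P-11"

    def test_no_motifs_empty_string(self):
        m = PprGeneModel("o", 100, [], "none", 0.0)
        assert render_motif_structure(m) == ""

    def test_zero_length_segments_omitted(self):
        m = self._model(
            [MotifHit(1, 35, "P", 50), MotifHit(36, 70, "P", 50)], 70
        )
        assert render_motif_structure(m) == "P-P"
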