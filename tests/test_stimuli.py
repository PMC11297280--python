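"""Lexicon filtering, neighborhood counts, and triplet/foil assembly."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smst.embedding import EmbeddingSpace, Phrase, phrase_similarity
from smst.errors import InfeasibilityError, ValidationError
from smst.stimuli import (
    FilterCriteria,
    LexicalEntry,
    SimilarityBands,
    StimulusSet,
    Triplet,
    TripletNotFound,
    build_triplet,
    count_phonological_neighbors,
    percentile_band_filter,
    rank_candidate_phrases,
    select_foils,
)


def _entry(token, pos="noun", freq=50.0, syll=3):
    return LexicalEntry(
        token=token, pos=pos, frequency=freq, char_count=len(token), syllable_count=syll
    )


class TestPercentileBandFilter:
    def test_short_word_excluded(self):
        # 6 characters is below the 7-13 band even with everything else interior
        entries = [_entry("abcdefg", freq=f) for f in (1, 50, 100)] + [_entry("abcdef", freq=50)]
        kept = percentile_band_filter(entries, FilterCriteria())
        assert all(e.char_count >= 7 for e in kept)
        assert not any(e.token == "abcdef" for e in kept)

    def test_interior_entry_kept(self):
        entries = [_entry(f"woord{i:02d}", freq=float(i)) for i in range(1, 100)]
        mid = _entry("middleww", freq=50.0, syll=2)
        kept = percentile_band_filter(entries + [mid], FilterCriteria())
        assert mid in kept

    def test_matches_bruteforce_percentile_scan(self):
        entries = [_entry(f"token{i:03d}", freq=float(i)) for i in range(1, 101)]
        crit = FilterCriteria(min_chars=1, max_chars=20, min_syll=1, max_syll=10)
        kept = percentile_band_filter(entries, crit)
        # oracle: nearest-rank percentile by explicit sort-and-rank
        freqs = sorted(e.frequency for e in entries)
        lo = freqs[max(1, math.ceil(0.35 * len(freqs))) - 1]
        hi = freqs[max(1, math.ceil(0.90 * len(freqs))) - 1]
        expected = [e for e in entries if lo <= e.frequency <= hi]
        assert kept == expected
        assert [e.frequency for e in kept] == list(range(35, 91))

    def test_order_preserved_and_per_pos_bands(self):
        nouns = [_entry(f"nounword{i:02d}", "noun", freq=float(i)) for i in range(1, 21)]
        adjs = [_entry(f"adjective{i:02d}", "adjective", freq=float(1000 + i)) for i in range(1, 21)]
        mixed = [x for pair in zip(nouns, adjs) for x in pair]
        kept = percentile_band_filter(mixed, FilterCriteria(freq_lo_pct=25, freq_hi_pct=75))
        # adjectives' much larger frequencies must be banded on their own scale
        assert any(e.pos == "adjective" for e in kept)
        assert any(e.pos == "noun" for e in kept)
        idx = [mixed.index(e) for e in kept]
        assert idx == sorted(idx)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            percentile_band_filter([], FilterCriteria())

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            FilterCriteria(freq_lo_pct=90, freq_hi_pct=35)


class TestPhonologicalNeighbors:
    @pytest.mark.parametrize(
        "word, lexicon, expected",
        [
            ("alma", ["alfa", "alga", "al", "alma"], 2),
            ("alma", [], 0),
            ("aaaa", ["aaab", "aaba", "abaa", "baaa", "aaaa"], 4),
            ("abc", ["abcd", "ab", "xbc"], 1),
        ],
    )
    def test_known_counts(self, word, lexicon, expected):
        assert count_phonological_neighbors(word, lexicon) == expected

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_bruteforce_hamming_scan(self, seed):
        rng = np.random.default_rng(seed)
        words = [
            "".join(rng.choice(list("abc"), size=rng.integers(2, 5)))
            for _ in range(30)
        ]
        w = words[0]
        oracle = sum(
            1
            for o in words
            if len(o) == len(w)
            and o != w
            and sum(a != b for a, b in zip(w, o)) == 1
        )
        assert count_phonological_neighbors(w, words) == oracle


def _band_space(noun_norm2=0.5):
    """Space where phrase similarity to the target is controllable.

    With unit adjectives orthogonal to the noun, phrase similarity
    s = (c + N2) / (1 + N2) for adjective-adjective cosine c and squared
    noun norm N2, so c = s*(1+N2) - N2 realizes any target s.
    """
    space = EmbeddingSpace(dim=8)
    space.add("nounx", np.concatenate([[0, 0], [math.sqrt(noun_norm2)], np.zeros(5)]))
    space.add("target", np.array([1.0, 0, 0, 0, 0, 0, 0, 0]))
    return space


def _add_adj_with_sim(space, name, s, noun_norm2=0.5):
    c = s * (1 + noun_norm2) - noun_norm2
    vec = np.zeros(8)
    # unit vector in the (target, spare) plane with dot product c against
    # the target adjective; orthogonal to the noun axis
    vec[0], vec[1] = c, math.sqrt(max(1 - c * c, 1e-12))
    space.add(name, vec)


class TestRankCandidatePhrases:
    def test_k_zero_empty(self, tiny_space):
        assert rank_candidate_phrases("n1", ["a1", "a2"], tiny_space, 0) == []

    def test_saturation_returns_all_sorted(self, tiny_space):
        out = rank_candidate_phrases("n1", ["a1", "a2"], tiny_space, 10)
        assert len(out) == 2
        sims = [s for _, s in out]
        assert sims == sorted(sims, reverse=True)

    def test_top3_matches_full_sort_oracle(self):
        rng = np.random.default_rng(42)
        space = EmbeddingSpace(dim=6)
        space.add("thenoun", rng.standard_normal(6))
        adjs = [f"adj{i}" for i in range(5)]
        for a in adjs:
            space.add(a, rng.standard_normal(6))
        out = rank_candidate_phrases("thenoun", adjs, space, 3)
        # oracle: full sort of all word-level cosines
        nv = space["thenoun"]
        sims = {
            a: float(np.dot(space[a], nv) / (np.linalg.norm(space[a]) * np.linalg.norm(nv)))
            for a in adjs
        }
        expected = sorted(adjs, key=lambda a: -sims[a])[:3]
        assert [p.adjective for p, _ in out] == expected


class TestBuildTriplet:
    def test_band_selection_from_known_similarities(self):
        space = _band_space()
        for name, s in (("closeadj", 0.72), ("distadj", 0.50), ("faradj", 0.30)):
            _add_adj_with_sim(space, name, s)
        t = build_triplet(
            "nounx", "target", ["closeadj", "distadj", "faradj"], space, SimilarityBands()
        )
        assert isinstance(t, Triplet)
        assert t.close_adj == "closeadj" and t.sim_close == pytest.approx(0.72, abs=1e-9)
        assert t.distant_adj == "distadj" and t.sim_distant == pytest.approx(0.50, abs=1e-9)

    def test_gap_between_bands_reports_both_empty(self):
        # 0.68 falls in the (0.65, 0.70) gap between the distant and close bands
        space = _band_space()
        for i in range(3):
            _add_adj_with_sim(space, f"gapadj{i}", 0.68)
        out = build_triplet(
            "nounx", "target", [f"gapadj{i}" for i in range(3)], space, SimilarityBands()
        )
        assert isinstance(out, TripletNotFound)
        assert set(out.empty_bands) == {"close", "distant"}

    def test_candidate_equal_to_target_rejected(self, tiny_space):
        with pytest.raises(ValidationError):
            build_triplet("n1", "a1", ["a1", "a2"], tiny_space, SimilarityBands())

    def test_matches_bruteforce_band_scan(self):
        rng = np.random.default_rng(7)
        space = EmbeddingSpace(dim=12)
        space.add("basenoun", rng.standard_normal(12) * 2)
        space.add("baseadj", rng.standard_normal(12))
        cands = [f"cand{i:02d}" for i in range(50)]
        for cname in cands:
            space.add(cname, rng.standard_normal(12))
        bands = SimilarityBands()
        out = build_triplet("basenoun", "baseadj", cands, space, bands)
        # oracle: exhaustive scan with phrase_similarity
        target = Phrase("baseadj", "basenoun")
        sims = {c: phrase_similarity(Phrase(c, "basenoun"), target, space) for c in cands}
        in_close = {c: s for c, s in sims.items() if bands.close_min <= s < 1}
        mid = (bands.distant_min + bands.distant_max) / 2
        in_dist = {
            c: s for c, s in sims.items() if bands.distant_min <= s <= bands.distant_max
        }
        if in_close and in_dist:
            assert isinstance(out, Triplet)
            assert out.close_adj == max(in_close, key=lambda c: (in_close[c], c))
            assert out.distant_adj == min(
                in_dist, key=lambda c: (abs(in_dist[c] - mid), c)
            )
        else:
            assert isinstance(out, TripletNotFound)


class TestSelectFoils:
    def _foil_space(self):
        space = EmbeddingSpace(dim=4)
        space.add("tadj", np.array([1.0, 0, 0, 0]))
        space.add("tnoun", np.array([0.0, 1, 0, 0]))
        space.add("nearadj", np.array([1.0, 0.5, 0, 0]))  # cosine 0.89 with tadj
        space.add("farad1", np.array([0.0, 0, 1, 0]))
        space.add("farad2", np.array([0.0, 0, 0, 1]))
        space.add("farad3", np.array([0.0, 0, 1, 1]))
        for i in range(4):
            v = np.zeros(4)
            v[2 + (i % 2)] = 1.0
            v[0] = 0.1
            space.add(f"fnoun{i}", v)
        return space

    def test_semantically_close_adjective_never_used(self):
        space = self._foil_space()
        targets = [Phrase("tadj", "tnoun")]
        foils = select_foils(
            ["fnoun0", "fnoun1"], ["nearadj", "farad1", "farad2"], targets, space,
            SimilarityBands(), 2,
        )
        assert len(foils) == 2
        assert all(f.adjective != "nearadj" for f in foils)

    def test_n_zero(self):
        space = self._foil_space()
        assert select_foils(["fnoun0"], ["farad1"], [], space, SimilarityBands(), 0) == []

    def test_pigeonhole_infeasibility(self):
        space = self._foil_space()
        targets = [Phrase("tadj", "tnoun")]
        with pytest.raises(InfeasibilityError, match="3"):
            select_foils(
                [f"fnoun{i}" for i in range(4)],
                ["nearadj", "farad1", "farad2", "farad3"],
                targets, space, SimilarityBands(), 4,
            )


class TestBuildStimulusSet:
    def test_paper_shaped_arithmetic(self, stimulus_set):
        trip, foil = stimulus_set.to_frames()
        assert len(trip) == 100 and len(foil) == 125
        # 3 phrases per triplet + 125 foil phrases; 225 distinct nouns
        assert 3 * len(trip) + len(foil) == 425
        assert trip.noun.nunique() + foil.noun.nunique() == 225
        adjs = (
            set(trip.target_adj) | set(trip.close_adj) | set(trip.distant_adj)
            | set(foil.adjective)
        )
        assert len(adjs) == 425  # no adjective reused anywhere

    def test_band_invariants_hold(self, stimulus_set, synthetic_world):
        space, _ = synthetic_world
        stimulus_set.validate(space, SimilarityBands())

    def test_seeded_build_reproducible(self, synthetic_world, tmp_path):
        space, lexicon = synthetic_world
        from smst.stimuli import build_stimulus_set

        a = build_stimulus_set(lexicon, space, n_triplets=5, n_foils=5, seed=11)
        b = build_stimulus_set(lexicon, space, n_triplets=5, n_foils=5, seed=11)
        a.to_tsv(tmp_path / "ta.tsv", tmp_path / "fa.tsv")
        b.to_tsv(tmp_path / "tb.tsv", tmp_path / "fb.tsv")
        assert (tmp_path / "ta.tsv").read_bytes() == (tmp_path / "tb.tsv").read_bytes()
        assert (tmp_path / "fa.tsv").read_bytes() == (tmp_path / "fb.tsv").read_bytes()

    def test_minimal_build(self, synthetic_world):
        space, lexicon = synthetic_world
        from smst.stimuli import build_stimulus_set

        ss = build_stimulus_set(lexicon, space, n_triplets=1, n_foils=0, seed=3)
        assert len(ss.triplets) == 1 and len(ss.foils) == 0

    def test_tsv_roundtrip(self, stimulus_set, tmp_path):
        stimulus_set.to_tsv(tmp_path / "t.tsv", tmp_path / "f.tsv")
        back = StimulusSet.from_tsv(tmp_path / "t.tsv", tmp_path / "f.tsv")
        assert back.triplets == stimulus_set.triplets
        assert back.foils == stimulus_set.foils

    def test_corrupt_table_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("noun\tclose_adj\nzoo\tbig\n")
        (tmp_path / "f.tsv").write_text("adjective\tnoun\n")
        with pytest.raises(ValidationError, match="missing columns"):
            StimulusSet.from_tsv(tmp_path / "bad.tsv", tmp_path / "f.tsv")


class TestTripletInvariants:
    def test_duplicate_adjectives_rejected(self):
        with pytest.raises(ValidationError):
            Triplet("zoo", "big", "big", "old", 0.8, 0.5)

    def test_band_assertion(self):
        t = Triplet("zoo", "big", "huge", "odd", sim_close=0.6, sim_distant=0.5)
        with pytest.raises(ValidationError, match="close"):
            t.assert_bands(SimilarityBands())
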