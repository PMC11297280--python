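"""Stimulus-set construction: lexicon filtering and similarity-banded triplets.

The recognition-memory design needs, for each shared noun, a *target*
adjective plus two lure adjectives graded by how semantically close the
resulting phrase is to the target phrase: a close lure (compound cosine
>= ``close_min``) and a distant lure (compound cosine inside
``[distant_min, distant_max]``). Foil phrases use novel nouns and
adjectives that are semantically unrelated to every target adjective.

Human curation steps of the original norming procedure (subjective
"meaningfulness" picks, pragmatic-fit vetoes) are replaced here by
deterministic rules: cosine rank order stands in for meaningfulness and a
greedy pass resolves adjective-reuse conflicts, so a seeded build is
exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from smst.embedding import EmbeddingSpace, Phrase
from smst.errors import InfeasibilityError, ValidationError

POS_VALUES = ("adjective", "noun")


@dataclass(frozen=True)
class LexicalEntry:
    """One row of a psycholinguistic lexicon table."""

    token: str
    pos: str
    frequency: float
    char_count: int
    syllable_count: int

    def __post_init__(self) -> None:
        if self.pos not in POS_VALUES:
            raise ValidationError(f"pos must be one of {POS_VALUES}, got {self.pos!r}")
        if self.frequency < 0:
            raise ValidationError(f"negative frequency for {self.token!r}")
        if self.char_count != len(self.token):
            raise ValidationError(
                f"char_count {self.char_count} != len({self.token!r})"
            )
        if self.syllable_count < 1:
            raise ValidationError(f"syllable_count < 1 for {self.token!r}")


@dataclass(frozen=True)
class FilterCriteria:
    """Lexical inclusion bounds.

    Frequency bounds are percentiles computed within part-of-speech
    (nearest-rank, inclusive); character and syllable bounds are absolute.
    """

    freq_lo_pct: float = 35.0
    freq_hi_pct: float = 90.0
    min_chars: int = 7
    max_chars: int = 13
    min_syll: int = 2
    max_syll: int = 6
    max_phon_neighbors: int = 5

    def __post_init__(self) -> None:
        pairs = [
            ("freq percentile", self.freq_lo_pct, self.freq_hi_pct),
            ("char count", self.min_chars, self.max_chars),
            ("syllable count", self.min_syll, self.max_syll),
        ]
        for name, lo, hi in pairs:
            if lo > hi:
                raise ValidationError(f"{name}: lower bound {lo} > upper bound {hi}")
            if lo <= 0 and name != "freq percentile":
                raise ValidationError(f"{name}: bounds must be positive")
        if not (0 <= self.freq_lo_pct <= 100 and 0 <= self.freq_hi_pct <= 100):
            raise ValidationError("frequency percentiles must lie in [0, 100]")
        if self.max_phon_neighbors < 0:
            raise ValidationError("max_phon_neighbors must be non-negative")


@dataclass(frozen=True)
class SimilarityBands:
    """Cosine-similarity bands for lure and foil admissibility.

    ``close_min``: close lures sit at or above this value.
    ``[distant_min, distant_max]``: distant lures sit inside this closed
    band; the default upper bound 0.65 leaves a buffer below the close
    band (the realized-stimulus criterion), so phrases falling in the gap
    (0.65, 0.70) serve as neither lure type.
    ``foil_adj_max``: a foil adjective must stay below this word-level
    cosine against every target adjective.
    """

    close_min: float = 0.70
    distant_min: float = 0.40
    distant_max: float = 0.65
    foil_adj_max: float = 0.70

    def __post_init__(self) -> None:
        if not (self.distant_min < self.distant_max <= self.close_min <= 1):
            raise ValidationError(
                "bands must satisfy distant_min < distant_max <= close_min <= 1"
            )


@dataclass(frozen=True)
class Triplet:
    """A noun with its target, close-lure and distant-lure adjectives."""

    noun: str
    target_adj: str
    close_adj: str
    distant_adj: str
    sim_close: float
    sim_distant: float

    def __post_init__(self) -> None:
        adjs = (self.target_adj, self.close_adj, self.distant_adj)
        if len(set(adjs)) != 3:
            raise ValidationError(f"adjectives must be pairwise distinct: {adjs}")

    def assert_bands(self, bands: SimilarityBands) -> None:
        if self.sim_close < bands.close_min:
            raise ValidationError(
                f"close-lure similarity {self.sim_close:.4f} < {bands.close_min}"
            )
        if not (bands.distant_min <= self.sim_distant <= bands.distant_max):
            raise ValidationError(
                f"distant-lure similarity {self.sim_distant:.4f} outside "
                f"[{bands.distant_min}, {bands.distant_max}]"
            )

    @property
    def target(self) -> Phrase:
        return Phrase(self.target_adj, self.noun)

    @property
    def close_lure(self) -> Phrase:
        return Phrase(self.close_adj, self.noun)

    @property
    def distant_lure(self) -> Phrase:
        return Phrase(self.distant_adj, self.noun)


@dataclass(frozen=True)
class TripletNotFound:
    """Report returned when a similarity band holds no candidate."""

    noun: str
    target_adj: str
    empty_bands: tuple[str, ...]


@dataclass
class StimulusSet:
    """The full stimulus pool: banded triplets plus foil phrases."""

    triplets: list[Triplet]
    foils: list[Phrase]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        triplet_nouns = [t.noun for t in self.triplets]
        if len(set(triplet_nouns)) != len(triplet_nouns):
            raise ValidationError("triplet nouns must be unique")
        overlap = set(triplet_nouns) & {f.noun for f in self.foils}
        if overlap:
            raise ValidationError(f"foil nouns overlap triplet nouns: {sorted(overlap)}")

    def validate(self, space: EmbeddingSpace, bands: SimilarityBands) -> None:
        """Re-check every similarity invariant against the embedding."""
        for t in self.triplets:
            t.assert_bands(bands)
        targets = sorted({t.target_adj for t in self.triplets})
        if targets and self.foils:
            tmat = space.matrix(targets)
            tmat = tmat / np.linalg.norm(tmat, axis=1, keepdims=True)
            for foil in self.foils:
                v = space[foil.adjective]
                sims = tmat @ (v / np.linalg.norm(v))
                if sims.max() >= bands.foil_adj_max:
                    raise ValidationError(
                        f"foil adjective {foil.adjective!r} has cosine "
                        f"{sims.max():.4f} >= {bands.foil_adj_max} with a target adjective"
                    )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        trip = pd.DataFrame(
            [
                {
                    "noun": t.noun,
                    "target_adj": t.target_adj,
                    "close_adj": t.close_adj,
                    "distant_adj": t.distant_adj,
                    "sim_close": t.sim_close,
                    "sim_distant": t.sim_distant,
                }
                for t in self.triplets
            ]
        )
        foil = pd.DataFrame(
            [{"adjective": f.adjective, "noun": f.noun} for f in self.foils]
        )
        return trip, foil

    def to_tsv(self, triplet_path: str | Path, foil_path: str | Path) -> None:
        trip, foil = self.to_frames()
        trip.to_csv(triplet_path, sep="\t", index=False)
        foil.to_csv(foil_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, triplet_path: str | Path, foil_path: str | Path, provenance: dict | None = None
    ) -> "StimulusSet":
        # round_trip: the default float parser can be off by one ulp,
        # which would break byte-identical reproducibility guarantees
        trip = pd.read_csv(triplet_path, sep="\t", float_precision="round_trip")
        foil = pd.read_csv(foil_path, sep="\t")
        required = {"noun", "target_adj", "close_adj", "distant_adj", "sim_close", "sim_distant"}
        missing = required - set(trip.columns)
        if missing:
            raise ValidationError(f"triplet table missing columns: {sorted(missing)}")
        triplets = [
            Triplet(
                noun=r.noun,
                target_adj=r.target_adj,
                close_adj=r.close_adj,
                distant_adj=r.distant_adj,
                sim_close=float(r.sim_close),
                sim_distant=float(r.sim_distant),
            )
            for r in trip.itertuples()
        ]
        foils = [Phrase(r.adjective, r.noun) for r in foil.itertuples()]
        return cls(triplets=triplets, foils=foils, provenance=provenance or {})


def read_lexicon(path: str | Path) -> list[LexicalEntry]:
    """Read a lexicon TSV with header token/pos/frequency/char_count/syllable_count."""
    df = pd.read_csv(path, sep="\t")
    return [
        LexicalEntry(
            token=str(r.token),
            pos=str(r.pos),
            frequency=float(r.frequency),
            char_count=int(r.char_count),
            syllable_count=int(r.syllable_count),
        )
        for r in df.itertuples()
    ]


def write_lexicon(entries: Sequence[LexicalEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "token": e.token,
                "pos": e.pos,
                "frequency": e.frequency,
                "char_count": e.char_count,
                "syllable_count": e.syllable_count,
            }
            for e in entries
        ]
    ).to_csv(path, sep="\t", index=False)


def _nearest_rank(sorted_vals: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: value at rank ceil(p/100 * n), 1-based."""
    n = len(sorted_vals)
    rank = max(1, math.ceil(pct / 100.0 * n))
    return float(sorted_vals[min(rank, n) - 1])


def percentile_band_filter(
    entries: Sequence[LexicalEntry], criteria: FilterCriteria
) -> list[LexicalEntry]:
    """Keep entries inside the frequency-percentile, length and syllable bands.

    Frequency percentiles are computed within each part-of-speech so that
    the (very different) adjective and noun frequency distributions are
    banded on their own scales. Input order is preserved.
    """
    if not entries:
        raise ValidationError("empty lexicon")
    bounds: dict[str, tuple[float, float]] = {}
    for pos in POS_VALUES:
        freqs = np.sort([e.frequency for e in entries if e.pos == pos])
        if len(freqs):
            bounds[pos] = (
                _nearest_rank(freqs, criteria.freq_lo_pct),
                _nearest_rank(freqs, criteria.freq_hi_pct),
            )
    kept = []
    for e in entries:
        lo, hi = bounds[e.pos]
        if not (lo <= e.frequency <= hi):
            continue
        if not (criteria.min_chars <= e.char_count <= criteria.max_chars):
            continue
        if not (criteria.min_syll <= e.syllable_count <= criteria.max_syll):
            continue
        kept.append(e)
    return kept


def count_phonological_neighbors(word: str, lexicon: Sequence[str]) -> int:
    """Count lexicon tokens at Hamming distance exactly 1 from ``word``.

    A phonological neighbor shares all but one character: same length,
    exactly one substituted position. Insertions/deletions do not count,
    and the word itself never counts.
    """
    if not word:
        raise ValidationError("empty word")
    n = 0
    L = len(word)
    for other in lexicon:
        if len(other) != L or other == word:
            continue
        mismatches = sum(1 for a, b in zip(word, other) if a != b)
        if mismatches == 1:
            n += 1
    return n


def phonological_neighbor_filter(
    entries: Sequence[LexicalEntry], max_neighbors: int
) -> list[LexicalEntry]:
    """Drop entries with more than ``max_neighbors`` Hamming-1 neighbors.

    Neighborhoods are counted against the full token set given, before any
    removal (so the filter is order-independent).
    """
    tokens = [e.token for e in entries]
    by_len: dict[int, list[str]] = {}
    for t in tokens:
        by_len.setdefault(len(t), []).append(t)
    kept = []
    for e in entries:
        pool = by_len.get(len(e.token), [])
        if count_phonological_neighbors(e.token, pool) <= max_neighbors:
            kept.append(e)
    return kept


def _token(x: LexicalEntry | str) -> str:
    return x.token if isinstance(x, LexicalEntry) else x


def rank_candidate_phrases(
    noun: LexicalEntry | str,
    adjectives: Sequence[LexicalEntry | str],
    space: EmbeddingSpace,
    k: int,
) -> list[tuple[Phrase, float]]:
    """Top-k adjective-noun pairings by word-level cosine, descending.

    Cosine between the *single-word* adjective and noun vectors serves as
    the meaningfulness proxy for candidate phrases. Ties break by
    lexicographic adjective order, so the ranking is deterministic.
    """
    if k < 0:
        raise ValidationError(f"k must be >= 0, got {k}")
    noun_tok = _token(noun)
    nv = space[noun_tok]
    nv = nv / np.linalg.norm(nv)
    adj_tokens = [_token(a) for a in adjectives]
    if not adj_tokens or k == 0:
        return []
    amat = space.matrix(adj_tokens)
    sims = (amat / np.linalg.norm(amat, axis=1, keepdims=True)) @ nv
    order = sorted(range(len(adj_tokens)), key=lambda i: (-sims[i], adj_tokens[i]))
    return [
        (Phrase(adj_tokens[i], noun_tok), float(sims[i])) for i in order[:k]
    ]


def _phrase_sims_to_target(
    noun: str, target_adj: str, candidates: Sequence[str], space: EmbeddingSpace
) -> np.ndarray:
    """Compound-vector cosine of each (candidate, noun) phrase with the target phrase."""
    nv = space[noun]
    tv = space[target_adj] + nv
    amat = space.matrix(list(candidates)) + nv
    return (amat @ tv) / (
        np.linalg.norm(amat, axis=1) * np.linalg.norm(tv)
    )


def build_triplet(
    noun: str,
    target_adj: str,
    candidates: Sequence[str],
    space: EmbeddingSpace,
    bands: SimilarityBands,
) -> Triplet | TripletNotFound:
    """Pick the close and distant lure adjectives for one target phrase.

    The close lure is the candidate whose phrase similarity to the target
    phrase is maximal within ``[close_min, 1)``; the distant lure is the
    candidate closest to the midpoint of the distant band, within it.
    Returns a :class:`TripletNotFound` naming the empty band(s) if either
    band holds no candidate.
    """
    cand = [_token(c) for c in candidates]
    if target_adj in cand:
        raise ValidationError(f"candidate list contains the target adjective {target_adj!r}")
    if not cand:
        return TripletNotFound(noun, target_adj, ("close", "distant"))
    sims = _phrase_sims_to_target(noun, target_adj, cand, space)

    close_idx = [i for i in range(len(cand)) if bands.close_min <= sims[i] < 1.0]
    distant_idx = [
        i for i in range(len(cand)) if bands.distant_min <= sims[i] <= bands.distant_max
    ]
    empty = tuple(
        name for name, idx in (("close", close_idx), ("distant", distant_idx)) if not idx
    )
    if empty:
        return TripletNotFound(noun, target_adj, empty)

    close_i = min(close_idx, key=lambda i: (-sims[i], cand[i]))
    mid = 0.5 * (bands.distant_min + bands.distant_max)
    distant_i = min(distant_idx, key=lambda i: (abs(sims[i] - mid), cand[i]))
    if cand[close_i] == cand[distant_i]:
        # a single candidate cannot serve both roles; drop it from the
        # distant band and retry there (close band keeps its maximum)
        distant_idx = [i for i in distant_idx if i != distant_i]
        if not distant_idx:
            return TripletNotFound(noun, target_adj, ("distant",))
        distant_i = min(distant_idx, key=lambda i: (abs(sims[i] - mid), cand[i]))

    return Triplet(
        noun=noun,
        target_adj=target_adj,
        close_adj=cand[close_i],
        distant_adj=cand[distant_i],
        sim_close=float(sims[close_i]),
        sim_distant=float(sims[distant_i]),
    )


def select_foils(
    nouns: Sequence[LexicalEntry | str],
    adjectives: Sequence[LexicalEntry | str],
    targets: Sequence[Phrase],
    space: EmbeddingSpace,
    bands: SimilarityBands,
    n: int,
) -> list[Phrase]:
    """Assemble ``n`` foil phrases from novel nouns and unrelated adjectives.

    Each noun is used at most once and every foil adjective keeps a
    word-level cosine below ``foil_adj_max`` against *every* target
    adjective. Nouns are paired greedily with the admissible adjective
    most similar to them (then never reused), so foils remain plausible
    phrases while staying semantically unrelated to the targets.
    """
    noun_toks = [_token(x) for x in nouns]
    adj_toks = [_token(x) for x in adjectives]
    target_nouns = {t.noun for t in targets}
    clash = set(noun_toks) & target_nouns
    if clash:
        raise ValidationError(f"foil nouns overlap target nouns: {sorted(clash)}")
    if n == 0:
        return []

    target_adjs = sorted({t.adjective for t in targets})
    if target_adjs:
        tmat = space.matrix(target_adjs)
        tmat = tmat / np.linalg.norm(tmat, axis=1, keepdims=True)
        admissible = []
        for a in adj_toks:
            v = space[a]
            if (tmat @ (v / np.linalg.norm(v))).max() < bands.foil_adj_max:
                admissible.append(a)
    else:
        admissible = list(adj_toks)

    max_achievable = min(len(admissible), len(noun_toks))
    if n > max_achievable:
        raise InfeasibilityError(
            f"requested {n} foils but at most {max_achievable} achievable "
            f"({len(admissible)} admissible adjectives, {len(noun_toks)} nouns)"
        )

    amat = space.matrix(admissible)
    amat = amat / np.linalg.norm(amat, axis=1, keepdims=True)
    used: set[str] = set()
    foils: list[Phrase] = []
    for noun in noun_toks[:n]:
        nv = space[noun]
        sims = amat @ (nv / np.linalg.norm(nv))
        order = sorted(
            range(len(admissible)), key=lambda i: (-sims[i], admissible[i])
        )
        pick = next(
            (admissible[i] for i in order if admissible[i] not in used and admissible[i] != noun),
            None,
        )
        if pick is None:
            raise InfeasibilityError(
                f"admissible adjective pool exhausted after {len(foils)} foils"
            )
        used.add(pick)
        foils.append(Phrase(pick, noun))
    return foils


def build_stimulus_set(
    lexicon: Sequence[LexicalEntry],
    space: EmbeddingSpace,
    criteria: FilterCriteria | None = None,
    bands: SimilarityBands | None = None,
    n_triplets: int = 100,
    n_foils: int = 125,
    seed: int = 0,
    top_k: int = 10,
) -> StimulusSet:
    """Filter the lexicon and assemble the full banded stimulus set.

    The build is greedy and seeded: nouns are processed in a seeded
    shuffle order; for each triplet noun the target adjective is taken
    from the top-``top_k`` candidate ranking (highest word-level cosine =
    the meaningfulness proxy), lures are banded by compound-phrase
    cosine, and no adjective is ever reused across phrases. Remaining
    nouns supply foils. Raises :class:`InfeasibilityError` naming the
    binding constraint when the pool cannot support the request.
    """
    criteria = criteria or FilterCriteria()
    bands = bands or SimilarityBands()

    filtered = percentile_band_filter(lexicon, criteria)
    filtered = phonological_neighbor_filter(filtered, criteria.max_phon_neighbors)
    filtered = [e for e in filtered if e.token in space]

    nouns = sorted(e.token for e in filtered if e.pos == "noun")
    adjectives = sorted(e.token for e in filtered if e.pos == "adjective")
    if len(nouns) < n_triplets + n_foils:
        raise InfeasibilityError(
            f"need {n_triplets + n_foils} nouns after filtering, have {len(nouns)}"
        )

    rng = np.random.default_rng(seed)
    noun_order = list(rng.permutation(nouns))

    used_adjs: set[str] = set()
    triplets: list[Triplet] = []
    consumed_nouns: list[str] = []
    for noun in noun_order:
        if len(triplets) == n_triplets:
            break
        avail = [a for a in adjectives if a not in used_adjs and a != noun]
        ranked = rank_candidate_phrases(noun, avail, space, k=top_k)
        built: Triplet | None = None
        for target_phrase, _sim in ranked:
            target_adj = target_phrase.adjective
            cand = [a for a in avail if a != target_adj]
            result = build_triplet(noun, target_adj, cand, space, bands)
            if isinstance(result, Triplet):
                built = result
                break
        if built is not None:
            built.assert_bands(bands)
            triplets.append(built)
            used_adjs.update({built.target_adj, built.close_adj, built.distant_adj})
            consumed_nouns.append(noun)

    if len(triplets) < n_triplets:
        raise InfeasibilityError(
            f"only {len(triplets)} of {n_triplets} triplets satisfiable: "
            "no noun left with candidates in both similarity bands"
        )

    foil_nouns = [n for n in noun_order if n not in consumed_nouns][:n_foils]
    avail_adjs = [a for a in adjectives if a not in used_adjs]
    foils = select_foils(
        foil_nouns,
        avail_adjs,
        [t.target for t in triplets],
        space,
        bands,
        n_foils,
    )

    provenance = {
        "seed": int(seed),
        "n_triplets": n_triplets,
        "n_foils": n_foils,
        "criteria": vars(criteria).copy(),
        "bands": vars(bands).copy(),
        "lexicon_size": len(lexicon),
        "filtered_size": len(filtered),
    }
    return StimulusSet(triplets=triplets, foils=foils, provenance=provenance)
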