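"""Synthetic embedding spaces and lexicon tables for pipeline exercise.

The generator emulates the two structural facts the stimulus pipeline
relies on in a real word embedding trained on a large corpus:

* semantic neighborhoods — tokens cluster around themes, so same-cluster
  cosine similarities stochastically exceed cross-cluster ones.  Cluster
  centroids are drawn inside a random low-dimensional subspace of the
  embedding space, which spreads *cross*-cluster cosines over a wide
  range (as between loosely related topics) instead of concentrating
  them at zero; token vectors scatter around their centroid in the full
  space.
* psycholinguistic marginals — corpus frequencies follow a Zipf law, and
  word lengths / syllable counts span (and deliberately exceed) the
  lexical filter bounds so filtering has real work to do.

Tokens are pronounceable consonant-vowel strings, so the character and
syllable counts in the lexicon table are consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from smst.embedding import EmbeddingSpace
from smst.errors import ValidationError
from smst.stimuli import LexicalEntry

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic embedding + lexicon generator."""

    n_nouns: int = 700
    n_adjectives: int = 2200
    dim: int = 200
    n_clusters: int = 24
    cluster_spread: float = 0.7
    zipf_exponent: float = 1.1
    centroid_subspace_dim: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValidationError("dim must be >= 2")
        if self.n_clusters > self.n_nouns:
            raise ValidationError("n_clusters must not exceed n_nouns")
        if self.cluster_spread <= 0:
            raise ValidationError("cluster_spread must be positive")
        if not (1 <= self.centroid_subspace_dim <= self.dim):
            raise ValidationError("centroid_subspace_dim must lie in [1, dim]")


def _make_token(rng: np.random.Generator, n_syllables: int) -> tuple[str, int]:
    """A pronounceable token built from CV / CVC syllables."""
    parts = []
    for _ in range(n_syllables):
        syl = rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        if rng.random() < 0.35:
            syl += rng.choice(list(_CONSONANTS))
        parts.append(syl)
    return "".join(parts), n_syllables


def _make_tokens(rng: np.random.Generator, n: int, taken: set[str]) -> list[tuple[str, int]]:
    # syllable distribution centered on the 2-6 filter band but spilling
    # outside it so the lexical filter is exercised
    syll_choices = np.arange(1, 8)
    syll_probs = np.array([0.04, 0.10, 0.26, 0.30, 0.18, 0.08, 0.04])
    out: list[tuple[str, int]] = []
    while len(out) < n:
        s = int(rng.choice(syll_choices, p=syll_probs))
        token, syl = _make_token(rng, s)
        if token in taken:
            continue
        taken.add(token)
        out.append((token, syl))
    return out


def _cluster_vectors(
    rng: np.random.Generator, n: int, cfg: FixtureConfig, centroids: np.ndarray
) -> np.ndarray:
    labels = rng.integers(0, cfg.n_clusters, size=n)
    noise = rng.standard_normal((n, cfg.dim)) * (cfg.cluster_spread / np.sqrt(cfg.dim))
    vecs = centroids[labels] + noise
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    # word2vec norms are not unity; jitter magnitudes (cosines unaffected)
    vecs *= rng.uniform(0.8, 1.2, size=(n, 1))
    return vecs


def generate_fixture_embedding(
    config: FixtureConfig,
) -> tuple[EmbeddingSpace, list[LexicalEntry]]:
    """Generate a clustered embedding space and a matching lexicon table.

    Returns the embedding plus one :class:`LexicalEntry` per token with
    Zipf-distributed frequencies (ranks shuffled within part-of-speech)
    and length/syllable marginals spanning the default filter bounds.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    # cluster centroids: unit vectors inside a random low-dim subspace
    basis, _ = np.linalg.qr(rng.standard_normal((config.dim, config.centroid_subspace_dim)))
    u = rng.standard_normal((config.n_clusters, config.centroid_subspace_dim))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    centroids = u @ basis.T

    taken: set[str] = set()
    noun_tokens = _make_tokens(rng, config.n_nouns, taken)
    adj_tokens = _make_tokens(rng, config.n_adjectives, taken)

    space = EmbeddingSpace(dim=config.dim)
    entries: list[LexicalEntry] = []
    for pos, tokens in (("noun", noun_tokens), ("adjective", adj_tokens)):
        vecs = _cluster_vectors(rng, len(tokens), config, centroids)
        ranks = rng.permutation(len(tokens)) + 1
        freqs = 1e6 * ranks.astype(float) ** (-config.zipf_exponent)
        for (token, syl), vec, freq in zip(tokens, vecs, freqs):
            space.add(token, vec)
            entries.append(
                LexicalEntry(
                    token=token,
                    pos=pos,
                    frequency=float(freq),
                    char_count=len(token),
                    syllable_count=syl,
                )
            )
    return space, entries
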