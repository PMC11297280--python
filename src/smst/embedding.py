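"""Word-embedding I/O and compound-phrase cosine similarity.

Phrases are adjective-noun pairs; a phrase is represented by the
component-wise *sum* of the two word vectors (a compound vector), and
phrase similarity is the cosine of the angle between compound vectors.
Both the text and binary word2vec dialects are supported.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from smst.errors import (
    DimensionError,
    DuplicateTokenError,
    FormatError,
    LookupError_,
    UndefinedSimilarityError,
    ValidationError,
)

#: vectors with L2 norm below this are rejected at load time so the cosine
#: precondition (non-zero inputs) is checkable once
ZERO_NORM_TOL = 1e-12


@dataclass(frozen=True)
class Phrase:
    """An adjective-noun phrase, e.g. ('exotic', 'zoo')."""

    adjective: str
    noun: str

    def __post_init__(self) -> None:
        if not self.adjective or not self.noun:
            raise ValidationError("phrase tokens must be non-empty")
        if self.adjective == self.noun:
            raise ValidationError(
                f"adjective and noun must differ (both {self.adjective!r})"
            )

    def __str__(self) -> str:
        return f"{self.adjective} {self.noun}"


@dataclass
class EmbeddingSpace:
    """A token -> dense-vector map with a fixed dimensionality.

    Invariants enforced at construction: every vector has exactly ``dim``
    finite components, tokens are unique, and no vector is (near-)zero.
    """

    dim: int
    entries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValidationError(f"dim must be positive, got {self.dim}")
        normalized: dict[str, np.ndarray] = {}
        for token, vec in self.entries.items():
            normalized[token] = self._validate(token, vec)
        self.entries = normalized

    def _validate(self, token: str, vec: np.ndarray) -> np.ndarray:
        if not token:
            raise ValidationError("empty token")
        v = np.asarray(vec, dtype=np.float64)
        if v.shape != (self.dim,):
            raise DimensionError(
                f"vector for {token!r} has {v.size} components, expected {self.dim}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"non-finite component in vector for {token!r}")
        if np.linalg.norm(v) < ZERO_NORM_TOL:
            raise ValidationError(f"zero vector for token {token!r}")
        return v

    def __contains__(self, token: str) -> bool:
        return token in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __getitem__(self, token: str) -> np.ndarray:
        try:
            return self.entries[token]
        except KeyError:
            raise LookupError_(f"token {token!r} has no embedding") from None

    def add(self, token: str, vec: np.ndarray) -> None:
        if token in self.entries:
            raise DuplicateTokenError(f"duplicate token {token!r}")
        self.entries[token] = self._validate(token, vec)

    def matrix(self, tokens: list[str]) -> np.ndarray:
        """Stack vectors for ``tokens`` into a (len(tokens), dim) array."""
        return np.stack([self[t] for t in tokens])


def load_embedding(path: str | Path, dialect: str = "word2vec-text") -> EmbeddingSpace:
    """Load a word2vec-format embedding file.

    Parameters
    ----------
    path
        Path to the embedding file.
    dialect
        ``"word2vec-text"`` (whitespace-separated UTF-8, optional
        ``"<count> <dim>"`` header) or ``"word2vec-binary"`` (ASCII header
        then little-endian float32 vectors).
    """
    path = Path(path)
    if dialect == "word2vec-text":
        return _load_text(path)
    if dialect == "word2vec-binary":
        return _load_binary(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_text(path: Path) -> EmbeddingSpace:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")

    first = lines[0].split()
    start = 0
    declared_count: int | None = None
    dim: int | None = None
    if len(first) == 2:
        # header line "<count> <dim>"
        try:
            declared_count, dim = int(first[0]), int(first[1])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed header line: {lines[0]!r}") from exc
        if declared_count < 0 or dim <= 0:
            raise FormatError(f"{path}: malformed header line: {lines[0]!r}")
        start = 1

    space: EmbeddingSpace | None = None
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split()
        token, comps = parts[0], parts[1:]
        if dim is None:
            dim = len(comps)
            if dim == 0:
                raise FormatError(f"{path}: line {lineno}: no vector components")
        if len(comps) != dim:
            raise FormatError(
                f"{path}: line {lineno}: expected {dim} components, got {len(comps)}"
            )
        try:
            vec = np.array(comps, dtype=np.float64)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric component") from exc
        if space is None:
            space = EmbeddingSpace(dim=dim)
        space.add(token, vec)

    if space is None:
        raise FormatError(f"{path}: no vectors found")
    if declared_count is not None and len(space) != declared_count:
        raise FormatError(
            f"{path}: header declares {declared_count} tokens, found {len(space)}"
        )
    return space


def _load_binary(path: Path) -> EmbeddingSpace:
    with open(path, "rb") as fh:
        header = b""
        while not header.endswith(b"\n"):
            ch = fh.read(1)
            if not ch:
                raise FormatError(f"{path}: truncated header")
            header += ch
        parts = header.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed header {header!r}")
        try:
            count, dim = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed header {header!r}") from exc
        space = EmbeddingSpace(dim=dim)
        for i in range(count):
            token_bytes = b""
            while True:
                ch = fh.read(1)
                if not ch:
                    raise FormatError(f"{path}: truncated at entry {i}")
                if ch == b" ":
                    break
                if ch != b"\n":  # some writers pad with newlines
                    token_bytes += ch
            raw = fh.read(4 * dim)
            if len(raw) != 4 * dim:
                raise FormatError(f"{path}: truncated vector at entry {i}")
            vec = np.frombuffer(raw, dtype="<f4").astype(np.float64)
            space.add(token_bytes.decode("utf-8"), vec)
    return space


def write_embedding(
    space: EmbeddingSpace, path: str | Path, dialect: str = "word2vec-text"
) -> None:
    """Write an EmbeddingSpace in the chosen word2vec dialect."""
    path = Path(path)
    if dialect == "word2vec-text":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(space)} {space.dim}\n")
            for token, vec in space.entries.items():
                comps = " ".join(repr(float(x)) for x in vec)
                fh.write(f"{token} {comps}\n")
    elif dialect == "word2vec-binary":
        with open(path, "wb") as fh:
            fh.write(f"{len(space)} {space.dim}\n".encode("utf-8"))
            for token, vec in space.entries.items():
                fh.write(token.encode("utf-8") + b" ")
                fh.write(struct.pack(f"<{space.dim}f", *vec.astype(np.float32)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def compound_vector(phrase: Phrase, space: EmbeddingSpace) -> np.ndarray:
    """Component-wise sum of the adjective and noun vectors.

    Summation (not averaging, no pre-normalization) preserves the
    aggregate-meaning representation used to norm the stimuli.
    """
    return space[phrase.adjective] + space[phrase.noun]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors: (a.b)/(||a|| ||b||)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < ZERO_NORM_TOL or nb < ZERO_NORM_TOL:
        raise UndefinedSimilarityError("cosine similarity undefined for zero vector")
    return float(np.dot(a, b) / (na * nb))


def phrase_similarity(p1: Phrase, p2: Phrase, space: EmbeddingSpace) -> float:
    """Cosine similarity between the compound vectors of two phrases."""
    return cosine_similarity(compound_vector(p1, space), compound_vector(p2, space))
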