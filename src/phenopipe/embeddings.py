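"""Sentence embedding backends behind a uniform sentence→vector contract.

Every backend maps a list of sentence strings to an ``(n, dim)`` float matrix,
deterministically: a fixed ``backend_id`` implies bitwise-reproducible
vectors.  Two backends ship by default:

``hashing``
    A seeded feature-hashing embedder: token n-grams are hashed into ``dim``
    signed buckets and the bucket counts are L2-normalized.  It is pure
    Python + NumPy, fully offline, and the default for tests and pipelines.

``transformer:<model-name>``
    Mean-pooled final-layer hidden states of a pretrained transformer
    (requires the optional ``transformers`` + ``torch`` stack; construction
    raises :class:`BackendUnavailableError` when absent — never a silent
    fallback).

Embeddings can be cached on disk keyed by (backend_id, text hash) so a corpus
is embedded once per backend.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EmbeddingBackend",
    "HashingBackend",
    "TransformerBackend",
    "BackendUnavailableError",
    "EmbeddingCache",
    "get_backend",
]


class BackendUnavailableError(RuntimeError):
    """The requested backend's dependencies or weights are not available."""


_TOKEN_RE = re.compile(r"\w+(?:'\w+)?", re.UNICODE)


class EmbeddingBackend:
    """Abstract sentence→vector contract.

    Subclasses must set ``backend_id``, ``dim`` and ``max_tokens`` (``None``
    for unlimited) and implement :meth:`_embed_one`.  ``embed`` is a pure
    function of ``(backend_id, text)``.
    """

    backend_id: str
    dim: int
    max_tokens: int | None = None

    def tokens(self, text: str) -> list[str]:
        return _TOKEN_RE.findall(text.lower())

    def tokenize_count(self, text: str) -> int:
        """Token count under this backend's tokenizer (>= 1 for non-empty
        text, so per-sentence statistics never hit an empty denominator)."""
        return max(1, len(self.tokens(text)))

    def _truncate(self, toks: list[str]) -> list[str]:
        if self.max_tokens is not None and len(toks) > self.max_tokens:
            return toks[: self.max_tokens]
        return toks

    def _embed_one(self, text: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        """Embed sentences; row i corresponds to texts[i]."""
        if any(t == "" for t in texts):
            raise ValueError("cannot embed an empty string")
        out = np.empty((len(texts), self.dim), dtype=np.float64)
        for i, t in enumerate(texts):
            v = self._embed_one(t)
            if v.shape != (self.dim,):
                raise AssertionError(
                    f"backend {self.backend_id} produced shape {v.shape}"
                )
            out[i] = v
        return out


class HashingBackend(EmbeddingBackend):
    """Seeded feature-hashing sentence embedder.

    Each token n-gram (unigrams and bigrams by default) is hashed with
    BLAKE2b, salted by ``(backend_id, seed)``, to a signed bucket in
    ``[0, dim)``; signed counts are accumulated and the vector is
    L2-normalized.  Sentences with disjoint vocabulary are orthogonal (up to
    hash collisions), which makes category-specific vocabularies linearly
    separable — the property the offline test pipeline relies on.
    """

    def __init__(self, dim: int = 768, seed: int = 0, ngrams: tuple[int, ...] = (1, 2),
                 max_tokens: int | None = None):
        if dim < 1:
            raise ValueError("dim must be positive")
        self.dim = dim
        self.seed = seed
        self.ngrams = ngrams
        self.max_tokens = max_tokens
        self.backend_id = f"hashing-d{dim}-s{seed}-n{''.join(map(str, ngrams))}"
        self._salt = self.backend_id.encode()

    def _bucket_sign(self, gram: str) -> tuple[int, int]:
        h = hashlib.blake2b(gram.encode("utf-8"), key=self._salt[:64],
                            digest_size=8).digest()
        val = int.from_bytes(h, "big")
        return (val >> 1) % self.dim, 1 if val & 1 else -1

    def _embed_one(self, text: str) -> np.ndarray:
        toks = self._truncate(self.tokens(text))
        v = np.zeros(self.dim, dtype=np.float64)
        for n in self.ngrams:
            for i in range(len(toks) - n + 1):
                bucket, sign = self._bucket_sign(" ".join(toks[i : i + n]))
                v[bucket] += sign
        norm = np.linalg.norm(v)
        if norm > 0:
            v /= norm
        return v


class TransformerBackend(EmbeddingBackend):
    """Mean-pooled (configurable to first-token-pooled) final-layer hidden
    states of a pretrained transformer.  Inputs beyond ``max_tokens``
    (default 512) are head-truncated by the model tokenizer."""

    def __init__(self, model_name: str, pooling: str = "mean",
                 max_tokens: int = 512):
        if pooling not in ("mean", "first"):
            raise ValueError("pooling must be 'mean' or 'first'")
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:
            raise BackendUnavailableError(
                f"transformer backend {model_name!r} requires the optional "
                "'torch' and 'transformers' packages"
            ) from exc
        self._torch = torch
        try:
            self._tokenizer = AutoTokenizer.from_pretrained(model_name)
            self._model = AutoModel.from_pretrained(model_name)
        except Exception as exc:  # weights absent / offline
            raise BackendUnavailableError(
                f"could not load transformer weights for {model_name!r}: {exc}"
            ) from exc
        self._model.eval()
        self.pooling = pooling
        self.max_tokens = max_tokens
        self.dim = int(self._model.config.hidden_size)
        self.backend_id = f"transformer-{model_name}-{pooling}"

    def tokens(self, text: str) -> list[str]:
        return self._tokenizer.tokenize(text)

    def _embed_one(self, text: str) -> np.ndarray:
        torch = self._torch
        enc = self._tokenizer(text, truncation=True, max_length=self.max_tokens,
                              return_tensors="pt")
        with torch.no_grad():
            hidden = self._model(**enc).last_hidden_state[0]
        if self.pooling == "mean":
            vec = hidden.mean(dim=0)
        else:
            vec = hidden[0]
        return vec.numpy().astype(np.float64)


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    """Backend factory: ``"hashing"`` or ``"transformer:<model-name>"``."""
    if name == "hashing":
        return HashingBackend(**kwargs)
    if name.startswith("transformer:"):
        return TransformerBackend(name.split(":", 1)[1], **kwargs)
    raise ValueError(f"unknown embedding backend {name!r}")


class EmbeddingCache:
    """On-disk embedding cache: one float matrix + JSON index per backend.

    Keyed by (backend_id, SHA1 of text); re-embedding a corpus with the same
    backend is a pure lookup.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _paths(self, backend_id: str) -> tuple[Path, Path]:
        stem = hashlib.sha1(backend_id.encode()).hexdigest()[:16]
        return (self.directory / f"{stem}.npy", self.directory / f"{stem}.json")

    @staticmethod
    def _key(text: str) -> str:
        return hashlib.sha1(text.encode("utf-8")).hexdigest()

    def embed(self, backend: EmbeddingBackend, texts: Sequence[str]) -> np.ndarray:
        mat_path, idx_path = self._paths(backend.backend_id)
        if idx_path.exists():
            index = json.loads(idx_path.read_text())
            matrix = np.load(mat_path)
        else:
            index = {"backend_id": backend.backend_id, "dim": backend.dim,
                     "keys": {}}
            matrix = np.empty((0, backend.dim))
        keys = index["keys"]
        missing = [t for t in dict.fromkeys(texts) if self._key(t) not in keys]
        if missing:
            new = backend.embed(missing)
            base = matrix.shape[0]
            for j, t in enumerate(missing):
                keys[self._key(t)] = base + j
            matrix = np.vstack([matrix, new]) if base else new
            np.save(mat_path, matrix)
            idx_path.write_text(json.dumps(index))
        rows = [keys[self._key(t)] for t in texts]
        return matrix[rows]
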