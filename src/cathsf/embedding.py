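"""Per-domain embeddings: residue-level embedding, mean pooling, channels.

A protein language model (pLM) turns a sequence of L symbols into an
L×d matrix of per-residue vectors; mean pooling over residues gives one
fixed-length vector per domain.  Two channels exist: AA (amino-acid
sequence embeddings) and 3Di (structural-alphabet sequence embeddings);
the classifier input is one channel or their concatenation, always in
fixed AA-then-3Di order.

Real pLMs (ProstT5, ProtT5, ESM2, Ankh, TM-Vec, ...) are reached through
the :class:`Embedder` adapter contract and are not bundled; their output
dimensionality is read from the adapter, never hard-coded.  A
deterministic hash-lookup mock embedder makes the pipeline testable
offline.  Pooled vectors are cached in an HDF5 store, one group per
channel, one dataset per domain id, float32.

Pooled vectors are not normalized or standardized by default; an optional
per-feature standardization (fitted on training data only) is available in
the classifier config.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Optional, Protocol, runtime_checkable

import h5py
import numpy as np

from .errors import ChannelMismatchError, IntegrityError
from .sa_encoding import SA_ALPHABET, SAString

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"  # 20 amino acids + unknown

CHANNELS = ("AA", "3Di")
INPUT_TYPES = ("AA", "3Di", "AA+3Di")

__all__ = [
    "AA_ALPHABET", "CHANNELS", "INPUT_TYPES",
    "ResidueEmbeddingMatrix", "PooledEmbedding", "Embedder",
    "HashLookupEmbedder", "embed_with", "pool_mean", "build_input_vector",
    "EmbeddingStore",
]


@dataclass(frozen=True)
class ResidueEmbeddingMatrix:
    """L×d per-residue embedding of one domain in one channel."""

    domain_id: str
    values: np.ndarray
    embedder_id: str
    channel: str

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise IntegrityError(f"unknown channel {self.channel!r}")
        if self.values.ndim != 2:
            raise IntegrityError("embedding matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError(
                f"non-finite embedding values for {self.domain_id!r}")


@dataclass(frozen=True)
class PooledEmbedding:
    """Fixed-length per-domain vector with channel provenance."""

    domain_id: str
    vector: np.ndarray
    channel: str  # "AA" | "3Di" | "AA+3Di"
    embedder_ids: tuple[str, ...]

    def __post_init__(self):
        if self.channel not in INPUT_TYPES:
            raise IntegrityError(f"unknown channel {self.channel!r}")
        if self.vector.ndim != 1:
            raise IntegrityError("pooled vector must be 1-D")

    @property
    def dim(self) -> int:
        return int(self.vector.shape[0])


@runtime_checkable
class Embedder(Protocol):
    """Adapter contract for a per-residue embedder.

    ``alphabet`` declares the symbols the embedder accepts (which decides
    the channel), ``dim`` its output dimensionality.
    """

    embedder_id: str
    channel: str
    alphabet: str
    dim: int

    def embed(self, sequence: str) -> np.ndarray: ...


class HashLookupEmbedder:
    """Deterministic mock embedder: a fixed lookup per (symbol, parity).

    The vector for position *i* holding symbol *s* depends only on *s* and
    on ``i % 2``; each lookup entry is drawn from an RNG seeded by a stable
    hash of ``(embedder_id, symbol, parity)``, so the table is identical
    across processes.  The position-parity dependence makes pooling
    order-sensitive enough to catch indexing bugs without modelling any
    real pLM geometry.
    """

    def __init__(self, channel: str = "AA", dim: int = 16,
                 embedder_id: Optional[str] = None):
        if channel not in CHANNELS:
            raise IntegrityError(f"unknown channel {channel!r}")
        self.channel = channel
        self.alphabet = AA_ALPHABET if channel == "AA" else SA_ALPHABET
        self.dim = dim
        self.embedder_id = embedder_id or f"mock-{channel.lower()}-d{dim}"
        self._table = {
            (sym, parity): self._entry(sym, parity)
            for sym in self.alphabet for parity in (0, 1)
        }

    def _entry(self, symbol: str, parity: int) -> np.ndarray:
        key = f"{self.embedder_id}:{symbol}:{parity}".encode()
        seed = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
        return np.random.default_rng(seed).standard_normal(self.dim)

    def embed(self, sequence: str) -> np.ndarray:
        return np.stack([self._table[(s, i % 2)]
                         for i, s in enumerate(sequence)])


def embed_with(sequence: str | SAString, embedder: Embedder,
               domain_id: str = "") -> ResidueEmbeddingMatrix:
    """Run an embedder on one sequence, with alphabet/channel checking."""
    if isinstance(sequence, SAString):
        domain_id = domain_id or sequence.domain_id
        sequence = sequence.letters
    if not sequence:
        raise IntegrityError("empty sequence")
    bad = set(sequence.upper()) - set(embedder.alphabet)
    if bad:
        raise ChannelMismatchError(
            f"symbols {sorted(bad)} not in the {embedder.channel} alphabet "
            f"of embedder {embedder.embedder_id!r}")
    values = np.asarray(embedder.embed(sequence.upper()), dtype=np.float64)
    if values.shape != (len(sequence), embedder.dim):
        raise IntegrityError(
            f"embedder {embedder.embedder_id!r} returned shape "
            f"{values.shape}, expected {(len(sequence), embedder.dim)}")
    return ResidueEmbeddingMatrix(domain_id=domain_id or sequence[:8],
                                  values=values,
                                  embedder_id=embedder.embedder_id,
                                  channel=embedder.channel)


def pool_mean(matrix: ResidueEmbeddingMatrix) -> PooledEmbedding:
    """Average-pool residue embeddings into one per-domain vector."""
    if matrix.values.shape[0] < 1:
        raise IntegrityError("cannot pool an empty embedding matrix")
    return PooledEmbedding(domain_id=matrix.domain_id,
                           vector=matrix.values.mean(axis=0),
                           channel=matrix.channel,
                           embedder_ids=(matrix.embedder_id,))


def build_input_vector(aa: Optional[PooledEmbedding],
                       tdi: Optional[PooledEmbedding],
                       input_type: str) -> PooledEmbedding:
    """Select or concatenate channels into the classifier input vector.

    ``AA+3Di`` concatenates in fixed AA-then-3Di order; slicing the result
    at the AA dimension recovers both parts exactly.
    """
    if input_type not in INPUT_TYPES:
        raise IntegrityError(f"unknown input_type {input_type!r}")
    if input_type == "AA":
        if aa is None:
            raise ChannelMismatchError("input_type AA requires an AA channel")
        return aa
    if input_type == "3Di":
        if tdi is None:
            raise ChannelMismatchError("input_type 3Di requires a 3Di channel")
        return tdi
    if aa is None or tdi is None:
        missing = "AA" if aa is None else "3Di"
        raise ChannelMismatchError(
            f"input_type AA+3Di: missing {missing} channel"
            + (f" for domain {tdi.domain_id!r}" if aa is None and tdi is not None
               else f" for domain {aa.domain_id!r}" if aa is not None else ""))
    if aa.domain_id != tdi.domain_id:
        raise IntegrityError(
            f"channel domain ids differ: {aa.domain_id!r} vs {tdi.domain_id!r}")
    return PooledEmbedding(
        domain_id=aa.domain_id,
        vector=np.concatenate([aa.vector, tdi.vector]),
        channel="AA+3Di",
        embedder_ids=aa.embedder_ids + tdi.embedder_ids,
    )


class EmbeddingStore:
    """HDF5-backed pooled-embedding cache.

    Layout: one group per channel; inside it one float32 dataset per
    domain id; group attributes record ``embedder_id`` and ``dim``.  The
    float32 precision matches the precomputed-embedding workflow the
    pipeline assumes; round-trips of float32 vectors are bit-exact.
    """

    def __init__(self, path: str, mode: str = "a"):
        self._fh = h5py.File(path, mode)
        self.path = path

    def __enter__(self) -> "EmbeddingStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self._fh.close()

    def put(self, emb: PooledEmbedding) -> None:
        grp = self._fh.require_group(emb.channel)
        eid = "+".join(emb.embedder_ids)
        if "embedder_id" in grp.attrs:
            if grp.attrs["embedder_id"] != eid:
                raise IntegrityError(
                    f"store channel {emb.channel} holds embeddings from "
                    f"{grp.attrs['embedder_id']!r}, not {eid!r}")
            if int(grp.attrs["dim"]) != emb.dim:
                raise IntegrityError(
                    f"dimension mismatch in channel {emb.channel}: store has "
                    f"{grp.attrs['dim']}, new vector has {emb.dim}")
        else:
            grp.attrs["embedder_id"] = eid
            grp.attrs["dim"] = emb.dim
        if emb.domain_id in grp:
            del grp[emb.domain_id]
        grp.create_dataset(emb.domain_id,
                           data=emb.vector.astype(np.float32))

    def put_many(self, embs: Iterable[PooledEmbedding]) -> None:
        for e in embs:
            self.put(e)

    def get(self, domain_id: str, channel: str) -> PooledEmbedding:
        if channel not in self._fh or domain_id not in self._fh[channel]:
            raise KeyError(f"{domain_id!r} not in channel {channel!r} "
                           f"of {self.path}")
        grp = self._fh[channel]
        return PooledEmbedding(
            domain_id=domain_id,
            vector=np.asarray(grp[domain_id], dtype=np.float32),
            channel=channel,
            embedder_ids=tuple(str(grp.attrs["embedder_id"]).split("+")),
        )

    def ids(self, channel: str) -> list[str]:
        if channel not in self._fh:
            return []
        return sorted(self._fh[channel].keys())

    def get_matrix(self, domain_ids: list[str], channel: str) -> np.ndarray:
        """Stack vectors for the given ids into an (n, d) float32 matrix."""
        return np.stack([self.get(d, channel).vector for d in domain_ids])
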