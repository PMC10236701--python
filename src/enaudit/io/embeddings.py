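"""Word2vec-format embedding tables (text and binary dialects).

Text dialect: first line ``<vocab> <dim>``, then one ``token v1 .. vd``
line per entry.  Binary dialect: same ASCII header line, then for each
entry the token bytes, a single space, and ``dim`` little-endian float32
values (an optional trailing newline per entry is tolerated, as written
by the original word2vec tool).
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = ["EmbeddingTable", "read_embeddings", "write_embeddings"]


class EmbeddingTable:
    """Token -> vector map with a fixed dimension."""

    def __init__(self, vectors: Mapping[str, np.ndarray]) -> None:
        if not vectors:
            raise ValueError("embedding table must not be empty")
        self._vectors: dict[str, np.ndarray] = {}
        dim: int | None = None
        for token, vector in vectors.items():
            array = np.asarray(vector, dtype=np.float32)
            if array.ndim != 1:
                raise ValueError(f"vector for {token!r} is not 1-D")
            if dim is None:
                dim = int(array.shape[0])
                if dim < 1:
                    raise ValueError("embedding dimension must be >= 1")
            elif array.shape[0] != dim:
                raise ValueError(
                    f"vector for {token!r} has length {array.shape[0]}, expected {dim}"
                )
            if not np.all(np.isfinite(array)):
                raise ValueError(f"non-finite components in vector for {token!r}")
            self._vectors[token] = array
        self.dimension = int(dim)  # type: ignore[arg-type]

    def get(self, token: str) -> np.ndarray | None:
        """Exact-token lookup; ``None`` when absent (not an error)."""
        return self._vectors.get(token)

    def __contains__(self, token: str) -> bool:
        return token in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def __iter__(self) -> Iterator[str]:
        return iter(self._vectors)

    def items(self):
        return self._vectors.items()


def _detect_format(path: Path) -> str:
    with open(path, "rb") as handle:
        header = handle.readline()
        probe = handle.read(1024)
    try:
        probe.decode("utf-8")
    except UnicodeDecodeError:
        return "word2vec-binary"
    return "word2vec-text"


def read_embeddings(path: str | Path, format: str = "auto") -> EmbeddingTable:
    """Read a word2vec table; the header-declared vocabulary is exact."""
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "word2vec-text":
        return _read_text(path)
    if format == "word2vec-binary":
        return _read_binary(path)
    raise ValueError(f"unknown embedding format {format!r}")


def _read_text(path: Path) -> EmbeddingTable:
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        vocab_size, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for _ in range(vocab_size):
            line = handle.readline()
            if not line:
                raise ValueError(f"{path}: truncated file")
            parts = line.rstrip("\n").split(" ")
            token = parts[0]
            values = [v for v in parts[1:] if v]
            if len(values) != dim:
                raise ValueError(
                    f"{path}: dimension mismatch for token {token!r}"
                )
            vectors[token] = np.array(values, dtype=np.float32)
    return EmbeddingTable(vectors)


def _read_binary(path: Path) -> EmbeddingTable:
    with open(path, "rb") as handle:
        header = handle.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        vocab_size, dim = int(header[0]), int(header[1])
        vector_bytes = dim * 4
        vectors: dict[str, np.ndarray] = {}
        for _ in range(vocab_size):
            token_bytes = bytearray()
            while True:
                ch = handle.read(1)
                if not ch:
                    raise ValueError(f"{path}: truncated file")
                if ch == b" ":
                    break
                if ch != b"\n":  # leading newline from the previous entry
                    token_bytes.extend(ch)
            payload = handle.read(vector_bytes)
            if len(payload) != vector_bytes:
                raise ValueError(f"{path}: truncated file")
            vectors[token_bytes.decode("utf-8")] = np.frombuffer(
                payload, dtype="<f4"
            ).copy()
    return EmbeddingTable(vectors)


def write_embeddings(
    table: EmbeddingTable, path: str | Path, format: str = "word2vec-text"
) -> None:
    """Write the table; token order is sorted for determinism."""
    path = Path(path)
    tokens = sorted(table)
    if format == "word2vec-text":
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write(f"{len(table)} {table.dimension}\n")
            for token in tokens:
                vector = table.get(token)
                values = " ".join(repr(float(v)) for v in vector)  # type: ignore[union-attr]
                handle.write(f"{token} {values}\n")
    elif format == "word2vec-binary":
        with open(path, "wb") as handle:
            handle.write(f"{len(table)} {table.dimension}\n".encode("utf-8"))
            for token in tokens:
                vector = np.asarray(table.get(token), dtype="<f4")
                handle.write(token.encode("utf-8") + b" ")
                handle.write(struct.pack(f"<{table.dimension}f", *vector))
                handle.write(b"\n")
    else:
        raise ValueError(f"unknown embedding format {format!r}")
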