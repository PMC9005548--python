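"""Tile feature embedding and cosine-similarity computation.

Patch comparison is done in a feature space through a pluggable embedding
contract: any callable mapping a tile to a fixed-length vector can stand in
for the convolutional backbone the method was originally built around. Two
implementations ship with the package:

* :class:`HistogramEmbedding` (``"default-handcrafted"``) — per-channel
  16-bin intensity histograms (L1-normalized), per-channel mean and standard
  deviation, and gradient-magnitude mean and standard deviation, all scaled
  to [0, 1]; 56 dimensions total. Deterministic and training-free.
* :class:`FileEmbedding` (``"file:<path>"``) — precomputed vectors read from
  a delimited text file keyed by tile id, so externally trained CNN features
  can be plugged in without the package training anything.

All similarity arithmetic is exact double precision; no approximate
nearest-neighbor shortcuts are taken anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .sampling import Tile

__all__ = [
    "EmbeddingModel",
    "HistogramEmbedding",
    "FileEmbedding",
    "get_model",
    "embed",
    "cosine_similarity",
    "similarity_matrix",
    "write_features",
    "read_features",
]


@runtime_checkable
class EmbeddingModel(Protocol):
    """Contract: a named, deterministic tile -> vector map of fixed dimension."""

    name: str
    dim: int

    def __call__(self, tile: Tile) -> np.ndarray: ...


@dataclass(frozen=True)
class HistogramEmbedding:
    """Handcrafted intensity/texture descriptor of an RGB tile.

    Features (in order): 16-bin histogram of each of R, G, B over [0, 256),
    each histogram L1-normalized; mean and std of each channel divided by
    255; mean and std of the gradient-magnitude image of the grayscale tile
    divided by 255. dim = 3*16 + 3*2 + 2 = 56.
    """

    n_bins: int = 16
    name: str = "default-handcrafted"

    @property
    def dim(self) -> int:
        return 3 * self.n_bins + 3 * 2 + 2

    def __call__(self, tile: Tile) -> np.ndarray:
        arr = np.asarray(tile.pixels, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected HxWx3 tile, got shape {arr.shape}")
        n_px = arr.shape[0] * arr.shape[1]
        parts: list[np.ndarray] = []
        for c in range(3):
            hist, _ = np.histogram(arr[..., c], bins=self.n_bins, range=(0.0, 256.0))
            parts.append(hist / n_px)
        means = arr.mean(axis=(0, 1)) / 255.0
        stds = arr.std(axis=(0, 1)) / 255.0
        gray = arr.mean(axis=2)
        gy, gx = np.gradient(gray)
        gmag = np.hypot(gx, gy)
        parts.extend([means, stds, np.array([gmag.mean() / 255.0, gmag.std() / 255.0])])
        return np.concatenate(parts)


@dataclass(frozen=True)
class FileEmbedding:
    """Embedding backed by a precomputed feature table keyed by tile id."""

    path: str
    _table: dict[str, np.ndarray] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        ids, matrix = read_features(self.path)
        object.__setattr__(self, "_table", dict(zip(ids, matrix)))

    @property
    def name(self) -> str:
        return f"file:{self.path}"

    @property
    def dim(self) -> int:
        return next(iter(self._table.values())).shape[0]

    def __call__(self, tile: Tile) -> np.ndarray:
        try:
            return self._table[tile.tile_id]
        except KeyError:
            raise KeyError(f"no precomputed feature for tile {tile.tile_id!r} in {self.path}") from None


def get_model(name: str) -> EmbeddingModel:
    """Resolve an embedding model by name: ``default-handcrafted`` or ``file:<path>``."""
    if name == "default-handcrafted":
        return HistogramEmbedding()
    if name.startswith("file:"):
        return FileEmbedding(name[len("file:"):])
    raise ValueError(f"unknown embedding model {name!r}")


def embed(tiles: list[Tile], model: EmbeddingModel | Callable[[Tile], np.ndarray]) -> np.ndarray:
    """Embed tiles in order; returns an (n_tiles, dim) float64 matrix."""
    if not tiles:
        raise ValueError("no tiles to embed")
    rows = []
    for tile in tiles:
        try:
            v = np.asarray(model(tile), dtype=np.float64)
        except Exception as exc:
            raise RuntimeError(f"embedding failed on tile {tile.tile_id!r}: {exc}") from exc
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite feature entries for tile {tile.tile_id!r}")
        rows.append(v)
    matrix = np.vstack(rows)
    if matrix.ndim != 2:
        raise ValueError("embedding must produce 1-D vectors")
    return matrix


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two feature vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def similarity_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine-similarity matrix of m >= 2 row vectors.

    The result is exactly symmetric with a unit diagonal and all entries
    clipped into [-1, 1].
    """
    x = np.asarray(vectors, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("similarity_matrix needs at least 2 vectors of equal length")
    norms = np.linalg.norm(x, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(f"zero-norm feature vector at index {int(zero[0])}")
    xn = x / norms[:, None]
    s = xn @ xn.T
    s = np.clip((s + s.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return s


def write_features(path: str | Path, tile_ids: list[str], matrix: np.ndarray) -> None:
    """Write a feature table: first column tile_id, then f0..f{dim-1}."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape[0] != len(tile_ids):
        raise ValueError("one feature row per tile id required")
    df = pd.DataFrame(matrix, columns=[f"f{i}" for i in range(matrix.shape[1])])
    df.insert(0, "tile_id", tile_ids)
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a feature table written by :func:`write_features`."""
    df = pd.read_csv(path)
    if "tile_id" not in df.columns:
        raise ValueError(f"feature file {path} lacks a tile_id column")
    ids = df["tile_id"].astype(str).tolist()
    matrix = df.drop(columns="tile_id").to_numpy(dtype=np.float64)
    if matrix.shape[1] == 0:
        raise ValueError(f"feature file {path} has no feature columns")
    return ids, matrix
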