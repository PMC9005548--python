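"""Random patch sampling from slide images with intensity-based tissue filters.

Only the case-level subtype label is available for a whole-slide image, so
patches are drawn at random from the slide and screened with three cheap
intensity criteria that keep densely cellular tissue and discard blank
background, low-contrast regions, and saturated color-marker ink:

1. the mean over all pixels and channels must lie in ``[mean_lo, mean_hi]``
   (default [50, 150] on the 8-bit scale),
2. the standard deviation of each of the R, G, B channels must exceed
   ``channel_std_min`` (default 20),
3. the spread between the largest and smallest per-channel mean must stay
   below ``channel_mean_range_max`` (default 100) — a strongly imbalanced
   channel mean is the signature of a pen marker, not stained tissue.

Every accepted patch inherits the case label (weak supervision).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FilterCriteria",
    "FilterResult",
    "SamplingConfig",
    "Tile",
    "SamplingError",
    "passes_filters",
    "sample_patches",
    "label_patches",
]

SUBTYPES = ("A", "O", "G")


class SamplingError(RuntimeError):
    """Raised when the requested number of accepted patches cannot be drawn."""


@dataclass(frozen=True)
class FilterCriteria:
    """Intensity thresholds for patch acceptance (8-bit scale)."""

    mean_lo: float = 50.0
    mean_hi: float = 150.0
    channel_std_min: float = 20.0
    channel_mean_range_max: float = 100.0

    def __post_init__(self) -> None:
        if not self.mean_lo < self.mean_hi:
            raise ValueError("mean_lo must be strictly below mean_hi")
        for name in ("mean_lo", "channel_std_min", "channel_mean_range_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class Tile:
    """An RGB patch with its slide of origin and top-left pixel coordinates.

    The patch covers the half-open extent ``[x, x+size) x [y, y+size)``.
    """

    pixels: np.ndarray
    slide_id: str
    origin: tuple[int, int]  # (x, y), 0-based, top-left
    size_px: int
    label: str | None = None

    @property
    def tile_id(self) -> str:
        x, y = self.origin
        return f"{self.slide_id}_{x}_{y}"


@dataclass(frozen=True)
class SamplingConfig:
    n_patches: int = 300
    patch_size_px: int = 224
    max_attempts: int | None = None  # defaults to 50 * n_patches
    seed: int = 0
    allow_partial: bool = False

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        if self.patch_size_px < 1:
            raise ValueError("patch_size_px must be >= 1")
        if self.max_attempts is not None and self.max_attempts < self.n_patches:
            raise ValueError("max_attempts must be >= n_patches")

    @property
    def attempts(self) -> int:
        return self.max_attempts if self.max_attempts is not None else 50 * self.n_patches


@dataclass(frozen=True)
class FilterResult:
    accepted: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __bool__(self) -> bool:
        return self.accepted


def _as_rgb_array(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty tile")
    return arr.astype(np.float64)


def passes_filters(tile: Tile | np.ndarray, criteria: FilterCriteria | None = None) -> FilterResult:
    """Check a tile against the three intensity acceptance criteria.

    Returns a :class:`FilterResult` whose ``reasons`` lists every criterion
    the tile failed (empty when accepted).
    """
    criteria = criteria or FilterCriteria()
    pixels = tile.pixels if isinstance(tile, Tile) else tile
    arr = _as_rgb_array(pixels)

    reasons: list[str] = []
    mean_all = float(arr.mean())
    if not (criteria.mean_lo <= mean_all <= criteria.mean_hi):
        reasons.append(
            f"mean intensity {mean_all:.2f} outside [{criteria.mean_lo:g}, {criteria.mean_hi:g}]"
        )
    channel_stds = arr.std(axis=(0, 1))
    low = [f"{c}={s:.2f}" for c, s in zip("RGB", channel_stds) if s <= criteria.channel_std_min]
    if low:
        reasons.append(
            f"channel std not above {criteria.channel_std_min:g}: " + ", ".join(low)
        )
    channel_means = arr.mean(axis=(0, 1))
    mean_range = float(channel_means.max() - channel_means.min())
    if mean_range >= criteria.channel_mean_range_max:
        reasons.append(
            f"channel-mean range {mean_range:.2f} >= {criteria.channel_mean_range_max:g} (marker rule)"
        )
    return FilterResult(accepted=not reasons, reasons=tuple(reasons))


def sample_patches(
    slide: np.ndarray,
    config: SamplingConfig | None = None,
    criteria: FilterCriteria | None = None,
    slide_id: str = "slide",
) -> list[Tile]:
    """Draw ``config.n_patches`` filter-passing patches from a slide.

    Candidate top-left origins are drawn uniformly, without replacement, from
    every position that keeps the patch inside the slide; candidates failing
    :func:`passes_filters` are discarded. Deterministic for a fixed seed.

    Raises :class:`SamplingError` when fewer than ``n_patches`` candidates are
    accepted within ``max_attempts``, unless ``allow_partial`` is set, in which
    case the accepted subset is returned with a warning.
    """
    config = config or SamplingConfig()
    criteria = criteria or FilterCriteria()
    arr = np.asarray(slide)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"slide must be HxWx3 RGB, got shape {arr.shape}")
    h, w = arr.shape[:2]
    s = config.patch_size_px
    if h < s or w < s:
        raise ValueError(f"slide {w}x{h} smaller than patch size {s}")

    ny, nx = h - s + 1, w - s + 1
    n_valid = ny * nx
    rng = np.random.default_rng(config.seed)
    n_draw = min(config.attempts, n_valid)
    candidates = rng.choice(n_valid, size=n_draw, replace=False)

    tiles: list[Tile] = []
    for flat in candidates:
        y, x = divmod(int(flat), nx)
        patch = arr[y : y + s, x : x + s]
        if passes_filters(patch, criteria):
            tiles.append(
                Tile(pixels=np.ascontiguousarray(patch), slide_id=slide_id, origin=(x, y), size_px=s)
            )
            if len(tiles) == config.n_patches:
                return tiles

    if config.allow_partial:
        warnings.warn(
            f"sample_patches: accepted only {len(tiles)}/{config.n_patches} patches "
            f"for slide {slide_id!r} within {n_draw} attempts",
            stacklevel=2,
        )
        return tiles
    raise SamplingError(
        f"accepted only {len(tiles)}/{config.n_patches} patches for slide {slide_id!r} "
        f"within {n_draw} attempts (set allow_partial to keep the subset)"
    )


def label_patches(tiles: list[Tile], case_label: str) -> list[Tile]:
    """Assign the case-level subtype label to every sampled tile.

    Only the three subtype codes are admissible here; the irrelevant
    category arises later, from prototype review, never from sampling.
    """
    if case_label not in SUBTYPES:
        raise ValueError(f"case label must be one of {SUBTYPES}, got {case_label!r}")
    return [replace(t, label=case_label) for t in tiles]
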