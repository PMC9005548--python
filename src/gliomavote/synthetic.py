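"""Synthetic slides, tiles, and MRI probability vectors for pipeline testing.

Real glioma slides cannot ship with a test suite, so this module renders
class-separable cartoon histology. Three subtype textures are modelled
after coarse morphological cues — dense irregular dark nuclei on a pink
background for astrocytoma (A), the same hypercellular field interrupted by
pale necrotic blobs for glioblastoma (G), and "fried egg" cells (bright
perinuclear halos with dark rims and central nuclei) for oligodendroglioma
(O) — plus an irrelevant-tissue distractor (I, reminiscent of blood-rich
stroma), blank white background, and a saturated color-marker blob. The
default A/O/G/I recipes are calibrated so their tiles pass the intensity
filters (pooled mean in [50, 150], per-channel std above 20, channel-mean
range below 100), while blank and marker tiles fail them; biological
fidelity beyond that is a non-goal.

Simulated MRI class-probability vectors have a controllable argmax accuracy
and sharpness so the label-fusion rule can be exercised at any reliability
level. All generators are pure functions of their seed and parameters; case
k of a case set is seeded independently of the number of cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse as draw_ellipse

from .sampling import SUBTYPES

__all__ = [
    "TileRecipe",
    "Region",
    "SlideComposition",
    "MriSimParams",
    "Case",
    "CaseSet",
    "DEFAULT_RECIPES",
    "REGION_CODES",
    "generate_tile",
    "generate_slide",
    "generate_mri_probs",
    "generate_case_set",
    "default_composition",
    "write_case_set",
]

TEXTURES = ("solid_nuclei", "necrotic_patch", "ring_cells")
TILE_LABELS = ("A", "O", "G", "I", "blank", "marker")

# Mask codes written by generate_slide; 0 is background.
REGION_CODES = {"A": 1, "O": 2, "G": 3, "I": 4, "blank": 5, "marker": 6}

# Render colors shared across recipes (8-bit RGB).
_NUCLEUS_COLOR = (64, 28, 96)
_RBC_COLOR = (100, 45, 55)  # irrelevant-tissue discs
_NECROSIS_COLOR = (225, 215, 222)
_HALO_COLOR = (180, 165, 170)
_RIM_COLOR = (90, 60, 110)


@dataclass(frozen=True)
class TileRecipe:
    """Parameters of one synthetic texture.

    ``nucleus_density`` is the expected number of nuclei (or cells) per
    1000 px^2 of tile area; ``noise_sd`` is the standard deviation of the
    additive Gaussian pixel noise on the 8-bit scale.
    """

    class_label: str
    base_color: tuple[int, int, int]
    nucleus_density: float = 0.0
    nucleus_radius_px: float = 6.0
    texture: str = "solid_nuclei"
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.class_label not in TILE_LABELS:
            raise ValueError(f"class_label must be one of {TILE_LABELS}")
        if self.texture not in TEXTURES:
            raise ValueError(f"texture must be one of {TEXTURES}")
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ValueError("base_color channels must lie in [0, 255]")
        if self.nucleus_density < 0 or self.nucleus_radius_px <= 0 or self.noise_sd < 0:
            raise ValueError("density/radius/noise parameters must be nonnegative")


DEFAULT_RECIPES: dict[str, TileRecipe] = {
    "A": TileRecipe("A", (180, 140, 165), nucleus_density=3.5, nucleus_radius_px=6.0,
                    texture="solid_nuclei"),
    "G": TileRecipe("G", (168, 122, 152), nucleus_density=4.5, nucleus_radius_px=6.0,
                    texture="necrotic_patch"),
    "O": TileRecipe("O", (155, 110, 145), nucleus_density=1.6, nucleus_radius_px=5.0,
                    texture="ring_cells"),
    "I": TileRecipe("I", (155, 135, 130), nucleus_density=8.0, nucleus_radius_px=4.0,
                    texture="solid_nuclei"),
    "blank": TileRecipe("blank", (255, 255, 255), nucleus_density=0.0, noise_sd=0.0),
    "marker": TileRecipe("marker", (0, 255, 0), nucleus_density=0.0, noise_sd=4.0),
}


@dataclass(frozen=True)
class Region:
    """Axis-aligned slide region: (x, y) top-left corner plus width/height."""

    x: int
    y: int
    width: int
    height: int
    recipe: TileRecipe


@dataclass(frozen=True)
class SlideComposition:
    width_px: int
    height_px: int
    regions: tuple[Region, ...] = ()
    background: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        for r in self.regions:
            if r.width <= 0 or r.height <= 0:
                raise ValueError("region extents must be positive")
            if r.x < 0 or r.y < 0 or r.x + r.width > self.width_px or r.y + r.height > self.height_px:
                raise ValueError(
                    f"region at ({r.x}, {r.y}) size {r.width}x{r.height} exceeds the "
                    f"{self.width_px}x{self.height_px} slide bounds"
                )
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                if a.x < b.x + b.width and b.x < a.x + a.width and a.y < b.y + b.height and b.y < a.y + a.height:
                    raise ValueError("regions must not overlap")


@dataclass(frozen=True)
class MriSimParams:
    """Controls the simulated MRI arm: argmax accuracy and vector sharpness."""

    accuracy: float = 0.7
    concentration: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if not 0.0 < self.concentration <= 1.0:
            raise ValueError("concentration must lie in (0, 1]")


@dataclass
class Case:
    case_id: str
    slide: np.ndarray
    mask: np.ndarray
    true_label: str
    mri_probs: dict[str, float]
    age: int


@dataclass
class CaseSet:
    cases: list[Case]
    mri: MriSimParams
    seed: int
    paths: dict = field(default_factory=dict)  # populated by write_case_set


def _render_texture(recipe: TileRecipe, height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Render one texture field as a float array in [0, 255]."""
    canvas = np.empty((height, width, 3), dtype=np.float64)
    canvas[:] = recipe.base_color

    n_cells = rng.poisson(recipe.nucleus_density * height * width / 1000.0)
    centers = rng.uniform(0, [height, width], size=(n_cells, 2))
    radii = recipe.nucleus_radius_px * rng.uniform(0.7, 1.4, size=(n_cells, 2))
    angles = rng.uniform(0, np.pi, size=n_cells)

    if recipe.texture == "ring_cells":
        # fried-egg cells: dark rim disc, bright halo, small central nucleus
        for (cy, cx), (ra, rb), ang in zip(centers, radii, angles):
            rim = 2.6 * np.array([ra, rb])
            halo = 2.2 * np.array([ra, rb])
            for rad, color in ((rim, _RIM_COLOR), (halo, _HALO_COLOR), ((ra, rb), _NUCLEUS_COLOR)):
                rr, cc = draw_ellipse(cy, cx, rad[0], rad[1], shape=(height, width), rotation=ang)
                canvas[rr, cc] = color
    else:
        color = _RBC_COLOR if recipe.class_label == "I" else _NUCLEUS_COLOR
        for (cy, cx), (ra, rb), ang in zip(centers, radii, angles):
            rr, cc = draw_ellipse(cy, cx, ra, rb, shape=(height, width), rotation=ang)
            canvas[rr, cc] = color
        if recipe.texture == "necrotic_patch":
            # one pale necrotic blob per ~224^2 of area, ~15% coverage total
            n_blobs = max(1, round(height * width / 224**2))
            for _ in range(n_blobs):
                cy, cx = rng.uniform(0, [height, width])
                ra = rng.uniform(0.18, 0.26) * min(height, width) / np.sqrt(n_blobs)
                rb = ra * rng.uniform(0.6, 1.0)
                rr, cc = draw_ellipse(cy, cx, ra, rb, shape=(height, width),
                                      rotation=rng.uniform(0, np.pi))
                canvas[rr, cc] = _NECROSIS_COLOR

    if recipe.noise_sd > 0:
        canvas += rng.normal(0.0, recipe.noise_sd, size=canvas.shape)
    return np.clip(canvas, 0.0, 255.0)


def generate_tile(recipe: TileRecipe, size_px: int = 224, seed: int = 0) -> np.ndarray:
    """Render one square tile; bitwise deterministic in (recipe, size, seed)."""
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    rng = np.random.default_rng(seed)
    return _render_texture(recipe, size_px, size_px, rng).round().astype(np.uint8)


def generate_slide(composition: SlideComposition, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render a slide and its region mask.

    Returns ``(slide, mask)`` where the mask holds 0 on background and the
    :data:`REGION_CODES` code of the region's class label elsewhere. Each
    region draws from its own seed stream so a region's content does not
    depend on how many regions precede it.
    """
    h, w = composition.height_px, composition.width_px
    slide = np.empty((h, w, 3), dtype=np.float64)
    slide[:] = composition.background
    mask = np.zeros((h, w), dtype=np.uint8)
    for i, region in enumerate(composition.regions):
        rng = np.random.default_rng([seed, i])
        patch = _render_texture(region.recipe, region.height, region.width, rng)
        slide[region.y : region.y + region.height, region.x : region.x + region.width] = patch
        mask[region.y : region.y + region.height, region.x : region.x + region.width] = REGION_CODES[
            region.recipe.class_label
        ]
    return slide.round().astype(np.uint8), mask


def generate_mri_probs(true_label: str, params: MriSimParams, rng: np.random.Generator) -> dict[str, float]:
    """Draw one 3-class probability vector with argmax accuracy ``params.accuracy``.

    With probability ``accuracy`` the peak sits on the true label, otherwise
    uniformly on one of the two other subtypes; the peak gets mass
    ``concentration`` plus an even share of the remainder.
    """
    if true_label not in SUBTYPES:
        raise ValueError(f"true_label must be one of {SUBTYPES}")
    if rng.random() < params.accuracy:
        peak = true_label
    else:
        others = [c for c in SUBTYPES if c != true_label]
        peak = others[rng.integers(len(others))]
    p = np.full(3, (1.0 - params.concentration) / 3.0)
    p[SUBTYPES.index(peak)] += params.concentration
    p /= p.sum()
    return {c: float(v) for c, v in zip(SUBTYPES, p)}


def default_composition(label: str, slide_size: int = 1024,
                        recipes: dict[str, TileRecipe] | None = None) -> SlideComposition:
    """Standard per-case layout: one large subtype region, an irrelevant-tissue
    region, and a small marker blob on white background."""
    recipes = recipes or DEFAULT_RECIPES
    if label not in SUBTYPES:
        raise ValueError(f"label must be one of {SUBTYPES}")
    u = slide_size / 1024.0
    regions = (
        Region(int(32 * u), int(32 * u), int(640 * u), int(928 * u), recipes[label]),
        Region(int(704 * u), int(64 * u), int(288 * u), int(320 * u), recipes["I"]),
        Region(int(800 * u), int(840 * u), int(96 * u), int(96 * u), recipes["marker"]),
    )
    return SlideComposition(width_px=slide_size, height_px=slide_size, regions=regions)


def _subseed(*parts: int) -> int:
    """Counter-based seed split: a stable child seed for one unit of work."""
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


def generate_case_set(
    n_cases: int,
    class_balance: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    mri: MriSimParams | None = None,
    seed: int = 0,
    slide_size: int = 1024,
    recipes: dict[str, TileRecipe] | None = None,
    prefix: str = "case",
    render_slides: bool = True,
) -> CaseSet:
    """Generate labeled synthetic slides with paired MRI probability vectors.

    Every per-case quantity (label, slide, MRI vector, age) is drawn from a
    counter-split seed stream, so case k is reproducible independently of
    ``n_cases``; ``class_balance`` gives the per-case label probabilities.
    With ``render_slides=False`` the expensive slide rendering is skipped
    (``slide`` and ``mask`` are empty), which is enough to study the
    simulated MRI arm on its own.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    balance = np.asarray(class_balance, dtype=np.float64)
    if balance.shape != (3,) or np.any(balance < 0) or abs(balance.sum() - 1.0) > 1e-9:
        raise ValueError("class_balance must be 3 nonnegative proportions summing to 1")
    mri = mri or MriSimParams()
    empty = np.zeros((0, 0, 3), dtype=np.uint8)
    cases: list[Case] = []
    for k in range(n_cases):
        case_rng = np.random.default_rng([mri.seed, seed, k])
        label = SUBTYPES[case_rng.choice(3, p=balance)]
        if render_slides:
            comp = default_composition(label, slide_size=slide_size, recipes=recipes)
            slide, mask = generate_slide(comp, seed=_subseed(seed, k))
        else:
            slide, mask = empty, empty[..., 0]
        probs = generate_mri_probs(label, mri, case_rng)
        age = int(case_rng.integers(25, 80))
        cases.append(Case(case_id=f"{prefix}_{k:03d}", slide=slide, mask=mask,
                          true_label=label, mri_probs=probs, age=age))
    return CaseSet(cases=cases, mri=mri, seed=seed)


def write_case_set(case_set: CaseSet, out_dir: str | Path) -> dict:
    """Write slides, masks, the case manifest, and the MRI probability file.

    Layout: ``slides/{case_id}.png``, ``masks/{case_id}.png``,
    ``manifest.csv`` (case_id, slide_path, true_label, mri_prob_path, age),
    and ``mri_probs.csv`` (case_id, p_A, p_O, p_G).
    """
    import pandas as pd

    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    mri_path = out / "mri_probs.csv"
    rows, mri_rows = [], []
    for case in case_set.cases:
        slide_path = out / "slides" / f"{case.case_id}.png"
        mask_path = out / "masks" / f"{case.case_id}.png"
        Image.fromarray(case.slide).save(slide_path)
        Image.fromarray(case.mask).save(mask_path)
        rows.append({
            "case_id": case.case_id,
            "slide_path": str(slide_path.relative_to(out)),
            "true_label": case.true_label,
            "mri_prob_path": str(mri_path.relative_to(out)),
            "age": case.age,
        })
        mri_rows.append({"case_id": case.case_id,
                         "p_A": case.mri_probs["A"], "p_O": case.mri_probs["O"],
                         "p_G": case.mri_probs["G"]})
    manifest_path = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    pd.DataFrame(mri_rows).to_csv(mri_path, index=False)
    paths = {"manifest": manifest_path, "mri_probs": mri_path, "root": out}
    case_set.paths = paths
    return paths
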