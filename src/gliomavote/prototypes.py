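"""Density-diversity prototype selection over a cosine-similarity matrix.

Within each category the sampled patches contain an unknown fraction of
noisy or non-representative tiles (stroma, blood, infiltration zones), so a
fixed number of prototypes is distilled from them in a density-peaks style:

* the similarity threshold ``s_t`` is the mean of all pairwise similarities
  in the category;
* the density ``rho_i`` of patch i counts how many other patches are more
  similar to it than ``s_t`` (strict inequality);
* patches are ranked by density (ties broken by original index), and the
  diversity ``delta_i`` of each patch is its distance ``1 - s`` to the
  nearest patch of strictly higher rank — the top-ranked patch receives the
  maximum of all other deltas so that it always heads the selection;
* walking the ranking, a patch is kept only when its diversity exceeds a
  threshold (the mean delta by default), until ``k_prototypes`` are kept.

High density favors patches typical of the category; the diversity gate
stops the selection from collecting near-duplicates of the same mode.
A final expert-review step can drop prototypes or reassign them to another
category, including the dedicated irrelevant category ``I``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import similarity_matrix

__all__ = [
    "SelectionConfig",
    "PrototypeSet",
    "ExpertReview",
    "DegenerateCategoryError",
    "similarity_threshold",
    "density",
    "diversity",
    "priority_order",
    "select_prototypes",
    "build_prototype_set",
    "apply_expert_review",
    "auto_review",
]

CATEGORY_ORDER = ("A", "O", "G", "I")


class DegenerateCategoryError(RuntimeError):
    """Raised when a category yields no usable prototypes."""


@dataclass(frozen=True)
class SelectionConfig:
    k_prototypes: int = 100
    delta_threshold_mode: str = "mean_delta"  # or "fixed"
    delta_threshold_value: float = 0.0  # used when mode == "fixed"
    signed_density: bool = False  # sign-sum variant; rank-equivalent to the count
    seed: int = 0  # reserved; the selector is deterministic

    def __post_init__(self) -> None:
        if self.k_prototypes < 1:
            raise ValueError("k_prototypes must be >= 1")
        if self.delta_threshold_mode not in ("mean_delta", "fixed"):
            raise ValueError("delta_threshold_mode must be 'mean_delta' or 'fixed'")


@dataclass
class PrototypeSet:
    """Selected representative feature vectors for one category."""

    category: str
    features: np.ndarray  # (k, dim)
    tile_ids: list[str]
    provenance: str = "automatic"  # or "expert-reviewed"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.tile_ids):
            raise ValueError("features must be (k, dim) with one row per tile id")

    def __len__(self) -> int:
        return len(self.tile_ids)


@dataclass(frozen=True)
class ExpertReview:
    """File-consumed review: drop prototypes or move them to another category."""

    exclusions: tuple[str, ...] = ()
    reassignments: tuple[tuple[str, str], ...] = ()  # (tile_id, new_category)


def similarity_threshold(S: np.ndarray) -> float:
    """Mean of the m(m-1)/2 off-diagonal (upper-triangle) similarities."""
    S = np.asarray(S, dtype=np.float64)
    m = S.shape[0]
    if S.ndim != 2 or S.shape[1] != m or m < 2:
        raise ValueError("need a square similarity matrix with m >= 2")
    iu = np.triu_indices(m, k=1)
    return float(S[iu].mean())


def density(S: np.ndarray, s_t: float, signed: bool = False) -> np.ndarray:
    """Per-patch density over the category's similarity matrix.

    Default: the count of other patches whose similarity exceeds ``s_t``
    (strict). With ``signed=True`` the sign-sum variant
    ``sum_j sign(s_ij - s_t)`` is returned instead; the two produce the same
    ranking since sign-sum = 2*count - (m-1) when no similarity ties s_t.
    """
    S = np.asarray(S, dtype=np.float64)
    if not np.isfinite(s_t):
        raise ValueError("s_t must be finite")
    if signed:
        contrib = np.sign(S - s_t)
    else:
        contrib = (S > s_t).astype(np.int64)
    np.fill_diagonal(contrib, 0)
    return contrib.sum(axis=1)


def priority_order(rho: np.ndarray) -> np.ndarray:
    """Selection priority: density descending, original index ascending."""
    rho = np.asarray(rho)
    idx = np.arange(rho.shape[0])
    return np.lexsort((idx, -rho))


def diversity(S: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Per-patch diversity: distance to the nearest higher-priority patch.

    Distances are ``d = 1 - s``. The first patch in priority order takes the
    maximum of the other deltas, so it always clears a mean-based threshold.
    """
    S = np.asarray(S, dtype=np.float64)
    rho = np.asarray(rho)
    m = S.shape[0]
    if rho.shape[0] != m:
        raise ValueError("rho length must match the similarity matrix")
    order = priority_order(rho)
    D = 1.0 - S
    delta = np.empty(m, dtype=np.float64)
    for pos in range(1, m):
        i = order[pos]
        delta[i] = D[i, order[:pos]].min()
    delta[order[0]] = delta[order[1:]].max() if m > 1 else 1.0
    return np.clip(delta, 0.0, 2.0)


def select_prototypes(
    S: np.ndarray,
    rho: np.ndarray,
    delta: np.ndarray,
    config: SelectionConfig | None = None,
) -> list[int]:
    """Accept patches in priority order while their diversity clears the gate.

    The top-priority patch is always accepted (its delta is defined to clear
    the threshold); every later patch needs ``delta > delta_threshold``.
    Returns accepted indices in acceptance order, at most ``k_prototypes``.
    """
    config = config or SelectionConfig()
    rho = np.asarray(rho)
    delta = np.asarray(delta, dtype=np.float64)
    m = rho.shape[0]
    if m == 0 or delta.shape[0] != m:
        raise DegenerateCategoryError("no patches to select from")
    if config.delta_threshold_mode == "mean_delta":
        threshold = float(delta.mean())
    else:
        threshold = float(config.delta_threshold_value)

    selected: list[int] = []
    for pos, i in enumerate(priority_order(rho)):
        if pos == 0 or delta[i] > threshold:
            selected.append(int(i))
            if len(selected) == config.k_prototypes:
                break
    if not selected:
        raise DegenerateCategoryError("selection produced no prototypes")
    return selected


def build_prototype_set(
    category: str,
    features: np.ndarray,
    tile_ids: list[str],
    config: SelectionConfig | None = None,
) -> PrototypeSet:
    """Run the full selection pipeline for one category's patch features."""
    config = config or SelectionConfig()
    features = np.asarray(features, dtype=np.float64)
    S = similarity_matrix(features)
    s_t = similarity_threshold(S)
    rho = density(S, s_t, signed=config.signed_density)
    delta = diversity(S, rho)
    idx = select_prototypes(S, rho, delta, config)
    threshold = float(delta.mean()) if config.delta_threshold_mode == "mean_delta" else config.delta_threshold_value
    return PrototypeSet(
        category=category,
        features=features[idx],
        tile_ids=[tile_ids[i] for i in idx],
        provenance="automatic",
        metadata={
            "s_t": s_t,
            "delta_threshold": threshold,
            "rho": [int(rho[i]) for i in idx],
            "delta": [float(delta[i]) for i in idx],
            "n_candidates": int(features.shape[0]),
        },
    )


def apply_expert_review(sets: dict[str, PrototypeSet], review: ExpertReview) -> dict[str, PrototypeSet]:
    """Drop or reassign prototypes per an expert's review.

    Reassignment may target the irrelevant category ``I``, creating it on
    first use. Prototype counts are conserved up to the exclusions:
    ``|before| = |after| + |exclusions|``.
    """
    index: dict[str, tuple[str, int]] = {}
    for cat, ps in sets.items():
        for i, tid in enumerate(ps.tile_ids):
            index[tid] = (cat, i)

    for tid in review.exclusions:
        if tid not in index:
            raise KeyError(f"exclusion references unknown prototype tile {tid!r}")
    moves: dict[str, str] = {}
    for tid, new_cat in review.reassignments:
        if tid not in index:
            raise KeyError(f"reassignment references unknown prototype tile {tid!r}")
        if new_cat not in CATEGORY_ORDER:
            raise ValueError(f"unknown target category {new_cat!r}")
        moves[tid] = new_cat
    dropped = set(review.exclusions)

    out_ids: dict[str, list[str]] = {}
    out_feats: dict[str, list[np.ndarray]] = {}
    for cat, ps in sets.items():
        for i, tid in enumerate(ps.tile_ids):
            if tid in dropped:
                continue
            target = moves.get(tid, cat)
            out_ids.setdefault(target, []).append(tid)
            out_feats.setdefault(target, []).append(ps.features[i])

    revised: dict[str, PrototypeSet] = {}
    for cat in out_ids:
        src = sets.get(cat)
        revised[cat] = PrototypeSet(
            category=cat,
            features=np.vstack(out_feats[cat]),
            tile_ids=out_ids[cat],
            provenance="expert-reviewed",
            metadata=dict(src.metadata) if src is not None else {},
        )
    return revised


def auto_review(sets: dict[str, PrototypeSet], percentile: float = 5.0) -> ExpertReview:
    """Heuristic stand-in for an expert: flag weakly cohesive prototypes.

    Prototypes whose mean within-category similarity falls below the given
    percentile of their category are proposed for exclusion. This is a
    convenience for fully automatic runs, not a claim about what a
    pathologist would flag.
    """
    exclusions: list[str] = []
    for ps in sets.values():
        if len(ps) < 3:
            continue
        S = similarity_matrix(ps.features)
        np.fill_diagonal(S, np.nan)
        cohesion = np.nanmean(S, axis=1)
        cutoff = np.percentile(cohesion, percentile)
        for tid, c in zip(ps.tile_ids, cohesion):
            if c < cutoff:
                exclusions.append(tid)
    return ExpertReview(exclusions=tuple(exclusions))
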