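"""Nearest-prototype patch classification and case-level majority voting.

Each sampled patch is assigned to the category (A, O, G, or the irrelevant
category I) whose prototypes it resembles most, measured by the average
cosine similarity to all of that category's prototype vectors. The case
label is the majority vote over patches, with I votes discarded; the
remaining vote counts over the three subtypes, normalized to a probability
distribution, give the confidence index as the maximum entry.

Ties — at the patch level and at the case level — are broken by the fixed
category order A, O, G, I. When every patch is assigned to I the case
abstains (no subtype label, confidence 0), which makes the downstream
fusion rule defer to the MRI arm.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .prototypes import CATEGORY_ORDER, PrototypeSet

__all__ = ["PatchClassification", "CasePrediction", "classify_patch", "classify_patches", "aggregate_case"]

SUBTYPES = ("A", "O", "G")


@dataclass(frozen=True)
class PatchClassification:
    tile_id: str
    mean_sims: dict[str, float]
    assigned: str


@dataclass(frozen=True)
class CasePrediction:
    """Case-level vote tally, normalized subtype distribution, and confidence.

    ``label`` is None and ``confidence`` 0.0 when every patch was assigned
    to the irrelevant category (abstention).
    """

    case_id: str
    votes: dict[str, int]
    probs: dict[str, float]
    label: str | None
    confidence: float

    @property
    def abstained(self) -> bool:
        return self.label is None


def _category_matrices(sets: dict[str, PrototypeSet]) -> list[tuple[str, np.ndarray]]:
    ordered = []
    for cat in CATEGORY_ORDER:
        if cat in sets:
            ps = sets[cat]
            if len(ps) == 0:
                raise ValueError(f"prototype set for category {cat!r} is empty")
            norms = np.linalg.norm(ps.features, axis=1)
            if np.any(norms == 0.0):
                raise ValueError(f"zero-norm prototype in category {cat!r}")
            ordered.append((cat, ps.features / norms[:, None]))
    if not ordered:
        raise ValueError("no prototype sets supplied")
    return ordered


def classify_patch(v: np.ndarray, sets: dict[str, PrototypeSet], tile_id: str = "") -> PatchClassification:
    """Assign one feature vector to its most similar prototype category."""
    v = np.asarray(v, dtype=np.float64).ravel()
    nv = np.linalg.norm(v)
    if nv == 0.0:
        raise ValueError("cannot classify a zero-norm feature vector")
    vn = v / nv
    mean_sims: dict[str, float] = {}
    best_cat, best = None, -np.inf
    for cat, proto in _category_matrices(sets):
        s = float(np.clip(proto @ vn, -1.0, 1.0).mean())
        mean_sims[cat] = s
        if s > best:  # strict: first category in fixed order wins ties
            best_cat, best = cat, s
    return PatchClassification(tile_id=tile_id, mean_sims=mean_sims, assigned=best_cat)


def classify_patches(
    features: np.ndarray, sets: dict[str, PrototypeSet], tile_ids: list[str] | None = None
) -> list[PatchClassification]:
    """Vectorized :func:`classify_patch` over an (n, dim) feature matrix."""
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm feature vector among patches")
    xn = x / norms[:, None]
    cats_mats = _category_matrices(sets)
    sims = np.column_stack(
        [np.clip(xn @ proto.T, -1.0, 1.0).mean(axis=1) for _, proto in cats_mats]
    )
    cats = [c for c, _ in cats_mats]
    winners = sims.argmax(axis=1)  # first max wins: ties fall to fixed order
    if tile_ids is None:
        tile_ids = [str(i) for i in range(x.shape[0])]
    return [
        PatchClassification(
            tile_id=tid,
            mean_sims={c: float(s) for c, s in zip(cats, row)},
            assigned=cats[w],
        )
        for tid, row, w in zip(tile_ids, sims, winners)
    ]


def aggregate_case(patches: list[PatchClassification], case_id: str) -> CasePrediction:
    """Majority vote over patch assignments, ignoring the irrelevant category.

    Vote counts over A/O/G are normalized to a probability distribution;
    the confidence index is its maximum. All-I cases abstain.
    """
    if not patches:
        raise ValueError("aggregate_case needs at least one patch")
    counts = Counter(p.assigned for p in patches)
    votes = {cat: int(counts.get(cat, 0)) for cat in CATEGORY_ORDER}
    total = sum(votes[c] for c in SUBTYPES)
    if total == 0:
        return CasePrediction(
            case_id=case_id,
            votes=votes,
            probs={c: 0.0 for c in SUBTYPES},
            label=None,
            confidence=0.0,
        )
    probs = {c: votes[c] / total for c in SUBTYPES}
    label = max(SUBTYPES, key=lambda c: (probs[c], -SUBTYPES.index(c)))
    return CasePrediction(case_id=case_id, votes=votes, probs=probs, label=label, confidence=probs[label])
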