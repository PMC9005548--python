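"""Confidence-gated label agreement between the WSI and MRI arms.

Histopathology is the primary source for subtype diagnosis, so the fused
decision keeps the slide-based label whenever its confidence index — the
maximum of the normalized patch-vote distribution — reaches the threshold
``C_t`` (default 0.6). Below the threshold (strict), or when the slide arm
abstained entirely, the MRI arm's argmax label is adopted instead. The MRI
arm itself is consumed as a per-case class-probability vector; no imaging
model is part of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import SUBTYPES, CasePrediction

__all__ = ["MriPrediction", "FusionConfig", "FusionDecision", "fuse", "read_mri_predictions"]


@dataclass(frozen=True)
class MriPrediction:
    case_id: str
    probs: dict[str, float]

    def __post_init__(self) -> None:
        p = np.array([self.probs.get(c, 0.0) for c in SUBTYPES], dtype=np.float64)
        if np.any(p < 0):
            raise ValueError(f"MRI probabilities for case {self.case_id!r} contain negatives")
        # tolerance accommodates vectors printed at 4 decimals
        if abs(p.sum() - 1.0) > 1e-3:
            raise ValueError(
                f"MRI probabilities for case {self.case_id!r} sum to {p.sum():.8f}, not 1"
            )

    @property
    def label(self) -> str:
        return max(SUBTYPES, key=lambda c: (self.probs.get(c, 0.0), -SUBTYPES.index(c)))


@dataclass(frozen=True)
class FusionConfig:
    confidence_threshold: float = 0.6  # C_t

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class FusionDecision:
    case_id: str
    final_label: str
    source: str  # "WSI" or "MRI"
    wsi_confidence: float
    threshold: float


def fuse(
    wsi: CasePrediction, mri: MriPrediction | None, config: FusionConfig | None = None
) -> FusionDecision:
    """Apply the label-agreement rule to one case.

    Keeps the WSI label when ``wsi.confidence >= C_t``; otherwise (strict
    less-than, or WSI abstention) adopts the MRI label. A missing MRI vector
    for a low-confidence case keeps the WSI label with a warning, provided
    the WSI arm did not abstain.
    """
    config = config or FusionConfig()
    if mri is not None and wsi.case_id != mri.case_id:
        raise ValueError(f"case id mismatch: WSI {wsi.case_id!r} vs MRI {mri.case_id!r}")

    low_confidence = wsi.abstained or wsi.confidence < config.confidence_threshold
    if low_confidence:
        if mri is None:
            if wsi.abstained:
                raise ValueError(
                    f"case {wsi.case_id!r}: WSI arm abstained and no MRI prediction is available"
                )
            warnings.warn(
                f"case {wsi.case_id!r}: confidence {wsi.confidence:.4f} below threshold "
                f"{config.confidence_threshold:g} but no MRI prediction; keeping the WSI label",
                stacklevel=2,
            )
            return FusionDecision(
                case_id=wsi.case_id,
                final_label=wsi.label,
                source="WSI",
                wsi_confidence=wsi.confidence,
                threshold=config.confidence_threshold,
            )
        return FusionDecision(
            case_id=wsi.case_id,
            final_label=mri.label,
            source="MRI",
            wsi_confidence=wsi.confidence,
            threshold=config.confidence_threshold,
        )
    return FusionDecision(
        case_id=wsi.case_id,
        final_label=wsi.label,
        source="WSI",
        wsi_confidence=wsi.confidence,
        threshold=config.confidence_threshold,
    )


def read_mri_predictions(path: str | Path) -> dict[str, MriPrediction]:
    """Read per-case MRI probability vectors: case_id, p_A, p_O, p_G."""
    df = pd.read_csv(path)
    required = {"case_id", "p_A", "p_O", "p_G"}
    if not required.issubset(df.columns):
        raise ValueError(f"MRI probability file {path} must have columns {sorted(required)}")
    out: dict[str, MriPrediction] = {}
    for row in df.itertuples(index=False):
        cid = str(row.case_id)
        out[cid] = MriPrediction(case_id=cid, probs={"A": row.p_A, "O": row.p_O, "G": row.p_G})
    return out
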