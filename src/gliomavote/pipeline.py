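"""Stage-wise orchestration of the full classification pipeline.

Stages (each reads the previous stage's files from a working directory and
writes its own, plus a small JSON manifest with the config hash, seed, and
input digests so every artifact can be re-derived):

    simulate            synthetic train/test case sets (slides, labels, MRI vectors)
    sample              random filtered patch sampling, train + test
    embed               feature tables for all sampled patches
    select-prototypes   density-diversity prototype sets per category (incl. I)
    review              optional expert-review edits of the prototype sets
    classify            patch voting -> per-case predictions with confidence
    fuse                confidence-gated label agreement with the MRI vectors
    evaluate            micro-F1 / kappa / balanced accuracy of the fused labels

Training patches are pooled over all training cases of a category; the
irrelevant category's prototypes come from an explicitly generated batch of
distractor tiles, since no slide is labeled "irrelevant". Every stage is a
pure function of the configuration and the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .embedding import embed, get_model, read_features, write_features
from .fusion import FusionConfig, fuse, read_mri_predictions
from .inference import SUBTYPES, CasePrediction, aggregate_case, classify_patches
from .metrics import evaluate
from .prototypes import (
    ExpertReview,
    PrototypeSet,
    SelectionConfig,
    apply_expert_review,
    build_prototype_set,
)
from .sampling import FilterCriteria, SamplingConfig, Tile, label_patches, sample_patches
from .synthetic import (
    DEFAULT_RECIPES,
    CaseSet,
    MriSimParams,
    generate_case_set,
    generate_tile,
    write_case_set,
)

__all__ = [
    "PipelineConfig",
    "DependencyError",
    "STAGES",
    "run_stage",
    "run_all",
    "load_prototype_sets",
    "read_expert_review",
]

STAGES = ("simulate", "sample", "embed", "select-prototypes", "review", "classify", "fuse", "evaluate")


class DependencyError(RuntimeError):
    """An upstream stage's artifacts are missing."""


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of the whole pipeline.

    Defaults reproduce the method's stated operating point: 300 patches per
    slide, intensity filters 50/150/20/100, 100 prototypes per category, and
    a fusion confidence threshold of 0.6.
    """

    seed: int = 0
    n_cases: int = 12
    n_train_per_class: int = 2
    class_balance: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    slide_size: int = 1024
    mri_accuracy: float = 0.7
    mri_concentration: float = 0.8
    n_irrelevant_tiles: int = 300
    embedding: str = "default-handcrafted"
    save_tiles: bool = False
    review_file: str | None = None
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    filters: FilterCriteria = field(default_factory=FilterCriteria)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        kwargs: dict = {}
        for key, sub in (("sampling", SamplingConfig), ("filters", FilterCriteria),
                         ("selection", SelectionConfig), ("fusion", FusionConfig)):
            if key in raw:
                kwargs[key] = sub(**raw.pop(key))
        if "class_balance" in raw:
            raw["class_balance"] = tuple(raw["class_balance"])
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_balance"] = list(d["class_balance"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _write_manifest(workdir: Path, stage: str, config: PipelineConfig,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "inputs": {str(p.relative_to(workdir)): _digest(p) for p in inputs},
        "outputs": [str(p.relative_to(workdir)) for p in outputs],
    }
    _atomic_write_text(workdir / f"{stage}.manifest.json", json.dumps(manifest, indent=2) + "\n")


def _require(workdir: Path, rel: str, produced_by: str) -> Path:
    path = workdir / rel
    if not path.exists():
        raise DependencyError(f"missing artifact {rel!r}; run the {produced_by!r} stage first")
    return path


def _frame_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


# --------------------------------------------------------------------------- stages

def stage_simulate(workdir: Path, config: PipelineConfig) -> dict:
    """Generate the training case set (balanced, one split per class) and the
    evaluation case set, each with slides, masks, manifest, and MRI vectors."""
    mri = MriSimParams(accuracy=config.mri_accuracy, concentration=config.mri_concentration,
                       seed=_derive_seed(config.seed, 11))
    # the training split needs every category: one degenerate-balance set per class
    train_cases = []
    for ci, cat in enumerate(SUBTYPES):
        balance = tuple(1.0 if c == cat else 0.0 for c in SUBTYPES)
        sub = generate_case_set(
            config.n_train_per_class, class_balance=balance, mri=mri,
            seed=_derive_seed(config.seed, 1, ci), slide_size=config.slide_size,
            prefix=f"train{cat}",
        )
        train_cases += sub.cases
    train = CaseSet(cases=train_cases, mri=mri, seed=config.seed)
    test = generate_case_set(
        config.n_cases, class_balance=config.class_balance,
        mri=mri, seed=_derive_seed(config.seed, 2), slide_size=config.slide_size, prefix="case",
    )
    outputs = []
    for name, cs in (("train", train), ("test", test)):
        paths = write_case_set(cs, workdir / name)
        outputs += [paths["manifest"], paths["mri_probs"]]
    _write_manifest(workdir, "simulate", config, [], outputs)
    return {"n_train": len(train.cases), "n_test": len(test.cases)}


def _load_cases(workdir: Path, split: str, stage_hint: str) -> pd.DataFrame:
    manifest = _require(workdir, f"{split}/manifest.csv", stage_hint)
    df = pd.read_csv(manifest)
    df["slide_path"] = df["slide_path"].map(lambda p: str(workdir / split / p))
    return df


def _sample_split(workdir: Path, split: str, config: PipelineConfig, labeled: bool) -> pd.DataFrame:
    cases = _load_cases(workdir, split, "simulate")
    rows = []
    split_code = {"train": 0, "test": 1}[split]
    for idx, row in enumerate(cases.itertuples(index=False)):
        slide = np.asarray(Image.open(row.slide_path).convert("RGB"))
        scfg = dataclasses.replace(config.sampling, seed=_derive_seed(config.seed, 3, split_code, idx))
        tiles = sample_patches(slide, scfg, config.filters, slide_id=str(row.case_id))
        if labeled:
            tiles = label_patches(tiles, str(row.true_label))
        for t in tiles:
            rows.append({"case_id": t.slide_id, "x": t.origin[0], "y": t.origin[1],
                         "size": t.size_px, "label": t.label if labeled else ""})
        if config.save_tiles:
            tiles_dir = workdir / "patches" / "tiles" / split
            tiles_dir.mkdir(parents=True, exist_ok=True)
            for t in tiles:
                Image.fromarray(t.pixels).save(tiles_dir / f"{t.tile_id}.png")
    return pd.DataFrame(rows)


def stage_sample(workdir: Path, config: PipelineConfig) -> dict:
    """Sample filtered patches for both splits; writes coordinate manifests
    (tiles are re-cut from the slides downstream unless save_tiles is set)."""
    (workdir / "patches").mkdir(parents=True, exist_ok=True)
    out = {}
    outputs, inputs = [], []
    for split, labeled in (("train", True), ("test", False)):
        inputs.append(_require(workdir, f"{split}/manifest.csv", "simulate"))
        df = _sample_split(workdir, split, config, labeled)
        path = workdir / "patches" / f"patches_{split}.csv"
        _frame_csv(df, path)
        outputs.append(path)
        out[f"n_patches_{split}"] = len(df)
    _write_manifest(workdir, "sample", config, inputs, outputs)
    return out


def _cut_tiles(workdir: Path, split: str) -> tuple[list[Tile], pd.DataFrame]:
    patches = pd.read_csv(_require(workdir, f"patches/patches_{split}.csv", "sample"),
                          keep_default_na=False)
    cases = _load_cases(workdir, split, "simulate")
    slides = {str(r.case_id): np.asarray(Image.open(r.slide_path).convert("RGB"))
              for r in cases.itertuples(index=False)}
    tiles = []
    for r in patches.itertuples(index=False):
        s = int(r.size)
        pix = slides[str(r.case_id)][int(r.y): int(r.y) + s, int(r.x): int(r.x) + s]
        tiles.append(Tile(pixels=pix, slide_id=str(r.case_id), origin=(int(r.x), int(r.y)),
                          size_px=s, label=(str(r.label) or None)))
    return tiles, patches


def stage_embed(workdir: Path, config: PipelineConfig) -> dict:
    """Embed every sampled patch with the configured model."""
    model = get_model(config.embedding)
    (workdir / "features").mkdir(parents=True, exist_ok=True)
    outputs, inputs, out = [], [], {}
    for split in ("train", "test"):
        inputs.append(_require(workdir, f"patches/patches_{split}.csv", "sample"))
        tiles, _ = _cut_tiles(workdir, split)
        matrix = embed(tiles, model)
        path = workdir / "features" / f"features_{split}.csv"
        tmp = path.with_suffix(".csv.tmp")
        write_features(tmp, [t.tile_id for t in tiles], matrix)
        os.replace(tmp, path)
        outputs.append(path)
        out[f"n_features_{split}"] = matrix.shape[0]
    _write_manifest(workdir, "embed", config, inputs, outputs)
    return out


def _prototype_paths(workdir: Path) -> tuple[Path, Path]:
    return workdir / "prototypes" / "prototypes.json", workdir / "prototypes" / "prototype_features.csv"


def save_prototype_sets(workdir: Path, sets: dict[str, PrototypeSet]) -> list[Path]:
    json_path, feat_path = _prototype_paths(workdir)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    ids, rows = [], []
    payload = {}
    for cat, ps in sets.items():
        payload[cat] = {
            "tile_ids": ps.tile_ids,
            "provenance": ps.provenance,
            "feature_file": feat_path.name,
            "metadata": ps.metadata,
        }
        ids += [f"{cat}:{tid}" for tid in ps.tile_ids]
        rows.append(ps.features)
    tmp = feat_path.with_suffix(".csv.tmp")
    write_features(tmp, ids, np.vstack(rows))
    os.replace(tmp, feat_path)
    _atomic_write_text(json_path, json.dumps(payload, indent=2) + "\n")
    return [json_path, feat_path]


def load_prototype_sets(workdir: Path) -> dict[str, PrototypeSet]:
    json_path, feat_path = _prototype_paths(workdir)
    if not json_path.exists():
        raise DependencyError("missing prototype manifest; run the 'select-prototypes' stage first")
    payload = json.loads(json_path.read_text())
    ids, matrix = read_features(feat_path)
    table = dict(zip(ids, matrix))
    sets = {}
    for cat, entry in payload.items():
        feats = np.vstack([table[f"{cat}:{tid}"] for tid in entry["tile_ids"]])
        sets[cat] = PrototypeSet(category=cat, features=feats, tile_ids=list(entry["tile_ids"]),
                                 provenance=entry["provenance"], metadata=entry.get("metadata", {}))
    return sets


def stage_select(workdir: Path, config: PipelineConfig) -> dict:
    """Build per-category prototype sets from the labeled training patches,
    plus the irrelevant category from a generated distractor-tile batch."""
    inputs = [_require(workdir, "features/features_train.csv", "embed"),
              _require(workdir, "patches/patches_train.csv", "sample")]
    ids, matrix = read_features(inputs[0])
    labels = pd.read_csv(inputs[1], keep_default_na=False)
    label_by_tile = {f"{r.case_id}_{r.x}_{r.y}": str(r.label) for r in labels.itertuples(index=False)}

    model = get_model(config.embedding)
    sets: dict[str, PrototypeSet] = {}
    for cat in SUBTYPES:
        idx = [i for i, tid in enumerate(ids) if label_by_tile.get(tid) == cat]
        if not idx:
            raise ValueError(f"no training patches for category {cat!r}")
        sets[cat] = build_prototype_set(cat, matrix[idx], [ids[i] for i in idx], config.selection)
    itiles = [
        Tile(pixels=generate_tile(DEFAULT_RECIPES["I"], config.sampling.patch_size_px,
                                  _derive_seed(config.seed, 4, k)),
             slide_id="irrelevant", origin=(k, 0), size_px=config.sampling.patch_size_px)
        for k in range(config.n_irrelevant_tiles)
    ]
    sets["I"] = build_prototype_set("I", embed(itiles, model), [t.tile_id for t in itiles],
                                    config.selection)
    outputs = save_prototype_sets(workdir, sets)
    _write_manifest(workdir, "select-prototypes", config, inputs, outputs)
    return {f"n_prototypes_{c}": len(ps) for c, ps in sets.items()}


def read_expert_review(path: str | Path) -> ExpertReview:
    """Read a review file: columns tile_id, action in {exclude, reassign}, new_category."""
    df = pd.read_csv(path, keep_default_na=False)
    exclusions, reassignments = [], []
    for r in df.itertuples(index=False):
        if r.action == "exclude":
            exclusions.append(str(r.tile_id))
        elif r.action == "reassign":
            reassignments.append((str(r.tile_id), str(r.new_category)))
        else:
            raise ValueError(f"unknown review action {r.action!r}")
    return ExpertReview(exclusions=tuple(exclusions), reassignments=tuple(reassignments))


def stage_review(workdir: Path, config: PipelineConfig) -> dict:
    """Apply an expert-review file to the prototype sets (no-op without one)."""
    json_path, feat_path = _prototype_paths(workdir)
    inputs = [_require(workdir, str(json_path.relative_to(workdir)), "select-prototypes")]
    if config.review_file is None:
        _write_manifest(workdir, "review", config, inputs, [json_path, feat_path])
        return {"reviewed": 0}
    review = read_expert_review(config.review_file)
    sets = apply_expert_review(load_prototype_sets(workdir), review)
    outputs = save_prototype_sets(workdir, sets)
    _write_manifest(workdir, "review", config, inputs, outputs)
    return {"reviewed": len(review.exclusions) + len(review.reassignments)}


def stage_classify(workdir: Path, config: PipelineConfig) -> dict:
    """Patch-level prototype voting and case-level aggregation on the test split."""
    inputs = [_require(workdir, "features/features_test.csv", "embed")]
    sets = load_prototype_sets(workdir)
    json_path, feat_path = _prototype_paths(workdir)
    inputs += [json_path, feat_path]
    ids, matrix = read_features(inputs[0])
    case_of = {tid: tid.rsplit("_", 2)[0] for tid in ids}

    rows = []
    for case_id in dict.fromkeys(case_of.values()):
        idx = [i for i, tid in enumerate(ids) if case_of[tid] == case_id]
        pcs = classify_patches(matrix[idx], sets, [ids[i] for i in idx])
        cp = aggregate_case(pcs, case_id)
        rows.append({
            "case_id": case_id,
            "p_A": cp.probs["A"], "p_O": cp.probs["O"], "p_G": cp.probs["G"],
            "wsi_label": cp.label or "", "confidence": cp.confidence,
            "n_votes_A": cp.votes["A"], "n_votes_O": cp.votes["O"],
            "n_votes_G": cp.votes["G"], "n_votes_I": cp.votes["I"],
        })
    path = workdir / "predictions.csv"
    _frame_csv(pd.DataFrame(rows), path)
    _write_manifest(workdir, "classify", config, inputs, [path])
    return {"n_cases": len(rows)}


def stage_fuse(workdir: Path, config: PipelineConfig) -> dict:
    """Confidence-gated label agreement of WSI predictions with MRI vectors."""
    pred_path = _require(workdir, "predictions.csv", "classify")
    mri_path = _require(workdir, "test/mri_probs.csv", "simulate")
    preds = pd.read_csv(pred_path, keep_default_na=False)
    mri = read_mri_predictions(mri_path)
    rows = []
    for r in preds.itertuples(index=False):
        cp = CasePrediction(
            case_id=str(r.case_id),
            votes={"A": int(r.n_votes_A), "O": int(r.n_votes_O),
                   "G": int(r.n_votes_G), "I": int(r.n_votes_I)},
            probs={"A": float(r.p_A), "O": float(r.p_O), "G": float(r.p_G)},
            label=str(r.wsi_label) or None,
            confidence=float(r.confidence),
        )
        decision = fuse(cp, mri.get(cp.case_id), config.fusion)
        rows.append({"case_id": decision.case_id, "final_label": decision.final_label,
                     "source": decision.source, "wsi_confidence": decision.wsi_confidence,
                     "C_t": decision.threshold})
    path = workdir / "final_predictions.csv"
    _frame_csv(pd.DataFrame(rows), path)
    _write_manifest(workdir, "fuse", config, [pred_path, mri_path], [path])
    return {"n_overridden": int(sum(r["source"] == "MRI" for r in rows))}


def stage_evaluate(workdir: Path, config: PipelineConfig) -> dict:
    """Score the fused labels against the simulated ground truth."""
    final_path = _require(workdir, "final_predictions.csv", "fuse")
    truth = _load_cases(workdir, "test", "simulate").set_index("case_id")["true_label"]
    preds = pd.read_csv(final_path).set_index("case_id")["final_label"]
    joined = pd.concat([truth, preds], axis=1, join="inner")
    report = evaluate(joined["true_label"].tolist(), joined["final_label"].tolist(),
                      class_set=list(SUBTYPES))
    path = workdir / "metrics.json"
    _atomic_write_text(path, json.dumps(report.as_dict(), indent=2) + "\n")
    _write_manifest(workdir, "evaluate", config, [final_path], [path])
    return report.as_dict()


_STAGE_FNS = {
    "simulate": stage_simulate,
    "sample": stage_sample,
    "embed": stage_embed,
    "select-prototypes": stage_select,
    "review": stage_review,
    "classify": stage_classify,
    "fuse": stage_fuse,
    "evaluate": stage_evaluate,
}


def run_stage(stage: str, workdir: str | Path, config: PipelineConfig) -> dict:
    """Run one named stage; raises :class:`DependencyError` when upstream
    artifacts are missing."""
    if stage not in _STAGE_FNS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FNS[stage](workdir, config)


def run_all(workdir: str | Path, config: PipelineConfig) -> dict:
    """Run every stage in order; returns the per-stage summary dicts."""
    summary = {}
    for stage in STAGES:
        summary[stage] = run_stage(stage, workdir, config)
    return summary
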