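"""End-to-end orchestration: phantom -> denoise -> segment -> candidates ->
features -> (LDA) -> classify -> evaluate, behind one YAML-style config.

Every stage writes its artifacts under the run directory with stable names
and the manifest records the config hash, the fan-out of per-stage seeds
(global seed + stage index) and a sha256 per artifact, so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import candidate_detection as cd
from . import evaluation as ev
from . import features as ft
from . import fixtures as fx
from . import lda as lda_mod
from . import preprocessing as pp
from .classifiers import HybridRuleSVM, build_classifier
from .errors import StageError, ValidationError

REQUIRED_BLOCKS = ("phantom", "denoise", "segment", "rules", "features", "model", "eval")

STAGE_ORDER = (
    "phantom",
    "denoise",
    "segment",
    "detect",
    "featurize",
    "reduce",
    "train",
    "eval",
)


def validate_config(cfg: dict) -> None:
    """Fail fast: every required stage block must exist before any compute."""
    if not isinstance(cfg, dict):
        raise ValidationError("pipeline config must be a mapping")
    for block in REQUIRED_BLOCKS:
        if block not in cfg:
            raise ValidationError(f"pipeline config is missing the '{block}' block")


def stage_seed(global_seed: int, stage: str) -> int:
    return int(global_seed) + STAGE_ORDER.index(stage)


def _rule_thresholds(rules_cfg: dict) -> cd.RuleThresholds:
    if "bounds" in rules_cfg:
        bounds = {
            k: (v[0], v[1]) for k, v in rules_cfg["bounds"].items()
        }
        return cd.RuleThresholds(bounds=bounds)
    return cd.default_rule_thresholds(
        background_intensity=rules_cfg.get("background_intensity", 0.2),
        noise_sigma=rules_cfg.get("noise_sigma", 0.05),
    )


@dataclass
class SliceResult:
    """All per-slice intermediate products of the detection pipeline."""

    labelled: fx.LabelledSlice
    denoised: pp.ImageSlice
    mask: np.ndarray
    candidates: list[cd.NoduleCandidate]
    kept_flags: list[bool]
    reasons: dict[int, list[str]]
    truth_labels: list[str]  # matched truth label per candidate


def match_truth(
    cand: cd.NoduleCandidate, labelled: fx.LabelledSlice, iou_threshold: float = 0.3
) -> str:
    """Label a candidate by its best-IoU ground-truth region; unmatched
    candidates are non-nodule."""
    best_iou, best_label = 0.0, "non-nodule"
    for mask, label in zip(labelled.truth_masks, labelled.truth_labels):
        inter = int((cand.region_mask & mask).sum())
        if inter == 0:
            continue
        union = int((cand.region_mask | mask).sum())
        iou = inter / union
        if iou > best_iou:
            best_iou, best_label = iou, label
    return best_label if best_iou >= iou_threshold else "non-nodule"


def process_slice(
    labelled: fx.LabelledSlice,
    denoise_cfg: pp.DenoiseConfig,
    seg_cfg: pp.SegmentConfig,
    thresholds: cd.RuleThresholds,
    min_area: int = 10,
) -> SliceResult:
    denoised = pp.denoise(labelled.image, denoise_cfg)
    mask = pp.segment_foreground(denoised, seg_cfg)
    cands = cd.label_candidates(mask, denoised, min_area=min_area)
    kept, _, reasons = cd.rule_crop(cands, thresholds)
    kept_ids = {id(c) for c in kept}
    return SliceResult(
        labelled=labelled,
        denoised=denoised,
        mask=mask,
        candidates=cands,
        kept_flags=[id(c) in kept_ids for c in cands],
        reasons=reasons,
        truth_labels=[match_truth(c, labelled) for c in cands],
    )


def _candidate_table(results: list[SliceResult], feat_cfg: ft.FeatureConfig) -> pd.DataFrame:
    rows = []
    names = feat_cfg.feature_names()
    for si, res in enumerate(results):
        for c, kept, lab in zip(res.candidates, res.kept_flags, res.truth_labels):
            vec = ft.extract_features(c, res.denoised, feat_cfg)
            row = {
                "slice_index": si,
                "slice_id": c.slice_id,
                "region_id": c.region_id,
                "truth_label": lab,
                "kept": kept,
            }
            row.update({f"desc_{k}": v for k, v in c.descriptors.as_dict().items()})
            row.update(dict(zip(names, vec.values)))
            rows.append(row)
    return pd.DataFrame(rows)


def _missed_nodules(results: list[SliceResult], slice_indices) -> int:
    """True nodules with no detected candidate matched to them (counted as
    false negatives by the headline sensitivity)."""
    missed = 0
    for si in slice_indices:
        res = results[si]
        for mask, label in zip(res.labelled.truth_masks, res.labelled.truth_labels):
            if label == "non-nodule":
                continue
            hit = False
            for c in res.candidates:
                inter = int((c.region_mask & mask).sum())
                if inter and inter / int((c.region_mask | mask).sum()) >= 0.3:
                    hit = True
                    break
            if not hit:
                missed += 1
    return missed


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    artifacts: dict[str, str] = {}

    def save_df(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.12g")
        artifacts[name] = _sha256(path)

    try:
        ph = dict(cfg["phantom"])
        n_slices = int(ph.pop("n_slices", 8))
        base = stage_seed(seed, "phantom")
        slices = [
            fx.generate_phantom(fx.PhantomSpec(seed=base * 1000 + i, **ph))
            for i in range(n_slices)
        ]
    except ValidationError as exc:
        raise StageError("phantom", str(exc)) from exc

    try:
        den_cfg = pp.DenoiseConfig(**cfg["denoise"])
        seg_cfg = pp.SegmentConfig(**cfg["segment"])
        thresholds = _rule_thresholds(cfg["rules"])
        min_area = int(cfg["rules"].get("min_area", 10))
        results = [
            process_slice(s, den_cfg, seg_cfg, thresholds, min_area=min_area)
            for s in slices
        ]
    except ValidationError as exc:
        raise StageError("detect", str(exc)) from exc

    import imageio.v3 as iio

    for i, res in enumerate(results):
        name = f"denoised_{i:03d}.png"
        iio.imwrite(out / name, (res.denoised.pixels * 65535).round().astype(np.uint16))
        artifacts[name] = _sha256(out / name)

    try:
        feat_cfg = ft.FeatureConfig(**cfg["features"])
        table = _candidate_table(results, feat_cfg)
        save_df(table, "features.csv")
        (out / "feature_config.json").write_text(
            json.dumps(
                {
                    "L": feat_cfg.L,
                    "distances": list(feat_cfg.distances),
                    "symmetric": feat_cfg.symmetric,
                    "calcification_T": feat_cfg.calcification_T,
                    "entropy_base": feat_cfg.entropy_base,
                },
                indent=2,
            )
        )
        artifacts["feature_config.json"] = _sha256(out / "feature_config.json")
    except ValidationError as exc:
        raise StageError("featurize", str(exc)) from exc

    eval_cfg = cfg["eval"]
    test_fraction = float(eval_cfg.get("test_fraction", 0.4))
    n_test = max(1, int(round(test_fraction * n_slices)))
    rng = np.random.default_rng(stage_seed(seed, "eval"))
    test_slices = set(rng.choice(n_slices, size=n_test, replace=False).tolist())
    table["is_test"] = table["slice_index"].isin(test_slices)

    feat_names = feat_cfg.feature_names()
    X = table[feat_names].to_numpy()
    y = np.where(table["truth_label"].to_numpy() == "non-nodule", -1, 1)
    tr = ~table["is_test"].to_numpy()
    te = table["is_test"].to_numpy()
    if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
        raise StageError("train", "a split lacks one of the classes; add slices")

    desc_all = [
        cd.RuleDescriptors(
            **{
                k: row[f"desc_{k}"]
                for k in cd.DESCRIPTOR_NAMES
            }
        )
        for _, row in table.iterrows()
    ]
    model_cfg = dict(cfg["model"])
    kind = model_cfg.pop("kind", "hybrid")
    lda_cfg = cfg.get("lda")

    try:
        proj = None
        Xtr, Xte = X[tr], X[te]
        if lda_cfg is not None and lda_cfg.get("enabled", True):
            proj = lda_mod.fit_lda(
                X[tr], y[tr],
                n_components=lda_cfg.get("n_components"),
                shrinkage=lda_cfg.get("shrinkage", 1e-4),
            )
            proj.to_json(out / "lda_projection.json")
            artifacts["lda_projection.json"] = _sha256(out / "lda_projection.json")
            Xtr, Xte = lda_mod.transform(proj, X[tr]), lda_mod.transform(proj, X[te])

        if kind == "hybrid":
            model = HybridRuleSVM(thresholds, **model_cfg)
            model.fit(Xtr, y[tr], [d for d, m in zip(desc_all, tr) if m])
            te_desc = [d for d, m in zip(desc_all, te) if m]
            y_pred, rationale = model.predict(Xte, te_desc)
            scores = model.scores(Xte, te_desc)
        else:
            model = build_classifier(kind, **model_cfg)
            model.fit(Xtr, y[tr])
            y_pred = model.predict(Xte)
            scores = np.asarray(model.scores(Xte), float)
            rationale = ["model"] * len(y_pred)
    except ValidationError as exc:
        raise StageError("train", str(exc)) from exc

    preds = table.loc[te, ["slice_index", "slice_id", "region_id", "truth_label"]].copy()
    preds["prediction"] = y_pred
    preds["score"] = scores
    preds["rationale"] = rationale
    save_df(preds.reset_index(drop=True), "predictions.csv")

    metrics = ev.confusion_metrics(y[te], y_pred, positive_label=1)
    roc, auc = ev.roc_auc(y[te], scores, positive_label=1)
    missed = _missed_nodules(results, sorted(test_slices))
    tp = int(np.sum((y[te] == 1) & (y_pred == 1)))
    fn = int(np.sum((y[te] == 1) & (y_pred != 1))) + missed
    detection_sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    report = {
        **metrics,
        "auc": auc,
        "roc": roc,
        "missed_nodules": missed,
        "detection_sensitivity": detection_sensitivity,
        "n_test_candidates": int(te.sum()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    artifacts["report.json"] = _sha256(out / "report.json")

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGE_ORDER},
        "artifacts": dict(sorted(artifacts.items())),
        "report": {
            k: report[k] for k in ("accuracy", "sensitivity", "specificity", "auc")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# The standard phantom benchmark (the artifact's stand-in headline numbers)
# ---------------------------------------------------------------------------

BENCHMARK_SPEC = dict(
    width=128,
    height=128,
    n_nodules=3,
    n_vessels=5,
    noise_sigma=0.05,
)


def benchmark_features(
    seed: int,
    n_slices: int = 6,
    spec_overrides: dict | None = None,
    denoise_cfg: pp.DenoiseConfig | None = None,
):
    """Generate phantoms, run detection, return the labelled feature set.

    Returns (X, y, descriptors, slice_index, results): y is +1 for true
    nodules, -1 for everything else; half the slices carry spiculated
    (malignant-like) nodules so both margin types are represented.
    """
    spec_kwargs = dict(BENCHMARK_SPEC)
    spec_kwargs.update(spec_overrides or {})
    den = denoise_cfg or pp.DenoiseConfig(method="catte", iterations=8)
    seg = pp.SegmentConfig(closing_radius=2)
    thresholds = cd.default_rule_thresholds()
    feat_cfg = ft.FeatureConfig()
    results = []
    for i in range(n_slices):
        spec = fx.PhantomSpec(
            seed=seed * 1000 + i, spiculation=(i % 2 == 1), **spec_kwargs
        )
        results.append(
            process_slice(fx.generate_phantom(spec), den, seg, thresholds)
        )
    X_rows, y_rows, descs, slice_idx = [], [], [], []
    for si, res in enumerate(results):
        for c, lab in zip(res.candidates, res.truth_labels):
            X_rows.append(ft.extract_features(c, res.denoised, feat_cfg).values)
            y_rows.append(-1 if lab == "non-nodule" else 1)
            descs.append(c.descriptors)
            slice_idx.append(si)
    return (
        np.vstack(X_rows),
        np.array(y_rows),
        descs,
        np.array(slice_idx),
        results,
    )
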