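"""Stage-based pipeline: simulate → frames → flow → features → split →
reduce → train → predict → confidence → review → evaluate → export.

Each stage reads its upstream artifacts from the project directory, writes
its own, and records a digest of (stage, config, seed) so re-running a
completed stage with unchanged configuration is a no-op.  Missing upstream
artifacts raise an error naming the stage to run first.

Note on stage order: the RICA reduction is fit on the labeled clips only
(no information leaking from test clips into the transform), so ``reduce``
depends on ``split`` as well as ``features``.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import confidence as conf_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import review as review_mod
from .backbone import ConvBackbone, make_flow_backbone
from .classifier import (
    BiLSTMNetwork,
    Hyperparameters,
    TrainedSequenceModel,
    predict as clf_predict,
    train as clf_train,
)
from .features import (
    STACK_SIZE,
    build_flow_stacks,
    concat_features,
    extract_stream_features,
    preprocess_frames,
    FeatureMatrix,
)
from .flow import TVL1Params, compute_tvl1_flow, flow_max_magnitude, flow_to_image
from .project import (
    BehaviorSet,
    ClipRecord,
    VideoRecord,
    select_labeled_clips,
    split_train_validate,
    split_video_into_clips,
)
from .rica import RicaTransform, apply_rica, fit_rica
from .synthetic import (
    BehaviorKernel,
    SyntheticBehaviorSpec,
    generate_video,
)

__all__ = ["PipelineConfig", "Project", "run_stage", "STAGES", "StageError"]

STAGES = [
    "simulate", "frames", "flow", "features", "split", "reduce",
    "train", "predict", "confidence", "review", "evaluate", "export",
]

_STAGE_DEPS = {
    "simulate": [],
    "frames": ["simulate"],
    "flow": ["frames"],
    "features": ["flow"],
    "split": ["simulate"],
    "reduce": ["features", "split"],
    "train": ["reduce"],
    "predict": ["train"],
    "confidence": ["predict"],
    "review": ["confidence"],
    "evaluate": ["predict"],
    "export": ["predict"],
}


class StageError(RuntimeError):
    pass


_KNOWN_KEYS = {
    "project_dir", "clip_seconds", "prop_labeled", "prop_validate",
    "seed", "backbone_seed", "input_size", "flow", "rica", "training",
    "confidence_method", "review", "simulate",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    project_dir: str = "project"
    clip_seconds: float = 60.0
    prop_labeled: float = 0.3
    prop_validate: float = 0.2
    seed: int = 0
    backbone_seed: int = 0
    input_size: int = 224
    flow: dict = field(default_factory=dict)  # TVL1Params overrides
    rica: dict = field(default_factory=lambda: {"d_out": 512, "lam": 1.0, "n_iter": 200})
    training: dict = field(default_factory=dict)  # Hyperparameters overrides
    confidence_method: str = "temperature"  # or "softmax"
    review: dict = field(default_factory=lambda: {"n_permutations": 100})
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.confidence_method not in ("softmax", "temperature"):
            raise ValueError("confidence_method must be softmax or temperature")
        if not 0 < cfg.prop_labeled < 1 or not 0 < cfg.prop_validate < 1:
            raise ValueError("prop_labeled and prop_validate must be in (0, 1)")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(io_mod.read_manifest(path) or {})


def _sanitize(clip_id: str) -> str:
    return clip_id.replace(":", "_")


class Project:
    """Artifact paths and loaders for one pipeline project directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.root = Path(cfg.project_dir)

    # -- paths ------------------------------------------------------------
    @property
    def manifest_path(self):
        return self.root / "manifest.yaml"

    def frames_path(self, video_id):
        return self.root / "frames" / f"{video_id}.zip"

    def flow_path(self, video_id):
        return self.root / "flow" / f"{video_id}.zip"

    def annotations_path(self, video_id):
        return self.root / "annotations" / f"{video_id}.csv"

    def features_path(self, clip_id):
        return self.root / "features" / f"{_sanitize(clip_id)}.npz"

    def reduced_path(self, clip_id):
        return self.root / "reduced" / f"{_sanitize(clip_id)}.npz"

    # -- loaders ----------------------------------------------------------
    def manifest(self) -> dict:
        if not self.manifest_path.exists():
            raise StageError("no manifest found; run stage 'simulate' first")
        return io_mod.read_manifest(self.manifest_path)

    def videos(self) -> list[VideoRecord]:
        return [io_mod.video_from_manifest(v) for v in self.manifest()["videos"]]

    def behavior_set(self) -> BehaviorSet:
        return io_mod.behavior_set_from_manifest(self.manifest())

    def clips(self) -> list[ClipRecord]:
        out = []
        for video in self.videos():
            out.extend(split_video_into_clips(video, self.cfg.clip_seconds))
        return out

    def labels_for_clip(self, clip: ClipRecord) -> np.ndarray:
        df = io_mod.read_frame_annotations(self.annotations_path(clip.video_id))
        labels = df.sort_values("frame")["label"].to_numpy(dtype=object)
        return labels[clip.start:clip.end]

    def splits(self) -> dict:
        path = self.root / "splits.json"
        if not path.exists():
            raise StageError("no data split found; run stage 'split' first")
        return json.loads(path.read_text())

    def load_model(self) -> TrainedSequenceModel:
        path = self.root / "model" / "checkpoint.npz"
        if not path.exists():
            raise StageError("no trained model found; run stage 'train' first")
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["metadata"]))
            params = {k: npz[f"param_{k}"] for k in meta["param_names"]}
        net = BiLSTMNetwork(
            K=meta["K"], d_in=meta["d_in"], hidden_units=meta["hidden_units"],
            dropout=meta["dropout"], bidirectional=meta["bidirectional"],
            seed=meta["network_seed"],
        )
        net.params = params
        return TrainedSequenceModel(
            network=net,
            behavior_set=BehaviorSet(meta["behaviors"]),
            fps=meta["fps"],
            sequence_seconds=meta["sequence_seconds"],
            log=meta["log"],
            stopping_reason=meta["stopping_reason"],
            best_epoch=meta["best_epoch"],
            seed=meta["seed"],
        )


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

_DEFAULT_KERNELS = {
    "rest": {"velocity": [0.0, 0.0], "jitter": 0.1},
    "walk": {"velocity": [1.5, 0.0], "jitter": 0.3},
    "run": {"velocity": [0.0, 3.0], "jitter": 0.5},
}


def _stage_simulate(project: Project, seed: int) -> None:
    sim = {
        "n_videos": 2, "video_seconds": 30.0, "fps": 4.0,
        "frame_size": [64, 64], "p_stay": 0.9,
        "behaviors": _DEFAULT_KERNELS,
        **project.cfg.simulate,
    }
    labels = sorted(sim["behaviors"])
    bset = BehaviorSet(labels)
    kernels = {
        name: BehaviorKernel(
            velocity=tuple(spec.get("velocity", (0.0, 0.0))),
            jitter=float(spec.get("jitter", 0.0)),
        )
        for name, spec in sim["behaviors"].items()
    }
    spec = SyntheticBehaviorSpec(
        behavior_set=bset, kernels=kernels, p_stay=sim["p_stay"],
        fps=sim["fps"], frame_size=tuple(sim["frame_size"]),
    )
    n_frames = max(2, round(sim["video_seconds"] * sim["fps"]))
    videos = []
    for v in range(int(sim["n_videos"])):
        video_id = f"video{v:02d}"
        frames, frame_labels = generate_video(spec, n_frames, seed=seed + v)
        io_mod.write_frame_archive(project.frames_path(video_id), frames)
        project.annotations_path(video_id).parent.mkdir(parents=True, exist_ok=True)
        io_mod.write_frame_annotations(
            project.annotations_path(video_id), video_id, frame_labels
        )
        videos.append(
            {"video_id": video_id, "n_frames": n_frames, "fps": sim["fps"],
             "cameras": 1}
        )
    io_mod.write_manifest(
        project.manifest_path,
        {"videos": videos, "behaviors": labels,
         "clip_seconds": project.cfg.clip_seconds, "seed": seed},
    )


def _stage_frames(project: Project, seed: int) -> None:
    # frame stores are produced by `simulate` (or supplied externally);
    # this stage validates that every video has its archive
    for video in project.videos():
        if not project.frames_path(video.video_id).exists():
            raise StageError(
                f"no frame archive for {video.video_id}; run stage "
                "'simulate' first (or provide frames/<video>.zip)"
            )


def _stage_flow(project: Project, seed: int) -> None:
    params = TVL1Params(**project.cfg.flow)
    for video in project.videos():
        frames = io_mod.read_frame_archive(project.frames_path(video.video_id))
        flows = [
            compute_tvl1_flow(frames[j], frames[j + 1], params)
            for j in range(len(frames) - 1)
        ]
        flows.append(flows[-1])  # last frame reuses the final flow field
        max_mag = flow_max_magnitude(flows)
        images = [flow_to_image(f, max_mag) for f in flows]
        io_mod.write_frame_archive(project.flow_path(video.video_id), images)


def _stage_features(project: Project, seed: int) -> None:
    cfg = project.cfg
    spatial_bb = ConvBackbone(in_channels=3, seed=cfg.backbone_seed)
    flow_bb = make_flow_backbone(spatial_bb, STACK_SIZE)
    for video in project.videos():
        if not project.flow_path(video.video_id).exists():
            raise StageError(
                f"no flow archive for {video.video_id}; run stage 'flow' first"
            )
        frames = io_mod.read_frame_archive(project.frames_path(video.video_id))
        flow_imgs = io_mod.read_frame_archive(project.flow_path(video.video_id))
        spatial_in = preprocess_frames(frames, size=cfg.input_size)
        temporal_in = build_flow_stacks(
            preprocess_frames(flow_imgs, size=cfg.input_size), STACK_SIZE
        )
        spatial = extract_stream_features(spatial_in, spatial_bb, "spatial")
        temporal = extract_stream_features(temporal_in, flow_bb, "temporal")
        concat = concat_features([spatial, temporal])
        for clip in split_video_into_clips(video, cfg.clip_seconds):
            io_mod.save_features(
                project.features_path(clip.clip_id),
                concat.values[clip.start:clip.end],
                stream="concat", clip_id=clip.clip_id, d=concat.d,
                backbone_seed=cfg.backbone_seed,
            )


def _stage_split(project: Project, seed: int) -> None:
    clips = project.clips()
    split = select_labeled_clips(clips, project.cfg.prop_labeled, seed)
    train_ids, val_ids = split_train_validate(
        split.labeled, project.cfg.prop_validate, seed
    )
    data = {
        "labeled": split.labeled, "unlabeled": split.unlabeled,
        "train": train_ids, "validate": val_ids,
        "prop_labeled": project.cfg.prop_labeled,
        "prop_validate": project.cfg.prop_validate,
    }
    (project.root / "splits.json").write_text(json.dumps(data, indent=1))


def _load_feature_map(project: Project, clip_ids, which) -> dict:
    out = {}
    for cid in clip_ids:
        path = (project.features_path(cid) if which == "features"
                else project.reduced_path(cid))
        if not path.exists():
            stage = "features" if which == "features" else "reduce"
            raise StageError(f"missing {which} for clip {cid}; run stage "
                             f"'{stage}' first")
        values, _ = io_mod.load_features(path)
        out[cid] = values
    return out


def _stage_reduce(project: Project, seed: int) -> None:
    cfg = project.cfg
    splits = project.splits()
    labeled = _load_feature_map(project, splits["labeled"], "features")
    X = np.concatenate(list(labeled.values()), axis=0)
    d_out = min(int(cfg.rica.get("d_out", 512)), X.shape[1], X.shape[0])
    transform = fit_rica(
        X, d_out=d_out, lam=float(cfg.rica.get("lam", 1.0)),
        n_iter=int(cfg.rica.get("n_iter", 200)), seed=seed,
    )
    (project.root / "reduced").mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        project.root / "reduced" / "rica.npz",
        W=transform.W, mean=transform.mean, std=transform.std,
        lam=transform.lam, seed=transform.seed,
    )
    all_ids = splits["labeled"] + splits["unlabeled"]
    feats = _load_feature_map(project, all_ids, "features")
    for cid, values in feats.items():
        io_mod.save_features(
            project.reduced_path(cid), apply_rica(transform, values),
            stream="reduced", clip_id=cid, d=d_out,
        )


def _clip_by_id(project: Project) -> dict[str, ClipRecord]:
    return {c.clip_id: c for c in project.clips()}


def _stage_train(project: Project, seed: int) -> None:
    cfg = project.cfg
    splits = project.splits()
    clip_map = _clip_by_id(project)
    bset = project.behavior_set()
    fps = project.videos()[0].fps
    hp = Hyperparameters(**cfg.training)

    def labeled_map(ids):
        feats = _load_feature_map(project, ids, "reduced")
        return {cid: (feats[cid], project.labels_for_clip(clip_map[cid]))
                for cid in ids}

    d_in = next(iter(
        _load_feature_map(project, splits["train"][:1], "reduced").values()
    )).shape[1]
    net = BiLSTMNetwork(
        K=bset.K, d_in=d_in, hidden_units=hp.hidden_units,
        dropout=hp.dropout, seed=seed,
    )
    model = clf_train(
        net, labeled_map(splits["train"]), labeled_map(splits["validate"]),
        bset, fps, hp, seed=seed,
    )
    out = project.root / "model"
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "K": bset.K, "d_in": d_in, "hidden_units": hp.hidden_units,
        "dropout": hp.dropout, "bidirectional": True, "network_seed": seed,
        "behaviors": list(bset.labels), "fps": fps,
        "sequence_seconds": hp.sequence_seconds, "log": model.log,
        "stopping_reason": model.stopping_reason,
        "best_epoch": model.best_epoch, "seed": seed,
        "param_names": sorted(model.network.params),
    }
    np.savez_compressed(
        out / "checkpoint.npz",
        metadata=json.dumps(meta),
        **{f"param_{k}": v for k, v in model.network.params.items()},
    )
    pd.DataFrame(model.log).to_csv(out / "training_log.csv", index=False)


def _stage_predict(project: Project, seed: int) -> None:
    splits = project.splits()
    model = project.load_model()
    out = project.root / "predictions"
    out.mkdir(parents=True, exist_ok=True)
    for cid in splits["unlabeled"] + splits["validate"]:
        feats = _load_feature_map(project, [cid], "reduced")[cid]
        result = clf_predict(model, feats)
        np.savez_compressed(
            out / f"{_sanitize(cid)}.npz",
            logits=result.logits, label_indices=result.label_indices,
        )


def _load_predictions(project: Project, cid: str):
    path = project.root / "predictions" / f"{_sanitize(cid)}.npz"
    if not path.exists():
        raise StageError(f"no predictions for clip {cid}; run stage "
                         "'predict' first")
    with np.load(path) as npz:
        return npz["logits"], npz["label_indices"]


def _stage_confidence(project: Project, seed: int) -> None:
    splits = project.splits()
    clip_map = _clip_by_id(project)
    bset = project.behavior_set()
    # temperature fitted on validation-set logits from the best-epoch model
    val_logits, val_true = [], []
    for cid in splits["validate"]:
        logits, _ = _load_predictions(project, cid)
        val_logits.append(logits)
        val_true.append(bset.to_indices(project.labels_for_clip(clip_map[cid])))
    tmodel = conf_mod.fit_temperature(
        np.concatenate(val_logits), np.concatenate(val_true)
    )
    rows = []
    for cid in splits["unlabeled"]:
        logits, pred_idx = _load_predictions(project, cid)
        true = project.labels_for_clip(clip_map[cid])
        rows.append(
            {
                "clip_id": cid,
                "n_frames": logits.shape[0],
                "conf_softmax": conf_mod.clip_confidence(
                    conf_mod.softmax_confidence(logits)
                ),
                "conf_temperature": conf_mod.clip_confidence(
                    conf_mod.scaled_confidence(logits, tmodel.T)
                ),
                "acc": conf_mod.clip_accuracy(bset.to_labels(pred_idx), true),
            }
        )
    out = project.root / "confidence"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "clips.csv", index=False)
    (out / "temperature.json").write_text(
        json.dumps({"T": tmodel.T, "nll_initial": tmodel.nll_initial,
                    "nll_fitted": tmodel.nll_fitted})
    )


def _confidence_table(project: Project) -> pd.DataFrame:
    path = project.root / "confidence" / "clips.csv"
    if not path.exists():
        raise StageError("no confidence table; run stage 'confidence' first")
    return pd.read_csv(path)


def _stage_review(project: Project, seed: int) -> None:
    cfg = project.cfg
    df = _confidence_table(project)
    conf_col = f"conf_{cfg.confidence_method}"
    summary = review_mod.review_summary(
        df["acc"].to_numpy(), df["n_frames"].to_numpy(),
        confidences=df[conf_col].to_numpy(),
        n_permutations=int(cfg.review.get("n_permutations", 100)),
        seed=seed,
    )
    out = project.root / "review"
    out.mkdir(parents=True, exist_ok=True)
    order = summary.curve_candidate.order
    pd.DataFrame(
        {
            "clip_id": df["clip_id"].to_numpy()[order],
            "confidence": df[conf_col].to_numpy()[order],
            "rank": np.arange(1, len(order) + 1),
        }
    ).to_csv(out / "order.csv", index=False)
    pd.DataFrame(
        {
            "k": np.arange(len(summary.curve_candidate.acc_k)),
            "acc_confidence": summary.curve_candidate.acc_k,
            "acc_optimal": summary.curve_optimal.acc_k,
            "acc_random": summary.curve_random.acc_k,
        }
    ).to_csv(out / "curves.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(
            {
                "mean_ior_confidence": summary.mean_ior_candidate,
                "mean_ior_optimal": summary.mean_ior_optimal,
                "review_efficiency": summary.efficiency,
            }
        )
    )


def _stage_evaluate(project: Project, seed: int) -> None:
    splits = project.splits()
    clip_map = _clip_by_id(project)
    bset = project.behavior_set()
    pred_all, true_all = [], []
    for cid in splits["unlabeled"]:
        _, pred_idx = _load_predictions(project, cid)
        pred_all.append(bset.to_labels(pred_idx))
        true_all.append(project.labels_for_clip(clip_map[cid]))
    pred = np.concatenate(pred_all)
    true = np.concatenate(true_all)
    per_class, f1_all = metrics_mod.per_class_prf(pred, true, bset)
    report = {
        "accuracy": metrics_mod.accuracy(pred, true),
        "f1_all": f1_all,
        "per_class": {
            label: {"precision": m.precision, "recall": m.recall, "f1": m.f1,
                    "degenerate": m.degenerate}
            for label, m in per_class.items()
        },
    }
    out = project.root / "evaluation"
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(json.dumps(report, indent=1))
    cm = metrics_mod.confusion_matrix(pred, true, bset)
    pd.DataFrame(cm, index=list(bset.labels), columns=list(bset.labels)).to_csv(
        out / "confusion.csv"
    )


def _stage_export(project: Project, seed: int, partial: bool = False) -> None:
    splits = project.splits()
    clip_map = _clip_by_id(project)
    bset = project.behavior_set()
    conf_df = None
    try:
        conf_df = _confidence_table(project).set_index("clip_id")
    except StageError:
        pass
    frame_rows, bout_rows = [], []
    for cid in sorted(clip_map):
        clip = clip_map[cid]
        if cid in set(splits["unlabeled"]):
            try:
                _, pred_idx = _load_predictions(project, cid)
            except StageError:
                if partial:
                    continue
                raise StageError(
                    f"clip {cid} has neither human labels nor predictions; "
                    "run stage 'predict' first or export with partial=True"
                )
            labels = bset.to_labels(pred_idx)
            source = "classifier"
            conf = (float(conf_df.loc[cid, "conf_temperature"])
                    if conf_df is not None and cid in conf_df.index else np.nan)
        else:
            labels = project.labels_for_clip(clip)
            source = "human"
            conf = np.nan
        for j, label in enumerate(labels):
            frame_rows.append(
                {"video_id": clip.video_id, "frame": clip.start + j,
                 "label": label, "clip_id": cid, "source": source,
                 "confidence": conf}
            )
        bouts = io_mod.frames_to_bouts(clip.video_id, labels)
        bouts["start_frame"] += clip.start
        bouts["end_frame"] += clip.start
        bouts["clip_id"] = cid
        bouts["source"] = source
        bout_rows.append(bouts)
    out = project.root / "export"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(frame_rows).to_csv(out / "frame_annotations.csv", index=False)
    pd.concat(bout_rows, ignore_index=True).to_csv(
        out / "bout_annotations.csv", index=False
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "frames": _stage_frames,
    "flow": _stage_flow,
    "features": _stage_features,
    "split": _stage_split,
    "reduce": _stage_reduce,
    "train": _stage_train,
    "predict": _stage_predict,
    "confidence": _stage_confidence,
    "review": _stage_review,
    "evaluate": _stage_evaluate,
    "export": _stage_export,
}


def _stage_digest(stage: str, cfg: PipelineConfig, seed: int) -> str:
    payload = json.dumps({"stage": stage, "cfg": asdict(cfg), "seed": seed},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_stage(stage: str, cfg: PipelineConfig, seed: int | None = None,
              force: bool = False) -> dict:
    """Run one pipeline stage; skip if already complete with this config.

    Returns the stage log entry (digest, elapsed seconds, skipped flag).
    """
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    seed = cfg.seed if seed is None else seed
    project = Project(cfg)
    project.root.mkdir(parents=True, exist_ok=True)
    log_path = project.root / ".stages.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else {}
    digest = _stage_digest(stage, cfg, seed)
    if not force and log.get(stage, {}).get("digest") == digest:
        return {**log[stage], "skipped": True}
    for dep in _STAGE_DEPS[stage]:
        if log.get(dep, {}).get("digest") is None:
            raise StageError(
                f"stage '{stage}' requires '{dep}'; run stage '{dep}' first"
            )
    t0 = time.perf_counter()
    _STAGE_FUNCS[stage](project, seed)
    entry = {"digest": digest, "seed": seed,
             "elapsed_s": round(time.perf_counter() - t0, 3),
             "skipped": False}
    log[stage] = entry
    log_path.write_text(json.dumps(log, indent=1))
    # freeze the config used for this run next to the artifacts
    io_mod.write_manifest(project.root / "config.frozen.yaml", asdict(cfg))
    return entry
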