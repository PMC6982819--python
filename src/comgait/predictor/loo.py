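"""Leave-one-subject-out evaluation harness.

Each fold trains on every other subject's stance segments and tests on
the held-out subject.  The speed-offset model, the feature min--max
extrema and the label normalization are refitted inside each fold from
training subjects only, so nothing measured on the test subject leaks
into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from comgait.predictor.metrics import (
    MetricsReport,
    compute_mae,
    compute_nrmse,
    compute_pearson,
)
from comgait.predictor.network import MLP, NetworkSpec, build_network
from comgait.predictor.training import TrainConfig, predict_outputs, train_network
from comgait.preprocessing import (
    ChannelScaler,
    StanceSegment,
    assemble_features,
    detect_gait_events,
    fit_feature_scaler,
    fit_speed_offset_model,
    integrate_segment,
    segment_trial,
)
from comgait.synthetic_data.trial import LABEL_CHANNELS, ImuTrial, StepLabels

logger = logging.getLogger(__name__)

SPEED_LABELS = ("slow", "moderate", "fast")


@dataclass(frozen=True)
class LooConfig:
    train: TrainConfig = TrainConfig()
    spec: NetworkSpec = NetworkSpec()
    input_rows: tuple[int, ...] | None = None   # feature-row subset (ablation)
    train_speeds: tuple[str, ...] | None = None  # speed-restricted training
    max_segments_per_trial: int | None = 30
    resample_points: int = 200


@dataclass
class PreparedSegment:
    segment: StanceSegment
    step_labels: StepLabels
    uid: str


@dataclass
class LooFold:
    test_subject: str
    train_uids: list[str]
    test_uids: list[str]

    @property
    def n_train(self) -> int:
        return len(self.train_uids)


@dataclass
class LooResult:
    report: MetricsReport
    folds: list[LooFold] = field(default_factory=list)


def prepare_trial(
    trial: ImuTrial, max_segments: int | None = 30
) -> list[PreparedSegment]:
    """Detect events, segment, and pair each stance with its label block."""
    if trial.labels is None or not trial.labels.steps:
        raise ValueError("trial lacks per-stance label blocks")
    events = detect_gait_events(trial)
    segments = segment_trial(trial, events)
    starts = np.array([s.t[0] for s in trial.labels.steps])
    out: list[PreparedSegment] = []
    for j, seg in enumerate(segments):
        k = int(np.argmin(np.abs(starts - seg.t[0])))
        if abs(starts[k] - seg.t[0]) > 0.1:
            logger.warning(
                "segment %d of %s/%s has no matching label block; dropped",
                j, trial.subject_id, trial.speed_label,
            )
            continue
        uid = f"{trial.subject_id}:{trial.speed_label}:{j}"
        out.append(PreparedSegment(seg, trial.labels.steps[k], uid))
    if max_segments is not None:
        out = out[:max_segments]
    return out


def prepare_cohort(
    trials: list[ImuTrial], max_segments: int | None = 30
) -> list[PreparedSegment]:
    prepared: list[PreparedSegment] = []
    for trial in trials:
        prepared.extend(prepare_trial(trial, max_segments))
    return prepared


def loo_folds(
    prepared: list[PreparedSegment],
    train_speeds: tuple[str, ...] | None = None,
) -> list[LooFold]:
    """Fold bookkeeping: per held-out subject, train/test segment ids."""
    subjects = sorted({p.segment.subject_id for p in prepared})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 subjects")
    folds = []
    for sid in subjects:
        train = [
            p.uid for p in prepared
            if p.segment.subject_id != sid
            and (train_speeds is None or p.segment.speed_label in train_speeds)
        ]
        test = [p.uid for p in prepared if p.segment.subject_id == sid]
        folds.append(LooFold(sid, train, test))
    return folds


def _label_block(
    p: PreparedSegment, n_points: int
) -> np.ndarray:
    t_query = np.linspace(p.segment.t[0], p.segment.t[-1], n_points)
    return p.step_labels.sample(t_query)


def _fit_fold(
    train: list[PreparedSegment],
    test: list[PreparedSegment],
    cfg: LooConfig,
    fold_seed: int,
) -> tuple[MLP, ChannelScaler, ChannelScaler, list[np.ndarray], list[np.ndarray]]:
    offset_model = fit_speed_offset_model([p.segment for p in train])
    for p in train + test:
        integrate_segment(p.segment, offset_model)
    feat_scaler = fit_feature_scaler([p.segment for p in train])

    train_feats, train_labs = [], []
    for p in train:
        fb = assemble_features(p.segment, feat_scaler, n_points=cfg.resample_points)
        train_feats.append(fb.values)
        train_labs.append(_label_block(p, cfg.resample_points))
    label_scaler = ChannelScaler().fit(np.hstack(train_labs))

    rows = list(cfg.input_rows) if cfg.input_rows is not None else None
    x = np.hstack(train_feats)
    if rows is not None:
        x = x[rows]
    y = np.hstack([label_scaler.transform(lb) for lb in train_labs])

    spec = NetworkSpec(
        input_dim=x.shape[0],
        hidden_dim=cfg.spec.hidden_dim,
        output_dim=cfg.spec.output_dim,
    )
    model = build_network(spec, seed=fold_seed)
    train_network(model, x, y, cfg.train)

    test_feats, test_labs = [], []
    for p in test:
        fb = assemble_features(p.segment, feat_scaler, n_points=cfg.resample_points)
        values = fb.values[rows] if rows is not None else fb.values
        test_feats.append(values)
        test_labs.append(_label_block(p, cfg.resample_points))
    return model, feat_scaler, label_scaler, test_feats, test_labs


def loo_evaluate(
    trials: list[ImuTrial],
    cfg: LooConfig | None = None,
    prepared: list[PreparedSegment] | None = None,
) -> LooResult:
    """Run the full leave-one-subject-out evaluation.

    Returns the metric report plus fold bookkeeping.  Subjects without
    usable segments are skipped with a warning.
    """
    cfg = cfg or LooConfig()
    if prepared is None:
        prepared = prepare_cohort(trials, cfg.max_segments_per_trial)
    by_uid = {p.uid: p for p in prepared}
    folds = loo_folds(prepared, cfg.train_speeds)

    records: list[dict] = []
    kept_folds: list[LooFold] = []
    for i, fold in enumerate(folds):
        if not fold.test_uids or not fold.train_uids:
            logger.warning("fold %s skipped: no segments", fold.test_subject)
            continue
        train = [by_uid[u] for u in fold.train_uids]
        test = [by_uid[u] for u in fold.test_uids]
        model, _, label_scaler, test_feats, test_labs = _fit_fold(
            train, test, cfg, fold_seed=cfg.train.seed + i
        )
        # pool predictions per (channel, speed) for the held-out subject
        by_speed: dict[str, tuple[list, list]] = {}
        for p, xf, lb in zip(test, test_feats, test_labs):
            pred = label_scaler.inverse(predict_outputs(model, xf))
            preds, obss = by_speed.setdefault(p.segment.speed_label, ([], []))
            preds.append(pred)
            obss.append(lb)
        for speed, (preds, obss) in by_speed.items():
            pred = np.hstack(preds)
            obs = np.hstack(obss)
            for c, name in enumerate(LABEL_CHANNELS):
                records.append({
                    "channel": name,
                    "subject": fold.test_subject,
                    "speed": speed,
                    "nrmse": compute_nrmse(pred[c], obs[c]),
                    "mae": compute_mae(pred[c], obs[c]),
                    "pearson": compute_pearson(pred[c], obs[c]),
                })
        kept_folds.append(fold)
    return LooResult(MetricsReport.from_records(records), kept_folds)


def speed_ablation_reports(
    trials: list[ImuTrial], cfg: LooConfig | None = None
) -> dict[str, LooResult]:
    """Three runs with speed-restricted training sets."""
    cfg = cfg or LooConfig()
    prepared = prepare_cohort(trials, cfg.max_segments_per_trial)
    out = {}
    for name, speeds in (
        ("all", None),
        ("slow+moderate", ("slow", "moderate")),
        ("moderate", ("moderate",)),
    ):
        run_cfg = LooConfig(
            train=cfg.train, spec=cfg.spec, input_rows=cfg.input_rows,
            train_speeds=speeds,
            max_segments_per_trial=cfg.max_segments_per_trial,
            resample_points=cfg.resample_points,
        )
        # fresh copies: integration mutates segments
        out[name] = loo_evaluate(trials, run_cfg, prepared=prepared)
    return out
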