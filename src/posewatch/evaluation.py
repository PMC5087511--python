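"""Metrics and the four seeded simulation sweeps.

Rate conventions
----------------
Rates are computed over *trials* — one rendered situation (a held posture, a
scripted fall, a scripted confounder) — not over frames, and positive and
negative trials form separate pools:

* ``tp_pct``: detected targets / positive trials (and ``fp = 100 - tp``),
* ``tn_pct``: correctly rejected non-targets / negative trials
  (``fn = 100 - tn``).

This complement convention is the only reading consistent with reporting
all four numbers from two trial pools, and it is what the sweep tables
print.

The sweeps re-run the full pipeline — generate data, train, evaluate — per
condition and seed, and return tidy :class:`pandas.DataFrame` tables:

* :func:`sweep_hidden` — posture accuracy vs hidden-layer size,
* :func:`sweep_instances` — posture accuracy vs training-set size,
* :func:`sweep_distance` — end-to-end fall alarms vs camera distance,
* :func:`sweep_angles` — end-to-end fall alarms vs camera/subject angles.

:func:`benchmark_suite` bundles the package's headline measurements
(posture true-positive/true-negative rates at the optimal configuration and
fall-alarm rates across distances and angles) behind one seeded entry point;
the acceptance script and the heavy end-to-end tests both call it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detectors import (
    ClassifierBundle,
    build_fall_classifier,
    build_lower_classifier,
    build_upper_classifier,
)
from .monitor import MonitorConfig, run_monitor
from .neural import NO_LABEL, NetworkConfig, predict_label
from .synthetic import (
    CameraModel,
    MotionScript,
    SubjectModel,
    bend_down,
    enrollment_calibration,
    fall,
    generate_distractor_features,
    generate_fall_windows,
    generate_posture_dataset,
    hold,
    quick_sit,
    render_script,
    subject_pool,
)

__all__ = [
    "EvalReport",
    "UndefinedRateError",
    "confusion_rates",
    "train_posture_pair",
    "evaluate_posture_bundle",
    "fall_alarm_rate",
    "sweep_hidden",
    "sweep_instances",
    "sweep_distance",
    "sweep_angles",
    "format_sweep_table",
    "benchmark_suite",
]


class UndefinedRateError(ValueError):
    """A rate over an empty trial pool was requested."""


@dataclass(frozen=True)
class EvalReport:
    """Percentages over one condition's positive and negative trial pools."""

    tp_pct: float
    tn_pct: float
    n_positive: int
    n_negative: int
    condition: str = ""

    @property
    def fp_pct(self) -> float:
        return 100.0 - self.tp_pct

    @property
    def fn_pct(self) -> float:
        return 100.0 - self.tn_pct


def confusion_rates(truth, detections, condition: str = "") -> EvalReport:
    """Trial-level rates; a truth label of ``"none"`` marks a negative trial.

    A positive trial counts as detected when the detection equals its truth
    label; a negative trial is correctly rejected when the detection is
    ``"none"``.  Both pools must be non-empty.
    """
    truth = [str(v) for v in truth]
    detections = [str(v) for v in detections]
    if len(truth) != len(detections):
        raise ValueError("truth and detections must have equal length")
    pos = [(t, d) for t, d in zip(truth, detections) if t != NO_LABEL]
    neg = [(t, d) for t, d in zip(truth, detections) if t == NO_LABEL]
    if not pos or not neg:
        raise UndefinedRateError("need at least one positive and one negative trial")
    tp = sum(1 for t, d in pos if d == t)
    tn = sum(1 for _, d in neg if d == NO_LABEL)
    return EvalReport(
        tp_pct=100.0 * tp / len(pos),
        tn_pct=100.0 * tn / len(neg),
        n_positive=len(pos),
        n_negative=len(neg),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# posture studies
# ---------------------------------------------------------------------------


def _derived(seed: int, k: int) -> int:
    return int((seed * 1009 + k) % (2**31))


def _net_config(n_hidden: int, seed: int, transfer: str, max_epochs: int) -> NetworkConfig:
    return NetworkConfig(
        n_in=1, n_out=2, n_hidden=n_hidden, transfer=transfer, seed=seed, max_epochs=max_epochs
    )


def train_posture_pair(
    seed: int,
    hidden=(12, 10),
    n_train=(632, 735),
    subjects: Optional[Sequence[SubjectModel]] = None,
    camera: Optional[CameraModel] = None,
    jitter_sigma: float = 0.02,
    transfer: str = "sigmoid",
    max_epochs: int = 20000,
):
    """Train the upper and lower posture classifiers for one seed."""
    subjects = list(subjects) if subjects is not None else subject_pool()
    camera = camera if camera is not None else CameraModel()
    ds_u = generate_posture_dataset(
        "upper", n_train[0], subjects, camera, jitter_sigma, seed=_derived(seed, 1)
    )
    ds_l = generate_posture_dataset(
        "lower", n_train[1], subjects, camera, jitter_sigma, seed=_derived(seed, 2)
    )
    upper = build_upper_classifier(
        ds_u, config=_net_config(hidden[0], _derived(seed, 3), transfer, max_epochs)
    )
    lower = build_lower_classifier(
        ds_l, config=_net_config(hidden[1], _derived(seed, 4), transfer, max_epochs)
    )
    return upper, lower


def evaluate_posture_bundle(
    bundle: ClassifierBundle,
    body: str,
    seed: int,
    n_test: int = 500,
    n_distractors: int = 500,
    subjects: Optional[Sequence[SubjectModel]] = None,
    camera: Optional[CameraModel] = None,
    jitter_sigma: float = 0.02,
    condition: str = "",
) -> EvalReport:
    """Held-out accuracy: fresh labeled frames (positives) plus distractor
    poses matching no class (negatives, correct when rejected as ``none``)."""
    subjects = list(subjects) if subjects is not None else subject_pool()
    camera = camera if camera is not None else CameraModel()
    test = generate_posture_dataset(
        body, n_test, subjects, camera, jitter_sigma, seed=_derived(seed, 5)
    )
    labels = list(bundle.mlp.classes_)
    outputs = bundle.mlp.decision_function(test.X)
    predicted = [
        predict_label(o, labels, bundle.confidence_threshold, bundle.margin) for o in outputs
    ]
    truth = [str(v) for v in test.y]
    if n_distractors > 0:
        Xd = generate_distractor_features(
            body, n_distractors, subjects, camera, jitter_sigma, seed=_derived(seed, 6)
        )
        outputs_d = bundle.mlp.decision_function(Xd)
        predicted += [
            predict_label(o, labels, bundle.confidence_threshold, bundle.margin)
            for o in outputs_d
        ]
        truth += [NO_LABEL] * len(Xd)
        return confusion_rates(truth, predicted, condition=condition)
    tp = 100.0 * np.mean([t == p for t, p in zip(truth, predicted)])
    return EvalReport(
        tp_pct=float(tp), tn_pct=float("nan"), n_positive=len(truth), n_negative=0,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# fall studies
# ---------------------------------------------------------------------------


def _as_range(level):
    if np.isscalar(level):
        return float(level), float(level)
    lo, hi = level
    return float(lo), float(hi)


def fall_alarm_rate(
    fall_bundle: ClassifierBundle,
    lower_bundle: Optional[ClassifierBundle],
    seed: int,
    n_sequences: int = 100,
    distance=(1.0, 4.5),
    vertical_angle=0.0,
    horizontal_rotation=0.0,
    subjects: Optional[Sequence[SubjectModel]] = None,
    camera: Optional[CameraModel] = None,
    monitor_config: Optional[MonitorConfig] = None,
    jitter_sigma: float = 0.02,
    ground_time: float = 20.0,
    negatives: bool = False,
) -> EvalReport:
    """End-to-end alarm rate of the monitor over scripted sequences.

    Positives are falls (descent time uniform 0.5–1.0 s, then
    ``ground_time`` on the floor); with ``negatives=True`` an equal number
    of confounder sequences (quick sit holding seated, deep bend with
    recovery) measures the true-negative rate.  Camera distance and angles
    are scalars or ``(lo, hi)`` ranges sampled uniformly per sequence.
    """
    subjects = list(subjects) if subjects is not None else subject_pool()
    base = camera if camera is not None else CameraModel()
    mc = monitor_config or MonitorConfig()
    rng = np.random.default_rng(_derived(seed, 7))

    def run_one(script: MotionScript, cam: CameraModel, subject: SubjectModel) -> bool:
        frames = render_script(
            subject, script, cam, seed=int(rng.integers(2**31)), jitter_sigma=jitter_sigma
        )
        calib = enrollment_calibration(subject, cam)
        events = run_monitor(
            frames, fall_bundle, lower_bundle, mc, calibration=calib,
            alarm_hook=lambda _event: None,  # the sweep tallies events itself
        )
        return any(e.kind == "alarm_started" for e in events)

    def sample_camera() -> CameraModel:
        d_lo, d_hi = _as_range(distance)
        v_lo, v_hi = _as_range(vertical_angle)
        h_lo, h_hi = _as_range(horizontal_rotation)
        return replace(
            base,
            distance=float(rng.uniform(d_lo, d_hi)),
            vertical_angle=float(rng.uniform(v_lo, v_hi)),
            horizontal_rotation=float(rng.uniform(h_lo, h_hi)),
        )

    alarms = 0
    for i in range(n_sequences):
        subject = subjects[i % len(subjects)]
        script = MotionScript(
            (hold("standing", 1.0), fall(float(rng.uniform(0.5, 1.0)), ground_time))
        )
        alarms += run_one(script, sample_camera(), subject)
    tp = 100.0 * alarms / n_sequences if n_sequences else float("nan")

    tn = float("nan")
    n_neg = 0
    if negatives:
        confound = 0
        for i in range(n_sequences):
            subject = subjects[i % len(subjects)]
            if i % 2 == 0:
                script = MotionScript(
                    (hold("standing", 1.0), quick_sit(0.8, max(2.0, ground_time)))
                )
            else:
                script = MotionScript(
                    (
                        hold("standing", 1.0),
                        bend_down(0.35, 2.4),
                        hold("standing", max(2.0, ground_time - 2.4)),
                    )
                )
            confound += run_one(script, sample_camera(), subject)
        n_neg = n_sequences
        tn = 100.0 * (n_sequences - confound) / n_sequences
    return EvalReport(
        tp_pct=tp,
        tn_pct=tn,
        n_positive=n_sequences,
        n_negative=n_neg,
        condition=f"d={distance}, v={vertical_angle}, h={horizontal_rotation}",
    )


def train_fall_pipeline(
    seed: int,
    n_fall: int = 600,
    n_nonfall: int = 600,
    subjects: Optional[Sequence[SubjectModel]] = None,
    camera: Optional[CameraModel] = None,
    jitter_sigma: float = 0.02,
    max_epochs: int = 20000,
    lower_bundle: Optional[ClassifierBundle] = None,
    lower_n_train: int = 735,
):
    """Train the fall-window classifier (and, if needed, the lower-body
    classifier the monitor uses for stand-up detection)."""
    subjects = list(subjects) if subjects is not None else subject_pool()
    camera = camera if camera is not None else CameraModel()
    windows = generate_fall_windows(
        n_fall, n_nonfall, subjects, camera, jitter_sigma=jitter_sigma, seed=_derived(seed, 8)
    )
    fall_bundle = build_fall_classifier(
        windows, config=_net_config(None, _derived(seed, 9), "sigmoid", max_epochs)
    )
    if lower_bundle is None:
        ds_l = generate_posture_dataset(
            "lower", lower_n_train, subjects, camera, jitter_sigma, seed=_derived(seed, 2)
        )
        lower_bundle = build_lower_classifier(
            ds_l, config=_net_config(10, _derived(seed, 4), "sigmoid", max_epochs)
        )
    return fall_bundle, lower_bundle


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

#: hidden-neuron cases (upper/lower), smallest to largest
HIDDEN_LEVELS = ((8, 6), (10, 8), (12, 10), (14, 12), (16, 14))
#: training-set size cases (upper/lower) spanning too-few to too-many
INSTANCE_LEVELS = ((250, 350), (500, 600), (632, 735), (800, 900), (1050, 1150), (1450, 1600))


def _posture_sweep(levels, vary: str, seeds, n_test, n_distractors, kwargs) -> pd.DataFrame:
    rows = []
    for case, level in enumerate(levels, start=1):
        for seed in seeds:
            common = dict(kwargs)
            if vary == "hidden":
                common["hidden"] = level
            else:
                common["n_train"] = level
            upper, lower = train_posture_pair(seed, **common)
            for body, bundle in (("upper", upper), ("lower", lower)):
                report = evaluate_posture_bundle(
                    bundle,
                    body,
                    seed,
                    n_test=n_test,
                    n_distractors=n_distractors,
                    subjects=common.get("subjects"),
                    camera=common.get("camera"),
                    jitter_sigma=common.get("jitter_sigma", 0.02),
                    condition=f"case {case}: {level[0]}/{level[1]}",
                )
                rows.append(
                    {
                        "case": case,
                        "level": f"{level[0]}/{level[1]}",
                        "seed": seed,
                        "body": body,
                        "tp_pct": report.tp_pct,
                        "tn_pct": report.tn_pct,
                        "fp_pct": report.fp_pct,
                        "fn_pct": report.fn_pct,
                        "n_positive": report.n_positive,
                        "n_negative": report.n_negative,
                        "converged": bundle.mlp.converged_,
                    }
                )
    return pd.DataFrame(rows)


def sweep_hidden(
    levels=HIDDEN_LEVELS, seeds=(1,), n_test: int = 300, n_distractors: int = 300, **kwargs
) -> pd.DataFrame:
    """Posture accuracy per (upper, lower) hidden-layer size pair."""
    if not levels:
        raise ValueError("sweep needs at least one level")
    return _posture_sweep(levels, "hidden", seeds, n_test, n_distractors, kwargs)


def sweep_instances(
    levels=INSTANCE_LEVELS, seeds=(1,), n_test: int = 300, n_distractors: int = 300, **kwargs
) -> pd.DataFrame:
    """Posture accuracy per (upper, lower) training-set size pair."""
    if not levels:
        raise ValueError("sweep needs at least one level")
    return _posture_sweep(levels, "instances", seeds, n_test, n_distractors, kwargs)


def _fall_sweep(conditions, seeds, n_sequences, negatives, train_kwargs, rate_kwargs):
    rows = []
    for case, (label, dist, vert, horiz) in enumerate(conditions, start=1):
        for seed in seeds:
            fall_bundle, lower_bundle = train_fall_pipeline(seed, **train_kwargs)
            report = fall_alarm_rate(
                fall_bundle,
                lower_bundle,
                seed,
                n_sequences=n_sequences,
                distance=dist,
                vertical_angle=vert,
                horizontal_rotation=horiz,
                negatives=negatives,
                **rate_kwargs,
            )
            rows.append(
                {
                    "case": case,
                    "level": label,
                    "seed": seed,
                    "tp_pct": report.tp_pct,
                    "tn_pct": report.tn_pct,
                    "n_positive": report.n_positive,
                    "n_negative": report.n_negative,
                }
            )
    return pd.DataFrame(rows)


def sweep_distance(
    levels=((0.6, 0.9), (1.0, 4.5), (4.6, 6.0)),
    seeds=(1,),
    n_sequences: int = 30,
    negatives: bool = True,
    train_kwargs: Optional[dict] = None,
    **rate_kwargs,
) -> pd.DataFrame:
    """End-to-end fall-alarm rates per camera-distance band."""
    if not levels:
        raise ValueError("sweep needs at least one level")
    conditions = [(f"{_as_range(l)[0]}-{_as_range(l)[1]} m", l, 0.0, 0.0) for l in levels]
    return _fall_sweep(conditions, seeds, n_sequences, negatives, train_kwargs or {}, rate_kwargs)


def sweep_angles(
    levels=(
        ("v0 h0-45", 2.5, 0.0, (0.0, 45.0)),
        ("v0 h45-90", 2.5, 0.0, (45.0, 90.0)),
        ("v0-35 h0", 2.5, (0.0, 35.0), 0.0),
        ("v35-45 h0", 2.5, (35.0, 45.0), 0.0),
        ("v45-60 h0", 2.5, (45.0, 60.0), 0.0),
    ),
    seeds=(1,),
    n_sequences: int = 30,
    negatives: bool = True,
    train_kwargs: Optional[dict] = None,
    **rate_kwargs,
) -> pd.DataFrame:
    """End-to-end fall-alarm rates per (vertical, horizontal) angle condition.

    Each level is ``(label, distance, vertical, horizontal)`` with scalars or
    ranges; labels must be unique.
    """
    if not levels:
        raise ValueError("sweep needs at least one level")
    labels = [l[0] for l in levels]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels in angle sweep")
    return _fall_sweep(levels, seeds, n_sequences, negatives, train_kwargs or {}, rate_kwargs)


def format_sweep_table(df: pd.DataFrame) -> str:
    """Aggregate a sweep over seeds/body halves and render a text table."""
    agg = (
        df.groupby(["case", "level"], sort=True)[["fp_pct", "fn_pct", "tp_pct", "tn_pct"]]
        .mean()
        .reset_index()
    )
    lines = [f"{'Case':<6}{'Level':<14}{'FP%':>8}{'FN%':>8}{'TP%':>8}{'TN%':>8}"]
    for _, row in agg.iterrows():
        lines.append(
            f"({row['case']})".ljust(6)
            + f"{row['level']:<14}"
            + "".join(
                f"{row[c]:>8.1f}" if np.isfinite(row[c]) else f"{'-':>8}"
                for c in ("fp_pct", "fn_pct", "tp_pct", "tn_pct")
            )
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# headline benchmark: everything the package claims, from scratch, one call
# ---------------------------------------------------------------------------


def benchmark_suite(
    base_seed: int = 1,
    n_seeds: int = 5,
    n_train=(632, 735),
    n_test: int = 500,
    n_distractors: int = 500,
    n_fall_train=(600, 600),
    n_sequences: int = 100,
    jitter_sigma: float = 0.02,
    ground_time: float = 20.0,
) -> dict:
    """Recompute the package's headline rates from scratch.

    Per seed: generate posture datasets at the optimal configuration
    (upper 15-12-5, lower 18-10-2, sigmoid), train, and measure held-out
    true-positive and distractor true-negative rates; train the fall-window
    classifier and measure end-to-end alarm rates over scripted falls at
    1–4.5 m (frontal) and at 2.5 m with the subject rotated 0–45 degrees.
    Returns mean percentages over seeds with the trial counts behind them.
    """
    subjects = subject_pool()
    camera = CameraModel()
    seeds = [base_seed + i for i in range(n_seeds)]

    per_seed: dict[str, list] = {k: [] for k in (
        "upper_tp", "upper_tn", "lower_tp", "lower_tn", "fall_tp_distance", "fall_tp_rotated"
    )}
    for seed in seeds:
        upper, lower = train_posture_pair(
            seed, hidden=(12, 10), n_train=n_train, subjects=subjects, camera=camera,
            jitter_sigma=jitter_sigma,
        )
        for body, bundle in (("upper", upper), ("lower", lower)):
            report = evaluate_posture_bundle(
                bundle, body, seed, n_test=n_test, n_distractors=n_distractors,
                subjects=subjects, camera=camera, jitter_sigma=jitter_sigma,
            )
            per_seed[f"{body}_tp"].append(report.tp_pct)
            per_seed[f"{body}_tn"].append(report.tn_pct)
        fall_bundle, _ = train_fall_pipeline(
            seed, n_fall=n_fall_train[0], n_nonfall=n_fall_train[1], subjects=subjects,
            camera=camera, jitter_sigma=jitter_sigma, lower_bundle=lower,
        )
        per_seed["fall_tp_distance"].append(
            fall_alarm_rate(
                fall_bundle, lower, seed, n_sequences=n_sequences, distance=(1.0, 4.5),
                subjects=subjects, camera=camera, jitter_sigma=jitter_sigma,
                ground_time=ground_time,
            ).tp_pct
        )
        per_seed["fall_tp_rotated"].append(
            fall_alarm_rate(
                fall_bundle, lower, seed, n_sequences=n_sequences, distance=2.5,
                horizontal_rotation=(0.0, 45.0), subjects=subjects, camera=camera,
                jitter_sigma=jitter_sigma, ground_time=ground_time,
            ).tp_pct
        )

    def mean(key: str) -> float:
        return float(np.mean(per_seed[key]))

    return {
        "posture_tp_pct": {
            "value": 0.5 * (mean("upper_tp") + mean("lower_tp")),
            "n": 2 * n_test * n_seeds,
        },
        "posture_tn_pct": {
            "value": 0.5 * (mean("upper_tn") + mean("lower_tn")),
            "n": 2 * n_distractors * n_seeds,
        },
        "upper_tp_pct": {"value": mean("upper_tp"), "n": n_test * n_seeds},
        "lower_tp_pct": {"value": mean("lower_tp"), "n": n_test * n_seeds},
        "fall_tp_distance_pct": {"value": mean("fall_tp_distance"), "n": n_sequences * n_seeds},
        "fall_tp_rotated_pct": {"value": mean("fall_tp_rotated"), "n": n_sequences * n_seeds},
        "per_seed": {k: list(map(float, v)) for k, v in per_seed.items()},
        "seeds": seeds,
    }
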