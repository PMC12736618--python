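"""Evaluation views and the end-to-end experiment runner.

Two reporting primitives mirror how grow-box results are read: a per-cycle
accuracy breakdown (how well each light or dark phase was classified) and a
detection-delay report (how many minutes after a light switch the
predictions settle on the new state — plants respond with a lag of several
minutes, so a nonzero delay is physiology, not only model error).

`run_experiment` orchestrates the full synthetic study: simulate plant A,
filter/split/standardize, train, evaluate, attribute — and optionally the
cross-plant scenario: zero-shot evaluation on a parameter-shifted plant B
followed by fine-tuning on B's own training split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import CircuitComponents, SweepConfig
from .dataio import AcquisitionConfig, DatasetContainer, write_dataset
from .preprocessing import (SplitSpec, chronological_split,
                            class_balance_report, filter_transitions,
                            labels_to_binary, standardize)
from .model import LSTMAttentionClassifier, TrainingHistory
from .synth import (LightSchedule, PlantProfile, default_profile,
                    generate_dataset, generate_schedule, make_variant_profile)
from . import attribution as attrib

__all__ = [
    "CycleReport",
    "DelayReport",
    "per_cycle_accuracy",
    "detection_delay",
    "ExperimentConfig",
    "run_experiment",
]

#: Sentinel for "no stable correct run observed before the next switch".
NO_DETECTION = -1


@dataclass
class CycleReport:
    """Accuracy per schedule phase plus the overall figure."""

    phases: pd.DataFrame
    overall_accuracy: float

    def to_json(self) -> str:
        return json.dumps({
            "overall_accuracy": self.overall_accuracy,
            "phases": self.phases.to_dict(orient="records")}, indent=1)


@dataclass
class DelayReport:
    """Per-transition detection delays in minutes (−1 = not detected)."""

    transitions: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(self.transitions.to_dict(orient="records"), indent=1)


def per_cycle_accuracy(predictions, schedule: LightSchedule,
                       timestamps) -> CycleReport:
    """Classification accuracy within each light/dark phase.

    `predictions` are hard labels (0/1 or "dark"/"light") aligned with
    `timestamps` (minutes); every timestamp must fall inside the schedule.
    """
    preds = labels_to_binary(predictions) if np.asarray(predictions).dtype.kind \
        in "US" else np.asarray(predictions, dtype=int)
    ts = np.asarray(timestamps, dtype=float)
    if len(preds) != len(ts):
        raise ValueError("predictions and timestamps must align")
    if len(ts) and not (schedule.start_time <= ts.min()
                        and ts.max() <= schedule.end_time):
        raise ValueError("timestamp outside the schedule span")
    rows = []
    assigned = 0
    for k, (state, lo, hi) in enumerate(schedule.boundaries()):
        last = hi == schedule.end_time
        sel = (ts >= lo) & ((ts <= hi) if last else (ts < hi))
        n = int(sel.sum())
        truth = 1 if state == "light" else 0
        n_correct = int(np.sum(preds[sel] == truth))
        rows.append({"phase": k, "state": state, "start_min": lo,
                     "end_min": hi, "n_samples": n, "n_correct": n_correct,
                     "accuracy": n_correct / n if n else float("nan")})
        assigned += n
    assert assigned == len(ts)
    frame = pd.DataFrame(rows)
    overall = (frame["n_correct"].sum() / assigned) if assigned else float("nan")
    return CycleReport(frame, float(overall))


def detection_delay(predictions, schedule: LightSchedule, timestamps,
                    stable_run: int = 3) -> DelayReport:
    """Minutes from each light switch to the first stable correct response.

    A transition counts as detected at the first timestamp from which
    `stable_run` consecutive predictions match the new state; the delay is
    that timestamp minus the switch time.  Runs are only sought before the
    next switch; otherwise the sentinel −1 is recorded.
    """
    preds = labels_to_binary(predictions) if np.asarray(predictions).dtype.kind \
        in "US" else np.asarray(predictions, dtype=int)
    ts = np.asarray(timestamps, dtype=float)
    switches = schedule.switch_times
    rows = []
    for j, sw in enumerate(switches):
        new_state = schedule.state_at(sw)  # switch minute starts the new phase
        truth = 1 if new_state == "light" else 0
        nxt = switches[j + 1] if j + 1 < len(switches) else schedule.end_time
        idx = np.flatnonzero((ts >= sw) & (ts < nxt))
        delay = NO_DETECTION
        correct = preds[idx] == truth
        for pos in range(len(idx)):
            run = correct[pos:pos + stable_run]
            if len(run) >= stable_run and run.all():
                delay = float(ts[idx[pos]] - sw)
                break
        rows.append({"switch_min": float(sw),
                     "direction": f"to_{new_state}",
                     "delay_min": delay})
    return DelayReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# end-to-end runner

@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one synthetic grow-box study."""

    duration_min: float = 48 * 60.0
    min_phase: float = 60.0
    max_phase: float = 180.0
    sweeps_per_burst: int = 20
    filter_window: float = 10.0
    split: SplitSpec = field(default_factory=SplitSpec)
    profile: PlantProfile = field(default_factory=default_profile)
    comps: CircuitComponents = field(default_factory=CircuitComponents)
    cross_plant: bool = True
    variant_shift: float = 0.3
    variant_seed: int = 11
    ig_steps: int = 50
    top_k: int = 10
    seed: int = 0

    def acquisition(self) -> AcquisitionConfig:
        return AcquisitionConfig(sweeps_per_burst=self.sweeps_per_burst)


def _prepare(ds: DatasetContainer, schedule: LightSchedule,
             cfg: ExperimentConfig):
    filtered = filter_transitions(ds, schedule, cfg.filter_window)
    train, val, test = chronological_split(filtered, cfg.split)
    (Xtr, Xva, Xte), stats = standardize(train, val, test)
    parts = {
        "train": (Xtr, labels_to_binary(train.labels), train.timestamps),
        "val": (Xva, labels_to_binary(val.labels), val.timestamps),
        "test": (Xte, labels_to_binary(test.labels), test.timestamps),
    }
    parts["containers"] = (train, val, test)
    balance = class_balance_report(train=train, val=val, test=test)
    return filtered, parts, stats, balance


def run_experiment(cfg: ExperimentConfig | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic pipeline; returns the results bundle.

    The bundle maps artifact names to in-memory objects (datasets, model,
    histories, reports, accuracy summary).  When `out_dir` is given the
    reports, plots, history CSV and model checkpoint are also written there.
    """
    cfg = cfg or ExperimentConfig()
    rng = np.random.default_rng(cfg.seed)
    s_sched, s_data, s_model = (int(rng.integers(2**31)) for _ in range(3))

    schedule = generate_schedule(cfg.duration_min, cfg.min_phase,
                                 cfg.max_phase, seed=s_sched)
    dataset = generate_dataset(schedule, cfg.profile, cfg.acquisition(),
                               cfg.comps, seed=s_data)
    filtered, parts, stats, balance = _prepare(dataset, schedule, cfg)

    clf = LSTMAttentionClassifier(random_state=s_model)
    clf.fit(parts["train"][0], parts["train"][1],
            validation_data=parts["val"][:2])
    history = clf.history_

    results: dict = {
        "schedule": schedule, "dataset": dataset, "model": clf,
        "history": history, "balance": balance,
        "acc_A_val": float(np.max(history.val_acc)),
        "acc_A_test": float(np.mean(
            clf.predict(parts["test"][0]) == parts["test"][1])),
    }

    # reports on the evaluated (test) span
    test_pred = clf.predict(parts["test"][0])
    results["cycle_report"] = per_cycle_accuracy(
        test_pred, schedule, parts["test"][2])
    # delay is measured on unfiltered predictions so sub-window delays show
    Xall, _ = standardize_all(dataset, stats)
    all_pred = clf.predict(Xall)
    results["all_predictions"] = all_pred
    results["delay_report"] = detection_delay(
        all_pred, schedule, dataset.timestamps)

    # attribution on one test sample
    x0 = parts["test"][0][0]
    attr = attrib.integrated_gradients(clf, x0, m=cfg.ig_steps,
                                       sample_id="test-0")
    freqs = cfg.acquisition().sweep.frequencies
    iv = attrib.feature_importance(attr, freqs)
    results["attribution"] = attr
    results["importance"] = iv
    results["top_features"] = attrib.top_k_features(iv, cfg.top_k)
    results["band_importance"] = attrib.band_importance(iv)

    if cfg.cross_plant:
        variant = make_variant_profile(cfg.profile, cfg.variant_shift,
                                       seed=cfg.variant_seed)
        ds_b = generate_dataset(schedule, variant, cfg.acquisition(),
                                cfg.comps, seed=s_data + 1)
        _, parts_b, _, _ = _prepare(ds_b, schedule, cfg)
        # zero-shot: plant A's frozen pipeline (its scaler and weights)
        # applied to plant B's raw data — B's own statistics only become
        # available once we retrain on it
        X_b_test_zero, _ = standardize_all(parts_b["containers"][2], stats)
        zero_shot = float(np.mean(
            clf.predict(X_b_test_zero) == parts_b["test"][1]))
        clf.fine_tune(parts_b["train"][0], parts_b["train"][1],
                      validation_data=parts_b["val"][:2])
        finetuned = float(np.mean(
            clf.predict(parts_b["test"][0]) == parts_b["test"][1]))
        results.update(acc_B_zero_shot=zero_shot, acc_B_finetuned=finetuned,
                       finetune_history=clf.history_,
                       variant_profile=variant)

    if out_dir is not None:
        _write_bundle(results, cfg, Path(out_dir))
    return results


def standardize_all(ds: DatasetContainer, stats) -> tuple[np.ndarray, None]:
    """Apply previously fitted standardization stats to a whole container."""
    cube = ds.data_cube()
    if stats.mode == "frequency":
        return (cube - stats.mean[None, None, :]) / stats.sd[None, None, :], None
    flat = cube.reshape(cube.shape[0], -1)
    return ((flat - stats.mean) / stats.sd).reshape(cube.shape), None


def _write_bundle(results: dict, cfg: ExperimentConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(results["dataset"], out / "dataset.h5")
    results["history"].to_frame().to_csv(out / "history.csv", index=False)
    (out / "cycle_report.json").write_text(results["cycle_report"].to_json())
    results["cycle_report"].phases.to_csv(out / "cycle_report.csv",
                                          index=False)
    (out / "delay_report.json").write_text(results["delay_report"].to_json())
    results["delay_report"].transitions.to_csv(out / "delay_report.csv",
                                               index=False)
    attrib.export_heatmap(results["attribution"], out / "heatmap.png")
    attrib.export_trends(results["dataset"],
                         results["top_features"]["index"].to_numpy(),
                         results["all_predictions"], results["schedule"],
                         out / "trends.png")
    results["top_features"].to_csv(out / "top_features.csv", index=False)
    results["band_importance"].to_csv(out / "band_importance.csv", index=False)
    results["model"].save(out / "model.npz")
    summary = {k: results[k] for k in
               ("acc_A_val", "acc_A_test", "acc_B_zero_shot",
                "acc_B_finetuned") if k in results}
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
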