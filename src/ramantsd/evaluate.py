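"""Confusion tables, per-hour misclassification, R^2, and report files.

Mirrors how two-donor TSD studies are reported: a 2x2 confusion matrix
(plus an always-empty unassigned column) per prediction set, class-wise
percent prediction rounded half-up to integer percent, a per-hour
fresh/old count table where an hour is flagged misclassified when
strictly more than 40% of its spectra land in the wrong class, and the
calibration / cross-validation / external R^2 triplet of the hour
regression.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "percent_prediction",
    "hour_misclassification",
    "r_squared",
    "evaluate_study",
    "render_report",
]

FRESH, OLD = "fresh", "old"


@dataclass
class ConfusionMatrix:
    """Counts indexed (true class x predicted class) plus an unassigned column."""

    counts: np.ndarray  # 2x2: rows true (fresh, old), cols predicted (fresh, old)
    unassigned: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=int))
    set_label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.unassigned = np.asarray(self.unassigned, dtype=int)
        if self.counts.shape != (2, 2) or self.unassigned.shape != (2,):
            raise ValueError("counts must be 2x2 and unassigned length 2")
        if (self.counts < 0).any() or (self.unassigned < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_labels(cls, true_labels, pred_labels, set_label: str = "") -> "ConfusionMatrix":
        order = (FRESH, OLD)
        counts = np.zeros((2, 2), dtype=int)
        for t, p in zip(true_labels, pred_labels):
            counts[order.index(t), order.index(p)] += 1
        return cls(counts, set_label=set_label)

    def row_total(self, cls_index: int) -> int:
        return int(self.counts[cls_index].sum() + self.unassigned[cls_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.vstack([self.counts.T, self.unassigned]),
            index=[f"predicted_{FRESH}", f"predicted_{OLD}", "predicted_unassigned"],
            columns=[f"true_{FRESH}", f"true_{OLD}"],
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def percent_prediction(cm: ConfusionMatrix, cls) -> int:
    """Class-wise percent of correctly assigned spectra, half-up integer.

    ``cls`` is 0/"fresh" or 1/"old".
    """
    idx = {FRESH: 0, OLD: 1, 0: 0, 1: 1}[cls]
    total = cm.row_total(idx)
    if total == 0:
        raise ValueError(f"class {cls!r} has no samples")
    return _round_half_up(100.0 * cm.counts[idx, idx] / total)


def hour_misclassification(per_hour_table, true_class_of_hour, threshold: float = 0.40):
    """Hours where the wrong-class fraction strictly exceeds ``threshold``.

    ``per_hour_table`` maps hour -> (n_predicted_fresh, n_predicted_old);
    ``true_class_of_hour`` maps hour -> "fresh" | "old".
    """
    flagged = []
    for hour in sorted(per_hour_table):
        n_fresh, n_old = per_hour_table[hour]
        total = n_fresh + n_old
        if total == 0:
            import warnings

            warnings.warn(f"hour {hour} has no spectra; excluded", RuntimeWarning)
            continue
        wrong = n_old if true_class_of_hour[hour] == FRESH else n_fresh
        if wrong / total > threshold:
            flagged.append(hour)
    return flagged


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.size < 2:
        raise ValueError("actual and predicted must be equal-length, length >= 2")
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst == 0:
        raise ValueError("actual values are constant; R^2 undefined")
    return 1.0 - float(np.sum((a - p) ** 2)) / sst


@dataclass
class EvaluationReport:
    confusion: dict  # set label -> ConfusionMatrix
    percent_prediction: dict  # set label -> {class -> int %}
    per_hour_table: dict  # hour -> (n fresh, n old), external set
    misclassified_hours: list
    r2: dict  # {"calibration", "cv", "prediction"} -> float
    per_hour_prediction_stats: dict  # hour -> (mean predicted hour, SD), external
    overall_accuracy: dict  # set label -> float %
    schedule: list = field(default_factory=list)
    config_hash: str = ""
    seed: int | None = None


def evaluate_study(results, threshold: float = 0.40) -> EvaluationReport:
    """Build the full report from fitted :class:`TSDStudyResults`."""
    rule = results.study.config.rule
    lab = rule.class_labels

    confusion, pct, acc = {}, {}, {}
    for s in results.sets:
        true_lab = np.where(results.class_true[s] == 1.0, lab[1], lab[0])
        cm = ConfusionMatrix.from_labels(true_lab, results.class_labels[s], set_label=s)
        confusion[s] = cm
        pct[s] = {lab[0]: percent_prediction(cm, 0), lab[1]: percent_prediction(cm, 1)}
        acc[s] = 100.0 * results.accuracy(s)

    hours_ext = results.hour_true["external"]
    labels_ext = results.class_labels["external"]
    preds_ext = results.hour_pred["external"]
    boundary_lo = results.study.config.class_boundary[0]
    per_hour, per_hour_stats, true_cls = {}, {}, {}
    for h in sorted(float(v) for v in set(hours_ext)):
        m = hours_ext == h
        per_hour[h] = (int((labels_ext[m] == lab[0]).sum()), int((labels_ext[m] == lab[1]).sum()))
        per_hour_stats[h] = (float(preds_ext[m].mean()), float(preds_ext[m].std(ddof=0)))
        true_cls[h] = lab[0] if h <= boundary_lo else lab[1]

    r2 = {
        "calibration": results.r_squared("calibration"),
        "cv": results.r_squared("cv"),
        "prediction": results.r_squared("external"),
    }
    return EvaluationReport(
        confusion=confusion,
        percent_prediction=pct,
        per_hour_table=per_hour,
        misclassified_hours=hour_misclassification(per_hour, true_cls, threshold),
        r2=r2,
        per_hour_prediction_stats=per_hour_stats,
        overall_accuracy=acc,
        schedule=sorted(float(v) for v in set(hours_ext)),
    )


def render_report(report: EvaluationReport, out_dir, results=None, make_plots: bool = True):
    """Write confusion CSVs, the per-hour table, the R^2 summary, raw
    predictions, and (optionally) linear/log per-hour prediction plots.

    Output is deterministic for a fixed report; every file set carries
    the config hash and seed in ``run_log.json``.  Returns the list of
    written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    for s, cm in report.confusion.items():
        path = out_dir / f"confusion_{s}.csv"
        frame = cm.to_frame()
        frame.loc["percent_prediction"] = [
            report.percent_prediction[s][FRESH],
            report.percent_prediction[s][OLD],
        ]
        frame.to_csv(path)
        written.append(path)

    rows = []
    for h in report.schedule:
        nf, no = report.per_hour_table[h]
        mean_p, sd_p = report.per_hour_prediction_stats[h]
        rows.append(
            {
                "hour": h,
                "predicted_fresh": nf,
                "predicted_old": no,
                "misclassified": h in report.misclassified_hours,
                "mean_predicted_hour": mean_p,
                "sd_predicted_hour": sd_p,
            }
        )
    per_hour_path = out_dir / "per_hour_external.csv"
    pd.DataFrame(rows).to_csv(per_hour_path, index=False)
    written.append(per_hour_path)

    r2_path = out_dir / "r2_summary.json"
    with open(r2_path, "w") as fh:
        json.dump(
            {
                "r2": report.r2,
                "overall_accuracy_percent": report.overall_accuracy,
                "percent_prediction": {
                    s: dict(v) for s, v in report.percent_prediction.items()
                },
                "misclassified_hours": report.misclassified_hours,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    written.append(r2_path)

    if results is not None:
        pred_rows = []
        for s in results.sets:
            for i, (ht, hp, cl) in enumerate(
                zip(results.hour_true[s], results.hour_pred[s], results.class_labels[s])
            ):
                pred_rows.append(
                    {
                        "set": s,
                        "index": i,
                        "true_hour": float(ht),
                        "predicted_hour": float(hp),
                        "predicted_class": cl,
                        "negative_prediction": bool(hp < 0),
                    }
                )
        pred_path = out_dir / "predictions.csv"
        pd.DataFrame(pred_rows).to_csv(pred_path, index=False)
        written.append(pred_path)

    log_path = out_dir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(
            {"config_hash": report.config_hash, "seed": report.seed,
             "schedule": report.schedule},
            fh,
            indent=2,
            sort_keys=True,
        )
    written.append(log_path)

    if make_plots:
        written.extend(_per_hour_plots(report, out_dir))
    return written


def _per_hour_plots(report: EvaluationReport, out_dir: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hours = np.array(report.schedule, float)
    means = np.array([report.per_hour_prediction_stats[h][0] for h in hours])
    sds = np.array([report.per_hour_prediction_stats[h][1] for h in hours])
    paths = []
    for scale in ("linear", "log"):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(hours, means, yerr=sds, fmt="o", capsize=3, label="predicted +/- 1 SD")
        lim = [min(hours.min(), 0.8), hours.max() * 1.1]
        ax.plot(lim, lim, "k--", lw=0.8, label="identity")
        if scale == "log":
            ax.set_xscale("log")
            ax.set_yscale("symlog", linthresh=1.0)
        ax.set_xlabel("true hour post-deposition")
        ax.set_ylabel("predicted hour")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        p = out_dir / f"per_hour_prediction_{scale}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def config_digest(obj) -> str:
    """Stable short hash of a JSON-serializable config document."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
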