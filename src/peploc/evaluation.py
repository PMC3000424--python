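"""Performance measures: overall accuracy and per-class SN/SP/PPV/MCC,
with fold aggregation as mean and sample standard deviation."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence


@dataclass
class ClassCounts:
    """One-vs-rest counts for a single class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/TN/FN over one evaluation set."""

    per_class: dict[str, ClassCounts]

    @property
    def classes(self) -> list[str]:
        return list(self.per_class)

    @property
    def n_instances(self) -> int:
        return sum(c.tp + c.fn for c in self.per_class.values())


@dataclass
class ClassMetrics:
    """SN/SP/PPV in percent, MCC in [-1, 1].

    ``undefined`` lists metrics whose denominator was zero; those are
    reported as 0 by convention rather than crashing.
    """

    sn: float
    sp: float
    ppv: float
    mcc: float
    undefined: tuple[str, ...] = ()


@dataclass
class MetricsReport:
    """Per-class metrics plus overall accuracy; optionally fold mean(SD)."""

    per_class: dict[str, ClassMetrics]
    accuracy: float
    per_fold: Optional[list["MetricsReport"]] = None
    sd_per_class: Optional[dict[str, ClassMetrics]] = None
    sd_accuracy: Optional[float] = None

    def to_dict(self) -> dict:
        out: dict = {
            "accuracy": self.accuracy,
            "per_class": {
                c: {"SN": m.sn, "SP": m.sp, "PPV": m.ppv, "MCC": m.mcc,
                    "undefined": list(m.undefined)}
                for c, m in self.per_class.items()
            },
        }
        if self.sd_accuracy is not None:
            out["accuracy_sd"] = self.sd_accuracy
        if self.sd_per_class is not None:
            out["per_class_sd"] = {
                c: {"SN": m.sn, "SP": m.sp, "PPV": m.ppv, "MCC": m.mcc}
                for c, m in self.sd_per_class.items()
            }
        if self.per_fold is not None:
            out["n_folds"] = len(self.per_fold)
            out["fold_accuracies"] = [f.accuracy for f in self.per_fold]
        return out


def confusion_counts(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Sequence[str],
) -> ConfusionCounts:
    """One-vs-rest confusion counts per class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    class_set = set(classes)
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in class_set:
            raise ValueError(f"label {lab!r} not among classes {sorted(class_set)}")

    per_class = {c: ClassCounts() for c in classes}
    for t, p in zip(true_labels, predicted_labels):
        for c in classes:
            counts = per_class[c]
            if t == c and p == c:
                counts.tp += 1
            elif t == c:
                counts.fn += 1
            elif p == c:
                counts.fp += 1
            else:
                counts.tn += 1
    return ConfusionCounts(per_class)


def _ratio(num: float, den: float, scale: float = 100.0) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den * scale, False


def class_metrics(c: ClassCounts) -> ClassMetrics:
    """SN, SP, PPV (percent) and MCC from one-vs-rest counts.

    Zero denominators yield 0 with the metric flagged as undefined.
    """
    undefined: list[str] = []
    sn, bad = _ratio(c.tp, c.tp + c.fn)
    if bad:
        undefined.append("SN")
    sp, bad = _ratio(c.tn, c.tn + c.fp)
    if bad:
        undefined.append("SP")
    ppv, bad = _ratio(c.tp, c.tp + c.fp)
    if bad:
        undefined.append("PPV")

    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        mcc = 0.0
        undefined.append("MCC")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return ClassMetrics(sn=sn, sp=sp, ppv=ppv, mcc=mcc, undefined=tuple(undefined))


def overall_accuracy(counts: ConfusionCounts) -> float:
    """Micro accuracy in percent: sum of TP over total instances."""
    total = counts.n_instances
    if total == 0:
        raise ValueError("empty evaluation set")
    correct = sum(c.tp for c in counts.per_class.values())
    return correct / total * 100.0


def report_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """Full metrics report for one evaluation set."""
    return MetricsReport(
        per_class={c: class_metrics(cc) for c, cc in counts.per_class.items()},
        accuracy=overall_accuracy(counts),
    )


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def aggregate_folds(per_fold: Sequence[MetricsReport]) -> MetricsReport:
    """Aggregate per-fold reports into per-metric mean and sample SD."""
    if not per_fold:
        raise ValueError("need at least one fold")
    classes = list(per_fold[0].per_class)
    mean_per_class: dict[str, ClassMetrics] = {}
    sd_per_class: dict[str, ClassMetrics] = {}
    for c in classes:
        stats = {}
        for metric in ("sn", "sp", "ppv", "mcc"):
            vals = [getattr(f.per_class[c], metric) for f in per_fold]
            stats[metric] = _mean_sd(vals)
        mean_per_class[c] = ClassMetrics(
            sn=stats["sn"][0], sp=stats["sp"][0],
            ppv=stats["ppv"][0], mcc=stats["mcc"][0],
        )
        sd_per_class[c] = ClassMetrics(
            sn=stats["sn"][1], sp=stats["sp"][1],
            ppv=stats["ppv"][1], mcc=stats["mcc"][1],
        )
    acc_mean, acc_sd = _mean_sd([f.accuracy for f in per_fold])
    return MetricsReport(
        per_class=mean_per_class,
        accuracy=acc_mean,
        per_fold=list(per_fold),
        sd_per_class=sd_per_class,
        sd_accuracy=acc_sd,
    )


def write_report_tsv(report: MetricsReport, path: str | Path, scheme: str = "-") -> None:
    """Write one row per class: scheme, class, SN, SP, PPV, MCC (mean and SD)."""
    sd = report.sd_per_class or {}
    with open(path, "w") as handle:
        handle.write("scheme\tclass\tSN\tSN_sd\tSP\tSP_sd\tPPV\tPPV_sd\tMCC\tMCC_sd\n")
        for c, m in report.per_class.items():
            s = sd.get(c, ClassMetrics(0, 0, 0, 0))
            handle.write(
                f"{scheme}\t{c}\t{m.sn:.2f}\t{s.sn:.2f}\t{m.sp:.2f}\t{s.sp:.2f}"
                f"\t{m.ppv:.2f}\t{s.ppv:.2f}\t{m.mcc:.4f}\t{s.mcc:.4f}\n"
            )
        handle.write(f"# overall accuracy\t{report.accuracy:.2f}"
                     f"\tSD\t{report.sd_accuracy or 0.0:.2f}\n")


def write_report_json(report: MetricsReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
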