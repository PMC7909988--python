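"""AOI statistics and accuracy of a mapping against ground truth.

The evaluation treats the manual fixation-by-fixation mapping as ground
truth and scores the automatic mapping per AOI in one-vs-rest fashion:
for AOI X, a fixation is positive when the ground truth assigns it to X.
The true positive rate (TPR) is the fraction of ground-truth-X fixations
the automatic mapping also assigns to X; the true negative rate (TNR)
is the fraction of ground-truth-not-X fixations the automatic mapping
also keeps out of X. The background gets no TPR/TNR of its own.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from cgom.io_gaze import BACKGROUND_LABEL, MappedFixation

__all__ = [
    "AoiStats",
    "ConfusionEntry",
    "TransitionMatrix",
    "aoi_stats",
    "confusion",
    "confusion_report",
    "transitions",
    "metrics_report",
]


@dataclass(frozen=True)
class AoiStats:
    """Fixation statistics for one AOI label.

    ``duration_mean_ms`` and ``duration_sd_ms`` are None when undefined
    (no fixations; SD additionally needs at least two with the default
    sample convention).
    """

    label: str
    fixation_count: int
    duration_mean_ms: float | None
    duration_sd_ms: float | None
    dwell_total_ms: float


@dataclass(frozen=True)
class ConfusionEntry:
    """One-vs-rest confusion counts and rates for one AOI."""

    label: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def tnr(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None


@dataclass(frozen=True)
class TransitionMatrix:
    """Counts of consecutive-fixation label pairs, self-transitions included."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (n_labels, n_labels) int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def switch_count(self) -> int:
        """Number of transitions that change the AOI (off-diagonal sum)."""
        return int(self.counts.sum() - np.trace(self.counts))


def aoi_stats(
    mapped: Sequence[MappedFixation],
    labels: Sequence[str] | None = None,
    ddof: int = 1,
) -> dict[str, AoiStats]:
    """Per-AOI fixation count, duration mean/SD and total dwell time.

    ``labels`` fixes the reported label set (zero-count AOIs included);
    by default every label present plus the background is reported.
    ``ddof=1`` gives the sample SD; pass 0 for the population SD.
    """
    if labels is None:
        seen = dict.fromkeys(m.aoi_label for m in mapped)
        seen.setdefault(BACKGROUND_LABEL)
        labels = list(seen)
    out: dict[str, AoiStats] = {}
    for label in labels:
        durs = np.array([m.duration_ms for m in mapped if m.aoi_label == label])
        n = len(durs)
        mean = float(durs.mean()) if n else None
        sd = float(durs.std(ddof=ddof)) if n > ddof else None
        out[label] = AoiStats(
            label=label,
            fixation_count=n,
            duration_mean_ms=mean,
            duration_sd_ms=sd,
            dwell_total_ms=float(durs.sum()),
        )
    return out


def _aligned_labels(
    ground_truth: Sequence[MappedFixation],
    predicted: Sequence[MappedFixation],
    drop_out_of_bounds: bool = False,
) -> tuple[list[str], list[str]]:
    truth_by_id = {m.fixation_id: m for m in ground_truth}
    pred_by_id = {m.fixation_id: m for m in predicted}
    unmatched = set(truth_by_id) ^ set(pred_by_id)
    if unmatched:
        raise ValueError(
            f"fixation ids not present in both mappings: {sorted(unmatched)}"
        )
    ids = sorted(truth_by_id)
    if drop_out_of_bounds:
        ids = [
            i for i in ids if truth_by_id[i].in_bounds and pred_by_id[i].in_bounds
        ]
    return (
        [truth_by_id[i].aoi_label for i in ids],
        [pred_by_id[i].aoi_label for i in ids],
    )


def confusion(
    ground_truth: Sequence[MappedFixation],
    predicted: Sequence[MappedFixation],
    aoi_label: str,
    drop_out_of_bounds: bool = False,
) -> ConfusionEntry:
    """One-vs-rest confusion counts for one AOI.

    Both mappings must cover the same fixation ids. With
    ``drop_out_of_bounds`` (for the "exclude" out-of-bounds policy),
    fixations flagged out of bounds in either mapping are dropped from
    the comparison first.
    """
    truth, pred = _aligned_labels(ground_truth, predicted, drop_out_of_bounds)
    tp = sum(1 for t, p in zip(truth, pred) if t == aoi_label and p == aoi_label)
    fn = sum(1 for t, p in zip(truth, pred) if t == aoi_label and p != aoi_label)
    fp = sum(1 for t, p in zip(truth, pred) if t != aoi_label and p == aoi_label)
    tn = sum(1 for t, p in zip(truth, pred) if t != aoi_label and p != aoi_label)
    return ConfusionEntry(aoi_label, tp, fp, tn, fn)


def confusion_report(
    ground_truth: Sequence[MappedFixation],
    predicted: Sequence[MappedFixation],
    aoi_labels: Sequence[str],
    drop_out_of_bounds: bool = False,
) -> dict[str, ConfusionEntry]:
    """Confusion entries for each AOI label (background excluded)."""
    return {
        label: confusion(ground_truth, predicted, label, drop_out_of_bounds)
        for label in aoi_labels
    }


def transitions(mapped: Sequence[MappedFixation], labels: Sequence[str] | None = None) -> TransitionMatrix:
    """Transition matrix over consecutive fixations of one recording.

    Counts every consecutive label pair including self-transitions, so
    the counts sum to N−1 for N fixations. Fewer than two fixations
    yield an all-zero matrix.
    """
    if labels is None:
        seen = dict.fromkeys(m.aoi_label for m in mapped)
        seen.setdefault(BACKGROUND_LABEL)
        labels = tuple(seen)
    else:
        labels = tuple(labels)
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(mapped, mapped[1:]):
        counts[index[a.aoi_label], index[b.aoi_label]] += 1
    return TransitionMatrix(labels, counts)


def metrics_report(
    ground_truth: Sequence[MappedFixation],
    predicted: Sequence[MappedFixation],
    aoi_labels: Sequence[str],
    drop_out_of_bounds: bool = False,
) -> dict:
    """JSON-serializable evaluation report.

    Per AOI: fixation statistics of both mappings, confusion counts and
    TPR/TNR of the predicted mapping against the ground truth.
    """
    stats_truth = aoi_stats(ground_truth, list(aoi_labels) + [BACKGROUND_LABEL])
    stats_pred = aoi_stats(predicted, list(aoi_labels) + [BACKGROUND_LABEL])
    conf = confusion_report(ground_truth, predicted, aoi_labels, drop_out_of_bounds)
    report: dict = {}
    for label in list(aoi_labels) + [BACKGROUND_LABEL]:
        entry = {
            "ground_truth": asdict(stats_truth[label]),
            "predicted": asdict(stats_pred[label]),
        }
        if label in conf:
            c = conf[label]
            entry.update(
                TP=c.tp, FP=c.fp, TN=c.tn, FN=c.fn, TPR=c.tpr, TNR=c.tnr
            )
        report[label] = entry
    return report
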