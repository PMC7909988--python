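"""Linear cost models for manual vs. computational gaze mapping.

Both evaluation procedures are modelled as a fixed setup cost plus a
variable cost proportional to the length of the eye-tracking recording:

    T(s) = F + r * s

with ``s`` the recording (gaze data sample) length in minutes, ``F``
the sum of fixed sub-times in minutes and ``r`` the work-minutes needed
per minute of recording. Components are tagged as operator time (a
human must sit there) or computational time (a machine runs
unattended); the model can be evaluated for the total procedure or for
operator time only. The break-even point is the sample length at which
the computational procedure's cumulative cost drops below the manual
one's:

    s* = (F_c - F_m) / (r_m - r_c)

The shipped defaults are the study's measured mean sub-times: manual
semantic gaze mapping (SGM) took 128.5 min for a 52-min sample
(preparation 1.5, mapping 126, export 1 — all operator time); the
computational procedure took 15 min collecting training images,
113 min labelling, 67 min network training, 1 min data export (fixed),
plus mapping at 40 min per 52-min sample (variable, computational).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "CostComponent",
    "CostModel",
    "BreakEven",
    "rate_from_observation",
    "total_cost",
    "break_even",
    "extrapolate",
    "sgm_cost_model",
    "cgom_cost_model",
    "read_cost_model",
    "write_cost_model",
]

#: measured means, in minutes, for the 52-minute study sample
SAMPLE_MINUTES = 52.0
SGM_TOTAL_MINUTES = 128.5
CGOM_MAPPING_MINUTES = 40.0


@dataclass(frozen=True)
class CostComponent:
    """One fixed sub-time of an evaluation procedure."""

    label: str
    minutes: float
    is_operator_time: bool

    def __post_init__(self) -> None:
        if self.minutes < 0:
            raise ValueError(f"{self.label}: minutes must be >= 0")


@dataclass(frozen=True)
class CostModel:
    """Fixed components plus one variable (per-recording-minute) stage."""

    name: str
    fixed_components: tuple[CostComponent, ...] = ()
    variable_rate: float = 0.0
    variable_is_operator_time: bool = True
    variable_label: str = "mapping"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fixed_components", tuple(self.fixed_components)
        )
        if self.variable_rate < 0:
            raise ValueError("variable_rate must be >= 0")

    def fixed_minutes(self, operator_only: bool = False) -> float:
        return sum(
            c.minutes
            for c in self.fixed_components
            if c.is_operator_time or not operator_only
        )

    def effective_rate(self, operator_only: bool = False) -> float:
        if operator_only and not self.variable_is_operator_time:
            return 0.0
        return self.variable_rate


@dataclass(frozen=True)
class BreakEven:
    """Break-even sample size, or the explicit absence of one.

    ``sample_minutes`` is None when the cost lines never cross (the
    computational procedure never becomes cheaper).
    """

    mode: str  # "total" or "operator_only"
    sample_minutes: float | None
    sample_hours_rounded: float | None

    @property
    def exists(self) -> bool:
        return self.sample_minutes is not None


def rate_from_observation(work_minutes: float, recording_minutes: float) -> float:
    """Work-minutes per recording-minute from one measured pair."""
    if recording_minutes <= 0:
        raise ValueError("recording length must be positive")
    if work_minutes < 0:
        raise ValueError("work minutes must be >= 0")
    return work_minutes / recording_minutes


def total_cost(
    model: CostModel, sample_minutes: float, operator_only: bool = False
) -> float:
    """Evaluate the cost line T(s) = F + r·s in minutes."""
    if sample_minutes < 0:
        raise ValueError("sample_minutes must be >= 0")
    return model.fixed_minutes(operator_only) + model.effective_rate(
        operator_only
    ) * sample_minutes


def break_even(
    manual: CostModel, computational: CostModel, operator_only: bool = False
) -> BreakEven:
    """Sample length at which the computational procedure pays off.

    Solves manual_total(s) = computational_total(s). When the
    computational line is never below the manual one the result has
    ``sample_minutes`` None (no break-even) rather than raising.
    """
    mode = "operator_only" if operator_only else "total"
    f_m = manual.fixed_minutes(operator_only)
    f_c = computational.fixed_minutes(operator_only)
    r_m = manual.effective_rate(operator_only)
    r_c = computational.effective_rate(operator_only)
    delta_f = f_c - f_m
    if r_m > r_c:
        s = max(delta_f / (r_m - r_c), 0.0)
    elif delta_f <= 0:
        s = 0.0  # computational already cheaper at s = 0 and stays so
    else:
        return BreakEven(mode, None, None)
    return BreakEven(mode, s, round(s / 60.0))


def extrapolate(model: CostModel, sample_minutes: float, operator_only: bool = False) -> float:
    """Total cost at the given sample length, in hours to the nearest half hour."""
    hours = total_cost(model, sample_minutes, operator_only) / 60.0
    return round(hours * 2.0) / 2.0


def sgm_cost_model(
    total_minutes: float = SGM_TOTAL_MINUTES,
    sample_minutes: float = SAMPLE_MINUTES,
    rate: float | None = None,
) -> CostModel:
    """Manual mapping (SGM) model from the study's measured means.

    The default folds preparation and export into the per-minute rate
    (total 128.5 min over the 52-min sample, all operator time),
    matching the single-ratio presentation of the measurements; pass
    ``rate`` to override with a printed ratio such as 2.48.
    """
    if rate is None:
        rate = rate_from_observation(total_minutes, sample_minutes)
    return CostModel(
        name="SGM",
        fixed_components=(),
        variable_rate=rate,
        variable_is_operator_time=True,
        variable_label="manual mapping",
    )


def cgom_cost_model(
    mapping_minutes: float = CGOM_MAPPING_MINUTES,
    sample_minutes: float = SAMPLE_MINUTES,
    rate: float | None = None,
) -> CostModel:
    """Computational mapping model from the study's measured means.

    Fixed stages: collecting training images (15 min), manual labelling
    (113 min), network training (67 min), gaze-data export (1 min);
    collecting, labelling and export are operator time, training runs
    unattended. The variable stage is the mapping itself, computational,
    at 40 min per 52-min sample by default.
    """
    if rate is None:
        rate = rate_from_observation(mapping_minutes, sample_minutes)
    return CostModel(
        name="cGOM",
        fixed_components=(
            CostComponent("collecting training images", 15.0, True),
            CostComponent("labelling training images", 113.0, True),
            CostComponent("training neural network", 67.0, False),
            CostComponent("gaze data export", 1.0, True),
        ),
        variable_rate=rate,
        variable_is_operator_time=False,
        variable_label="computational mapping",
    )


def write_cost_model(model: CostModel, path) -> None:
    """Serialize a cost model to JSON."""
    doc = {
        "name": model.name,
        "fixed_components": [
            {"label": c.label, "minutes": c.minutes, "operator": c.is_operator_time}
            for c in model.fixed_components
        ],
        "variable": {
            "label": model.variable_label,
            "rate_min_per_min": model.variable_rate,
            "operator": model.variable_is_operator_time,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)


def read_cost_model(path) -> CostModel:
    """Read a cost model from the JSON layout of :func:`write_cost_model`."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    var = doc.get("variable", {})
    return CostModel(
        name=doc["name"],
        fixed_components=tuple(
            CostComponent(c["label"], float(c["minutes"]), bool(c["operator"]))
            for c in doc.get("fixed_components", [])
        ),
        variable_rate=float(var.get("rate_min_per_min", 0.0)),
        variable_is_operator_time=bool(var.get("operator", True)),
        variable_label=var.get("label", "mapping"),
    )
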