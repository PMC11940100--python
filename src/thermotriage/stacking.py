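"""Stepwise mutation stacking and epistasis flagging.

Given singles ranked by measured stability, the planner builds the greedy
stacking series Mu1, Mu2, ... where step k adds the k-th ranked mutation to
the cumulative set. Once the stacked variants have been characterized, the
epistasis flagger compares each step's stability metric (half-life, Tm, or
relative activity) with the previous step's: a drop marks the added
mutation as negatively epistatic in the context of the existing stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .structure import Mutation

Flag = Literal["POSITIVE", "NEUTRAL", "NEGATIVE"]


@dataclass(frozen=True)
class StackStep:
    index: int                      # 1-based
    added: Mutation
    cumulative: frozenset[Mutation]
    label: str


@dataclass
class StackPlan:
    steps: list[StackStep]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.steps]
        if len(set(labels)) != len(labels):
            raise ValueError("step labels must be unique")
        for k, step in enumerate(self.steps, start=1):
            if step.index != k or len(step.cumulative) != k:
                raise ValueError("cumulative sets must grow by one mutation per step")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.steps]

    def mutation_string(self, label: str) -> str:
        for step in self.steps:
            if step.label == label:
                ordered = [s.added for s in self.steps[: step.index]]
                return "/".join(str(m) for m in ordered)
        raise KeyError(label)


@dataclass
class VariantRecord:
    t_half: float | None = None            # min, at the stated temperature
    tm: float | None = None                # degrees C
    relative_activity: float | None = None  # % of wild type
    uncertainty: dict[str, float] = field(default_factory=dict)

    def metric(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise KeyError(f"metric {name!r} not recorded")
        return value


@dataclass
class StepFlag:
    label: str
    flag: Flag
    value: float
    previous: float
    delta: float


def plan_stepwise(ranked: list[Mutation], label_prefix: str = "Mu") -> StackPlan:
    """Build the greedy stacking plan from a ranked list of single mutations.

    Step k's variant carries the top-k ranked mutations and is labelled
    ``Mu<k>``. Two mutations at the same position cannot be stacked.
    """
    if not ranked:
        raise ValueError("ranked mutation list must be non-empty")
    positions = [m.position for m in ranked]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate positions in ranked list: {dupes}; "
                         "only one substitution per site can be stacked")
    steps = []
    for k, mut in enumerate(ranked, start=1):
        steps.append(StackStep(
            index=k,
            added=mut,
            cumulative=frozenset(ranked[:k]),
            label=f"{label_prefix}{k}",
        ))
    return StackPlan(steps=steps)


def flag_epistasis(
    plan: StackPlan,
    series: dict[str, VariantRecord | float],
    metric: str = "t_half",
    baseline_label: str = "WT",
    rel_tolerance: float = 0.01,
) -> list[StepFlag]:
    """Flag each stacking step by the sign of its stability change.

    ``series`` maps variant labels to records (or raw metric values); it
    must cover every plan label, and may include the baseline (default
    "WT") against which step 1 is judged — without a baseline, step 1 is
    flagged POSITIVE by convention. NEUTRAL means equal within the metric's
    reported uncertainty when available, else within ``rel_tolerance``
    relative.
    """
    def value_of(label: str) -> tuple[float, float | None]:
        rec = series[label]
        if isinstance(rec, VariantRecord):
            return rec.metric(metric), rec.uncertainty.get(metric)
        return float(rec), None

    missing = [lab for lab in plan.labels if lab not in series]
    if missing:
        raise KeyError(f"series is missing labels {missing}")

    flags: list[StepFlag] = []
    prev_value: float | None = None
    prev_unc: float | None = None
    if baseline_label in series:
        prev_value, prev_unc = value_of(baseline_label)

    for step in plan.steps:
        value, unc = value_of(step.label)
        if prev_value is None:
            flags.append(StepFlag(step.label, "POSITIVE", value, value, 0.0))
        else:
            delta = value - prev_value
            tol_parts = [u for u in (unc, prev_unc) if u is not None]
            tol = max(tol_parts) if tol_parts else rel_tolerance * abs(prev_value)
            if abs(delta) <= tol:
                flag: Flag = "NEUTRAL"
            elif delta > 0:
                flag = "POSITIVE"
            else:
                flag = "NEGATIVE"
            flags.append(StepFlag(step.label, flag, value, prev_value, delta))
        prev_value, prev_unc = value, unc
    return flags
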