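"""Operating-rule selection: grid search over k-of-n and mean-Cp cutoffs.

Evaluates every combination of replicate requirement ``k`` and censored
mean-Cp cutoff on a cohort's case and control groups, and selects the rule
with the best balance of sensitivity and specificity.  "Best balance" is
formalized as Youden's J = sensitivity + specificity - 1; a constrained
variant picks the most sensitive rule among those meeting a specificity
floor (the narrative of raising specificity without losing sensitivity).

The search is in-sample: the selected rule's accuracy is evaluated on the
same data that chose it, and is therefore optimistic relative to unseen
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .calling import CallingRule, call_sample
from .diagnostics import pdr
from .qpcr_data import Cohort, Group

__all__ = ["RuleGridPoint", "evaluate_grid", "select_rule", "default_cutoff_grid"]


@dataclass(frozen=True)
class RuleGridPoint:
    """Diagnostic performance of one (k, cutoff) rule variant."""

    k_required: int
    mean_cp_cutoff: Optional[float]
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int

    @property
    def youden(self) -> float:
        """Youden's J = sensitivity + specificity - 1, in [-1, 1]."""
        return self.sensitivity + self.specificity - 1.0


def default_cutoff_grid(step: float = 1.0) -> list[Optional[float]]:
    """``None`` (no cutoff) plus 36..45 cycles — the range between a strong
    mean signal and the detection threshold."""
    grid: list[Optional[float]] = [None]
    c = 36.0
    while c <= 45.0 + 1e-9:
        grid.append(round(c, 6))
        c += step
    return grid


def evaluate_grid(
    cohort: Cohort,
    base_rule: CallingRule,
    k_values: Iterable[int],
    cutoff_values: Iterable[Optional[float]],
    case_group: Group = Group.CRC,
    control_group: Group = Group.NORMAL,
) -> list[RuleGridPoint]:
    """Evaluate every (k, cutoff) combination on one specimen's cohort.

    Calls are recomputed under each variant of ``base_rule``; sensitivity is
    the case-group PDR and specificity the complement of the control-group
    PDR, over valid samples only.

    Raises
    ------
    ValueError
        Empty grid, or either group has no valid samples of the rule's
        specimen.
    """
    k_values = sorted(set(k_values))
    cutoff_values = list(dict.fromkeys(cutoff_values))
    if not k_values or not cutoff_values:
        raise ValueError("empty rule grid")

    cases = cohort.subset(specimen=base_rule.specimen, group=case_group).samples
    controls = cohort.subset(specimen=base_rule.specimen, group=control_group).samples
    if not cases or not controls:
        raise ValueError(
            f"cohort lacks {case_group.value} or {control_group.value} samples "
            f"for specimen {base_rule.specimen.value}"
        )

    grid = []
    for k in k_values:
        for cutoff in cutoff_values:
            rule = replace(base_rule, k_required=k, mean_cp_cutoff=cutoff)
            case_calls = [c for c in (call_sample(s, rule) for s in cases) if c.valid]
            control_calls = [c for c in (call_sample(s, rule) for s in controls) if c.valid]
            if not case_calls or not control_calls:
                raise ValueError("a group has no valid samples under the rule")
            grid.append(
                RuleGridPoint(
                    k_required=k,
                    mean_cp_cutoff=cutoff,
                    sensitivity=pdr(case_calls).rate,
                    specificity=pdr(control_calls).complement().rate,
                    n_cases=len(case_calls),
                    n_controls=len(control_calls),
                )
            )
    return grid


def _tie_break_key(point: RuleGridPoint) -> tuple:
    # higher specificity first, then smaller k, then prefer no cutoff / higher
    # (laxer) cutoff for a deterministic final ordering
    return (
        -point.specificity,
        point.k_required,
        point.mean_cp_cutoff is not None,
        -(point.mean_cp_cutoff or 0.0),
    )


def select_rule(
    grid: Sequence[RuleGridPoint],
    criterion: str = "youden",
    specificity_floor: Optional[float] = None,
) -> Optional[RuleGridPoint]:
    """Pick the operating rule from an evaluated grid.

    ``criterion="youden"`` maximizes Youden's J, breaking ties by higher
    specificity then smaller k.  ``criterion=
    "min_specificity_then_max_sensitivity"`` restricts to points with
    specificity >= ``specificity_floor`` and maximizes sensitivity there;
    returns ``None`` (explicit no-solution) when no point meets the floor.
    """
    if not grid:
        raise ValueError("empty grid")
    if criterion == "youden":
        best = max(grid, key=lambda p: (p.youden, tuple(-v for v in _tie_break_key(p))))
        return best
    if criterion == "min_specificity_then_max_sensitivity":
        if specificity_floor is None:
            raise ValueError("specificity_floor required for the constrained criterion")
        feasible = [p for p in grid if p.specificity >= specificity_floor]
        if not feasible:
            return None
        return max(
            feasible, key=lambda p: (p.sensitivity, tuple(-v for v in _tie_break_key(p)))
        )
    raise ValueError(f"unknown criterion {criterion!r}")
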