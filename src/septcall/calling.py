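"""Sample-level positivity calling for triplicate methylation qPCR.

The decision rule has four layers, applied per sample:

1. **Replicate validity** — a replicate is valid only if the *ACTB* internal
   control amplified and its Cp is at or below a specimen-specific threshold
   (36.0 cycles for plasma, 38.0 for stool); strictly above the threshold, or
   no ACTB signal at all, means the well cannot be interpreted.
2. **Sample validity** — replicate validities are combined by a configurable
   policy; by default one invalid replicate invalidates the sample
   (conservative, mirroring commercial assay practice).
3. **Replicate detection** — methylated *SEPT9* is "detected" in a replicate
   iff its Cp is strictly below 45.0 cycles.
4. **k-of-n call** — a valid sample is positive iff at least ``k_required``
   of its ``n`` replicates detect the marker and, when a mean-Cp cutoff is
   configured, the censored mean Cp is strictly below it.

The *censored mean Cp* averages all ``n`` replicates, substituting the
maximal cycle count (50.0) for every non-detected replicate, so that samples
with partial or no signal still have a defined, monotone score.  The same
score is used downstream for ROC analysis.

Threshold strictness follows the assay definitions literally: invalid only
when *strictly greater* than the ACTB threshold, detected/positive only when
*strictly less* than the detection threshold/cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from .qpcr_data import (
    Cohort,
    ReplicateMeasurement,
    SampleRecord,
    Specimen,
)

__all__ = [
    "InvalidPolicy",
    "CallingRule",
    "CallResult",
    "ConfigurationError",
    "replicate_valid",
    "sept9_detected",
    "censored_mean_cp",
    "call_sample",
    "call_cohort",
    "plasma_default_rule",
    "stool_default_rule",
    "default_rules",
    "rule_from_dict",
    "load_rules",
]


class ConfigurationError(ValueError):
    """A rule is applied to the wrong specimen or is internally inconsistent."""


class InvalidPolicy(str, Enum):
    """How replicate-level validity aggregates to the sample level."""

    ANY_REPLICATE_INVALID = "any_replicate_invalid"  # 1 invalid well kills the sample
    ALL_REPLICATES_INVALID = "all_replicates_invalid"  # invalid only if every well is
    MAJORITY_INVALID = "majority_invalid"  # invalid if > n/2 wells are


@dataclass(frozen=True)
class CallingRule:
    """Full decision rule for one specimen type.

    Parameters
    ----------
    specimen
        Specimen the rule applies to; calling a sample of the other type is a
        configuration error.
    actb_max_cp
        Validity threshold in cycles: a replicate is invalid iff ACTB Cp is
        strictly greater than this (or ACTB is non-detected).
    sept9_detect_cp
        Detection threshold: marker detected iff Cp strictly below (default
        45.0 cycles).
    k_required
        Positive replicates required for a positive sample (the "k/n"
        algorithm; 1, 2 or 3 for triplicates).
    mean_cp_cutoff
        Optional extra requirement: censored mean Cp strictly below this
        value (cycles).  ``None`` disables it.
    censor_cp
        Cp substituted for non-detected replicates in the mean (default 50.0,
        the total cycle count).
    invalid_policy
        Replicate-to-sample validity aggregation.
    """

    specimen: Specimen
    actb_max_cp: float
    k_required: int
    sept9_detect_cp: float = 45.0
    mean_cp_cutoff: Optional[float] = None
    censor_cp: float = 50.0
    invalid_policy: InvalidPolicy = InvalidPolicy.ANY_REPLICATE_INVALID

    def __post_init__(self) -> None:
        if not (0 < self.sept9_detect_cp <= self.censor_cp):
            raise ConfigurationError(
                f"need 0 < sept9_detect_cp <= censor_cp, got "
                f"{self.sept9_detect_cp} / {self.censor_cp}"
            )
        if self.k_required < 1:
            raise ConfigurationError("k_required must be >= 1")
        if self.mean_cp_cutoff is not None and self.mean_cp_cutoff > self.censor_cp:
            raise ConfigurationError("mean_cp_cutoff must be <= censor_cp")


@dataclass(frozen=True)
class CallResult:
    """Per-sample outcome of applying a :class:`CallingRule`.

    ``positive`` is ``None`` (not evaluable) when the sample is invalid.
    ``n_detected`` and ``mean_cp_censored`` are reported for invalid samples
    too, but carry no diagnostic meaning there.
    """

    sample_id: str
    valid: bool
    n_detected: int
    mean_cp_censored: float
    positive: Optional[bool]


def replicate_valid(rep: ReplicateMeasurement, rule: CallingRule) -> bool:
    """True iff the internal control amplified at or below the validity
    threshold.  Cp exactly at the threshold is valid (invalid only when
    *strictly greater*)."""
    return rep.actb_cp is not None and rep.actb_cp <= rule.actb_max_cp


def sept9_detected(rep: ReplicateMeasurement, rule: CallingRule) -> bool:
    """True iff the marker amplified strictly below the detection threshold.
    Cp exactly at the threshold counts as not detected."""
    return rep.sept9_cp is not None and rep.sept9_cp < rule.sept9_detect_cp


def censored_mean_cp(sample: SampleRecord, rule: CallingRule) -> float:
    """Arithmetic mean of marker Cps over all replicates, with each
    non-detected replicate contributing ``rule.censor_cp``.

    A replicate also counts as non-detected here when its Cp is at/above the
    detection threshold, so the score is consistent with the detection rule
    (one definition serves both calling and ROC).
    """
    total = 0.0
    for rep in sample.replicates:
        total += rep.sept9_cp if sept9_detected(rep, rule) else rule.censor_cp
    return total / len(sample.replicates)


def _sample_valid(sample: SampleRecord, rule: CallingRule) -> bool:
    n = len(sample.replicates)
    n_invalid = sum(not replicate_valid(rep, rule) for rep in sample.replicates)
    if rule.invalid_policy is InvalidPolicy.ANY_REPLICATE_INVALID:
        return n_invalid == 0
    if rule.invalid_policy is InvalidPolicy.ALL_REPLICATES_INVALID:
        return n_invalid < n
    # MAJORITY_INVALID: invalid iff strictly more than half the wells are
    return n_invalid <= n / 2


def call_sample(sample: SampleRecord, rule: CallingRule) -> CallResult:
    """Apply the full decision rule to one sample.

    Raises
    ------
    ConfigurationError
        When ``sample.specimen`` differs from ``rule.specimen`` or
        ``k_required`` exceeds the replicate count.
    """
    if sample.specimen is not rule.specimen:
        raise ConfigurationError(
            f"sample {sample.sample_id} is {sample.specimen.value} but rule is "
            f"for {rule.specimen.value}"
        )
    n = len(sample.replicates)
    if rule.k_required > n:
        raise ConfigurationError(f"k_required={rule.k_required} exceeds n={n}")
    valid = _sample_valid(sample, rule)
    n_detected = sum(sept9_detected(rep, rule) for rep in sample.replicates)
    mean_cp = censored_mean_cp(sample, rule)
    if not valid:
        positive: Optional[bool] = None
    else:
        positive = n_detected >= rule.k_required and (
            rule.mean_cp_cutoff is None or mean_cp < rule.mean_cp_cutoff
        )
    return CallResult(
        sample_id=sample.sample_id,
        valid=valid,
        n_detected=n_detected,
        mean_cp_censored=mean_cp,
        positive=positive,
    )


def call_cohort(
    cohort: Cohort, rules: Mapping[Specimen, CallingRule]
) -> list[CallResult]:
    """Call every sample using the rule matching its specimen type.

    Samples whose specimen has no rule in ``rules`` raise a
    :class:`ConfigurationError`.
    """
    out = []
    for sample in cohort:
        if sample.specimen not in rules:
            raise ConfigurationError(
                f"no rule configured for specimen {sample.specimen.value}"
            )
        out.append(call_sample(sample, rules[sample.specimen]))
    return out


def plasma_default_rule() -> CallingRule:
    """The chosen plasma rule: ACTB <= 36.0, 1/3 algorithm, no mean-Cp cutoff."""
    return CallingRule(specimen=Specimen.PLASMA, actb_max_cp=36.0, k_required=1)


def stool_default_rule() -> CallingRule:
    """The chosen stool rule: ACTB <= 38.0, 3/3 algorithm, mean Cp < 40.0."""
    return CallingRule(
        specimen=Specimen.STOOL, actb_max_cp=38.0, k_required=3, mean_cp_cutoff=40.0
    )


def default_rules() -> dict[Specimen, CallingRule]:
    return {
        Specimen.PLASMA: plasma_default_rule(),
        Specimen.STOOL: stool_default_rule(),
    }


def rule_from_dict(specimen: Specimen, settings: Mapping) -> CallingRule:
    """Build a rule from a plain mapping (YAML/JSON config)."""
    base = default_rules()[specimen]
    kwargs = {}
    for key in (
        "actb_max_cp",
        "k_required",
        "sept9_detect_cp",
        "mean_cp_cutoff",
        "censor_cp",
    ):
        if key in settings:
            kwargs[key] = settings[key]
    if "invalid_policy" in settings:
        kwargs["invalid_policy"] = InvalidPolicy(settings["invalid_policy"])
    return replace(base, **kwargs)


def load_rules(path: str | Path) -> dict[Specimen, CallingRule]:
    """Read per-specimen rule settings from a YAML (or JSON) config file.

    Top-level keys are specimen names; unspecified settings fall back to the
    default rules.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    rules = default_rules()
    for key, settings in raw.items():
        specimen = Specimen(key.lower())
        rules[specimen] = rule_from_dict(specimen, settings or {})
    return rules
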