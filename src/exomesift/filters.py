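"""GATK-style hard filtering of SNV calls with eight fixed clauses.

A call passes iff

    DP > 20  AND  QUAL > 30
    AND NOT (QD < 2.0)  AND NOT (FS > 60.0)  AND NOT (MQ < 35.0)
    AND NOT (HaplotypeScore > 13.0)
    AND NOT (MQRankSum < -12.5)  AND NOT (ReadPosRankSum < -8.0)

DP and QUAL are pass requirements; the rest are failure conditions — the
convention used by GATK hard-filter expressions. Every inequality is strict,
so boundary values fail the pass-form clauses (DP=20 fails) and pass the
fail-form clauses (QD=2.0 passes).

A clause whose annotation is absent from the call is governed by the missing
policy: ``lenient`` (default, matching how variant-filtration tools treat
absent annotations) records the clause as missing without failing it; ``strict``
fails it. QUAL is always present, so only the seven INFO clauses can be missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import ValidationError
from .model import SampleCallset, VariantCall

MissingPolicy = Literal["lenient", "strict"]

#: Clause names in fixed evaluation order.
CLAUSE_NAMES: tuple[str, ...] = (
    "DP",
    "QUAL",
    "QD",
    "FS",
    "MQ",
    "HaplotypeScore",
    "MQRankSum",
    "ReadPosRankSum",
)


@dataclass(frozen=True, slots=True)
class FilterThresholds:
    """The eight hard-filter parameters, defaulting to the published values."""

    min_dp: float = 20.0  # pass requires DP > min_dp
    min_qual: float = 30.0  # pass requires QUAL > min_qual
    fail_qd_below: float = 2.0
    fail_fs_above: float = 60.0
    fail_mq_below: float = 35.0
    fail_haplotypescore_above: float = 13.0
    fail_mqranksum_below: float = -12.5
    fail_readposranksum_below: float = -8.0

    def __post_init__(self) -> None:
        import math

        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            if not math.isfinite(v):
                raise ValidationError(f"threshold {f} must be finite, got {v}")


@dataclass(frozen=True, slots=True)
class FilterVerdict:
    """Outcome of evaluating the eight clauses on one call."""

    passed: bool
    failed_clauses: tuple[str, ...]
    missing_clauses: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_clauses) == 0):
            raise ValidationError("passed must mirror an empty failed_clauses list")


def evaluate(
    call: VariantCall,
    thresholds: FilterThresholds = FilterThresholds(),
    missing_policy: MissingPolicy = "lenient",
) -> FilterVerdict:
    """Evaluate all eight clauses on one call and return the verdict."""
    if missing_policy not in ("lenient", "strict"):
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    ann = call.annotations
    t = thresholds
    # (clause, value or None, fails-when-present predicate)
    clauses = (
        ("DP", ann.get("DP"), lambda v: not v > t.min_dp),
        ("QUAL", call.qual, lambda v: not v > t.min_qual),
        ("QD", ann.get("QD"), lambda v: v < t.fail_qd_below),
        ("FS", ann.get("FS"), lambda v: v > t.fail_fs_above),
        ("MQ", ann.get("MQ"), lambda v: v < t.fail_mq_below),
        ("HaplotypeScore", ann.get("HaplotypeScore"), lambda v: v > t.fail_haplotypescore_above),
        ("MQRankSum", ann.get("MQRankSum"), lambda v: v < t.fail_mqranksum_below),
        ("ReadPosRankSum", ann.get("ReadPosRankSum"), lambda v: v < t.fail_readposranksum_below),
    )
    failed: list[str] = []
    missing: list[str] = []
    for name, value, fails in clauses:
        if value is None:
            missing.append(name)
            if missing_policy == "strict":
                failed.append(name)
        elif fails(value):
            failed.append(name)
    return FilterVerdict(
        passed=not failed,
        failed_clauses=tuple(failed),
        missing_clauses=tuple(missing),
    )


def filter_callset(
    callset: SampleCallset,
    thresholds: FilterThresholds = FilterThresholds(),
    missing_policy: MissingPolicy = "lenient",
) -> SampleCallset:
    """Keep exactly the calls whose verdict is *passed*. Idempotent."""
    return callset.replace_calls(
        c for c in callset if evaluate(c, thresholds, missing_policy).passed
    )
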