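"""Case/control SNV selection as identity-keyed set algebra.

Three selection strategies over a cohort of per-sample callsets:

* **Method A** — per-sample catalog: each sample's SNVs that pass the hard
  filter. Purely descriptive; no cross-sample comparison.
* **Method B** — filter first, subtract later: each case's *filtered* SNVs
  minus the union of the controls' *filtered* SNVs.
* **Method C** — subtract first, filter later: each case's *raw* SNVs minus
  the union of the controls' *raw* SNVs, then the hard filter applied to the
  surviving case calls.

The order matters. A variant shared by a case and a control but of poor
quality in the control disappears from the control's filtered callset, so
method B wrongly reports it as case-specific; method C subtracts at the raw
level and cannot make that mistake. Consequently method C's output is always
contained in method B's.

"Absent in controls" means absent from the union over all controls, and
subtraction compares variant identity (chrom, pos, ref, alt) only — genotypes
differ between carriers of the same variant and must not affect membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .errors import ValidationError
from .filters import FilterThresholds, FilterVerdict, MissingPolicy, evaluate, filter_callset
from .model import CohortStudy, SampleCallset, VariantKey, select_snvs

Level = Literal["raw", "filtered"]

#: Per-sample record of filter verdicts for the calls a method evaluated.
Provenance = dict[str, dict[VariantKey, FilterVerdict]]


@dataclass(slots=True)
class MethodResult:
    """Output of one selection method over a cohort.

    ``per_sample`` maps sample id to its selected variant keys (for A: every
    sample's filtered SNVs; for B/C: each case's case-specific filtered SNVs).
    ``common`` is the intersection over the case sets — the variants present in
    every case and in no control — and is empty by definition for method A.
    """

    method: Literal["A", "B", "C"]
    per_sample: dict[str, set[VariantKey]]
    common: set[VariantKey]
    provenance: Provenance = field(default_factory=dict)

    def case_ids(self) -> list[str]:
        return list(self.per_sample)


def _verdicts(
    callset: SampleCallset,
    thresholds: FilterThresholds,
    missing_policy: MissingPolicy,
) -> dict[VariantKey, FilterVerdict]:
    return {c.key: evaluate(c, thresholds, missing_policy) for c in callset}


def control_union(
    cohort: CohortStudy,
    level: Level,
    thresholds: FilterThresholds = FilterThresholds(),
    missing_policy: MissingPolicy = "lenient",
) -> set[VariantKey]:
    """Union of the controls' SNV keys, at raw or filtered level."""
    if level not in ("raw", "filtered"):
        raise ValidationError(f"unknown level {level!r}")
    if not cohort.controls:
        raise ValidationError("control union needs at least one control")
    union: set[VariantKey] = set()
    for control in cohort.controls:
        snvs = select_snvs(control)
        if level == "filtered":
            snvs = filter_callset(snvs, thresholds, missing_policy)
        union |= snvs.keys()
    return union


def run_method_a(
    cohort: CohortStudy,
    thresholds: FilterThresholds = FilterThresholds(),
    missing_policy: MissingPolicy = "lenient",
) -> MethodResult:
    """Per-sample filtered SNV catalogs for every case and control."""
    per_sample: dict[str, set[VariantKey]] = {}
    provenance: Provenance = {}
    for sample in cohort.all_samples():
        snvs = select_snvs(sample)
        verdicts = _verdicts(snvs, thresholds, missing_policy)
        per_sample[sample.sample_id] = {k for k, v in verdicts.items() if v.passed}
        provenance[sample.sample_id] = verdicts
    return MethodResult("A", per_sample, common=set(), provenance=provenance)


def run_method_b(
    cohort: CohortStudy,
    thresholds: FilterThresholds = FilterThresholds(),
    missing_policy: MissingPolicy = "lenient",
) -> MethodResult:
    """Filter each case, then subtract the filtered control union."""
    excluded = control_union(cohort, "filtered", thresholds, missing_policy)
    per_sample: dict[str, set[VariantKey]] = {}
    provenance: Provenance = {}
    for case in cohort.cases:
        snvs = select_snvs(case)
        verdicts = _verdicts(snvs, thresholds, missing_policy)
        passed = {k for k, v in verdicts.items() if v.passed}
        per_sample[case.sample_id] = passed - excluded
        provenance[case.sample_id] = verdicts
    common = set.intersection(*per_sample.values()) if per_sample else set()
    return MethodResult("B", per_sample, common=common, provenance=provenance)


def run_method_c(
    cohort: CohortStudy,
    thresholds: FilterThresholds = FilterThresholds(),
    missing_policy: MissingPolicy = "lenient",
) -> MethodResult:
    """Subtract the raw control union first, then filter the survivors."""
    excluded = control_union(cohort, "raw", thresholds, missing_policy)
    per_sample: dict[str, set[VariantKey]] = {}
    provenance: Provenance = {}
    for case in cohort.cases:
        snvs = select_snvs(case)
        raw_specific = snvs.keys() - excluded
        restricted = snvs.replace_calls(c for c in snvs if c.key in raw_specific)
        verdicts = _verdicts(restricted, thresholds, missing_policy)
        per_sample[case.sample_id] = {k for k, v in verdicts.items() if v.passed}
        provenance[case.sample_id] = verdicts
    common = set.intersection(*per_sample.values()) if per_sample else set()
    return MethodResult("C", per_sample, common=common, provenance=provenance)


def intersect_cases(result: MethodResult) -> set[VariantKey]:
    """Variants common to every case's case-specific set (methods B/C only)."""
    if result.method == "A":
        raise ValidationError("method A has no cross-case intersection semantics")
    if not result.per_sample:
        return set()
    return set.intersection(*result.per_sample.values())


def genotype_concordance(
    a: SampleCallset,
    b: SampleCallset,
    keys: set[VariantKey],
) -> tuple[float, list[dict]]:
    """Fraction of shared variant keys whose unordered genotypes match exactly.

    Used to compare calls from two tissues of the same donor (e.g. brain vs
    blood): near-1 concordance over the studied variants indicates a germline
    rather than somatic origin. Returns the fraction and a per-key table.
    """
    if not keys:
        raise ValidationError("concordance over an empty key set is undefined")
    table = []
    matches = 0
    for key in sorted(keys):
        call_a, call_b = a.get(key), b.get(key)
        if call_a is None:
            raise ValidationError(f"key {key} absent from callset {a.sample_id}")
        if call_b is None:
            raise ValidationError(f"key {key} absent from callset {b.sample_id}")
        match = sorted(call_a.genotype) == sorted(call_b.genotype)
        matches += match
        table.append(
            {
                "key": str(key),
                "genotype_a": "/".join(call_a.genotype),
                "genotype_b": "/".join(call_b.genotype),
                "concordant": match,
            }
        )
    return matches / len(keys), table
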