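"""Per-chromosome SNV burden profiles and case/control comparison.

The comparison unit is the *percentage* of a sample's SNVs falling on each
chromosome (not the raw count), which normalizes out per-sample differences in
total variant yield. Group means with sample standard deviations (n-1
denominator) reproduce mean-with-SD-error-bar style summaries; the case-vs-
control contrast per chromosome uses Welch's two-sample t-test by default
(appropriate for small unequal groups with unequal variances), with
Mann-Whitney as an option. No multiple-testing correction is applied by
default; a Bonferroni option across the 24 chromosomes is available.

chrY is present in every profile and simply counts zero for female samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import ValidationError
from .model import CANONICAL_CHROMS, SampleCallset, VariantKey

logger = logging.getLogger(__name__)

TestName = Literal["welch_t", "mann_whitney"]


@dataclass(slots=True)
class ChromProfile:
    """One sample's per-chromosome SNV counts and percentage shares."""

    sample_id: str
    counts: dict[str, int]
    percentages: dict[str, float]
    empty: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(slots=True)
class ChromComparison:
    """Case-vs-control contrast for a single chromosome."""

    chrom: str
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    diff: float  # mean_case - mean_control, in percentage points
    diff_count: float  # same contrast on mean raw counts
    p_value: Optional[float]
    significant: bool


@dataclass(slots=True)
class GroupComparison:
    """Per-chromosome group comparison table plus the test configuration."""

    test: TestName
    alpha: float
    n_case: int
    n_control: int
    rows: list[ChromComparison] = field(default_factory=list)
    label: str = "case_vs_control"

    def row(self, chrom: str) -> ChromComparison:
        for r in self.rows:
            if r.chrom == chrom:
                return r
        raise ValidationError(f"no chromosome {chrom!r} in comparison")


def profile(
    calls: Union[SampleCallset, Iterable[VariantKey]],
    sample_id: Optional[str] = None,
) -> ChromProfile:
    """Count SNVs per chromosome and express each as a percent of the total.

    Accepts either a callset or a bare collection of variant keys. An empty
    input yields an all-zero, flagged profile.
    """
    if isinstance(calls, SampleCallset):
        keys: Iterable[VariantKey] = calls.keys()
        sample_id = sample_id or calls.sample_id
    else:
        keys = calls
        sample_id = sample_id or "<keys>"
    counts = {chrom: 0 for chrom in CANONICAL_CHROMS}
    for key in keys:
        counts[key.chrom] += 1
    total = sum(counts.values())
    if total == 0:
        return ChromProfile(sample_id, counts, dict.fromkeys(CANONICAL_CHROMS, 0.0), empty=True)
    percentages = {c: 100.0 * n / total for c, n in counts.items()}
    return ChromProfile(sample_id, counts, percentages)


def group_summary(
    profiles: Sequence[ChromProfile],
) -> dict[str, dict[str, float]]:
    """Per-chromosome mean and sample SD of percentage shares.

    Returns ``{chrom: {"mean": m, "sd": s, "n": n}}``; with a single profile the
    SD is 0 by convention (n=1 is visible in the "n" entry).
    """
    if not profiles:
        raise ValidationError("group summary needs at least one profile")
    out = {}
    n = len(profiles)
    for chrom in CANONICAL_CHROMS:
        values = np.array([p.percentages[chrom] for p in profiles])
        sd = float(values.std(ddof=1)) if n > 1 else 0.0
        out[chrom] = {"mean": float(values.mean()), "sd": sd, "n": n}
    return out


def _two_sample_p(
    case_vals: np.ndarray, control_vals: np.ndarray, test: TestName
) -> Optional[float]:
    if len(case_vals) < 2 or len(control_vals) < 2:
        return None
    if np.ptp(case_vals) == 0 and np.ptp(control_vals) == 0:
        # degenerate: no within-group variance; decided by the means alone
        return 1.0 if case_vals[0] == control_vals[0] else 0.0
    if test == "welch_t":
        return float(stats.ttest_ind(case_vals, control_vals, equal_var=False).pvalue)
    return float(stats.mannwhitneyu(case_vals, control_vals, alternative="two-sided").pvalue)


def compare_groups(
    case_profiles: Sequence[ChromProfile],
    control_profiles: Sequence[ChromProfile],
    test: TestName = "welch_t",
    alpha: float = 0.001,
    bonferroni: bool = False,
    label: str = "case_vs_control",
) -> GroupComparison:
    """Two-sided per-chromosome comparison of percentage shares between groups.

    With fewer than two samples in either group the p-value is reported as
    missing (None) and only the descriptive contrast is emitted. The
    significance flag compares p against ``alpha`` (divided by 24 when
    ``bonferroni`` is set).
    """
    if test not in ("welch_t", "mann_whitney"):
        raise ValidationError(f"unknown test {test!r}")
    if not case_profiles or not control_profiles:
        raise ValidationError("both groups need at least one profile")
    threshold = alpha / len(CANONICAL_CHROMS) if bonferroni else alpha
    comparison = GroupComparison(
        test=test,
        alpha=alpha,
        n_case=len(case_profiles),
        n_control=len(control_profiles),
        label=label,
    )
    for chrom in CANONICAL_CHROMS:
        case_pct = np.array([p.percentages[chrom] for p in case_profiles])
        ctrl_pct = np.array([p.percentages[chrom] for p in control_profiles])
        case_cnt = np.array([p.counts[chrom] for p in case_profiles], dtype=float)
        ctrl_cnt = np.array([p.counts[chrom] for p in control_profiles], dtype=float)
        p_value = _two_sample_p(case_pct, ctrl_pct, test)
        mean_case = float(case_pct.mean())
        mean_control = float(ctrl_pct.mean())
        comparison.rows.append(
            ChromComparison(
                chrom=chrom,
                mean_case=mean_case,
                sd_case=float(case_pct.std(ddof=1)) if len(case_pct) > 1 else 0.0,
                mean_control=mean_control,
                sd_control=float(ctrl_pct.std(ddof=1)) if len(ctrl_pct) > 1 else 0.0,
                diff=mean_case - mean_control,
                diff_count=float(case_cnt.mean() - ctrl_cnt.mean()),
                p_value=p_value,
                significant=(p_value is not None and p_value < threshold
                             and not math.isnan(p_value)),
            )
        )
    return comparison


#: Default stratum pairings: male cases vs male controls, and cases split by sex.
DEFAULT_STRATA: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("case", "M"), ("control", "M")),
    (("case", "M"), ("case", "F")),
)


def stratify_by_sex(
    profiles: Mapping[str, ChromProfile],
    manifest: Iterable,  # objects with sample_id / group / sex attributes
    strata: Sequence[tuple[tuple[str, str], tuple[str, str]]] = DEFAULT_STRATA,
    test: TestName = "welch_t",
    alpha: float = 0.001,
) -> list[GroupComparison]:
    """Run configured sex-stratified group comparisons.

    Each stratum names two (group, sex) cells, e.g. male cases vs male
    controls; a stratum with an empty cell is skipped with a warning so that a
    single-sex cohort still yields the comparisons it can support.
    """
    entries = list(manifest)
    missing_sex = [e.sample_id for e in entries if getattr(e, "sex", None) not in ("M", "F")]
    if missing_sex:
        raise ValidationError(f"samples without recorded sex: {missing_sex}")

    def cell(group: str, sex: str) -> list[ChromProfile]:
        return [
            profiles[e.sample_id]
            for e in entries
            if e.group == group and e.sex == sex and e.sample_id in profiles
        ]

    results = []
    for (g1, s1), (g2, s2) in strata:
        a, b = cell(g1, s1), cell(g2, s2)
        label = f"{g1}_{s1}_vs_{g2}_{s2}"
        if not a or not b:
            logger.warning("stratum %s skipped: empty cell", label)
            continue
        results.append(compare_groups(a, b, test=test, alpha=alpha, label=label))
    return results
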