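"""Seeded simulator of per-sample raw exome SNV callsets with planted truth.

The generator emulates the raw output of a germline variant caller over a
small case/control brain-exome cohort (default: five cases, three controls,
the cases two male / three female and the controls male, sequenced to ~50x
coverage) so that every pipeline stage — SNV selection, hard filtering, the
three case/control selection methods, chromosome-burden statistics — can be
exercised against known ground truth without any external data.

Three planted variant classes:

* **background** polymorphisms shared across the cohort. Each carries a
  population allele frequency drawn from a Beta distribution; samples carry it
  by Hardy-Weinberg draws (``background_mode="hw"``), or every sample carries
  it (``background_mode="shared"``, the clean fully-shared regime used to
  verify exact recovery of planted case-specific variants).
* **case-specific** variants present in every case and no control, always
  good-tier. A configurable fraction is forced onto chrX — the enrichment
  knob emulating an X-linked excess in cases.
* **borderline-shared** variants present in cases (good tier) *and* in every
  control with deliberately sub-threshold annotations, guaranteed to fail at
  least one hard-filter clause in each control. These are the calls that turn
  into false "case-specific" hits when subtraction happens after filtering
  (method B) and that subtraction at the raw level (method C) removes.

Annotation tiers are truncated-normal/exponential draws: the good tier is
truncated into the passing region of every clause (DP~N(50,10) floored at 21,
QUAL~N(200,50) floored above 30, QD~N(15,4), FS~Exp(3) capped at 60,
MQ~N(60,2), HaplotypeScore~Exp(1.5) capped at 13, rank-sums~N(0,1)); the
borderline tier starts from a good draw and forces one uniformly chosen
clause past its threshold. HaplotypeScore, MQRankSum and ReadPosRankSum are
dropped at ``missing_annotation_rate`` (never a forced clause), mimicking
annotations a caller only sometimes emits.

Sex is honoured on the allosomes: chrY variants are generated only for male
samples, and male chrX/chrY genotypes are drawn hemizygously (a single allele)
but emitted diploid-coded (alt/alt), matching how published variant tables
print diploid genotypes for male donors. Planted (case-specific and
borderline) variants avoid chrY so that mixed-sex cohorts can share them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .model import CANONICAL_CHROMS, CohortStudy, SampleCallset, VariantCall, VariantKey
from .vcfio import GRCH37_CHROM_LENGTHS, ManifestEntry, write_manifest, write_vcf

_NUC = np.array(list("ACGT"))

# Approximate protein-coding gene counts per chromosome, used as relative
# exome-target weights for the autosomes.
_GENE_COUNTS = {
    "1": 2058, "2": 1309, "3": 1078, "4": 752, "5": 876, "6": 1048,
    "7": 989, "8": 677, "9": 786, "10": 733, "11": 1298, "12": 1034,
    "13": 327, "14": 830, "15": 613, "16": 873, "17": 1197, "18": 270,
    "19": 1472, "20": 544, "21": 234, "22": 488,
}

_X_WEIGHT = 0.03
_Y_WEIGHT = 0.002


def default_chrom_weights() -> dict[str, float]:
    """Exome-share weights: autosomes by gene count, chrX 0.03, chrY 0.002."""
    autosome_total = sum(_GENE_COUNTS.values())
    scale = (1.0 - _X_WEIGHT - _Y_WEIGHT) / autosome_total
    weights = {c: n * scale for c, n in _GENE_COUNTS.items()}
    weights["X"] = _X_WEIGHT
    weights["Y"] = _Y_WEIGHT
    return weights


@dataclass(frozen=True, slots=True)
class AnnotationTier:
    """Parameters of the good-quality annotation distributions."""

    dp_mean: float = 50.0
    dp_sd: float = 10.0
    qual_mean: float = 200.0
    qual_sd: float = 50.0
    qd_mean: float = 15.0
    qd_sd: float = 4.0
    fs_mean: float = 3.0
    mq_mean: float = 60.0
    mq_sd: float = 2.0
    haplotypescore_mean: float = 1.5
    ranksum_sd: float = 1.0


#: Default roster sexes mirroring the study design (cases M,F,F,F,M; controls M).
_CASE_SEX_PATTERN = ("M", "F", "F", "F", "M")


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Simulation parameters; defaults reproduce the study-scale cohort."""

    seed: int = 0
    n_cases: int = 5
    n_controls: int = 3
    case_sexes: Optional[Sequence[str]] = None
    control_sexes: Optional[Sequence[str]] = None
    chrom_weights: Optional[dict[str, float]] = None
    n_background: int = 20000
    af_beta: tuple[float, float] = (0.8, 0.8)
    background_mode: Literal["hw", "shared"] = "hw"
    n_case_specific: int = 30
    case_specific_chrX_fraction: float = 0.0
    n_borderline_shared: int = 50
    missing_annotation_rate: float = 0.05
    tier: AnnotationTier = field(default_factory=AnnotationTier)

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        for name in ("n_background", "n_case_specific", "n_borderline_shared"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.case_specific_chrX_fraction <= 1.0:
            raise ValidationError("case_specific_chrX_fraction must be in [0,1]")
        if not 0.0 <= self.missing_annotation_rate <= 1.0:
            raise ValidationError("missing_annotation_rate must be in [0,1]")
        if self.background_mode not in ("hw", "shared"):
            raise ValidationError(f"unknown background_mode {self.background_mode!r}")
        weights = self.resolved_chrom_weights()
        if set(weights) != set(CANONICAL_CHROMS):
            raise ValidationError("chrom_weights must cover every canonical chromosome")
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValidationError("chrom_weights must sum to 1")
        for sexes, n, what in (
            (self.case_sexes, self.n_cases, "case_sexes"),
            (self.control_sexes, self.n_controls, "control_sexes"),
        ):
            if sexes is not None:
                if len(sexes) != n or not set(sexes) <= {"M", "F"}:
                    raise ValidationError(f"{what} must list M/F for each sample")

    def resolved_chrom_weights(self) -> dict[str, float]:
        return dict(self.chrom_weights) if self.chrom_weights else default_chrom_weights()

    def resolved_sexes(self) -> tuple[list[str], list[str]]:
        cases = (
            list(self.case_sexes)
            if self.case_sexes is not None
            else [_CASE_SEX_PATTERN[i % len(_CASE_SEX_PATTERN)] for i in range(self.n_cases)]
        )
        controls = (
            list(self.control_sexes)
            if self.control_sexes is not None
            else ["M"] * self.n_controls
        )
        return cases, controls


@dataclass(slots=True)
class SimTruth:
    """Planted ground truth: the three disjoint variant classes and, per
    sample, the genotype and annotation tier of every planted call."""

    planted_case_specific: set[VariantKey]
    planted_shared: set[VariantKey]
    planted_borderline_shared: set[VariantKey]
    assignments: dict[str, dict[VariantKey, dict]]

    def to_json_dict(self) -> dict:
        return {
            "planted_case_specific": sorted(map(str, self.planted_case_specific)),
            "planted_shared": sorted(map(str, self.planted_shared)),
            "planted_borderline_shared": sorted(map(str, self.planted_borderline_shared)),
            "assignments": {
                sid: {
                    str(k): {"genotype": list(v["genotype"]), "tier": v["tier"]}
                    for k, v in sorted(per.items(), key=lambda kv: str(kv[0]))
                }
                for sid, per in self.assignments.items()
            },
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "SimTruth":
        return cls(
            planted_case_specific={VariantKey.parse(s) for s in data["planted_case_specific"]},
            planted_shared={VariantKey.parse(s) for s in data["planted_shared"]},
            planted_borderline_shared={
                VariantKey.parse(s) for s in data["planted_borderline_shared"]
            },
            assignments={
                sid: {
                    VariantKey.parse(k): {"genotype": tuple(v["genotype"]), "tier": v["tier"]}
                    for k, v in per.items()
                }
                for sid, per in data["assignments"].items()
            },
        )


# --- key generation -------------------------------------------------------


def _draw_keys(
    rng: np.random.Generator,
    n: int,
    weights: dict[str, float],
    seen: set[tuple[str, int]],
    force_chrom: Optional[str] = None,
    exclude_y: bool = False,
) -> list[VariantKey]:
    """Draw n unique variant keys (unique by chrom+pos across the cohort)."""
    if n == 0:
        return []
    chrom_names = list(weights)
    probs = np.array([weights[c] for c in chrom_names], dtype=float)
    if exclude_y and force_chrom is None and "Y" in chrom_names:
        probs[chrom_names.index("Y")] = 0.0
        if probs.sum() == 0:
            raise ValidationError("chrom_weights leave no chromosome to draw from")
        probs = probs / probs.sum()
    keys: list[VariantKey] = []
    attempts = 0
    while len(keys) < n:
        attempts += 1
        if attempts > 1000:
            raise ValidationError("cannot place requested variants: position space exhausted")
        m = n - len(keys)
        if force_chrom is not None:
            chroms = [force_chrom] * m
        else:
            chroms = [chrom_names[i] for i in rng.choice(len(chrom_names), size=m, p=probs)]
        for chrom in chroms:
            pos = int(rng.integers(1, GRCH37_CHROM_LENGTHS[chrom] + 1))
            if (chrom, pos) in seen:
                continue
            seen.add((chrom, pos))
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + int(rng.integers(1, 4))) % 4
            keys.append(VariantKey(chrom, pos, str(_NUC[ref_i]), str(_NUC[alt_i])))
    return keys


# --- annotation tiers -----------------------------------------------------


def _good_annotations(rng: np.random.Generator, n: int, tier: AnnotationTier) -> dict[str, np.ndarray]:
    """Vectorized good-tier draws, truncated into every clause's passing region."""
    return {
        "DP": np.clip(np.rint(rng.normal(tier.dp_mean, tier.dp_sd, n)), 21, None).astype(int),
        "QUAL": np.clip(rng.normal(tier.qual_mean, tier.qual_sd, n), 31.0, None),
        "QD": np.clip(rng.normal(tier.qd_mean, tier.qd_sd, n), 2.0, None),
        "FS": np.clip(rng.exponential(tier.fs_mean, n), 0.0, 60.0),
        "MQ": np.clip(rng.normal(tier.mq_mean, tier.mq_sd, n), 35.0, None),
        "HaplotypeScore": np.clip(rng.exponential(tier.haplotypescore_mean, n), 0.0, 13.0),
        "MQRankSum": np.clip(rng.normal(0.0, tier.ranksum_sd, n), -12.5, None),
        "ReadPosRankSum": np.clip(rng.normal(0.0, tier.ranksum_sd, n), -8.0, None),
    }


_FORCEABLE = ("DP", "QUAL", "QD", "FS", "MQ", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")


def _force_borderline(rng: np.random.Generator, ann: dict[str, np.ndarray], idx: np.ndarray) -> np.ndarray:
    """Force one uniformly chosen clause past its threshold for rows ``idx``.

    Returns the forced clause name per row (needed to protect it from the
    missing-annotation dropout)."""
    choice = rng.integers(0, len(_FORCEABLE), len(idx))
    forced = np.array([_FORCEABLE[c] for c in choice])
    for row, clause in zip(idx, forced):
        if clause == "DP":
            ann["DP"][row] = int(rng.integers(0, 21))  # DP <= 20 fails
        elif clause == "QUAL":
            ann["QUAL"][row] = rng.uniform(0.0, 30.0)
        elif clause == "QD":
            ann["QD"][row] = rng.uniform(0.0, 1.99)
        elif clause == "FS":
            ann["FS"][row] = rng.uniform(60.01, 200.0)
        elif clause == "MQ":
            ann["MQ"][row] = rng.uniform(0.0, 34.99)
        elif clause == "HaplotypeScore":
            ann["HaplotypeScore"][row] = rng.uniform(13.01, 40.0)
        elif clause == "MQRankSum":
            ann["MQRankSum"][row] = rng.uniform(-20.0, -12.51)
        else:
            ann["ReadPosRankSum"][row] = rng.uniform(-16.0, -8.01)
    return forced


_OPTIONAL_ANN = ("HaplotypeScore", "MQRankSum", "ReadPosRankSum")


# --- genotype draws -------------------------------------------------------


def _genotype_given_carrier(rng: np.random.Generator, key: VariantKey, af: float, sex: str) -> tuple[str, str]:
    """Genotype conditional on the sample carrying the variant."""
    if sex == "M" and key.chrom in ("X", "Y"):
        return (key.alt, key.alt)  # hemizygous, diploid-coded
    p_hom = af / (2.0 - af)  # P(hom | carrier) under Hardy-Weinberg
    if rng.random() < p_hom:
        return (key.alt, key.alt)
    return (key.ref, key.alt)


def _carries(rng: np.random.Generator, key: VariantKey, af: float, sex: str) -> Optional[tuple[str, str]]:
    """Unconditional Hardy-Weinberg draw; None when the sample lacks the variant."""
    if key.chrom == "Y":
        if sex == "F":
            return None
        return (key.alt, key.alt) if rng.random() < af else None
    if key.chrom == "X" and sex == "M":
        return (key.alt, key.alt) if rng.random() < af else None
    a1 = rng.random() < af
    a2 = rng.random() < af
    if not (a1 or a2):
        return None
    if a1 and a2:
        return (key.alt, key.alt)
    return (key.ref, key.alt)


# --- main entry points ----------------------------------------------------


def simulate_cohort(config: SimConfig) -> tuple[CohortStudy, SimTruth]:
    """Generate a cohort of raw per-sample callsets plus planted ground truth.

    Deterministic for a fixed config (including the seed). The three planted
    classes are pairwise disjoint by construction; case-specific keys appear in
    every case and no control; borderline-shared keys appear good-tier in every
    case and sub-threshold in every control.
    """
    rng = np.random.default_rng(config.seed)
    weights = config.resolved_chrom_weights()
    case_sexes, control_sexes = config.resolved_sexes()
    any_female = "F" in case_sexes or "F" in control_sexes

    seen: set[tuple[str, int]] = set()
    background = _draw_keys(rng, config.n_background, weights, seen)
    n_forced = round(config.case_specific_chrX_fraction * config.n_case_specific)
    case_specific = _draw_keys(rng, n_forced, weights, seen, force_chrom="X")
    case_specific += _draw_keys(
        rng, config.n_case_specific - n_forced, weights, seen, exclude_y=any_female
    )
    borderline = _draw_keys(
        rng, config.n_borderline_shared, weights, seen, exclude_y=any_female
    )

    a, b = config.af_beta
    background_af = np.clip(rng.beta(a, b, len(background)), 0.01, 0.99)
    planted_af = np.clip(rng.beta(a, b, len(case_specific) + len(borderline)), 0.01, 0.99)

    sample_plan = [(f"A{i + 1}", "case", case_sexes[i]) for i in range(config.n_cases)]
    sample_plan += [(f"C{i + 1}", "control", control_sexes[i]) for i in range(config.n_controls)]

    cases, controls = [], []
    assignments: dict[str, dict[VariantKey, dict]] = {}
    for sample_id, group, sex in sample_plan:
        planned: list[tuple[VariantKey, tuple[str, str], str]] = []  # key, gt, tier
        for key, af in zip(background, background_af):
            if config.background_mode == "shared":
                if key.chrom == "Y" and sex == "F":
                    continue
                gt = _genotype_given_carrier(rng, key, float(af), sex)
            else:
                gt = _carries(rng, key, float(af), sex)
                if gt is None:
                    continue
            planned.append((key, gt, "good"))
        for j, key in enumerate(case_specific):
            if group != "case":
                continue
            gt = _genotype_given_carrier(rng, key, float(planted_af[j]), sex)
            planned.append((key, gt, "good"))
        off = len(case_specific)
        for j, key in enumerate(borderline):
            gt = _genotype_given_carrier(rng, key, float(planted_af[off + j]), sex)
            tier = "good" if group == "case" else "borderline"
            planned.append((key, gt, tier))

        calls = _materialize_calls(rng, planned, config)
        callset = SampleCallset(sample_id, group, sex, calls)
        (cases if group == "case" else controls).append(callset)
        assignments[sample_id] = {
            key: {"genotype": gt, "tier": tier} for key, gt, tier in planned
        }

    truth = SimTruth(
        planted_case_specific=set(case_specific),
        planted_shared=set(background),
        planted_borderline_shared=set(borderline),
        assignments=assignments,
    )
    return CohortStudy(cases=cases, controls=controls), truth


def _materialize_calls(
    rng: np.random.Generator,
    planned: Sequence[tuple[VariantKey, tuple[str, str], str]],
    config: SimConfig,
) -> list[VariantCall]:
    n = len(planned)
    if n == 0:
        return []
    ann = _good_annotations(rng, n, config.tier)
    borderline_rows = np.array([i for i, (_, _, tier) in enumerate(planned) if tier == "borderline"])
    forced_by_row: dict[int, str] = {}
    if len(borderline_rows):
        forced = _force_borderline(rng, ann, borderline_rows)
        forced_by_row = dict(zip(borderline_rows.tolist(), forced.tolist()))
    dropout = {
        key: rng.random(n) < config.missing_annotation_rate for key in _OPTIONAL_ANN
    }
    calls = []
    for i, (key, gt, _tier) in enumerate(planned):
        annotations = {
            "DP": int(ann["DP"][i]),
            "QD": float(ann["QD"][i]),
            "FS": float(ann["FS"][i]),
            "MQ": float(ann["MQ"][i]),
        }
        forced_clause = forced_by_row.get(i)
        for opt in _OPTIONAL_ANN:
            if dropout[opt][i] and opt != forced_clause:
                continue
            annotations[opt] = float(ann[opt][i])
        if forced_clause == "DP":
            annotations["DP"] = int(ann["DP"][i])
        calls.append(
            VariantCall(
                key=key,
                qual=float(ann["QUAL"][i]),
                genotype=gt,
                annotations=annotations,
            )
        )
    return calls


def write_cohort(
    cohort: CohortStudy,
    truth: SimTruth,
    directory: Union[str, Path],
) -> Path:
    """Write per-sample VCFs, a cohort manifest TSV and the truth JSON.

    Returns the manifest path; everything written is loadable with
    :func:`exomesift.vcfio.load_cohort` and :meth:`SimTruth.from_json_dict`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for sample in cohort.all_samples():
        vcf_name = f"{sample.sample_id}.vcf"
        write_vcf(sample, directory / vcf_name)
        entries.append(ManifestEntry(sample.sample_id, vcf_name, sample.group, sample.sex))
    manifest_path = directory / "manifest.tsv"
    write_manifest(entries, manifest_path)
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    return manifest_path


def clean_config(**overrides) -> SimConfig:
    """A convenience config with no borderline calls and no annotation dropout,
    fully shared background — the regime where both selection methods must
    recover the planted case-specific set exactly."""
    base = dict(
        n_borderline_shared=0,
        missing_annotation_rate=0.0,
        background_mode="shared",
    )
    base.update(overrides)
    return SimConfig(**base)
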