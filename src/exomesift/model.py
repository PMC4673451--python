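"""Domain types for single-nucleotide variant calls, per-sample callsets and cohorts.

Variant identity is the tuple (chrom, pos, ref, alt). Genotype is deliberately
NOT part of identity: the same SNV can be carried het by one donor and hom-alt
by another, and every set operation in the pipeline (subtraction against
controls, cross-case intersection) must treat those as the same variant.

Coordinates are 1-based point positions as in VCF. Chromosome names are kept in
their un-prefixed canonical form ("1".."22", "X", "Y"); dialects such as "chrX"
are normalized on ingest by :func:`normalize_chrom`.

Male chrX calls are stored with diploid genotype coding. Published variant
tables for male donors print diploid genotypes on chrX, so hemizygosity is a
simulation concern, not a storage concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

from .errors import ValidationError

#: Canonical chromosome names, in karyotype order.
CANONICAL_CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CANONICAL_SET = frozenset(CANONICAL_CHROMS)
_NUCLEOTIDES = frozenset("ACGT")

#: INFO annotations carried on a call, in the order they are written to VCF.
ANNOTATION_KEYS: tuple[str, ...] = (
    "DP",
    "QD",
    "FS",
    "MQ",
    "HaplotypeScore",
    "MQRankSum",
    "ReadPosRankSum",
)


def normalize_chrom(name: str, *, map_numeric_xy: bool = False) -> str:
    """Map a chromosome name to its canonical un-prefixed form.

    A leading "chr" is stripped case-insensitively. ``"23"``/``"24"`` are
    rejected by default; with ``map_numeric_xy=True`` they map to X/Y (a
    convention some tools use). Anything outside the canonical set raises
    :class:`ValidationError`.
    """
    stripped = name.strip()
    if stripped[:3].lower() == "chr":
        stripped = stripped[3:]
    if map_numeric_xy and stripped in ("23", "24"):
        stripped = "X" if stripped == "23" else "Y"
    if stripped not in _CANONICAL_SET:
        raise ValidationError(f"unrecognized chromosome name: {name!r}")
    return stripped


def chrom_sort_key(chrom: str) -> int:
    """Karyotype ordering index for a canonical chromosome name."""
    return CANONICAL_CHROMS.index(chrom)


@dataclass(frozen=True, order=True, slots=True)
class VariantKey:
    """Identity of a variant: canonical chromosome, 1-based position, ref, alt.

    For an SNV ref and alt are single nucleotides; indel alleles are allowed so
    that raw caller output can be represented before SNV selection, but SNV-only
    invariants are enforced by :func:`select_snvs` downstream.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chrom not in _CANONICAL_SET:
            raise ValidationError(f"non-canonical chromosome {self.chrom!r}")
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _NUCLEOTIDES:
                raise ValidationError(f"allele {allele!r} has non-ACGT characters")
        if self.ref == self.alt:
            raise ValidationError("ref and alt must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:  # "X:142967468:T>G"
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Inverse of ``str()``: parse "chrom:pos:ref>alt"."""
        try:
            chrom, pos, change = text.split(":")
            ref, alt = change.split(">")
            return cls(chrom, int(pos), ref, alt)
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"cannot parse variant key {text!r}: {exc}") from exc


@dataclass(frozen=True, slots=True)
class VariantCall:
    """One called variant with its quality annotations and genotype.

    ``annotations`` holds the caller's INFO values (DP, QD, FS, MQ,
    HaplotypeScore, MQRankSum, ReadPosRankSum); a missing annotation is simply
    absent from the mapping, which keeps "missing" distinguishable from zero.
    ``genotype`` is an unordered diploid pair of allele strings; at least one
    allele equals alt (a call asserts the variant).
    """

    key: VariantKey
    qual: float
    genotype: tuple[str, str]
    annotations: Mapping[str, float] = field(default_factory=dict)
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValidationError(f"QUAL must be >= 0, got {self.qual}")
        gt = tuple(self.genotype)
        if len(gt) != 2:
            raise ValidationError("genotype must be a diploid pair")
        allowed = {self.key.ref, self.key.alt}
        if not set(gt) <= allowed:
            raise ValidationError(
                f"genotype alleles {gt} not drawn from ref/alt {allowed}"
            )
        if self.key.alt not in gt:
            raise ValidationError("a call must carry at least one alt allele")
        # canonical unordered form: ref allele first
        object.__setattr__(self, "genotype", tuple(sorted(gt, key=lambda a: a != self.key.ref)))
        unknown = set(self.annotations) - set(ANNOTATION_KEYS)
        if unknown:
            raise ValidationError(f"unknown annotation keys: {sorted(unknown)}")

    @property
    def is_hom_alt(self) -> bool:
        return self.genotype[0] == self.genotype[1] == self.key.alt


class SampleCallset:
    """A sample's variant calls, keyed by :class:`VariantKey` (no duplicates)."""

    __slots__ = ("sample_id", "group", "sex", "_calls")

    def __init__(
        self,
        sample_id: str,
        group: str,
        sex: str,
        calls: Iterable[VariantCall] = (),
    ) -> None:
        if group not in ("case", "control"):
            raise ValidationError(f"group must be 'case' or 'control', got {group!r}")
        if sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {sex!r}")
        self.sample_id = sample_id
        self.group = group
        self.sex = sex
        self._calls: dict[VariantKey, VariantCall] = {}
        for call in calls:
            self.add(call)

    def add(self, call: VariantCall) -> None:
        if call.key in self._calls:
            raise ValidationError(
                f"duplicate variant {call.key} in sample {self.sample_id}"
            )
        self._calls[call.key] = call

    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self._calls.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._calls

    def __getitem__(self, key: VariantKey) -> VariantCall:
        return self._calls[key]

    def get(self, key: VariantKey) -> Optional[VariantCall]:
        return self._calls.get(key)

    def keys(self) -> set[VariantKey]:
        return set(self._calls)

    def sorted_calls(self) -> list[VariantCall]:
        """Calls in (karyotype, position, ref, alt) order, for deterministic output."""
        return sorted(
            self._calls.values(),
            key=lambda c: (chrom_sort_key(c.key.chrom), c.key.pos, c.key.ref, c.key.alt),
        )

    def replace_calls(self, calls: Iterable[VariantCall]) -> "SampleCallset":
        """New callset with the same sample metadata and the given calls."""
        return SampleCallset(self.sample_id, self.group, self.sex, calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleCallset):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.group == other.group
            and self.sex == other.sex
            and self._calls == other._calls
        )

    def __repr__(self) -> str:
        return (
            f"SampleCallset({self.sample_id!r}, {self.group!r}, {self.sex!r}, "
            f"{len(self)} calls)"
        )


def select_snvs(callset: SampleCallset) -> SampleCallset:
    """Keep only single-nucleotide substitutions, dropping indels.

    SNVs are separated from indels before any filtering or comparison step.
    Idempotent; the result is a subset of the input by key.
    """
    return callset.replace_calls(c for c in callset if c.key.is_snv)


@dataclass(slots=True)
class CohortStudy:
    """A case/control cohort: at least one case and one control, unique ids."""

    cases: list[SampleCallset]
    controls: list[SampleCallset]

    def __post_init__(self) -> None:
        if not self.cases or not self.controls:
            raise ValidationError("cohort needs at least one case and one control")
        for s in self.cases:
            if s.group != "case":
                raise ValidationError(f"sample {s.sample_id} in cases has group {s.group}")
        for s in self.controls:
            if s.group != "control":
                raise ValidationError(
                    f"sample {s.sample_id} in controls has group {s.group}"
                )
        ids = [s.sample_id for s in self.all_samples()]
        if len(ids) != len(set(ids)):
            raise ValidationError("sample ids must be unique across the cohort")

    def all_samples(self) -> list[SampleCallset]:
        return list(self.cases) + list(self.controls)

    def sample(self, sample_id: str) -> SampleCallset:
        for s in self.all_samples():
            if s.sample_id == sample_id:
                return s
        raise ValidationError(f"no sample {sample_id!r} in cohort")
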