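"""VCF 4.x and cohort-manifest I/O.

Reading goes through cyvcf2 and writing through pysam, so both ends speak
standard htslib-compatible VCF. Only single-sample VCFs are handled: one
genotype column, QUAL, and the site-level INFO annotations used by the hard
filter (DP, QD, FS, MQ, HaplotypeScore, MQRankSum, ReadPosRankSum).

Multi-allelic records are split into biallelic calls that share the record's
site-level annotations. A split call is emitted for every ALT allele carried in
the genotype; genotype alleles belonging to a sibling ALT are coded as ref in
the split call (each biallelic call can only speak about its own alt).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import cyvcf2
import pysam

from .errors import ParseError, ValidationError
from .model import (
    ANNOTATION_KEYS,
    CANONICAL_CHROMS,
    CohortStudy,
    SampleCallset,
    VariantCall,
    VariantKey,
    normalize_chrom,
)

#: GRCh37 chromosome lengths, for ##contig header lines and simulated positions.
GRCH37_CHROM_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}

_INFO_TYPES = {"DP": ("1", "Integer")}
_NUCS = frozenset("ACGT")


def read_vcf(
    path: Union[str, Path],
    sample_id: str,
    group: str,
    sex: str,
) -> SampleCallset:
    """Load a single-sample VCF into a :class:`SampleCallset`.

    One call is produced per carried ALT allele per record; non-SNV calls are
    retained (SNV/indel separation happens in :func:`~exomesift.model.select_snvs`).
    Chromosome names are normalized on ingest.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"VCF not found: {path}")
    try:
        reader = cyvcf2.VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    calls: list[VariantCall] = []
    try:
        for recno, variant in enumerate(reader, start=1):
            calls.extend(_record_to_calls(variant, recno, path))
    finally:
        reader.close()
    return SampleCallset(sample_id, group, sex, calls)


def _record_to_calls(variant, recno: int, path: Path) -> list[VariantCall]:
    where = f"{path.name} record {recno} ({variant.CHROM}:{variant.POS})"
    try:
        chrom = normalize_chrom(variant.CHROM)
    except ValidationError as exc:
        raise ParseError(f"{where}: {exc}") from exc
    if variant.QUAL is None:
        raise ParseError(f"{where}: missing QUAL")
    if not variant.genotypes:
        raise ParseError(f"{where}: no genotype column")
    gt = variant.genotypes[0]
    allele_idx = [a for a in gt[:-1] if a is not None and a >= 0]
    if len(allele_idx) == 1:  # haploid coding read back as diploid hom
        allele_idx = allele_idx * 2
    if len(allele_idx) != 2:
        raise ParseError(f"{where}: genotype is not diploid")
    rsid = variant.ID or None
    annotations = {}
    for key in ANNOTATION_KEYS:
        value = variant.INFO.get(key)
        if value is None:
            continue
        annotations[key] = int(value) if key == "DP" else float(value)
    ref = variant.REF.upper()
    calls = []
    for alt_i, alt in enumerate(variant.ALT, start=1):
        alt = alt.upper()
        if not (set(alt) <= _NUCS and set(ref) <= _NUCS):
            continue  # symbolic / spanning-deletion alleles carry no SNV
        if alt_i not in allele_idx:
            continue  # this sample does not carry this alt
        alleles = tuple(alt if a == alt_i else ref for a in allele_idx)
        try:
            key = VariantKey(chrom, variant.POS, ref, alt)
            calls.append(
                VariantCall(
                    key=key,
                    qual=float(variant.QUAL),
                    genotype=alleles,
                    annotations=annotations,
                    rsid=rsid,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{where}: {exc}") from exc
    return calls


def _build_header(sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in CANONICAL_CHROMS:
        header.contigs.add(chrom, length=GRCH37_CHROM_LENGTHS[chrom])
    for key in ANNOTATION_KEYS:
        number, vtype = _INFO_TYPES.get(key, ("1", "Float"))
        header.info.add(key, number, vtype, f"{key} site annotation")
    header.formats.add("GT", "1", "String", "Genotype")
    header.add_sample(sample_id)
    return header


def write_vcf(callset: SampleCallset, path: Union[str, Path]) -> None:
    """Write a callset as an uncompressed single-sample VCF.

    Records are sorted in karyotype/position order; missing annotations are
    simply omitted from INFO so they round-trip as missing.
    """
    path = Path(path)
    header = _build_header(callset.sample_id)
    try:
        writer = pysam.VariantFile(str(path), "w", header=header)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot write VCF {path}: {exc}") from exc
    try:
        for call in callset.sorted_calls():
            rec = writer.new_record(
                contig=call.key.chrom,
                start=call.key.pos - 1,
                alleles=(call.key.ref, call.key.alt),
                id=call.rsid,
                qual=call.qual,
            )
            for key in ANNOTATION_KEYS:
                if key in call.annotations:
                    rec.info[key] = call.annotations[key]
            allele_code = {call.key.ref: 0, call.key.alt: 1}
            rec.samples[callset.sample_id]["GT"] = tuple(
                allele_code[a] for a in call.genotype
            )
            writer.write(rec)
    finally:
        writer.close()


@dataclass(frozen=True, slots=True)
class ManifestEntry:
    sample_id: str
    path: str
    group: str
    sex: str


MANIFEST_COLUMNS = ("sample_id", "path", "group", "sex")


def read_manifest(path: Union[str, Path]) -> list[ManifestEntry]:
    """Parse a cohort manifest TSV (columns sample_id, path, group, sex)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"manifest missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            if row["group"] not in ("case", "control"):
                raise ParseError(f"{path.name} line {lineno}: bad group {row['group']!r}")
            if row["sex"] not in ("M", "F"):
                raise ParseError(f"{path.name} line {lineno}: bad sex {row['sex']!r}")
            entries.append(
                ManifestEntry(row["sample_id"], row["path"], row["group"], row["sex"])
            )
    ids = [e.sample_id for e in entries]
    if len(ids) != len(set(ids)):
        raise ParseError(f"duplicate sample ids in manifest {path}")
    return entries


def write_manifest(entries: Iterable[ManifestEntry], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for e in entries:
            writer.writerow([e.sample_id, e.path, e.group, e.sex])


def load_cohort(manifest_path: Union[str, Path]) -> CohortStudy:
    """Read every VCF named in a manifest and assemble the cohort.

    Relative VCF paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    cases, controls = [], []
    for entry in read_manifest(manifest_path):
        vcf_path = Path(entry.path)
        if not vcf_path.is_absolute():
            vcf_path = base / vcf_path
        callset = read_vcf(vcf_path, entry.sample_id, entry.group, entry.sex)
        (cases if entry.group == "case" else controls).append(callset)
    return CohortStudy(cases=cases, controls=controls)


def annotations_close(a: Optional[float], b: Optional[float], sig: int = 6) -> bool:
    """True when two annotation values agree to ``sig`` significant digits
    (both-missing counts as agreement)."""
    if a is None or b is None:
        return a is None and b is None
    if a == b:
        return True
    return math.isclose(a, b, rel_tol=10.0 ** (1 - sig), abs_tol=1e-9)
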