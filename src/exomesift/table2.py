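"""The packaged worked example: the published table of 84 case-specific SNVs.

The fixture TSV mirrors the published table of SNVs present in all five case
exomes and in none of the controls (method B; the 42-row subset also found by
the stricter method C is marked by the ``method_c`` column, which corresponds
to the bold rows of the original). Genotypes are carried verbatim for the five
case donors A1-A5. Rows whose variant falls outside an annotated codon carry
``NA`` in the codon/aa columns.

All summary numbers are recomputed from the parsed records at call time;
nothing is hard-coded, so a mutated fixture changes the summary (and trips the
checksum check first).
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .consequence import classify, parse_codon_change, parse_protein_notation
from .errors import IntegrityError, ParseError
from .model import CANONICAL_CHROMS, chrom_sort_key

_FIXTURE_SHA256 = "ba1949b5d2b6eb967229887441a89cdde4f647e32a1590462e0b7ccd409591c5"


@dataclass(frozen=True, slots=True)
class Table2Record:
    chrom: str
    pos: int
    rsid: str
    gene: str
    codon_change: Optional[str]  # None for the NA rows
    aa_change: Optional[str]
    genotypes: tuple[str, str, str, str, str]  # donors A1..A5
    method_c: bool

    @property
    def residue_index(self) -> Optional[int]:
        if self.aa_change is None:
            return None
        return parse_protein_notation(self.aa_change)[1]


def _fixture_bytes() -> bytes:
    return resources.files("exomesift").joinpath("data/table2.tsv").read_bytes()


def load_table2() -> list[Table2Record]:
    """Load and validate the packaged fixture (checksum-guarded)."""
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise IntegrityError(
            f"table2 fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    records = []
    reader = csv.DictReader(raw.decode().splitlines(), delimiter="\t")
    for lineno, row in enumerate(reader, start=2):
        if row["chrom"] not in CANONICAL_CHROMS:
            raise ParseError(f"table2 line {lineno}: bad chromosome {row['chrom']!r}")
        codon = None if row["codon_change"] == "NA" else row["codon_change"]
        aa = None if row["aa_change"] == "NA" else row["aa_change"]
        if (codon is None) != (aa is None):
            raise ParseError(f"table2 line {lineno}: codon/aa NA mismatch")
        records.append(
            Table2Record(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                rsid=row["rsid"],
                gene=row["gene"],
                codon_change=codon,
                aa_change=aa,
                genotypes=tuple(row[f"gt_a{i}"] for i in range(1, 6)),
                method_c=row["method_c"] == "true",
            )
        )
    sites = [(r.chrom, r.pos) for r in records]
    if len(sites) != len(set(sites)):
        raise ParseError("table2 fixture has duplicate chrom/pos sites")
    return records


def classify_record(record: Table2Record):
    """Run the consequence classifier on one record's printed codon change.

    Returns None for the NA (non-codon) rows. The residue index fed to the
    classifier comes from the printed protein notation, whose letters the
    classifier then re-derives from the codons alone.
    """
    if record.codon_change is None:
        return None
    change = parse_codon_change(record.codon_change, record.residue_index)
    return classify(change)


def table2_summary() -> dict:
    """Counts recomputed from the fixture: totals, the method-C subset,
    per-chromosome breakdown and the chrX method-C gene set."""
    records = load_table2()
    method_c = [r for r in records if r.method_c]
    per_chrom: dict[str, dict[str, int]] = {}
    for r in records:
        entry = per_chrom.setdefault(r.chrom, {"total": 0, "method_c": 0})
        entry["total"] += 1
        entry["method_c"] += r.method_c
    return {
        "total": len(records),
        "method_c": len(method_c),
        "per_chromosome": dict(
            sorted(per_chrom.items(), key=lambda kv: chrom_sort_key(kv[0]))
        ),
        "chrX_method_c_genes": sorted(r.gene for r in method_c if r.chrom == "X"),
    }
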