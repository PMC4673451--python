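"""Serialization of method results and comparison statistics.

Everything is emitted as plain JSON/TSV so downstream plotting or inspection
needs no package code; the JSON form round-trips back into the in-memory
result for the set-valued fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

from .chromstats import GroupComparison
from .methods import MethodResult
from .model import CohortStudy, VariantKey, chrom_sort_key


def method_result_to_dict(result: MethodResult) -> dict:
    return {
        "method": result.method,
        "per_sample": {
            sid: sorted(map(str, keys)) for sid, keys in result.per_sample.items()
        },
        "common": sorted(map(str, result.common)),
        "provenance": {
            sid: {
                str(key): {
                    "passed": v.passed,
                    "failed_clauses": list(v.failed_clauses),
                    "missing_clauses": list(v.missing_clauses),
                }
                for key, v in sorted(verdicts.items(), key=lambda kv: str(kv[0]))
            }
            for sid, verdicts in result.provenance.items()
        },
    }


def method_result_sets_from_dict(data: dict) -> tuple[str, dict[str, set[VariantKey]], set[VariantKey]]:
    """Reload the set-valued part of a serialized method result."""
    per_sample = {
        sid: {VariantKey.parse(s) for s in keys}
        for sid, keys in data["per_sample"].items()
    }
    common = {VariantKey.parse(s) for s in data["common"]}
    return data["method"], per_sample, common


COMPARISON_COLUMNS = (
    "label", "chrom", "mean_case", "sd_case", "mean_control", "sd_control",
    "diff", "diff_count", "p_value", "significant",
)


def comparison_tsv_lines(comparison: GroupComparison) -> list[str]:
    lines = ["\t".join(COMPARISON_COLUMNS)]
    for r in comparison.rows:
        p = "NA" if r.p_value is None else f"{r.p_value:.6g}"
        lines.append(
            "\t".join(
                [
                    comparison.label, r.chrom,
                    f"{r.mean_case:.6g}", f"{r.sd_case:.6g}",
                    f"{r.mean_control:.6g}", f"{r.sd_control:.6g}",
                    f"{r.diff:.6g}", f"{r.diff_count:.6g}",
                    p, str(int(r.significant)),
                ]
            )
        )
    return lines


_COMMON_HEADER = ("chrom", "pos", "id", "gene", "codon_change", "aa_change")


def common_set_tsv_lines(
    result: MethodResult, cohort: Optional[CohortStudy] = None
) -> list[str]:
    """The common (all-cases, no-control) set in published-table layout.

    Gene and codon columns are "NA" here: annotation against a gene model is
    outside this package's scope. Genotype columns are filled from the cohort
    when it is supplied.
    """
    case_ids = list(result.per_sample)
    header = list(_COMMON_HEADER) + [f"GT_{sid}" for sid in case_ids]
    lines = ["\t".join(header)]
    for key in sorted(result.common, key=lambda k: (chrom_sort_key(k.chrom), k.pos)):
        row = [key.chrom, str(key.pos), ".", "NA", "NA", "NA"]
        for sid in case_ids:
            gt = "NA"
            if cohort is not None:
                call = cohort.sample(sid).get(key)
                if call is not None:
                    gt = "/".join(call.genotype)
                    if call.rsid:
                        row[2] = call.rsid
            row.append(gt)
        lines.append("\t".join(row))
    return lines


def write_report(
    result: MethodResult,
    out_dir: Union[str, Path],
    comparison: Optional[GroupComparison] = None,
    cohort: Optional[CohortStudy] = None,
) -> dict:
    """Write result.json, common.tsv and (optionally) stats.tsv plus a
    human-readable summary.txt; returns the summary dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = method_result_to_dict(result)
    (out_dir / "result.json").write_text(json.dumps(payload, indent=1) + "\n")
    (out_dir / "common.tsv").write_text(
        "\n".join(common_set_tsv_lines(result, cohort)) + "\n"
    )
    if comparison is not None:
        (out_dir / "stats.tsv").write_text(
            "\n".join(comparison_tsv_lines(comparison)) + "\n"
        )
    summary = {
        "method": result.method,
        "per_sample_sizes": {sid: len(keys) for sid, keys in result.per_sample.items()},
        "common_size": len(result.common),
    }
    lines = [f"method {result.method}"]
    for sid, size in summary["per_sample_sizes"].items():
        lines.append(f"  {sid}: {size} selected SNVs")
    if result.method == "A":
        lines.append("  (per-sample catalogs; no cross-sample comparison)")
    elif result.common:
        lines.append(f"  common to all cases, absent from controls: {len(result.common)}")
    else:
        lines.append("  zero shared case-specific SNVs")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
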