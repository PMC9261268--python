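"""Curation of multi-source collision cross-section (CCS) records.

Literature CCS compilations contain repeated measurements of the same
ion (same neutral structure, same adduct) reported by different
laboratories on different ion-mobility platforms.  This module
consolidates such records into one value per (InChIKey, adduct) pair —
the median of all contributing measurements — together with the
relative standard deviation (RSD) of the replicates, flags
high-variance duplicates, and audits agreement between drift-tube
(DTIMS) and traveling-wave (TWIMS) measurements.

The InChIKey is the sole compound identity; names are free text and are
never used for matching.
"""

from __future__ import annotations

import csv
import json
import re
import statistics
import warnings
from dataclasses import dataclass, field

ADDUCTS = ("[M+H]+", "[M+Na]+")
PLATFORMS = ("TWIMS", "DTIMS")

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


@dataclass(frozen=True)
class RawCCSRecord:
    """One literature CCS measurement of a single ion."""

    compound_name: str
    inchikey: str
    smiles: str
    formula: str
    monoisotopic_mass: float
    adduct: str
    ccs: float
    ims_platform: str
    source_id: str


@dataclass(frozen=True)
class RejectedRecord:
    """A raw record that failed validation, with the reason."""

    record: RawCCSRecord
    reason: str


@dataclass
class ConsolidatedCCSRecord:
    """Median CCS for one (InChIKey, adduct) key with replicate statistics.

    ``rsd_pct`` is the sample standard deviation (n-1 denominator) of the
    contributing CCS values divided by their mean, times 100; it is 0 for
    a single measurement.  ``high_rsd_flag`` marks keys whose replicates
    disagree by more than ``rsd_threshold`` percent (default 2%), the
    level beyond which inter-laboratory CCS reproducibility is suspect.
    """

    inchikey: str
    adduct: str
    median_ccs: float
    n_measurements: int
    rsd_pct: float
    contributing: list[tuple[str, float, str]] = field(default_factory=list)
    high_rsd_flag: bool = False


@dataclass(frozen=True)
class CrossPlatformComparison:
    """Per-key deviation of the drift-tube CCS from the traveling-wave CCS."""

    inchikey: str
    adduct: str
    tw_ccs: float
    dt_ccs: float
    deviation_pct: float


def validate_records(
    records: list[RawCCSRecord],
) -> tuple[list[RawCCSRecord], list[RejectedRecord]]:
    """Split records into valid ones and per-record rejection reports."""
    valid: list[RawCCSRecord] = []
    rejected: list[RejectedRecord] = []
    for rec in records:
        if not rec.inchikey or not _INCHIKEY_RE.match(rec.inchikey):
            rejected.append(RejectedRecord(rec, f"malformed InChIKey: {rec.inchikey!r}"))
        elif rec.adduct not in ADDUCTS:
            rejected.append(RejectedRecord(rec, f"unsupported adduct: {rec.adduct!r}"))
        elif not (rec.ccs > 0):
            rejected.append(RejectedRecord(rec, f"non-positive CCS: {rec.ccs!r}"))
        else:
            valid.append(rec)
    return valid, rejected


@dataclass
class ConsolidationResult:
    """Outcome of a consolidation run: accepted keys plus rejected inputs."""

    records: list[ConsolidatedCCSRecord]
    rejected: list[RejectedRecord]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def consolidate(
    records: list[RawCCSRecord], rsd_threshold: float = 2.0
) -> ConsolidationResult:
    """Collapse raw records to one median-CCS record per (InChIKey, adduct).

    The median is taken over all contributing raw values for the key,
    regardless of platform (an even count yields the mean of the two
    central values).  Invalid records are reported, never fatal.  Output
    order is deterministic: sorted by InChIKey, then adduct.
    """
    valid, rejected = validate_records(records)
    groups: dict[tuple[str, str], list[RawCCSRecord]] = {}
    for rec in valid:
        groups.setdefault((rec.inchikey, rec.adduct), []).append(rec)

    out: list[ConsolidatedCCSRecord] = []
    for (inchikey, adduct) in sorted(groups):
        members = groups[(inchikey, adduct)]
        values = [m.ccs for m in members]
        med = statistics.median(values)
        if len(values) > 1:
            rsd = statistics.stdev(values) / statistics.mean(values) * 100.0
        else:
            rsd = 0.0
        out.append(
            ConsolidatedCCSRecord(
                inchikey=inchikey,
                adduct=adduct,
                median_ccs=med,
                n_measurements=len(values),
                rsd_pct=rsd,
                contributing=[(m.source_id, m.ccs, m.ims_platform) for m in members],
                high_rsd_flag=rsd > rsd_threshold,
            )
        )
    return ConsolidationResult(records=out, rejected=rejected)


def flag_high_rsd(
    consolidated: list[ConsolidatedCCSRecord], rsd_threshold: float = 2.0
) -> list[ConsolidatedCCSRecord]:
    """Return the keys whose replicate RSD exceeds the threshold, worst first."""
    flagged = [c for c in consolidated if c.rsd_pct > rsd_threshold]
    return sorted(flagged, key=lambda c: -c.rsd_pct)


def compare_platforms(
    records: list[RawCCSRecord],
) -> tuple[list[CrossPlatformComparison], dict]:
    """Compare drift-tube to traveling-wave CCS per dual-platform key.

    For every (InChIKey, adduct) key measured on both platforms, the
    per-platform value is the median within that platform and the
    deviation is (DT - TW) / TW * 100.  Returns the per-key rows and a
    summary over |deviation|: percent within 2%, mean, min, max.
    """
    valid, _ = validate_records(records)
    groups: dict[tuple[str, str], dict[str, list[float]]] = {}
    for rec in valid:
        groups.setdefault((rec.inchikey, rec.adduct), {}).setdefault(
            rec.ims_platform, []
        ).append(rec.ccs)

    rows: list[CrossPlatformComparison] = []
    for (inchikey, adduct) in sorted(groups):
        by_platform = groups[(inchikey, adduct)]
        if "TWIMS" in by_platform and "DTIMS" in by_platform:
            tw = statistics.median(by_platform["TWIMS"])
            dt = statistics.median(by_platform["DTIMS"])
            rows.append(
                CrossPlatformComparison(
                    inchikey=inchikey,
                    adduct=adduct,
                    tw_ccs=tw,
                    dt_ccs=dt,
                    deviation_pct=(dt - tw) / tw * 100.0,
                )
            )
    if not rows:
        warnings.warn("no key measured on both platforms", stacklevel=2)
        summary = {
            "n": 0,
            "pct_within_2pct": float("nan"),
            "mean_abs_deviation_pct": float("nan"),
            "min_abs_deviation_pct": float("nan"),
            "max_abs_deviation_pct": float("nan"),
        }
        return rows, summary
    abs_dev = [abs(r.deviation_pct) for r in rows]
    summary = {
        "n": len(rows),
        "pct_within_2pct": 100.0 * sum(d < 2.0 for d in abs_dev) / len(abs_dev),
        "mean_abs_deviation_pct": sum(abs_dev) / len(abs_dev),
        "min_abs_deviation_pct": min(abs_dev),
        "max_abs_deviation_pct": max(abs_dev),
    }
    return rows, summary


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

RAW_CSV_HEADER = [
    "name",
    "inchikey",
    "smiles",
    "formula",
    "monoisotopic_mass",
    "adduct",
    "ccs",
    "platform",
    "source",
]


def load_raw_csv(path) -> list[RawCCSRecord]:
    """Read raw CCS records from the canonical CSV dialect.

    Expected header: ``name,inchikey,smiles,formula,monoisotopic_mass,
    adduct,ccs,platform,source`` (UTF-8, decimal point).
    """
    records: list[RawCCSRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(RAW_CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"missing CSV columns: {sorted(missing)}")
        for row in reader:
            records.append(
                RawCCSRecord(
                    compound_name=row["name"],
                    inchikey=row["inchikey"],
                    smiles=row["smiles"],
                    formula=row["formula"],
                    monoisotopic_mass=float(row["monoisotopic_mass"] or "nan"),
                    adduct=row["adduct"],
                    ccs=float(row["ccs"]),
                    ims_platform=row["platform"],
                    source_id=row["source"],
                )
            )
    return records


def write_raw_csv(records: list[RawCCSRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RAW_CSV_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.compound_name,
                    r.inchikey,
                    r.smiles,
                    r.formula,
                    f"{r.monoisotopic_mass:.6f}",
                    r.adduct,
                    f"{r.ccs:.4f}",
                    r.ims_platform,
                    r.source_id,
                ]
            )


def write_consolidated_csv(records: list[ConsolidatedCCSRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["inchikey", "adduct", "median_ccs", "n_measurements", "rsd_pct", "high_rsd_flag"]
        )
        for r in records:
            writer.writerow(
                [r.inchikey, r.adduct, f"{r.median_ccs:.4f}", r.n_measurements,
                 f"{r.rsd_pct:.4f}", int(r.high_rsd_flag)]
            )


def consolidation_report(
    result: ConsolidationResult,
    platform_summary: dict | None = None,
) -> dict:
    """Build the JSON-serializable consolidation report."""
    per_adduct: dict[str, dict] = {}
    for adduct in ADDUCTS:
        subset = [r for r in result.records if r.adduct == adduct]
        per_adduct[adduct] = {
            "n_consolidated": len(subset),
            "n_multi_measurement": sum(r.n_measurements > 1 for r in subset),
            "n_high_rsd": sum(r.high_rsd_flag for r in subset),
        }
    report = {
        "n_raw_accepted": sum(r.n_measurements for r in result.records),
        "n_rejected": len(result.rejected),
        "rejected": [
            {"inchikey": rr.record.inchikey, "source": rr.record.source_id, "reason": rr.reason}
            for rr in result.rejected
        ],
        "per_adduct": per_adduct,
        "flagged_keys": [
            {"inchikey": r.inchikey, "adduct": r.adduct, "rsd_pct": round(r.rsd_pct, 4)}
            for r in flag_high_rsd(result.records)
        ],
    }
    if platform_summary is not None:
        report["platform_summary"] = platform_summary
    return report


def write_report_json(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
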