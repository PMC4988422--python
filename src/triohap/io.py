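"""Tabular and JSON file formats for the pipeline.

Tab-separated values are the primary tabular format (matching what
fragment-analysis software exports); no standard sequence/variant format
applies to sized-peak data.  All files are UTF-8 with decimal points and
a header row; parse errors name the offending row.  Correction models
are serialised to JSON in their numerically stable (mapped-domain)
representation — power-basis coefficients are included for display but
never read back.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from numpy.polynomial import Polynomial

from .correction import CorrectedPeak, CorrectionModel, CorrectionTable, ShiftRecord
from .dyestats import VariabilityReport
from .model import Dye, Genotype, PeakObservation, TrioGenotypes
from .phasing import PhasedTrio
from .synthetic_data import Family

MISSING = "N"

PEAK_COLUMNS = ("family_id", "run_id", "member", "dye", "marker", "observed_size", "height")


class ParseError(ValueError):
    """A malformed input row; the message names file, row and column."""


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return MISSING
    return format(float(value), ".10g")


def read_peak_table(path: str) -> list[PeakObservation]:
    """Read a sized-peak TSV into typed observations.

    Expected header: ``family_id  run_id  member  dye  marker
    observed_size  height`` (height may be empty).
    """
    peaks: list[PeakObservation] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in PEAK_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=2):  # header is row 1
            try:
                height = row.get("height", "")
                peaks.append(
                    PeakObservation(
                        family_id=row["family_id"],
                        run_id=row["run_id"],
                        member=row["member"],
                        dye=row["dye"],
                        marker=row["marker"],
                        observed_size=float(row["observed_size"]),
                        height=float(height) if height not in ("", MISSING) else None,
                        flags=tuple(f for f in row.get("flags", "").split(",") if f)
                        if "flags" in row and row["flags"]
                        else (),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
    return peaks


def write_peak_table(peaks: Iterable[PeakObservation], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(PEAK_COLUMNS + ("flags",))
        for p in peaks:
            writer.writerow(
                [
                    p.family_id,
                    p.run_id,
                    p.member,
                    p.dye,
                    p.marker,
                    _fmt(p.observed_size),
                    _fmt(p.height) if p.height is not None else "",
                    ",".join(p.flags),
                ]
            )


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class TruthTable:
    """Simulated ground truth: genotypes, haplotype origins and risk flags."""

    trios: dict[str, TrioGenotypes] = field(default_factory=dict)
    #: per family: marker -> (paternal allele, maternal allele) for the child
    origins: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    #: per (family, member, hap label): at-risk flag
    risks: dict[tuple[str, str, str], bool] = field(default_factory=dict)


TRUTH_COLUMNS = ("family_id", "member", "hap", "marker", "allele", "risk", "status")


def write_truth(families: Sequence[Family], path: str, child_index: int = 0) -> None:
    """Write one row per (member, haplotype, marker) of each family."""
    from .synthetic_data import family_to_trio

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(TRUTH_COLUMNS)
        for fam in families:
            trio = family_to_trio(fam, child_index)
            fh_hap, mh_hap = fam.child_haps(child_index)
            rows = [
                ("child", "paternal", fh_hap),
                ("child", "maternal", mh_hap),
                ("father", "h1", fam.father_haps[0]),
                ("father", "h2", fam.father_haps[1]),
                ("mother", "h1", fam.mother_haps[0]),
                ("mother", "h2", fam.mother_haps[1]),
            ]
            for member, hap_label, hap in rows:
                for marker, allele in hap.alleles:
                    writer.writerow(
                        [
                            fam.family_id,
                            member,
                            hap_label,
                            marker,
                            _fmt(allele),
                            int(hap.risk),
                            trio.affected_status[member],
                        ]
                    )


def read_truth(path: str) -> TruthTable:
    truth = TruthTable()
    haps: dict[tuple[str, str, str], dict[str, float]] = {}
    statuses: dict[tuple[str, str], str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in TRUTH_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                key = (row["family_id"], row["member"], row["hap"])
                haps.setdefault(key, {})[row["marker"]] = float(row["allele"])
                truth.risks[key] = bool(int(row["risk"]))
                statuses[(row["family_id"], row["member"])] = row["status"]
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
    for (family_id, member, hap_label), alleles in haps.items():
        trio = truth.trios.setdefault(family_id, TrioGenotypes(family_id=family_id))
        for marker, allele in alleles.items():
            key = (member, marker)
            if key in trio.genotypes:
                first = trio.genotypes[key].alleles[0]
                trio.genotypes[key] = Genotype(alleles=(first, allele))
            else:
                trio.genotypes[key] = Genotype(alleles=(allele, allele))
        if member == "child":
            side = 0 if hap_label == "paternal" else 1
            fam_orig = truth.origins.setdefault(family_id, {})
            for marker, allele in alleles.items():
                pair = list(fam_orig.get(marker, (np.nan, np.nan)))
                pair[side] = allele
                fam_orig[marker] = (pair[0], pair[1])
    for (family_id, member), status in statuses.items():
        truth.trios[family_id].affected_status[member] = status
    return truth


# ---------------------------------------------------------------------------
# shifts / corrected peaks

CORRECTED_COLUMNS = PEAK_COLUMNS + ("reference_size", "shift", "corrected_size", "flags")


def write_corrected(
    shifts: Sequence[ShiftRecord], corrected: Sequence[CorrectedPeak], path: str
) -> None:
    """Write per-peak reference assignment, raw shift and corrected size.

    ``shifts`` and ``corrected`` must be parallel (both produced from the
    same peak list, in order).
    """
    if len(shifts) != len(corrected):
        raise ValueError("shift and corrected lists are not parallel")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(CORRECTED_COLUMNS)
        for rec, cp in zip(shifts, corrected):
            p = rec.peak
            writer.writerow(
                [
                    p.family_id,
                    p.run_id,
                    p.member,
                    p.dye,
                    p.marker,
                    _fmt(p.observed_size),
                    _fmt(p.height) if p.height is not None else "",
                    _fmt(rec.reference_size),
                    _fmt(rec.shift),
                    _fmt(cp.corrected_size),
                    ",".join(dict.fromkeys(p.flags + rec.flags + cp.flags)),
                ]
            )


def read_corrected(path: str) -> tuple[list[ShiftRecord], list[CorrectedPeak]]:
    shifts: list[ShiftRecord] = []
    corrected: list[CorrectedPeak] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in CORRECTED_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                flags = tuple(f for f in row["flags"].split(",") if f)
                peak = PeakObservation(
                    family_id=row["family_id"],
                    run_id=row["run_id"],
                    member=row["member"],
                    dye=row["dye"],
                    marker=row["marker"],
                    observed_size=float(row["observed_size"]),
                    height=float(row["height"]) if row["height"] else None,
                )
                ref = None if row["reference_size"] == MISSING else float(row["reference_size"])
                cor = None if row["corrected_size"] == MISSING else float(row["corrected_size"])
                shifts.append(
                    ShiftRecord(
                        peak=peak,
                        reference_size=ref,
                        flags=("unassigned",) if ref is None else (),
                    )
                )
                corrected.append(
                    CorrectedPeak(peak=peak, corrected_size=cor, flags=flags)
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
    return shifts, corrected


# ---------------------------------------------------------------------------
# genotypes

GENOTYPE_COLUMNS = ("family_id", "member", "marker", "allele1", "allele2", "status", "flags")


def write_genotypes(trios: Iterable[TrioGenotypes], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(GENOTYPE_COLUMNS)
        for trio in trios:
            for (member, marker), g in sorted(trio.genotypes.items()):
                writer.writerow(
                    [
                        trio.family_id,
                        member,
                        marker,
                        _fmt(g.alleles[0]),
                        _fmt(g.alleles[1]),
                        trio.affected_status.get(member, "unknown"),
                        ",".join(g.flags),
                    ]
                )


def read_genotypes(path: str) -> dict[str, TrioGenotypes]:
    trios: dict[str, TrioGenotypes] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in GENOTYPE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                trio = trios.setdefault(
                    row["family_id"], TrioGenotypes(family_id=row["family_id"])
                )
                trio.genotypes[(row["member"], row["marker"])] = Genotype(
                    alleles=(float(row["allele1"]), float(row["allele2"])),
                    flags=tuple(f for f in row["flags"].split(",") if f),
                )
                trio.affected_status[row["member"]] = row["status"]
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
    return trios


# ---------------------------------------------------------------------------
# correction table / variability report


def write_correction_table(
    table: CorrectionTable, path: str, dyes: Optional[Sequence[Dye]] = None
) -> None:
    """Write the mean-coefficient table: rows by reference size, one
    ``<dye>-R`` column per dye, missing cells rendered ``N``."""
    dyes = tuple(dyes) if dyes is not None else table.dyes
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["reference_size"] + [f"{d}-R" for d in dyes])
        for size in table.sizes:
            writer.writerow(
                [_fmt(size)] + [_fmt(table.coefficient(d, size)) for d in dyes]
            )


def read_correction_table(path: str) -> CorrectionTable:
    table = CorrectionTable()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if "reference_size" not in (reader.fieldnames or []):
            raise ParseError(f"{path}: missing column 'reference_size'")
        dyes = [c[:-2] for c in reader.fieldnames if c.endswith("-R")]
        for i, row in enumerate(reader, start=2):
            try:
                size = float(row["reference_size"])
                for dye in dyes:
                    cell = row[f"{dye}-R"]
                    if cell != MISSING:
                        table.cells[(dye, size)] = (float(cell), 1)
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
    return table


def write_variability_report(report: VariabilityReport, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["reference_size"]
            + [f"intra_{d}" for d in report.dyes]
            + ["inter_before", "inter_after", "n_runs"]
        )
        for size in sorted(report.rows):
            row = report.rows[size]
            writer.writerow(
                [_fmt(size)]
                + [_fmt(row["intra"][d]) for d in report.dyes]
                + [_fmt(row["inter_before"]), _fmt(row["inter_after"]), row["n_runs"]]
            )


# ---------------------------------------------------------------------------
# correction models JSON


def write_models(models: Mapping[Dye, CorrectionModel], path: str) -> None:
    payload = {}
    for dye, m in models.items():
        payload[dye] = {
            "degree": m.degree,
            "coef_scaled": list(m.coefficients_scaled),
            "domain": [float(v) for v in m.poly.domain],
            "window": [float(v) for v in m.poly.window],
            "x_range": list(m.x_range),
            "r_squared": m.r_squared,
            "se": m.se,
            "n_points": m.n_points,
            # display only: not evaluable if re-parsed at low precision
            "coef_raw_display": list(m.coefficients_raw),
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_models(path: str) -> dict[Dye, CorrectionModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    models: dict[Dye, CorrectionModel] = {}
    for dye, d in payload.items():
        poly = Polynomial(
            np.array(d["coef_scaled"], dtype=float),
            domain=np.array(d["domain"], dtype=float),
            window=np.array(d["window"], dtype=float),
        )
        models[dye] = CorrectionModel(
            dye=dye,
            degree=int(d["degree"]),
            poly=poly,
            r_squared=float(d["r_squared"]),
            se=None if d["se"] is None else float(d["se"]),
            n_points=int(d["n_points"]),
            x_range=(float(d["x_range"][0]), float(d["x_range"][1])),
        )
    return models


# ---------------------------------------------------------------------------
# haplotypes

HAPLOTYPE_COLUMNS = (
    "family_id",
    "origin",
    "str_allele",
    "vntr_allele",
    "rflp_allele",
    "ambiguous_markers",
    "mendel_violations",
)


def write_haplotypes(phased: Iterable[PhasedTrio], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(HAPLOTYPE_COLUMNS)
        for pt in phased:
            if pt.child_haplotypes is not None:
                for hap in pt.child_haplotypes:
                    writer.writerow(
                        [
                            pt.family_id,
                            hap.origin,
                            _fmt(hap.str_allele),
                            _fmt(hap.vntr_allele),
                            hap.rflp_allele or MISSING,
                            ",".join(pt.ambiguous_markers),
                            "",
                        ]
                    )
            else:
                writer.writerow(
                    [
                        pt.family_id,
                        "unresolved",
                        MISSING,
                        MISSING,
                        MISSING,
                        ",".join(pt.ambiguous_markers),
                        "; ".join(d for _, d in pt.mendel_violations),
                    ]
                )
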