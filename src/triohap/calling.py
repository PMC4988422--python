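"""Allele binning against the reference ladder and trio genotype assembly."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .correction import CorrectedPeak, CorrectionModel, apply_correction
from .model import (
    MEMBERS,
    Dye,
    Genotype,
    Panel,
    PeakObservation,
    ReferenceLadder,
    TrioGenotypes,
)

__all__ = ["AlleleCall", "RunMismatchError", "bin_to_ladder", "call_corrected_peaks", "call_trio_run"]


class RunMismatchError(ValueError):
    """Raised when a run's dye/member labels contradict the panel assignment."""


@dataclass(frozen=True)
class AlleleCall:
    """One corrected peak binned to a ladder rung (or a no-call).

    When called, ``distance = |corrected_size − called_allele|`` is within
    the binning tolerance.  Ties (a size exactly equidistant from two
    rungs) are never broken by convention: the peak is a no-call with a
    ``tie`` flag, because for diagnosis a wrong call is worse than a
    missing one.
    """

    corrected_size: float
    called_allele: Optional[float]
    distance: float
    flags: tuple[str, ...] = ()
    peak: Optional[PeakObservation] = None


def bin_to_ladder(
    corrected_size: float, ladder: ReferenceLadder, tolerance: Optional[float] = None
) -> AlleleCall:
    """Bin a corrected size to the nearest ladder rung within tolerance."""
    tol = ladder.marker.tolerance_bp if tolerance is None else tolerance
    if not 0 < tol < ladder.min_spacing / 2.0 + 1e-12:
        raise ValueError(
            f"tolerance {tol} must lie in (0, half the minimum rung spacing "
            f"{ladder.min_spacing / 2.0}]"
        )
    dists = sorted((abs(corrected_size - r), r) for r in ladder.rungs)
    best_d, best_r = dists[0]
    if best_d > tol:
        return AlleleCall(
            corrected_size=corrected_size,
            called_allele=None,
            distance=best_d,
            flags=("out_of_tolerance",),
        )
    if len(dists) > 1 and abs(dists[1][0] - best_d) < 1e-9:
        return AlleleCall(
            corrected_size=corrected_size,
            called_allele=None,
            distance=best_d,
            flags=("tie",),
        )
    return AlleleCall(
        corrected_size=corrected_size, called_allele=best_r, distance=best_d
    )


def call_corrected_peaks(
    corrected: Iterable[CorrectedPeak], panel: Panel
) -> list[AlleleCall]:
    """Bin a batch of corrected peaks against their markers' ladders."""
    calls = []
    for cp in corrected:
        if cp.corrected_size is None:
            continue
        call = bin_to_ladder(cp.corrected_size, panel.ladder(cp.peak.marker))
        calls.append(
            AlleleCall(
                corrected_size=call.corrected_size,
                called_allele=call.called_allele,
                distance=call.distance,
                flags=call.flags + cp.flags,
                peak=cp.peak,
            )
        )
    return calls


def _assemble(calls: Iterable[AlleleCall], family_id: str) -> TrioGenotypes:
    grouped: dict[tuple[str, str], list[AlleleCall]] = {}
    for call in calls:
        assert call.peak is not None
        grouped.setdefault((call.peak.member, call.peak.marker), []).append(call)
    trio = TrioGenotypes(family_id=family_id)
    for key, group in grouped.items():
        called = [c for c in group if c.called_allele is not None]
        alleles = sorted({c.called_allele for c in called})
        if len(called) == 0 or len(called) > 2 or len(alleles) > 2:
            # no usable peak, or more peaks/alleles than a diploid genotype
            continue
        if len(alleles) == 2:
            trio.genotypes[key] = Genotype(alleles=(alleles[0], alleles[1]))
        else:
            flags = ("single_peak",) if len(called) == 1 else ()
            trio.genotypes[key] = Genotype(alleles=(alleles[0], alleles[0]), flags=flags)
    return trio


def call_trio_run(
    peaks: Iterable[PeakObservation],
    models: Mapping[Dye, CorrectionModel],
    panel: Panel,
) -> TrioGenotypes:
    """Correct, bin and assemble the peaks of one (family, run) into genotypes.

    Per member and marker: two called peaks yield a heterozygote; one
    yields a homozygote flagged ``single_peak`` (a single peak cannot
    distinguish a true homozygote from allelic dropout, so the ambiguity
    is flagged, never guessed); zero or more than two leave the marker
    uncalled for that member.
    """
    peaks = list(peaks)
    fams = {p.family_id for p in peaks}
    runs = {p.run_id for p in peaks}
    if len(fams) != 1 or len(runs) != 1:
        raise RunMismatchError(
            f"call_trio_run expects one (family, run); got families {sorted(fams)} "
            f"runs {sorted(runs)}"
        )
    for p in peaks:
        expected = panel.dye_assignment[p.member]
        if p.dye != expected:
            raise RunMismatchError(
                f"family {p.family_id} run {p.run_id}: member {p.member!r} labeled "
                f"with dye {p.dye!r} but the panel assigns {expected!r}"
            )
    corrected = apply_correction(peaks, models)
    calls = call_corrected_peaks(corrected, panel)
    return _assemble(calls, family_id=next(iter(fams)))


def assemble_genotypes_from_calls(
    calls: Iterable[AlleleCall], family_id: str
) -> TrioGenotypes:
    """Assemble genotypes from pre-binned calls (CLI path on corrected tables)."""
    return _assemble(calls, family_id)
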