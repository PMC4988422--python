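"""Dye mobility-shift measurement and polynomial correction.

Fluorophore labels retard DNA fragments by different amounts during
capillary electrophoresis, so the same allele sizes differently under
FAM, HEX and TAMRA.  The correction pipeline is:

1. :func:`assign_reference` — pair each observed peak with a reference
   allele size ``R`` and record the *shift* (observed − R);
2. :func:`build_correction_table` — average shifts per (dye, R) into
   mean correction coefficients;
3. :func:`fit_correction_model` — fit a per-dye polynomial ``f(x)`` of
   the *observed* allele size ``x`` (reconstructed as ``R +
   coefficient``) predicting the correction coefficient;
4. :func:`apply_correction` — ``corrected = observed − f(observed)``.

Fitting is done on a mapped/scaled abscissa (``numpy.polynomial``'s
domain mapping).  Power-basis coefficients of a degree-6 polynomial over
x ≈ 220–515 bp suffer catastrophic cancellation: printed at 3 significant
digits they are not evaluable, so raw-basis coefficients are exposed for
display only and every computation goes through the stable form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from numpy.polynomial import Polynomial

from .model import Dye, PeakObservation, ReferenceLadder, TrioGenotypes

__all__ = [
    "ShiftRecord",
    "CorrectionTable",
    "CorrectionModel",
    "CorrectedPeak",
    "assign_reference",
    "build_correction_table",
    "fit_correction_model",
    "fit_all_models",
    "apply_correction",
    "corrected_residual_records",
]


@dataclass(frozen=True)
class ShiftRecord:
    """One peak paired with its reference allele size.

    ``shift`` is exactly ``peak.observed_size − reference_size``.  A peak
    that could not be assigned to any ladder rung has ``reference_size``
    ``None`` and carries the ``"unassigned"`` flag; such records are
    excluded from correction-table building.
    """

    peak: PeakObservation
    reference_size: Optional[float]
    flags: tuple[str, ...] = ()

    @property
    def assigned(self) -> bool:
        return self.reference_size is not None

    @property
    def shift(self) -> Optional[float]:
        if self.reference_size is None:
            return None
        return self.peak.observed_size - self.reference_size


def _truth_alleles(
    truth: Mapping[str, TrioGenotypes], peak: PeakObservation
) -> Optional[tuple[float, ...]]:
    trio = truth.get(peak.family_id)
    if trio is None:
        return None
    g = trio.genotype(peak.member, peak.marker)
    return None if g is None else g.alleles


def assign_reference(
    peaks: Iterable[PeakObservation],
    ladders: Mapping[str, ReferenceLadder],
    truth: Optional[Mapping[str, TrioGenotypes]] = None,
    prior_mean_shift: Optional[Mapping[Dye, float]] = None,
) -> list[ShiftRecord]:
    """Assign each peak a reference allele size and record its shift.

    With *truth* (simulated or family-validated genotypes, keyed by
    family id), each (family, member, marker) group of peaks is
    rank-matched against that member's true alleles: the k-th smallest
    observed size gets the k-th smallest distinct true allele.  Rank
    matching is robust to the dye shift itself, which on a 4-bp ladder
    can move a peak nearer the *adjacent* allele than its own.  Without
    truth, the reference is the ladder rung nearest to ``observed −
    prior_mean_shift[dye]`` (prior defaults to 0); a candidate farther
    than half the minimum rung spacing is left unassigned rather than
    force-matched.
    """
    prior = prior_mean_shift or {}
    peaks = list(peaks)
    for peak in peaks:
        if peak.marker not in ladders:
            raise KeyError(f"peak marker {peak.marker!r} has no reference ladder")

    refs: dict[int, Optional[float]] = {}
    if truth is not None:
        groups: dict[tuple[str, str, str], list[int]] = {}
        for i, peak in enumerate(peaks):
            if _truth_alleles(truth, peak) is not None:
                groups.setdefault(
                    (peak.family_id, peak.member, peak.marker), []
                ).append(i)
        for key, idxs in groups.items():
            alleles = sorted(set(_truth_alleles(truth, peaks[idxs[0]])))
            idxs = sorted(idxs, key=lambda i: peaks[i].observed_size)
            if len(idxs) == len(alleles):
                for i, allele in zip(idxs, alleles):
                    refs[i] = float(allele)
            else:
                # peak/allele count mismatch: fall back to nearest true allele
                for i in idxs:
                    refs[i] = float(
                        min(alleles, key=lambda a: abs(peaks[i].observed_size - a))
                    )

    records: list[ShiftRecord] = []
    for i, peak in enumerate(peaks):
        if i in refs:
            records.append(ShiftRecord(peak=peak, reference_size=refs[i]))
            continue
        ladder = ladders[peak.marker]
        expected = peak.observed_size - float(prior.get(peak.dye, 0.0))
        rung, dist = ladder.nearest(expected)
        if dist > ladder.min_spacing / 2.0:
            records.append(
                ShiftRecord(peak=peak, reference_size=None, flags=("unassigned",))
            )
        else:
            records.append(ShiftRecord(peak=peak, reference_size=float(rung)))
    return records


@dataclass
class CorrectionTable:
    """Mean shift (correction coefficient) per (dye, reference size).

    ``cells`` maps ``(dye, R)`` to ``(mean shift, n observations)``;
    absent keys are missing cells (allele never observed for that dye).
    """

    cells: dict[tuple[Dye, float], tuple[float, int]] = field(default_factory=dict)

    def coefficient(self, dye: Dye, size: float) -> Optional[float]:
        cell = self.cells.get((dye, float(size)))
        return None if cell is None else cell[0]

    def n(self, dye: Dye, size: float) -> int:
        cell = self.cells.get((dye, float(size)))
        return 0 if cell is None else cell[1]

    @property
    def dyes(self) -> tuple[Dye, ...]:
        return tuple(sorted({d for d, _ in self.cells}))

    @property
    def sizes(self) -> tuple[float, ...]:
        return tuple(sorted({r for _, r in self.cells}))

    def points(self, dye: Dye) -> list[tuple[float, float]]:
        """Non-missing ``(R, coefficient)`` pairs for one dye, sorted by R."""
        return sorted(
            (r, mean) for (d, r), (mean, _) in self.cells.items() if d == dye
        )

    @classmethod
    def from_mean_shift_table(
        cls, table: Mapping[Dye, Sequence[tuple[float, float]]]
    ) -> "CorrectionTable":
        cells = {
            (dye, float(r)): (float(c), 1)
            for dye, pairs in table.items()
            for r, c in pairs
        }
        return cls(cells=cells)


def build_correction_table(shifts: Iterable[ShiftRecord]) -> CorrectionTable:
    """Average assigned shifts into per-(dye, R) correction coefficients."""
    acc: dict[tuple[Dye, float], list[float]] = {}
    for rec in shifts:
        if not rec.assigned:
            continue
        acc.setdefault((rec.peak.dye, rec.reference_size), []).append(rec.shift)
    if not acc:
        raise ValueError("no assigned shift records to build a correction table from")
    return CorrectionTable(
        cells={key: (float(np.mean(vals)), len(vals)) for key, vals in acc.items()}
    )


@dataclass(frozen=True)
class CorrectionModel:
    """Per-dye polynomial ``f(x)``: observed size → correction coefficient.

    ``poly`` is a :class:`numpy.polynomial.Polynomial` with its own
    domain mapping (the numerically stable representation used for all
    evaluation).  ``r_squared`` is ``1 − SSE/SST``; ``se`` is the
    residual standard error ``sqrt(SSE/(n − degree − 1))``, ``None`` when
    there are no residual degrees of freedom (exact interpolation).
    Evaluation outside ``x_range`` clamps to the endpoint value.
    """

    dye: Dye
    degree: int
    poly: Polynomial
    r_squared: float
    se: Optional[float]
    n_points: int
    x_range: tuple[float, float]

    @property
    def coefficients_scaled(self) -> tuple[float, ...]:
        """Coefficients on the mapped domain — the evaluable representation."""
        return tuple(float(c) for c in self.poly.coef)

    @property
    def coefficients_raw(self) -> tuple[float, ...]:
        """Power-basis coefficients in bp (ascending degree).

        Display only: a degree-6 power-basis polynomial over hundreds of
        bp cancels catastrophically, so rounding these for storage
        destroys the fit.  Use :meth:`predict` / ``poly`` for computation.
        """
        return tuple(float(c) for c in self.poly.convert().coef)

    def predict(self, x: float) -> tuple[float, bool]:
        """Correction coefficient at observed size *x*, with a clamp flag."""
        lo, hi = self.x_range
        clamped = x < lo or x > hi
        return float(self.poly(min(max(x, lo), hi))), clamped


def fit_correction_model(
    table: CorrectionTable, dye: Dye, degree: int = 6
) -> CorrectionModel:
    """Least-squares polynomial fit of correction coefficient vs observed size.

    The abscissa is the observed allele size implied by each cell,
    ``x = R + coefficient`` — the size a peak of that allele actually
    reports — so the fitted model can be evaluated directly on raw
    observed sizes at correction time.  STR and VNTR cells are pooled
    into one model per dye.
    """
    pts = table.points(dye)
    if len(pts) < degree + 1:
        raise ValueError(
            f"{len(pts)} cells for dye {dye!r} cannot support degree {degree}; "
            f"need >= {degree + 1} (try a lower degree)"
        )
    x = np.array([r + c for r, c in pts], dtype=float)
    y = np.array([c for _, c in pts], dtype=float)
    poly = Polynomial.fit(x, y, degree)
    resid = y - poly(x)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    df = len(pts) - (degree + 1)
    se = float(np.sqrt(sse / df)) if df > 0 else None
    return CorrectionModel(
        dye=dye,
        degree=degree,
        poly=poly,
        r_squared=r2,
        se=se,
        n_points=len(pts),
        x_range=(float(x.min()), float(x.max())),
    )


def fit_all_models(
    table: CorrectionTable, degree: int = 6
) -> dict[Dye, CorrectionModel]:
    return {dye: fit_correction_model(table, dye, degree) for dye in table.dyes}


@dataclass(frozen=True)
class CorrectedPeak:
    """A peak with its dye-shift-corrected size (or a per-peak error)."""

    peak: PeakObservation
    corrected_size: Optional[float]
    flags: tuple[str, ...] = ()
    error: Optional[str] = None


def apply_correction(
    peaks: Iterable[PeakObservation], models: Mapping[Dye, CorrectionModel]
) -> list[CorrectedPeak]:
    """Subtract each peak's predicted correction coefficient from its size.

    A peak whose dye has no model gets a per-peak error record; the rest
    of the batch is still corrected.  Peaks outside a model's fitted
    range are corrected with the range-endpoint coefficient and flagged
    ``extrapolated``.
    """
    out: list[CorrectedPeak] = []
    for peak in peaks:
        model = models.get(peak.dye)
        if model is None:
            out.append(
                CorrectedPeak(
                    peak=peak,
                    corrected_size=None,
                    error=f"no correction model for dye {peak.dye!r}",
                )
            )
            continue
        coef, clamped = model.predict(peak.observed_size)
        out.append(
            CorrectedPeak(
                peak=peak,
                corrected_size=peak.observed_size - coef,
                flags=("extrapolated",) if clamped else (),
            )
        )
    return out


def corrected_residual_records(
    corrected: Iterable[CorrectedPeak], shifts: Iterable[ShiftRecord]
) -> list[ShiftRecord]:
    """Re-express corrected sizes as residual shifts against the reference.

    Pairs each corrected peak with its original reference assignment and
    emits records whose peak carries the *corrected* size, so the same
    variability statistics can be computed before (raw shifts) and after
    (corrected residuals) correction.
    """
    by_peak = {id(rec.peak): rec for rec in shifts}
    out: list[ShiftRecord] = []
    for cp in corrected:
        rec = by_peak.get(id(cp.peak))
        if rec is None or not rec.assigned or cp.corrected_size is None:
            continue
        shadow = PeakObservation(
            family_id=cp.peak.family_id,
            run_id=cp.peak.run_id,
            member=cp.peak.member,
            dye=cp.peak.dye,
            marker=cp.peak.marker,
            observed_size=cp.corrected_size,
            height=cp.peak.height,
            flags=cp.peak.flags + cp.flags,
        )
        out.append(ShiftRecord(peak=shadow, reference_size=rec.reference_size))
    return out
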