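"""Analytical evaluation of dye-shift variability.

Two complementary spreads characterise the trio-multiplex design:

* **intra-dye SD** — for one dye at one reference allele, the sample SD
  of shifts across injections (runs); dominated by run-to-run
  electrophoretic variation plus peak noise.
* **inter-dye SD** — within a single injection, the sample SD of shifts
  across the dyes sharing an allele, averaged over injections; the run
  effect is common to the co-injected dyes and cancels, so after mean
  dye-shift correction this spread reflects only peak-level noise.

The design's headline property is that correction drives the inter-dye
SD well below every intra-dye SD, making within-family cross-member
comparisons (the basis of trio phasing) more precise than any
cross-run comparison.  A Friedman rank test over (run, allele) blocks
assesses whether the dyes differ systematically in |shift|, and Pearson
correlations quantify how the shift depends on fragment size.

Sample SDs use the n−1 denominator throughout.  With only three dyes per
block, sample and population SD differ by a factor of ~1.22, so
comparisons against externally published SD tables are qualitative
unless the same convention is known to apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .correction import ShiftRecord
from .model import Dye

__all__ = [
    "VariabilityReport",
    "CorrelationResult",
    "FriedmanResult",
    "intra_dye_sd",
    "inter_dye_sd",
    "friedman_statistic",
    "friedman_inter_dye",
    "shift_size_correlation",
    "variability_report",
]


def _sample_sd(values: Sequence[float]) -> Optional[float]:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1))


def intra_dye_sd(shifts: Iterable[ShiftRecord]) -> dict[tuple[Dye, float], tuple[Optional[float], int]]:
    """Sample SD of shifts per (dye, reference size), pooled across runs.

    Returns ``{(dye, R): (sd, n)}``; cells with fewer than two
    observations report ``sd = None`` (undetermined).
    """
    acc: dict[tuple[Dye, float], list[float]] = {}
    for rec in shifts:
        if rec.assigned:
            acc.setdefault((rec.peak.dye, rec.reference_size), []).append(rec.shift)
    return {key: (_sample_sd(vals), len(vals)) for key, vals in acc.items()}


def inter_dye_sd(shifts: Iterable[ShiftRecord]) -> dict[float, tuple[Optional[float], int]]:
    """Mean over runs of the cross-dye sample SD of shifts, per reference size.

    Only runs in which at least two dyes report the same reference allele
    contribute (one value per dye per run; duplicate peaks of one dye at
    one allele are averaged first).  Returns ``{R: (mean SD, n runs)}``;
    an allele with no qualifying run is undetermined (``None``).
    """
    # (run, R) -> dye -> shifts
    blocks: dict[tuple[str, float], dict[Dye, list[float]]] = {}
    for rec in shifts:
        if not rec.assigned:
            continue
        blk = blocks.setdefault((rec.peak.run_id, rec.reference_size), {})
        blk.setdefault(rec.peak.dye, []).append(rec.shift)
    per_size: dict[float, list[float]] = {}
    for (_, size), by_dye in blocks.items():
        if len(by_dye) < 2:
            continue
        vals = [float(np.mean(v)) for v in by_dye.values()]
        per_size.setdefault(size, []).append(float(np.std(vals, ddof=1)))
    return {
        size: (float(np.mean(sds)), len(sds)) for size, sds in per_size.items()
    }


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    n_blocks: int
    n_treatments: int


def friedman_statistic(matrix: np.ndarray) -> FriedmanResult:
    """Friedman rank test on a blocks × treatments matrix.

    Within each block the treatments are ranked (average ranks on ties)
    and the statistic is the closed form
    ``chi2 = 12/(b k (k+1)) * sum_j Rj^2 − 3 b (k+1)``
    with ``b`` blocks, ``k`` treatments and ``Rj`` the rank sums; the
    p-value comes from the chi-square distribution with ``k−1`` df.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("need a 2-D blocks x treatments matrix")
    b, k = matrix.shape
    if b < 2 or k < 2:
        raise ValueError(f"need >=2 blocks and >=2 treatments, got {b}x{k}")
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (b * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * b * (k + 1)
    chi2 = max(chi2, 0.0)  # guard tiny negative from float error on tied data
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return FriedmanResult(statistic=chi2, p_value=p, n_blocks=b, n_treatments=k)


def friedman_inter_dye(
    shifts: Iterable[ShiftRecord], dyes: Sequence[Dye]
) -> FriedmanResult:
    """Friedman test of |shift| across dyes, blocked by (run, reference size).

    Each complete block is one (run, R) pair at which every listed dye
    reports a shift (averaged if duplicated); incomplete blocks are
    dropped.  A significant statistic means the dyes differ systematically
    in shift magnitude within injections.
    """
    blocks: dict[tuple[str, float], dict[Dye, list[float]]] = {}
    for rec in shifts:
        if not rec.assigned:
            continue
        blk = blocks.setdefault((rec.peak.run_id, rec.reference_size), {})
        blk.setdefault(rec.peak.dye, []).append(abs(rec.shift))
    rows = [
        [float(np.mean(by_dye[d])) for d in dyes]
        for by_dye in blocks.values()
        if all(d in by_dye for d in dyes)
    ]
    if len(rows) < 2:
        raise ValueError(
            f"Friedman test needs >=2 complete blocks, found {len(rows)}"
        )
    return friedman_statistic(np.array(rows))


@dataclass(frozen=True)
class CorrelationResult:
    dye: Dye
    size_range: tuple[float, float]
    r: float
    p_value: float
    n: int


def shift_size_correlation(
    shifts: Iterable[ShiftRecord], dye: Dye, size_range: tuple[float, float]
) -> CorrelationResult:
    """Pearson correlation of (reference size, shift) for one dye in a range.

    Two-sided p-value from the t transform.  Degenerate inputs (fewer
    than three points, or zero variance on either axis) raise.
    """
    lo, hi = size_range
    pts = [
        (rec.reference_size, rec.shift)
        for rec in shifts
        if rec.assigned and rec.peak.dye == dye and lo <= rec.reference_size <= hi
    ]
    if len(pts) < 3:
        raise ValueError(f"need >=3 points for a correlation, found {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: correlation undetermined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        dye=dye,
        size_range=(float(lo), float(hi)),
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(pts),
    )


@dataclass
class VariabilityReport:
    """Per-allele variability summary in the calibration-table layout.

    ``rows`` maps each reference size to a dict with per-dye intra-dye
    SDs, the inter-dye SD before and after correction, and observation
    counts; ``None`` marks undetermined cells (n < 2).
    """

    dyes: tuple[Dye, ...]
    rows: dict[float, dict] = field(default_factory=dict)


def variability_report(
    raw_shifts: Sequence[ShiftRecord],
    corrected_shifts: Sequence[ShiftRecord],
    dyes: Sequence[Dye],
) -> VariabilityReport:
    """Assemble intra-dye and before/after inter-dye SDs per reference size."""
    intra = intra_dye_sd(raw_shifts)
    inter_before = inter_dye_sd(raw_shifts)
    inter_after = inter_dye_sd(corrected_shifts)
    sizes = sorted(
        {r for _, r in intra} | set(inter_before) | set(inter_after)
    )
    report = VariabilityReport(dyes=tuple(dyes))
    for size in sizes:
        row = {
            "intra": {d: intra.get((d, size), (None, 0))[0] for d in dyes},
            "n_intra": {d: intra.get((d, size), (None, 0))[1] for d in dyes},
            "inter_before": inter_before.get(size, (None, 0))[0],
            "inter_after": inter_after.get(size, (None, 0))[0],
            "n_runs": inter_before.get(size, (None, 0))[1],
        }
        report.rows[size] = row
    return report
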