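"""Synthetic trio genotypes and sized-peak tables.

No public capillary-electrophoresis dataset exists for this panel, so the
generator provides ground-truthed inputs for every downstream stage.  Two
layers are simulated:

* **Genetics** — founder haplotypes drawn i.i.d. from per-marker allele
  frequency vectors, children receiving one uniformly chosen haplotype
  from each parent (Mendelian transmission by construction), and a
  pathogenic-risk flag carried on founder haplotypes.
* **Measurement** — observed peak size = reference size + dye-specific
  mean mobility shift ``mu_dye(R)`` + a run effect shared by all dyes in
  one injection + dye-specific noise:

  ``observed = R + mu_dye(R) + runEffect(run) + eps(dye, peak)``

  with ``runEffect ~ N(0, sigma_run^2)`` drawn once per injection and
  ``eps ~ N(0, sigma_eps_dye^2)`` per peak.

The shared-run-effect / dye-noise decomposition is a modeling assumption:
it is the minimal structure under which the cross-dye spread inside one
injection (inter-dye SD) can sit below the per-dye spread across
injections (intra-dye SD), which is the signature of co-electrophoresed
trio data.  :func:`calibrate_noise` inverts that decomposition from
published variability numbers via the c4 small-sample SD bias factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import (
    DEFAULT_DYES,
    MEMBERS,
    Dye,
    Genotype,
    PeakObservation,
    TrioGenotypes,
    calibration_mean_shift_table,
    load_shift_calibration,
)

__all__ = [
    "ShiftModelParams",
    "PopulationModel",
    "Family",
    "FounderHaplotype",
    "NoiseCalibration",
    "c4_constant",
    "calibrate_noise",
    "default_shift_params",
    "simulate_families",
    "simulate_trios",
    "simulate_peak_table",
]


def c4_constant(n: int) -> float:
    """Expectation of the sample SD of ``n`` standard-normal draws.

    ``c4(n) = sqrt(2/(n-1)) * Gamma(n/2) / Gamma((n-1)/2)``.  Used to
    convert between an observed mean sample SD and the generative sigma:
    for three dyes, ``c4(3) = sqrt(pi)/2 ~ 0.8862``.
    """
    if n < 2:
        raise ValueError(f"c4 requires n >= 2, got {n}")
    return math.sqrt(2.0 / (n - 1)) * math.exp(
        math.lgamma(n / 2.0) - math.lgamma((n - 1) / 2.0)
    )


@dataclass(frozen=True)
class ShiftModelParams:
    """Measurement-model parameters for the peak simulator.

    Parameters
    ----------
    mean_shift
        Per-dye table of ``(reference size, mean shift)`` pairs in bp.
        Between tabulated sizes the shift is piecewise-linearly
        interpolated; beyond the table it is held at the nearest endpoint
        and the emitted peak is flagged ``mu_extrapolated`` (polynomial
        extrapolation outside the calibrated range is deliberately
        avoided).
    sigma_run
        SD (bp) of the run effect shared by all dyes in one injection.
    sigma_eps
        Per-dye SD (bp) of peak-level noise.
    seed
        Root RNG seed; per-family substreams are derived from
        ``(seed, family index)`` so output is independent of generation
        order.
    """

    mean_shift: Mapping[Dye, Sequence[tuple[float, float]]]
    sigma_run: float = 0.0
    sigma_eps: Mapping[Dye, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_run < 0:
            raise ValueError("sigma_run must be >= 0")
        for dye, s in self.sigma_eps.items():
            if s < 0:
                raise ValueError(f"sigma_eps[{dye!r}] must be >= 0")

    def mu(self, dye: Dye, size: float) -> tuple[float, bool]:
        """Mean shift for *dye* at reference size, with extrapolation flag."""
        table = self.mean_shift[dye]
        xs = np.array([x for x, _ in table], dtype=float)
        ys = np.array([y for _, y in table], dtype=float)
        extrapolated = bool(size < xs[0] or size > xs[-1])
        # np.interp already clamps to the endpoint values outside the domain
        return float(np.interp(size, xs, ys)), extrapolated

    def eps_sd(self, dye: Dye) -> float:
        return float(self.sigma_eps.get(dye, 0.0))


@dataclass(frozen=True)
class NoiseCalibration:
    """Result of inverting published variability numbers into model sigmas."""

    sigma_eps: float
    sigma_run_per_dye: dict[Dye, float]
    warnings: tuple[str, ...] = ()

    @property
    def sigma_run(self) -> float:
        """Single panel run-effect SD: mean of the per-dye values."""
        return float(np.mean(list(self.sigma_run_per_dye.values())))


def calibrate_noise(
    intra_sd: Mapping[Dye, float], inter_sd_after: float
) -> NoiseCalibration:
    """Invert intra-/inter-dye shift SDs into generator noise components.

    After mean-shift correction, the spread across the three dyes inside
    one injection reflects only peak-level noise (the shared run effect
    cancels), so its expected sample SD is ``sigma_eps * c4(3)``; hence
    ``sigma_eps = inter_sd_after / c4(3)``.  The per-dye spread across
    injections is ``sqrt(sigma_run^2 + sigma_eps^2)``, giving
    ``sigma_run_dye = sqrt(max(0, intra_sd_dye^2 - sigma_eps^2))``.
    A dye whose intra SD falls below ``sigma_eps`` gets its run component
    clamped to zero with a warning record.
    """
    if inter_sd_after < 0 or any(s < 0 for s in intra_sd.values()):
        raise ValueError("variability SDs must be >= 0")
    sigma_eps = inter_sd_after / c4_constant(3)
    per_dye: dict[Dye, float] = {}
    warns: list[str] = []
    for dye, s in intra_sd.items():
        if s < sigma_eps:
            per_dye[dye] = 0.0
            msg = (
                f"intra-dye SD {s} for {dye} is below the dye-noise floor "
                f"{sigma_eps:.4f}; run-effect component clamped to 0"
            )
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
        else:
            per_dye[dye] = math.sqrt(s * s - sigma_eps * sigma_eps)
    return NoiseCalibration(
        sigma_eps=sigma_eps, sigma_run_per_dye=per_dye, warnings=tuple(warns)
    )


def default_shift_params(seed: int = 0) -> ShiftModelParams:
    """Parameters calibrated from the bundled PAH-panel measurements.

    The mean-shift table is the bundled per-dye coefficient table; the
    noise components are inverted from the variability row at the 226-bp
    STR allele via :func:`calibrate_noise`.
    """
    cal = load_shift_calibration()
    i226 = cal["reference_sizes"].index(226)
    intra = {dye: cal["intra_dye_sd"][dye][i226] for dye in cal["intra_dye_sd"]}
    nc = calibrate_noise(intra, cal["inter_dye_sd_after"][i226])
    return ShiftModelParams(
        mean_shift=calibration_mean_shift_table(),
        sigma_run=nc.sigma_run,
        sigma_eps={dye: nc.sigma_eps for dye in intra},
        seed=seed,
    )


@dataclass(frozen=True)
class FounderHaplotype:
    """One founder haplotype: an allele per marker plus a risk flag."""

    alleles: tuple[tuple[str, float], ...]  # ((marker, allele), ...) sorted by marker
    risk: bool = False

    def allele(self, marker: str) -> float:
        for m, a in self.alleles:
            if m == marker:
                return a
        raise KeyError(marker)


@dataclass
class Family:
    """Ground truth for one simulated nuclear family.

    ``children`` holds, per child, the index (0 or 1) of the transmitted
    haplotype in each parent's pair — the phase information downstream
    phasing is tested against.
    """

    family_id: str
    father_haps: tuple[FounderHaplotype, FounderHaplotype]
    mother_haps: tuple[FounderHaplotype, FounderHaplotype]
    children: list[tuple[int, int]]  # (father hap index, mother hap index)

    def child_haps(self, i: int) -> tuple[FounderHaplotype, FounderHaplotype]:
        fi, mi = self.children[i]
        return self.father_haps[fi], self.mother_haps[mi]

    def markers(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.father_haps[0].alleles)


@dataclass(frozen=True)
class PopulationModel:
    """Allele frequencies and sampling sizes for the genetics layer.

    ``allele_freqs`` maps each marker to a ``{ladder allele: frequency}``
    mapping (frequencies sum to 1); ``risk_freq`` is the probability that
    a founder haplotype carries the pathogenic flag.
    """

    allele_freqs: Mapping[str, Mapping[float, float]]
    risk_freq: float = 0.0
    n_families: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for marker, freqs in self.allele_freqs.items():
            vals = np.array(list(freqs.values()), dtype=float)
            if (vals < 0).any():
                raise ValueError(f"negative allele frequency for marker {marker!r}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"allele frequencies for {marker!r} sum to {vals.sum()}, not 1"
                )
        if not 0.0 <= self.risk_freq <= 1.0:
            raise ValueError("risk_freq must be in [0, 1]")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")


def _draw_haplotype(pop: PopulationModel, rng: np.random.Generator) -> FounderHaplotype:
    alleles = []
    for marker in sorted(pop.allele_freqs):
        freqs = pop.allele_freqs[marker]
        keys = sorted(freqs)
        probs = np.array([freqs[k] for k in keys], dtype=float)
        alleles.append((marker, float(keys[rng.choice(len(keys), p=probs)])))
    risk = bool(rng.random() < pop.risk_freq)
    return FounderHaplotype(alleles=tuple(alleles), risk=risk)


def _status(h1: FounderHaplotype, h2: FounderHaplotype) -> str:
    n = int(h1.risk) + int(h2.risk)
    return ("unaffected", "carrier", "affected")[n]


def simulate_families(pop: PopulationModel, n_children: int = 1) -> list[Family]:
    """Draw founder haplotypes and transmit them to ``n_children`` per family.

    Each family uses an RNG substream keyed by ``(seed, family index)``,
    so the output for family *i* does not depend on how many families are
    generated or in what order.
    """
    families = []
    for i in range(pop.n_families):
        rng = np.random.default_rng([pop.seed, i])
        father = (_draw_haplotype(pop, rng), _draw_haplotype(pop, rng))
        mother = (_draw_haplotype(pop, rng), _draw_haplotype(pop, rng))
        children = [
            (int(rng.integers(2)), int(rng.integers(2))) for _ in range(n_children)
        ]
        families.append(
            Family(
                family_id=f"F{i + 1:04d}",
                father_haps=father,
                mother_haps=mother,
                children=children,
            )
        )
    return families


def family_to_trio(family: Family, child_index: int = 0) -> TrioGenotypes:
    """Project one child of a :class:`Family` onto trio genotypes."""
    fh, mh = family.child_haps(child_index)
    trio = TrioGenotypes(family_id=family.family_id)
    for marker in family.markers():
        pairs = {
            "child": (fh.allele(marker), mh.allele(marker)),
            "father": tuple(h.allele(marker) for h in family.father_haps),
            "mother": tuple(h.allele(marker) for h in family.mother_haps),
        }
        for member, pair in pairs.items():
            trio.genotypes[(member, marker)] = Genotype(alleles=pair)
    trio.affected_status = {
        "child": _status(fh, mh),
        "father": _status(*family.father_haps),
        "mother": _status(*family.mother_haps),
    }
    return trio


def simulate_trios(pop: PopulationModel) -> list[TrioGenotypes]:
    """Simulate ``pop.n_families`` trios under Mendelian transmission."""
    return [family_to_trio(f) for f in simulate_families(pop, n_children=1)]


def simulate_peak_table(
    trios: Iterable[TrioGenotypes],
    params: ShiftModelParams,
    assignment: Optional[Mapping[str, Dye]] = None,
) -> list[PeakObservation]:
    """Emit sized peaks for each trio under the measurement model.

    One injection (run) per family; homozygous genotypes emit a single
    peak per marker per member.  Deterministic given ``params.seed``: the
    run effect and peak noises for family *i* come from an RNG substream
    keyed by ``(seed, injection counter, i)``.
    """
    if assignment is None:
        assignment = dict(zip(MEMBERS, DEFAULT_DYES))
    if sorted(assignment) != sorted(MEMBERS):
        raise ValueError(f"assignment must cover exactly {MEMBERS}, got {sorted(assignment)}")
    if len(set(assignment.values())) != len(MEMBERS):
        raise ValueError("trio members must carry distinct dyes")

    peaks: list[PeakObservation] = []
    for i, trio in enumerate(trios):
        rng = np.random.default_rng([params.seed, 1, i])
        run_effect = rng.normal(0.0, params.sigma_run) if params.sigma_run > 0 else 0.0
        run_id = f"{trio.family_id}_r1"
        for member in MEMBERS:
            dye = assignment[member]
            for (mem, marker), genotype in sorted(trio.genotypes.items()):
                if mem != member:
                    continue
                for allele in sorted(set(genotype.alleles)):
                    mu, extrapolated = params.mu(dye, allele)
                    sd = params.eps_sd(dye)
                    eps = rng.normal(0.0, sd) if sd > 0 else 0.0
                    peaks.append(
                        PeakObservation(
                            family_id=trio.family_id,
                            run_id=run_id,
                            member=member,
                            dye=dye,
                            marker=marker,
                            observed_size=allele + mu + run_effect + eps,
                            flags=("mu_extrapolated",) if extrapolated else (),
                        )
                    )
    return peaks
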