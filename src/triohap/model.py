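"""Core domain types for trio-based STR/VNTR mini-haplotyping.

The panel under study multiplexes two repeat-length markers at the PAH
locus — a tetranucleotide STR and a 30-bp VNTR — in a single capillary
injection per family trio, with each trio member amplified under its own
fluorophore (child FAM, father HEX, mother TAMRA by default).  Because the
two markers occupy non-overlapping size ranges they can share a dye, and
because the three members share one injection, dye-specific mobility
shifts can be measured and corrected within each family.

Allele identity throughout the package is the *reference allele size* in
bp (the fragment length expected from the reference genome assembly), not
the repeat count; repeat count is derivable from the ladder spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

MEMBERS = ("child", "father", "mother")
DEFAULT_DYES = ("FAM", "HEX", "TAMRA")

#: Dye names are plain strings; the canonical trio set is FAM/HEX/TAMRA but
#: any panel may declare its own labels, provided each member maps to a
#: distinct dye.
Dye = str

AFFECTED_STATUSES = ("affected", "carrier", "unaffected", "unknown")


@dataclass(frozen=True)
class Marker:
    """A repeat-length polymorphic marker typed by fragment size.

    Parameters
    ----------
    name
        Marker label, e.g. ``"STR"`` or ``"VNTR"``.
    repeat_unit_bp
        Repeat unit length in bp (4 for the tetranucleotide STR, 30 for
        the VNTR).
    size_range
        ``(min, max)`` expected fragment size range in bp.  Ranges of
        markers co-loaded under one dye must not overlap.
    tolerance_bp
        Default allele-binning tolerance: a corrected size farther than
        this from every ladder rung is a no-call.
    """

    name: str
    repeat_unit_bp: int
    size_range: tuple[float, float]
    tolerance_bp: float = 1.5

    def __post_init__(self) -> None:
        if self.repeat_unit_bp <= 0:
            raise ValueError(f"repeat_unit_bp must be positive, got {self.repeat_unit_bp}")
        lo, hi = self.size_range
        if not lo < hi:
            raise ValueError(f"size_range must satisfy min < max, got {self.size_range}")
        if self.tolerance_bp <= 0:
            raise ValueError("tolerance_bp must be positive")


@dataclass(frozen=True)
class ReferenceLadder:
    """Ordered reference allele sizes (ladder rungs) for one marker.

    Rungs are strictly increasing and consecutive spacings are positive
    multiples of the marker's repeat unit.  The ladder need not be
    uniformly spaced (the VNTR ladder 334/454/484/514 has spacings of
    120, 30 and 30 bp).
    """

    marker: Marker
    rungs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.rungs) == 0:
            raise ValueError("ladder needs at least one rung")
        unit = self.marker.repeat_unit_bp
        for a, b in zip(self.rungs, self.rungs[1:]):
            gap = b - a
            if gap <= 0:
                raise ValueError(f"ladder rungs must be strictly increasing ({a} -> {b})")
            k = gap / unit
            if abs(k - round(k)) > 1e-9 or round(k) < 1:
                raise ValueError(
                    f"rung spacing {gap} bp is not a positive multiple of the "
                    f"{unit}-bp repeat unit"
                )

    @property
    def min_spacing(self) -> float:
        if len(self.rungs) == 1:
            return float("inf")
        return min(b - a for a, b in zip(self.rungs, self.rungs[1:]))

    def nearest(self, size: float) -> tuple[float, float]:
        """Return ``(rung, distance)`` for the rung closest to *size*.

        On an exact tie the lower rung is returned; callers that must
        treat ties specially should compare distances themselves.
        """
        best = min(self.rungs, key=lambda r: (abs(size - r), r))
        return best, abs(size - best)

    def __contains__(self, allele: float) -> bool:
        return any(abs(allele - r) < 1e-9 for r in self.rungs)


@dataclass(frozen=True)
class PeakObservation:
    """One sized fluorescent peak from a fragment-analysis run.

    ``(family_id, run_id)`` groups peaks that were co-electrophoresed in
    the same capillary injection; the shared injection is what makes
    inter-dye comparisons within a trio meaningful.
    """

    family_id: str
    run_id: str
    member: str
    dye: Dye
    marker: str
    observed_size: float
    height: Optional[float] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.observed_size <= 0:
            raise ValueError(f"observed_size must be positive, got {self.observed_size}")
        if self.member not in MEMBERS:
            raise ValueError(f"unknown member {self.member!r}; expected one of {MEMBERS}")


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of ladder alleles; homozygotes repeat the allele.

    The pair is stored sorted ascending so equality testing is canonical.
    """

    alleles: tuple[float, float]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    def __contains__(self, allele: float) -> bool:
        return allele in self.alleles


@dataclass
class TrioGenotypes:
    """Called two-allele genotypes per member and marker for one family.

    ``genotypes`` maps ``(member, marker_name)`` to a :class:`Genotype`;
    a marker that failed calling for a member is simply absent.  Statuses
    default to ``"unknown"`` and are filled in by the simulator (ground
    truth) or by the user (clinical ascertainment).
    """

    family_id: str
    genotypes: dict[tuple[str, str], Genotype] = field(default_factory=dict)
    affected_status: dict[str, str] = field(
        default_factory=lambda: {m: "unknown" for m in MEMBERS}
    )

    def genotype(self, member: str, marker: str) -> Optional[Genotype]:
        return self.genotypes.get((member, marker))

    def markers(self) -> list[str]:
        seen: list[str] = []
        for _, marker in self.genotypes:
            if marker not in seen:
                seen.append(marker)
        return seen


@dataclass(frozen=True)
class MiniHaplotype:
    """A phased (STR, optional RFLP, VNTR) allele combination.

    The RFLP slot preserves the three-marker mini-haplotype shape used for
    indirect PAH diagnosis but is never populated by this tool; it is
    carried through only when supplied externally.
    """

    str_allele: float
    vntr_allele: float
    rflp_allele: Optional[str] = None
    origin: str = "ambiguous"  # paternal | maternal | ambiguous
    risk: bool = False

    def __post_init__(self) -> None:
        if self.origin not in ("paternal", "maternal", "ambiguous"):
            raise ValueError(f"invalid origin {self.origin!r}")


@dataclass
class Panel:
    """A multiplex panel: markers with ladders, dye assignment, thresholds."""

    ladders: dict[str, ReferenceLadder]
    dye_assignment: dict[str, Dye]
    correction_degree: int = 6
    alpha: float = 0.01

    def __post_init__(self) -> None:
        ranges = sorted(
            (lad.marker.size_range, name) for name, lad in self.ladders.items()
        )
        for (r1, n1), (r2, n2) in zip(ranges, ranges[1:]):
            if r2[0] < r1[1]:
                raise ValueError(
                    f"size ranges of markers {n1!r} and {n2!r} overlap "
                    f"({r1} vs {r2}); same-dye co-loading requires disjoint ranges"
                )
        missing = [m for m in MEMBERS if m not in self.dye_assignment]
        if missing:
            raise ValueError(f"dye assignment missing members: {missing}")
        dyes = list(self.dye_assignment.values())
        if len(set(dyes)) != len(dyes):
            raise ValueError(f"each trio member needs a distinct dye, got {dyes}")
        for name, lad in self.ladders.items():
            lo, hi = lad.marker.size_range
            if not all(lo <= r <= hi for r in lad.rungs):
                raise ValueError(f"ladder rungs of {name!r} fall outside its size range")

    @property
    def dyes(self) -> tuple[Dye, ...]:
        return tuple(self.dye_assignment[m] for m in MEMBERS)

    def ladder(self, marker: str) -> ReferenceLadder:
        try:
            return self.ladders[marker]
        except KeyError:
            raise KeyError(f"marker {marker!r} not in panel {sorted(self.ladders)}") from None

    def member_for_dye(self, dye: Dye) -> str:
        for member, d in self.dye_assignment.items():
            if d == dye:
                return member
        raise KeyError(f"dye {dye!r} not assigned to any member")


_PANEL_KEYS = {"markers", "dye_assignment", "correction_degree", "alpha"}
_MARKER_KEYS = {"name", "repeat_unit_bp", "size_range", "ladder", "tolerance_bp"}


def panel_from_dict(cfg: Mapping) -> Panel:
    """Build a validated :class:`Panel` from a JSON-style mapping.

    Unknown keys are rejected so that typos in a panel file fail loudly
    instead of silently falling back to defaults.
    """
    unknown = set(cfg) - _PANEL_KEYS
    if unknown:
        raise ValueError(f"unknown panel config keys: {sorted(unknown)}")
    ladders: dict[str, ReferenceLadder] = {}
    for mcfg in cfg["markers"]:
        bad = set(mcfg) - _MARKER_KEYS
        if bad:
            raise ValueError(f"unknown marker config keys: {sorted(bad)}")
        marker = Marker(
            name=mcfg["name"],
            repeat_unit_bp=int(mcfg["repeat_unit_bp"]),
            size_range=tuple(float(v) for v in mcfg["size_range"]),
            tolerance_bp=float(mcfg.get("tolerance_bp", 1.5)),
        )
        ladders[marker.name] = ReferenceLadder(
            marker=marker, rungs=tuple(float(r) for r in mcfg["ladder"])
        )
    return Panel(
        ladders=ladders,
        dye_assignment=dict(cfg["dye_assignment"]),
        correction_degree=int(cfg.get("correction_degree", 6)),
        alpha=float(cfg.get("alpha", 0.01)),
    )


def load_panel(path: Optional[str] = None) -> Panel:
    """Load a panel JSON file, or the bundled default PAH STR/VNTR panel."""
    if path is None:
        text = resources.files("triohap.data").joinpath("panel.json").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return panel_from_dict(json.loads(text))


def load_shift_calibration() -> dict:
    """Return the bundled dye-shift calibration for the PAH panel.

    Keys: ``reference_sizes`` (12 ladder alleles), ``mean_shift`` (per-dye
    mean observed-minus-reference shift at each allele, bp),
    ``intra_dye_sd`` / ``inter_dye_sd_before`` / ``inter_dye_sd_after``
    (shift variability, bp; ``None`` marks a cell with no data).
    """
    text = resources.files("triohap.data").joinpath("shift_calibration.json").read_text()
    return json.loads(text)


def calibration_mean_shift_table() -> dict[Dye, list[tuple[float, float]]]:
    """Per-dye ``(reference size, mean shift)`` pairs from the bundled calibration."""
    cal = load_shift_calibration()
    sizes = cal["reference_sizes"]
    return {
        dye: [(float(r), float(c)) for r, c in zip(sizes, coefs)]
        for dye, coefs in cal["mean_shift"].items()
    }
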