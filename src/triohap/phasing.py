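"""Mendelian checking, trio phasing and indirect risk inference.

The PAH locus spans ~100 kb with high linkage disequilibrium, so the
STR and VNTR alleles transmitted together by a parent are treated as one
non-recombining mini-haplotype within a family.  Phasing a trio
therefore reduces to, per marker, partitioning the child's two alleles
into a paternal and a maternal one consistent with the parents'
genotypes; the per-marker origins are then assembled into two child
mini-haplotypes.  Indirect diagnosis tracks which parental haplotypes a
second child (sibling, fetus or embryo) inherited relative to an
affected proband: the two haplotypes transmitted to an affected child
are by definition the at-risk ones, so the relative's count of at-risk
haplotypes (0/1/2) predicts unaffected/carrier/affected without
observing the causal variant.

Ambiguity is never resolved by guessing: an uninformative marker leaves
the haplotype flagged, and a relative whose inheritance cannot be traced
(or shows a recombination-like inconsistency) is called indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import Genotype, MiniHaplotype, TrioGenotypes

__all__ = [
    "PhasedTrio",
    "RiskCall",
    "mendel_check",
    "phase_trio",
    "infer_risk",
]


@dataclass
class PhasedTrio:
    """Result of phasing one trio.

    ``origin_map`` gives, per marker, the resolved ``(paternal allele,
    maternal allele)`` pair, or ``None`` where multiple partitions are
    consistent (marker ambiguous).  ``child_haplotypes`` is the pair of
    assembled mini-haplotypes when both panel markers resolved, else
    ``None`` with ``ambiguous`` set.
    """

    family_id: str
    trio: TrioGenotypes
    origin_map: dict[str, Optional[tuple[float, float]]] = field(default_factory=dict)
    ambiguous_markers: tuple[str, ...] = ()
    #: markers skipped because a member had no called genotype
    skipped_markers: tuple[str, ...] = ()
    mendel_violations: tuple[tuple[str, str], ...] = ()  # (marker, detail)
    child_haplotypes: Optional[tuple[MiniHaplotype, MiniHaplotype]] = None

    @property
    def ambiguous(self) -> bool:
        return len(self.ambiguous_markers) > 0

    @property
    def fully_phased(self) -> bool:
        return (
            bool(self.origin_map)
            and not self.ambiguous
            and not self.skipped_markers
            and not self.mendel_violations
        )


def _partitions(child: Genotype, father: Genotype, mother: Genotype) -> list[tuple[float, float]]:
    """All (paternal, maternal) orderings of the child alleles consistent
    with the parental genotypes; duplicates collapsed for homozygotes."""
    a, b = child.alleles
    candidates = {(a, b), (b, a)}
    return sorted(p for p in candidates if p[0] in father and p[1] in mother)


def mendel_check(trio: TrioGenotypes, marker: str) -> Optional[str]:
    """Return ``None`` if the trio is Mendelian-consistent at *marker*,
    else a human-readable violation detail.

    Consistency means the child's two alleles admit a partition with one
    allele present in the father's genotype and the other in the
    mother's.  A member with no called genotype raises ``KeyError`` —
    the check is skipped, not silently passed.
    """
    genos = {}
    for member in ("child", "father", "mother"):
        g = trio.genotype(member, marker)
        if g is None:
            raise KeyError(
                f"family {trio.family_id}: no called genotype for {member} at {marker}"
            )
        genos[member] = g
    if _partitions(genos["child"], genos["father"], genos["mother"]):
        return None
    c, f, m = genos["child"], genos["father"], genos["mother"]
    for allele in set(c.alleles):
        if allele not in f and allele not in m:
            return (
                f"child allele {allele:g} at {marker} present in neither parent "
                f"(father {f.alleles}, mother {m.alleles})"
            )
    return (
        f"child genotype {c.alleles} at {marker} cannot be partitioned between "
        f"father {f.alleles} and mother {m.alleles}"
    )


def phase_trio(trio: TrioGenotypes, markers: Optional[list[str]] = None) -> PhasedTrio:
    """Phase a trio into parental-origin mini-haplotypes.

    Per marker, every partition of the child genotype into (paternal,
    maternal) consistent with the parents is enumerated: a unique
    partition resolves the marker; multiple partitions leave it
    ambiguous.  Any Mendelian violation refuses phasing for the family
    (violations are reported, no origins are assigned).
    """
    candidates = markers if markers is not None else trio.markers()
    markers = []
    skipped = []
    violations = []
    for marker in candidates:
        if any(trio.genotype(m, marker) is None for m in ("child", "father", "mother")):
            skipped.append(marker)  # uncalled genotype: check skipped, not passed
            continue
        markers.append(marker)
        detail = mendel_check(trio, marker)
        if detail is not None:
            violations.append((marker, detail))
    if violations:
        return PhasedTrio(
            family_id=trio.family_id,
            trio=trio,
            skipped_markers=tuple(skipped),
            mendel_violations=tuple(violations),
        )

    origin_map: dict[str, Optional[tuple[float, float]]] = {}
    ambiguous = []
    for marker in markers:
        parts = _partitions(
            trio.genotype("child", marker),
            trio.genotype("father", marker),
            trio.genotype("mother", marker),
        )
        if len(parts) == 1:
            origin_map[marker] = parts[0]
        else:
            origin_map[marker] = None
            ambiguous.append(marker)

    haplotypes = None
    if "STR" in origin_map and "VNTR" in origin_map and not ambiguous:
        pat = MiniHaplotype(
            str_allele=origin_map["STR"][0],
            vntr_allele=origin_map["VNTR"][0],
            origin="paternal",
        )
        mat = MiniHaplotype(
            str_allele=origin_map["STR"][1],
            vntr_allele=origin_map["VNTR"][1],
            origin="maternal",
        )
        haplotypes = (pat, mat)
    return PhasedTrio(
        family_id=trio.family_id,
        trio=trio,
        origin_map=origin_map,
        ambiguous_markers=tuple(ambiguous),
        skipped_markers=tuple(skipped),
        child_haplotypes=haplotypes,
    )


@dataclass(frozen=True)
class RiskCall:
    """Predicted status of a relative from haplotype tracing.

    ``predicted_status`` is ``affected``/``carrier``/``unaffected`` when
    both parental transmissions could be traced, else ``indeterminate``.
    ``confidence`` is ``full`` when every marker was informative for both
    parents, ``partial`` when the call rests on a subset of markers.
    """

    predicted_status: str
    confidence: str
    n_risk_haplotypes: Optional[int] = None
    warnings: tuple[str, ...] = ()


def _trace_parent(
    transmitted: dict[str, float],
    parent_genotypes: dict[str, Genotype],
    relative_origin: dict[str, Optional[tuple[float, float]]],
    side: int,
) -> tuple[Optional[bool], bool, list[str]]:
    """Decide whether the relative inherited the proband-transmitted
    (at-risk) haplotype from one parent.

    Returns ``(got_risk | None, partial, warnings)``.  For each marker
    where the relative's origin is resolved and the parent is
    heterozygous with the transmitted allele distinguishable from the
    untransmitted one, the relative's allele votes risk or safe; the
    votes must agree, otherwise a recombination-like signal makes the
    trace indeterminate.
    """
    votes: list[bool] = []
    warnings: list[str] = []
    informative = 0
    usable = 0
    for marker, trans_allele in transmitted.items():
        origins = relative_origin.get(marker)
        if origins is None:
            continue
        usable += 1
        geno = parent_genotypes[marker]
        other = [a for a in geno.alleles if a != trans_allele]
        if not other or other[0] == trans_allele or geno.is_homozygous:
            continue  # parent uninformative at this marker
        informative += 1
        votes.append(origins[side] == trans_allele)
    if not votes:
        return None, True, ["no informative marker for this parent"]
    if len(set(votes)) > 1:
        warnings.append(
            "inconsistent marker origins (recombination-like signal); trace refused"
        )
        return None, True, warnings
    partial = informative < len(transmitted)
    return votes[0], partial, warnings


def infer_risk(proband: PhasedTrio, relative: TrioGenotypes) -> RiskCall:
    """Predict a relative's status by tracing at-risk parental haplotypes.

    Preconditions: the proband's trio has ``affected`` child status and is
    fully phased; *relative* shares the proband's parents (same parental
    genotypes).  Both haplotypes transmitted to the affected proband are
    designated at-risk; each parent's untransmitted haplotype is not.
    The relative is phased against the same parents and each parental
    transmission is traced; 2/1/0 inherited at-risk haplotypes predict
    affected/carrier/unaffected.  Any untraceable transmission yields
    ``indeterminate`` — a wrong definitive call is never risked.
    """
    if proband.trio.affected_status.get("child") != "affected":
        raise ValueError("indirect inference requires an affected, phased proband")
    if not proband.fully_phased:
        raise ValueError(
            f"proband family {proband.family_id} is not fully phased "
            f"(ambiguous: {proband.ambiguous_markers}, "
            f"violations: {proband.mendel_violations})"
        )

    rel_phased = phase_trio(relative)
    if rel_phased.mendel_violations:
        return RiskCall(
            predicted_status="indeterminate",
            confidence="partial",
            warnings=tuple(d for _, d in rel_phased.mendel_violations),
        )

    markers = [m for m, o in proband.origin_map.items() if o is not None]
    transmitted_pat = {m: proband.origin_map[m][0] for m in markers}
    transmitted_mat = {m: proband.origin_map[m][1] for m in markers}
    father_geno = {m: proband.trio.genotype("father", m) for m in markers}
    mother_geno = {m: proband.trio.genotype("mother", m) for m in markers}

    warnings: list[str] = []
    n_risk = 0
    partial_any = False
    for member, transmitted, parent_geno, side in (
        ("father", transmitted_pat, father_geno, 0),
        ("mother", transmitted_mat, mother_geno, 1),
    ):
        if proband.trio.affected_status.get(member) == "affected":
            # both of this parent's haplotypes are at risk; no tracing needed
            n_risk += 1
            continue
        got_risk, partial, warns = _trace_parent(
            transmitted, parent_geno, rel_phased.origin_map, side
        )
        warnings.extend(warns)
        partial_any = partial_any or partial
        if got_risk is None:
            return RiskCall(
                predicted_status="indeterminate",
                confidence="partial",
                warnings=tuple(warnings),
            )
        n_risk += int(got_risk)

    status = ("unaffected", "carrier", "affected")[n_risk]
    return RiskCall(
        predicted_status=status,
        confidence="partial" if partial_any else "full",
        n_risk_haplotypes=n_risk,
        warnings=tuple(warnings),
    )
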