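"""Recombination-based fine mapping of a dominant allele.

Given phased half-sib families descending from founders that carry a large
trait-associated haplotype, this module (1) discovers founder haplotypes
private to affected founders, (2) classifies each descendant's paternally
inherited chromosome as intact carrier, non-carrier or recombinant and
localizes crossover breakpoints between adjacent informative markers, and
(3) shrinks the locus interval using recombinant haplotypes whose carriers
have concordant validated phenotypes.

The trait model is hard-wired autosomal dominant: an affected recombinant
must carry the causal position on the retained founder portion; an
unaffected recombinant must not.  Interval boundaries use the conservative
(outer) edge of each breakpoint's inter-marker gap, so marker sparsity can
never push the true position out of the reported interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConflictError, DegenerateInputError, LineageError
from .formats_io import (
    MISSING,
    GenomicInterval,
    HaplotypePanel,
    HornStatus,
    PedigreeRecord,
    PhenotypeRecord,
)


@dataclass(frozen=True)
class FounderHaplotype:
    """A haplotype carried by affected founders and absent (over its full
    span) from every unaffected founder in the reference set."""

    founder: str
    haplotype_key: str
    marker_span: Tuple[int, int]  # inclusive marker indices
    bp_span: GenomicInterval
    carriers: Tuple[str, ...] = ()

    @property
    def alleles(self) -> np.ndarray:
        return np.frombuffer(self.haplotype_key.encode(), dtype=np.uint8) - ord("0")


@dataclass(frozen=True)
class RecombinantObservation:
    """A descendant chromosome carrying part of a founder haplotype.

    ``breakpoint`` is (last-founder-state, first-other-state) when the
    founder segment is retained on the left, i.e. always the pair of
    adjacent informative marker indices flanking the crossover, left first.
    """

    descendant: str
    founder_haplotype: FounderHaplotype
    breakpoint: Tuple[int, int]
    bp_gap: GenomicInterval
    retained_side: str  # "left" | "right"
    phenotype: PhenotypeRecord


@dataclass
class DetectionResult:
    """Classification of all usable descendants against one founder
    haplotype."""

    observations: List[RecombinantObservation] = field(default_factory=list)
    intact_carriers: List[str] = field(default_factory=list)
    non_carriers: List[str] = field(default_factory=list)
    multi_breakpoint: List[str] = field(default_factory=list)
    uninformative: List[str] = field(default_factory=list)
    excluded_families: Dict[str, int] = field(default_factory=dict)


@dataclass
class MappingResult:
    interval: GenomicInterval
    supporting_recombinants: List[RecombinantObservation]
    left_boundary_source: Optional[RecombinantObservation] = None
    right_boundary_source: Optional[RecombinantObservation] = None
    ignored: List[RecombinantObservation] = field(default_factory=list)


def discover_founder_haplotypes(
    affected_founders: HaplotypePanel,
    unaffected_founders: Optional[HaplotypePanel],
    min_length_markers: int = 1,
    min_affected_carriers: int = 1,
) -> List[FounderHaplotype]:
    """Founder haplotypes present in affected founders and never seen, over
    the full marker map, in any unaffected founder.

    Absence from controls is monotone under span extension (a longer segment
    is at least as private), so qualifying haplotypes are reported at full
    map span; an affected haplotype matched end-to-end by any control is
    disqualified.  Results are deduplicated by haplotype key, annotated with
    every affected carrier, filtered to ``min_affected_carriers`` distinct
    carriers, and sorted by descending carrier count (the haplotype shared
    by the most affected founders first), then key.
    """
    mm = affected_founders.marker_map
    m = mm.n_markers
    if m < min_length_markers:
        return []
    if unaffected_founders is not None and unaffected_founders.marker_map != mm:
        raise DegenerateInputError("affected and unaffected founders must share a marker map")

    controls = (
        unaffected_founders.haplotypes
        if unaffected_founders is not None and unaffected_founders.haplotypes.size
        else np.empty((0, m), dtype=np.uint8)
    )
    by_key: Dict[str, List[str]] = {}
    H = affected_founders.haplotypes
    for i, ind in enumerate(affected_founders.individual_ids):
        for row in (H[2 * i], H[2 * i + 1]):
            if (row == MISSING).any():
                continue  # an incompletely called haplotype has no full-span key
            if controls.shape[0] and bool(np.any(np.all(controls == row, axis=1))):
                continue
            key = "".join(str(int(a)) for a in row)
            carriers = by_key.setdefault(key, [])
            if ind not in carriers:
                carriers.append(ind)

    out = [
        FounderHaplotype(
            founder=carriers[0],
            haplotype_key=key,
            marker_span=(0, m - 1),
            bp_span=mm.span(0, m - 1),
            carriers=tuple(carriers),
        )
        for key, carriers in by_key.items()
        if len(carriers) >= min_affected_carriers
    ]
    out.sort(key=lambda f: (-len(f.carriers), f.haplotype_key))
    return out


def _paternal_row(
    d_rows: np.ndarray, sire_a: np.ndarray, sire_b: np.ndarray
) -> np.ndarray:
    """Pick the descendant haplotype inherited from the sire: the one with
    fewer violations at markers where the sire is homozygous (a paternal
    gamete must match the sire allele there)."""
    hom = (sire_a == sire_b) & (sire_a != MISSING)
    violations = [
        int(np.sum(hom & (row != sire_a) & (row != MISSING))) for row in d_rows
    ]
    return d_rows[int(np.argmin(violations))]


def detect_recombinants(
    founder_hap: FounderHaplotype,
    descendants: HaplotypePanel,
    pedigree: Sequence[PedigreeRecord],
    phenotypes: Sequence[PhenotypeRecord] = (),
    min_progeny_per_sire: int = 10,
) -> DetectionResult:
    """Classify descendants of carrier sires against a founder haplotype.

    The panel must contain the sires as well as the descendants (phased).
    Only half-sib families with at least ``min_progeny_per_sire`` progeny in
    the panel are analysed; smaller families are logged in
    ``excluded_families``.  For each retained descendant the paternally
    inherited haplotype is compared to the founder haplotype at informative
    markers (markers where the sire's two haplotypes differ): all-founder
    states give an intact carrier, all-other a non-carrier, one state switch
    a recombinant with its breakpoint localized to the flanking informative
    marker pair, and two or more switches a multi-breakpoint chromosome,
    reported but excluded from mapping.
    """
    mm = descendants.marker_map
    s0, s1 = founder_hap.marker_span
    fh = founder_hap.alleles
    pheno = {p.individual: p for p in phenotypes}
    ped = {r.individual: r for r in pedigree}
    in_panel = set(descendants.individual_ids)

    # carrier sires: individuals siring progeny in the pedigree, with one
    # haplotype equal to the founder haplotype over its span
    all_sires = {r.sire for r in pedigree if r.sire is not None}
    sire_rows: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for i, ind in enumerate(descendants.individual_ids):
        if ind not in all_sires:
            continue
        a = descendants.haplotypes[2 * i, s0 : s1 + 1]
        b = descendants.haplotypes[2 * i + 1, s0 : s1 + 1]
        if np.array_equal(a, fh):
            sire_rows[ind] = (a, b)
        elif np.array_equal(b, fh):
            sire_rows[ind] = (b, a)

    families: Dict[str, List[str]] = {}
    for ind in descendants.individual_ids:
        rec = ped.get(ind)
        if rec is None:
            if ind in all_sires:
                continue  # founders need no pedigree entry
            raise LineageError(f"descendant {ind!r} not in pedigree")
        if rec.sire in sire_rows:
            families.setdefault(rec.sire, []).append(ind)

    result = DetectionResult()
    positions = mm.positions_bp
    for sire in sorted(families):
        progeny = families[sire]
        if len(progeny) < min_progeny_per_sire:
            result.excluded_families[sire] = len(progeny)
            continue
        f_hap, o_hap = sire_rows[sire]
        informative = np.flatnonzero(
            (f_hap != o_hap) & (f_hap != MISSING) & (o_hap != MISSING)
        )
        for child in progeny:
            ra, rb = descendants.rows_of(child)
            d_rows = descendants.haplotypes[[ra, rb], s0 : s1 + 1]
            pat = _paternal_row(d_rows, f_hap, o_hap)
            called = informative[pat[informative] != MISSING]
            if called.size == 0:
                result.uninformative.append(child)
                continue
            state = pat[called] == f_hap[called]
            switches = np.flatnonzero(state[:-1] != state[1:])
            if switches.size == 0:
                (result.intact_carriers if state[0] else result.non_carriers).append(child)
                continue
            if switches.size > 1:
                result.multi_breakpoint.append(child)
                continue
            t = int(switches[0])
            lo = int(called[t]) + s0
            hi = int(called[t + 1]) + s0
            retained = "left" if state[0] else "right"
            p_lo, p_hi = int(positions[lo]), int(positions[hi])
            if p_hi > p_lo + 1:  # strictly-between bases
                gap = GenomicInterval(mm.chromosome, p_lo, p_hi - 1)
            else:  # adjacent in bp: fall back to the flanking-marker pair
                gap = GenomicInterval(mm.chromosome, p_lo - 1, p_hi)
            result.observations.append(
                RecombinantObservation(
                    descendant=child,
                    founder_haplotype=founder_hap,
                    breakpoint=(lo, hi),
                    bp_gap=gap,
                    retained_side=retained,
                    phenotype=pheno.get(
                        child, PhenotypeRecord(child, HornStatus.UNKNOWN, False)
                    ),
                )
            )
    return result


def refine_interval(
    founder_hap: FounderHaplotype,
    recombinants: Sequence[RecombinantObservation],
    min_concordant_carriers: int = 2,
) -> MappingResult:
    """Shrink the locus interval using phenotype-concordant recombinants.

    Recombinant haplotypes are grouped by (breakpoint, retained side); a
    group counts only if it has at least ``min_concordant_carriers``
    carriers, all with validated and identical polled/horned phenotypes
    (scurs and unknown phenotypes are ignored and logged).  Under the
    dominant model, an affected (polled) group restricts the interval to the
    retained founder portion, out to the outer edge of the breakpoint gap;
    an unaffected (horned) group excludes the surely retained portion, in to
    the inner edge.  Contradictory evidence (an empty interval) raises
    :class:`ConflictError` naming the two boundary-setting observations.
    """
    mm_chrom = founder_hap.bp_span.chromosome
    lo, hi = founder_hap.bp_span.start, founder_hap.bp_span.end
    lo_src: Optional[RecombinantObservation] = None
    hi_src: Optional[RecombinantObservation] = None
    ignored: List[RecombinantObservation] = []
    groups: Dict[Tuple[int, int, str], List[RecombinantObservation]] = {}
    for obs in recombinants:
        if obs.founder_haplotype.haplotype_key != founder_hap.haplotype_key:
            raise DegenerateInputError(
                f"observation {obs.descendant!r} references a different founder haplotype"
            )
        st = obs.phenotype.horn_status
        if st in (HornStatus.SCURS, HornStatus.UNKNOWN) or not obs.phenotype.validated:
            ignored.append(obs)
            continue
        groups.setdefault((*obs.breakpoint, obs.retained_side), []).append(obs)

    supporting: List[RecombinantObservation] = []
    for key in sorted(groups):
        members = groups[key]
        statuses = {o.phenotype.horn_status for o in members}
        if len(members) < min_concordant_carriers or len(statuses) != 1:
            ignored.extend(members)
            continue
        status = statuses.pop()
        obs = members[0]
        affected = status == HornStatus.POLLED
        retained_left = obs.retained_side == "left"
        if affected == retained_left:
            # polled+left: causal on the retained prefix, out to the gap's
            # outer-right edge; horned+right: the surely retained suffix is
            # excluded.  Both cap the right bound at the gap end.
            if obs.bp_gap.end < hi:
                hi, hi_src = obs.bp_gap.end, obs
        else:
            # polled+right / horned+left: mirror case, raises the left bound
            # to the gap's outer-left edge.
            if obs.bp_gap.start > lo:
                lo, lo_src = obs.bp_gap.start, obs
        if lo >= hi:
            left_name = lo_src.descendant if lo_src else "founder-span start"
            right_name = hi_src.descendant if hi_src else "founder-span end"
            raise ConflictError(
                f"contradictory recombinants: left bound from {left_name} "
                f"meets/passes right bound from {right_name}",
                left=lo_src,
                right=hi_src,
            )
        supporting.extend(members)

    interval = GenomicInterval(mm_chrom, lo, hi)
    return MappingResult(
        interval=interval,
        supporting_recombinants=supporting,
        left_boundary_source=lo_src,
        right_boundary_source=hi_src,
        ignored=ignored,
    )
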