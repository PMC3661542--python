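"""Candidate-variant prioritization.

Three complementary reductions of an interval's variant list, mirroring how
a dominant causal mutation is isolated from whole-genome sequencing of
carriers:

* control-panel subtraction — any variant also called in an unaffected
  control genome cannot be causal;
* genotype-phenotype concordance — across a multi-breed panel of
  homozygous-affected animals the causal variant must be homozygous
  alternate in every tested individual ("complete concordance": a single
  discordant call removes a candidate);
* dichotomous (bisection) marker selection — to localize a recombination
  boundary, repeatedly genotype the untested candidate nearest the midpoint
  of the current interval, halving it each round.

Every retained or removed variant carries an audit-trail entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .errors import CandidatesExhausted, DegenerateInputError
from .formats_io import (
    GenomicInterval,
    HornStatus,
    PhenotypeRecord,
    VariantRecord,
)


@dataclass
class CandidateSet:
    """An interval's surviving candidates plus a complete per-variant audit
    trail: every input variant has a terminal disposition."""

    interval: GenomicInterval
    variants: List[VariantRecord]
    provenance: Dict[tuple, List[Tuple[str, str, str]]] = field(default_factory=dict)

    def log(self, variant: VariantRecord, stage: str, action: str, detail: str = ""):
        self.provenance.setdefault(variant.key, []).append((stage, action, detail))

    def audit_dataframe(self) -> pd.DataFrame:
        rows = [
            {"variant": str(key), "stage": s, "action": a, "detail": d}
            for key, events in self.provenance.items()
            for s, a, d in events
        ]
        return pd.DataFrame(rows, columns=["variant", "stage", "action", "detail"])


@dataclass(frozen=True)
class ConcordanceReport:
    variant: VariantRecord
    n_tested: int
    n_concordant: int
    discordant_individuals: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_concordant > self.n_tested:
            raise ValueError("n_concordant cannot exceed n_tested")


def _hull(variants: Sequence[VariantRecord]) -> GenomicInterval:
    chrom = variants[0].chromosome
    lo = min(v.position_bp for v in variants)
    hi = max(v.position_bp for v in variants)
    return GenomicInterval.from_1based(chrom, lo, hi)


def subtract_controls(
    case_variants: Sequence[VariantRecord],
    control_variant_sets: Sequence[Sequence[VariantRecord]],
    interval: Optional[GenomicInterval] = None,
) -> CandidateSet:
    """Retain case variants absent from every control set.

    Identity is the exact ``(chromosome, position, ref, alt)`` key; the
    audit trail names the first control set carrying each removed variant.
    An empty result is valid.
    """
    if not case_variants:
        raise DegenerateInputError("empty case variant list")
    iv = interval or _hull(case_variants)
    seen_in: Dict[tuple, int] = {}
    for c_idx, cset in enumerate(control_variant_sets):
        for v in cset:
            seen_in.setdefault(v.key, c_idx)
    out = CandidateSet(iv, [])
    for v in case_variants:
        if v.key in seen_in:
            out.log(v, "subtract_controls", "removed", f"present_in_control_{seen_in[v.key]}")
        else:
            out.variants.append(v)
            out.log(v, "subtract_controls", "retained", "absent_from_all_controls")
    return out


_EXPECTED_DOMINANT_HOMOZYGOUS = {
    HornStatus.POLLED: "1/1",  # homozygous-affected panel: hom alternate
    HornStatus.HORNED: "0/0",
}


def concordance_filter(
    candidates: CandidateSet,
    genotypes: pd.DataFrame,
    phenotypes: Sequence[PhenotypeRecord],
    expected_model: str = "dominant",
    min_tested: int = 1,
    max_discordant: int = 0,
) -> Tuple[CandidateSet, List[ConcordanceReport]]:
    """Keep candidates fully concordant with phenotype across the panel.

    ``genotypes`` has columns (variant, individual, genotype); ``variant``
    matches :attr:`VariantRecord.descriptor`.  Missing calls (``./.``)
    reduce ``n_tested`` and never count either way.  A candidate with zero
    informative calls is retained but flagged ``untested``.
    ``max_discordant`` defaults to 0 ("complete concordance").
    """
    if expected_model != "dominant":
        raise ValueError("only the dominant model is supported")
    pheno = {p.individual: p for p in phenotypes}
    by_variant = dict(tuple(genotypes.groupby("variant", sort=False)))
    out = CandidateSet(candidates.interval, [], provenance=dict(candidates.provenance))
    reports: List[ConcordanceReport] = []
    for v in candidates.variants:
        calls = by_variant.get(v.descriptor)
        n_tested = 0
        discordant: List[str] = []
        if calls is not None:
            for row in calls.itertuples():
                ph = pheno.get(row.individual)
                expected = ph and _EXPECTED_DOMINANT_HOMOZYGOUS.get(ph.horn_status)
                if expected is None or row.genotype in ("./.", ".|."):
                    continue
                n_tested += 1
                if row.genotype.replace("|", "/") != expected:
                    discordant.append(row.individual)
        reports.append(
            ConcordanceReport(v, n_tested, n_tested - len(discordant), tuple(discordant))
        )
        if n_tested == 0:
            out.variants.append(v)
            out.log(v, "concordance_filter", "retained", "untested")
        elif len(discordant) <= max_discordant and n_tested >= min_tested:
            out.log(v, "concordance_filter", "retained", f"concordant_in_{n_tested}")
            out.variants.append(v)
        else:
            reason = (
                f"discordant_in_{','.join(discordant)}"
                if discordant
                else f"tested_in_only_{n_tested}"
            )
            out.log(v, "concordance_filter", "removed", reason)
    return out, reports


def dichotomous_select(
    candidates_in_order: Sequence[VariantRecord],
    tested: Set[tuple],
    current_interval: GenomicInterval,
) -> VariantRecord:
    """Next candidate to genotype: the untested one closest (in bp) to the
    midpoint of the current interval.  Ties break toward the smaller
    position.  Raises :class:`CandidatesExhausted` when no untested
    candidate remains inside the interval.
    """
    inside = [
        v
        for v in candidates_in_order
        if v.key not in tested and current_interval.contains_1based(v.position_bp)
    ]
    if not inside:
        raise CandidatesExhausted(
            f"no untested candidate inside {current_interval.chromosome}:"
            f"{current_interval.start_1based}-{current_interval.end_1based}"
        )
    mid = (current_interval.start_1based + current_interval.end_1based) / 2.0
    return min(inside, key=lambda v: (abs(v.position_bp - mid), v.position_bp))


def coverage_audit(
    interval: GenomicInterval,
    covered_regions: Sequence[GenomicInterval],
    assembly_gaps: Sequence[GenomicInterval] = (),
) -> List[GenomicInterval]:
    """Subregions of ``interval`` covered neither by sequencing nor by an
    already-resolved assembly gap — the regions still needing targeted
    resequencing before a candidate list may be called exhaustive."""
    events = sorted(
        (max(r.start, interval.start), min(r.end, interval.end))
        for r in list(covered_regions) + list(assembly_gaps)
        if r.chromosome == interval.chromosome and r.end > interval.start and r.start < interval.end
    )
    out: List[GenomicInterval] = []
    cursor = interval.start
    for s, e in events:
        if s > cursor:
            out.append(GenomicInterval(interval.chromosome, cursor, s))
        cursor = max(cursor, e)
    if cursor < interval.end:
        out.append(GenomicInterval(interval.chromosome, cursor, interval.end))
    return out
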