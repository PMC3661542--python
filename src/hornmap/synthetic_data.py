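"""Synthetic genotype, pedigree and variant-catalog generation.

Three scenario types drive everything downstream:

* :class:`SweepScenario` — multi-breed phased haplotype panels with one
  haplotype planted at elevated frequency across breeds in a contiguous
  marker window (the selective-sweep signature).  Background haplotypes are
  mosaics of a small per-breed founder pool, which produces the long-range
  within-breed haplotype sharing (LD) that makes a windowed top-haplotype
  statistic meaningful; independent per-marker alleles would not.
* :class:`PedigreeScenario` — paternal half-sib families segregating a
  dominant causal mutation that rides one founder haplotype, with
  Poisson-distributed crossovers per meiosis (no interference) and
  breakpoints uniform in bp.
* :class:`VariantScenario` — case variant catalogs in an interval, control
  catalogs sharing a configurable number of decoys, and a multi-breed
  homozygote genotyping panel in which only the causal variant is fully
  phenotype-concordant.

All randomness flows through a single ``numpy`` Generator seeded from the
scenario, so identical scenarios give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .formats_io import (
    GenomicInterval,
    HaplotypePanel,
    HornStatus,
    MarkerMap,
    PedigreeRecord,
    PhenotypeRecord,
    VariantKind,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


class SweepScenario(BaseModel):
    """Study conditions for the sweep scan: 17 horned breeds genotyped over
    ~1,000 markers on the proximal chromosome tip, scanned in 79-marker
    windows."""

    n_breeds: int = 17
    haplotypes_per_breed: int = 200
    n_markers: int = 1000
    marker_spacing_bp: int = 3000
    background_pool_size: int = 30
    sweep_window: Tuple[int, int] = (460, 79)  # (start_index, width)
    sweep_haplotype_frequency: Optional[Tuple[float, ...]] = None
    allele_frequency_spectrum: Tuple = ("uniform", 0.05, 0.95)
    mosaic_switch_rate: float = 0.01
    chromosome: str = "1"
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        start, width = self.sweep_window
        if width < 1 or start < 0 or start + width > self.n_markers:
            raise ConfigurationError(
                f"sweep_window {self.sweep_window} outside [0, {self.n_markers})"
            )
        if self.sweep_haplotype_frequency is not None:
            f = self.sweep_haplotype_frequency
            if len(f) != self.n_breeds:
                raise ConfigurationError(
                    f"sweep frequency vector length {len(f)} != n_breeds {self.n_breeds}"
                )
            if any(not 0.0 <= x <= 1.0 for x in f):
                raise ConfigurationError("sweep frequencies must lie in [0, 1]")
        if self.marker_spacing_bp < 1:
            raise ConfigurationError("marker_spacing_bp must be positive")
        return self


class PedigreeScenario(BaseModel):
    """Half-sib mapping design: heterozygous polled founder sires, a shared
    causal founder haplotype, and phenotyped progeny."""

    n_founders_polled: int = 9
    n_founders_horned: int = 5
    progeny_per_sire: int = Field(default=50, ge=1)
    crossover_rate: float = 1.0  # expected crossovers per meiosis, whole segment
    causal_position_bp: Optional[int] = None  # default: map midpoint
    causal_founder_haplotype: int = 0  # flat row index into the first panel
    phenotype_error_rate: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        if not 0.0 <= self.phenotype_error_rate <= 1.0:
            raise ConfigurationError("phenotype_error_rate must lie in [0, 1]")
        if self.crossover_rate < 0:
            raise ConfigurationError("crossover_rate must be >= 0")
        return self


class VariantScenario(BaseModel):
    """Case/control variant catalogs plus a concordance genotyping panel."""

    interval: Tuple[str, int, int]  # (chromosome, start_1based, end_1based)
    n_case_variants: int = 1610
    n_shared_with_controls: int = 1598
    n_controls: int = 55
    n_private_per_control: int = 5
    n_genotyped_animals: int = 32
    n_genotype_breeds: int = 7
    genotype_missing_rate: float = 0.02
    causal_descriptor: Optional[str] = None  # default: SNV at interval midpoint
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        chrom, s, e = self.interval
        if s > e:
            raise ConfigurationError(f"interval {self.interval} is empty")
        if self.n_shared_with_controls > self.n_case_variants - 1:
            raise ConfigurationError(
                "n_shared_with_controls must leave the causal variant unshared "
                f"({self.n_shared_with_controls} > {self.n_case_variants} - 1)"
            )
        if self.n_case_variants > e - s + 1:
            raise ConfigurationError("interval too small for n_case_variants")
        if self.n_genotype_breeds > self.n_genotyped_animals:
            raise ConfigurationError("more genotyping breeds than animals")
        return self

    @property
    def genomic_interval(self) -> GenomicInterval:
        chrom, s, e = self.interval
        return GenomicInterval.from_1based(chrom, s, e)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a pedigree simulation."""

    causal_position_bp: int
    causal_haplotype_key: str
    causal_founders: List[str]
    breakpoints: Dict[str, List[int]] = field(default_factory=dict)
    carrier: Dict[str, bool] = field(default_factory=dict)


@dataclass
class VariantCatalogs:
    """Output bundle of :func:`simulate_variant_catalogs`."""

    case_variants: List[VariantRecord]
    control_variant_sets: List[List[VariantRecord]]
    genotype_table: pd.DataFrame
    phenotypes: List[PhenotypeRecord]
    causal_variant: VariantRecord


# ---------------------------------------------------------------------------
# breed panels with a planted sweep
# ---------------------------------------------------------------------------


def _marker_map(scenario: SweepScenario) -> MarkerMap:
    positions = scenario.marker_spacing_bp * np.arange(1, scenario.n_markers + 1)
    return MarkerMap(
        scenario.chromosome,
        tuple((f"M{j:05d}", int(p)) for j, p in enumerate(positions)),
    )


def _mosaic_haplotypes(
    rng: np.random.Generator,
    pool: np.ndarray,
    n_haplotypes: int,
    switch_rate: float,
) -> np.ndarray:
    """Haplotypes as mosaics of pool rows: the source row is redrawn at each
    marker with probability ``switch_rate``."""
    P, m = pool.shape
    switch = rng.random((n_haplotypes, m)) < switch_rate
    switch[:, 0] = True  # segment 0 starts at the first marker
    seg_id = np.cumsum(switch, axis=1) - 1
    max_segs = int(seg_id.max()) + 1
    sources = rng.integers(0, P, size=(n_haplotypes, max_segs))
    src = np.take_along_axis(sources, seg_id, axis=1)
    return pool[src, np.arange(m)[None, :]]


def simulate_breed_panels(scenario: SweepScenario) -> List[HaplotypePanel]:
    """Generate per-breed phased panels with the planted sweep haplotype.

    Each breed has its own allele-frequency spectrum and background founder
    pool; each sampled haplotype is a pool mosaic, then — with the breed's
    sweep frequency — its alleles inside ``sweep_window`` are overwritten by
    the single sweep haplotype shared across breeds.
    """
    rng = np.random.default_rng(scenario.seed)
    mm = _marker_map(scenario)
    start, width = scenario.sweep_window
    kind, lo, hi = scenario.allele_frequency_spectrum
    if kind != "uniform":
        raise ConfigurationError(f"unsupported allele_frequency_spectrum {kind!r}")

    sweep_hap = (rng.random(width) < 0.5).astype(np.uint8)
    freqs = scenario.sweep_haplotype_frequency
    if freqs is None:
        # per-breed sweep frequencies spanning the range observed on real
        # horned breed panels (0.443 to 0.885)
        freqs = tuple(rng.uniform(0.443, 0.885, size=scenario.n_breeds))

    panels = []
    for b in range(scenario.n_breeds):
        breed = f"B{b + 1:02d}"
        afs = rng.uniform(lo, hi, size=scenario.n_markers)
        pool = (rng.random((scenario.background_pool_size, scenario.n_markers)) < afs).astype(
            np.uint8
        )
        H = _mosaic_haplotypes(
            rng, pool, scenario.haplotypes_per_breed, scenario.mosaic_switch_rate
        )
        carry = rng.random(scenario.haplotypes_per_breed) < freqs[b]
        H[carry, start : start + width] = sweep_hap
        n_ind = scenario.haplotypes_per_breed // 2
        if scenario.haplotypes_per_breed % 2:
            raise ConfigurationError("haplotypes_per_breed must be even (2 per diploid)")
        ids = [f"{breed}_{i:04d}" for i in range(n_ind)]
        panels.append(HaplotypePanel(breed, mm, H, ids))
    return panels


# ---------------------------------------------------------------------------
# half-sib pedigree with a planted dominant mutation
# ---------------------------------------------------------------------------


def _meiosis(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    positions: np.ndarray,
    crossover_rate: float,
    track_pos_bp: Optional[int] = None,
) -> Tuple[np.ndarray, List[int], Optional[bool]]:
    """One gamete from two parental haplotypes.

    The crossover count is Poisson(``crossover_rate``); breakpoints are
    uniform in bp over the mapped segment.  A marker at position ``p`` takes
    its allele from the current source haplotype, switching at every
    breakpoint ``x`` so that markers with ``p >= x`` come from the other
    source.  Returns (gamete, breakpoints, from_a_at_track) where the last
    element says whether ``track_pos_bp`` was inherited from ``hap_a``.
    """
    lo, hi = int(positions[0]), int(positions[-1])
    n_x = rng.poisson(crossover_rate)
    breakpoints = sorted(int(x) for x in rng.integers(lo + 1, hi + 1, size=n_x))
    start_a = bool(rng.random() < 0.5)
    # source at position p: start, flipped once per breakpoint <= p
    flips = np.searchsorted(breakpoints, positions, side="right")
    from_a = (flips % 2 == 0) == start_a
    gamete = np.where(from_a, hap_a, hap_b)
    tracked = None
    if track_pos_bp is not None:
        flips_t = int(np.searchsorted(breakpoints, track_pos_bp, side="right"))
        tracked = (flips_t % 2 == 0) == start_a
    return gamete.astype(np.uint8), breakpoints, tracked


def simulate_pedigree(
    scenario: PedigreeScenario, panels: Sequence[HaplotypePanel]
) -> Tuple[List[PedigreeRecord], HaplotypePanel, List[PhenotypeRecord], TruthRecord]:
    """Simulate paternal half-sib families from founders drawn out of breed
    panels.

    Polled founder sires are heterozygous carriers: haplotype A is the
    shared causal founder haplotype (drawn once from the first panel),
    haplotype B a random background haplotype.  Horned founders carry two
    background haplotypes.  Each progeny receives one paternal meiosis
    product and one random background haplotype as the maternal gamete
    (dams are unrecorded, as in a half-sib design).  Phenotype is polled iff
    the progeny inherited the causal position from the carrier haplotype,
    flipped with ``phenotype_error_rate``.
    """
    rng = np.random.default_rng(scenario.seed)
    mm = panels[0].marker_map
    positions = mm.positions_bp
    all_rows = np.concatenate([p.haplotypes for p in panels], axis=0)
    n_rows = all_rows.shape[0]
    if not 0 <= scenario.causal_founder_haplotype < n_rows:
        raise ConfigurationError(
            f"causal_founder_haplotype {scenario.causal_founder_haplotype} "
            f"outside the {n_rows} available haplotypes"
        )
    causal_pos = (
        scenario.causal_position_bp
        if scenario.causal_position_bp is not None
        else int(positions[len(positions) // 2])
    )
    if not int(positions[0]) <= causal_pos <= int(positions[-1]):
        raise ConfigurationError(
            f"causal_position_bp {causal_pos} outside the mapped segment"
        )
    causal_hap = all_rows[scenario.causal_founder_haplotype].copy()

    def background() -> np.ndarray:
        # reject rows identical in content to the causal haplotype, so the
        # causal founder haplotype is carried by affected founders only
        while True:
            i = int(rng.integers(n_rows))
            if i == scenario.causal_founder_haplotype:
                continue
            row = all_rows[i]
            if np.array_equal(row, causal_hap):
                continue
            return row.copy()

    pedigree: List[PedigreeRecord] = []
    phenotypes: List[PhenotypeRecord] = []
    rows: List[np.ndarray] = []
    ids: List[str] = []
    truth = TruthRecord(
        causal_position_bp=causal_pos,
        causal_haplotype_key="".join(str(int(a)) for a in causal_hap),
        causal_founders=[],
    )

    founders: List[Tuple[str, bool, np.ndarray, np.ndarray]] = []
    for s in range(scenario.n_founders_polled):
        fid = f"SIRE_P{s + 1:02d}"
        founders.append((fid, True, causal_hap.copy(), background()))
        truth.causal_founders.append(fid)
    for s in range(scenario.n_founders_horned):
        founders.append((f"SIRE_H{s + 1:02d}", False, background(), background()))

    for fid, polled, hap_a, hap_b in founders:
        ids.append(fid)
        rows.extend([hap_a, hap_b])
        pedigree.append(PedigreeRecord(fid, None, None, "SIM"))
        status = HornStatus.POLLED if polled else HornStatus.HORNED
        phenotypes.append(PhenotypeRecord(fid, status, True))
        truth.carrier[fid] = polled

    for fid, polled, hap_a, hap_b in founders:
        for c in range(scenario.progeny_per_sire):
            cid = f"{fid}_C{c + 1:03d}"
            gamete, bps, from_a = _meiosis(
                rng, hap_a, hap_b, positions, scenario.crossover_rate, causal_pos
            )
            maternal = background()
            carrier = bool(polled and from_a)
            is_polled = carrier
            if scenario.phenotype_error_rate > 0 and rng.random() < scenario.phenotype_error_rate:
                is_polled = not is_polled
            ids.append(cid)
            rows.extend([gamete, maternal])
            pedigree.append(PedigreeRecord(cid, fid, None, "SIM"))
            phenotypes.append(
                PhenotypeRecord(
                    cid, HornStatus.POLLED if is_polled else HornStatus.HORNED, True
                )
            )
            truth.breakpoints[cid] = bps
            truth.carrier[cid] = carrier

    panel = HaplotypePanel("SIM", mm, np.array(rows, dtype=np.uint8), ids)
    return pedigree, panel, phenotypes, truth


def simulate_homozygous_carriers(
    scenario: PedigreeScenario,
    panels: Sequence[HaplotypePanel],
    n_carriers: int = 15,
    seed: Optional[int] = None,
) -> Tuple[HaplotypePanel, TruthRecord]:
    """A cohort of trait-homozygous animals for IBD-style mapping.

    Each chromosome of each carrier is an independent meiosis product of the
    causal founder haplotype and a random background haplotype, accepted
    only if it transmits the causal position — so every animal carries two
    copies, each trimmed by historical recombination.  The segment shared by
    the whole cohort therefore shrinks around the causal position as
    ``n_carriers`` grows.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    mm = panels[0].marker_map
    positions = mm.positions_bp
    all_rows = np.concatenate([p.haplotypes for p in panels], axis=0)
    causal_hap = all_rows[scenario.causal_founder_haplotype].copy()
    causal_pos = (
        scenario.causal_position_bp
        if scenario.causal_position_bp is not None
        else int(positions[len(positions) // 2])
    )
    rows: List[np.ndarray] = []
    while len(rows) < 2 * n_carriers:
        bg = all_rows[int(rng.integers(all_rows.shape[0]))]
        gamete, _, from_causal = _meiosis(
            rng, causal_hap, bg, positions, scenario.crossover_rate, causal_pos
        )
        if from_causal:
            rows.append(gamete)
    ids = [f"HOM{i + 1:02d}" for i in range(n_carriers)]
    truth = TruthRecord(
        causal_position_bp=causal_pos,
        causal_haplotype_key="".join(str(int(a)) for a in causal_hap),
        causal_founders=[],
    )
    return HaplotypePanel("HOM", mm, np.array(rows, dtype=np.uint8), ids), truth


# ---------------------------------------------------------------------------
# variant catalogs
# ---------------------------------------------------------------------------


def simulate_variant_catalogs(scenario: VariantScenario) -> VariantCatalogs:
    """Generate case/control variant catalogs and a concordance panel.

    The case list holds the causal variant plus decoys at distinct positions
    in the interval; exactly ``n_shared_with_controls`` decoys also appear in
    at least one control set (the causal never does).  The genotype table
    covers a homozygous-affected panel spread over ``n_genotype_breeds``
    breeds: the causal variant is homozygous-alternate in every animal,
    while every decoy is discordant in at least one animal of at least one
    breed.
    """
    rng = np.random.default_rng(scenario.seed)
    chrom, s1, e1 = scenario.interval
    mid = (s1 + e1) // 2

    if scenario.causal_descriptor is not None:
        from .formats_io import parse_descriptor

        causal = parse_descriptor(scenario.causal_descriptor, chromosome=chrom)
        if not scenario.genomic_interval.contains_1based(causal.position_bp):
            raise ConfigurationError("causal variant lies outside the interval")
    else:
        causal = VariantRecord(
            chrom, mid, VariantKind.SNV, f"g.{mid}G>A", ref_allele="G", alt_allele="A"
        )

    n_decoys = scenario.n_case_variants - 1
    size = e1 - s1 + 1
    positions = rng.choice(
        np.arange(s1, e1 + 1), size=min(size, scenario.n_case_variants + 8), replace=False
    )
    positions = [int(p) for p in positions if p != causal.position_bp][:n_decoys]
    decoys = []
    for p in positions:
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_b, alt_b = str(_BASES[ref]), str(_BASES[alt])
        decoys.append(
            VariantRecord(
                chrom, p, VariantKind.SNV, f"g.{p}{ref_b}>{alt_b}",
                ref_allele=ref_b, alt_allele=alt_b,
            )
        )
    case_variants = sorted([causal] + decoys, key=lambda v: v.position_bp)

    control_sets: List[List[VariantRecord]] = [[] for _ in range(scenario.n_controls)]
    shared_idx = rng.choice(n_decoys, size=scenario.n_shared_with_controls, replace=False)
    if scenario.n_controls > 0:
        for i in sorted(int(x) for x in shared_idx):
            k = 1 + int(rng.integers(0, min(3, scenario.n_controls)))
            for c in rng.choice(scenario.n_controls, size=k, replace=False):
                control_sets[int(c)].append(decoys[i])
        # private control-only variants outside the case list
        for c in range(scenario.n_controls):
            for _ in range(scenario.n_private_per_control):
                p = int(rng.integers(s1, e1 + 1))
                ref, alt = rng.choice(4, size=2, replace=False)
                control_sets[c].append(
                    VariantRecord(
                        chrom, p, VariantKind.SNV,
                        f"g.{p}{_BASES[ref]}>{_BASES[alt]}",
                        ref_allele=str(_BASES[ref]), alt_allele=str(_BASES[alt]),
                    )
                )

    # concordance panel: homozygous polled animals across breeds
    breeds = [f"GB{k + 1}" for k in range(scenario.n_genotype_breeds)]
    animal_breeds = [breeds[k % len(breeds)] for k in range(scenario.n_genotyped_animals)]
    animals = [f"{b}_A{k:03d}" for k, b in enumerate(animal_breeds)]
    phenotypes = [PhenotypeRecord(a, HornStatus.POLLED, True) for a in animals]

    survivors = {v.key for v in case_variants} - {
        v.key for cs in control_sets for v in cs
    }
    rows = []
    for v in case_variants:
        if v.key not in survivors:
            continue  # genotyping is only done on subtraction survivors
        is_causal = v.key == causal.key
        discordant_at = None if is_causal else int(rng.integers(len(animals)))
        for k, a in enumerate(animals):
            if not is_causal and k == discordant_at:
                gt = str(rng.choice(["0/0", "0/1"]))
            elif rng.random() < scenario.genotype_missing_rate:
                gt = "./."
            else:
                gt = "1/1" if is_causal or rng.random() < 0.8 else str(
                    rng.choice(["1/1", "0/1"])
                )
            rows.append({"variant": v.descriptor, "individual": a, "genotype": gt})
    genotype_table = pd.DataFrame(rows, columns=["variant", "individual", "genotype"])

    return VariantCatalogs(
        case_variants=case_variants,
        control_variant_sets=control_sets,
        genotype_table=genotype_table,
        phenotypes=phenotypes,
        causal_variant=causal,
    )
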