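"""Domain types, file formats, marker/sample QC and variant-descriptor arithmetic.

Conventions
-----------
* Marker positions and all printed/HGVS-style coordinates are 1-based
  inclusive, exactly as they appear in genotyping reports.
* :class:`GenomicInterval` is 0-based half-open internally (BED convention);
  conversion happens only at the boundary, via the ``from_1based`` /
  ``start_1based`` / ``end_1based`` helpers.
* Haplotype matrices are ``uint8`` with allele codes 0 and 1 and
  :data:`MISSING` (255) for a missing allele.  Missing alleles are never
  imputed here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    ParseError,
    PhasingError,
)

MISSING: int = 255
"""Allele code for a missing call in haplotype matrices."""


# ---------------------------------------------------------------------------
# core coordinate / map types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome segment, 0-based half-open.

    Use :meth:`from_1based` when constructing from printed (1-based
    inclusive) coordinates, and ``start_1based`` / ``end_1based`` when
    printing.
    """

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chromosome}"
            )

    @classmethod
    def from_1based(cls, chromosome: str, start_1based: int, end_1based: int) -> "GenomicInterval":
        return cls(chromosome, start_1based - 1, end_1based)

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_1based(self, position_bp: int) -> bool:
        return self.start_1based <= position_bp <= self.end_1based

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if self.chromosome != other.chromosome:
            return None
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        if lo >= hi:
            return None
        return GenomicInterval(self.chromosome, lo, hi)

    def to_bed_line(self, name: str = ".") -> str:
        return f"{self.chromosome}\t{self.start}\t{self.end}\t{name}"


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map for one chromosome.

    ``markers`` is a sequence of ``(marker_id, position_bp)`` with 1-based
    positions, strictly increasing, unique ids.
    """

    chromosome: str
    markers: tuple

    def __post_init__(self):
        ids = [m[0] for m in self.markers]
        pos = [m[1] for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids are not unique")
        if any(p <= 0 for p in pos):
            raise ValueError("marker positions must be positive")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker positions must be strictly increasing")
        object.__setattr__(self, "markers", tuple((str(i), int(p)) for i, p in self.markers))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> tuple:
        return tuple(m[0] for m in self.markers)

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([m[1] for m in self.markers], dtype=np.int64)

    def span(self, start_index: int, end_index: int) -> GenomicInterval:
        """0-based half-open interval covering markers start_index..end_index
        (inclusive marker indices)."""
        pos = self.positions_bp
        return GenomicInterval.from_1based(
            self.chromosome, int(pos[start_index]), int(pos[end_index])
        )


@dataclass
class HaplotypePanel:
    """A breed-labelled matrix of phased haplotypes over a marker map.

    Rows ``2*i`` and ``2*i + 1`` are the two phased chromosomes of
    ``individual_ids[i]``.
    """

    breed: str
    marker_map: MarkerMap
    haplotypes: np.ndarray
    individual_ids: list

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != 2 * len(self.individual_ids):
            raise ValueError(
                f"{self.haplotypes.shape[0]} haplotype rows for "
                f"{len(self.individual_ids)} individuals (need 2 per individual)"
            )
        if self.haplotypes.shape[1] != self.marker_map.n_markers:
            raise ValueError("haplotype columns do not match marker count")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return self.marker_map.n_markers

    def rows_of(self, individual: str) -> tuple:
        i = self.individual_ids.index(individual)
        return 2 * i, 2 * i + 1

    def genotypes(self) -> np.ndarray:
        """(n_individuals, n_markers) diploid allele-count matrix; MISSING
        where either allele is missing."""
        a = self.haplotypes[0::2].astype(np.int16)
        b = self.haplotypes[1::2].astype(np.int16)
        g = a + b
        g[(a == MISSING) | (b == MISSING)] = MISSING
        return g.astype(np.uint8)


class HornStatus(str, Enum):
    POLLED = "polled"
    HORNED = "horned"
    SCURS = "scurs"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PedigreeRecord:
    individual: str
    sire: Optional[str]
    dam: Optional[str]
    breed: str


@dataclass(frozen=True)
class PhenotypeRecord:
    individual: str
    horn_status: HornStatus
    validated: bool = True

    def __post_init__(self):
        object.__setattr__(self, "horn_status", HornStatus(self.horn_status))


def check_pedigree(records: Sequence[PedigreeRecord]) -> None:
    """Raise if any individual is its own ancestor (cycle detection)."""
    parents = {r.individual: [p for p in (r.sire, r.dam) if p is not None] for r in records}

    state: dict = {}

    def visit(node):
        state[node] = 1
        for p in parents.get(node, ()):
            s = state.get(p, 0)
            if s == 1:
                raise ValueError(f"pedigree cycle involving {node!r}")
            if s == 0:
                visit(p)
        state[node] = 2

    for r in records:
        if state.get(r.individual, 0) == 0:
            visit(r.individual)


# ---------------------------------------------------------------------------
# variant records and HGVS-style descriptors
# ---------------------------------------------------------------------------


class VariantKind(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    DELINS_DUP = "delins_dup"


@dataclass(frozen=True)
class VariantRecord:
    """A candidate polymorphism.

    ``ref_allele``/``alt_allele`` are base strings for SNVs and small indels,
    and 1-based inclusive coordinate pairs for duplications and
    duplication-delins events.
    """

    chromosome: str
    position_bp: int
    kind: VariantKind
    descriptor: str
    ref_allele: Union[str, tuple, None] = None
    alt_allele: Union[str, tuple, None] = None

    @property
    def key(self) -> tuple:
        """Identity used for control-panel subtraction: exact
        (chromosome, position, ref, alt)."""
        return (self.chromosome, self.position_bp, self.ref_allele, self.alt_allele)

    @property
    def replaced_length(self) -> Optional[int]:
        """Length in bp of the reference segment removed/replaced (inclusive
        coordinates: end - start + 1)."""
        if self.kind in (VariantKind.DELETION, VariantKind.DELINS_DUP):
            a, b = self.ref_allele
            return b - a + 1
        if self.kind == VariantKind.SNV:
            return 1
        return None

    @property
    def inserted_length(self) -> Optional[int]:
        """Length in bp of the inserted (duplicated) segment."""
        if self.kind in (VariantKind.DUPLICATION, VariantKind.DELINS_DUP):
            a, b = self.alt_allele
            return b - a + 1
        return None


_SNV_RE = re.compile(r"^g\.(\d+)\s*([ACGT])>([ACGT])$")
_DUP_RE = re.compile(r"^g\.(\d+)_(\d+)\s*dup$")
_DEL_RE = re.compile(r"^g\.(\d+)_(\d+)\s*del$")
_DELINS_DUP_RE = re.compile(r"^g\.(\d+)_(\d+)\s*delins\s*(\d+)_(\d+)\s*dup$")


def parse_descriptor(descriptor: str, chromosome: str = "1") -> VariantRecord:
    """Parse an HGVS-style genomic descriptor into a :class:`VariantRecord`.

    Supported forms (whitespace between tokens is tolerated; the canonical
    form emitted by :func:`format_descriptor` has none)::

        g.POS REF>ALT
        g.A_Bdup
        g.A_Bdel
        g.A_BdelinsC_Ddup

    Coordinates are stored 1-based inclusive as printed; derived segment
    lengths are ``end - start + 1``.
    """
    d = descriptor.strip()
    m = _DELINS_DUP_RE.match(d)
    if m:
        a, b, c, e = (int(x) for x in m.groups())
        _check_pair(a, b, d)
        _check_pair(c, e, d)
        return VariantRecord(
            chromosome, a, VariantKind.DELINS_DUP, format_descriptor_delins_dup(a, b, c, e),
            ref_allele=(a, b), alt_allele=(c, e),
        )
    m = _DUP_RE.match(d)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        _check_pair(a, b, d)
        return VariantRecord(
            chromosome, a, VariantKind.DUPLICATION, f"g.{a}_{b}dup",
            ref_allele=(a, b), alt_allele=(a, b),
        )
    m = _DEL_RE.match(d)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        _check_pair(a, b, d)
        return VariantRecord(
            chromosome, a, VariantKind.DELETION, f"g.{a}_{b}del",
            ref_allele=(a, b), alt_allele=None,
        )
    m = _SNV_RE.match(d)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        return VariantRecord(
            chromosome, pos, VariantKind.SNV, f"g.{pos}{ref}>{alt}",
            ref_allele=ref, alt_allele=alt,
        )
    raise ParseError(f"unsupported descriptor grammar: {descriptor!r}")


def _check_pair(a: int, b: int, descriptor: str) -> None:
    if b < a:
        raise ParseError(f"coordinate pair {a}_{b} not ascending in {descriptor!r}")


def format_descriptor_delins_dup(a: int, b: int, c: int, d: int) -> str:
    return f"g.{a}_{b}delins{c}_{d}dup"


def format_descriptor(record: VariantRecord) -> str:
    """Canonical descriptor string; ``parse_descriptor`` round-trips it."""
    return record.descriptor


# ---------------------------------------------------------------------------
# haplotype panel I/O
# ---------------------------------------------------------------------------

DIALECTS = ("phased-vcf", "hapmatrix-tsv")


def read_haplotype_panel(
    path: Union[str, Path],
    dialect: str,
    breed: Optional[str] = None,
    marker_map: Optional[MarkerMap] = None,
) -> HaplotypePanel:
    """Read a phased haplotype panel.

    Parameters
    ----------
    dialect:
        ``"phased-vcf"`` (VCF v4.2, all GT fields phased with ``|``) or
        ``"hapmatrix-tsv"`` (see :func:`write_haplotype_panel`).
    breed:
        Breed label; overrides any label stored in the file.
    marker_map:
        For ``hapmatrix-tsv`` files without position metadata, supplies
        chromosome and positions; otherwise unit-spaced positions on
        chromosome "1" are synthesized.
    """
    path = Path(path)
    if dialect == "phased-vcf":
        return _read_phased_vcf(path, breed)
    if dialect == "hapmatrix-tsv":
        return _read_hapmatrix(path, breed, marker_map)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_haplotype_panel(panel: HaplotypePanel, path: Union[str, Path], dialect: str) -> None:
    path = Path(path)
    if dialect == "phased-vcf":
        _write_phased_vcf(panel, path)
    elif dialect == "hapmatrix-tsv":
        _write_hapmatrix(panel, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _read_phased_vcf(path: Path, breed: Optional[str]) -> HaplotypePanel:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports its own diagnostics
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc
    file_breed = None
    for line in vcf.raw_header.splitlines():
        if line.startswith("##hornmap_breed="):
            file_breed = line.split("=", 1)[1].strip()
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF contains no samples")
    markers, columns = [], []
    for rec_no, v in enumerate(vcf, start=1):
        marker_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        markers.append((v.CHROM, marker_id, v.POS))
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, g in enumerate(v.genotypes):
            if len(g) < 3:
                raise ParseError(
                    f"{path}: record {rec_no} ({marker_id}): haploid or missing GT"
                )
            a, b, phased = g[0], g[1], g[-1]
            if not phased and not (a == b or a < 0 or b < 0):
                raise PhasingError(
                    f"{path}: record {rec_no} ({marker_id}): unphased genotype "
                    f"for sample {samples[i]!r}"
                )
            col[2 * i] = MISSING if a < 0 else a
            col[2 * i + 1] = MISSING if b < 0 else b
        columns.append(col)
    if not markers:
        raise ParseError(f"{path}: VCF contains no variant records")
    chroms = {c for c, _, _ in markers}
    if len(chroms) != 1:
        raise ParseError(f"{path}: expected a single chromosome, found {sorted(chroms)}")
    mm = MarkerMap(markers[0][0], tuple((mid, pos) for _, mid, pos in markers))
    mat = np.stack(columns, axis=1)
    return HaplotypePanel(breed or file_breed or "unknown", mm, mat, samples)


def _write_phased_vcf(panel: HaplotypePanel, path: Path) -> None:
    mm = panel.marker_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={mm.chromosome}>\n")
        fh.write(f"##hornmap_breed={panel.breed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.individual_ids)
            + "\n"
        )
        H = panel.haplotypes
        for j, (mid, pos) in enumerate(mm.markers):
            gts = []
            for i in range(panel.n_individuals):
                a, b = H[2 * i, j], H[2 * i + 1, j]
                gts.append(
                    f"{'.' if a == MISSING else int(a)}|{'.' if b == MISSING else int(b)}"
                )
            fh.write(
                f"{mm.chromosome}\t{pos}\t{mid}\tA\tC\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _write_hapmatrix(panel: HaplotypePanel, path: Path) -> None:
    mm = panel.marker_map
    with open(path, "w") as fh:
        fh.write(f"#chromosome={mm.chromosome}\n")
        fh.write("#positions=" + "\t".join(str(p) for _, p in mm.markers) + "\n")
        fh.write(f"#breed={panel.breed}\n")
        fh.write("individual_id\tphase\t" + "\t".join(mm.marker_ids) + "\n")
        H = panel.haplotypes
        for i, ind in enumerate(panel.individual_ids):
            for phase, row in (("A", H[2 * i]), ("B", H[2 * i + 1])):
                alleles = "\t".join("." if a == MISSING else str(int(a)) for a in row)
                fh.write(f"{ind}\t{phase}\t{alleles}\n")


def _read_hapmatrix(
    path: Path, breed: Optional[str], marker_map: Optional[MarkerMap]
) -> HaplotypePanel:
    chrom, positions, file_breed = None, None, None
    rows, ids_in_order = [], []
    header = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#chromosome="):
                chrom = line.split("=", 1)[1]
                continue
            if line.startswith("#positions="):
                positions = [int(x) for x in line.split("=", 1)[1].split("\t")]
                continue
            if line.startswith("#breed="):
                file_breed = line.split("=", 1)[1]
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:2] != ["individual_id", "phase"]:
                    raise ParseError(
                        f"{path}:{line_no}: header must start with "
                        "'individual_id\\tphase'"
                    )
                header = fields[2:]
                continue
            if len(fields) != len(header) + 2:
                raise ParseError(
                    f"{path}:{line_no}: expected {len(header) + 2} fields, "
                    f"got {len(fields)}"
                )
            ind, phase = fields[0], fields[1]
            if phase not in ("A", "B"):
                raise ParseError(f"{path}:{line_no}: phase must be A or B, got {phase!r}")
            try:
                alleles = [MISSING if a == "." else int(a) for a in fields[2:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: bad allele code: {exc}") from exc
            if any(a not in (0, 1, MISSING) for a in alleles):
                raise ParseError(f"{path}:{line_no}: allele codes must be 0, 1 or '.'")
            rows.append((ind, phase, alleles))
            if ind not in ids_in_order:
                ids_in_order.append(ind)
    if header is None or not rows:
        raise ParseError(f"{path}: no haplotype rows found")
    by_ind = {}
    for ind, phase, alleles in rows:
        by_ind.setdefault(ind, {})[phase] = alleles
    mat_rows = []
    for ind in ids_in_order:
        phases = by_ind[ind]
        if set(phases) != {"A", "B"}:
            raise ParseError(f"{path}: individual {ind!r} lacks one of phases A/B")
        mat_rows.append(phases["A"])
        mat_rows.append(phases["B"])
    mat = np.array(mat_rows, dtype=np.uint8)
    if marker_map is not None:
        mm = marker_map
        if mm.n_markers != len(header):
            raise ParseError(
                f"{path}: marker_map has {mm.n_markers} markers, file has {len(header)}"
            )
    else:
        if positions is None:
            positions = list(range(1, len(header) + 1))
        mm = MarkerMap(chrom or "1", tuple(zip(header, positions)))
    return HaplotypePanel(breed or file_breed or "unknown", mm, mat, ids_in_order)


# ---------------------------------------------------------------------------
# tabular I/O: pedigree, phenotypes, variant tables, genotype calls, BED
# ---------------------------------------------------------------------------


def read_pedigree(path: Union[str, Path]) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"individual", "sire", "dam", "breed"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: pedigree needs columns {sorted(needed)}")
    recs = [
        PedigreeRecord(
            r.individual,
            r.sire if r.sire not in ("", ".", "0") else None,
            r.dam if r.dam not in ("", ".", "0") else None,
            r.breed,
        )
        for r in df.itertuples()
    ]
    check_pedigree(recs)
    return recs


def write_pedigree(records: Iterable[PedigreeRecord], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "individual": r.individual,
                "sire": r.sire or ".",
                "dam": r.dam or ".",
                "breed": r.breed,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: Union[str, Path]) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"individual", "status", "validated"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: phenotype table needs columns {sorted(needed)}")
    return [
        PhenotypeRecord(r.individual, HornStatus(r.status), r.validated in ("1", "true", "True"))
        for r in df.itertuples()
    ]


def write_phenotypes(records: Iterable[PhenotypeRecord], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "individual": r.individual,
                "status": r.horn_status.value,
                "validated": int(r.validated),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_variant_table(path: Union[str, Path]) -> list:
    """Read a VCF-like TSV (CHROM, POS, ID, REF, ALT[, KIND, DESCRIPTOR])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"CHROM", "POS", "REF", "ALT"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: variant table needs columns {sorted(needed)}")
    out = []
    for r in df.itertuples():
        desc = getattr(r, "DESCRIPTOR", "")
        if desc:
            rec = parse_descriptor(desc, chromosome=r.CHROM)
        else:
            rec = VariantRecord(
                r.CHROM,
                int(r.POS),
                VariantKind.SNV,
                f"g.{int(r.POS)}{r.REF}>{r.ALT}",
                ref_allele=r.REF,
                alt_allele=r.ALT,
            )
        out.append(rec)
    return out


def write_variant_table(records: Iterable[VariantRecord], path: Union[str, Path]) -> None:
    rows = []
    for v in records:
        snv = v.kind == VariantKind.SNV
        rows.append(
            {
                "CHROM": v.chromosome,
                "POS": v.position_bp,
                "ID": ".",
                "REF": v.ref_allele if snv else ".",
                "ALT": v.alt_allele if snv else ".",
                "KIND": v.kind.value,
                "DESCRIPTOR": v.descriptor,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_calls(path: Union[str, Path]) -> pd.DataFrame:
    """Genotype-call table: columns variant (descriptor), individual,
    genotype in {0/0, 0/1, 1/1, ./.}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"variant", "individual", "genotype"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: genotype table needs columns {sorted(needed)}")
    return df


def write_genotype_calls(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, Path], names=None) -> None:
    intervals = list(intervals)
    names = list(names) if names is not None else ["."] * len(intervals)
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(iv.to_bed_line(name) + "\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QCConfig:
    """Thresholds for marker/sample quality control.

    Defaults follow standard SNP-array practice for this kind of study:
    marker call rate 0.90, sample call rate 0.95, within-breed HWE
    chi-square (1 df) at alpha 1e-4, monomorphic markers removed,
    Mendelian-inconsistent calls set to missing.
    """

    marker_call_rate: float = 0.90
    sample_call_rate: float = 0.95
    hwe_alpha: float = 1e-4
    remove_monomorphic: bool = True


@dataclass
class QCReport:
    """Audit of every QC removal/edit, in application order."""

    entries: list = field(default_factory=list)

    def add(self, kind: str, target: str, reason: str, value=None):
        self.entries.append(
            {"kind": kind, "target": target, "reason": reason, "value": value}
        )

    def removed_samples(self) -> list:
        return [e["target"] for e in self.entries if e["kind"] == "sample"]

    def removed_markers(self) -> list:
        return [e["target"] for e in self.entries if e["kind"] == "marker"]

    def mendelian_edits(self) -> list:
        return [e for e in self.entries if e["kind"] == "mendelian"]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["kind", "target", "reason", "value"])


def qc_filter(
    panel: HaplotypePanel,
    pedigree: Sequence[PedigreeRecord] = (),
    thresholds: Optional[QCConfig] = None,
) -> tuple:
    """Apply sample/marker QC to a (single-breed) panel.

    Order of operations: (1) samples below the sample call rate are removed
    (call rate over the input marker set); (2) Mendelian-inconsistent
    genotype calls, given the pedigree, are set to missing; (3) markers below
    the marker call rate, monomorphic markers, and markers deviating from
    Hardy-Weinberg equilibrium within the breed (chi-square, 1 df) are
    removed.  Mendelian edits precede call-rate evaluation so that the filter
    is idempotent.

    Returns ``(filtered_panel, QCReport)``; raises
    :class:`DegenerateInputError` if nothing survives.
    """
    cfg = thresholds or QCConfig()
    report = QCReport()
    current = panel
    for _ in range(20):  # to a fixed point: each filter can re-trigger the others
        current, changed = _qc_pass(current, pedigree, cfg, report)
        if not changed:
            break
    return current, report


def _qc_pass(
    panel: HaplotypePanel,
    pedigree: Sequence[PedigreeRecord],
    cfg: QCConfig,
    report: QCReport,
) -> tuple:
    changed = False
    H = panel.haplotypes.copy()
    ids = list(panel.individual_ids)

    # -- sample call rate (genotype-level: both alleles called)
    called = (H[0::2] != MISSING) & (H[1::2] != MISSING)
    rate = called.mean(axis=1)
    keep = rate >= cfg.sample_call_rate
    for i in np.flatnonzero(~keep):
        report.add("sample", ids[i], "sample_call_rate", float(rate[i]))
        changed = True
    row_keep = np.repeat(keep, 2)
    H = H[row_keep]
    ids = [s for s, k in zip(ids, keep) if k]
    if not ids:
        raise DegenerateInputError("no samples survive the sample call-rate filter")

    # -- Mendelian consistency: offspring must share >=1 allele with each
    #    genotyped parent; violations are set to missing on the offspring
    ped_by_ind = {r.individual: r for r in pedigree}
    index = {s: i for i, s in enumerate(ids)}
    for child, rec in ped_by_ind.items():
        if child not in index:
            continue
        ci = index[child]
        for parent in (rec.sire, rec.dam):
            if parent is None or parent not in index:
                continue
            pi = index[parent]
            ca, cb = H[2 * ci].astype(np.int16), H[2 * ci + 1].astype(np.int16)
            pa, pb = H[2 * pi].astype(np.int16), H[2 * pi + 1].astype(np.int16)
            full = (ca != MISSING) & (cb != MISSING) & (pa != MISSING) & (pb != MISSING)
            shares = (ca == pa) | (ca == pb) | (cb == pa) | (cb == pb)
            bad = full & ~shares
            for j in np.flatnonzero(bad):
                report.add(
                    "mendelian",
                    child,
                    f"inconsistent_with_{parent}",
                    panel.marker_map.marker_ids[j],
                )
                changed = True
            H[2 * ci, bad] = MISSING
            H[2 * ci + 1, bad] = MISSING

    # -- marker filters
    a, b = H[0::2], H[1::2]
    full = (a != MISSING) & (b != MISSING)
    call_rate = full.mean(axis=0)
    marker_keep = np.ones(H.shape[1], dtype=bool)
    mids = panel.marker_map.marker_ids
    for j in np.flatnonzero(call_rate < cfg.marker_call_rate):
        marker_keep[j] = False
        report.add("marker", mids[j], "marker_call_rate", float(call_rate[j]))
    for j in np.flatnonzero(marker_keep):
        col = H[:, j]
        obs = col[col != MISSING]
        if cfg.remove_monomorphic and (obs.size == 0 or np.all(obs == obs[0])):
            marker_keep[j] = False
            report.add("marker", mids[j], "monomorphic", None)
            continue
        p = _hwe_pvalue(a[:, j], b[:, j], full[:, j])
        if p is not None and p < cfg.hwe_alpha:
            marker_keep[j] = False
            report.add("marker", mids[j], "hwe", float(p))
    if not marker_keep.any():
        raise DegenerateInputError("no markers survive the marker filters")
    if not marker_keep.all():
        changed = True

    mm = MarkerMap(
        panel.marker_map.chromosome,
        tuple(m for m, k in zip(panel.marker_map.markers, marker_keep) if k),
    )
    return HaplotypePanel(panel.breed, mm, H[:, marker_keep], ids), changed


def harmonize_panels(panels: Sequence[HaplotypePanel]) -> list:
    """Subset panels to the markers present in all of them.

    Per-breed QC can remove different markers in different breeds; analyses
    that compare panels (the sweep scan, IBD lookups) require one shared
    marker map, so the union dataset keeps only markers surviving QC in
    every breed.
    """
    if not panels:
        return []
    common = set(panels[0].marker_map.marker_ids)
    for p in panels[1:]:
        common &= set(p.marker_map.marker_ids)
    out = []
    for p in panels:
        keep = [j for j, mid in enumerate(p.marker_map.marker_ids) if mid in common]
        mm = MarkerMap(
            p.marker_map.chromosome, tuple(p.marker_map.markers[j] for j in keep)
        )
        out.append(HaplotypePanel(p.breed, mm, p.haplotypes[:, keep], list(p.individual_ids)))
    return out


def drop_dataset_monomorphic(panels: Sequence[HaplotypePanel]) -> tuple:
    """Remove markers monomorphic over the whole dataset (all panels pooled).

    Within-breed monomorphism is common and expected under drift; only a
    marker carrying a single allele across every breed is uninformative for
    cross-breed analyses.  Panels must share a marker map (see
    :func:`harmonize_panels`).  Returns ``(panels, removed_marker_ids)``.
    """
    if not panels:
        return [], []
    mm = panels[0].marker_map
    stacked = np.concatenate([p.haplotypes for p in panels], axis=0)
    keep = np.ones(mm.n_markers, dtype=bool)
    removed = []
    for j in range(mm.n_markers):
        col = stacked[:, j]
        obs = col[col != MISSING]
        if obs.size == 0 or np.all(obs == obs[0]):
            keep[j] = False
            removed.append(mm.marker_ids[j])
    if keep.all():
        return list(panels), []
    new_mm = MarkerMap(mm.chromosome, tuple(m for m, k in zip(mm.markers, keep) if k))
    out = [
        HaplotypePanel(p.breed, new_mm, p.haplotypes[:, keep], list(p.individual_ids))
        for p in panels
    ]
    return out, removed


def _hwe_pvalue(a_col: np.ndarray, b_col: np.ndarray, full: np.ndarray) -> Optional[float]:
    """Chi-square (1 df) Hardy-Weinberg test on diploid genotype counts;
    None when the test is undefined (monomorphic or empty)."""
    g = a_col[full].astype(np.int16) + b_col[full].astype(np.int16)
    n = g.size
    if n == 0:
        return None
    n0, n1, n2 = int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2))
    p = (2 * n0 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return None
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))
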