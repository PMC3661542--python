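"""End-to-end pipeline: simulate → qc → scan → ibd → map → prioritize.

A single :class:`PipelineConfig` carries every threshold and scenario; the
global seed is expanded into independent per-stage substreams so stages can
be re-run in isolation yet reproducibly.  Each stage writes its artifact
under the output directory and appends a log entry with the artifact's
SHA-256, and a failure halts the run with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .errors import HornmapError
from .formats_io import (
    GenomicInterval,
    HornStatus,
    QCConfig,
    drop_dataset_monomorphic,
    harmonize_panels,
    qc_filter,
    write_bed,
    write_genotype_calls,
    write_haplotype_panel,
    write_pedigree,
    write_phenotypes,
    write_variant_table,
)
from .ibd_mapping import haplotype_frequency_in_panels, shared_segment
from .recomb_mapping import detect_recombinants, discover_founder_haplotypes, refine_interval
from .sweep_scan import scan
from .synthetic_data import (
    PedigreeScenario,
    SweepScenario,
    VariantScenario,
    simulate_breed_panels,
    simulate_homozygous_carriers,
    simulate_pedigree,
    simulate_variant_catalogs,
)
from .variant_prioritization import concordance_filter, subtract_controls


class StageError(HornmapError):
    """A pipeline stage failed; the message names the stage and the cause."""


class PipelineConfig(BaseModel):
    """All pipeline knobs in one serializable object.

    Scenario sizes default to a compact demonstration design that runs in
    seconds; thresholds default to the study values (79-marker windows,
    unit step, mean+4SD flag, 0.90/0.95 call rates, minimum ten progeny per
    sire, minimum two concordant carriers).
    """

    seed: int = 0
    out_dir: str = "hornmap_run"

    # stage toggles
    run_qc: bool = True
    run_scan: bool = True
    run_ibd: bool = True
    run_map: bool = True
    run_prioritize: bool = True

    # thresholds
    window_width: int = Field(default=79, ge=1)
    window_step: int = Field(default=1, ge=1)
    k: float = Field(default=4.0, gt=0)
    marker_call_rate: float = Field(default=0.90, ge=0, le=1)
    sample_call_rate: float = Field(default=0.95, ge=0, le=1)
    hwe_alpha: float = Field(default=1e-4, gt=0, le=1)
    min_progeny_per_sire: int = Field(default=10, ge=1)
    min_concordant_carriers: int = Field(default=2, ge=1)
    min_affected_carriers: int = Field(default=2, ge=1)
    n_homozygous_carriers: int = Field(default=15, ge=1)

    # scenarios (seeds are overwritten from the global seed)
    sweep: SweepScenario = SweepScenario(
        n_breeds=6, haplotypes_per_breed=60, n_markers=300, sweep_window=(140, 79)
    )
    pedigree: PedigreeScenario = PedigreeScenario(
        n_founders_polled=5, n_founders_horned=3, progeny_per_sire=25
    )
    variants: VariantScenario = VariantScenario(
        interval=("1", 1, 1_000_000),  # superseded by the mapped interval
        n_case_variants=200,
        n_shared_with_controls=187,
        n_controls=10,
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


@dataclass
class PipelineReport:
    artifacts: Dict[str, str] = field(default_factory=dict)
    log: List[dict] = field(default_factory=list)
    scan_summary: Optional[object] = None
    ibd_segment: Optional[object] = None
    ibd_frequencies: Optional[dict] = None
    mapping: Optional[object] = None
    final_candidates: Optional[list] = None
    truth: Optional[object] = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _substream_seeds(seed: int, n: int) -> List[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()

    def record(stage: str, name: str, path: Path):
        report.artifacts[name] = str(path)
        report.log.append({"stage": stage, "artifact": str(path), "sha256": _sha256(path)})

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except HornmapError as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return deco

    sweep_seed, ped_seed, var_seed = _substream_seeds(config.seed, 3)

    # ---- simulate ---------------------------------------------------------
    @stage("simulate")
    def _simulate():
        sweep = config.sweep.model_copy(update={"seed": sweep_seed})
        panels = simulate_breed_panels(sweep)
        panel_dir = out / "panels"
        panel_dir.mkdir(exist_ok=True)
        for p in panels:
            path = panel_dir / f"{p.breed}.hapmatrix.tsv"
            write_haplotype_panel(p, path, "hapmatrix-tsv")
            record("simulate", f"panel_{p.breed}", path)
        ped_scenario = config.pedigree.model_copy(update={"seed": ped_seed})
        pedigree, ped_panel, phenotypes, truth = simulate_pedigree(ped_scenario, panels)
        write_haplotype_panel(ped_panel, out / "pedigree_panel.hapmatrix.tsv", "hapmatrix-tsv")
        write_pedigree(pedigree, out / "pedigree.tsv")
        write_phenotypes(phenotypes, out / "phenotypes.tsv")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "causal_position_bp": truth.causal_position_bp,
                    "causal_founders": truth.causal_founders,
                    "n_breakpoints": sum(len(b) for b in truth.breakpoints.values()),
                },
                indent=2,
            )
        )
        for name in ("pedigree_panel.hapmatrix.tsv", "pedigree.tsv", "phenotypes.tsv", "truth.json"):
            record("simulate", name, out / name)
        report.truth = truth
        return sweep, ped_scenario, panels, pedigree, ped_panel, phenotypes, truth

    sweep_sc, ped_sc, panels, pedigree, ped_panel, phenotypes, truth = _simulate

    # ---- qc ---------------------------------------------------------------
    if config.run_qc:
        @stage("qc")
        def _qc():
            # per-breed QC without monomorphism removal, then dataset-level
            # monomorphism on the harmonized marker set
            cfg = QCConfig(
                marker_call_rate=config.marker_call_rate,
                sample_call_rate=config.sample_call_rate,
                hwe_alpha=config.hwe_alpha,
                remove_monomorphic=False,
            )
            cleaned, frames = [], []
            for p in panels:
                q, rep = qc_filter(p, pedigree=(), thresholds=cfg)
                cleaned.append(q)
                df = rep.to_dataframe()
                if not df.empty:
                    df.insert(0, "breed", p.breed)
                    frames.append(df)
            cleaned = harmonize_panels(cleaned)
            cleaned, mono = drop_dataset_monomorphic(cleaned)
            frames.append(
                pd.DataFrame(
                    [
                        {"breed": "ALL", "kind": "marker", "target": m,
                         "reason": "monomorphic_dataset", "value": None}
                        for m in mono
                    ],
                    columns=["breed", "kind", "target", "reason", "value"],
                )
            )
            frames = [f for f in frames if not f.empty]
            qc_df = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=["breed", "kind", "target", "reason", "value"])
            )
            qc_df.to_csv(out / "qc_report.tsv", sep="\t", index=False)
            record("qc", "qc_report.tsv", out / "qc_report.tsv")
            return cleaned

        panels = _qc

    # ---- scan -------------------------------------------------------------
    if config.run_scan:
        @stage("scan")
        def _scan():
            summary = scan(panels, width=config.window_width, step=config.window_step, k=config.k)
            summary.to_dataframe().to_csv(out / "scan.tsv", sep="\t", index=False)
            record("scan", "scan.tsv", out / "scan.tsv")
            return summary

        report.scan_summary = _scan

    # ---- ibd --------------------------------------------------------------
    if config.run_ibd:
        @stage("ibd")
        def _ibd():
            hom_sc = ped_sc.model_copy(
                update={"causal_position_bp": truth.causal_position_bp}
            )
            hom_panel, _ = simulate_homozygous_carriers(
                hom_sc, panels, n_carriers=config.n_homozygous_carriers, seed=ped_seed + 1
            )
            positions = hom_panel.marker_map.positions_bp
            anchor = int(np.argmin(np.abs(positions - truth.causal_position_bp)))
            seg = shared_segment(hom_panel.haplotypes, hom_panel.marker_map, anchor=anchor)
            if seg is None:
                raise HornmapError("homozygous carriers share no segment at the anchor")
            freqs = haplotype_frequency_in_panels(seg, panels)
            write_bed([seg.bp_span], out / "ibd_segment.bed", names=["shared_segment"])
            record("ibd", "ibd_segment.bed", out / "ibd_segment.bed")
            pd.DataFrame(
                [{"breed": b, "frequency": f} for b, f in sorted(freqs.items())]
            ).to_csv(out / "ibd_frequencies.tsv", sep="\t", index=False)
            record("ibd", "ibd_frequencies.tsv", out / "ibd_frequencies.tsv")
            return seg, freqs

        report.ibd_segment, report.ibd_frequencies = _ibd

    # ---- map --------------------------------------------------------------
    mapped_interval: Optional[GenomicInterval] = None
    if config.run_map:
        @stage("map")
        def _map():
            pheno = {p.individual: p for p in phenotypes}
            founder_ids = [r.individual for r in pedigree if r.sire is None]
            aff = [i for i in founder_ids if pheno[i].horn_status == HornStatus.POLLED]
            unaff = [i for i in founder_ids if pheno[i].horn_status == HornStatus.HORNED]
            aff_panel = _subset_panel(ped_panel, aff)
            unaff_panel = _subset_panel(ped_panel, unaff)
            founder_haps = discover_founder_haplotypes(
                aff_panel, unaff_panel, min_affected_carriers=config.min_affected_carriers
            )
            if not founder_haps:
                raise HornmapError("no founder haplotype shared by enough affected founders")
            fh = founder_haps[0]
            detection = detect_recombinants(
                fh, ped_panel, pedigree, phenotypes,
                min_progeny_per_sire=config.min_progeny_per_sire,
            )
            mapping = refine_interval(
                fh, detection.observations,
                min_concordant_carriers=config.min_concordant_carriers,
            )
            write_bed([mapping.interval], out / "interval.bed", names=["polled_interval"])
            record("map", "interval.bed", out / "interval.bed")
            pd.DataFrame(
                [
                    {
                        "descendant": o.descendant,
                        "breakpoint_left": o.breakpoint[0],
                        "breakpoint_right": o.breakpoint[1],
                        "retained_side": o.retained_side,
                        "phenotype": o.phenotype.horn_status.value,
                    }
                    for o in detection.observations
                ]
            ).to_csv(out / "recombinants.tsv", sep="\t", index=False)
            record("map", "recombinants.tsv", out / "recombinants.tsv")
            return mapping

        report.mapping = _map
        mapped_interval = report.mapping.interval

    # ---- prioritize -------------------------------------------------------
    if config.run_prioritize:
        @stage("prioritize")
        def _prioritize():
            if mapped_interval is not None:
                iv = (
                    mapped_interval.chromosome,
                    mapped_interval.start_1based,
                    mapped_interval.end_1based,
                )
            else:
                iv = config.variants.interval
            var_sc = config.variants.model_copy(update={"seed": var_seed, "interval": iv})
            catalogs = simulate_variant_catalogs(var_sc)
            write_variant_table(catalogs.case_variants, out / "case_variants.tsv")
            write_genotype_calls(catalogs.genotype_table, out / "genotypes.tsv")
            subtracted = subtract_controls(
                catalogs.case_variants, catalogs.control_variant_sets,
                interval=var_sc.genomic_interval,
            )
            final, reports = concordance_filter(
                subtracted, catalogs.genotype_table, catalogs.phenotypes
            )
            write_variant_table(final.variants, out / "final_candidates.tsv")
            final.audit_dataframe().to_csv(out / "prioritization_audit.tsv", sep="\t", index=False)
            for name in (
                "case_variants.tsv", "genotypes.tsv", "final_candidates.tsv",
                "prioritization_audit.tsv",
            ):
                record("prioritize", name, out / name)
            return final.variants

        report.final_candidates = _prioritize

    pd.DataFrame(report.log).to_csv(out / "log.tsv", sep="\t", index=False)
    return report


def _subset_panel(panel, individuals):
    from .formats_io import HaplotypePanel

    idx = [panel.individual_ids.index(i) for i in individuals]
    rows = [r for i in idx for r in (2 * i, 2 * i + 1)]
    return HaplotypePanel(
        panel.breed, panel.marker_map, panel.haplotypes[rows], list(individuals)
    )
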