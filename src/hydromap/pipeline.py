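"""End-to-end orchestration: QC -> association scan -> shared homozygosity
-> pileup calling -> recessive concordance -> LD, with per-stage outputs.

The pipeline consumes PED/MAP genotypes (plus sidecars) and optionally a
pileup TSV; when no genotype input is configured it simulates a founder
population from the embedded generator, in which case the simulation truth
is used to derive pileups over the top candidate region.  Every output
file records the package version, seed and thresholds in its header.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml

from . import __version__, association, io as hio, popgen, qc, roh, variants
from .datatypes import GenotypeMatrix
from .simulate import SimulationConfig, TruthRecord, simulate_population, simulate_pileups
from .variants import CallerThresholds, VariantCall

log = logging.getLogger("hydromap")

PathLike = Union[str, Path]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    # inputs; when ped_path is None a population is simulated
    ped_path: Optional[str] = None
    map_path: Optional[str] = None
    alleles_path: Optional[str] = None
    phenotypes_path: Optional[str] = None
    pileup_path: Optional[str] = None
    cds_fasta_path: Optional[str] = None

    # thresholds
    maf_min: float = 0.05
    marker_cr_min: float = 0.90
    sample_cr_min: float = 0.90
    alpha: float = 0.05
    min_run_markers: int = 3
    caller: CallerThresholds = field(default_factory=CallerThresholds)
    het_band: Tuple[float, float] = (0.15, 0.85)

    # simulation fallback + reproducibility
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mean_depth: float = 216.0
    base_error_rate: float = 0.01
    seed: int = 0

    out_dir: str = "hydromap_out"

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        caller = CallerThresholds(**raw.pop("caller", {}))
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "het_band" in raw:
            raw["het_band"] = tuple(raw["het_band"])
        cfg = cls(caller=caller, simulation=sim, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name, lo, hi in (
            ("maf_min", 0.0, 0.5),
            ("marker_cr_min", 0.0, 1.0),
            ("sample_cr_min", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_run_markers < 1:
            raise ValueError("min_run_markers must be >= 1")


@dataclass
class PipelineReport:
    """Machine-readable summary of one run."""

    seed: int
    n_markers_in: int
    n_markers_qc: int
    n_samples_qc: int
    bonferroni_threshold: float
    n_significant: int
    top_marker_id: Optional[str]
    top_marker_p: Optional[float]
    top_region: Optional[roh.SharedRegion]
    n_variants_called: int
    n_concordant: int
    concordant_variants: List[VariantCall]
    ld_top_pair_r2: Optional[float]
    simulated: bool
    truth_locus_in_top_region: Optional[bool]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage in order and write per-stage outputs.

    Returns the summary report; a run is considered successful for
    screening purposes when at least one concordant variant survives
    (the CLI maps this to the exit status).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth: Optional[TruthRecord] = None
    simulated = config.ped_path is None
    if simulated:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        gm, truth = simulate_population(sim_cfg)
        hio.write_ped_map(gm, out / "simulated")
        log.info("simulated %d samples x %d markers", gm.n_samples, gm.n_markers)
    else:
        if config.map_path is None:
            raise ValueError("map_path is required with ped_path")
        gm = hio.read_ped_map(
            config.ped_path,
            config.map_path,
            config.alleles_path,
            config.phenotypes_path,
        )

    # QC -----------------------------------------------------------------
    gm_qc, report = qc.apply_qc(
        gm, config.maf_min, config.marker_cr_min, config.sample_cr_min
    )
    log.info(
        "QC: %d -> %d markers (%.1f%% retained), %d samples removed",
        report.n_markers_in,
        report.n_markers_out,
        100 * report.fraction_retained,
        report.n_samples_removed,
    )
    with open(out / "qc_report.tsv", "w") as fh:
        fh.write(f"# hydromap {__version__}; seed={config.seed}\n")
        fh.write("metric\tvalue\n")
        fh.write(f"n_markers_in\t{report.n_markers_in}\n")
        fh.write(f"n_markers_out\t{report.n_markers_out}\n")
        fh.write(f"fraction_retained\t{report.fraction_retained:.4f}\n")
        fh.write(f"n_failed_maf\t{report.n_failed_maf}\n")
        fh.write(f"n_failed_callrate\t{report.n_failed_callrate}\n")
        fh.write(f"n_samples_removed\t{report.n_samples_removed}\n")

    # association scan ----------------------------------------------------
    results, threshold = association.scan(gm_qc, alpha=config.alpha)
    mtable = association.manhattan_table(results)
    with open(out / "association.tsv", "w") as fh:
        fh.write(
            f"# hydromap {__version__}; seed={config.seed}; alpha={config.alpha}; "
            f"bonferroni={threshold:.6g}\n"
        )
        mtable.to_csv(fh, sep="\t", index=False)
    significant = [r for r in results if r.significant]
    top = min(results, key=lambda r: r.p_chi2) if results else None
    log.info(
        "scan: %d/%d markers significant at %.3g",
        len(significant),
        len(results),
        threshold,
    )

    # shared homozygosity: only the associated region is examined ----------
    top_region = None
    regions: List[roh.SharedRegion] = []
    if significant and len(gm_qc.case_ids) >= 2:
        top_sig = min(significant, key=lambda r: r.p_chi2)
        window = _window_around(gm_qc, top_sig, half_width_bp=15_000_000)
        regions = roh.rank_regions(
            roh.shared_homozygous_regions(
                gm_qc, region_of_interest=window, min_markers=config.min_run_markers
            )
        )
    hio.write_regions(regions, out / "shared_regions.tsv", seed=config.seed)
    if regions:
        top_region = regions[0]
        coded = roh.genotype_matrix_codes(gm_qc, top_region)
        with open(out / "region_genotypes.tsv", "w") as fh:
            fh.write(f"# hydromap {__version__}; seed={config.seed}\n")
            coded.to_csv(fh, sep="\t")

    # pileup calling + concordance ----------------------------------------
    calls: List[VariantCall] = []
    concordant: List[VariantCall] = []
    if config.pileup_path is not None:
        pileups = hio.read_pileups(config.pileup_path)
    elif simulated and truth is not None and top_region is not None:
        idx = [
            j
            for j, m in enumerate(truth.positions_bp)
            if top_region.start_bp <= m <= top_region.end_bp
        ]
        pileups = simulate_pileups(
            truth,
            idx,
            mean_depth=config.mean_depth,
            base_error_rate=config.base_error_rate,
            seed=config.seed + 1,
        )
    else:
        pileups = []
    if pileups:
        calls = variants.call_variants(pileups, config.caller, config.het_band)
        case_ids = [s for s in gm_qc.case_ids]
        control_ids = [s for s in gm_qc.control_ids]
        concordant = variants.concordance_filter(calls, case_ids, control_ids)
        hio.write_vcf(
            calls,
            gm_qc.sample_ids,
            out / "variants.vcf",
            seed=config.seed,
            thresholds_desc=str(config.caller),
        )
        log.info("caller: %d sites, %d concordant", len(calls), len(concordant))

    # LD -------------------------------------------------------------------
    ld_r2_val = None
    if top is not None and top_region is not None:
        ld_r2_val = _ld_top_pair(gm_qc, top, top_region)

    truth_hit = None
    if truth is not None and top_region is not None:
        truth_hit = top_region.contains(truth.disease_position_bp)

    report_out = PipelineReport(
        seed=config.seed,
        n_markers_in=report.n_markers_in,
        n_markers_qc=report.n_markers_out,
        n_samples_qc=gm_qc.n_samples,
        bonferroni_threshold=threshold,
        n_significant=len(significant),
        top_marker_id=top.marker_id if top else None,
        top_marker_p=top.p_chi2 if top else None,
        top_region=top_region,
        n_variants_called=len(calls),
        n_concordant=len(concordant),
        concordant_variants=concordant,
        ld_top_pair_r2=ld_r2_val,
        simulated=simulated,
        truth_locus_in_top_region=truth_hit,
    )
    _write_summary(report_out, config, out / "summary.tsv")
    return report_out


def _window_around(
    gm: GenotypeMatrix, top: association.AssociationResult, half_width_bp: int
) -> Tuple[str, int, int]:
    return (
        top.chromosome,
        max(1, top.position_bp - half_width_bp),
        top.position_bp + half_width_bp,
    )


def _ld_top_pair(
    gm: GenotypeMatrix,
    top: association.AssociationResult,
    region: roh.SharedRegion,
) -> Optional[float]:
    """r^2 between the top associated marker and the region's central marker."""
    j_top = gm.marker_index(top.marker_id)
    mid = (region.start_index + region.end_index) // 2
    if mid == j_top:
        mid = region.start_index if j_top != region.start_index else region.end_index
        if mid == j_top:
            return None
    try:
        res = popgen.ld_r2(
            gm.genotypes[:, j_top],
            gm.genotypes[:, mid],
            locus_a=top.marker_id,
            locus_b=gm.markers[mid].marker_id,
        )
    except ValueError:
        return None
    return res.r2


def _write_summary(rep: PipelineReport, config: PipelineConfig, path: Path) -> None:
    lines = [
        f"# hydromap {__version__}; seed={rep.seed}; alpha={config.alpha}; "
        f"maf_min={config.maf_min}; marker_cr_min={config.marker_cr_min}; "
        f"sample_cr_min={config.sample_cr_min}; caller={config.caller}",
        "key\tvalue",
        f"n_markers_in\t{rep.n_markers_in}",
        f"n_markers_qc\t{rep.n_markers_qc}",
        f"n_samples_qc\t{rep.n_samples_qc}",
        f"bonferroni_threshold\t{rep.bonferroni_threshold:.6g}",
        f"n_significant\t{rep.n_significant}",
        f"top_marker\t{rep.top_marker_id}",
        f"top_marker_p\t{rep.top_marker_p if rep.top_marker_p is None else format(rep.top_marker_p, '.6g')}",
    ]
    if rep.top_region is not None:
        r = rep.top_region
        lines += [
            f"top_region\t{r.chromosome}:{r.start_bp}-{r.end_bp}",
            f"top_region_length_mb\t{roh.region_length_mb(r.start_bp, r.end_bp)}",
            f"top_region_controls_sharing\t{r.n_controls_sharing}",
        ]
    lines += [
        f"n_variants_called\t{rep.n_variants_called}",
        f"n_concordant\t{rep.n_concordant}",
    ]
    for v in rep.concordant_variants:
        lines.append(f"concordant_variant\t{v.chromosome}:{v.position_bp} {v.ref_base}>{v.alt_base}")
    if rep.ld_top_pair_r2 is not None:
        lines.append(f"ld_top_pair_r2\t{rep.ld_top_pair_r2:.4f}")
    if rep.truth_locus_in_top_region is not None:
        lines.append(f"truth_locus_in_top_region\t{rep.truth_locus_in_top_region}")
    path.write_text("\n".join(lines) + "\n")
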