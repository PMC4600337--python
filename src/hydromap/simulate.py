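"""Synthetic founder-effect populations segregating a recessive lethal allele.

The generator emulates an inbred closed breed in which all affected animals
descend from a single founder: cases are homozygous by descent for a long
chromosomal segment around the disease locus, obligate carriers (dams of
cases) carry exactly one copy of the founder haplotype, and unrelated
controls may carry one copy at the population carrier frequency but are
never homozygous for it.  SNP-array genotyping error and missingness are
layered on top, and read pileups consistent with the underlying genotypes
can be derived for any subset of sites.

Defaults mirror a mapping study of a perinatally lethal recessive disorder:
13 cases, 69 controls, 17 obligate-carrier dams, ~44 kb marker spacing,
a ~10.5 Mb mean autozygous segment, and a carrier frequency of 0.17.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (
    CASE,
    CONTROL,
    MISSING,
    OBLIGATE_CARRIER,
    GenotypeMatrix,
    MarkerRecord,
    PileupSite,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of one simulated founder population.

    Attributes
    ----------
    n_cases, n_controls, n_obligate_carriers:
        Cohort sizes.  Defaults match a small mapping cohort in an inbred
        breed (13 cases, 69 controls, 17 obligate-carrier dams).
    n_markers, marker_spacing_bp:
        Evenly spaced array markers on one chromosome; 44 kb spacing
        approximates a ~54k equine SNP chip genome-wide density.
    disease_locus_marker:
        0-based index of the marker carrying the recessive lethal allele.
    carrier_frequency:
        Per-haplotype probability that a control chromosome carries the
        founder segment.
    case_ibd_length_mean_bp:
        Mean of the exponential length distribution of each founder-segment
        copy around the disease locus.
    genotyping_error_rate, missing_rate:
        Per-genotype probabilities of a single-step miscall and of a
        missing call.  Defaults (0.1% error, 0.4% missing) reflect typical
        SNP BeadChip duplicate concordance and a ~99.6% mean call rate.
    """

    n_cases: int = 13
    n_controls: int = 69
    n_obligate_carriers: int = 17
    n_markers: int = 1000
    marker_spacing_bp: int = 44_000
    chromosome_label: str = "1"
    disease_locus_marker: int = 500
    carrier_frequency: float = 0.17
    case_ibd_length_mean_bp: float = 10_500_000.0
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.004
    seed: int = 0

    def validate(self) -> None:
        if self.n_markers < 10:
            raise ValueError(f"n_markers must be >= 10, got {self.n_markers}")
        if not (0 <= self.disease_locus_marker < self.n_markers):
            raise ValueError(
                f"disease_locus_marker {self.disease_locus_marker} out of range "
                f"for {self.n_markers} markers"
            )
        for name in ("carrier_frequency", "genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.carrier_frequency >= 1.0:
            raise ValueError(
                "carrier_frequency must be < 1: controls free of two founder "
                "haplotypes would be impossible"
            )
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("need at least one case and one control")
        if self.case_ibd_length_mean_bp <= 0:
            raise ValueError("case_ibd_length_mean_bp must be positive")
        if self.marker_spacing_bp < 1:
            raise ValueError("marker_spacing_bp must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth retained alongside a simulated population.

    ``case_ibd_intervals`` maps each case to the bp interval (marker-snapped,
    1-based inclusive) over which its two founder-segment copies overlap,
    i.e. where it is autozygous; every interval contains the disease locus.
    ``true_genotypes`` are the codes before genotyping error and missingness.
    """

    disease_marker_index: int
    founder_haplotype: np.ndarray  # alt-allele indicator per marker
    case_ibd_intervals: Dict[str, Tuple[int, int]]
    true_genotypes: np.ndarray  # (n_samples, n_markers) codes, no missing
    sample_ids: List[str]
    positions_bp: np.ndarray
    chromosome: str
    ref_bases: np.ndarray
    alt_bases: np.ndarray

    @property
    def disease_position_bp(self) -> int:
        return int(self.positions_bp[self.disease_marker_index])


def _draw_segment(
    rng: np.random.Generator,
    positions: np.ndarray,
    locus_pos: int,
    mean_len: float,
) -> Tuple[int, int]:
    """Marker-index span of one founder segment containing the disease locus.

    The distance from the locus to the nearest ancestral recombination is
    memoryless, so each side of the segment extends by an independent
    exponential draw.  Side means equal ``mean_len`` so that the
    intersection of a case's two copies — its homozygous-by-descent
    segment, exponential on each side with half the mean — has expected
    total length ``mean_len``.  Endpoints snap to marker positions.
    """
    lo = locus_pos - rng.exponential(mean_len)
    hi = locus_pos + rng.exponential(mean_len)
    i = int(np.searchsorted(positions, lo, side="left"))
    j = int(np.searchsorted(positions, hi, side="right") - 1)
    # the segment always covers its own locus marker
    k = int(np.searchsorted(positions, locus_pos))
    return min(i, k), max(j, k)


def _haplotype(
    rng: np.random.Generator,
    bg_freqs: np.ndarray,
    founder: np.ndarray,
    segment: Optional[Tuple[int, int]],
) -> np.ndarray:
    """One chromosome: background draws, overwritten by the founder segment."""
    hap = (rng.uniform(size=bg_freqs.size) < bg_freqs).astype(np.int8)
    if segment is not None:
        i, j = segment
        hap[i : j + 1] = founder[i : j + 1]
    return hap


def simulate_population(config: SimulationConfig) -> Tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a genotyped case/control/carrier cohort with a founder allele.

    Cases carry two independent copies of the founder haplotype over
    exponential-length segments around the disease locus (their intersection
    is the autozygous interval); obligate carriers carry exactly one copy;
    controls carry a copy per chromosome with probability
    ``carrier_frequency`` and are redrawn if both chromosomes carry one, so
    no control is ever homozygous for the founder allele at the disease
    locus.  Genotyping error then flips codes by single steps and
    missingness is applied independently.  Fully deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    m = config.n_markers
    positions = config.marker_spacing_bp * (1 + np.arange(m, dtype=np.int64))
    d = config.disease_locus_marker
    locus_pos = int(positions[d])

    # Background alt-allele frequencies keep unlinked markers above a 5% MAF
    # by design; the disease allele exists only on the founder haplotype.
    bg_freqs = rng.uniform(0.05, 0.5, size=m)
    bg_freqs[d] = 0.0
    founder = (rng.uniform(size=m) < bg_freqs).astype(np.int8)
    founder[d] = 1

    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    ref_bases = _BASES[ref_idx]
    alt_bases = _BASES[alt_idx]

    sample_ids: List[str] = (
        [f"case_{i + 1:02d}" for i in range(config.n_cases)]
        + [f"control_{i + 1:02d}" for i in range(config.n_controls)]
        + [f"carrier_{i + 1:02d}" for i in range(config.n_obligate_carriers)]
    )
    phenotypes = {s: CASE for s in sample_ids[: config.n_cases]}
    phenotypes.update(
        {s: CONTROL for s in sample_ids[config.n_cases : config.n_cases + config.n_controls]}
    )
    phenotypes.update(
        {s: OBLIGATE_CARRIER for s in sample_ids[config.n_cases + config.n_controls :]}
    )

    n = len(sample_ids)
    true_g = np.empty((n, m), dtype=np.int8)
    case_ibd: Dict[str, Tuple[int, int]] = {}

    for row, sid in enumerate(sample_ids):
        pheno = phenotypes[sid]
        if pheno == CASE:
            seg1 = _draw_segment(rng, positions, locus_pos, config.case_ibd_length_mean_bp)
            seg2 = _draw_segment(rng, positions, locus_pos, config.case_ibd_length_mean_bp)
            h1 = _haplotype(rng, bg_freqs, founder, seg1)
            h2 = _haplotype(rng, bg_freqs, founder, seg2)
            i = max(seg1[0], seg2[0])
            j = min(seg1[1], seg2[1])
            case_ibd[sid] = (int(positions[i]), int(positions[j]))
        elif pheno == OBLIGATE_CARRIER:
            seg1 = _draw_segment(rng, positions, locus_pos, config.case_ibd_length_mean_bp)
            h1 = _haplotype(rng, bg_freqs, founder, seg1)
            h2 = _haplotype(rng, bg_freqs, founder, None)
        else:  # control
            while True:
                c1 = rng.uniform() < config.carrier_frequency
                c2 = rng.uniform() < config.carrier_frequency
                if not (c1 and c2):
                    break
            seg1 = (
                _draw_segment(rng, positions, locus_pos, config.case_ibd_length_mean_bp)
                if c1
                else None
            )
            seg2 = (
                _draw_segment(rng, positions, locus_pos, config.case_ibd_length_mean_bp)
                if c2
                else None
            )
            h1 = _haplotype(rng, bg_freqs, founder, seg1)
            h2 = _haplotype(rng, bg_freqs, founder, seg2)
        true_g[row] = h1 + h2

    observed = true_g.copy()

    # Symmetric single-step genotyping error: hom -> het, het -> either hom.
    if config.genotyping_error_rate > 0:
        flip = rng.uniform(size=observed.shape) < config.genotyping_error_rate
        direction = rng.integers(0, 2, size=observed.shape)  # for het flips
        homref = flip & (observed == 0)
        homalt = flip & (observed == 2)
        het = flip & (observed == 1)
        observed[homref | homalt] = 1
        observed[het] = (2 * direction[het]).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.uniform(size=observed.shape) < config.missing_rate
        observed[miss] = MISSING

    markers = [
        MarkerRecord(
            marker_id=f"SNP{k + 1:05d}",
            chromosome=config.chromosome_label,
            position_bp=int(positions[k]),
            alleles=(str(ref_bases[k]), str(alt_bases[k])),
        )
        for k in range(m)
    ]
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        phenotypes=phenotypes,
        markers=markers,
        genotypes=observed,
    )
    truth = TruthRecord(
        disease_marker_index=d,
        founder_haplotype=founder,
        case_ibd_intervals=case_ibd,
        true_genotypes=true_g,
        sample_ids=sample_ids,
        positions_bp=positions,
        chromosome=config.chromosome_label,
        ref_bases=ref_bases,
        alt_bases=alt_bases,
    )
    return gm, truth


# -- pileups ------------------------------------------------------------------

#: Modelled read length; supporting observations land in the first 25 bases
#: of a read with probability 25 / READ_LENGTH.
READ_LENGTH = 75


def simulate_pileups(
    truth: TruthRecord,
    sites: Sequence[int],
    mean_depth: float,
    base_error_rate: float,
    seed: int,
    sample_ids: Optional[Sequence[str]] = None,
) -> List[PileupSite]:
    """Per-sample read pileups at the given marker indices.

    Coverage is Poisson(``mean_depth``); alternative-supporting read counts
    are Binomial(coverage, f) with f = ``base_error_rate``, 0.5 and
    1 - ``base_error_rate`` for genotype codes 0, 1 and 2.  Deterministic
    per seed.
    """
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be positive, got {mean_depth}")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = truth.sample_ids
    out: List[PileupSite] = []
    for sid in sample_ids:
        row = truth.sample_ids.index(sid)
        for site in sites:
            g = int(truth.true_genotypes[row, site])
            f = {0: base_error_rate, 1: 0.5, 2: 1.0 - base_error_rate}[g]
            cov = int(rng.poisson(mean_depth))
            alt = int(rng.binomial(cov, f)) if cov > 0 else 0
            first25 = int(rng.binomial(alt, 25.0 / READ_LENGTH)) if alt > 0 else 0
            qual = float(np.clip(rng.normal(35.0, 2.0), 2.0, 42.0))
            out.append(
                PileupSite(
                    sample_id=sid,
                    chromosome=truth.chromosome,
                    position_bp=int(truth.positions_bp[site]),
                    ref_base=str(truth.ref_bases[site]),
                    alt_base=str(truth.alt_bases[site]),
                    unique_read_support=alt,
                    first25_support=first25,
                    raw_coverage=cov,
                    base_quality=round(qual, 1),
                    alt_fraction=(alt / cov) if cov > 0 else 0.0,
                )
            )
    return out


def pileups_from_genotypes(
    genotypes: Dict[str, int],
    chromosome: str,
    position_bp: int,
    ref_base: str,
    alt_base: str,
    mean_depth: float,
    base_error_rate: float,
    seed: int,
) -> List[PileupSite]:
    """Pileups for one extra (off-array) site with explicitly given genotypes."""
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be positive, got {mean_depth}")
    rng = np.random.default_rng(seed)
    out = []
    for sid, g in genotypes.items():
        f = {0: base_error_rate, 1: 0.5, 2: 1.0 - base_error_rate}[int(g)]
        cov = int(rng.poisson(mean_depth))
        alt = int(rng.binomial(cov, f)) if cov > 0 else 0
        first25 = int(rng.binomial(alt, 25.0 / READ_LENGTH)) if alt > 0 else 0
        qual = float(np.clip(rng.normal(35.0, 2.0), 2.0, 42.0))
        out.append(
            PileupSite(
                sample_id=sid,
                chromosome=chromosome,
                position_bp=position_bp,
                ref_base=ref_base,
                alt_base=alt_base,
                unique_read_support=alt,
                first25_support=first25,
                raw_coverage=cov,
                base_quality=round(qual, 1),
                alt_fraction=(alt / cov) if cov > 0 else 0.0,
            )
        )
    return out
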