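"""Runs of homozygosity and shared-homozygosity (IBS) mapping.

In a founder population, animals affected by a recessive disorder are
autozygous for the chromosomal segment carrying the causal allele, so the
segment appears as a run of homozygosity shared identical-by-state by every
case.  This module detects per-sample runs, intersects homozygous-identical
stretches across cases, counts how many controls share each candidate
region, and ranks regions so that the disease region (all cases, few or no
controls) surfaces first.

Rules, stated once and applied throughout:

* heterozygous markers terminate runs;
* missing genotypes are tolerated *inside* a run or region but can neither
  start nor end one — and a control with a missing genotype anywhere in a
  region does not count as sharing it;
* sharing across cases requires the *identical* homozygous allele at every
  marker (identical-by-state), not merely "any homozygous";
* region boundaries are the positions of the first and last qualifying
  markers — no extension into inter-marker gaps.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import groupby
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix


@dataclass
class ROHSegment:
    """A maximal run of homozygosity in one sample."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    start_index: int  # first marker index (within the matrix) of the run
    end_index: int  # last marker index, inclusive
    n_markers: int  # homozygous (non-missing) markers inside the run
    allele_states: np.ndarray  # genotype codes over the run span (may hold MISSING)


@dataclass
class SharedRegion:
    """An interval homozygous-identical across all cases."""

    chromosome: str
    start_bp: int
    end_bp: int
    start_index: int
    end_index: int
    marker_ids: List[str]
    shared_codes: np.ndarray  # homozygous code (0 or 2) per marker of the region
    n_cases_sharing: int
    n_controls_sharing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, position_bp: int) -> bool:
        return self.start_bp <= position_bp <= self.end_bp


def _is_hom(g: int) -> bool:
    return g == 0 or g == 2


def homozygous_runs(
    genotypes: np.ndarray,
    gm: GenotypeMatrix,
    sample_id: str = "",
    min_markers: int = 3,
) -> List[ROHSegment]:
    """Maximal runs of consecutive homozygous markers for one sample.

    ``genotypes`` is the sample's code vector aligned with ``gm.markers``.
    Runs never span chromosomes; runs with fewer than ``min_markers``
    homozygous markers are discarded.
    """
    g = np.asarray(genotypes)
    segments: List[ROHSegment] = []
    idx = 0
    for chrom, group in groupby(
        range(gm.n_markers), key=lambda j: gm.markers[j].chromosome
    ):
        js = list(group)
        run_start: Optional[int] = None
        last_hom: Optional[int] = None
        n_hom = 0
        for j in js + [None]:  # sentinel flushes the trailing run
            code = int(g[j]) if j is not None else 1
            if _is_hom(code):
                if run_start is None:
                    run_start = j
                last_hom = j
                n_hom += 1
            elif code == MISSING and run_start is not None:
                continue  # tolerated inside; boundary fixed by last_hom
            else:
                if run_start is not None and n_hom >= min_markers:
                    segments.append(
                        ROHSegment(
                            sample_id=sample_id,
                            chromosome=chrom,
                            start_bp=gm.markers[run_start].position_bp,
                            end_bp=gm.markers[last_hom].position_bp,
                            start_index=run_start,
                            end_index=last_hom,
                            n_markers=n_hom,
                            allele_states=g[run_start : last_hom + 1].copy(),
                        )
                    )
                run_start = None
                last_hom = None
                n_hom = 0
    return segments


def shared_homozygous_regions(
    gm: GenotypeMatrix,
    case_ids: Optional[Sequence[str]] = None,
    region_of_interest: Optional[Tuple[str, int, int]] = None,
    min_markers: int = 3,
) -> List[SharedRegion]:
    """Regions at which every case is homozygous for the identical allele.

    A marker qualifies when all non-missing case genotypes are homozygous
    and equal; markers where some case is missing are tolerated inside a
    region but trimmed from its ends.  For each region the number of
    controls homozygous for the same allele at every marker is counted
    (a missing control genotype disqualifies that control).

    ``region_of_interest`` = (chromosome, start_bp, end_bp) restricts the
    search window.  Returns an empty list when nothing is shared.
    """
    if case_ids is None:
        case_ids = gm.case_ids
    case_ids = list(case_ids)
    if len(case_ids) < 2:
        raise ValueError("shared-homozygosity mapping needs at least 2 cases")
    case_rows = np.array([gm.sample_index(s) for s in case_ids])
    ctrl_rows = np.array(
        [gm.sample_index(s) for s in gm.control_ids], dtype=np.int64
    )

    in_window = np.ones(gm.n_markers, dtype=bool)
    if region_of_interest is not None:
        chrom, lo, hi = region_of_interest
        in_window = np.array(
            [
                m.chromosome == chrom and lo <= m.position_bp <= hi
                for m in gm.markers
            ]
        )

    G = gm.genotypes[case_rows]  # cases x markers
    hom = (G == 0) | (G == 2)
    miss = G == MISSING
    # the consensus homozygous code where one exists
    any_obs = ~miss
    # marker qualifies fully: all cases homozygous and identical
    # marker qualifies weakly: non-missing cases homozygous and identical,
    # at least one observed
    codes = np.where(miss, -2, G)  # -2 never matches a real code

    regions: List[SharedRegion] = []
    chrom_of = [m.chromosome for m in gm.markers]

    def qualify(j: int) -> Tuple[bool, bool, int]:
        """(weak, full, shared_code) at marker j."""
        col_obs = any_obs[:, j]
        if not in_window[j] or not col_obs.any():
            return False, False, -1
        obs_codes = G[col_obs, j]
        if not ((obs_codes == obs_codes[0]).all() and _is_hom(int(obs_codes[0]))):
            return False, False, -1
        return True, bool(col_obs.all()), int(obs_codes[0])

    j = 0
    n = gm.n_markers
    while j < n:
        weak, full, code = qualify(j)
        if not full:
            j += 1
            continue
        # extend the region marker by marker; the shared homozygous code may
        # differ between markers (it follows the shared haplotype), but at
        # each single marker all cases must agree.  Weak (some-case-missing)
        # markers are allowed inside; the last fully observed marker is the
        # provisional end.
        start = j
        last_full = j
        shared: List[int] = []
        k = j
        while k < n and chrom_of[k] == chrom_of[start]:
            w, f, c = qualify(k)
            if not w:
                break
            shared.append(c)
            if f:
                last_full = k
            k += 1
        end = last_full
        span = end - start + 1
        if span >= min_markers:
            region_codes = np.array(shared[:span], dtype=np.int8)
            n_ctrl = _count_sharing_controls(gm, ctrl_rows, start, end, region_codes)
            regions.append(
                SharedRegion(
                    chromosome=chrom_of[start],
                    start_bp=gm.markers[start].position_bp,
                    end_bp=gm.markers[end].position_bp,
                    start_index=start,
                    end_index=end,
                    marker_ids=[gm.markers[x].marker_id for x in range(start, end + 1)],
                    shared_codes=region_codes,
                    n_cases_sharing=len(case_ids),
                    n_controls_sharing=n_ctrl,
                )
            )
        j = max(k, j + 1)
    return regions


def _count_sharing_controls(
    gm: GenotypeMatrix,
    ctrl_rows: np.ndarray,
    start: int,
    end: int,
    region_codes: np.ndarray,
) -> int:
    if ctrl_rows.size == 0:
        return 0
    block = gm.genotypes[np.ix_(ctrl_rows, range(start, end + 1))]
    return int((block == region_codes[None, :]).all(axis=1).sum())


def rank_regions(
    regions: Sequence[SharedRegion], n_cases_total: Optional[int] = None
) -> List[SharedRegion]:
    """Disease-candidate ordering of shared regions.

    Most cases sharing first, then fewest controls sharing, then longest;
    ties broken by start coordinate for determinism.
    """
    return sorted(
        regions,
        key=lambda r: (
            -r.n_cases_sharing,
            r.n_controls_sharing,
            -r.length_bp,
            r.chromosome,
            r.start_bp,
        ),
    )


def region_length_mb(start_bp: int, end_bp: int) -> float:
    """Interval length in megabases, half-up to 2 decimals (1-based inclusive)."""
    if start_bp > end_bp:
        raise ValueError(f"start_bp {start_bp} exceeds end_bp {end_bp}")
    mb = Decimal(end_bp - start_bp + 1) / Decimal(10**6)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


#: Display codes for the genotype-matrix export.
ASSOCIATED_HOM = "associated_hom"
HET = "het"
NORMAL_HOM = "normal_hom"
MISSING_CODE = "missing"


def genotype_matrix_codes(
    gm: GenotypeMatrix,
    region: SharedRegion,
    associated_allele_codes: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-sample, per-marker display classification over a region.

    Each cell is one of ``associated_hom`` (homozygous for the
    disease-associated allele), ``het``, ``normal_hom`` (homozygous for the
    other allele) or ``missing`` — the coding used to visualize a candidate
    region as a colour matrix.  Rows are markers, columns samples.
    """
    if associated_allele_codes is None:
        associated_allele_codes = region.shared_codes
    codes = np.asarray(associated_allele_codes)
    span = region.end_index - region.start_index + 1
    if codes.size != span:
        raise ValueError("one associated allele code per region marker required")
    out = {}
    for sid in gm.sample_ids:
        row = gm.sample_index(sid)
        g = gm.genotypes[row, region.start_index : region.end_index + 1]
        labels = np.where(
            g == MISSING,
            MISSING_CODE,
            np.where(g == 1, HET, np.where(g == codes, ASSOCIATED_HOM, NORMAL_HOM)),
        )
        out[sid] = labels
    return pd.DataFrame(out, index=region.marker_ids)
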