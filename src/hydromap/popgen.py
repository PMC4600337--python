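"""Linkage disequilibrium and carrier-screen allele-frequency estimation.

LD between two biallelic loci is reported as the squared correlation r^2 =
D^2 / (pA(1-pA) pB(1-pB)).  From unphased genotypes the two-locus
haplotype frequencies are estimated by expectation-maximization over the
double-heterozygote phase ambiguity (the estimator behind standard
haplotype-based LD software); a fast squared-Pearson-correlation of
genotype codes is retained as a cross-check.

Carrier screening of a random population sample yields the allele
frequency as (het + 2 x homalt) / (2 x total) and the carrier percentage
as 100 x het / total.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .datatypes import MISSING


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScreenCounts:
    """Genotype counts from a population carrier screen."""

    n_homref: int
    n_het: int
    n_homalt: int

    def __post_init__(self) -> None:
        if min(self.n_homref, self.n_het, self.n_homalt) < 0:
            raise ValueError("screen counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_homref + self.n_het + self.n_homalt


@dataclass(frozen=True)
class LDResult:
    """Pairwise linkage disequilibrium between two loci."""

    locus_a: str
    locus_b: str
    r2: float
    haplotype_freqs: Tuple[float, float, float, float]  # (AB, Ab, aB, ab); A,B = alt
    method: str


def ld_r2(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    method: str = "em",
    locus_a: str = "locus_a",
    locus_b: str = "locus_b",
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> LDResult:
    """Squared-correlation LD between two loci from unphased genotype codes.

    ``em`` estimates the four haplotype frequencies by EM and computes
    r^2 from the disequilibrium coefficient; ``genotype_correlation``
    squares the Pearson correlation of the code vectors.  Samples missing
    at either locus are dropped; monomorphic loci are an error (r^2 is
    undefined).
    """
    if method not in ("em", "genotype_correlation"):
        raise ValueError(f"unknown LD method {method!r}")
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    if ga.shape != gb.shape:
        raise ValueError("genotype vectors must have equal length")
    keep = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[keep].astype(float), gb[keep].astype(float)
    n = ga.size
    if n < 2:
        raise ValueError("need at least 2 samples non-missing at both loci")
    pa = ga.sum() / (2 * n)
    pb = gb.sum() / (2 * n)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus: r^2 undefined")

    if method == "genotype_correlation":
        r = np.corrcoef(ga, gb)[0, 1]
        hap = _haps_from_freqs(pa, pb, float(r) * np.sqrt(pa * (1 - pa) * pb * (1 - pb)))
        return LDResult(locus_a, locus_b, float(np.clip(r * r, 0.0, 1.0)), hap, method)

    p = _em_haplotype_freqs(ga, gb, pa, pb, max_iter, tol)
    d = p[0] - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return LDResult(locus_a, locus_b, float(np.clip(r2, 0.0, 1.0)), tuple(p), "em")


def _haps_from_freqs(pa: float, pb: float, d: float) -> Tuple[float, float, float, float]:
    return (
        float(pa * pb + d),
        float(pa * (1 - pb) - d),
        float((1 - pa) * pb - d),
        float((1 - pa) * (1 - pb) + d),
    )


def _em_haplotype_freqs(
    ga: np.ndarray,
    gb: np.ndarray,
    pa: float,
    pb: float,
    max_iter: int,
    tol: float,
) -> np.ndarray:
    """EM over the 3x3 genotype-pair counts; phase is ambiguous only for
    double heterozygotes, which are split between AB/ab and Ab/aB in the
    ratio of the current haplotype-product frequencies."""
    n = ga.size
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.count_nonzero((ga == i) & (gb == j))
    # fixed haplotype contributions from unambiguous genotype pairs;
    # order: (AB, Ab, aB, ab) with A, B the alt alleles (code-counted)
    fixed = np.zeros(4)
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            # haplotype composition of genotype pair (i, j)
            a_alleles = [1] * i + [0] * (2 - i)
            b_alleles = [1] * j + [0] * (2 - j)
            # for non double-het pairs at least one locus is homozygous,
            # so the two haplotypes are determined
            pairs = list(zip(a_alleles, b_alleles))
            for a, b in pairs:
                fixed[_hap_index(a, b)] += c
    dh = counts[1, 1]

    p = np.array(_haps_from_freqs(pa, pb, 0.0))
    p = np.clip(p, 1e-12, None)
    p /= p.sum()
    for _ in range(max_iter):
        cis = p[0] * p[3]  # AB/ab
        trans = p[1] * p[2]  # Ab/aB
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        hap_counts = fixed.copy()
        hap_counts[0] += dh * w
        hap_counts[3] += dh * w
        hap_counts[1] += dh * (1 - w)
        hap_counts[2] += dh * (1 - w)
        new_p = hap_counts / (2 * n)
        if np.abs(new_p - p).max() < tol * max(p.max(), 1e-12):
            p = new_p
            break
        p = new_p
    return p


def _hap_index(a: int, b: int) -> int:
    # (AB, Ab, aB, ab) with 1 = alt allele present
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(a, b)]


def haplotype_r2(haplotypes_a: np.ndarray, haplotypes_b: np.ndarray) -> float:
    """r^2 by direct counting on phased haplotypes (oracle for the EM path)."""
    ha = np.asarray(haplotypes_a, dtype=float)
    hb = np.asarray(haplotypes_b, dtype=float)
    pa, pb = ha.mean(), hb.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus: r^2 undefined")
    pab = float(np.mean(ha * hb))
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def allele_frequency_from_screen(counts: ScreenCounts) -> float:
    """Alternative-allele frequency (het + 2 x homalt) / (2 x total)."""
    if counts.total == 0:
        raise ValueError("empty screen: no genotyped animals")
    return (counts.n_het + 2 * counts.n_homalt) / (2 * counts.total)


def carrier_percentage(counts: ScreenCounts) -> float:
    """Heterozygote share of the screened sample, percent to 1 decimal."""
    if counts.total == 0:
        raise ValueError("empty screen: no genotyped animals")
    return _round_half_up(100.0 * counts.n_het / counts.total, 1)


@dataclass
class ValidationSummary:
    """Genotype-by-phenotype concordance at one candidate variant."""

    counts: Dict[str, Dict[str, int]]  # phenotype class -> genotype label -> n
    all_cases_homalt: bool
    no_control_homalt: bool
    all_carriers_het: bool


def validation_summary(
    case_genotypes: Sequence[int],
    control_genotypes: Sequence[int],
    carrier_genotypes: Sequence[int],
) -> ValidationSummary:
    """Tabulate validation genotypes per phenotype class and check the
    recessive expectations: cases homozygous-alternative, controls never,
    obligate carriers heterozygous.  Empty classes pass vacuously."""

    def tab(gs: Sequence[int]) -> Dict[str, int]:
        gs = np.asarray(list(gs)) if len(gs) else np.array([], dtype=int)
        return {
            "homref": int(np.count_nonzero(gs == 0)),
            "het": int(np.count_nonzero(gs == 1)),
            "homalt": int(np.count_nonzero(gs == 2)),
            "missing": int(np.count_nonzero(gs == MISSING)),
        }

    cases = tab(case_genotypes)
    controls = tab(control_genotypes)
    carriers = tab(carrier_genotypes)
    n_cases_obs = cases["homref"] + cases["het"] + cases["homalt"]
    n_carriers_obs = carriers["homref"] + carriers["het"] + carriers["homalt"]
    return ValidationSummary(
        counts={"case": cases, "control": controls, "obligate_carrier": carriers},
        all_cases_homalt=cases["homalt"] == n_cases_obs,
        no_control_homalt=controls["homalt"] == 0,
        all_carriers_het=carriers["het"] == n_carriers_obs,
    )
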