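"""Rule-based pileup variant caller, recessive concordance filter and CDS
consequence annotation.

The caller reproduces a conservative exon-resequencing filter for pooled
barcoded short reads: a candidate substitution in a sample is considered
only when supported by >= 3 unique reads, seen at least once within the
first 25 bases of a read (the most accurately mapped, highest-quality part
of a read), at raw coverage >= 10x, mean supporting base quality >= 20 and
a non-reference allele fraction >= 15%.  All five comparisons are
inclusive.  Genotypes are then assigned from the allele fraction with a
heterozygote band, candidate variants are screened for the recessive
case/control segregation pattern, and coding substitutions are annotated
against a CDS sequence (standard genetic code).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .datatypes import PileupSite

HOMREF = "homref"
HET = "het"
HOMALT = "homalt"
NOCALL = "nocall"

#: Names of the five per-sample caller rules, in report order.
RULE_NAMES = ("unique_reads", "first25", "coverage", "base_quality", "alt_fraction")


@dataclass(frozen=True)
class CallerThresholds:
    """Inclusive lower bounds of the five caller rules."""

    min_unique_reads: int = 3
    min_first25: int = 1
    min_coverage: int = 10
    min_base_quality: float = 20.0
    min_alt_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "min_unique_reads",
            "min_first25",
            "min_coverage",
            "min_base_quality",
            "min_alt_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the five caller rules for one sample at one site."""

    flags: Mapping[str, bool]
    passed: bool

    def failed_rules(self) -> List[str]:
        return [name for name in RULE_NAMES if not self.flags[name]]


def filter_site(site: PileupSite, thresholds: CallerThresholds = CallerThresholds()) -> FilterResult:
    """Evaluate the five discovery rules; overall pass iff all pass."""
    flags = {
        "unique_reads": site.unique_read_support >= thresholds.min_unique_reads,
        "first25": site.first25_support >= thresholds.min_first25,
        "coverage": site.raw_coverage >= thresholds.min_coverage,
        "base_quality": site.base_quality >= thresholds.min_base_quality,
        "alt_fraction": site.alt_fraction >= thresholds.min_alt_fraction,
    }
    return FilterResult(flags=flags, passed=all(flags.values()))


def genotype_from_pileup(
    site: PileupSite,
    het_band: Tuple[float, float] = (0.15, 0.85),
    thresholds: Optional[CallerThresholds] = None,
) -> str:
    """Genotype one sample from its allele fraction.

    Below the band -> ``homref``; inside it (inclusive) -> ``het``; above ->
    ``homalt``.  When ``thresholds`` are given the site must first meet the
    site-adequacy rules (coverage and base quality); otherwise ``nocall``.
    The variant-evidence rules (read support, alt fraction) are discovery
    criteria and do not veto a confident homozygous-reference genotype.
    """
    lo, hi = het_band
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"invalid het band {het_band}")
    if thresholds is not None:
        if (
            site.raw_coverage < thresholds.min_coverage
            or site.base_quality < thresholds.min_base_quality
        ):
            return NOCALL
    if site.alt_fraction < lo:
        return HOMREF
    if site.alt_fraction <= hi:
        return HET
    return HOMALT


@dataclass
class VariantCall:
    """One candidate substitution with per-sample genotypes and rule flags."""

    chromosome: str
    position_bp: int
    ref_base: str
    alt_base: str
    genotypes: Dict[str, str]  # sample -> HOMREF/HET/HOMALT/NOCALL
    sample_filters: Dict[str, FilterResult]
    discovered: bool  # some sample passed all five discovery rules
    concordant: Optional[bool] = None

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chromosome, self.position_bp, self.ref_base, self.alt_base)


def call_variants(
    pileups: Iterable[PileupSite],
    thresholds: CallerThresholds = CallerThresholds(),
    het_band: Tuple[float, float] = (0.15, 0.85),
) -> List[VariantCall]:
    """Group pileup records by site and genotype every sample.

    A site becomes a candidate variant (``discovered``) when at least one
    sample passes all five rules.  Sites are returned in genomic order.
    """
    by_site: Dict[Tuple[str, int, str, str], List[PileupSite]] = {}
    for p in pileups:
        by_site.setdefault((p.chromosome, p.position_bp, p.ref_base, p.alt_base), []).append(p)

    calls: List[VariantCall] = []
    for key in sorted(by_site, key=lambda k: (k[0], k[1], k[2], k[3])):
        sites = by_site[key]
        filters = {s.sample_id: filter_site(s, thresholds) for s in sites}
        genotypes = {
            s.sample_id: genotype_from_pileup(s, het_band, thresholds) for s in sites
        }
        calls.append(
            VariantCall(
                chromosome=key[0],
                position_bp=key[1],
                ref_base=key[2],
                alt_base=key[3],
                genotypes=genotypes,
                sample_filters=filters,
                discovered=any(f.passed for f in filters.values()),
            )
        )
    return calls


@dataclass(frozen=True)
class ConcordanceResult:
    concordant: bool
    reason: str


def recessive_concordance(
    call: VariantCall,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
) -> ConcordanceResult:
    """Does the variant segregate as a fully penetrant recessive allele?

    Concordant iff every case is homozygous-alternative and no control is;
    controls may be heterozygous (carriers).  A case without a genotype
    (nocall) fails with its own reason code rather than being ignored; a
    control nocall is treated as non-homozygous.
    """
    for sid in case_ids:
        g = call.genotypes.get(sid, NOCALL)
        if g == NOCALL:
            return ConcordanceResult(False, f"case_nocall:{sid}")
        if g != HOMALT:
            return ConcordanceResult(False, f"case_not_homalt:{sid}")
    for sid in control_ids:
        if call.genotypes.get(sid, NOCALL) == HOMALT:
            return ConcordanceResult(False, f"control_homalt:{sid}")
    return ConcordanceResult(True, "ok")


def concordance_filter(
    calls: Iterable[VariantCall],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    require_discovered: bool = True,
) -> List[VariantCall]:
    """Annotate calls in place and return those fitting the recessive model."""
    surviving = []
    for call in calls:
        res = recessive_concordance(call, case_ids, control_ids)
        call.concordant = res.concordant and (call.discovered or not require_discovered)
        if call.concordant:
            surviving.append(call)
    return surviving


# -- CDS annotation -----------------------------------------------------------

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
STOP_GAIN = "stop_gain"
STOP_LOSS = "stop_loss"


@dataclass(frozen=True)
class CDSVariant:
    """A coding substitution and its predicted protein consequence."""

    transcript_id: str
    cds_position: int  # 1-based within the CDS
    ref_base: str
    alt_base: str
    codon_index: int  # 1-based codon number
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str
    truncation_aa: Optional[int]  # residues lost; stop_gain only


def codon_index(cds_position: int) -> int:
    """1-based codon number of a 1-based CDS position: ceil(pos / 3)."""
    if cds_position < 1:
        raise ValueError(f"cds_position must be >= 1, got {cds_position}")
    return math.ceil(cds_position / 3)


def annotate_cds(
    cds_sequence: str,
    cds_position: int,
    ref_base: str,
    alt_base: str,
    protein_length: Optional[int] = None,
    transcript_id: str = "",
) -> CDSVariant:
    """Classify a coding substitution by its codon change.

    ``protein_length`` is the residue count of the full-length protein;
    when omitted it is inferred from the CDS (terminal stop codon excluded).
    For a stop gain the truncation is protein_length - codon_index + 1
    residues.  Raises if the CDS base at ``cds_position`` is not
    ``ref_base``.
    """
    seq = str(cds_sequence).upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if not (1 <= cds_position <= len(seq)):
        raise ValueError(f"cds_position {cds_position} outside CDS of length {len(seq)}")
    ref_base = ref_base.upper()
    alt_base = alt_base.upper()
    observed = seq[cds_position - 1]
    if observed != ref_base:
        raise ValueError(
            f"reference mismatch at CDS position {cds_position}: CDS has "
            f"{observed!r}, expected {ref_base!r}"
        )

    ci = codon_index(cds_position)
    codon_start = (ci - 1) * 3
    ref_codon = seq[codon_start : codon_start + 3]
    within = (cds_position - 1) % 3
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]

    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ref_aa == alt_aa:
        consequence = SYNONYMOUS
    elif alt_aa == "*":
        consequence = STOP_GAIN
    elif ref_aa == "*":
        consequence = STOP_LOSS
    else:
        consequence = MISSENSE

    if protein_length is None:
        translated = str(Seq(seq).translate())
        protein_length = len(translated.rstrip("*")) if translated.endswith("*") else len(translated)

    truncation = None
    if consequence == STOP_GAIN:
        truncation = protein_length - ci + 1

    return CDSVariant(
        transcript_id=transcript_id,
        cds_position=cds_position,
        ref_base=ref_base,
        alt_base=alt_base,
        codon_index=ci,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
        truncation_aa=truncation,
    )
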