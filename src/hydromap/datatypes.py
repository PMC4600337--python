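"""Core in-memory containers shared across the pipeline stages.

Genotypes are coded as counts of the alternative allele: 0 = homozygous
reference/common, 1 = heterozygous, 2 = homozygous alternative.  Missing
genotypes carry the sentinel :data:`MISSING` (-1).  All genomic coordinates
are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

#: Genotype sentinel for a missing call.
MISSING: int = -1

#: Phenotype labels.
CASE = "case"
CONTROL = "control"
OBLIGATE_CARRIER = "obligate_carrier"

PHENOTYPES = (CASE, CONTROL, OBLIGATE_CARRIER)


@dataclass(frozen=True)
class MarkerRecord:
    """One biallelic SNP marker on the genotyping array."""

    marker_id: str
    chromosome: str
    position_bp: int
    alleles: Tuple[str, str]  # (reference-like, alternative-like)

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(
                f"marker {self.marker_id}: position_bp must be >= 1, "
                f"got {self.position_bp}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x markers genotype codes plus phenotype labels and marker map.

    The substrate of QC, association scanning and homozygosity mapping.

    Attributes
    ----------
    sample_ids:
        Ordered sample identifiers (rows of ``genotypes``).
    phenotypes:
        Mapping sample id -> one of ``case``, ``control``, ``obligate_carrier``.
    markers:
        Ordered markers (columns of ``genotypes``), strictly sorted by
        (chromosome, position).
    genotypes:
        ``(n_samples, n_markers)`` int8 array of codes in {0, 1, 2, MISSING}.
    """

    sample_ids: List[str]
    phenotypes: Dict[str, str]
    markers: List[MarkerRecord]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")
        for sid in self.sample_ids:
            if self.phenotypes.get(sid) not in PHENOTYPES:
                raise ValueError(
                    f"sample {sid!r}: phenotype must be one of {PHENOTYPES}, "
                    f"got {self.phenotypes.get(sid)!r}"
                )
        keys = [(m.chromosome, m.position_bp) for m in self.markers]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("markers must be strictly ordered by (chromosome, position)")

    # -- convenience accessors ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def samples_with_phenotype(self, phenotype: str) -> List[str]:
        return [s for s in self.sample_ids if self.phenotypes[s] == phenotype]

    @property
    def case_ids(self) -> List[str]:
        return self.samples_with_phenotype(CASE)

    @property
    def control_ids(self) -> List[str]:
        return self.samples_with_phenotype(CONTROL)

    @property
    def obligate_carrier_ids(self) -> List[str]:
        return self.samples_with_phenotype(OBLIGATE_CARRIER)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def marker_index(self, marker_id: str) -> int:
        for i, m in enumerate(self.markers):
            if m.marker_id == marker_id:
                return i
        raise KeyError(f"unknown marker id {marker_id!r}")

    def subset(
        self,
        sample_ids: Optional[Sequence[str]] = None,
        marker_indices: Optional[Sequence[int]] = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples and/or markers."""
        if sample_ids is None:
            sample_ids = self.sample_ids
        if marker_indices is None:
            marker_indices = range(self.n_markers)
        rows = [self.sample_index(s) for s in sample_ids]
        cols = list(marker_indices)
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            phenotypes={s: self.phenotypes[s] for s in sample_ids},
            markers=[self.markers[j] for j in cols],
            genotypes=self.genotypes[np.ix_(rows, cols)].copy(),
        )


@dataclass(frozen=True)
class PileupSite:
    """Per-sample read-support summary at one candidate variant position.

    ``unique_read_support`` counts distinct read alignments carrying the
    alternative base; ``first25_support`` counts those observations falling in
    the first 25 bases of their read (the highest-quality part of a read);
    ``base_quality`` is the mean phred quality of the supporting bases.
    """

    sample_id: str
    chromosome: str
    position_bp: int
    ref_base: str
    alt_base: str
    unique_read_support: int
    first25_support: int
    raw_coverage: int
    base_quality: float
    alt_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alt_fraction <= 1.0):
            raise ValueError(f"alt_fraction must be in [0,1], got {self.alt_fraction}")
        if self.unique_read_support > self.raw_coverage:
            raise ValueError("unique_read_support cannot exceed raw_coverage")
        if self.first25_support > self.unique_read_support:
            raise ValueError("first25_support cannot exceed unique_read_support")
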