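"""Marker and sample quality control for SNP-array genotypes.

Filters follow common array-QC practice for case/control mapping panels:
markers are dropped when the minor allele frequency falls below 5% or the
marker call rate below 90%, then samples with a call rate below 90% are
removed.  Thresholds are strict: a marker at exactly the threshold passes.
MAF and call rates are computed over all phenotype classes jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .datatypes import MISSING, GenotypeMatrix


@dataclass
class QCReport:
    """Summary of one QC pass."""

    n_markers_in: int
    n_markers_out: int
    n_failed_maf: int
    n_failed_callrate: int
    n_samples_removed: int
    per_sample_call_rate: Dict[str, float] = field(default_factory=dict)

    @property
    def fraction_retained(self) -> float:
        """Markers retained / markers in, in [0, 1]."""
        return self.n_markers_out / self.n_markers_in if self.n_markers_in else 0.0

    @property
    def fraction_discarded_low_maf(self) -> float:
        """Share of *discarded* markers that failed the MAF filter."""
        discarded = self.n_markers_in - self.n_markers_out
        return self.n_failed_maf / discarded if discarded else 0.0


def compute_maf(marker_genotypes: np.ndarray) -> float:
    """Folded minor allele frequency of one marker, missing excluded.

    Returns min(f, 1-f) with f the alternative-allele frequency over
    non-missing genotypes; always in [0, 0.5].
    """
    g = np.asarray(marker_genotypes)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise ValueError("MAF is uncomputable: all genotypes missing")
    f = (np.count_nonzero(obs == 1) + 2 * np.count_nonzero(obs == 2)) / (2 * obs.size)
    return float(min(f, 1.0 - f))


def marker_call_rate(marker_genotypes: np.ndarray) -> float:
    """Fraction of non-missing genotypes at one marker."""
    g = np.asarray(marker_genotypes)
    if g.size == 0:
        raise ValueError("empty genotype vector")
    return float(np.count_nonzero(g != MISSING) / g.size)


def sample_call_rate(sample_genotypes: np.ndarray) -> float:
    """Fraction of non-missing genotypes for one sample."""
    return marker_call_rate(sample_genotypes)


def apply_qc(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    marker_cr_min: float = 0.90,
    sample_cr_min: float = 0.90,
) -> Tuple[GenotypeMatrix, QCReport]:
    """Filter markers (MAF, then call rate) and then samples (call rate).

    Markers are assessed on the full sample set; samples are assessed on the
    retained markers.  Comparisons are strict (< threshold fails).  Raises
    ``ValueError`` if no marker or no sample survives.
    """
    g = gm.genotypes
    nonmiss = g != MISSING
    n_obs = nonmiss.sum(axis=0)
    alt_counts = (g == 1).sum(axis=0) + 2 * (g == 2).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, alt_counts / (2.0 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    cr = n_obs / gm.n_samples

    fail_maf = maf < maf_min
    # all-missing markers have no defined MAF; they fail on call rate alone
    fail_maf &= n_obs > 0
    fail_cr = cr < marker_cr_min
    keep_markers = ~(fail_maf | fail_cr)

    kept_idx = np.flatnonzero(keep_markers)
    if kept_idx.size == 0:
        raise ValueError("QC removed every marker; check thresholds and input")

    sub = gm.genotypes[:, kept_idx]
    sample_cr = (sub != MISSING).sum(axis=1) / kept_idx.size
    keep_samples = sample_cr >= sample_cr_min
    if not keep_samples.any():
        raise ValueError("QC removed every sample; check thresholds and input")

    kept_samples = [s for s, k in zip(gm.sample_ids, keep_samples) if k]
    out = gm.subset(sample_ids=kept_samples, marker_indices=kept_idx.tolist())

    report = QCReport(
        n_markers_in=gm.n_markers,
        n_markers_out=int(kept_idx.size),
        n_failed_maf=int(fail_maf.sum()),
        n_failed_callrate=int(fail_cr.sum()),
        n_samples_removed=int((~keep_samples).sum()),
        per_sample_call_rate={
            s: float(r) for s, r in zip(gm.sample_ids, sample_cr)
        },
    )
    return out, report
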