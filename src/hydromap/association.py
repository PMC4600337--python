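"""Genome-wide genotypic case/control association scan.

Each marker is tested with a Pearson chi-square statistic on the 2x3
(case/control x genotype) contingency table, the design used by classic
genotypic GWAS.  Because a fully penetrant recessive locus concentrates
cases in one homozygote cell, tables routinely contain empty cells; an
exact test over 2x3 tables (multivariate hypergeometric enumeration with
fixed margins) is provided as the small-sample alternative.  Genome-wide
significance uses a Bonferroni-corrected threshold alpha / n_markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .datatypes import CASE, CONTROL, MISSING, GenotypeMatrix

#: Enumeration bound for the exact test (grand total of the table).
FISHER_MAX_TOTAL = 500


class Chi2Result(NamedTuple):
    stat: float
    df: int
    p: float
    degenerate: bool


@dataclass
class AssociationResult:
    """Per-marker association outcome."""

    marker_id: str
    chromosome: str
    position_bp: int
    table: np.ndarray  # 2x3 counts, rows (case, control), cols (0,1,2)
    chi2_stat: float
    df: int
    p_chi2: float
    p_fisher: Optional[float]
    significant: bool
    recessive_consistent: bool
    degenerate: bool


def genotype_counts(gm: GenotypeMatrix, marker: Union[int, str]) -> np.ndarray:
    """2x3 genotype count table (rows case/control, columns codes 0/1/2).

    Obligate carriers and missing genotypes are excluded.  Raises if the
    marker is unknown or if every case and control is missing.
    """
    j = gm.marker_index(marker) if isinstance(marker, str) else marker
    if not (0 <= j < gm.n_markers):
        raise KeyError(f"marker index {j} out of range")
    table = np.zeros((2, 3), dtype=np.int64)
    for row, ids in enumerate((gm.case_ids, gm.control_ids)):
        for sid in ids:
            g = gm.genotypes[gm.sample_index(sid), j]
            if g != MISSING:
                table[row, g] += 1
    if table.sum() == 0:
        raise ValueError(
            f"marker {gm.markers[j].marker_id}: all case/control genotypes missing"
        )
    return table


def chisq_2x3(table: np.ndarray) -> Chi2Result:
    """Pearson chi-square on a 2x3 table with zero-margin reduction.

    Columns (and rows) with zero total are dropped and the degrees of
    freedom reduced to (rows-1) x (nonzero columns-1).  A table with fewer
    than two nonzero rows or columns is degenerate: statistic 0, df 0, p 1.
    """
    t = np.asarray(table, dtype=float)
    if t.sum() <= 0:
        raise ValueError("empty contingency table")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return Chi2Result(0.0, 0, 1.0, True)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(chi2_dist.sf(stat, df))
    return Chi2Result(stat, df, p, False)


def fisher_2x3(table: np.ndarray) -> float:
    """Exact two-sided p-value for a 2x3 table by full enumeration.

    Sums the multivariate hypergeometric probabilities (margins fixed) of
    every table whose probability does not exceed the observed table's —
    the probability-ordering convention of standard exact tests.  Bounded
    to grand totals <= 500; larger tables should use the chi-square path.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 3):
        raise ValueError(f"expected a 2x3 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty contingency table")
    if n > FISHER_MAX_TOTAL:
        raise ValueError(
            f"table total {n} exceeds the exact-test enumeration bound "
            f"({FISHER_MAX_TOTAL}); use the chi-square test instead"
        )
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    lf = gammaln(np.arange(n + 1) + 1.0)
    const = lf[row].sum() + lf[col].sum() - lf[n]

    def logp(a: int, b: int) -> float:
        c = row[0] - a - b
        cells = (a, b, c, col[0] - a, col[1] - b, col[2] - c)
        return float(const - sum(lf[x] for x in cells))

    lp_obs = logp(int(t[0, 0]), int(t[0, 1]))
    total = 0.0
    for a in range(min(row[0], col[0]) + 1):
        bmax = min(row[0] - a, col[1])
        for b in range(bmax + 1):
            c = row[0] - a - b
            if c > col[2]:
                continue
            lp = logp(a, b)
            if lp <= lp_obs + 1e-9:
                total += np.exp(lp)
    return float(min(total, 1.0))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
    return alpha / n_tests


def recessive_pattern(table: np.ndarray) -> bool:
    """Whether a 2x3 table matches a fully penetrant recessive locus.

    True iff all (non-missing) cases sit in a single homozygote column and
    no control sits in that column.
    """
    t = np.asarray(table, dtype=np.int64)
    n_cases = t[0].sum()
    if n_cases == 0:
        return False
    for col in (0, 2):
        if t[0, col] == n_cases and t[1, col] == 0:
            return True
    return False


def scan(
    gm: GenotypeMatrix,
    alpha: float = 0.05,
    test: str = "chi2",
) -> Tuple[List[AssociationResult], float]:
    """Test every marker; returns per-marker results and the Bonferroni level.

    ``test`` is ``chi2``, ``fisher`` or ``both``; Fisher p-values are only
    attempted when the table total is within the enumeration bound.
    Markers where all case/control genotypes are missing are reported as
    degenerate (p = 1).
    """
    if test not in ("chi2", "fisher", "both"):
        raise ValueError(f"unknown test {test!r}")
    threshold = bonferroni_threshold(alpha, gm.n_markers)
    case_rows = np.array([gm.sample_index(s) for s in gm.case_ids])
    ctrl_rows = np.array([gm.sample_index(s) for s in gm.control_ids])

    results: List[AssociationResult] = []
    for j, marker in enumerate(gm.markers):
        table = np.zeros((2, 3), dtype=np.int64)
        for row, idx in enumerate((case_rows, ctrl_rows)):
            gj = gm.genotypes[idx, j]
            for code in (0, 1, 2):
                table[row, code] = int(np.count_nonzero(gj == code))
        if table.sum() == 0:
            res = Chi2Result(0.0, 0, 1.0, True)
        else:
            res = chisq_2x3(table)
        p_fisher = None
        if test in ("fisher", "both") and 0 < table.sum() <= FISHER_MAX_TOTAL:
            p_fisher = fisher_2x3(table)
        p_primary = p_fisher if test == "fisher" and p_fisher is not None else res.p
        results.append(
            AssociationResult(
                marker_id=marker.marker_id,
                chromosome=marker.chromosome,
                position_bp=marker.position_bp,
                table=table,
                chi2_stat=res.stat,
                df=res.df,
                p_chi2=res.p,
                p_fisher=p_fisher,
                significant=bool(p_primary < threshold),
                recessive_consistent=recessive_pattern(table),
                degenerate=res.degenerate,
            )
        )
    return results, threshold


def manhattan_table(results: List[AssociationResult]) -> pd.DataFrame:
    """Plot-ready table: chromosome, position, -log10 p per marker."""
    return pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in results],
            "chromosome": [r.chromosome for r in results],
            "position_bp": [r.position_bp for r in results],
            "neg_log10_p": [
                -np.log10(max(r.p_chi2, np.finfo(float).tiny)) for r in results
            ],
            "significant": [r.significant for r in results],
        }
    )
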