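"""Runs of homozygosity, cross-case IBS sharing, ranking and region export."""

import dataclasses

import numpy as np
import pytest

from hydromap.datatypes import CASE, CONTROL, MISSING
from hydromap.roh import (
    ASSOCIATED_HOM,
    HET,
    MISSING_CODE,
    NORMAL_HOM,
    SharedRegion,
    genotype_matrix_codes,
    homozygous_runs,
    rank_regions,
    region_length_mb,
    shared_homozygous_regions,
)
from hydromap.simulate import SimulationConfig, simulate_population

from conftest import make_matrix


class TestHomozygousRuns:
    def test_het_terminates_run(self):
        gm = make_matrix([[2, 2, 2, 1, 2]])
        runs = homozygous_runs(gm.genotypes[0], gm, "s0", min_markers=2)
        assert len(runs) == 1
        assert (runs[0].start_index, runs[0].end_index) == (0, 2)
        assert runs[0].n_markers == 3

    def test_missing_tolerated_inside_not_at_edges(self):
        gm = make_matrix([[2, MISSING, 2, 1]])
        runs = homozygous_runs(gm.genotypes[0], gm, min_markers=2)
        assert len(runs) == 1
        assert (runs[0].start_index, runs[0].end_index) == (0, 2)
        assert runs[0].n_markers == 2  # the missing marker is not counted

        gm2 = make_matrix([[MISSING, 2, 2, MISSING, 1]])
        runs2 = homozygous_runs(gm2.genotypes[0], gm2, min_markers=2)
        assert (runs2[0].start_index, runs2[0].end_index) == (1, 2)

    def test_all_het_no_runs(self):
        gm = make_matrix([[1, 1, 1]])
        assert homozygous_runs(gm.genotypes[0], gm, min_markers=1) == []

    def test_min_markers_filters_short_runs(self):
        gm = make_matrix([[2, 2, 1, 0, 0, 0]])
        runs = homozygous_runs(gm.genotypes[0], gm, min_markers=3)
        assert len(runs) == 1
        assert runs[0].n_markers == 3

    def test_runs_do_not_span_chromosomes(self):
        from hydromap.datatypes import GenotypeMatrix, MarkerRecord

        markers = [
            MarkerRecord("a1", "1", 100, ("A", "B")),
            MarkerRecord("a2", "1", 200, ("A", "B")),
            MarkerRecord("b1", "2", 100, ("A", "B")),
            MarkerRecord("b2", "2", 200, ("A", "B")),
        ]
        gm = GenotypeMatrix(
            ["s0"], {"s0": "control"}, markers, np.array([[2, 2, 2, 2]], dtype=np.int8)
        )
        runs = homozygous_runs(gm.genotypes[0], gm, min_markers=2)
        assert [(r.chromosome, r.start_index, r.end_index) for r in runs] == [
            ("1", 0, 1),
            ("2", 2, 3),
        ]


def _bruteforce_shared(gm, min_markers):
    """Exhaustive window check: independent oracle for shared regions.

    A marker qualifies when all non-missing case genotypes are an identical
    homozygote (with at least one observed); a maximal qualifying window
    trimmed to fully observed end markers is a region.
    """
    case_rows = [gm.sample_index(s) for s in gm.case_ids]
    G = gm.genotypes[case_rows]
    n = gm.n_markers

    def weak(j):
        col = G[:, j]
        obs = col[col != MISSING]
        return obs.size > 0 and (obs == obs[0]).all() and obs[0] in (0, 2)

    def full(j):
        return weak(j) and (G[:, j] != MISSING).all()

    same_chrom = lambda i, j: gm.markers[i].chromosome == gm.markers[j].chromosome
    out = []
    for i in range(n):
        for j in range(i, n):
            if not same_chrom(i, j):
                continue
            if not all(weak(k) for k in range(i, j + 1)):
                continue
            # maximality of the weak window: no qualifying extension
            if i > 0 and same_chrom(i - 1, i) and weak(i - 1):
                continue
            if j < n - 1 and same_chrom(j, j + 1) and weak(j + 1):
                continue
            out.append((i, j))
    # trim weak (some-case-missing) end markers inward to fully observed ones
    trimmed = set()
    for i, j in out:
        ii, jj = i, j
        while ii <= jj and not full(ii):
            ii += 1
        while jj >= ii and not full(jj):
            jj -= 1
        if ii <= jj and jj - ii + 1 >= min_markers:
            trimmed.add((ii, jj))
    return sorted(trimmed)


class TestSharedRegions:
    def test_two_cases_simple_region(self):
        g = [
            [1, 1, 0, 2, 2, 2, 2, 1],
            [1, 0, 1, 2, 2, 2, 2, 2],
        ]
        gm = make_matrix(g, phenotypes=[CASE, CASE])
        regions = shared_homozygous_regions(gm, min_markers=2)
        assert len(regions) == 1
        assert (regions[0].start_index, regions[0].end_index) == (3, 6)

    def test_opposite_homozygotes_break_sharing(self):
        g = [
            [2, 2, 2, 2, 2],
            [2, 2, 0, 2, 2],
        ]
        gm = make_matrix(g, phenotypes=[CASE, CASE])
        regions = shared_homozygous_regions(gm, min_markers=2)
        assert [(r.start_index, r.end_index) for r in regions] == [(0, 1), (3, 4)]

    def test_control_sharing_requires_identical_alleles_no_missing(self):
        g = [
            [2, 0, 2],  # case
            [2, 0, 2],  # case
            [2, 0, 2],  # control: shares
            [2, 2, 2],  # control: differs at middle marker
            [2, MISSING, 2],  # control: missing disqualifies
            [1, 0, 2],  # control: het
        ]
        gm = make_matrix(g, phenotypes=[CASE, CASE, CONTROL, CONTROL, CONTROL, CONTROL])
        regions = shared_homozygous_regions(gm, min_markers=3)
        assert len(regions) == 1
        assert regions[0].n_controls_sharing == 1
        assert regions[0].n_cases_sharing == 2

    def test_no_shared_region_returns_empty(self):
        gm = make_matrix([[2, 0], [0, 2]], phenotypes=[CASE, CASE])
        assert shared_homozygous_regions(gm, min_markers=1) == []

    def test_requires_two_cases(self):
        gm = make_matrix([[2, 2]], phenotypes=[CASE])
        with pytest.raises(ValueError):
            shared_homozygous_regions(gm)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_bruteforce_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_samples = int(rng.integers(4, 10))
        n_markers = int(rng.integers(8, 30))
        n_cases = int(rng.integers(2, n_samples))
        g = rng.choice([0, 1, 2, MISSING], size=(n_samples, n_markers), p=[0.35, 0.2, 0.35, 0.1])
        phen = [CASE] * n_cases + [CONTROL] * (n_samples - n_cases)
        gm = make_matrix(g, phenotypes=phen)
        got = [
            (r.start_index, r.end_index)
            for r in shared_homozygous_regions(gm, min_markers=2)
        ]
        assert got == _bruteforce_shared(gm, min_markers=2)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotonic_in_cases(self, seed):
        """Adding a case can only shrink or split shared regions."""
        rng = np.random.default_rng(100 + seed)
        g = rng.choice([0, 1, 2], size=(6, 40), p=[0.45, 0.1, 0.45])
        gm = make_matrix(g, phenotypes=[CASE] * 6)
        small = shared_homozygous_regions(gm, case_ids=gm.sample_ids[:3], min_markers=1)
        big = shared_homozygous_regions(gm, case_ids=gm.sample_ids, min_markers=1)
        small_spans = [(r.start_index, r.end_index) for r in small]
        for r in big:
            assert any(
                lo <= r.start_index and r.end_index <= hi for lo, hi in small_spans
            )

    def test_boundaries_tighten_with_more_cases(self):
        """The top region closes in on the truth IBD intersection as cases grow."""
        widths = {}
        for n_cases in (4, 8, 13):
            w = []
            for seed in range(10):
                cfg = SimulationConfig(
                    n_cases=n_cases,
                    seed=300 + seed,
                    genotyping_error_rate=0.0,
                    missing_rate=0.0,
                )
                gm, truth = simulate_population(cfg)
                regions = rank_regions(shared_homozygous_regions(gm))
                top = regions[0]
                w.append(top.length_bp)
            widths[n_cases] = np.mean(w)
        assert widths[13] <= widths[8] <= widths[4]


class TestRanking:
    def _region(self, start, n_cases, n_controls, length):
        return SharedRegion(
            chromosome="1",
            start_bp=start,
            end_bp=start + length - 1,
            start_index=0,
            end_index=0,
            marker_ids=["m"],
            shared_codes=np.array([2]),
            n_cases_sharing=n_cases,
            n_controls_sharing=n_controls,
        )

    def test_fewest_controls_first(self):
        regions = [
            self._region(100, 13, 4, 50),
            self._region(200, 13, 1, 50),
            self._region(300, 13, 6, 50),
        ]
        ranked = rank_regions(regions)
        assert [r.n_controls_sharing for r in ranked] == [1, 4, 6]

    def test_tie_break_by_start(self):
        regions = [self._region(500, 13, 2, 10), self._region(100, 13, 2, 10)]
        assert [r.start_bp for r in rank_regions(regions)] == [100, 500]

    def test_empty(self):
        assert rank_regions([]) == []

    def test_case_count_dominates(self):
        regions = [self._region(100, 12, 0, 99), self._region(200, 13, 5, 10)]
        assert rank_regions(regions)[0].n_cases_sharing == 13


class TestRegionLength:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(1, 1_000_000, 1.00), (5, 5, 0.00), (1, 2_460_000, 2.46)],
    )
    def test_examples(self, start, end, expected):
        assert region_length_mb(start, end) == expected

    def test_start_after_end_rejected(self):
        with pytest.raises(ValueError):
            region_length_mb(10, 9)


class TestGenotypeMatrixCodes:
    def test_classification(self):
        g = [
            [2, 0],  # case: associated-hom at both (shared codes 2, 0)
            [2, 0],
            [1, MISSING],  # control: het then missing
            [0, 2],  # control: normal-hom at both
        ]
        gm = make_matrix(g, phenotypes=[CASE, CASE, CONTROL, CONTROL])
        region = shared_homozygous_regions(gm, min_markers=2)[0]
        coded = genotype_matrix_codes(gm, region)
        assert list(coded["s0"]) == [ASSOCIATED_HOM, ASSOCIATED_HOM]
        assert list(coded["s2"]) == [HET, MISSING_CODE]
        assert list(coded["s3"]) == [NORMAL_HOM, NORMAL_HOM]
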