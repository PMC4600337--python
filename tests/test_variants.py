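"""Caller rules, genotype banding, recessive concordance, CDS annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from hydromap.datatypes import PileupSite
from hydromap.simulate import SimulationConfig, simulate_population, simulate_pileups
from hydromap.variants import (
    HET,
    HOMALT,
    HOMREF,
    NOCALL,
    RULE_NAMES,
    STOP_GAIN,
    SYNONYMOUS,
    CallerThresholds,
    annotate_cds,
    call_variants,
    codon_index,
    concordance_filter,
    filter_site,
    genotype_from_pileup,
    recessive_concordance,
)


def site(support=5, first25=2, cov=50, qual=30.0, frac=None, sample="s", pos=100):
    if frac is None:
        frac = support / cov if cov else 0.0
    return PileupSite(
        sample_id=sample,
        chromosome="1",
        position_bp=pos,
        ref_base="C",
        alt_base="T",
        unique_read_support=support,
        first25_support=first25,
        raw_coverage=cov,
        base_quality=qual,
        alt_fraction=frac,
    )


class TestFilterSite:
    def test_all_boundaries_inclusive(self):
        s = site(support=3, first25=1, cov=10, qual=20.0, frac=0.15)
        res = filter_site(s)
        assert res.passed
        assert all(res.flags.values())

    @pytest.mark.parametrize(
        "kwargs,failing_rule",
        [
            ({"support": 2, "first25": 1, "frac": 0.2}, "unique_reads"),
            ({"first25": 0, "frac": 0.2}, "first25"),
            ({"cov": 9, "support": 3, "frac": 0.4}, "coverage"),
            ({"qual": 19.9, "frac": 0.2}, "base_quality"),
            ({"frac": 0.149}, "alt_fraction"),
        ],
    )
    def test_single_rule_failures(self, kwargs, failing_rule):
        res = filter_site(site(**kwargs))
        assert not res.passed
        assert res.failed_rules() == [failing_rule]

    @given(
        support=st.integers(0, 30),
        extra_cov=st.integers(0, 300),
        first25=st.integers(0, 30),
        qual=st.floats(0, 45),
        frac=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=300)
    def test_equals_bruteforce_rules(self, support, extra_cov, first25, qual, frac):
        first25 = min(first25, support)
        cov = support + extra_cov
        s = site(support=support, first25=first25, cov=cov, qual=qual, frac=frac)
        t = CallerThresholds()
        expected = (
            support >= 3 and first25 >= 1 and cov >= 10 and qual >= 20 and frac >= 0.15
        )
        assert filter_site(s, t).passed == expected


class TestGenotypeFromPileup:
    @pytest.mark.parametrize(
        "frac,expected",
        [(0.0, HOMREF), (0.1, HOMREF), (0.15, HET), (0.5, HET), (0.85, HET), (0.86, HOMALT), (1.0, HOMALT)],
    )
    def test_band(self, frac, expected):
        assert genotype_from_pileup(site(frac=frac)) == expected

    def test_inadequate_site_is_nocall(self):
        s = site(cov=5, frac=1.0)
        assert genotype_from_pileup(s, thresholds=CallerThresholds()) == NOCALL
        assert genotype_from_pileup(site(qual=10.0), thresholds=CallerThresholds()) == NOCALL

    def test_homref_not_vetoed_by_discovery_rules(self):
        """A confident reference genotype needs no variant support."""
        s = site(support=0, first25=0, cov=100, frac=0.0)
        assert genotype_from_pileup(s, thresholds=CallerThresholds()) == HOMREF

    def test_recovers_truth_from_clean_pileups(self):
        """Error-free deep pileups reproduce the underlying genotypes exactly."""
        cfg = SimulationConfig(seed=4, genotyping_error_rate=0.0, missing_rate=0.0)
        _, truth = simulate_population(cfg)
        sites = list(range(200, 240))
        piles = simulate_pileups(truth, sites, mean_depth=30, base_error_rate=0.0, seed=8)
        code = {HOMREF: 0, HET: 1, HOMALT: 2}
        calls = call_variants(piles)
        mismatches = total = 0
        for c in calls:
            j = int(np.flatnonzero(truth.positions_bp == c.position_bp)[0])
            for sid, g in c.genotypes.items():
                if g == NOCALL:  # Poisson coverage can dip below min_coverage
                    continue
                total += 1
                mismatches += code[g] != truth.true_genotypes[truth.sample_ids.index(sid), j]
        assert total > 3000
        assert mismatches == 0

    def test_noisy_pileups_high_concordance(self):
        """1% base error at depth 200: genotype concordance above 99%."""
        cfg = SimulationConfig(seed=6, genotyping_error_rate=0.0, missing_rate=0.0)
        _, truth = simulate_population(cfg)
        sites = list(range(400, 420))
        piles = simulate_pileups(truth, sites, mean_depth=200, base_error_rate=0.01, seed=9)
        code = {HOMREF: 0, HET: 1, HOMALT: 2}
        calls = call_variants(piles)
        ok = total = 0
        for c in calls:
            j = int(np.flatnonzero(truth.positions_bp == c.position_bp)[0])
            for sid, g in c.genotypes.items():
                if g == NOCALL:
                    continue
                total += 1
                ok += code[g] == truth.true_genotypes[truth.sample_ids.index(sid), j]
        assert total >= 1000
        assert ok / total >= 0.99


class TestRecessiveConcordance:
    def _call(self, genos):
        return call_variants(
            [
                site(sample=sid, frac={0: 0.0, 1: 0.5, 2: 1.0}[g], support={0: 0, 1: 25, 2: 50}[g], first25={0: 0, 1: 5, 2: 10}[g])
                for sid, g in genos.items()
            ]
        )[0]

    def test_textbook_concordant_pattern(self):
        genos = {f"case{i}": 2 for i in range(4)}
        genos["ctrl0"] = 1  # a carrier control is allowed
        genos.update({f"ctrl{i}": 0 for i in range(1, 6)})
        call = self._call(genos)
        res = recessive_concordance(
            call, [f"case{i}" for i in range(4)], [f"ctrl{i}" for i in range(6)]
        )
        assert res.concordant

    def test_homalt_control_fails(self):
        call = self._call({"case0": 2, "case1": 2, "ctrl0": 2})
        res = recessive_concordance(call, ["case0", "case1"], ["ctrl0"])
        assert not res.concordant
        assert res.reason.startswith("control_homalt")

    def test_het_case_fails(self):
        call = self._call({"case0": 2, "case1": 1, "ctrl0": 0})
        res = recessive_concordance(call, ["case0", "case1"], ["ctrl0"])
        assert not res.concordant
        assert res.reason.startswith("case_not_homalt")

    def test_case_nocall_distinct_reason(self):
        call = self._call({"case0": 2, "ctrl0": 0})
        res = recessive_concordance(call, ["case0", "case_absent"], ["ctrl0"])
        assert not res.concordant
        assert res.reason.startswith("case_nocall")

    def test_end_to_end_truth_variant_survives_decoys(self):
        """The causal variant survives the filter; decoys mostly do not."""
        cfg = SimulationConfig(seed=12, genotyping_error_rate=0.0, missing_rate=0.0)
        gm, truth = simulate_population(cfg)
        d = truth.disease_marker_index
        sites = list(range(d - 25, d + 26))  # 50 decoys + the causal site
        piles = simulate_pileups(truth, sites, mean_depth=216, base_error_rate=0.01, seed=13)
        calls = call_variants(piles)
        surviving = concordance_filter(calls, gm.case_ids, gm.control_ids)
        survivors = {c.position_bp for c in surviving}
        assert truth.disease_position_bp in survivors
        assert len(survivors) < len(sites) / 2


class TestCodonIndex:
    @pytest.mark.parametrize("pos,expected", [(1, 1), (3, 1), (4, 2), (6, 2), (7, 3)])
    def test_examples(self, pos, expected):
        assert codon_index(pos) == expected

    def test_positive_positions_only(self):
        with pytest.raises(ValueError):
            codon_index(0)


class TestAnnotateCDS:
    def test_stop_gain_cag_to_tag(self):
        cds = "ATG" + "CAG" + "GGA" + "TAA"
        v = annotate_cds(cds, 4, "C", "T")
        assert (v.ref_codon, v.alt_codon) == ("CAG", "TAG")
        assert (v.ref_aa, v.alt_aa) == ("Q", "*")
        assert v.consequence == STOP_GAIN
        assert v.codon_index == 2
        assert v.truncation_aa == 2  # residues 2 and 3 of the 3-residue protein

    def test_identity_substitution_synonymous(self):
        v = annotate_cds("ATGCAGTAA", 4, "C", "C")
        assert v.consequence == SYNONYMOUS
        assert v.ref_codon == v.alt_codon

    def test_missense_and_stop_loss(self):
        assert annotate_cds("ATGCATTAA", 5, "A", "G").consequence == "missense"
        v = annotate_cds("ATGTAATAA", 5, "A", "T")  # TAA -> TTA (Leu)
        assert v.consequence == "stop_loss"

    def test_reference_mismatch_names_position(self):
        with pytest.raises(ValueError, match="position 4"):
            annotate_cds("ATGCAGTAA", 4, "G", "T")

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            annotate_cds("ATGCA", 1, "A", "G")

    def test_truncation_roundtrip_translation(self):
        """Translating the mutated CDS stops exactly at the reported codon."""
        rng = np.random.default_rng(3)
        # random 60-codon CDS without premature stops, ATG start, TAA end
        aa_codons = [
            c
            for c in (
                a + b + d
                for a in "ACGT"
                for b in "ACGT"
                for d in "ACGT"
            )
            if str(Seq(c).translate()) not in "*M"
        ]
        cds = "ATG" + "".join(rng.choice(aa_codons, size=58)) + "TAA"
        # engineer a CAA -> TAA stop gain at codon 30
        cds = cds[: 29 * 3] + "CAA" + cds[30 * 3 :]
        v = annotate_cds(cds, 29 * 3 + 1, "C", "T")
        assert v.consequence == STOP_GAIN
        mutated = cds[: v.cds_position - 1] + v.alt_base + cds[v.cds_position :]
        protein = str(Seq(mutated).translate(to_stop=True))
        assert len(protein) == v.codon_index - 1
        assert v.truncation_aa == 59 - v.codon_index + 1
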