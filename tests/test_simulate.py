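"""Cohort simulation determinism and variant-QC filter behaviour."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from starallele.matcher import call_cohort
from starallele.simulate import (
    QCThresholds,
    SimConfig,
    apply_filters,
    hwe_exact_p,
    mendel_error_rate,
    minor_allele_count,
    missing_rate,
    simulate_cohort,
)
from .conftest import KEYS


def make_cfg(defs, freqs, **kw):
    gene = defs.gene
    return SimConfig(defs={gene: defs}, hap_freqs={gene: freqs}, **kw)


class TestSimulateCohort:
    def test_same_seed_byte_identical(self, cyp2c19_defs):
        cfg = make_cfg(cyp2c19_defs, {"*1": 0.6, "*2": 0.4},
                       n_samples=30, n_trios=4, seed=11)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.vcf_text == b.vcf_text
        assert a.truth.diplotypes == b.truth.diplotypes

    def test_degenerate_all_reference(self, cyp2c19_defs):
        cfg = make_cfg(cyp2c19_defs, {"*1": 1.0}, n_samples=5, seed=1)
        res = simulate_cohort(cfg)
        for line in res.vcf_text.splitlines():
            if not line.startswith("#"):
                assert set(line.split("\t")[9:]) == {"0|0"}
        assert all(v == ("*1", "*1") for v in res.truth.diplotypes.values())

    def test_haplotype_fraction_within_3_se(self, cyp2c19_defs):
        n = 2000
        cfg = make_cfg(cyp2c19_defs, {"*1": 0.5, "*2": 0.5}, n_samples=n, seed=3)
        res = simulate_cohort(cfg)
        count = sum(
            (a == "*2") + (b == "*2") for a, b in res.truth.diplotypes.values()
        )
        frac = count / (2 * n)
        se = math.sqrt(0.25 / (2 * n))
        assert abs(frac - 0.5) <= 3 * se

    def test_dropped_deletion_site_makes_star6_look_reference(
        self, tmp_path, cyp2c9_defs
    ):
        cfg = make_cfg(cyp2c9_defs, {"*1": 0.5, "*6": 0.5}, n_samples=40, seed=5,
                       drop_sites=frozenset({KEYS["rs9332131"]}))
        res = simulate_cohort(cfg)
        assert "rs9332131" not in res.vcf_text
        path = tmp_path / "c.vcf"
        res.write(str(path))
        calls = call_cohort(str(path), {"CYP2C9": cyp2c9_defs})
        assert any(t != ("*1", "*1") for t in res.truth.diplotypes.values())
        assert all(c.phased_label == "*1|*1" for c in calls)

    def test_trio_children_inherit_parental_haplotypes(self, cyp2c19_defs):
        cfg = make_cfg(cyp2c19_defs, {"*1": 0.4, "*2": 0.3, "*35": 0.3},
                       n_samples=30, n_trios=10, seed=9)
        res = simulate_cohort(cfg)
        for row in res.pedigree.itertuples(index=False):
            c = res.truth.diplotypes[(row.child, "CYP2C19")]
            f = res.truth.diplotypes[(row.father, "CYP2C19")]
            m = res.truth.diplotypes[(row.mother, "CYP2C19")]
            assert c[0] in f and c[1] in m

    def test_unknown_allele_rejected(self, cyp2c19_defs):
        with pytest.raises(ValueError, match="\\*99"):
            make_cfg(cyp2c19_defs, {"*99": 1.0}, n_samples=5, seed=1)

    def test_frequencies_must_sum_to_one(self, cyp2c19_defs):
        with pytest.raises(ValueError, match="sum"):
            make_cfg(cyp2c19_defs, {"*1": 0.5, "*2": 0.4}, n_samples=5, seed=1)

    def test_roundtrip_recovers_exact_haplotype_counts(self, tmp_path, cyp2c19_defs):
        cfg = make_cfg(cyp2c19_defs, {"*1": 0.5, "*2": 0.3, "*35": 0.2},
                       n_samples=200, seed=13)
        res = simulate_cohort(cfg)
        path = tmp_path / "c.vcf"
        res.write(str(path))
        calls = call_cohort(str(path), {"CYP2C19": cyp2c19_defs})
        assert all(
            (c.hap1.call, c.hap2.call) == res.truth.diplotypes[(c.sample, "CYP2C19")]
            for c in calls
        )


# --- QC metric oracles -------------------------------------------------------

def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-fraction enumeration of the conditional heterozygote distribution."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n - n_a
    probs = {}
    for h in range(n_a % 2, min(n_a, n_A) + 1, 2):
        haa = (n_a - h) // 2
        hAA = n - h - haa
        probs[h] = Fraction(
            2 ** h * math.factorial(n) * math.factorial(n_a) * math.factorial(n_A),
            math.factorial(hAA) * math.factorial(h) * math.factorial(haa)
            * math.factorial(2 * n),
        )
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(10, 0, 0) == 1.0

    def test_two_hets_enumeration(self):
        # (0, 2, 0): outcomes h in {0, 2} given 2 A and 2 a alleles
        assert hwe_exact_p(0, 2, 0) == pytest.approx(hwe_oracle(0, 2, 0), abs=1e-12)

    def test_proportionate_large_sample_near_one(self):
        # 25 AA / 50 Aa / 25 aa is the modal configuration
        assert hwe_exact_p(25, 50, 25) > 0.9

    def test_matches_enumeration_oracle_up_to_50_alleles(self):
        for n_AA in range(0, 9):
            for n_Aa in range(0, 9):
                for n_aa in range(0, 9):
                    if n_AA + n_Aa + n_aa == 0:
                        continue
                    assert hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(
                        hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12
                    ), (n_AA, n_Aa, n_aa)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


def mendel_oracle(f, m, c):
    """Possible iff one child allele can come from each parent."""
    transmit = {0: {0}, 1: {0, 1}, 2: {1}}
    child_pairs = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    x, y = child_pairs[c]
    return ((x in transmit[f] and y in transmit[m])
            or (y in transmit[f] and x in transmit[m]))


def gt_array(*genotypes):
    """0/1/2 allele-count genotypes to (n, 2) allele-index arrays."""
    pairs = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (-1, -1)}
    return np.array([pairs[g] for g in genotypes])


TRIO_PED = pd.DataFrame(
    [{"family": "T1", "child": "C", "father": "F", "mother": "M"}]
)


class TestMendel:
    def test_all_27_combinations_against_oracle(self):
        samples = ["F", "M", "C"]
        for f in range(3):
            for m in range(3):
                for c in range(3):
                    rate = mendel_error_rate(gt_array(f, m, c), samples, TRIO_PED)
                    assert rate == (0.0 if mendel_oracle(f, m, c) else 1.0), (f, m, c)

    def test_uncalled_trio_excluded_from_denominator(self):
        rate = mendel_error_rate(gt_array(-1, 0, 2), ["F", "M", "C"], TRIO_PED)
        assert rate == 0.0

    def test_example_cases(self):
        # child 1/1 with both parents 0/0 is an error
        assert mendel_error_rate(gt_array(0, 0, 2), ["F", "M", "C"], TRIO_PED) == 1.0
        # child 0/1 with parents 0/0 x 1/1 is consistent
        assert mendel_error_rate(gt_array(0, 2, 1), ["F", "M", "C"], TRIO_PED) == 0.0


class TestSimpleMetrics:
    def test_missing_rate(self):
        assert missing_rate(gt_array(0, 1, 2)) == 0.0
        assert missing_rate(gt_array(*([-1] + [0] * 19))) == 0.05

    def test_minor_allele_count(self):
        assert minor_allele_count(gt_array(1, *([0] * 9))) == 1
        assert minor_allele_count(gt_array(2, 2, 2)) == 0
        assert minor_allele_count(gt_array(2, 1, 0, 0)) == 3


class TestApplyFilters:
    def _sim(self, tmp_path, cyp2c19_defs, **kw):
        # every definition site polymorphic so MAC never trips on a clean cohort
        cfg = make_cfg(cyp2c19_defs, {"*1": 0.4, "*2": 0.3, "*35": 0.2, "*15": 0.1},
                       n_samples=60, n_trios=5, seed=21, **kw)
        res = simulate_cohort(cfg)
        path = tmp_path / "c.vcf"
        res.write(str(path))
        return res, str(path)

    def test_clean_cohort_fully_retained(self, tmp_path, cyp2c19_defs):
        res, path = self._sim(tmp_path, cyp2c19_defs)
        decisions = apply_filters(path, res.pedigree)
        assert decisions["retained"].all()

    def test_singleton_removed_for_mac(self, tmp_path, vcf_writer, cyp2c19_defs):
        gts = ["1|0"] + ["0|0"] * 19
        path = vcf_writer(tmp_path / "a.vcf", [f"S{i}" for i in range(20)],
                          [("10", 94781859, "rs4244285", "G", "A", gts)])
        decisions = apply_filters(str(path))
        assert not decisions["retained"].item()
        assert "mac" in decisions["failed"].item()

    def test_high_missingness_removed(self, tmp_path, vcf_writer):
        gts = [".|."] * 2 + ["0|1"] * 18
        path = vcf_writer(tmp_path / "a.vcf", [f"S{i}" for i in range(20)],
                          [("10", 100, ".", "G", "A", gts)])
        decisions = apply_filters(str(path))
        assert not decisions["retained"].item()
        assert "missing_rate" in decisions["failed"].item()

    def test_extreme_het_excess_fails_hwe(self, tmp_path, vcf_writer):
        gts = ["0|1"] * 100
        thresholds = QCThresholds(min_hwe_p=1e-3)
        path = vcf_writer(tmp_path / "a.vcf", [f"S{i}" for i in range(100)],
                          [("10", 100, ".", "G", "A", gts)])
        decisions = apply_filters(str(path), thresholds=thresholds)
        assert "hwe" in decisions["failed"].item()

    def test_idempotent(self, tmp_path, cyp2c19_defs, vcf_writer):
        res, path = self._sim(tmp_path, cyp2c19_defs, missing_rate=0.08)
        out1 = str(tmp_path / "f1.vcf")
        out2 = str(tmp_path / "f2.vcf")
        d1 = apply_filters(path, res.pedigree, out_vcf=out1)
        d2 = apply_filters(out1, res.pedigree, out_vcf=out2)
        assert d2["retained"].all()
        body1 = [l for l in open(out1) if not l.startswith("#")]
        body2 = [l for l in open(out2) if not l.startswith("#")]
        assert body1 == body2
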