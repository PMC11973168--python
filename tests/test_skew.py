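import math

import numpy as np
import pytest
from scipy import stats

from helpers import make_placements
from skewdomain.model import GenomicInterval, PhasedVariant
from skewdomain.skew import (
    CorrelationResult,
    ExtremeRegion,
    HaplotypeCounts,
    RegionCandidate,
    SkewResult,
    binomial_two_sided_p,
    consistent_skew_variants,
    count_haplotype_reads,
    cross_assay_skew_correlation,
    genotype_group_meta,
    select_extreme_regions,
    skew_test,
    zero_bias_sites,
)


def oracle_binomial_p(k, n):
    """Independent enumeration oracle: two-sided p as the fsum of all
    outcome probabilities not exceeding the observed one, exact pmf at 0.5."""
    pmf = {}
    for i in range(n + 1):
        pmf[i] = math.comb(n, i) * 2.0 ** (-n)
    obs = pmf[k]
    return min(1.0, math.fsum(v for v in pmf.values() if v <= obs))


def hc(c1, c2, vid="v1", assay="ATAC", donor="d1", **kw):
    return HaplotypeCounts(vid, assay, donor, c1, c2, **kw)


class TestCounting:
    def test_direct_tally(self):
        variants = [PhasedVariant("c", 50, "A", "G", (0, 1), variant_id="v")]
        peaks = [GenomicInterval("c", 0, 100)]
        hap1 = make_placements([(f"a{i}", "hap1", "c", 20, 80) for i in range(12)])
        hap2 = make_placements([(f"b{i}", "hap2", "c", 30, 90) for i in range(8)])
        (rec,) = count_haplotype_reads(
            {"hap1": hap1, "hap2": hap2}, variants, peaks, "ATAC", "d1"
        )
        assert (rec.count_hap1, rec.count_hap2) == (12, 8)
        assert rec.in_peak

    def test_outside_peak_flagged(self):
        variants = [PhasedVariant("c", 500, "A", "G", (0, 1), variant_id="v")]
        peaks = [GenomicInterval("c", 0, 100)]
        hap1 = make_placements([("a", "hap1", "c", 480, 555)])
        hap2 = make_placements([("b", "hap2", "c", 480, 555)])
        (rec,) = count_haplotype_reads(
            {"hap1": hap1, "hap2": hap2}, variants, peaks, "ATAC", "d1"
        )
        assert not rec.in_peak

    def test_homozygous_yields_no_record(self):
        variants = [PhasedVariant("c", 50, "A", "G", (1, 1))]
        empty = make_placements([("a", "hap1", "c", 0, 75)])
        recs = count_haplotype_reads(
            {"hap1": empty, "hap2": empty}, variants,
            [GenomicInterval("c", 0, 100)], "ATAC", "d1",
        )
        assert recs == []

    def test_unphased_het_skipped(self):
        variants = [PhasedVariant("c", 50, "A", "G", (0, 1), phased=False)]
        empty = make_placements([("a", "hap1", "c", 0, 75)])
        recs = count_haplotype_reads(
            {"hap1": empty, "hap2": empty}, variants,
            [GenomicInterval("c", 0, 100)], "ATAC", "d1",
        )
        assert recs == []

    def test_read_boundary_overlap_rule(self):
        # read covering the variant base exactly at its last position counts
        variants = [PhasedVariant("c", 74, "A", "G", (0, 1))]
        hap1 = make_placements([("a", "hap1", "c", 0, 75)])   # covers pos 74
        hap2 = make_placements([("b", "hap2", "c", 75, 150)])  # does not
        (rec,) = count_haplotype_reads(
            {"hap1": hap1, "hap2": hap2}, variants,
            [GenomicInterval("c", 0, 200)], "ATAC", "d1",
        )
        assert (rec.count_hap1, rec.count_hap2) == (1, 0)


class TestZeroing:
    def test_within_tolerance_not_zeroed(self):
        out = zero_bias_sites([hc(50, 50)], {"v1": (100, 100, 102)}, 0.2)
        assert not out[0].zeroed

    def test_depth_discrepancy_zeroed(self):
        out = zero_bias_sites([hc(50, 5)], {"v1": (60, 100, 10)}, 0.2)
        assert out[0].zeroed
        assert (out[0].count_hap1, out[0].count_hap2) == (0, 0)

    def test_reference_dropout_zeroed(self):
        out = zero_bias_sites([hc(40, 45)], {"v1": (0, 90, 85)}, 0.2)
        assert out[0].zeroed

    def test_all_zero_depths_zeroed(self):
        out = zero_bias_sites([hc(0, 0)], {"v1": (0, 0, 0)}, 0.2)
        assert out[0].zeroed

    @pytest.mark.parametrize("tau", [0.0, -0.5, 1.5])
    def test_invalid_tolerance(self, tau):
        with pytest.raises(ValueError):
            zero_bias_sites([hc(1, 1)], {"v1": (2, 2, 2)}, tau)


class TestSkewTest:
    def test_balanced(self):
        r = skew_test(hc(10, 10))
        assert r.skew == 0.5
        assert r.p_value == 1.0
        assert r.direction == "none"

    def test_total_skew_closed_form(self):
        r = skew_test(hc(20, 0))
        assert r.p_value == pytest.approx(2 * 0.5**20, rel=1e-12)
        assert r.direction == "up"

    def test_down_direction(self):
        r = skew_test(hc(0, 20))
        assert r.direction == "down"

    def test_zero_total_undefined(self):
        r = skew_test(hc(0, 0))
        assert r.p_value is None and r.skew is None and r.direction == "none"
        assert r.n_total == 0

    def test_zeroed_undefined(self):
        r = skew_test(hc(0, 0, zeroed=True))
        assert r.p_value is None

    def test_oracle_equivalence_all_n_up_to_30(self):
        for n in range(1, 31):
            for k in range(n + 1):
                assert binomial_two_sided_p(k, n) == oracle_binomial_p(k, n), (k, n)

    def test_betabinomial_more_conservative(self):
        p_bin = skew_test(hc(18, 2)).p_value
        p_bb = skew_test(hc(18, 2), method="betabinomial", rho=0.2).p_value
        assert p_bb > p_bin

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            skew_test(hc(5, 5), method="wasp")

    def test_overdispersion_estimate_recovers_truth(self):
        from skewdomain.skew import estimate_overdispersion

        rng = np.random.default_rng(3)
        rho_true = 0.1
        a = (1 - rho_true) / (2 * rho_true)
        counts = []
        for i in range(500):
            n = 100
            p = rng.beta(a, a)
            c1 = rng.binomial(n, p)
            counts.append(hc(c1, n - c1, vid=f"v{i}"))
        rho_hat = estimate_overdispersion(counts)
        assert rho_hat == pytest.approx(rho_true, abs=0.03)

    def test_overdispersion_needs_enough_sites(self):
        from skewdomain.skew import estimate_overdispersion

        with pytest.raises(ValueError):
            estimate_overdispersion([hc(5, 5)])

    def test_type_one_error_calibration(self):
        # balanced truth: rejection rate at alpha=0.05 must stay at or below
        # 5.5% (discreteness makes the exact test conservative)
        rng = np.random.default_rng(42)
        n_var = 2000
        depth = 60
        rejections = 0
        for c1 in rng.binomial(depth, 0.5, size=n_var):
            p = binomial_two_sided_p(int(c1), depth)
            rejections += p <= 0.05
        rate = rejections / n_var
        assert rate <= 0.055 + 3 * np.sqrt(0.05 * 0.95 / n_var)

    def test_power_monotone_in_imbalance_and_depth(self):
        rng = np.random.default_rng(7)
        rates = {}
        for depth in (20, 60, 180):
            for ratio in (0.5, 0.65, 0.8):
                rej = 0
                n_var = 400
                for c1 in rng.binomial(depth, ratio, size=n_var):
                    rej += binomial_two_sided_p(int(c1), depth) <= 0.05
                rates[(depth, ratio)] = rej / n_var
        for depth in (20, 60, 180):
            assert rates[(depth, 0.5)] <= rates[(depth, 0.65)] + 0.05
            assert rates[(depth, 0.65)] <= rates[(depth, 0.8)] + 0.05
        for ratio in (0.65, 0.8):
            assert rates[(20, ratio)] <= rates[(60, ratio)] + 0.05
            assert rates[(60, ratio)] <= rates[(180, ratio)] + 0.05


class TestConsistency:
    def r(self, vid, donor, skew, p):
        return SkewResult(vid, "ATAC", donor, skew, p, "none", 50)

    def test_agreeing_directions_kept(self):
        results = [self.r("v", "d1", 0.9, 1e-5), self.r("v", "d2", 0.8, 1e-4)]
        assert consistent_skew_variants(results) == ["v"]

    def test_mixed_directions_dropped(self):
        results = [self.r("v", "d1", 0.9, 1e-5), self.r("v", "d2", 0.1, 1e-5)]
        assert consistent_skew_variants(results) == []

    def test_never_significant_dropped(self):
        results = [self.r("v", "d1", 0.6, 0.3), self.r("v", "d2", 0.55, 0.6)]
        assert consistent_skew_variants(results) == []


class TestExtremeRegions:
    def region(self, classes, het_counts=(40, 0)):
        donors = [f"d{i + 1}" for i in range(len(classes))]
        skews = {}
        for d, cls in zip(donors, classes):
            if cls == "het":
                res = skew_test(hc(*het_counts, donor=d))
                skews[d] = res
        return RegionCandidate(
            region=GenomicInterval("c", 0, 400),
            causal_variant_id="v1",
            genotype_class=dict(zip(donors, classes)),
            skew=skews,
        )

    def test_extreme_het_selected(self):
        cand = self.region(["hom-ref", "het", "hom-alt"], het_counts=(40, 0))
        assert binomial_two_sided_p(40, 40) < 1e-4
        assert len(select_extreme_regions([cand])) == 1

    def test_weak_het_rejected(self):
        cand = self.region(["hom-ref", "het", "hom-alt"], het_counts=(12, 8))
        p = binomial_two_sided_p(12, 20)
        assert 0.4 < p < 0.6  # sanity: the derived example's ~0.50
        assert select_extreme_regions([cand]) == []

    def test_all_hom_ref_rejected(self):
        cand = self.region(["hom-ref", "hom-ref", "hom-ref"])
        assert select_extreme_regions([cand]) == []

    def test_no_het_donor_ineligible(self):
        cand = self.region(["hom-ref", "hom-alt", "hom-alt"])
        assert select_extreme_regions([cand]) == []


class TestMeta:
    def make_region(self, i, values):
        classes = ["hom-ref", "het", "hom-alt"]
        return ExtremeRegion(
            region=GenomicInterval("c", i * 1000, i * 1000 + 400),
            causal_variant_id=f"v{i}",
            genotype_class={f"d{j + 1}": classes[j] for j in range(3)},
            coverage={f"d{j + 1}": values[j] for j in range(3)},
        )

    def test_equal_groups_t_zero_p_one(self):
        regions = [self.make_region(i, (5.0, 5.0, 1.0)) for i in range(5)]
        meta = genotype_group_meta(regions)
        test = next(t for t in meta.pairwise
                    if {t.class_a, t.class_b} == {"hom-ref", "het"})
        assert test.t_stat == 0.0 and test.p_value == 1.0

    def test_closed_form_t(self):
        # hom-ref values [2,4,3] vs hom-alt [1,2,3]: diffs [1,2,0]
        vals = [(2.0, 0.0, 1.0), (4.0, 0.0, 2.0), (3.0, 0.0, 3.0)]
        regions = [self.make_region(i, v) for i, v in enumerate(vals)]
        meta = genotype_group_meta(regions)
        test = next(t for t in meta.pairwise
                    if {t.class_a, t.class_b} == {"hom-ref", "hom-alt"})
        assert abs(test.t_stat) == pytest.approx(math.sqrt(3), rel=1e-9)
        expected_p = 2 * stats.t.sf(math.sqrt(3), df=2)
        assert test.p_value == pytest.approx(expected_p, rel=1e-9)
        assert expected_p == pytest.approx(0.225, abs=0.001)

    def test_missing_class_dropped_pairwise(self):
        regions = [self.make_region(i, (5.0, 3.0, 1.0)) for i in range(3)]
        # a region with only hom-ref and het donors
        regions.append(
            ExtremeRegion(
                region=GenomicInterval("c", 9000, 9400),
                causal_variant_id="vx",
                genotype_class={"d1": "hom-ref", "d2": "het"},
                coverage={"d1": 7.0, "d2": 4.0},
            )
        )
        meta = genotype_group_meta(regions)
        ref_alt = next(t for t in meta.pairwise
                       if {t.class_a, t.class_b} == {"hom-ref", "hom-alt"})
        ref_het = next(t for t in meta.pairwise
                       if {t.class_a, t.class_b} == {"hom-ref", "het"})
        assert ref_alt.n_pairs == 3
        assert ref_het.n_pairs == 4

    def test_single_pair_undefined(self):
        regions = [self.make_region(0, (5.0, 3.0, 1.0))]
        meta = genotype_group_meta(regions)
        assert all(t.p_value is None for t in meta.pairwise)

    def test_zero_variance_nonzero_diff_flagged(self):
        regions = [self.make_region(i, (5.0, 3.0, 1.0)) for i in range(4)]
        meta = genotype_group_meta(regions)
        test = next(t for t in meta.pairwise
                    if {t.class_a, t.class_b} == {"hom-ref", "hom-alt"})
        assert test.zero_variance
        assert test.p_value is not None and test.p_value < 1e-300

    def test_simulated_cohort_ordering_and_significance(self):
        """Damage factor 0, coupling 50: cohesin coverage orders
        hom-ref > het > hom-alt and the extreme pair is significant."""
        from skewdomain.synth import SyntheticConfig, simulate_counts, simulate_diploid_donors

        n_regions = 51
        cfg = SyntheticConfig(
            chrom_lengths={"chrS": 300_000}, n_elements=n_regions,
            element_spacing=5000, coupling=50.0, baseline=5.0, depth=100.0,
            damage_factor=0.0, snv_density=0, seed=202,
        )
        forced = [["hom-ref"] * n_regions, ["het"] * n_regions,
                  ["hom-alt"] * n_regions]
        _, donors, intervals = simulate_diploid_donors(cfg, forced_genotypes=forced)
        regions = []
        coverage: dict[str, dict[int, float]] = {}
        for di, donor in enumerate(donors):
            counts, _ = simulate_counts(
                donor.elements, "RAD21", cfg, donor=donor.donor_id,
                seed=1000 + di,
            )
            coverage[donor.donor_id] = {
                i: (c.total / (iv.length / 1000))
                for i, (c, iv) in enumerate(zip(counts, intervals))
            }
        classes = ["hom-ref", "het", "hom-alt"]
        for i, iv in enumerate(intervals):
            regions.append(
                ExtremeRegion(
                    region=iv, causal_variant_id=f"r{i}",
                    genotype_class={d.donor_id: classes[j]
                                    for j, d in enumerate(donors)},
                    coverage={d.donor_id: coverage[d.donor_id][i]
                              for d in donors},
                )
            )
        meta = genotype_group_meta(regions)
        assert (meta.group_means["hom-ref"] > meta.group_means["het"]
                > meta.group_means["hom-alt"])
        test = next(t for t in meta.pairwise
                    if {t.class_a, t.class_b} == {"hom-ref", "hom-alt"})
        assert test.p_value <= 0.05


class TestCrossAssay:
    def res(self, vid, skew, assay="ATAC", donor="d1"):
        return SkewResult(vid, assay, donor, skew, 0.01, "none", 100)

    def test_identical_vectors_rho_one(self):
        a = [self.res(f"v{i}", s) for i, s in enumerate((0.1, 0.4, 0.6, 0.9))]
        b = [self.res(f"v{i}", s, assay="RAD21")
             for i, s in enumerate((0.1, 0.4, 0.6, 0.9))]
        out = cross_assay_skew_correlation(a, b, n_boot=50, seed=0)
        assert out.rho == pytest.approx(1.0)

    def test_opposite_vectors_rho_minus_one(self):
        a = [self.res(f"v{i}", s) for i, s in enumerate((0.1, 0.4, 0.6, 0.9))]
        b = [self.res(f"v{i}", 1 - s, assay="RAD21")
             for i, s in enumerate((0.1, 0.4, 0.6, 0.9))]
        out = cross_assay_skew_correlation(a, b, n_boot=50, seed=0)
        assert out.rho == pytest.approx(-1.0)

    def test_too_few_matches_undefined(self):
        a = [self.res("v1", 0.3), self.res("v2", 0.7)]
        b = [self.res("v1", 0.3, assay="RAD21"), self.res("v2", 0.7, assay="RAD21")]
        assert cross_assay_skew_correlation(a, b) is None

    def test_null_coupling_ci_covers_zero(self):
        """kappa = 0: ATAC and cohesin skews are independent, so the 95% CI
        should cover 0 in >= 90% of replicate cohorts."""
        rng = np.random.default_rng(31)
        n_reps, n_var, depth = 30, 200, 100
        covered = 0
        for rep in range(n_reps):
            a, b = [], []
            for i in range(n_var):
                c1a = rng.binomial(depth, 0.5)
                c1b = rng.binomial(depth, 0.5)
                a.append(self.res(f"v{i}", c1a / depth))
                b.append(self.res(f"v{i}", c1b / depth, assay="RAD21"))
            out = cross_assay_skew_correlation(a, b, n_boot=200, seed=rep)
            covered += out.ci_low <= 0 <= out.ci_high
        assert covered / n_reps >= 0.9

    def test_generator_coupling_recovery(self):
        """Data from the synthetic generator with coupling > 0: ATAC and
        cohesin skews correlate positively (CI excludes 0) at n=200, d=100."""
        from skewdomain.model import GenomicInterval as GI
        from skewdomain.synth import (
            RegulatoryElement,
            SyntheticConfig,
            simulate_counts,
        )

        rng = np.random.default_rng(23)
        cfg = SyntheticConfig(
            chrom_lengths={"chrS": 1_200_000}, n_elements=200,
            element_spacing=5000, coupling=50.0, baseline=2.0,
            depth=100.0, background=0.0, seed=23,
        )
        elems = []
        for i in range(200):
            a1, a2 = rng.uniform(0.05, 1.0, size=2)
            iv = GI("chrS", 5000 + i * 5000, 5400 + i * 5000)
            elems.append(RegulatoryElement(iv, "enhancer", (a1, a2), f"v{i}"))
        atac, _ = simulate_counts(elems, "ATAC", cfg, seed=1)
        rad21, _ = simulate_counts(elems, "RAD21", cfg, seed=2)
        res_a = [skew_test(c) for c in atac if c.total > 0]
        res_b = [skew_test(c) for c in rad21 if c.total > 0]
        out = cross_assay_skew_correlation(res_a, res_b, n_boot=300, seed=9)
        assert out.n >= 190
        assert out.ci_low > 0

    def test_positive_coupling_detected(self):
        """Shared activity drives both assays: CI must exclude 0."""
        rng = np.random.default_rng(17)
        n_var, depth = 200, 100
        a, b = [], []
        for i in range(n_var):
            ratio = rng.uniform(0.1, 0.9)
            a.append(self.res(f"v{i}", rng.binomial(depth, ratio) / depth))
            b.append(self.res(f"v{i}", rng.binomial(depth, ratio) / depth,
                              assay="RAD21"))
        out = cross_assay_skew_correlation(a, b, n_boot=300, seed=5)
        assert out.ci_low > 0
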