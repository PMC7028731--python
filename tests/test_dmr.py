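"""Unit and oracle tests for the DMR caller.

The brute-force reference used for oracle equivalence re-implements run
formation with nested scans, BH with the direct step-up formula and the
permutation screen by explicit enumeration, sharing no code with the caller.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from methcrosstalk.dmr import (
    CandidateRegion,
    DmrParams,
    adjust_fdr,
    call_dmrs,
    compute_beta,
    fds_max,
    fold_difference_score,
    form_candidate_regions,
    permutation_screen,
)
from methcrosstalk import dmr as dmr_mod
from methcrosstalk.meth_io import GenomicInterval

score_region = dmr_mod.test_region  # avoid the test_* name at module scope

from conftest import make_beta_cohort, make_cohort


class TestComputeBeta:
    def test_arithmetic(self):
        assert compute_beta(3, 1) == 0.75

    def test_boundary(self):
        assert compute_beta(0, 20) == 0.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            compute_beta(0, 0)


class TestFoldDifferenceScore:
    @pytest.mark.parametrize(
        "bc,bn,expected",
        [
            (0.5, 0.5, 0.0),
            (1.0, 0.0, math.log2(101)),          # ~6.658
            (0.81, 0.195, 2.0),                   # |log2(0.82/0.205)|
        ],
    )
    def test_direct_formula(self, bc, bn, expected):
        assert fold_difference_score(bc, bn, 0.01) == pytest.approx(expected)

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = rng.random(2)
            fds = fold_difference_score(a, b)
            assert fds == pytest.approx(fold_difference_score(b, a))
            assert 0 <= fds <= fds_max(0.01)


class TestFormCandidateRegions:
    def test_single_run_span(self):
        pos = [1000 + 50 * i for i in range(6)]
        cohort = make_beta_cohort(pos, [[0.8]] * 6, [[0.5]] * 6)
        cands = form_candidate_regions(cohort, min_cpgs=5)
        assert len(cands) == 1
        c = cands[0]
        assert c.direction == "hyper"
        assert (c.interval.start, c.interval.end) == (1000, 1251)  # 5 gaps x 50 bp

    def test_sign_flip_splits_runs_below_min_cpgs(self):
        pos = [1000 + 50 * i for i in range(6)]
        case = [[0.8], [0.8], [0.8], [0.2], [0.8], [0.8]]
        ctrl = [[0.5]] * 6
        cohort = make_beta_cohort(pos, case, ctrl)
        assert form_candidate_regions(cohort, min_cpgs=5) == []
        cands = form_candidate_regions(cohort, min_cpgs=2)
        assert [len(c.site_index) for c in cands] == [3, 2]

    def test_gap_rule_never_merges_distant_clusters(self):
        pos = [100, 150, 200, 1200, 1250, 1300]
        cohort = make_beta_cohort(pos, [[0.8]] * 6, [[0.5]] * 6)
        cands = form_candidate_regions(cohort, max_gap=300, min_cpgs=3)
        assert len(cands) == 2

    def test_zero_delta_breaks_run(self):
        pos = [100, 150, 200, 250, 300]
        case = [[0.8], [0.8], [0.5], [0.8], [0.8]]
        cohort = make_beta_cohort(pos, case, [[0.5]] * 5)
        assert form_candidate_regions(cohort, min_cpgs=3) == []


class TestTestRegion:
    def fisher_oracle(self, table):
        """Two-sided Fisher p by hypergeometric enumeration."""
        (a, b), (c, d) = table
        n1, n2, k = a + b, c + d, a + c
        obs = hypergeom.pmf(a, n1 + n2, k, n1)
        p = 0.0
        for x in range(max(0, k - n2), min(k, n1) + 1):
            px = hypergeom.pmf(x, n1 + n2, k, n1)
            if px <= obs * (1 + 1e-9):
                p += px
        return min(p, 1.0)

    def region_for(self, cohort):
        return form_candidate_regions(cohort, min_site_delta=0.0001, min_cpgs=1)[0]

    def test_matches_hypergeometric_enumeration(self):
        cohort = make_cohort([100], [[20, 10]], [[20, 20]], 1, 1)
        region = self.region_for(cohort)
        p, bc, bn = score_region(region, cohort)
        assert p == pytest.approx(self.fisher_oracle([[20, 0], [10, 10]]))
        assert (bc, bn) == (1.0, 0.5)

    def test_identical_groups_p_one(self):
        cohort = make_cohort([100], [[5, 5]], [[10, 10]], 1, 1)
        region = CandidateRegion(GenomicInterval("chr1", 100, 101), (0,), "hyper")
        # equal group rates: association p must be 1
        assert score_region(region, cohort)[0] == pytest.approx(1.0)

    def test_two_by_two_n2(self):
        cohort = make_cohort([100], [[1, 0]], [[1, 1]], 1, 1)
        region = self.region_for(cohort)
        assert score_region(region, cohort)[0] == pytest.approx(1.0)


class TestAdjustFdr:
    def bh_oracle(self, p):
        """Direct step-up formula: q_i = min over p_(j) >= p_(i) of p_(j)*m/j."""
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        for i in range(m):
            q[i] = min(
                min(p[order[j]] * m / (j + 1) for j in range(m) if p[order[j]] >= p[i] - 1e-15),
                1.0,
            )
        return q

    def test_worked_example(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_identity(self):
        assert adjust_fdr([0.5]) == pytest.approx([0.5])

    def test_all_ones(self):
        assert adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(adjust_fdr(p), self.bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestPermutationScreen:
    def toy_region(self, cohort):
        return form_candidate_regions(cohort, min_site_delta=0.0001, min_cpgs=1)[0]

    def test_perfect_separation_exact_mode(self):
        # 6v6, case beta 1, ctrl beta 0: only the true split and its
        # complement reach |delta| = 1 among all C(12,6)=924 splits
        pos = [100 + 10 * i for i in range(6)]
        cohort = make_beta_cohort(pos, [[1.0] * 6] * 6, [[0.0] * 6] * 6)
        region = self.toy_region(cohort)
        assert permutation_screen(region, cohort) == pytest.approx(2 / 924)

    def test_exchangeable_null_p_one(self):
        pos = [100, 110, 120, 130, 140]
        cohort = make_beta_cohort(pos, [[0.5] * 6] * 5, [[0.5] * 6] * 5)
        region = GenomicInterval("chr1", 100, 141)
        cand = CandidateRegion(region, tuple(range(5)), "hyper")
        assert permutation_screen(cand, cohort) == pytest.approx(1.0)

    def test_sampling_mode_deterministic(self):
        rng = np.random.default_rng(3)
        pos = [100 + 10 * i for i in range(5)]
        case = rng.random((5, 4))
        ctrl = rng.random((5, 4)) * 0.3
        cohort = make_beta_cohort(pos, case, ctrl)
        region = self.toy_region(cohort)
        p1 = permutation_screen(region, cohort, n_perm=150, seed=11, exact_limit=1)
        p2 = permutation_screen(region, cohort, n_perm=150, seed=11, exact_limit=1)
        assert p1 == p2 and 0 < p1 <= 1


def brute_force_caller(cohort, params):
    """Independent reference: nested-loop runs + direct filters."""
    b = cohort.betas()
    ci, ni = cohort.case_index, cohort.control_index
    delta = np.nanmean(b[:, ci], axis=1) - np.nanmean(b[:, ni], axis=1)
    pos = cohort.sites["pos"].to_numpy()
    member = [
        0 if (np.isnan(d) or abs(d) < params.min_site_delta or d == 0) else (1 if d > 0 else -1)
        for d in delta
    ]
    runs = []
    i = 0
    while i < len(member):
        if member[i] == 0:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(member)
            and member[j + 1] == member[i]
            and pos[j + 1] - pos[j] <= params.max_gap
        ):
            j += 1
        if j - i + 1 >= params.min_cpgs:
            runs.append((i, j, member[i]))
        i = j + 1
    from scipy.stats import fisher_exact

    kept = []
    pvals = []
    for (i, j, sgn) in runs:
        mc = np.nansum(cohort.meth[i : j + 1][:, ci])
        tc = np.nansum(cohort.total[i : j + 1][:, ci])
        mn = np.nansum(cohort.meth[i : j + 1][:, ni])
        tn = np.nansum(cohort.total[i : j + 1][:, ni])
        p = fisher_exact(
            [[int(mc), int(tc - mc)], [int(mn), int(tn - mn)]], alternative="two-sided"
        )[1]
        pvals.append(p)
        kept.append((i, j, sgn, p))
    m = len(pvals)
    out = []
    for (i, j, sgn, p) in kept:
        rank_q = min(
            (pj * m / (sorted(pvals).index(pj) + 1) for pj in sorted(pvals) if pj >= p),
            default=1.0,
        )
        q = min(rank_q, 1.0)
        length = pos[j] - pos[i] + 1
        if length > params.min_length and p < params.max_p and q < params.max_q:
            out.append((int(pos[i]), int(pos[j]) + 1, "hyper" if sgn > 0 else "hypo"))
    return out


class TestCallDmrs:
    def test_length_boundary_strictly_more_than_200(self):
        # half-open interval spans first..last+1; a 200 bp region is excluded
        # ("more than 200 bp" is strict), 201 bp is kept
        def cohort_with_span(last_offset):
            pos = [1000, 1050, 1100, 1150, 1000 + last_offset]
            return make_beta_cohort(pos, [[0.9] * 6] * 5, [[0.1] * 6] * 5)

        params = DmrParams(seed=0)
        assert call_dmrs(cohort_with_span(199), params) == []      # length 200
        assert len(call_dmrs(cohort_with_span(200), params)) == 1  # length 201

    def test_oracle_equivalence_small_cohorts(self):
        rng = np.random.default_rng(5)
        params = DmrParams(min_cpgs=3, min_length=50, max_perm_p=1.1, seed=0)
        for trial in range(15):
            n_sites = int(rng.integers(6, 20))
            pos = np.cumsum(rng.integers(20, 200, n_sites)) + 100
            case = rng.random((n_sites, 4))
            ctrl = rng.random((n_sites, 4))
            cohort = make_beta_cohort(pos, case, ctrl, depth=50)
            got = [
                (d.interval.start, d.interval.end, d.direction)
                for d in call_dmrs(cohort, params)
            ]
            expected = brute_force_caller(cohort, params)
            assert got == sorted(expected), f"trial {trial}"

    def test_direction_consistency_and_fds_bound(self):
        from methcrosstalk.simulate import SimConfig, generate_methylation_cohort

        cfg = SimConfig(seed=2, n_genes=40, chrom_length=900_000, n_hyper_dmr=6,
                        n_hypo_dmr=4, n_marker_dmr=2)
        cohort, _ = generate_methylation_cohort(cfg)
        dmrs = call_dmrs(cohort, DmrParams(seed=2))
        assert dmrs, "expected calls on planted data"
        for d in dmrs:
            assert (d.direction == "hyper") == (d.beta_case > d.beta_ctrl)
            assert d.fds <= fds_max(0.01) + 1e-12
            assert 0 <= d.q_value <= 1
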