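import math

import numpy as np
import pytest

from txdemux.demux import (
    AF_FLOOR,
    DemuxConfig,
    GenotypeModel,
    InsufficientCellsError,
    af_distance,
    cell_maf_profiles,
    classify_cells,
    demultiplex,
    estimate_genotype,
    genotype_score,
    refine,
    select_eligible_cells,
    simulate_doublet_profiles,
    stage1_discover,
    stage2_rescue,
)
from txdemux.simulate import SimConfig, draw_genotypes, simulate_sample

from conftest import make_matrix, opposite_pair


class TestMafProfiles:
    def test_fraction_definition_and_absence(self):
        m = make_matrix([[1, 5, 0]], [[4, 5, 0]])
        af, cov = cell_maf_profiles(m)
        assert af[0, 0] == pytest.approx(0.25)
        assert af[1, 0] == pytest.approx(1.0)
        assert not cov[2, 0]  # total 0: entry absent, not zero

    def test_covered_zero_alt_is_observed_zero(self):
        m = make_matrix([[0, 0]], [[3, 0]])
        af, cov = cell_maf_profiles(m)
        assert cov[0, 0] and af[0, 0] == 0.0
        assert not cov[1, 0]


class TestEligibility:
    def test_threshold(self):
        tot = np.zeros((30, 25), dtype=int)
        tot[:30, :10] = 1   # 10 cells cover 30 sites
        tot[:5, 10:] = 1    # 15 cells cover 5 sites
        m = make_matrix(np.zeros_like(tot), tot)
        cfg = DemuxConfig(min_snvs_per_cell=25, knn_k=2)
        assert list(select_eligible_cells(m, cfg)) == list(range(10))

    def test_insufficient_cells_error(self):
        tot = np.ones((30, 5), dtype=int)
        m = make_matrix(np.zeros_like(tot), tot)
        with pytest.raises(InsufficientCellsError):
            select_eligible_cells(m, DemuxConfig(min_snvs_per_cell=25, knn_k=10))


class TestAfDistance:
    def test_identity_opposite_and_undefined(self):
        af1 = np.zeros(20)
        af2 = np.ones(20)
        cov = np.ones(20, dtype=bool)
        assert af_distance(af1, cov, af1, cov) == 0.0
        assert af_distance(af1, cov, af2, cov) == 1.0
        cov3 = np.zeros(20, dtype=bool)
        cov3[:3] = True
        assert math.isnan(af_distance(af1, cov, af2, cov3, min_shared_sites=5))

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.random(15), rng.random(15)
            ca, cb = rng.random(15) < 0.7, rng.random(15) < 0.7
            d1 = af_distance(a, ca, b, cb, 1)
            d2 = af_distance(b, cb, a, ca, 1)
            if not math.isnan(d1):
                assert d1 == pytest.approx(d2)
                assert 0.0 <= d1 <= 1.0


class TestEstimateGenotype:
    @pytest.mark.parametrize(
        "alt,tot,expected",
        [(0, 0, 0.5), (10, 10, 11 / 12), (5, 10, 0.5)],
    )
    def test_pseudocount_formula(self, alt, tot, expected):
        m = make_matrix([[alt]], [[tot]])
        af, support = estimate_genotype(m, np.array([0]), pseudocount=1.0)
        assert af[0] == pytest.approx(expected)
        assert support[0] == tot

    def test_empty_cell_set_rejected(self):
        m = make_matrix([[1]], [[2]])
        with pytest.raises(ValueError, match="empty"):
            estimate_genotype(m, np.array([], dtype=int))


class TestGenotypeScore:
    def test_perfect_fit_near_zero(self):
        # cell af matches a clamped homozygous model at every site
        tot = np.full((10, 1), 5)
        alt = np.zeros_like(tot)
        m = make_matrix(alt, tot)
        score = genotype_score(m, np.zeros(10))
        assert score[0] == pytest.approx(math.log(1 - AF_FLOOR), abs=1e-9)

    def test_homozygous_opposite_attains_floor(self):
        # 50 sites, depth 2, all alt, model af 0 (clamped to the floor):
        # every read contributes log(AF_FLOOR)
        tot = np.full((50, 1), 2)
        alt = tot.copy()
        m = make_matrix(alt, tot)
        score = genotype_score(m, np.zeros(50))
        assert score[0] == pytest.approx(math.log(AF_FLOOR))

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        tot = rng.integers(0, 5, (20, 10))
        alt = rng.binomial(tot, 0.3)
        m = make_matrix(alt, tot)
        af = rng.random(20)
        assert np.array_equal(
            genotype_score(m, af), genotype_score(m, af), equal_nan=True
        )

    def test_zero_coverage_cell_undefined(self):
        m = make_matrix([[1, 0]], [[2, 0]])
        score = genotype_score(m, np.array([0.5]))
        assert math.isnan(score[1])


class TestDoubletSimulation:
    def test_counts_are_parent_sums(self):
        m = make_matrix([[0, 4]], [[4, 4]])
        alt, tot = simulate_doublet_profiles(m, [0], [1], n=3, seed=0)
        assert (np.asarray(alt.todense()) == 4).all()
        assert (np.asarray(tot.todense()) == 8).all()

    def test_invalid_n(self):
        m = make_matrix([[0, 4]], [[4, 4]])
        with pytest.raises(ValueError):
            simulate_doublet_profiles(m, [0], [1], n=0, seed=0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        tot = rng.integers(0, 4, (10, 20))
        alt = rng.binomial(tot, 0.5)
        m = make_matrix(alt, tot)
        a1, t1 = simulate_doublet_profiles(m, range(10), range(10, 20), 15, seed=9)
        a2, t2 = simulate_doublet_profiles(m, range(10), range(10, 20), 15, seed=9)
        assert (a1 != a2).nnz == 0 and (t1 != t2).nnz == 0


def brute_force_classify(matrix, model, config):
    """Independent per-cell enumeration of the argmax-likelihood label."""
    alt = np.asarray(matrix.alt.todense())
    tot = np.asarray(matrix.total.todense())
    profiles = [model.af_gt1, model.af_gt2, model.af_doublet]
    labels = []
    for c in range(matrix.n_cells):
        if (tot[:, c] > 0).sum() == 0:
            labels.append("unassigned")
            continue
        lls = []
        for af in profiles:
            ll = 0.0
            for s in range(matrix.n_sites):
                if tot[s, c] == 0:
                    continue
                p = min(max(af[s], AF_FLOOR), 1 - AF_FLOOR)
                ll += alt[s, c] * math.log(p) + (tot[s, c] - alt[s, c]) * math.log(1 - p)
            lls.append(ll)
        order = sorted(range(3), key=lambda i: lls[i])
        margin = lls[order[-1]] - lls[order[-2]]
        if margin < config.assign_margin:
            labels.append("unassigned")
        else:
            labels.append(["GT1", "GT2", "doublet"][order[-1]])
    return np.asarray(labels, dtype=object)


class TestClassifyCells:
    def test_matches_brute_force_on_tiny_instances(self):
        rng = np.random.default_rng(21)
        cfg = DemuxConfig(assign_margin=1.0)
        for trial in range(40):
            n_sites = rng.integers(1, 6)
            n_cells = rng.integers(1, 11)
            tot = rng.integers(0, 5, (n_sites, n_cells))
            alt = rng.binomial(tot, rng.random((n_sites, 1)))
            m = make_matrix(alt, tot)
            model = GenotypeModel(
                af_gt1=rng.random(n_sites),
                support_gt1=rng.integers(1, 50, n_sites),
                af_gt2=rng.random(n_sites),
                support_gt2=rng.integers(1, 50, n_sites),
                n_cells_gt1=5,
                n_cells_gt2=5,
            )
            got, _ = classify_cells(m, model, cfg, doublet_threshold=-np.inf)
            expected = brute_force_classify(m, model, cfg)
            assert list(got) == list(expected), f"trial {trial}"

    def test_zero_coverage_cell_unassigned(self):
        m = make_matrix([[1, 0]], [[2, 0]])
        model = GenotypeModel(np.array([0.1]), np.array([10]),
                              np.array([0.9]), np.array([10]))
        labels, _ = classify_cells(m, model, DemuxConfig())
        assert labels[1] == "unassigned"

    def test_synthetic_doublets_mostly_self_classify(self, mixed_sample, mixed_result):
        # build doublets from confidently assigned singlets and check that
        # at least the calibration quantile of them is recovered as doublet
        m = mixed_sample.matrix
        labels = mixed_result.labels
        gt1 = np.flatnonzero(labels == "GT1")
        gt2 = np.flatnonzero(labels == "GT2")
        alt, tot = simulate_doublet_profiles(m, gt1, gt2, n=100, seed=5)
        from txdemux.matrix import AlleleCountMatrix

        synth = AlleleCountMatrix(
            sites=list(m.sites),
            barcodes=[f"D{i}" for i in range(100)],
            alt=alt,
            total=tot,
        )
        cfg = DemuxConfig(seed=1)
        af1, s1 = estimate_genotype(m, gt1)
        af2, s2 = estimate_genotype(m, gt2)
        model = GenotypeModel(af1, s1, af2, s2, gt1.size, gt2.size)
        lab, _ = classify_cells(synth, model, cfg, doublet_threshold=-np.inf)
        assert np.mean(lab == "doublet") >= 0.95


class TestStage1:
    def test_separates_opposite_genotypes_exactly(self):
        pair = opposite_pair(100)
        cfg = SimConfig(n_total=400, n_sites=100, minor_counts=(200,),
                        doublet_rate=0.0, seed=5)
        s = simulate_sample(pair, 200, 0.0, cfg, seed=9)
        g1, g2 = stage1_discover(s.matrix, DemuxConfig(seed=1))
        assert {tuple(sorted(s.truth[g1])), tuple(sorted(s.truth[g2]))} == {
            tuple(["GT1"] * 200),
            tuple(["GT2"] * 200),
        }

    def test_single_genotype_returns_none(self):
        pair = opposite_pair(100)
        pair.gt2[:] = pair.gt1
        pair.true_af2[:] = pair.true_af1
        cfg = SimConfig(n_total=400, n_sites=100, minor_counts=(1,),
                        doublet_rate=0.0, seed=5)
        s = simulate_sample(pair, 1, 0.0, cfg, seed=9)
        assert stage1_discover(s.matrix, DemuxConfig(seed=1)) is None


class TestStage2:
    def test_rescues_exactly_eight_minor_cells(self, sim_pair):
        cfg = SimConfig(n_total=1000, n_sites=400, minor_counts=(8,),
                        doublet_rate=0.0, seed=3)
        s = simulate_sample(sim_pair, 8, 0.0, cfg, seed=21)
        dc = DemuxConfig(seed=1)
        elig = select_eligible_cells(s.matrix, dc)
        dom_af, _ = estimate_genotype(s.matrix, elig)
        flagged = stage2_rescue(s.matrix, dom_af, dc, eligible=elig)
        assert flagged is not None
        assert set(flagged) == set(np.flatnonzero(s.truth == "GT2"))

    def test_single_genotype_yields_none(self):
        pair = opposite_pair(200)
        pair.gt2[:] = pair.gt1
        pair.true_af2[:] = pair.true_af1
        cfg = SimConfig(n_total=500, n_sites=200, minor_counts=(1,),
                        doublet_rate=0.0, seed=5)
        s = simulate_sample(pair, 1, 0.0, cfg, seed=9)
        dc = DemuxConfig(seed=1)
        elig = select_eligible_cells(s.matrix, dc)
        dom_af, _ = estimate_genotype(s.matrix, elig)
        assert stage2_rescue(s.matrix, dom_af, dc, eligible=elig) is None

    def test_identical_scores_mad_zero_none(self):
        # every cell identical -> all scores equal -> MAD 0 -> no rescue
        tot = np.full((30, 40), 2)
        alt = np.zeros_like(tot)
        m = make_matrix(alt, tot)
        dc = DemuxConfig(seed=1, min_snvs_per_cell=5)
        elig = select_eligible_cells(m, dc)
        dom_af, _ = estimate_genotype(m, elig)
        assert stage2_rescue(m, dom_af, dc, eligible=elig) is None


class TestRefine:
    def test_loglik_nondecreasing_and_terminates(self, mixed_sample):
        dc = DemuxConfig(seed=1)
        groups = stage1_discover(mixed_sample.matrix, dc)
        assert groups is not None
        result, trace = refine(mixed_sample.matrix, groups[0], groups[1], dc)
        assert result is not None
        assert result.n_iterations <= dc.max_iter
        diffs = np.diff(trace)
        # monotone up to a small relative wobble from the derived doublet
        # profile and the pseudocount prior
        assert (diffs >= -1e-4 * np.abs(trace[:-1])).all()

    def test_fixed_point_detected_quickly(self, mixed_sample, mixed_result):
        # re-running from the converged partition terminates immediately
        labels = mixed_result.labels
        elig = select_eligible_cells(mixed_sample.matrix, DemuxConfig(seed=1))
        em = np.zeros(mixed_sample.matrix.n_cells, bool)
        em[elig] = True
        gt1 = np.flatnonzero((labels == "GT1") & em)
        gt2 = np.flatnonzero((labels == "GT2") & em)
        result, trace = refine(mixed_sample.matrix, gt1, gt2, DemuxConfig(seed=1))
        assert result.converged
        assert result.n_iterations <= 3

    def test_max_iter_contract(self, mixed_sample):
        dc = DemuxConfig(seed=1, max_iter=1)
        groups = stage1_discover(mixed_sample.matrix, dc)
        result, trace = refine(mixed_sample.matrix, groups[0], groups[1], dc)
        assert result.n_iterations == 1
        assert len(trace) == 1

    def test_swapped_initialization_same_partition(self, mixed_sample):
        dc = DemuxConfig(seed=1)
        g1, g2 = stage1_discover(mixed_sample.matrix, dc)
        r_ab, _ = refine(mixed_sample.matrix, g1, g2, dc)
        r_ba, _ = refine(mixed_sample.matrix, g2, g1, dc)
        swap = {"GT1": "GT2", "GT2": "GT1"}
        swapped = np.asarray([swap.get(l, l) for l in r_ba.labels], dtype=object)
        assert np.array_equal(r_ab.labels, swapped)


class TestDemultiplex:
    def test_labels_partition_barcodes(self, mixed_sample, mixed_result):
        counts = mixed_result.counts()
        assert sum(counts.values()) == mixed_sample.matrix.n_cells
        assert set(mixed_result.labels) <= {"GT1", "GT2", "doublet", "unassigned"}

    def test_deterministic_given_seed(self, mixed_sample):
        r1 = demultiplex(mixed_sample.matrix, DemuxConfig(seed=4))
        r2 = demultiplex(mixed_sample.matrix, DemuxConfig(seed=4))
        assert np.array_equal(r1.labels, r2.labels)
        assert np.allclose(r1.loglik_gt1, r2.loglik_gt1)

    def test_single_genotype_sample_reports_no_second(self):
        pair = opposite_pair(200)
        pair.gt2[:] = pair.gt1
        pair.true_af2[:] = pair.true_af1
        cfg = SimConfig(n_total=300, n_sites=200, minor_counts=(1,),
                        doublet_rate=0.0, seed=5)
        s = simulate_sample(pair, 1, 0.0, cfg, seed=9)
        res = demultiplex(s.matrix, DemuxConfig(seed=1))
        assert not res.second_genotype_found
        assert set(res.labels) <= {"GT1", "unassigned"}

    def test_empty_matrix_rejected(self):
        m = make_matrix(np.zeros((0, 2)), np.zeros((0, 2)))
        with pytest.raises(ValueError):
            demultiplex(m, DemuxConfig())

    def test_af_recovery_on_supported_sites(self, mixed_sample, mixed_result, sim_pair):
        # estimated genotype allele fractions track the simulation truth at
        # well-supported sites (ambient 10% shifts them by well under 0.05)
        from txdemux.benchmark import match_labels

        mapping = match_labels(mixed_result.labels, mixed_sample.truth)
        m = mixed_sample.matrix
        truth_af = {"GT1": sim_pair.true_af1, "GT2": sim_pair.true_af2}
        for pred_label in ("GT1", "GT2"):
            cells = np.flatnonzero(np.asarray(mixed_result.labels) == pred_label)
            true_vec = truth_af[mapping[pred_label]]
            af, support = estimate_genotype(m, cells)
            mask = support >= 20
            mae = float(np.abs(af[mask] - true_vec[mask]).mean())
            assert mae <= 0.05
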