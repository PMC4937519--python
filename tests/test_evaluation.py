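"""Cα-RMSD, correlation, precision, bootstrap recovery and cutoff scans."""

import numpy as np
import pytest

from xlwalk.evaluation import (bootstrap_recovery, build_score_matrix,
                               calpha_rmsd, cutoff_scan, evaluate_ensemble,
                               make_theoretical_dataset, pearson,
                               precision_top_k, subset_size)
from xlwalk.fixtures import FixtureSpec, make_fixture
from xlwalk.scoring import ScoringConfig
from xlwalk.structures_io import (Atom, NormalParams, StructureModel,
                                  fit_sasd_distribution)


def ca_structure(positions, chain="A"):
    return StructureModel([
        Atom(i + 1, "CA", "C", chain, i + 1, "ALA", np.asarray(p, float))
        for i, p in enumerate(positions)])


def kabsch_rmsd_oracle(x, y):
    """Independent closed-form Kabsch superposition (plain numpy SVD)."""
    x = np.asarray(x, float) - np.mean(x, axis=0)
    y = np.asarray(y, float) - np.mean(y, axis=0)
    u, s, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1, 1, d]) @ vt
    diff = x @ rot - y
    return float(np.sqrt((diff ** 2).sum() / len(x)))


class TestCalphaRMSD:
    def test_identity_is_zero(self):
        s = ca_structure(np.random.default_rng(0).normal(0, 5, (10, 3)))
        assert calpha_rmsd(s, s) == pytest.approx(0.0, abs=1e-6)

    def test_translation_invariance(self):
        pos = np.random.default_rng(1).normal(0, 5, (10, 3))
        a = ca_structure(pos)
        b = ca_structure(pos + np.array([5.0, 5.0, 5.0]))
        assert calpha_rmsd(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation
        pos = np.random.default_rng(2).normal(0, 5, (12, 3))
        rot = Rotation.from_euler("xyz", [30, 45, 60], degrees=True)
        assert calpha_rmsd(ca_structure(pos),
                           ca_structure(rot.apply(pos))) == \
            pytest.approx(0.0, abs=1e-6)

    def test_matches_independent_kabsch(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(0, 5, (10, 3))
        moved = pos.copy()
        moved[0] += np.array([2.0, 0.0, 0.0])
        got = calpha_rmsd(ca_structure(pos), ca_structure(moved))
        assert got == pytest.approx(kabsch_rmsd_oracle(pos, moved), abs=1e-6)

    def test_matches_biotite_superimpose(self):
        import biotite.structure as struc
        rng = np.random.default_rng(4)
        pos = rng.normal(0, 6, (15, 3))
        moved = pos + rng.normal(0, 1.0, (15, 3))
        arr = struc.AtomArray(15)
        arr.coord = np.asarray(pos, np.float32)
        arr2 = struc.AtomArray(15)
        arr2.coord = np.asarray(moved, np.float32)
        fitted, _ = struc.superimpose(arr, arr2)
        expected = float(struc.rmsd(arr, fitted))
        got = calpha_rmsd(ca_structure(moved), ca_structure(pos))
        assert got == pytest.approx(expected, abs=1e-4)

    def test_too_few_shared_residues(self):
        a = ca_structure([(0, 0, 0), (1, 0, 0)])
        b = ca_structure([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(ValueError, match=">= 3"):
            calpha_rmsd(a, b)


class TestPearson:
    def test_perfect_positive(self):
        rmsds = [1.0, 2.0, 5.0, 9.0]
        assert pearson(rmsds, rmsds) == pytest.approx(1.0)

    def test_perfect_negative(self):
        rmsds = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(-rmsds, rmsds) == pytest.approx(-1.0)

    def test_five_point_table(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # hand computation: cov/sx/sy
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pearson(x, y) == pytest.approx(expected)

    def test_zero_variance_is_nan(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestPrecisionTopK:
    def test_all_true_positives(self):
        scores = np.linspace(0, 1, 30)
        rmsds = np.full(30, 2.0)
        assert precision_top_k(scores, rmsds, k=20) == pytest.approx(1.0)

    def test_half_true_positives_no_ties(self):
        scores = np.linspace(0, 1, 40)
        rmsds = np.where(np.arange(40) % 2 == 0, 2.0, 10.0)
        assert precision_top_k(scores, rmsds, k=20) == pytest.approx(0.5)

    def test_deterministic_without_ties(self):
        rng = np.random.default_rng(5)
        scores = rng.permutation(np.linspace(0, 1, 30))
        rmsds = rng.uniform(0, 10, 30)
        a = precision_top_k(scores, rmsds, resamples=1, seed=0)
        b = precision_top_k(scores, rmsds, resamples=999, seed=12345)
        assert a == b

    def test_tie_cluster_hypergeometric(self):
        """30 models tied at the best score, 15 of them true positives,
        k=20: expected precision 20·(15/30)/20 = 0.5."""
        scores = np.zeros(30)
        rmsds = np.concatenate([np.full(15, 2.0), np.full(15, 10.0)])
        got = precision_top_k(scores, rmsds, k=20, resamples=2000, seed=7)
        assert got == pytest.approx(0.5, abs=0.02)

    def test_fewer_than_k_raises(self):
        with pytest.raises(ValueError):
            precision_top_k([0.0] * 5, [1.0] * 5, k=20)


class TestTheoreticalDataset:
    def test_free_pair_included(self, free_pair_ca):
        fx, _, _, result = free_pair_ca
        ds = make_theoretical_dataset(fx.structure, cutoff=33.0,
                                      reference_sasd=result)
        assert len(ds) == 1 and ds.provenance == "theoretical"

    def test_wall_pair_excluded_by_cutoff(self, wall_case):
        fx, _, _, result = wall_case
        d = result.get(("A", 1), ("A", 2)).distance  # ≈ 37.5 Å
        ds = make_theoretical_dataset(fx.structure, cutoff=33.0,
                                      reference_sasd=result)
        assert d > 33.0 and len(ds) == 0

    def test_buried_residue_excluded(self, buried_case):
        fx, _, _, result = buried_case
        ds = make_theoretical_dataset(fx.structure, cutoff=np.inf,
                                      reference_sasd=result)
        buried = fx.truth["buried_residue"]
        assert all(buried not in rec.pair for rec in ds)

    def test_infinite_cutoff_returns_every_measured_pair(self, wall_case):
        fx, _, _, result = wall_case
        ds = make_theoretical_dataset(fx.structure, cutoff=np.inf,
                                      reference_sasd=result)
        assert len(ds) == len(result.measured())


class TestSubsetSize:
    @pytest.mark.parametrize("pct,n,expected", [
        (20, 10, 2), (1, 10, 1), (25, 10, 3), (5, 10, 1), (90, 10, 9),
        (15, 10, 2),  # 1.5 rounds half-up
    ])
    def test_round_half_up_floor_one(self, pct, n, expected):
        assert subset_size(pct, n) == expected


@pytest.fixture(scope="module")
def ensemble_eval(small_ensemble):
    fx, ref_dist, distances, rmsds = small_ensemble
    values = list(ref_dist.measured().values())
    dist = fit_sasd_distribution(values, 33.0)
    config = ScoringConfig(distribution=dist)
    theoretical = make_theoretical_dataset(fx.structure,
                                           reference_sasd=ref_dist)
    return fx, distances, rmsds, config, theoretical


class TestEnsembleEvaluation:
    def test_mnxl_correlates_with_quality(self, ensemble_eval):
        _, distances, rmsds, config, theoretical = ensemble_eval
        ev = evaluate_ensemble(distances, rmsds, theoretical, config, k=5)
        assert ev.correlation > 0.5

    def test_scores_cover_unit_interval(self, ensemble_eval):
        _, distances, rmsds, config, theoretical = ensemble_eval
        ev = evaluate_ensemble(distances, rmsds, theoretical, config, k=5)
        assert ev.normalized_scores.min() == pytest.approx(0.0)
        assert ev.normalized_scores.max() == pytest.approx(1.0)


class TestBootstrap:
    def test_full_recovery_equals_direct_evaluation(self, ensemble_eval):
        _, distances, rmsds, config, theoretical = ensemble_eval
        curve = bootstrap_recovery(theoretical, distances, rmsds, config,
                                   percent_ladder=[100], n_boot=3, seed=0,
                                   k=5)
        ev = evaluate_ensemble(distances, rmsds, theoretical, config, k=5)
        assert curve.subset_sizes == [len(theoretical)]
        assert curve.mean_correlation[0] == pytest.approx(ev.correlation)

    def test_bit_reproducible_from_seed(self, ensemble_eval):
        _, distances, rmsds, config, theoretical = ensemble_eval
        kw = dict(percent_ladder=[50, 10], n_boot=20, k=5)
        a = bootstrap_recovery(theoretical, distances, rmsds, config,
                               seed=42, **kw)
        b = bootstrap_recovery(theoretical, distances, rmsds, config,
                               seed=42, **kw)
        assert a.mean_correlation == b.mean_correlation
        assert a.mean_precision == b.mean_precision

    def test_empty_theoretical_set_raises(self, ensemble_eval):
        from xlwalk.structures_io import CrosslinkDataset
        _, distances, rmsds, config, _ = ensemble_eval
        with pytest.raises(ValueError):
            bootstrap_recovery(CrosslinkDataset([]), distances, rmsds, config)

    def test_score_matrix_sums_match_direct_scores(self, ensemble_eval):
        from xlwalk.scoring import classify_crosslinks, score_mnxl
        _, distances, rmsds, config, theoretical = ensemble_eval
        matrix = build_score_matrix(distances, theoretical, config)
        full = np.arange(len(theoretical))
        raw = matrix.subset_raw("mnxl", full)
        for i, name in enumerate(matrix.names):
            cls = classify_crosslinks(theoretical, distances[name], config)
            assert raw[i] == pytest.approx(score_mnxl(cls, config))


class TestCutoffScan:
    def test_single_cutoff_matches_direct(self, ensemble_eval):
        _, distances, rmsds, config, theoretical = ensemble_eval
        rows = cutoff_scan(distances, rmsds, theoretical, cutoffs=[33.0],
                           config=config, k=5)
        ev = evaluate_ensemble(distances, rmsds, theoretical,
                               config.with_cutoff(33.0), k=5)
        assert rows[0]["correlation"] == pytest.approx(ev.correlation)

    def test_invariant_when_no_classification_changes(self):
        """If every crosslink sits below the smallest cutoff in every model,
        the scan output is identical across cutoffs."""
        from xlwalk.sasd_search import PairResult, SASDResult, MEASURED
        from xlwalk.structures_io import CrosslinkDataset, CrosslinkRecord
        rng = np.random.default_rng(8)
        pairs = [(("A", 2 * i + 1), ("A", 2 * i + 2)) for i in range(4)]
        dataset = CrosslinkDataset(
            [CrosslinkRecord(a[0], a[1], b[0], b[1]) for a, b in pairs])
        distances, rmsds = {}, {}
        for m in range(6):
            res = SASDResult()
            for p in pairs:
                res.pairs[p] = PairResult(p, MEASURED,
                                          float(rng.uniform(5, 15)))
            distances[f"m{m}"] = res
            rmsds[f"m{m}"] = float(rng.uniform(0, 10))
        config = ScoringConfig(distribution=NormalParams(10.0, 3.0))
        rows = cutoff_scan(distances, rmsds, dataset,
                           cutoffs=[20.0, 40.0, 60.0], config=config, k=3)
        rs = [r["correlation"] for r in rows]
        assert rs[0] == pytest.approx(rs[1]) == pytest.approx(rs[2])
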