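import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import netcbi as nc
from netcbi.errors import ParameterError, UndefinedAUCError
from netcbi.evaluation import _fast_auc

from conftest import random_column_stochastic


def brute_force_concordance(scores, positives):
    """Exhaustive positive-negative pair enumeration with half-credit ties."""
    positives = set(positives)
    pos = [s for k, s in enumerate(scores) if k in positives]
    neg = [s for k, s in enumerate(scores) if k not in positives]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        roc, auc = nc.roc_auc([3.0, 2.0, 1.0], positives={0})
        assert auc == pytest.approx(1.0)
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_all_tied_scores_give_half(self):
        _, auc = nc.roc_auc([1.0, 1.0], positives={0})
        assert auc == pytest.approx(0.5)

    def test_hand_counted_pairwise(self):
        _, auc = nc.roc_auc([0.9, 0.8, 0.7, 0.6], positives={0, 2})
        assert auc == pytest.approx(3 / 4)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 4, size=20).astype(float)
        roc, _ = nc.roc_auc(scores, positives=set(range(6)))
        fpf = [p[0] for p in roc]
        tpf = [p[1] for p in roc]
        assert fpf == sorted(fpf) and tpf == sorted(tpf)
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedAUCError):
            nc.roc_auc([1.0, 2.0], positives=set())
        with pytest.raises(UndefinedAUCError):
            nc.roc_auc([1.0, 2.0], positives={0, 1})

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        scores=st.lists(st.integers(0, 5), min_size=3, max_size=15),
        seed=st.integers(0, 1000),
    )
    def test_trapezoid_equals_concordance_and_sklearn(self, scores, seed):
        """Threshold-sweep trapezoid, rank form, brute-force pair counting and
        sklearn must all agree on arbitrary tied integer scores."""
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(1, len(scores)))
        positives = set(rng.choice(len(scores), size=n_pos, replace=False).tolist())
        scores = [float(s) for s in scores]
        _, trap = nc.roc_auc(scores, positives)
        assert trap == pytest.approx(nc.concordance_auc(scores, positives), abs=1e-12)
        assert trap == pytest.approx(brute_force_concordance(scores, positives), abs=1e-12)
        labels = [1 if k in positives else 0 for k in range(len(scores))]
        assert trap == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        pos_mask = np.array(labels, dtype=bool)
        assert trap == pytest.approx(_fast_auc(np.array(scores), pos_mask), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_invariance_to_permutation_and_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(12)
        positives = set(rng.choice(12, size=4, replace=False).tolist())
        _, base = nc.roc_auc(scores, positives)
        perm = rng.permutation(12)
        permuted_positives = {int(np.flatnonzero(perm == p)[0]) for p in positives}
        _, permuted = nc.roc_auc(scores[perm], permuted_positives)
        assert permuted == pytest.approx(base, abs=1e-12)
        _, transformed = nc.roc_auc(np.exp(3 * scores) + 1, positives)
        assert transformed == pytest.approx(base, abs=1e-12)


def small_instance(seed=0, n=4, m=3):
    rng = np.random.default_rng(seed)
    sim_m = nc.SimilarityMatrix(
        ids=tuple(f"m{i}" for i in range(n)),
        values=np.clip((lambda x: (x + x.T) / 2)(rng.random((n, n))), 0, 1),
    )
    sim_p = nc.SimilarityMatrix(
        ids=tuple(f"p{j}" for j in range(m)),
        values=np.clip((lambda x: (x + x.T) / 2)(rng.random((m, m))), 0, 1),
    )
    while True:
        adjacency = (rng.random((n, m)) < 0.45).astype(float)
        rows = adjacency.sum(axis=1)
        cols = adjacency.sum(axis=0)
        if ((rows > 0) & (rows < m)).any() and ((cols > 0) & (cols < n)).any():
            break
    net = nc.AssociationNetwork(
        mirna_ids=sim_m.ids, phenotype_ids=sim_p.ids, adjacency=adjacency
    )
    return sim_m, sim_p, net


class TestLoocvMirnaQuery:
    def test_per_query_auc_matches_concordance_oracle(self):
        """4x3 toy: every per-query AUC re-derived by exhaustive pair counting
        on independently recomputed scores."""
        sim_m, sim_p, net = small_instance(seed=3)
        report = nc.loocv_mirna_query("mbsi", sim_m, None, net)
        by_id = {q.query_id: q for q in report.per_query}
        for i, mid in enumerate(net.mirna_ids):
            positives = set(np.flatnonzero(net.adjacency[i]).tolist())
            if not positives or len(positives) == net.m:
                assert mid not in by_id
                continue
            reduced = net.adjacency.copy()
            reduced[i] = 0.0
            scores = nc.mbsi_scores(sim_m, net.with_adjacency(reduced)).scores[i]
            assert by_id[mid].auc == pytest.approx(
                brute_force_concordance(scores.tolist(), positives), abs=1e-12
            )
        assert report.average_auc == pytest.approx(
            np.mean([q.auc for q in report.per_query]), abs=1e-12
        )

    def test_mbsi_scores_unchanged_by_own_row_removal(self):
        """MBSI's sum over l != i never reads row i, so removal is a no-op on
        the query row's scores; the protocol still performs it."""
        sim_m, _, net = small_instance(seed=5)
        full = nc.mbsi_scores(sim_m, net).scores
        for i in range(net.n):
            reduced = net.adjacency.copy()
            reduced[i] = 0.0
            loo = nc.mbsi_scores(sim_m, net.with_adjacency(reduced)).scores
            np.testing.assert_allclose(loo[i], full[i], atol=1e-12)

    def test_single_association_auc_is_normalized_rank(self):
        """With one held-out phenotype, AUC reduces to the fraction of
        negatives ranked strictly below it plus half the ties."""
        sim_m, sim_p, net = small_instance(seed=9, n=6, m=5)
        report = nc.loocv_mirna_query(
            "netcbi",
            nc.normalize_columns(sim_m),
            nc.normalize_columns(sim_p),
            net,
            nc.SmoothingParams(0.3, 0.3),
        )
        m_rel = nc.relevance_matrix(nc.normalize_columns(sim_m), 0.3)
        p_rel = nc.relevance_matrix(nc.normalize_columns(sim_p), 0.3)
        by_id = {q.query_id: q for q in report.per_query}
        for i, mid in enumerate(net.mirna_ids):
            positives = np.flatnonzero(net.adjacency[i])
            if positives.size != 1:
                continue
            reduced = net.adjacency.copy()
            reduced[i] = 0.0
            from netcbi.inference import _pearson_columns

            scores = _pearson_columns(reduced @ p_rel, m_rel[:, i])
            pos_score = scores[positives[0]]
            neg = np.delete(scores, positives[0])
            expected = ((neg < pos_score).sum() + 0.5 * (neg == pos_score).sum()) / neg.size
            assert by_id[mid].auc == pytest.approx(expected, abs=1e-12)

    def test_queries_without_associations_are_skipped(self):
        sim_m, sim_p, net = small_instance(seed=3)
        adjacency = net.adjacency.copy()
        adjacency[0] = 0.0
        net0 = net.with_adjacency(adjacency)
        report = nc.loocv_mirna_query("mbsi", sim_m, None, net0)
        assert net0.mirna_ids[0] not in {q.query_id for q in report.per_query}
        assert any(net0.mirna_ids[0] == s[0] for s in report.skipped)


class TestLoocvPhenotypeQuery:
    def test_reduced_equals_full_pbsi_scores(self):
        """PBSI's sum over l != j never reads column j: holding the column out
        cannot change the scores it produces for that column."""
        _, sim_p, net = small_instance(seed=7)
        full = nc.pbsi_scores(sim_p, net).scores
        for j in range(net.m):
            reduced = net.adjacency.copy()
            reduced[:, j] = 0.0
            loo = nc.pbsi_scores(sim_p, net.with_adjacency(reduced)).scores
            np.testing.assert_allclose(loo[:, j], full[:, j], atol=1e-12)

    def test_per_query_auc_matches_concordance_oracle(self):
        _, sim_p, net = small_instance(seed=2, n=3, m=3)
        report = nc.loocv_phenotype_query(sim_p, net)
        by_id = {q.query_id: q for q in report.per_query}
        for j, pid in enumerate(net.phenotype_ids):
            positives = set(np.flatnonzero(net.adjacency[:, j]).tolist())
            if not positives or len(positives) == net.n:
                continue
            scores = nc.pbsi_scores(sim_p, net).scores[:, j]
            assert by_id[pid].auc == pytest.approx(
                brute_force_concordance(scores.tolist(), positives), abs=1e-12
            )

    def test_only_associated_mirna_ranked_first_gives_auc_one(self):
        sim_p = nc.SimilarityMatrix(
            ids=("p1", "p2"), values=np.array([[1.0, 0.9], [0.9, 1.0]])
        )
        net = nc.AssociationNetwork(
            mirna_ids=("m1", "m2"),
            phenotype_ids=("p1", "p2"),
            adjacency=np.array([[1.0, 1.0], [0.0, 0.0]]),
        )
        report = nc.loocv_phenotype_query(sim_p, net)
        assert all(q.auc == pytest.approx(1.0) for q in report.per_query)


class TestGridSearch:
    def test_single_point_grid_selected(self):
        sim_m, sim_p, net = small_instance(seed=1)
        result = nc.grid_search(
            nc.normalize_columns(sim_m), nc.normalize_columns(sim_p), net, (0.3,), (0.7,)
        )
        assert result.selected == (0.3, 0.7)
        assert len(result.grid) == 1

    def test_selected_is_argmax_of_recorded_grid(self, signal_dataset):
        sim_m, sim_p, net, _ = signal_dataset
        result = nc.grid_search(
            nc.normalize_columns(sim_m),
            nc.normalize_columns(sim_p),
            net,
            (0.1, 0.5, 0.9),
            (0.1, 0.5, 0.9),
        )
        best = max(
            range(len(result.grid)),
            key=lambda k: (
                result.grid_aucs[k],
                (-result.grid[k][0], -result.grid[k][1]),
            ),
        )
        assert result.selected == result.grid[best]

    def test_grid_point_auc_matches_plain_loocv(self):
        sim_m, sim_p, net = small_instance(seed=4)
        smn, spn = nc.normalize_columns(sim_m), nc.normalize_columns(sim_p)
        result = nc.grid_search(smn, spn, net, (0.2,), (0.6,))
        report = nc.loocv_mirna_query("netcbi", smn, spn, net, nc.SmoothingParams(0.2, 0.6))
        assert result.grid_aucs[0] == pytest.approx(report.average_auc, abs=1e-10)

    def test_empty_grid_rejected(self):
        sim_m, sim_p, net = small_instance(seed=1)
        with pytest.raises(ParameterError):
            nc.grid_search(nc.normalize_columns(sim_m), nc.normalize_columns(sim_p), net, (), (0.1,))


class TestNestedLoocv:
    def test_single_point_grid_equals_plain_loocv(self):
        sim_m, sim_p, net = small_instance(seed=6, n=6, m=4)
        smn, spn = nc.normalize_columns(sim_m), nc.normalize_columns(sim_p)
        result = nc.nested_loocv(smn, spn, net, (0.4,), (0.4,))
        report = nc.loocv_mirna_query("netcbi", smn, spn, net, nc.SmoothingParams(0.4, 0.4))
        assert result.outer_auc == pytest.approx(report.average_auc, abs=1e-10)

    def test_outer_auc_matches_brute_force_re_run(self):
        """8 miRNAs, 2x2 grid: re-execute every outer fold from public
        primitives (full inner LOOCV per grid point, tie-broken selection,
        validation scoring) and compare fold by fold."""
        sim_m, sim_p, net = small_instance(seed=8, n=8, m=4)
        smn, spn = nc.normalize_columns(sim_m), nc.normalize_columns(sim_p)
        alpha_grid = beta_grid = (0.2, 0.8)
        result = nc.nested_loocv(smn, spn, net, alpha_grid, beta_grid)

        from netcbi.inference import _pearson_columns

        expected_aucs = []
        expected_choices = []
        for v in range(net.n):
            positives = set(np.flatnonzero(net.adjacency[v]).tolist())
            if not positives or len(positives) == net.m:
                continue
            train = net.adjacency.copy()
            train[v] = 0.0
            net_train = net.with_adjacency(train)
            candidates = []
            for alpha in alpha_grid:
                for beta in beta_grid:
                    inner = nc.loocv_mirna_query(
                        "netcbi", smn, spn, net_train, nc.SmoothingParams(alpha, beta)
                    )
                    candidates.append((inner.average_auc, (-alpha, -beta), (alpha, beta)))
            _, _, choice = max(candidates)
            expected_choices.append(choice)
            alpha, beta = choice
            scores = _pearson_columns(
                train @ nc.relevance_matrix(spn, beta),
                nc.relevance_matrix(smn, alpha)[:, v],
            )
            expected_aucs.append(brute_force_concordance(scores.tolist(), positives))

        assert result.selected_per_fold == tuple(expected_choices)
        assert result.outer_auc == pytest.approx(np.mean(expected_aucs), abs=1e-10)

    def test_fold_summary_shape(self):
        sim_m, sim_p, net = small_instance(seed=6, n=6, m=4)
        smn, spn = nc.normalize_columns(sim_m), nc.normalize_columns(sim_p)
        result = nc.nested_loocv(smn, spn, net, (0.2, 0.8), (0.2, 0.8))
        (mean_a, mean_b), (sd_a, sd_b) = result.fold_mean_sd
        assert 0.2 <= mean_a <= 0.8 and 0.2 <= mean_b <= 0.8
        assert sd_a >= 0 and sd_b >= 0
        assert result.selected in result.grid
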