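"""Two-state clustering, labeling, and per-subject dynamics summaries."""


import numpy as np
import pytest

from dynfc import (
    CohortSpec,
    FCMatrix,
    StatePool,
    StateSequence,
    WindowedFC,
    assign_windows,
    fit_states,
    group_centroids,
    inter_transition_interval,
    label_states,
    make_state_covariances,
    matrix_from_vector,
    mean_dwell_time,
    prevalence,
    simulate_subject,
    sliding_window_fc,
    state_variability,
    summarize_dynamics,
    vectorize_fc,
)
from dynfc.states import STATE_I, STATE_S, StateModel, _runs


def state_z_vector(n_rois, between, within=0.6, n_modules=2):
    cov = make_state_covariances(n_rois, n_modules, within, between)
    z = np.arctanh(np.clip(cov - np.eye(n_rois), -0.999, 0.999))
    np.fill_diagonal(z, 0.0)
    return np.asarray([z[i, j] for i in range(n_rois) for j in range(i + 1, n_rois)])


def pool_from_vectors(vectors):
    v = np.asarray(vectors, float)
    return StatePool(
        vectors=v,
        subject_ids=np.array(["s0"] * len(v)),
        window_index=np.arange(len(v)),
    )


def seq(labels, step=1.0, sid="s0"):
    return StateSequence(subject_id=sid, labels=np.array(list(labels)), step_seconds=step)


def windows_from_vectors(vectors, tr=1.0, sid="s0"):
    mats = [FCMatrix(matrix_from_vector(v)) for v in vectors]
    return WindowedFC(
        window_trs=2, matrices=mats, window_start_frames=np.arange(len(mats)),
        tr_seconds=tr, subject_id=sid,
    )


class TestFitStates:
    def test_well_separated_clusters_pure_assignment(self, rng):
        a = state_z_vector(8, 0.05)
        b = state_z_vector(8, 0.45)
        vecs = np.vstack(
            [a + rng.normal(0, 0.02, a.size) for _ in range(30)]
            + [b + rng.normal(0, 0.02, b.size) for _ in range(30)]
        )
        model = fit_states(pool_from_vectors(vecs), n_init=10, seed=0)
        labels = assign_windows(model, windows_from_vectors(vecs)).labels
        assert set(labels[:30]) != set(labels[30:])
        assert len(np.unique(labels[:30])) == 1 and len(np.unique(labels[30:])) == 1

    def test_cosine_scale_invariance(self, rng):
        a = state_z_vector(6, 0.0)
        b = state_z_vector(6, 0.45)
        vecs = np.vstack(
            [a + rng.normal(0, 0.05, a.size) for _ in range(20)]
            + [b + rng.normal(0, 0.05, b.size) for _ in range(20)]
        )
        scales = rng.uniform(0.5, 5.0, size=40)[:, None]
        m1 = fit_states(pool_from_vectors(vecs), n_init=10, seed=1)
        m2 = fit_states(pool_from_vectors(vecs * scales), n_init=10, seed=1)
        l1 = assign_windows(m1, windows_from_vectors(vecs)).labels
        l2 = assign_windows(m2, windows_from_vectors(vecs * scales)).labels
        np.testing.assert_array_equal(l1, l2)

    def test_reaches_exhaustive_cosine_optimum(self, rng):
        """Every bipartition of a 14-vector pool is enumerated; for a fixed
        partition the optimal spherical centroid is the normalized mean, so
        the partition's inertia is sum_c (|c| - ||sum of unit vectors||)."""
        a = state_z_vector(6, 0.05)
        b = state_z_vector(6, 0.45)
        vecs = np.vstack(
            [a + rng.normal(0, 0.3, a.size) for _ in range(7)]
            + [b + rng.normal(0, 0.3, b.size) for _ in range(7)]
        )
        xn = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        n = len(vecs)
        best = np.inf
        for code in range(1, 2 ** (n - 1)):  # nonempty proper bipartitions
            mask = np.array([(code >> i) & 1 for i in range(n)], bool)
            if mask.all() or not mask.any():
                continue
            inertia = (mask.sum() - np.linalg.norm(xn[mask].sum(axis=0))) + (
                (~mask).sum() - np.linalg.norm(xn[~mask].sum(axis=0))
            )
            best = min(best, inertia)
        model = fit_states(pool_from_vectors(vecs), n_init=100, seed=3)
        assert model.inertia == pytest.approx(best, abs=1e-9)

    def test_degenerate_pool_rejected(self):
        vecs = np.tile(state_z_vector(6, 0.2), (10, 1))
        with pytest.raises(ValueError, match="distinct"):
            fit_states(pool_from_vectors(vecs), n_init=2)


class TestLabelStates:
    def test_labels_match_generative_identity(self):
        seg = state_z_vector(8, 0.05)
        integ = state_z_vector(8, 0.45)
        model = label_states(StateModel(centroid_i=seg, centroid_s=integ, inertia=0.0))
        # labeling must recover the truth regardless of input slot order
        np.testing.assert_allclose(model.centroid_i, integ)
        np.testing.assert_allclose(model.centroid_s, seg)
        assert (
            model.label_metrics[STATE_I]["global_efficiency"]
            > model.label_metrics[STATE_S]["global_efficiency"]
        )

    def test_order_invariance(self):
        seg = state_z_vector(8, 0.05)
        integ = state_z_vector(8, 0.45)
        m1 = label_states(StateModel(centroid_i=seg, centroid_s=integ, inertia=0.0))
        m2 = label_states(StateModel(centroid_i=integ, centroid_s=seg, inertia=0.0))
        np.testing.assert_allclose(m1.centroid_i, m2.centroid_i)
        np.testing.assert_allclose(m1.centroid_s, m2.centroid_s)

    def test_identical_centroids_unlabelable(self):
        v = state_z_vector(6, 0.2)
        with pytest.raises(ValueError, match="tie"):
            label_states(StateModel(centroid_i=v, centroid_s=v.copy(), inertia=0.0))


class TestAssignWindows:
    def _model(self):
        return label_states(
            StateModel(
                centroid_i=state_z_vector(6, 0.45),
                centroid_s=state_z_vector(6, 0.05),
                inertia=0.0,
            )
        )

    def test_centroid_window_gets_its_own_label(self):
        model = self._model()
        labels = assign_windows(model, windows_from_vectors([model.centroid_i])).labels
        assert labels[0] == STATE_I

    def test_matches_brute_force_nearest_centroid(self, rng):
        model = self._model()
        vecs = rng.normal(0.2, 0.4, size=(50, 15))
        vecs[np.linalg.norm(vecs, axis=1) == 0] = 0.1
        labels = assign_windows(model, windows_from_vectors(vecs)).labels

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        for v, lab in zip(vecs, labels):
            ds = 1 - cos(v, model.centroid_s)
            di = 1 - cos(v, model.centroid_i)
            assert lab == (STATE_I if di < ds else STATE_S)  # tie -> S


class TestSequenceMetrics:
    def test_prevalence_examples(self):
        assert prevalence(seq("SSII")) == (50.0, 50.0)
        assert prevalence(seq("SSSS")) == (100.0, 0.0)

    def test_prevalence_matches_count(self, rng):
        labels = rng.choice(["S", "I"], size=1000)
        p_s, p_i = prevalence(seq(labels))
        assert p_s == pytest.approx(100 * np.sum(labels == "S") / 1000)
        assert p_s + p_i == 100.0

    def test_mean_dwell_time_run_arithmetic(self):
        s = seq("SSIISSS")
        assert mean_dwell_time(s, STATE_S) == pytest.approx(2.5)
        assert mean_dwell_time(s, STATE_I) == pytest.approx(2.0)

    def test_constant_sequence(self):
        s = seq("S" * 12, step=0.5)
        assert mean_dwell_time(s, STATE_S) == pytest.approx(6.0)
        assert mean_dwell_time(s, STATE_I) is None

    def test_mdt_matches_brute_force_run_scan(self, rng):
        labels = rng.choice(["S", "I"], size=500)
        s = seq(labels, step=0.72)
        for state in (STATE_S, STATE_I):
            runs, cur = [], 0
            for lab in labels:
                if lab == state:
                    cur += 1
                elif cur:
                    runs.append(cur)
                    cur = 0
            if cur:
                runs.append(cur)
            expected = np.mean(runs) * 0.72 if runs else None
            got = mean_dwell_time(s, state)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)

    def test_time_accounting_identity(self, rng):
        """MDT_state x (number of that state's runs), summed over states,
        equals the total sequence duration exactly."""
        labels = rng.choice(["S", "I"], size=731)
        s = seq(labels, step=0.987)
        total = 0.0
        for state in (STATE_S, STATE_I):
            runs = [r for st, r in _runs(s.labels) if st == state]
            if runs:
                total += mean_dwell_time(s, state) * len(runs)
        assert total == pytest.approx(731 * 0.987, abs=1e-9)

    def test_iti_examples(self):
        assert inter_transition_interval(seq("SSIISS")) == pytest.approx(2.0)
        assert inter_transition_interval(seq("SISISI")) == pytest.approx(1.0)
        assert inter_transition_interval(seq("SSII")) is None  # single transition

    def test_iti_approximates_mean_interior_run_length(self):
        from dynfc import simulate_state_sequence

        chain = simulate_state_sequence(0.05, 0.05, 20_000, seed=8)
        labels = np.where(chain == 0, "S", "I")
        s = seq(labels)
        runs = [r for _, r in _runs(s.labels)][1:-1]  # interior runs only
        assert inter_transition_interval(s) == pytest.approx(np.mean(runs), rel=1e-12)

    def test_relabeling_swaps_the_summary(self, rng):
        labels = rng.choice(["S", "I"], size=200)
        swapped = np.where(labels == "S", "I", "S")
        vecs = rng.normal(0.3, 0.2, size=(200, 10))
        w = windows_from_vectors(vecs)
        d1 = summarize_dynamics(seq(labels), w)
        d2 = summarize_dynamics(seq(swapped), w)
        assert (d1.prev_s, d1.mdt_s, d1.var_s) == (d2.prev_i, d2.mdt_i, d2.var_i)
        assert (d1.prev_i, d1.mdt_i, d1.var_i) == (d2.prev_s, d2.mdt_s, d2.var_s)
        assert d1.iti == d2.iti


class TestStateVariability:
    def test_identical_windows_score_zero(self):
        v = state_z_vector(6, 0.2)
        w = windows_from_vectors([v, v, v])
        assert state_variability(seq("SSS"), w, STATE_S) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_pair_scores_equal_distances(self):
        base = np.full(10, 1.0)
        delta = np.zeros(10)
        delta[0], delta[1] = 0.5, -0.5  # orthogonal to the mean direction
        w = windows_from_vectors([base + delta, base - delta])
        score = state_variability(seq("SS"), w, STATE_S)

        def cosdist(a, b):
            return 1 - a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        assert score == pytest.approx(100 * cosdist(base + delta, base), abs=1e-9)

    def test_matches_brute_force_mean_distance(self, rng):
        vecs = rng.normal(0.4, 0.3, size=(40, 15))
        labels = rng.choice(["S", "I"], size=40)
        w = windows_from_vectors(vecs)
        for state in ("S", "I"):
            got = state_variability(seq(labels), w, state)
            member = vecs[labels == state]
            center = member.mean(axis=0)
            dists = [
                1 - v @ center / (np.linalg.norm(v) * np.linalg.norm(center))
                for v in member
            ]
            assert got == pytest.approx(100 * np.mean(dists), abs=1e-9)

    def test_unvisited_state_absent(self):
        w = windows_from_vectors([np.full(10, 0.4)])
        assert state_variability(seq("S"), w, STATE_I) is None


class TestGroupCentroids:
    def test_single_subject_single_window(self):
        v = state_z_vector(6, 0.3)
        w = windows_from_vectors([v])
        cents = group_centroids([seq("S")], [w], {"s0": "g"})
        np.testing.assert_allclose(cents[("g", "S")], matrix_from_vector(v))

    def test_identical_subjects_group_equals_subject_median(self, rng):
        vecs = rng.normal(0.3, 0.2, size=(6, 10))
        labels = "SSSIII"
        w1 = windows_from_vectors(vecs, sid="a")
        w2 = windows_from_vectors(vecs, sid="b")
        cents = group_centroids(
            [seq(labels, sid="a"), seq(labels, sid="b")], [w1, w2], {"a": "g", "b": "g"}
        )
        stack = np.asarray([m.values for m in w1.matrices[:3]])
        np.testing.assert_allclose(cents[("g", "S")], np.median(stack, axis=0))

    def test_matches_median_then_mean_oracle(self, rng):
        n_sub = 4
        seqs, wins, groups = [], [], {}
        all_vecs, all_labels = [], []
        for k in range(n_sub):
            vecs = rng.normal(0.3, 0.2, size=(8, 10))
            labels = rng.choice(["S", "I"], size=8)
            while len(set(labels)) < 2:
                labels = rng.choice(["S", "I"], size=8)
            sid = f"s{k}"
            seqs.append(seq(labels, sid=sid))
            wins.append(windows_from_vectors(vecs, sid=sid))
            groups[sid] = "m" if k < 2 else "f"
            all_vecs.append(vecs)
            all_labels.append(labels)
        cents = group_centroids(seqs, wins, groups)
        # brute force for group "m", state "S"
        meds = []
        for k in range(2):
            stack = np.asarray(
                [matrix_from_vector(v) for v, l in zip(all_vecs[k], all_labels[k]) if l == "S"]
            )
            meds.append(np.median(stack, axis=0))
        np.testing.assert_allclose(cents[("m", "S")], np.mean(meds, axis=0), atol=1e-12)


class TestPipelineRecovery:
    def test_recovered_prevalence_tracks_generative_occupancy(self, small_spec):
        """On a well-separated synthetic cohort the per-subject recovered
        Prev_S must rank-correlate strongly with the true state occupancy."""
        from scipy.stats import spearmanr

        windowed, truth = [], []
        spec = CohortSpec(
            n_subjects=40, n_rois=8, n_modules=2, n_frames=400, seed=21,
            between_r_segregated=0.05, between_r_integrated=0.45,
        )
        for i in range(spec.n_subjects):
            ts, states = simulate_subject(spec, i)
            windowed.append(sliding_window_fc(ts, 40))
            truth.append(np.mean(states == 0))
        pool = StatePool.from_windowed(windowed)
        model = fit_states(pool, n_init=5, seed=0)
        prev = [prevalence(assign_windows(model, w))[0] for w in windowed]
        rho = spearmanr(prev, truth).statistic
        assert rho > 0.9
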