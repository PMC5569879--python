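import numpy as np
import pytest
from scipy import linalg

from mibci.montage import CLASS_ORDER, Dataset, Trial
from mibci.rcsp import (
    ClassCovarianceSummary,
    IncompleteTrainingSetError,
    RCSPConfig,
    RCSPTransformer,
    SpatialFilterBank,
    ZeroEnergyTrialError,
    bank_from_summaries,
    build_filter_bank,
    build_summaries,
    csp_pair_filters,
    extract_features,
    grid_search,
    normalized_covariance,
    pair_order,
    regularized_covariance,
)

rng = np.random.default_rng(12345)


def random_spd(n, r=None):
    a = (r or rng).standard_normal((n, n))
    return a @ a.T + n * np.eye(n)


def trials_from_cov(cov, n, t, label, r):
    chol = np.linalg.cholesky(cov)
    return [Trial(data=chol @ r.standard_normal((cov.shape[0], t)),
                  veog=np.zeros(t), label=label, fs=256.0) for _ in range(n)]


def four_class_dataset(n_per_class=8, t=128, n_ch=6, seed=0, subject="S1", scale=None):
    """Each class inflates variance on its own channel pair."""
    r = np.random.default_rng(seed)
    trials = []
    for k, label in enumerate(CLASS_ORDER):
        cov = np.eye(n_ch)
        gain = scale[label] if scale else 4.0
        cov[k % n_ch, k % n_ch] = gain
        cov[(k + 3) % n_ch, (k + 3) % n_ch] = gain / 2
        trials.extend(trials_from_cov(cov, n_per_class, t, label, r))
    splits = ["train"] * len(trials)
    return Dataset(subject_id=subject, trials=trials, splits=splits)


class TestNormalizedCovariance:
    def test_identity_trial(self):
        s = normalized_covariance(np.eye(2))
        assert np.allclose(s, [[0.5, 0.0], [0.0, 0.5]])

    def test_single_active_channel(self):
        s = normalized_covariance(np.array([[2.0, 0.0], [0.0, 0.0]]))
        assert np.allclose(s, [[1.0, 0.0], [0.0, 0.0]])

    def test_unit_trace_and_psd(self):
        e = rng.standard_normal((6, 512))
        s = normalized_covariance(e)
        assert np.trace(s) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.eigvalsh(s).min() >= -1e-10
        assert np.abs(s - s.T).max() < 1e-12

    def test_zero_energy_rejected(self):
        with pytest.raises(ZeroEnergyTrialError):
            normalized_covariance(np.zeros((3, 16)))


class TestRegularizedCovariance:
    def setup_method(self):
        self.s1 = random_spd(6, np.random.default_rng(1))
        self.s2 = random_spd(6, np.random.default_rng(2))
        self.summary = ClassCovarianceSummary(
            label="R", S_sum=self.s1 * 10, M=10, S_hat_sum=self.s2 * 40, M_hat=40
        )

    def test_zero_shrinkage_recovers_classical_average(self):
        out = regularized_covariance(self.summary, RCSPConfig(0.0, 0.0))
        assert np.allclose(out, self.s1)

    def test_full_identity_shrinkage(self):
        out = regularized_covariance(self.summary, RCSPConfig(0.0, 1.0))
        assert np.allclose(out, np.trace(self.s1) / 6 * np.eye(6))

    def test_full_generic_shrinkage(self):
        out = regularized_covariance(self.summary, RCSPConfig(1.0, 0.0))
        assert np.allclose(out, self.s2)

    def test_trace_preserved_by_gamma(self):
        for gamma in (0.0, 0.3, 0.7, 1.0):
            out = regularized_covariance(self.summary, RCSPConfig(0.4, gamma))
            ref = regularized_covariance(self.summary, RCSPConfig(0.4, 0.0))
            assert np.trace(out) == pytest.approx(np.trace(ref), abs=1e-10)

    def test_off_diagonal_energy_decreases_monotonically_in_gamma(self):
        energies = []
        for gamma in np.linspace(0, 1, 11):
            out = regularized_covariance(self.summary, RCSPConfig(0.2, gamma))
            energies.append(np.sum((out - np.diag(np.diag(out))) ** 2))
        assert np.all(np.diff(energies) <= 1e-12)
        assert energies[-1] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RCSPConfig(beta=1.2, gamma=0.0)
        empty = ClassCovarianceSummary(label="R", S_sum=np.eye(3), M=0)
        with pytest.raises(ValueError):
            regularized_covariance(empty, RCSPConfig(0.0, 0.0))


class TestCSPPairFilters:
    def test_diagonal_covariances_isolate_channels(self):
        s1, s2 = np.diag([0.9, 0.1]), np.diag([0.1, 0.9])
        w, det = csp_pair_filters(s1, s2, alpha=1, return_details=True)
        assert np.allclose(sorted(det["lam1"]), [0.1, 0.9], atol=1e-10)
        # each retained filter projects onto exactly one channel (up to sign/scale)
        for q in range(2):
            col = np.abs(w[:, q]) / np.abs(w[:, q]).max()
            assert sorted(col) == pytest.approx([0.0, 1.0], abs=1e-10)

    def test_whitened_complementarity(self):
        s1, s2 = random_spd(6), random_spd(6)
        _, det = csp_pair_filters(s1, s2, alpha=2, return_details=True)
        p, b = det["P"], det["B"]
        lam2 = np.diag(b.T @ (p @ s2 @ p.T) @ b)
        assert np.abs(det["lam1"] + lam2 - 1.0).max() < 1e-8

    def test_whitening_contract(self):
        s1, s2 = random_spd(6), random_spd(6)
        _, det = csp_pair_filters(s1, s2, alpha=2, return_details=True)
        p = det["P"]
        assert np.abs(p @ (s1 + s2) @ p.T - np.eye(6)).max() < 1e-8

    def test_equal_covariances_give_half_eigenvalues(self):
        s = random_spd(5)
        _, det = csp_pair_filters(s, s.copy(), alpha=2, return_details=True)
        assert np.allclose(det["lam1"], 0.5, atol=1e-10)

    def test_generalized_eigenproblem_oracle(self):
        """beta=gamma=0 filters match solving Sigma1 w = lam (Sigma1+Sigma2) w
        directly: projected variance ratios agree to 1e-6."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            s1, s2 = random_spd(6, r), random_spd(6, r)
            alpha = 2
            w = csp_pair_filters(s1, s2, alpha)
            lam, _ = linalg.eigh(s1, s1 + s2)
            lam = np.sort(lam)[::-1]
            oracle = np.sort(np.concatenate([lam[:alpha], lam[-alpha:]]))
            mine = np.sort([
                (w[:, q] @ s1 @ w[:, q]) / (w[:, q] @ (s1 + s2) @ w[:, q])
                for q in range(2 * alpha)
            ])
            assert np.abs(mine - oracle).max() < 1e-6

    def test_alpha_too_large_rejected(self):
        with pytest.raises(ValueError):
            csp_pair_filters(np.eye(3), np.eye(3), alpha=2)


class TestFeatures:
    def make_bank(self, w):
        pairs = [("R", "RF")]
        return SpatialFilterBank(filters={("R", "RF"): w}, config=RCSPConfig(), pairs=pairs)

    def test_known_variance_ratio(self):
        # two projected rows with variances (3, 1) -> (log .75, log .25)
        t = 4000
        r = np.random.default_rng(0)
        e = np.vstack([np.sqrt(3) * r.standard_normal(t), r.standard_normal(t)])
        bank = self.make_bank(np.eye(2))
        y = extract_features(e, bank)
        assert y == pytest.approx([np.log(0.75), np.log(0.25)], abs=0.02)

    def test_blocks_exponentials_sum_to_one(self):
        ds = four_class_dataset()
        bank = build_filter_bank(ds, [], RCSPConfig(alpha=2))
        y = extract_features(ds.trials[0].data, bank)
        assert y.shape == (24,)
        for block in y.reshape(6, 4):
            assert np.exp(block).sum() == pytest.approx(1.0, abs=1e-8)

    def test_scale_invariance(self):
        ds = four_class_dataset()
        bank = build_filter_bank(ds, [], RCSPConfig(alpha=2))
        e = ds.trials[3].data
        assert np.allclose(extract_features(e, bank), extract_features(10 * e, bank), atol=1e-8)


class TestBankConstruction:
    def test_six_filters_for_four_classes(self):
        ds = four_class_dataset()
        bank = build_filter_bank(ds, [], RCSPConfig(alpha=2))
        assert len(bank.filters) == 6
        assert bank.pairs == pair_order()
        assert all(w.shape == (6, 4) for w in bank.filters.values())
        assert bank.n_features == 24

    def test_generic_pool_counts(self):
        own = four_class_dataset(n_per_class=5, seed=1)
        others = [four_class_dataset(n_per_class=5, seed=s, subject=f"S{s}") for s in (2, 3)]
        gen_trials = [t for d in others for t in d.train_trials]
        summaries = build_summaries(own.train_trials, gen_trials)
        for c in CLASS_ORDER:
            assert summaries[c].M == 5
            assert summaries[c].M_hat == 10  # M x (L - 1)
            assert np.trace(summaries[c].S_sum) == pytest.approx(5.0, abs=1e-8)

    def test_beta_zero_ignores_generic_pool(self):
        own = four_class_dataset(n_per_class=6, seed=4)
        others = [four_class_dataset(n_per_class=6, seed=5, subject="S2")]
        with_pool = build_filter_bank(own, others, RCSPConfig(beta=0.0))
        without = build_filter_bank(own, [], RCSPConfig(beta=0.0))
        for pair in with_pool.pairs:
            assert np.allclose(with_pool.filters[pair], without.filters[pair])

    def test_missing_class_rejected(self):
        ds = four_class_dataset(n_per_class=4)
        partial = Dataset(
            subject_id="S1",
            trials=[t for t in ds.trials if t.label != "LH"],
            splits=["train"] * sum(t.label != "LH" for t in ds.trials),
        )
        with pytest.raises(IncompleteTrainingSetError, match="LH"):
            build_filter_bank(partial, [], RCSPConfig())

    def test_pattern_recovery(self):
        """The most discriminative filter column loads maximally on the
        channel whose variance the class inflates (>= 8 of 10 seeds)."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            cov1, cov2 = np.eye(6), np.eye(6)
            cov1[2, 2] = 6.0  # class R activates channel 2
            tr = trials_from_cov(cov1, 12, 256, "R", r) + trials_from_cov(cov2, 12, 256, "RF", r)
            ds = Dataset(subject_id="S1", trials=tr, splits=["train"] * 24)
            summaries = build_summaries(ds.train_trials, [], classes=("R", "RF"))
            bank = bank_from_summaries(summaries, RCSPConfig(alpha=1), classes=("R", "RF"))
            w = bank.filters[("R", "RF")]
            if int(np.argmax(np.abs(w[:, 0]))) == 2:
                hits += 1
        assert hits >= 8


class TestRCSPTransformer:
    def test_sklearn_shape_contract(self):
        ds = four_class_dataset(n_per_class=6)
        X = np.stack([t.data for t in ds.trials])
        y = np.array(ds.labels(), dtype=object)
        tf = RCSPTransformer(beta=0.2, gamma=0.1, alpha=2).fit(X, y, generic_X=X, generic_y=y)
        feats = tf.transform(X)
        assert feats.shape == (len(y), 24)
        assert tf.get_params() == {"beta": 0.2, "gamma": 0.1, "alpha": 2}


class TestGridSearch:
    def test_cell_counts(self):
        ds = four_class_dataset(n_per_class=6, t=64)
        _, mat = grid_search(ds, [], grid_step=0.5, n_folds=2,
                             classifier_factory=lambda: _tiny_clf())
        assert mat.shape == (3, 3) and mat.size == 9
        _, mat = grid_search(ds, [], grid_step=0.1, n_folds=2,
                             classifier_factory=lambda: _tiny_clf())
        assert mat.size == 121

    def test_tie_break_prefers_small_beta_then_gamma(self):
        ds = four_class_dataset(n_per_class=6, t=64)
        pool = [four_class_dataset(n_per_class=6, t=64, seed=9, subject="S2")]
        # constant evaluator -> global tie -> (0, 0) must win
        (beta, gamma), mat = grid_search(
            ds, pool, grid_step=0.5, n_folds=2, evaluator=lambda *a: 0.5
        )
        assert (beta, gamma) == (0.0, 0.0)
        assert np.all(mat == 0.5)

    def test_generic_pooling_helps_small_samples(self):
        """With very few own trials per class, the selected beta is positive
        in most replicates: the pooled covariance stabilizes estimation."""
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            covs = {}
            for k, label in enumerate(CLASS_ORDER):
                cov = np.eye(6)
                cov[k % 6, k % 6] = 3.0
                covs[label] = cov
            own_trials = [t for label in CLASS_ORDER
                          for t in trials_from_cov(covs[label], 6, 24, label, r)]
            own = Dataset(subject_id="S1", trials=own_trials, splits=["train"] * 24)
            others = []
            for s in range(3):
                tr = [t for label in CLASS_ORDER
                      for t in trials_from_cov(covs[label], 20, 24, label, r)]
                others.append(Dataset(subject_id=f"G{s}", trials=tr, splits=["train"] * 80))
            (beta, _), _ = grid_search(own, others, grid_step=0.5, n_folds=3,
                                       seed=seed, classifier_factory=lambda: _tiny_clf())
            wins += beta > 0
        assert wins > 10


def _tiny_clf():
    from mibci.classify import KNNSVMClassifier

    return KNNSVMClassifier(k=3)
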