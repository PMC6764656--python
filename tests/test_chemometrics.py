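import numpy as np
import pytest

from uraman import chemometrics as cm
from uraman import preprocess as pp
from uraman import spectra_io as io
from uraman import synthetic_data as sd
from uraman.errors import (
    ClassSizeError,
    CoverageError,
    DimensionError,
    InsufficientDataError,
)


def make_set(matrix, grid=None, ids=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if grid is None:
        grid = np.arange(matrix.shape[1], dtype=float) + 250.0
    if ids is None:
        ids = [f"S{i}" for i in range(matrix.shape[0])]
    return io.SpectrumSet(grid=grid, matrix=matrix, specimen_ids=ids)


class TestSummarize:
    def test_identical_rows_have_zero_sd(self):
        row = np.linspace(0, 1, 20)
        mean, sd = cm.summarize_spectra(make_set(np.tile(row, (5, 1))))
        np.testing.assert_allclose(mean, row, rtol=1e-14)
        np.testing.assert_allclose(sd, 0.0, atol=1e-15)

    def test_two_point_sample_sd(self):
        v = np.linspace(1, 3, 10)
        mean, sd = cm.summarize_spectra(make_set(np.vstack([v, -v])))
        np.testing.assert_allclose(mean, 0.0, atol=1e-14)
        np.testing.assert_allclose(sd, np.abs(v) * np.sqrt(2), rtol=1e-12)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(6, 15))
        m1, s1 = cm.summarize_spectra(make_set(mat))
        m2, s2 = cm.summarize_spectra(make_set(mat[::-1]))
        np.testing.assert_allclose(m1, m2, rtol=1e-12)
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(InsufficientDataError):
            cm.summarize_spectra(make_set(np.ones((1, 5))))


class TestPCA:
    def test_rank_one_data_concentrates_variance(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=30)
        coeffs = rng.normal(size=8)
        mat = 1.5 + np.outer(coeffs, direction)
        model = cm.fit_pca(make_set(mat))
        assert model.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(model.variance_fraction[1:] < 1e-12)

    def test_variances_match_covariance_eigenvalues(self):
        """Three points in the plane: component variances equal the
        eigenvalues of the hand-computable 2x2 covariance matrix."""
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 2.0]])
        model = cm.fit_pca(make_set(pts))
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(pts.T)))[::-1]
        # scores are U*S: singular values squared / (n-1) are the variances
        comp_var = np.sum(model.scores**2, axis=0) / (pts.shape[0] - 1)
        np.testing.assert_allclose(comp_var, eigvals, rtol=1e-10)
        np.testing.assert_allclose(
            model.variance_fraction, eigvals / eigvals.sum(), rtol=1e-10
        )

    def test_duplicating_rows_preserves_loadings(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(5, 12))
        base = cm.fit_pca(make_set(mat))
        doubled = cm.fit_pca(
            make_set(np.vstack([mat, mat]), ids=[f"S{i}" for i in range(10)])
        )
        k = base.n_components
        np.testing.assert_allclose(
            doubled.loadings[: k - 1], base.loadings[: k - 1], atol=1e-8
        )
        np.testing.assert_allclose(
            doubled.variance_fraction[: k - 1],
            base.variance_fraction[: k - 1],
            atol=1e-9,
        )

    def test_scores_centered_and_uncorrelated(self):
        rng = np.random.default_rng(3)
        model = cm.fit_pca(make_set(rng.normal(size=(20, 40))))
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-9)
        cross = model.scores.T @ model.scores
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-8

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        model = cm.fit_pca(make_set(rng.normal(size=(10, 25))))
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)

    def test_row_permutation_gives_identical_model(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(9, 14))
        a = cm.fit_pca(make_set(mat))
        perm = rng.permutation(9)
        b = cm.fit_pca(
            make_set(mat[perm], ids=[f"S{i}" for i in perm])
        )
        # the final component spans the centering null space and is
        # arbitrary; compare the well-determined ones
        k = a.n_components - 1
        np.testing.assert_allclose(a.loadings[:k], b.loadings[:k], atol=1e-9)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(6, 10))
        model = cm.fit_pca(make_set(mat))
        recon = model.mean_spectrum + model.scores @ model.loadings
        np.testing.assert_allclose(recon, mat, atol=1e-8)

    def test_single_row_rejected(self):
        with pytest.raises(InsufficientDataError):
            cm.fit_pca(make_set(np.ones((1, 5))))


class TestSelectNPcs:
    FRACS = np.array([0.60, 0.30, 0.05, 0.04, 0.01])

    @pytest.mark.parametrize(
        "target,expected", [(0.90, 2), (0.95, 3), (0.60, 1), (1.0, 5)]
    )
    def test_cumulative_threshold(self, target, expected):
        assert cm.select_n_pcs(self.FRACS, target) == expected

    def test_unreachable_target(self):
        with pytest.raises(CoverageError):
            cm.select_n_pcs(np.array([0.5, 0.3]), 0.95)

    def test_matches_cumsum_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            raw = rng.uniform(0.01, 1.0, size=rng.integers(2, 12))
            fracs = np.sort(raw / raw.sum())[::-1]
            target = rng.uniform(0.05, 1.0)
            # brute-force oracle: scan cumulative sums
            cum, expected = 0.0, None
            for k, f in enumerate(fracs, start=1):
                cum += f
                if cum >= target - 1e-9:
                    expected = k
                    break
            assert cm.select_n_pcs(fracs, target) == expected


class TestLoadingAttribution:
    def test_single_channel_components_rank_first(self):
        grid = np.arange(250.0, 260.0)
        model = cm.PCAModel(
            mean_spectrum=np.zeros(10),
            loadings=np.eye(3, 10),
            scores=np.zeros((4, 3)),
            variance_fraction=np.array([0.6, 0.3, 0.1]),
            grid=grid,
            specimen_ids=list("abcd"),
        )
        att = cm.loading_attribution(model, 3)
        for j in range(3):
            top = att.per_component.query(f"component == {j + 1} and rank == 1")
            assert top["shift"].iloc[0] == grid[j]

    def test_varied_urea_band_dominates_combined_ranking(self):
        """Cohort whose only varied band is urea at 1002 cm^-1 (other
        metabolite bands present but constant): the combined attribution
        must locate 1002 within two grid channels. Normalization is
        switched off so the variation stays where it was generated
        (vector normalization deliberately redistributes it)."""
        cfg = sd.CohortConfig(
            n_female=10, n_male=10, specimens_per_donor=1,
            scans_per_specimen=2, donor_cv=0.0, day_cv=0.0, noise_sd=0.002,
            age_slope={"urea": -0.012}, seed=21,
        )
        scans, _ = sd.generate_cohort(cfg)
        spectra = pp.preprocess_set(
            io.assemble_set(scans, cfg.grid),
            pp.PreprocessConfig(normalize=False),
        )
        model = cm.fit_pca(pp.truncate_window(spectra))
        att = cm.loading_attribution(model, 4)
        assert abs(att.combined["shift"].iloc[0] - 1002.0) <= 4.0

    def test_combined_invariant_to_sign_flips(self):
        rng = np.random.default_rng(8)
        model = cm.fit_pca(make_set(rng.normal(size=(8, 20))))
        att = cm.loading_attribution(model, 3)
        flipped = cm.PCAModel(
            mean_spectrum=model.mean_spectrum,
            loadings=-model.loadings,
            scores=-model.scores,
            variance_fraction=model.variance_fraction,
            grid=model.grid,
            specimen_ids=model.specimen_ids,
        )
        att2 = cm.loading_attribution(flipped, 3)
        np.testing.assert_allclose(
            att.combined["weight"], att2.combined["weight"], rtol=1e-12
        )


def scores_model(scores, ids=None):
    """PCAModel wrapper around given score coordinates (identity loadings)."""
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    return cm.PCAModel(
        mean_spectrum=np.zeros(k),
        loadings=np.eye(k),
        scores=scores,
        variance_fraction=np.full(k, 1.0 / k),
        grid=np.arange(k, dtype=float) + 250.0,
        specimen_ids=ids or [f"S{i}" for i in range(n)],
    )


class TestDAPC:
    def test_class_means_recovered(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(50, 3)) + np.array([5.0, 0, 0])
        b = rng.normal(size=(50, 3)) - np.array([5.0, 0, 0])
        model = cm.fit_dapc(
            scores_model(np.vstack([a, b])),
            ["A"] * 50 + ["B"] * 50,
            n_pcs=3,
        )
        np.testing.assert_allclose(
            model.class_means[0], [5, 0, 0], atol=0.5
        )
        np.testing.assert_allclose(
            model.class_means[1], [-5, 0, 0], atol=0.5
        )

    def test_single_class_rejected(self):
        with pytest.raises(ClassSizeError):
            cm.fit_dapc(
                scores_model(np.random.default_rng(0).normal(size=(6, 2))),
                ["A"] * 6,
                n_pcs=2,
            )

    def test_tiny_class_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ClassSizeError, match="B"):
            cm.fit_dapc(
                scores_model(rng.normal(size=(5, 2))),
                ["A", "A", "A", "A", "B"],
                n_pcs=2,
            )

    def test_duplicating_rows_keeps_class_means(self):
        rng = np.random.default_rng(11)
        S = rng.normal(size=(12, 2))
        y = ["A"] * 6 + ["B"] * 6
        m1 = cm.fit_dapc(scores_model(S), y, n_pcs=2)
        m2 = cm.fit_dapc(
            scores_model(np.vstack([S, S]), ids=[f"T{i}" for i in range(24)]),
            y + y,
            n_pcs=2,
        )
        np.testing.assert_allclose(m1.class_means, m2.class_means, rtol=1e-12)

    def test_predict_at_class_mean(self):
        rng = np.random.default_rng(12)
        S = np.vstack(
            [rng.normal(size=(20, 2)) + [3, 0], rng.normal(size=(20, 2)) - [3, 0]]
        )
        model = cm.fit_dapc(
            scores_model(S), ["A"] * 20 + ["B"] * 20, n_pcs=2, priors="uniform"
        )
        labels, post = cm.predict_dapc(model, model.class_means[0][None, :])
        assert labels[0] == "A"
        assert post[0, 0] > 0.5

    def test_equidistant_tie_broken_lexicographically(self):
        S = np.array(
            [[1.0, 0], [1, 0.1], [1, -0.1], [-1, 0], [-1, 0.1], [-1, -0.1]]
        )
        model = cm.fit_dapc(
            scores_model(S), ["a", "a", "a", "b", "b", "b"], n_pcs=2,
            priors="uniform",
        )
        labels, post = cm.predict_dapc(model, np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-9)
        assert labels[0] == "a"

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(13)
        S = rng.normal(size=(30, 4))
        y = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        model = cm.fit_dapc(scores_model(S), y, n_pcs=4)
        _, post = cm.predict_dapc(model, rng.normal(size=(50, 4)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_doubling_prior_raises_posterior_everywhere(self):
        """Direct Bayes-rule oracle: with likelihoods fixed, scaling one
        class's prior strictly increases its posterior at every point."""
        rng = np.random.default_rng(14)
        S = np.vstack(
            [rng.normal(size=(15, 2)) + [2, 0], rng.normal(size=(15, 2)) - [2, 0]]
        )
        y = ["A"] * 15 + ["B"] * 15
        equal = cm.fit_dapc(scores_model(S), y, n_pcs=2, priors="uniform")
        tilted = cm.fit_dapc(scores_model(S), y, n_pcs=2, priors="uniform")
        tilted.priors = np.array([2.0 / 3.0, 1.0 / 3.0])
        pts = rng.normal(size=(20, 2)) * 3
        _, p_eq = cm.predict_dapc(equal, pts)
        _, p_tilt = cm.predict_dapc(tilted, pts)
        assert np.all(p_tilt[:, 0] > p_eq[:, 0])
        # oracle: posterior = prior*lik / sum(prior*lik), computed directly
        lik = p_eq / 0.5  # equal-prior posteriors are normalized likelihoods
        expect = lik * tilted.priors
        expect /= expect.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(p_tilt, expect, rtol=1e-9)

    def test_full_rank_equal_priors_is_nearest_mahalanobis(self):
        """Brute-force check on 20 random points."""
        rng = np.random.default_rng(15)
        S = np.vstack(
            [
                rng.normal(size=(15, 3)) + [2, 1, 0],
                rng.normal(size=(15, 3)) - [2, 1, 0],
            ]
        )
        y = ["A"] * 15 + ["B"] * 15
        model = cm.fit_dapc(scores_model(S), y, n_pcs=3, priors="uniform")
        pts = rng.normal(size=(20, 3)) * 2
        labels, _ = cm.predict_dapc(model, pts)
        inv = np.linalg.inv(model.pooled_covariance)
        for x, lab in zip(pts, labels):
            d = [
                float((x - mu) @ inv @ (x - mu)) for mu in model.class_means
            ]
            assert model.classes[int(np.argmin(d))] == lab

    def test_matches_sklearn_lda_posteriors(self):
        """Independent oracle: sklearn's LDA with the same priors."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        rng = np.random.default_rng(16)
        S = np.vstack(
            [rng.normal(size=(25, 3)) + [1.5, 0, 0], rng.normal(size=(25, 3))]
        )
        y = np.array(["A"] * 25 + ["B"] * 25)
        model = cm.fit_dapc(scores_model(S), list(y), n_pcs=3)
        ref = sklearn_lda(solver="lsqr", priors=model.priors).fit(S, y)
        pts = rng.normal(size=(30, 3)) * 2
        labels, post = cm.predict_dapc(model, pts)
        # sklearn pools the covariance with denominator n, this package
        # uses the unbiased n - k; posteriors agree up to that factor
        np.testing.assert_allclose(
            post, ref.predict_proba(pts), atol=0.02
        )
        assert list(labels) == list(ref.predict(pts))


class TestPersistence:
    def test_pca_roundtrip(self, tmp_path, preprocessed_cohort):
        spectra, _, _ = preprocessed_cohort
        model = cm.fit_pca(spectra)
        cm.save_pca_model(model, tmp_path / "pca")
        back = cm.load_pca_model(tmp_path / "pca")
        np.testing.assert_allclose(back.loadings, model.loadings, atol=1e-12)
        np.testing.assert_allclose(back.scores, model.scores, atol=1e-12)
        assert back.specimen_ids == model.specimen_ids

    def test_dapc_roundtrip(self, tmp_path, preprocessed_cohort):
        spectra, meta, _ = preprocessed_cohort
        labels = dict(zip(meta["specimen_id"], meta["sex"]))
        keep = [
            i for i, s in enumerate(spectra.specimen_ids) if s in labels
        ]
        sub = spectra.subset(keep)
        model = cm.fit_dapc(cm.fit_pca(sub), labels, n_pcs=4)
        cm.save_dapc_model(model, tmp_path / "dapc")
        back = cm.load_dapc_model(tmp_path / "dapc")
        assert back.classes == model.classes
        np.testing.assert_allclose(
            back.class_means, model.class_means, atol=1e-12
        )
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(5, 4))
        l1, p1 = cm.predict_dapc(model, pts)
        l2, p2 = cm.predict_dapc(back, pts)
        assert list(l1) == list(l2)
        np.testing.assert_allclose(p1, p2, atol=1e-10)
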