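from itertools import combinations

import numpy as np
import pytest

from rsim import (
    CountMatrix,
    CovariateTable,
    InputError,
    NormalizedMatrix,
    SimulationConfig,
    fdp_and_sensitivity,
    filter_taxa,
    fit_reference_model,
    generate,
    misclassification_rate,
    pcoa_coordinates,
    per_taxon_tests,
    permanova,
)
from rsim.evaluation import _bh_reject
from rsim.synthetic_data import SimulationTruth


def make_truth(da, nonda):
    taxa = tuple(sorted(da | nonda))
    return SimulationTruth(
        abundances=np.ones((len(taxa), 2)),
        sampling_fractions=np.ones(2),
        da_taxa=frozenset(da),
        nonda_taxa=frozenset(nonda),
        latent_values=np.zeros(2),
        group_labels=None,
        taxon_ids=taxa,
        sample_ids=("s1", "s2"),
    )


def coords_to_nm(points: np.ndarray) -> NormalizedMatrix:
    """Interpret rows of ``points`` as samples in feature space."""
    n, k = points.shape
    return NormalizedMatrix(
        points.T + 100.0,  # shift keeps values positive; distances unchanged
        tuple(f"f{j}" for j in range(k)),
        tuple(f"s{i}" for i in range(n)),
        np.ones(n),
    )


class TestMisclassificationRate:
    def test_counting(self, strong_signal_sim):
        cm, truth = strong_signal_sim
        model = fit_reference_model(filter_taxa(cm), eta=0.05, seed=0)
        rate = misclassification_rate(model, truth)
        expected = len(model.reference_set & truth.da_taxa) / len(model.reference_set)
        assert rate == expected
        assert 0.0 <= rate <= 1.0

    def test_hand_cases(self):
        truth = make_truth({"d"}, {"a", "b", "c"})

        class Fake:
            reference_set = frozenset({"a", "b", "c", "d"})

        assert misclassification_rate(Fake(), truth) == 0.25
        Fake.reference_set = frozenset({"a", "b"})
        assert misclassification_rate(Fake(), truth) == 0.0
        Fake.reference_set = frozenset({"d"})
        assert misclassification_rate(Fake(), truth) == 1.0


class TestPerTaxonTests:
    def test_identical_groups_give_p_one(self):
        nm = NormalizedMatrix(
            np.array([[1.0, 1.0, 1.0, 1.0], [1, 2, 1, 2]]),
            ("flat", "var"),
            ("a", "b", "c", "d"),
            np.ones(4),
        )
        cov = CovariateTable(("a", "b", "c", "d"), np.array([0, 0, 1, 1]))
        res = per_taxon_tests(nm, cov, test="t_test", log_transform=False)
        assert res.p_values[0] == pytest.approx(1.0)

    def test_welch_textbook_example(self):
        # groups [1,2,3] vs [4,5,6]: t = -3.674, Welch df = 4, p ~ 0.0214
        nm = NormalizedMatrix(
            np.array([[1.0, 2, 3, 4, 5, 6]]),
            ("t",),
            tuple("abcdef"),
            np.ones(6),
        )
        cov = CovariateTable(tuple("abcdef"), np.array([0, 0, 0, 1, 1, 1]))
        res = per_taxon_tests(nm, cov, test="t_test", log_transform=False)
        assert abs(res.statistics[0]) == pytest.approx(3.674, abs=1e-3)
        assert res.p_values[0] == pytest.approx(0.0214, abs=5e-4)

    def test_perfect_correlation_rejected_with_tiny_p(self):
        y = np.array([0.1, 0.5, 0.3, 0.9, 0.7])
        nm = NormalizedMatrix(
            np.vstack([y, y[::-1]]), ("pos", "neg"), tuple("abcde"), np.ones(5)
        )
        cov = CovariateTable(tuple("abcde"), y)
        res = per_taxon_tests(nm, cov, test="pearson", log_transform=False)
        assert res.statistics[0] == pytest.approx(1.0)
        assert res.p_values[0] < 1e-10

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = np.concatenate([rng.uniform(0, 1, 40), rng.uniform(0, 1e-3, 10)])
        ours = _bh_reject(p, 0.05)
        theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(ours, theirs)

    def test_binary_covariate_required_for_t_test(self):
        nm = NormalizedMatrix(np.ones((1, 4)), ("t",), tuple("abcd"), np.ones(4))
        cov = CovariateTable(tuple("abcd"), np.array([0.0, 0.5, 1.0, 2.0]))
        with pytest.raises(InputError, match="binary"):
            per_taxon_tests(nm, cov, test="t_test")


class TestFdpAndSensitivity:
    def test_exact_recovery(self):
        truth = make_truth({"d1", "d2"}, {"n1", "n2"})
        assert fdp_and_sensitivity({"d1", "d2"}, truth) == (0.0, 1.0)

    def test_empty_rejections_convention(self):
        truth = make_truth({"d1"}, {"n1"})
        assert fdp_and_sensitivity(set(), truth) == (0.0, 0.0)

    def test_mixed_counting(self):
        truth = make_truth({"d1", "d2", "d3", "d4"}, {"n1", "n2"})
        fdp, sens = fdp_and_sensitivity({"n1", "d1"}, truth)
        assert (fdp, sens) == (0.5, 0.25)

    def test_no_da_taxa_sensitivity_missing(self):
        truth = make_truth(set(), {"n1", "n2"})
        fdp, sens = fdp_and_sensitivity({"n1"}, truth)
        assert fdp == 1.0 and sens is None


class TestPermanova:
    def test_exhaustive_toy_two_vs_two(self):
        # 1-D points {0, 0.1} vs {10, 10.1}: of the 6 balanced splits only
        # the observed one and its mirror attain the maximal F, so p = 2/6.
        nm = coords_to_nm(np.array([[0.0], [0.1], [10.0], [10.1]]))
        cov = CovariateTable(nm.sample_ids, np.array([0, 0, 1, 1]))
        f, p = permanova(nm, cov, n_permutations=999, log_transform=False)
        assert p == pytest.approx(2 / 6)
        assert f > 100

    def test_brute_force_oracle_on_random_data(self):
        """The pseudo-F and exhaustive p must match a from-scratch
        enumeration over all balanced group assignments."""
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        nm = coords_to_nm(pts - pts.min() + 1)
        cov = CovariateTable(nm.sample_ids, labels.astype(float))
        f, p = permanova(nm, cov, n_permutations=10_000, log_transform=False)

        def brute_f(pts, lab):
            n = len(lab)
            d2 = np.array(
                [[np.sum((pts[i] - pts[j]) ** 2) for j in range(n)] for i in range(n)]
            )
            sst = d2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in (0, 1):
                idx = np.flatnonzero(lab == g)
                ssw += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
            return ((sst - ssw) / 1) / (ssw / (n - 2))

        f_expected = brute_f(pts, labels)
        assert f == pytest.approx(f_expected, abs=1e-10)
        count = 0
        total = 0
        for members in combinations(range(8), 4):
            lab = np.zeros(8, dtype=int)
            lab[list(members)] = 1
            total += 1
            if brute_f(pts, lab) >= f_expected - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 5))
        labels = np.repeat([0, 1], 6)
        nm = coords_to_nm(pts - pts.min() + 1)
        cov = CovariateTable(nm.sample_ids, labels.astype(float))
        f, _ = permanova(nm, cov, n_permutations=99, log_transform=False)
        dm = skbio_stats.DistanceMatrix(squareform(pdist(pts)), ids=list(nm.sample_ids))
        res = skbio_stats.permanova(dm, labels.astype(str), permutations=99)
        assert f == pytest.approx(res["test statistic"], rel=1e-9)

    def test_p_uniform_under_exchangeable_labels(self):
        rng = np.random.default_rng(9)
        from scipy import stats as sps

        pvals = []
        for rep in range(200):
            pts = rng.normal(size=(10, 4))
            labels = rng.permutation(np.repeat([0, 1], 5)).astype(float)
            nm = coords_to_nm(pts - pts.min() + 1)
            cov = CovariateTable(nm.sample_ids, labels)
            _, p = permanova(
                nm, cov, n_permutations=49, log_transform=False, seed=rep
            )
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").statistic < 0.1

    def test_single_member_group_rejected(self):
        nm = coords_to_nm(np.zeros((4, 2)))
        cov = CovariateTable(nm.sample_ids, np.array([0, 1, 1, 1]))
        with pytest.raises(InputError, match="at least 2"):
            permanova(nm, cov)


class TestPcoa:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(9, 2))
        nm = coords_to_nm(pts)
        coords, eigvals = pcoa_coordinates(nm, k=2, log_transform=False)
        # classical MDS recovers Euclidean input up to rotation/reflection:
        # compare via Procrustes
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts - pts.mean(0), coords)
        assert disparity < 1e-12

    def test_identical_samples_collapse_to_origin(self):
        nm = coords_to_nm(np.zeros((5, 3)))
        coords, eigvals = pcoa_coordinates(nm, k=2, log_transform=False)
        assert np.allclose(coords, 0.0)

    def test_collinear_points_live_on_one_axis(self):
        pts = np.column_stack([np.arange(4.0), 2 * np.arange(4.0)])
        nm = coords_to_nm(pts)
        coords, eigvals = pcoa_coordinates(nm, k=3, log_transform=False)
        positive = eigvals[eigvals > 1e-9]
        assert positive[0] / positive.sum() >= 0.999

    def test_eigenvalue_sum_equals_centered_inertia(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 3))
        nm = coords_to_nm(pts)
        _, eigvals = pcoa_coordinates(nm, k=2, log_transform=False)
        centered = pts - pts.mean(axis=0)
        assert eigvals[eigvals > 0].sum() == pytest.approx(
            np.sum(centered**2), rel=1e-9
        )

    def test_k_too_large_rejected(self):
        nm = coords_to_nm(np.zeros((3, 2)))
        with pytest.raises(InputError, match="k must lie"):
            pcoa_coordinates(nm, k=3)


def test_permanova_power_improves_after_normalization():
    """With true differentially abundant taxa, the group signal is easier
    to detect on reference-normalized data than on raw counts, where
    depth variation drowns it (mean over 10 replicates)."""
    import warnings

    from rsim import SimulationConfig, filter_taxa, generate, rsim_normalize

    power_norm, power_raw = 0, 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(1, 11):
            cm, truth = generate(
                SimulationConfig(d=100, n=40, prop_da=0.1, signal=2.5, seed=seed)
            )
            cmf = filter_taxa(cm)
            cov = CovariateTable(cm.sample_ids, truth.latent_values)
            nm, _ = rsim_normalize(cmf, eta=0.05, seed=seed)
            _, p = permanova(nm, cov, n_permutations=99, seed=seed)
            power_norm += p <= 0.05
            raw = NormalizedMatrix(
                cmf.counts, cmf.taxon_ids, cmf.sample_ids,
                np.ones(cmf.n_samples), None, "raw",
            )
            _, p_raw = permanova(raw, cov, n_permutations=99, seed=seed)
            power_raw += p_raw <= 0.05
    assert power_norm >= power_raw
    assert power_norm >= 5  # detects the planted signal in most replicates
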