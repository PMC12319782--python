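import itertools

import numpy as np
import pytest

import eegsilence as es
from eegsilence.headmodel import CovarianceModel
from eegsilence.silencemap import ContributionMap, _is_connected
from eegsilence.spectral import EEGRecording

from conftest import make_orthogonal_leadfield


def path_source_space(p, beta_spacing=10.0):
    """1-D path graph embedded on a line (single 'R' hemisphere)."""
    pos = np.stack([np.full(p, 30.0), np.arange(p) * beta_spacing,
                    np.zeros(p)], axis=1)
    adj = {i: frozenset(j for j in (i - 1, i + 1) if 0 <= j < p) for i in range(p)}
    return es.SourceSpace(positions=pos, hemisphere=np.array(["R"] * p),
                          adjacency=adj, spacing=beta_spacing,
                          parcels=np.array(["other"] * p))


def rec(X, band="Full", condition="rest"):
    return EEGRecording(X=X, fs=256.0, condition=condition, band=band)


class TestSourceProjection:
    def test_orthonormal_recovery(self, orthogonal_leadfield):
        lf = orthogonal_leadfield
        rng = np.random.default_rng(0)
        s = rng.standard_normal(500)
        X = np.outer(lf.A_norm[:, 1], s)
        proj = es.source_projection(rec(X), lf)
        assert np.allclose(proj.mu[1], s, atol=1e-12)

    def test_zero_input(self, orthogonal_leadfield):
        proj = es.source_projection(rec(np.zeros((16, 100))), orthogonal_leadfield)
        assert (proj.variance == 0).all()

    def test_crosstalk_closed_form(self):
        """Two correlated columns: Var(mu_1) = (1 + c g)^2-weighted mixture."""
        a1 = np.array([1.0, 0.0, -1.0, 0.0]) / np.sqrt(2)
        a2 = np.array([0.5, 0.5, -0.5, -0.5])
        A = np.stack([a1, a2], axis=1)
        lf = es.normalize_leadfield(A)
        g = float(a1 @ a2)
        rng = np.random.default_rng(1)
        s = rng.standard_normal((2, 200000))
        X = A @ s
        proj = es.source_projection(rec(X), lf)
        # mu_1 = s_1 + g s_2 -> Var = 1 + g^2 (independent unit sources)
        assert proj.variance[0] == pytest.approx(1 + g**2, rel=0.02)
        assert proj.variance[1] == pytest.approx(1 + g**2, rel=0.02)

    def test_dimension_mismatch(self, orthogonal_leadfield):
        with pytest.raises(ValueError, match="channels"):
            es.source_projection(rec(np.zeros((7, 10))), orthogonal_leadfield)


class TestSourceContribution:
    def test_self_normalization_unity(self, orthogonal_leadfield):
        """A single active unit-variance source with a one-hot model has beta=1."""
        lf = orthogonal_leadfield
        n, p = lf.A.shape
        C_x = np.outer(lf.A_norm[:, 2], lf.A_norm[:, 2])
        s_var = np.zeros(p)
        s_var[2] = 1.0
        cov = CovarianceModel(C_x=C_x, C_z=np.zeros((n, n)), s_var=s_var,
                              selec=np.arange(n))
        beta = es.source_contribution(rec(np.zeros((n, 10))), lf, cov)
        assert beta.beta[2] == pytest.approx(1.0, rel=1e-9)

    def test_silenced_source_beta_zero(self, orthogonal_leadfield):
        lf = orthogonal_leadfield
        n, p = lf.A.shape
        active = [0, 1, 3, 4, 5, 6, 7]
        C_x = sum(np.outer(lf.A_norm[:, q], lf.A_norm[:, q]) for q in active)
        s_var = np.ones(p)
        cov = CovarianceModel(C_x=C_x, C_z=np.zeros((n, n)), s_var=s_var,
                              selec=np.arange(n))
        beta = es.source_contribution(rec(np.zeros((n, 10))), lf, cov)
        assert beta.beta[2] < 1e-9  # orthogonal leakage-free silence
        assert beta.beta[0] == pytest.approx(1.0, rel=1e-9)

    def test_scale_invariance(self, orthogonal_leadfield):
        lf = orthogonal_leadfield
        rng = np.random.default_rng(2)
        X = lf.A_norm @ rng.standard_normal((8, 5000))
        b1 = es.source_contribution(rec(X), lf, es.estimate_covariances(X, lf))
        Xs = 7.0 * X
        b2 = es.source_contribution(rec(Xs), lf, es.estimate_covariances(Xs, lf))
        assert np.allclose(b1.beta, b2.beta, rtol=1e-8)

    def test_uninformative_covariance(self, orthogonal_leadfield):
        lf = orthogonal_leadfield
        n, p = lf.A.shape
        cov = CovarianceModel(C_x=np.eye(n), C_z=np.zeros((n, n)),
                              s_var=np.zeros(p), selec=np.arange(n))
        with pytest.raises(ValueError, match="uninformative covariance"):
            es.source_contribution(rec(np.zeros((n, 10))), lf, cov)


class TestContributionRatio:
    def test_identity_and_values(self):
        num = ContributionMap(beta=np.array([2.0, 1.0]), band="Theta", numerator="rest")
        den = ContributionMap(beta=np.array([1.0, 1.0]), band="Theta", numerator="S1")
        ratio = es.contribution_ratio(num, den)
        assert np.allclose(ratio.beta, [2.0, 1.0])
        same = es.contribution_ratio(num, num)
        assert np.allclose(same.beta, 1.0)

    def test_active_source_small_ratio(self):
        rest = ContributionMap(beta=np.array([1.0, 1.0, 1.0]), band="Full",
                               numerator="rest")
        s1 = ContributionMap(beta=np.array([1.0, 4.0, 1.0]), band="Full",
                             numerator="S1")
        ratio = es.contribution_ratio(rest, s1)
        assert ratio.beta[1] == pytest.approx(0.25)
        assert int(np.argmin(ratio.beta)) == 1

    def test_band_mismatch(self):
        a = ContributionMap(beta=np.ones(2), band="Theta", numerator="rest")
        b = ContributionMap(beta=np.ones(2), band="Alpha", numerator="S1")
        with pytest.raises(ValueError, match="band mismatch"):
            es.contribution_ratio(a, b)


class TestCSpeCSelect:
    def test_path_example(self):
        sources = path_source_space(6)
        beta = np.array([5.0, 0.1, 0.2, 4.0, 4.0, 4.0])
        roi = es.cspec_select(beta, sources, "R", es.CSpeCConfig(k=2))
        assert set(roi.indices.tolist()) == {1, 2}

    def test_k_equals_hemisphere(self):
        sources = path_source_space(5)
        roi = es.cspec_select(np.ones(5), sources, "R", es.CSpeCConfig(k=5))
        assert len(roi) == 5

    def test_uniform_beta_tie_break_deterministic(self):
        sources = path_source_space(6)
        cfg = es.CSpeCConfig(k=3)
        r1 = es.cspec_select(np.ones(6), sources, "R", cfg)
        r2 = es.cspec_select(np.ones(6), sources, "R", cfg)
        assert np.array_equal(r1.indices, r2.indices)
        assert _is_connected(r1.index_set(),
                             {i: set(sources.adjacency[i]) for i in range(6)})

    def test_matches_brute_force_on_random_graphs(self):
        """Selector equals exhaustive search over connected k-subsets."""
        import networkx as nx

        rng = np.random.default_rng(11)
        for trial in range(30):
            p = int(rng.integers(5, 13))
            while True:
                G = nx.gnp_random_graph(p, float(rng.uniform(0.25, 0.6)),
                                        seed=int(rng.integers(1 << 30)))
                if nx.is_connected(G):
                    break
            pos = np.stack([np.full(p, 30.0), rng.uniform(-50, 50, p),
                            rng.uniform(-50, 50, p)], axis=1)
            adj = {u: frozenset(G[u]) for u in G}
            sources = es.SourceSpace(positions=pos, hemisphere=np.array(["R"] * p),
                                     adjacency=adj, spacing=10.0,
                                     parcels=np.array(["other"] * p))
            beta = rng.uniform(0, 10, p)
            k = int(rng.integers(1, 5))
            roi = es.cspec_select(beta, sources, "R", es.CSpeCConfig(k=k))
            best = min((beta[list(c)].sum()
                        for c in itertools.combinations(range(p), k)
                        if _is_connected(set(c), {u: set(v) for u, v in adj.items()})))
            assert beta[roi.indices].sum() == pytest.approx(best, abs=1e-9)

    def test_k_too_large(self):
        sources = path_source_space(4)
        with pytest.raises(ValueError, match="exceeds hemisphere"):
            es.cspec_select(np.ones(4), sources, "R", es.CSpeCConfig(k=9))


class TestLocalizeRegion:
    @pytest.fixture(scope="class")
    def localization(self, study_geometry):
        """One scaled silence-localization run shared by the class."""
        montage, sources, lf = study_geometry
        sc = es.SyntheticScenario(seed=17, bands=("Full",), fs=128.0,
                                  rest_duration_s=60, condition_duration_s=60)
        case, gt = es.simulate_scenario(sc, lf, subject="SM", role="case",
                                        conditions=("rest",))
        ctrl, _ = es.simulate_scenario(sc, lf, subject="c1", role="control",
                                       conditions=("rest",))
        roi = es.localize_region(case[("rest", "Full")], ctrl[("rest", "Full")],
                                 lf, "R", es.CSpeCConfig(k=100), mode="silence")
        return sources, gt, roi

    def test_planted_silence_recovered(self, localization):
        sources, gt, roi = localization
        truth = set(gt.silent_indices.tolist())
        S = roi.index_set()
        assert len(S & truth) / len(S | truth) >= 0.5

    def test_region_in_correct_hemisphere(self, localization):
        sources, gt, roi = localization
        assert (sources.hemisphere[roi.indices] == "R").all()

    def test_deeper_silence_localizes_no_worse(self, study_geometry):
        """Average center-of-mass error does not increase when the planted
        silence deepens (50% residual variance vs 1%)."""
        montage, sources, lf = study_geometry
        errs = {0.5: [], 0.01: []}
        for seed in (61, 62, 63, 64):
            for frac in errs:
                sc = es.SyntheticScenario(seed=seed, bands=("Full",), fs=128.0,
                                          rest_duration_s=60, condition_duration_s=60,
                                          lesion_var_frac=frac)
                case, gt = es.simulate_scenario(sc, lf, subject="SM", role="case",
                                                conditions=("rest",))
                ctrl, _ = es.simulate_scenario(sc, lf, subject="c", role="control",
                                               conditions=("rest",))
                roi = es.localize_region(case[("rest", "Full")], ctrl[("rest", "Full")],
                                         lf, "R", es.CSpeCConfig(k=100), mode="silence")
                com = np.linalg.norm(sources.positions[roi.indices].mean(0)
                                     - sources.positions[gt.silent_indices].mean(0))
                errs[frac].append(com)
        assert np.mean(errs[0.01]) <= np.mean(errs[0.5]) + 2.0

    def test_null_contrast_flagged(self, study_geometry):
        """task == base gives ratios near 1 and an uninformative warning."""
        montage, sources, lf = study_geometry
        sc = es.SyntheticScenario(seed=5, bands=("Full",), fs=128.0,
                                  rest_duration_s=30)
        ctrl, _ = es.simulate_scenario(sc, lf, subject="c", role="control",
                                       conditions=("rest",))
        r = ctrl[("rest", "Full")]
        with pytest.warns(UserWarning, match="uninformative"):
            roi = es.localize_region(r, r, lf, "R",
                                     es.CSpeCConfig(k=50, r_max=1), mode="silence")
        assert roi.provenance["uninformative"]

    def test_degenerate_base(self, study_geometry):
        _, _, lf = study_geometry
        z = rec(np.zeros((lf.n_channels, 100)))
        with pytest.raises(ValueError, match="degenerate base"):
            es.localize_region(z, z, lf, "R", es.CSpeCConfig(k=10))

    def test_activation_mode_recovers_active_region(self, study_geometry):
        """Planted high-S1 posterior region found by activation localization."""
        montage, sources, lf = study_geometry
        sc = es.SyntheticScenario(seed=23, bands=("Full",), fs=128.0,
                                  rest_duration_s=60, condition_duration_s=60,
                                  slope_alpha=1.0)
        ctrl, gt = es.simulate_scenario(sc, lf, subject="c2", role="control",
                                        conditions=("rest", "S1"))
        roi = es.localize_region(ctrl[("S1", "Full")], ctrl[("rest", "Full")],
                                 lf, "R", es.CSpeCConfig(k=100), mode="activation")
        visual_R = np.where(np.isin(sources.parcels, ["ventral_R", "dorsal_R"]))[0]
        overlap = len(roi.index_set() & set(visual_R.tolist())) / len(roi)
        assert overlap >= 0.5


class TestRefineHighRes:
    def test_exact_child_consistency(self, orthogonal_leadfield):
        """With a 1->2 child mapping and a noiseless planted contrast the
        refined region equals the children of the low-res region."""
        # tiny two-level path geometry
        p_low, factor = 6, 2
        low = path_source_space(p_low)
        p_high = p_low * factor
        pos = np.stack([np.full(p_high, 30.0), np.arange(p_high) * 5.0,
                        np.zeros(p_high)], axis=1)
        adj = {i: frozenset(j for j in (i - 1, i + 1) if 0 <= j < p_high)
               for i in range(p_high)}
        high = es.SourceSpace(positions=pos, hemisphere=np.array(["R"] * p_high),
                              adjacency=adj, spacing=5.0,
                              parcels=np.array(["other"] * p_high),
                              tier="high", parent=np.repeat(np.arange(p_low), factor))
        region_low = es.RegionOfInterest(indices=[2, 3], hemisphere="R", mode="silence")
        # build an orthogonal high-res leadfield and a silent contrast
        lf = make_orthogonal_leadfield(n=24, p=p_high)
        lf = es.Leadfield(A=lf.A, A_norm=lf.A_norm, col_norms=lf.col_norms,
                          sources=high)
        rng = np.random.default_rng(3)
        var = np.ones(p_high)
        var[region_low.indices[0] * factor:(region_low.indices[-1] + 1) * factor] = 1e-4
        Sb = rng.standard_normal((p_high, 6000))
        base_X = lf.A_norm @ Sb
        task_X = lf.A_norm @ (Sb * np.sqrt(var)[:, None])
        cfg = es.CSpeCConfig(k=2)
        out = es.refine_high_res(region_low, high, rec(task_X), rec(base_X), lf, cfg)
        expected = {4, 5, 6, 7}
        assert set(out.indices.tolist()) <= expected
        assert len(out) == 4  # k scaled by resolution ratio 2

    def test_missing_parent_mapping(self, study_geometry):
        _, sources, lf = study_geometry
        region = es.RegionOfInterest(indices=[0, 1], hemisphere="R")
        with pytest.raises(ValueError, match="parent"):
            es.refine_high_res(region, sources, rec(np.zeros((lf.n_channels, 100))),
                               rec(np.zeros((lf.n_channels, 100))), lf,
                               es.CSpeCConfig(k=2))
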