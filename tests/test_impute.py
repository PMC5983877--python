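import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssimpute import ld
from ssimpute.impute import (
    MissingnessModel,
    build_D,
    build_d,
    delta_dep,
    delta_ind,
    impute_z,
    impute_z_varN,
    mask_and_impute,
    rescale_observed_z,
    window_impute,
    z_to_effect,
    zscore_pvalue,
)


class TestDeltas:
    @pytest.mark.parametrize("nk,nl,expected", [(100, 100, 1.0), (50, 200, 0.5), (1, 10**6, 1e-3)])
    def test_dependent(self, nk, nl, expected):
        assert delta_dep(nk, nl) == pytest.approx(expected)
        assert delta_dep(nl, nk) == pytest.approx(expected)  # symmetric

    @pytest.mark.parametrize(
        "nk,nl,nmax,expected", [(200, 200, 200, 1.0), (50, 200, 200, 0.5), (100, 100, 200, 0.5)]
    )
    def test_independent(self, nk, nl, nmax, expected):
        assert delta_ind(nk, nl, nmax) == pytest.approx(expected)

    @given(
        nk=st.integers(1, 10**6), nl=st.integers(1, 10**6), extra=st.integers(0, 10**6)
    )
    @settings(max_examples=200, deadline=None)
    def test_dependent_dominates_independent(self, nk, nl, extra):
        nmax = max(nk, nl) + extra
        dd, di = delta_dep(nk, nl), delta_ind(nk, nl, nmax)
        assert dd >= di - 1e-12
        if extra == 0:
            assert dd == pytest.approx(di)

    def test_dep_ind_equality_only_at_tight_nmax(self):
        grid = np.array([1, 2, 5, 10, 100, 1000, 10**4, 10**5])
        NK, NL = np.meshgrid(grid, grid)
        for slack in (1.0, 1.5, 4.0):
            nmax = np.maximum(NK, NL) * slack
            dd = delta_dep(NK, NL)
            di = delta_ind(NK, NL, 1) * 1 / nmax * np.sqrt(NK * NL) * 0 + np.sqrt(NK * NL) / nmax
            assert (dd >= di - 1e-12).all()
            if slack == 1.0:
                np.testing.assert_allclose(dd, di)
            else:
                assert (dd > di).all()


class TestBuildSystems:
    def setup_method(self):
        self.C = np.array([[1.0, 0.8], [0.8, 1.0]])

    def test_equal_sample_sizes_leave_matrix_unchanged(self):
        for mode in ("dependent", "independent"):
            model = MissingnessModel(mode=mode, N=[200, 200])
            np.testing.assert_array_equal(build_D(self.C, model), self.C)

    def test_dependent_attenuation(self):
        model = MissingnessModel(mode="dependent", N=[50, 200])
        D = build_D(self.C, model)
        assert D[0, 1] == pytest.approx(0.4)
        assert D[0, 0] == 1.0

    def test_known_disjoint_samples_zero_correlation(self):
        overlap = np.array([[50.0, 0.0], [0.0, 200.0]])
        model = MissingnessModel(mode="known", N=[50, 200], overlap=overlap)
        assert build_D(self.C, model)[0, 1] == 0.0

    def test_known_overlap_invariants_enforced(self):
        bad = np.array([[50.0, 100.0], [100.0, 200.0]])  # overlap > min(N)
        with pytest.raises(ValueError):
            MissingnessModel(mode="known", N=[50, 200], overlap=bad)

    def test_build_d_scaling(self):
        c = np.array([0.8, 0.4])
        model = MissingnessModel(mode="dependent", N=[100, 400])
        d = build_d(c, model)
        np.testing.assert_allclose(d, [0.8 * 0.5, 0.4])
        model_eq = MissingnessModel(mode="dependent", N=[400, 400])
        np.testing.assert_array_equal(build_d(c, model_eq), c)

    def test_build_d_zero_correlation_stays_zero(self):
        model = MissingnessModel(mode="dependent", N=[10, 400])
        assert build_d(np.array([0.0, 0.3]), model)[0] == 0.0


class TestImputeZ:
    def test_tag_self_imputation_at_lambda_zero(self):
        C = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        z = np.array([2.0, -1.0, 0.5])
        c = C[:, 1]  # target IS tag 1
        assert impute_z(z, C, c) == pytest.approx(z[1], abs=1e-10)

    def test_full_shrinkage_gives_zero(self):
        C = np.array([[1.0, 0.3], [0.3, 1.0]])
        c = np.array([0.9, 0.8])
        C1, c1 = ld.shrink(C, c, 1.0)
        assert impute_z(np.array([5.0, 4.0]), C1, c1) == 0.0

    def test_three_tag_system_matches_generic_solver(self):
        C = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        c = np.array([0.6, 0.3, 0.1])
        z = np.array([4.0, 2.0, -1.0])
        expected = float(c @ np.linalg.solve(C, z))  # independent generic solve
        assert impute_z(z, C, c) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            impute_z(np.ones(3), np.eye(2), np.ones(2))

    def test_sign_flip_equivariance(self, rng):
        # flipping a tag's allele coding (z_k, row/col k of C, entry k of c)
        # leaves the imputed z unchanged
        g = rng.standard_normal((300, 6))
        C = np.corrcoef(g, rowvar=False)
        np.fill_diagonal(C, 1.0)
        c = C[1:, 0].copy()
        C_t = C[1:, 1:].copy()
        z = rng.normal(size=5)
        C_lam, c_lam = ld.shrink(C_t, c, 0.1)
        base = impute_z(z, C_lam, c_lam)
        k = 2
        z2, c2, C2 = z.copy(), c.copy(), C_t.copy()
        z2[k] *= -1
        c2[k] *= -1
        C2[k, :] *= -1
        C2[:, k] *= -1
        C2[k, k] = 1.0
        C_lam2, c_lam2 = ld.shrink(C2, c2, 0.1)
        flipped = impute_z(z2, C_lam2, c_lam2)
        assert flipped == pytest.approx(base, rel=1e-12)


class TestVarNReduction:
    def test_equal_sample_sizes_bitwise_identical_to_base(self, rng):
        g = rng.standard_normal((400, 6))
        C = np.corrcoef(g, rowvar=False)
        np.fill_diagonal(C, 1.0)
        c = C[1:, 0].copy()
        C_lam, c_lam = ld.shrink(C[1:, 1:], c, 0.1)
        z = rng.normal(size=5)
        model = MissingnessModel(mode="dependent", N=np.full(5, 1000.0))
        D = build_D(C_lam, model)
        d = build_d(c_lam, model)
        assert impute_z_varN(z, d, D) == impute_z(z, C_lam, c_lam)  # bitwise

    def test_single_tag_closed_form(self):
        # c=0.8 (lambda=0), N_tag = N_max/4 -> d=0.4, D=1, z=5 -> 2.0
        model = MissingnessModel(mode="dependent", N=[100.0], n_max=400)
        d = build_d(np.array([0.8]), model)
        D = build_D(np.eye(1), model)
        assert impute_z_varN(np.array([5.0]), d, D) == pytest.approx(2.0)

    def test_five_tag_system_matches_generic_solver(self, rng):
        C = np.corrcoef(rng.standard_normal((200, 5)), rowvar=False)
        np.fill_diagonal(C, 1.0)
        c = 0.5 * np.ones(5)
        N = np.array([100.0, 400, 200, 400, 50])
        model = MissingnessModel(mode="independent", N=N)
        C_lam, c_lam = ld.shrink(C, c, 0.1)
        D, d = build_D(C_lam, model), build_d(c_lam, model)
        z = rng.normal(size=5)
        expected = float(d @ np.linalg.solve(D, z))
        assert impute_z_varN(z, d, D) == pytest.approx(expected, rel=1e-10)

    def test_quality_decreases_as_a_sample_size_drops(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        c = np.array([0.7, 0.6])
        C_lam, c_lam = ld.shrink(C, c, 0.1)
        prev = np.inf
        for n1 in (400, 200, 100, 10):
            model = MissingnessModel(mode="dependent", N=[float(n1), 400.0])
            D, d = build_D(C_lam, model), build_d(c_lam, model)
            q = float(d @ np.linalg.solve(D, d))
            assert q <= prev + 1e-12 and 0 <= q <= 1 + 1e-9
            prev = q


class TestEffectConversion:
    def test_closed_form(self):
        assert z_to_effect(2.0, 400, 1.0) == pytest.approx(0.1)
        assert z_to_effect(0.0, 400, 0.5) == 0.0

    def test_round_trip(self):
        a = z_to_effect(3.3, 1000, 0.8)
        z_back = a * np.sqrt(1000) * 0.8
        assert z_back == pytest.approx(3.3)

    def test_noise_quality_suppressed(self):
        assert np.isnan(z_to_effect(2.0, 400, 1e-6))

    @pytest.mark.parametrize("z,nu,nmax,expected", [(3.0, 100, 400, 6.0), (2.0, 400, 400, 2.0), (0.0, 7, 400, 0.0)])
    def test_rescale_observed(self, z, nu, nmax, expected):
        assert rescale_observed_z(z, nu, nmax) == pytest.approx(expected)

    def test_pvalue_definition(self):
        from scipy import stats

        assert zscore_pvalue(1.96) == pytest.approx(2 * (1 - stats.norm.cdf(1.96)))
        assert zscore_pvalue(30.0) > 0  # survival function avoids 1 - cdf underflow


class TestWindowImpute:
    def _records(self, small_panel, drop=("v3",)):
        rec = pd.DataFrame(
            {
                "variant_id": small_panel.variants["variant_id"],
                "chromosome": "1",
                "position": small_panel.variants["position"],
                "effect_allele": "G",
                "other_allele": "A",
                "z": [1.5, 1.4, -1.5, 0.3, -0.2, 0.8],
                "sample_size": 10_000,
                "panel_index": np.arange(6),
            }
        )
        return rec[~rec["variant_id"].isin(drop)].reset_index(drop=True)

    def test_tags_emitted_as_tags_and_targets_imputed(self, small_panel):
        res = window_impute(self._records(small_panel), small_panel, maf_min=0.0)
        by_id = res.set_index("variant_id")
        assert by_id.loc["v3", "source"] == "imputed"
        assert (by_id.drop("v3")["source"] == "tag").all()
        assert by_id.loc["v0", "z_imp"] == 1.5

    def test_windows_are_local(self, rng):
        # two windows with disjoint tag blocks: imputing jointly or per
        # chromosome-half gives the same answers
        from ssimpute.simulate import BlockSpec, RegionSpec, SimulationConfig, simulate_genotypes

        regions = [
            RegionSpec(blocks=[BlockSpec(4, 0.9, 0.3)], chromosome="1", start=100_000),
            RegionSpec(blocks=[BlockSpec(4, 0.9, 0.3)], chromosome="1", start=5_100_000),
        ]
        panel = simulate_genotypes(SimulationConfig(n_individuals=800, regions=regions), rng)
        rec = pd.DataFrame(
            {
                "variant_id": panel.variants["variant_id"],
                "chromosome": "1",
                "position": panel.variants["position"],
                "effect_allele": "G",
                "other_allele": "A",
                "z": rng.normal(size=8),
                "sample_size": 5000,
                "panel_index": np.arange(8),
            }
        )
        rec = rec.drop(index=[1, 6]).reset_index(drop=True)  # one target per block
        joint = window_impute(rec, panel, maf_min=0.0)
        left = window_impute(rec.iloc[:3], panel.subset(range(4)), maf_min=0.0)
        j = joint[joint["source"] == "imputed"].set_index("variant_id")
        l = left[left["source"] == "imputed"].set_index("variant_id")
        for vid in l.index:
            assert j.loc[vid, "z_imp"] == pytest.approx(l.loc[vid, "z_imp"], rel=1e-12)

    def test_window_with_zero_tags_reports_zero_quality(self, small_panel):
        rec = self._records(small_panel).iloc[:0]
        res = window_impute(rec, small_panel, maf_min=0.0)
        assert res.empty  # no tags anywhere -> no windows to report


class TestMaskAndImpute:
    def test_perfect_proxy_recovers_focal_z(self, small_panel):
        rec = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(6)],
                "chromosome": "1",
                "position": small_panel.variants["position"],
                "effect_allele": "G",
                "other_allele": "A",
                "z": [1.5, 1.5, -1.5, 0.3, -0.2, 0.8],
                "sample_size": 10_000,
                "panel_index": np.arange(6),
            }
        )
        res = mask_and_impute(rec, small_panel, "v0", lam=1e-6)
        assert res.z_imp == pytest.approx(1.5, rel=1e-3)  # v1 duplicates v0
        assert res.r2_pred > 0.99

    def test_zero_ld_focal_gets_negligible_z_and_quality(self, rng):
        n = 2000
        dosages = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        panel_vars = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(5)], "chromosome": "1",
             "position": [1000, 2000, 3000, 4000, 5000], "ref": "A", "alt": "G"}
        )
        from ssimpute.io import ReferencePanel

        panel = ReferencePanel(dosages, panel_vars)
        rec = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(5)], "chromosome": "1",
             "position": [1000, 2000, 3000, 4000, 5000], "effect_allele": "G",
             "other_allele": "A", "z": [5.0, 4.0, 3.0, 2.0, 1.0],
             "sample_size": 10_000, "panel_index": np.arange(5)}
        )
        res = mask_and_impute(rec, panel, "v0")
        assert abs(res.z_imp) < 1.0
        assert res.r2_pred < 0.05

    def test_missing_focal_rejected(self, small_panel, summary_frame):
        with pytest.raises(KeyError):
            mask_and_impute(summary_frame.assign(panel_index=range(6)), small_panel, "nope")
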