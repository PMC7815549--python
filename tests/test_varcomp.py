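"""Univariate A/D/H/E likelihood, fitting, LRTs and derived quantities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedvar.pedigree import (
    IndividualRecord,
    PedigreeGraph,
    RelationshipMatrices,
    relationship_matrices,
)
from pedvar.simulate import SimulationConfig, simulate_blocks
from pedvar.varcomp import (
    ADHE,
    Block,
    ComponentSpec,
    Dataset,
    FitError,
    broad_sense_h2,
    build_dataset,
    compare_fits,
    family_covariance,
    fit_univariate,
    likelihood_ratio_test,
)

NA_FULL = {"A": 0.11, "D": 0.28, "H": 0.066, "E": 0.34}


def _mz_pair_mats(shared_household=True):
    h = 1.0 if shared_household else 0.0
    return RelationshipMatrices(
        ids=["t1", "t2"],
        additive=np.array([[1.0, 1.0], [1.0, 1.0]]),
        dominance=np.array([[1.0, 1.0], [1.0, 1.0]]),
        household=np.array([[1.0, h], [h, 1.0]]),
    )


class TestComponentSpec:
    def test_e_required(self):
        with pytest.raises(ValueError, match="E"):
            ComponentSpec(("A", "D"))

    def test_d_requires_a(self):
        with pytest.raises(ValueError, match="D requires A"):
            ComponentSpec(("D", "E"))

    def test_parse_and_canonical_order(self):
        assert tuple(ComponentSpec.parse("EDAH")) == ("A", "D", "H", "E")


class TestFamilyCovariance:
    def test_singleton_pure_e(self):
        mats = RelationshipMatrices(["i"], np.eye(1), np.eye(1), np.eye(1))
        S = family_covariance(ComponentSpec(("E",)), {"E": 1.0}, mats)
        assert S == pytest.approx(np.array([[1.0]]))

    def test_mz_pair_full_model_values(self):
        """MZ pair sharing a household under the full-model NA variance
        components: off-diagonal A+D+H = 0.456, diagonal total = 0.796."""
        S = family_covariance(ADHE, NA_FULL, _mz_pair_mats())
        assert S[0, 1] == pytest.approx(0.456)
        assert S[0, 0] == pytest.approx(0.796)

    def test_spouse_pair_offdiagonal_is_household_only(self):
        mats = RelationshipMatrices(
            ids=["f", "m"],
            additive=np.eye(2),
            dominance=np.eye(2),
            household=np.ones((2, 2)),
        )
        S = family_covariance(ADHE, NA_FULL, mats)
        assert S[0, 1] == pytest.approx(NA_FULL["H"])


def _dataset_from_families(fams, components=("A", "D", "H", "E")):
    blocks = []
    for k, (R, y, X) in enumerate(fams):
        blocks.append(Block(R=R, y=np.asarray(y, float), X=np.asarray(X, float),
                            family_id=f"f{k}"))
    return Dataset(blocks, components)


class TestLoglikelihood:
    def test_single_standard_normal_observation(self):
        R = {"E": np.eye(1)}
        ds = _dataset_from_families([(R, [0.0], [[1.0]])], components=("E",))
        ll = ds.loglik({"E": 1.0}, beta=np.array([0.0]))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_dense_multivariate_normal(self):
        """3-member family log-density equals an independent dense MVN
        evaluation."""
        mats = RelationshipMatrices(
            ids=["f", "m", "c"],
            additive=np.array([[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1.0]]),
            dominance=np.eye(3),
            household=np.ones((3, 3)),
        )
        sigma2 = NA_FULL
        S = family_covariance(ADHE, sigma2, mats)
        y = np.array([0.3, -0.2, 0.9])
        X = np.column_stack([np.ones(3), [50.0, 48.0, 17.0], [0.0, 1.0, 1.0]])
        beta = np.array([0.1, -0.004, 0.15])
        R = {"A": mats.additive, "D": mats.dominance, "H": mats.household,
             "E": np.eye(3)}
        ds = _dataset_from_families([(R, y, X)])
        ll = ds.loglik(sigma2, beta=beta)
        oracle = stats.multivariate_normal(mean=X @ beta, cov=S).logpdf(y)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_duplicating_family_doubles_contribution(self):
        R = {"A": np.array([[1, 0.5], [0.5, 1]]), "D": np.eye(2),
             "H": np.eye(2), "E": np.eye(2)}
        y, X = [0.5, -0.1], [[1.0, 30, 0], [1.0, 28, 1]]
        one = _dataset_from_families([(R, y, X)])
        two = _dataset_from_families([(R, y, X), (R, y, X)])
        beta = np.array([0.0, 0.0, 0.0])
        assert two.loglik(NA_FULL, beta) == pytest.approx(
            2 * one.loglik(NA_FULL, beta), abs=1e-10
        )

    def test_family_order_irrelevant(self):
        rng = np.random.default_rng(5)
        fams = []
        for _ in range(6):
            R = {"A": np.array([[1, 0.5], [0.5, 1]]), "D": np.eye(2),
                 "H": np.eye(2), "E": np.eye(2)}
            fams.append((R, rng.normal(size=2),
                         np.column_stack([np.ones(2), rng.normal(size=2),
                                          [0, 1]])))
        a = _dataset_from_families(fams).loglik(NA_FULL, np.zeros(3))
        b = _dataset_from_families(fams[::-1]).loglik(NA_FULL, np.zeros(3))
        assert a == pytest.approx(b, abs=1e-10)

    def test_profile_gradient_matches_finite_differences(self):
        ds = simulate_blocks(SimulationConfig(n_families=80), seed=4)
        theta = np.array([0.1, 0.2, 0.05, 0.3])
        f0, g = ds.profile_negloglik(theta, grad=True)
        for k in range(4):
            h = 1e-6
            up, dn = theta.copy(), theta.copy()
            up[k] += h
            dn[k] -= h
            fd = (ds.profile_negloglik(up) - ds.profile_negloglik(dn)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-4, abs=1e-4)


class TestFitting:
    def test_zero_household_truth_recovered_at_boundary(self):
        cfg = SimulationConfig(
            n_families=600,
            sigma2={"na": {"A": 0.3, "D": 0.0, "H": 0.0, "E": 0.5},
                    "si": {"A": 0.3, "D": 0.0, "H": 0.0, "E": 0.5}},
            component_correlations={"A": 0.5, "D": 0.0, "H": 0.0, "E": 0.3},
        )
        ds = simulate_blocks(cfg, seed=21)
        fit = fit_univariate(ds)
        assert fit.sigma2["H"] < 0.04

    def test_nested_fit_never_beats_full(self):
        ds = simulate_blocks(SimulationConfig(n_families=300), seed=9)
        full = fit_univariate(ds)
        for red in ("ADE", "AHE", "AE"):
            rfit = fit_univariate(ds, ComponentSpec.parse(red))
            assert rfit.loglik <= full.loglik + 1e-4

    def test_total_variance_near_one_after_int(self):
        """Fitting inverse-normal-transformed phenotypes: the component sum
        recovers the unit variance of the transformed scale (minus the small
        share taken by the fixed effects)."""
        from pedvar.simulate import simulate_pedigrees, simulate_phenotypes

        cfg = SimulationConfig(n_families=1200)
        fams = simulate_pedigrees(cfg, 31)
        phenos = simulate_phenotypes(fams, cfg, 32)
        peds = {f.family_id: f.ped for f in fams}
        ds = build_dataset(peds, phenos, "na", transform=True)
        fit = fit_univariate(ds)
        assert fit.total_variance == pytest.approx(1.0, rel=0.05)

    def test_pure_twin_design_matches_falconer_moments(self):
        """With only MZ and DZ pairs, ML ADE estimates agree with the
        closed-form moment solution A = 4 rDZ - rMZ, D = 2 rMZ - 4 rDZ
        (times the total variance)."""
        cfg = SimulationConfig(
            n_families=4000,
            template_weights={"mz_pair": 0.5, "dz_pair": 0.5},
            sigma2={"na": {"A": 0.3, "D": 0.2, "H": 0.0, "E": 0.5},
                    "si": {"A": 0.3, "D": 0.2, "H": 0.0, "E": 0.5}},
            component_correlations={"A": 0.5, "D": 0.5, "H": 0.0, "E": 0.3},
            age_twin=(35.0, 8.0, 20.0, 60.0),  # adults: no household sharing
        )
        ds = simulate_blocks(cfg, seed=14)
        fit = fit_univariate(ds, ComponentSpec.parse("ADE"))
        # moment estimates from the same data
        rs = {"mz": [], "dz": []}
        for g in ds.groups:
            if g.Y.shape[1] != 2:
                continue
            kind = "mz" if g.R["A"][0, 1] == 1.0 else "dz"
            rs[kind].append(g.Y)
        resid = {}
        for kind in rs:
            Y = np.vstack(rs[kind])
            Y = np.vstack([Y, Y[:, ::-1]])
            resid[kind] = np.corrcoef(Y[:, 0], Y[:, 1])[0, 1]
        total = fit.total_variance
        a_moment = (4 * resid["dz"] - resid["mz"]) * total
        d_moment = (2 * resid["mz"] - 4 * resid["dz"]) * total
        assert fit.sigma2["A"] == pytest.approx(a_moment, abs=0.08)
        assert fit.sigma2["D"] == pytest.approx(d_moment, abs=0.08)

    def test_boundary_estimate_flagged_with_nan_se(self):
        cfg = SimulationConfig(
            n_families=400,
            sigma2={"na": {"A": 0.4, "D": 0.0, "H": 0.0, "E": 0.6},
                    "si": {"A": 0.4, "D": 0.0, "H": 0.0, "E": 0.6}},
            component_correlations={"A": 0.5, "D": 0.0, "H": 0.0, "E": 0.3},
        )
        ds = simulate_blocks(cfg, seed=77)
        fit = fit_univariate(ds)
        for c in fit.spec:
            if fit.boundary[c]:
                assert np.isnan(fit.se[c])


class TestLRT:
    def test_identical_fits_give_zero(self):
        res = likelihood_ratio_test(-100.0, -100.0, 1)
        assert res.chi2 == 0.0 and res.p_value == pytest.approx(1.0)

    def test_negative_chi2_raises(self):
        with pytest.raises(FitError):
            likelihood_ratio_test(-101.0, -100.0, 1)

    def test_mixture_p_halves_central_p(self):
        res = likelihood_ratio_test(-95.0, -100.0, 1, mixture=True)
        assert res.p_value_mixture == pytest.approx(res.p_value / 2)

    def test_compare_fits_counts_df(self):
        ds = simulate_blocks(SimulationConfig(n_families=150), seed=2)
        full = fit_univariate(ds, compute_se=False)
        red = fit_univariate(ds, ComponentSpec.parse("AE"), compute_se=False)
        res = compare_fits(full, red)
        assert res.delta_df == 2
        assert res.chi2 >= 0


class TestDerived:
    def test_broad_h2_from_printed_components(self):
        from pedvar.varcomp import UnivariateFit

        f = UnivariateFit(
            spec=ADHE, sigma2=dict(NA_FULL), se={}, beta=np.zeros(3),
            beta_se=np.zeros(3), loglik=0.0, n_obs=0, converged=True,
        )
        h2, se = broad_sense_h2(f)
        assert round(h2, 2) == 0.49
        assert np.isnan(se)  # no information matrix supplied

    def test_zero_genetic_variance_gives_zero_h2(self):
        from pedvar.varcomp import UnivariateFit

        f = UnivariateFit(
            spec=ComponentSpec(("H", "E")), sigma2={"H": 0.2, "E": 0.8},
            se={}, beta=np.zeros(3), beta_se=np.zeros(3), loglik=0.0,
            n_obs=0, converged=True,
        )
        assert broad_sense_h2(f)[0] == 0.0
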