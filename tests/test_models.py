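"""Category-probability functions: oracle agreement, reductions, invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ersmix import (
    ItemParameters,
    PersonState,
    alpha2_from_mdp,
    cd_model_probs,
    ers_gpcm_probs,
    eta_weight,
    gpcm_category_probs,
    mixture_ers_gpcm_probs,
    multidim_cd_probs,
    restrict_model,
)

from conftest import oracle_category_probs


def make_items(I=4, G=2, J=4, seed=0, mdp=None, subscales=1):
    r = np.random.default_rng(seed)
    alpha1 = r.uniform(0.6, 1.4, I)
    beta = r.uniform(-1, 1, (G, I))
    beta -= beta.mean(axis=1, keepdims=True)
    tau = r.uniform(-0.8, 0.8, (I, J - 1))
    tau -= tau.mean(axis=1, keepdims=True)
    sub = np.arange(I) % subscales if subscales > 1 else None
    alpha2 = alpha2_from_mdp(mdp, alpha1) if mdp else None
    m = np.full(subscales, mdp) if mdp else None
    return ItemParameters(alpha1=alpha1, beta=beta, tau=tau, alpha2=alpha2, mdp=m,
                          subscale_of_item=sub)


class TestGpcm:
    def test_flat_case_is_uniform(self):
        p = gpcm_category_probs(0.0, 1.0, 0.0, np.zeros(3))
        assert np.allclose(p, 0.25, atol=1e-15)

    def test_low_trait_limit_concentrates_on_first_category(self):
        p = gpcm_category_probs(-40.0, 1.0, 0.0, np.zeros(3))
        assert p[0] > 1 - 1e-10 and np.isfinite(p).all()

    def test_derived_example(self):
        p = gpcm_category_probs(1.0, 1.0, 0.0, np.array([-0.6, 0.0, 0.6]))
        expected = oracle_category_probs(1.0, 1.0, 0.0, [-0.6, 0.0, 0.6])
        assert np.allclose(p, expected, atol=1e-15)
        assert np.allclose(p, [0.0253, 0.1254, 0.3408, 0.5085], atol=5e-4)

    def test_adjacent_log_odds_identity(self):
        tau = np.array([-0.4, 0.1, 0.5])
        p = gpcm_category_probs(0.7, 1.3, -0.2, tau)
        logodds = np.log(p[1:] / p[:-1])
        assert np.allclose(logodds, 1.3 * 0.7 - (-0.2 + tau), atol=1e-9)

    @pytest.mark.parametrize("bad", [dict(alpha=0.0), dict(alpha=-1.0), dict(tau=[])])
    def test_invalid_inputs_rejected(self, bad):
        kw = dict(theta=0.0, alpha=1.0, beta=0.0, tau=[-0.5, 0.5])
        kw.update(bad)
        with pytest.raises(ValueError):
            gpcm_category_probs(kw["theta"], kw["alpha"], kw["beta"], kw["tau"])

    @given(
        theta=st.floats(-3, 3),
        alpha=st.floats(0.2, 2.5),
        beta=st.floats(-2, 2),
        j=st.integers(2, 7),
        seed=st.integers(0, 10**6),
    )
    def test_oracle_equivalence_randomized(self, theta, alpha, beta, j, seed):
        tau = np.random.default_rng(seed).uniform(-1.5, 1.5, j - 1)
        p = gpcm_category_probs(theta, alpha, beta, tau)
        assert abs(p.sum() - 1.0) < 1e-12 and (p >= 0).all()
        assert np.abs(p - oracle_category_probs(theta, alpha, beta, tau)).max() < 1e-12


class TestErsGpcm:
    def test_unit_omega_reduces_to_gpcm_bitwise(self):
        tau = np.array([-0.6, 0.0, 0.6])
        a = ers_gpcm_probs(0.4, 1.1, 0.3, tau, omega=1.0)
        b = gpcm_category_probs(0.4, 1.1, 0.3, tau)
        assert (a == b).all()

    def test_omega_scales_thresholds(self):
        tau = np.array([-0.6, 0.0, 0.6])
        a = ers_gpcm_probs(0.2, 1.0, 0.0, tau, omega=0.5)
        b = gpcm_category_probs(0.2, 1.0, 0.0, 0.5 * tau)
        assert np.allclose(a, b, atol=1e-15)

    def test_large_omega_suppresses_extremes(self):
        tau = np.array([-0.6, 0.0, 0.6])
        p1 = ers_gpcm_probs(0.0, 1.0, 0.0, tau, omega=1.0)
        p2 = ers_gpcm_probs(0.0, 1.0, 0.0, tau, omega=2.0)
        assert p2[0] + p2[-1] < p1[0] + p1[-1]

    def test_extreme_mass_strictly_decreasing_in_omega(self):
        tau = np.array([-0.8, -0.3, 0.3, 0.8])
        masses = [
            ers_gpcm_probs(0.0, 1.0, 0.0, tau, omega=w)[[0, -1]].sum()
            for w in (0.25, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(masses, masses[1:]))

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ValueError):
            ers_gpcm_probs(0.0, 1.0, 0.0, [-0.5, 0.5], omega=0.0)


class TestMixtureAndCd:
    def test_normal_class_matches_unit_omega_ers(self):
        items = make_items()
        person = PersonState(theta=0.6, omega=0.4, class_label=0)
        probs = mixture_ers_gpcm_probs(person, items, 0)
        for i in range(items.n_items):
            ref = ers_gpcm_probs(0.6, items.alpha1[i], items.beta[0, i], items.tau[i], 1.0)
            assert (probs[i] == ref).all()

    def test_beta_shift_moves_log_odds_additively(self):
        items = make_items(G=2)
        items.beta[1] = items.beta[0] + 0.5
        person = PersonState(theta=0.1, omega=0.7, class_label=1)
        p0 = mixture_ers_gpcm_probs(person, items, 0)
        # same omega in both evaluations: compare against class 0 with forced omega
        ref = np.stack([
            ers_gpcm_probs(0.1, items.alpha1[i], items.beta[0, i] + 0.5, items.tau[i], 0.7)
            for i in range(items.n_items)
        ])
        p1 = mixture_ers_gpcm_probs(person, items, 1)
        assert np.allclose(p1, ref, atol=1e-15)
        lo0 = np.log(ref[:, 1:] / ref[:, :-1])
        lo_plain = np.stack([
            np.log(np.asarray(ers_gpcm_probs(0.1, items.alpha1[i], items.beta[0, i], items.tau[i], 0.7))[1:]
                   / np.asarray(ers_gpcm_probs(0.1, items.alpha1[i], items.beta[0, i], items.tau[i], 0.7))[:-1])
            for i in range(items.n_items)
        ])
        assert np.allclose(lo0 - lo_plain, -0.5, atol=1e-9)

    def test_single_class_keeps_person_omega(self):
        items = make_items(G=1)
        person = PersonState(theta=-0.3, omega=0.5, class_label=0)
        probs = mixture_ers_gpcm_probs(person, items, 0)
        for i in range(items.n_items):
            ref = ers_gpcm_probs(-0.3, items.alpha1[i], items.beta[0, i], items.tau[i], 0.5)
            assert (probs[i] == ref).all()

    def test_missing_class_difficulties_rejected(self):
        items = make_items(G=2)
        person = PersonState(theta=0.0, omega=1.0, class_label=0)
        with pytest.raises(ValueError):
            mixture_ers_gpcm_probs(person, items, 2)

    def test_cd_with_unit_alpha2_equals_mixture(self):
        items = make_items(G=2)
        items.alpha2 = np.ones(items.n_items)
        person = PersonState(theta=0.8, omega=0.6, class_label=1)
        a = cd_model_probs(person, items, 1)
        b = mixture_ers_gpcm_probs(person, items, 1)
        assert (a == b).all()

    def test_cd_with_zero_alpha2_ignores_style(self):
        items = make_items(G=2)
        items.alpha2 = np.zeros(items.n_items)
        person = PersonState(theta=0.8, omega=0.2, class_label=1)
        a = cd_model_probs(person, items, 1)
        for i in range(items.n_items):
            ref = gpcm_category_probs(0.8, items.alpha1[i], items.beta[1, i], items.tau[i])
            assert np.allclose(a[i], ref, atol=1e-15)

    def test_cd_worked_threshold_scaling(self):
        items = make_items(G=2)
        items.alpha2 = np.full(items.n_items, 0.2)
        person = PersonState(theta=0.0, omega=0.5, class_label=1)
        a = cd_model_probs(person, items, 1)
        eta = 0.5**0.2
        for i in range(items.n_items):
            ref = ers_gpcm_probs(0.0, items.alpha1[i], items.beta[1, i], items.tau[i], eta)
            assert np.allclose(a[i], ref, atol=1e-12)

    def test_multidim_single_subscale_is_cd_model(self):
        items = make_items(G=2, mdp=1.6)
        person = PersonState(theta=[0.5], omega=0.7, class_label=1)
        a = multidim_cd_probs(person, items, 1)
        b = cd_model_probs(person, items, 1)
        assert (a == b).all()

    def test_multidim_items_depend_only_on_their_subscale(self):
        items = make_items(I=6, G=2, mdp=1.6, subscales=2)
        p1 = PersonState(theta=[0.5, -1.0], omega=0.7, class_label=1)
        p2 = PersonState(theta=[0.5, 2.0], omega=0.7, class_label=1)
        a = multidim_cd_probs(p1, items, 1, subscale=0)
        b = multidim_cd_probs(p2, items, 1, subscale=0)
        assert (a == b).all()
        c = multidim_cd_probs(p1, items, 1, subscale=1)
        d = multidim_cd_probs(p2, items, 1, subscale=1)
        assert not np.allclose(c, d)

    def test_common_omega_gives_subscale_invariant_eta(self):
        items = make_items(I=6, G=2, subscales=2)
        items.alpha2 = np.full(6, 0.3)
        person = PersonState(theta=[0.0, 0.0], omega=0.5, class_label=1)
        assert np.allclose(person.eta(items.alpha2), 0.5**0.3)


class TestEtaAndMdp:
    def test_worked_example_two_decimals(self):
        assert round(eta_weight(0.5, 0.2), 2) == 0.87
        assert round(eta_weight(1.0, 0.2), 2) == 1.00
        assert round(eta_weight(1.5, 0.2), 2) == 1.08

    def test_identity_cases_exact(self):
        assert eta_weight(1.0, 0.73) == 1.0
        assert eta_weight(2.7, 0.0) == 1.0
        assert eta_weight(0.4, 1.0) == 0.4

    def test_invalid_omega(self):
        with pytest.raises(ValueError):
            eta_weight(0.0, 0.2)

    def test_alpha2_from_mdp_examples(self):
        assert alpha2_from_mdp(1.5, 1.5) == 0.0
        assert np.isclose(alpha2_from_mdp(1.5, 0.9), 1.2)
        assert np.isclose(alpha2_from_mdp(1.5, 1.452), np.sqrt(2.25 - 1.452**2))

    def test_alpha1_exceeding_mdp_rejected(self):
        with pytest.raises(ValueError):
            alpha2_from_mdp(1.5, 1.6)

    @given(mdp=st.floats(0.5, 3.0), frac=st.floats(0.0, 1.0))
    def test_conservation_round_trip(self, mdp, frac):
        alpha1 = frac * mdp
        if alpha1 <= 0:
            return
        alpha2 = alpha2_from_mdp(mdp, alpha1)
        assert abs(alpha1**2 + alpha2**2 - mdp**2) < 1e-12


class TestRestrictions:
    def test_pcm_fixes_unit_discrimination(self):
        items = make_items()
        out = restrict_model(items, "PCM")
        assert (out.alpha1 == 1.0).all()
        assert (out.tau == items.tau).all()

    def test_grsm_ties_thresholds_but_keeps_beta(self):
        items = make_items()
        out = restrict_model(items, "GRSM")
        assert (out.tau == out.tau[0]).all()
        assert (out.beta == items.beta).all()
        p0 = gpcm_category_probs(0.0, 1.0, out.beta[0, 0], out.tau[0])
        p1 = gpcm_category_probs(0.0, 1.0, out.beta[0, 1], out.tau[1])
        if not np.isclose(out.beta[0, 0], out.beta[0, 1]):
            assert not np.allclose(p0, p1)

    def test_rsm_is_order_independent_composition(self):
        items = make_items()
        a = restrict_model(items, "RSM")
        b = restrict_model(restrict_model(items, "PCM"), "GRSM")
        c = restrict_model(restrict_model(items, "GRSM"), "PCM")
        assert (a.alpha1 == b.alpha1).all() and (a.tau == b.tau).all()
        assert (b.alpha1 == c.alpha1).all() and (b.tau == c.tau).all()

    def test_unknown_restriction_rejected(self):
        with pytest.raises(ValueError):
            restrict_model(make_items(), "NOMINAL")
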