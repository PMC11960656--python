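"""Survival-cure likelihood, OU kernel and joint density against oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from phylocure.data import ChannelObservation, Dataset, SpeciesRecord, compute_eq
from phylocure.model import (
    ModelData,
    ModelParameters,
    channel_loglik,
    cure_logit,
    joint_logdensity,
    phylo_kernel,
    rate_from_gamma,
)
from phylocure.phylo import DistanceMatrix, patristic_distances, simulate_yule_tree


class TestChannelLoglik:
    def test_cured_never_detected_contributes_zero(self):
        assert channel_loglik(False, 123.0, 1.0, 0.5) == pytest.approx(0.0)

    def test_zero_effort_ccdf_is_one(self):
        assert channel_loglik(False, 0.0, 0.0, 1.0) == pytest.approx(0.0)

    def test_censored_closed_form(self):
        got = channel_loglik(False, 50.0, 0.3, 0.01)
        assert got == pytest.approx(
            math.log(0.3 + 0.7 * math.exp(-0.5)), abs=1e-9
        )
        assert got == pytest.approx(-0.3221749, abs=1e-6)

    def test_detected_closed_form(self):
        got = channel_loglik(True, 50.0, 0.3, 0.01)
        assert got == pytest.approx(
            math.log(0.7) + math.log(0.01) - 0.5, abs=1e-9
        )
        assert got == pytest.approx(-5.4618451, abs=1e-6)

    def test_detected_with_certain_cure_is_minus_inf(self):
        assert channel_loglik(True, 1.0, 1.0, 0.5) == -np.inf

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            channel_loglik(True, 1.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            channel_loglik(True, 1.0, np.nan, 1.0)
        with pytest.raises(ValueError):
            channel_loglik(False, -1.0, 0.5, 1.0)

    def test_underflow_safe_for_huge_effort(self):
        # p + (1-p) e^{-lam N} -> log p without under/overflow
        got = channel_loglik(False, 1e6, 0.25, 1.0)
        assert got == pytest.approx(math.log(0.25), abs=1e-12)

    def test_censored_monotone_in_p_and_effort(self):
        ps = np.linspace(0.01, 0.99, 25)
        lls = channel_loglik(False, 30.0, ps, 0.05)
        assert np.all(np.diff(lls) >= 0)
        efforts = np.linspace(0.0, 200.0, 25)
        lls = channel_loglik(False, efforts, 0.4 * np.ones(25), 0.05)
        assert np.all(np.diff(lls) <= 0)

    @pytest.mark.parametrize("p,lam", [(0.0, 1.0), (0.3, 0.01), (0.9, 2.0)])
    def test_total_probability_by_quadrature(self, p, lam):
        # integral of the detection density over effort, plus the limiting
        # censored mass at infinite effort, must be 1
        dens = lambda e: math.exp(channel_loglik(True, e, p, lam))
        integral, _ = integrate.quad(dens, 0.0, np.inf)
        limit_mass = math.exp(channel_loglik(False, 1e9 / lam, p, lam))
        assert integral + limit_mass == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_detection_probability(self):
        # P(detected and effort <= C) = (1-p)(1 - e^{-lam C})
        rng = np.random.default_rng(1234)
        p, lam, C, n = 0.35, 0.02, 60.0, 10**6
        cured = rng.uniform(size=n) < p
        E = rng.exponential(1.0 / lam, size=n)
        frac = float(np.mean(~cured & (E <= C)))
        expected = (1 - p) * (1 - math.exp(-lam * C))
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) <= 3 * se


class TestRateFromGamma:
    def test_values(self):
        assert rate_from_gamma(0.0) == pytest.approx(1.0)
        assert rate_from_gamma(math.log(100.0)) == pytest.approx(0.01)
        assert rate_from_gamma(5.0) == pytest.approx(0.0067379, abs=1e-7)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rate_from_gamma(np.inf)


class TestCureLogit:
    def params(self, alpha=(0.0, 0.0), beta=0.0, n=1):
        return ModelParameters(
            gamma_lit=0.0,
            gamma_vid=0.0,
            alpha=np.array(alpha),
            beta=beta,
            k=np.zeros(n),
            eta_sq=1.0,
            rho_sq=1.0,
        )

    def test_zero_predictor_gives_half(self):
        assert cure_logit(0, 0.0, 0.0, self.params()) == pytest.approx(0.5)

    def test_unit_predictor(self):
        got = cure_logit(0, 1.0, 0.0, self.params(beta=1.0))
        assert got == pytest.approx(0.731059, abs=1e-6)

    def test_saturation(self):
        assert cure_logit(0, 0.0, 40.0, self.params()) == pytest.approx(1.0)
        assert 0.0 < cure_logit(0, 0.0, -40.0, self.params()) < 1e-15


class TestPhyloKernel:
    def test_diagonal_and_closed_form(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        km = phylo_kernel(D, 1.0, 0.5)
        assert km.K[0, 0] == pytest.approx(1.0)
        assert km.K[0, 1] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_large_decay_approaches_identity(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        km = phylo_kernel(D, 2.5, 1e4)
        np.testing.assert_allclose(km.K, 2.5 * np.eye(2), atol=1e-12)

    def test_invalid_parameters(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError):
            phylo_kernel(D, -1.0, 1.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_positive_definite_on_random_trees(self, seed):
        # OU kernels on tree metrics are PD: smallest eigenvalue above
        # -10 * eps * eta_sq before jitter
        tree = simulate_yule_tree(12, seed)
        D = patristic_distances(tree).D
        eta_sq = 1.7
        K = eta_sq * np.exp(-0.8 * D)
        min_eig = float(np.linalg.eigvalsh(K).min())
        assert min_eig > -10 * np.finfo(float).eps * eta_sq

    def test_cholesky_factor_reconstructs_kernel(self):
        tree = simulate_yule_tree(8, 5)
        km = phylo_kernel(patristic_distances(tree), 1.2, 2.0)
        np.testing.assert_allclose(
            km.L @ km.L.T, km.K + km.jitter * np.eye(8), atol=1e-10
        )


def _toy_dataset(n=3, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        brain = float(rng.uniform(5, 25))
        body = float(rng.uniform(200, 900))
        records.append(
            SpeciesRecord(
                species_id=f"Genus sp{i}",
                feeding="generalist" if i % 2 == 0 else "specialist",
                brain_mass=brain,
                body_mass=body,
                eq=compute_eq(brain, body),
                literature=ChannelObservation(i == 0, float(rng.uniform(1, 30))),
                video=ChannelObservation(False, float(rng.uniform(5, 500))),
            )
        )
    return Dataset(records)


def _toy_distance(n=3):
    D = np.array(
        [[0.0, 0.5, 1.4], [0.5, 0.0, 1.4], [1.4, 1.4, 0.0]]
    )[:n, :n]
    return D


class TestJointLogdensity:
    def _setup(self):
        dataset = _toy_dataset()
        data = ModelData.from_dataset(dataset)
        D = DistanceMatrix(tuple(data.species_ids), _toy_distance())
        params = ModelParameters(
            gamma_lit=0.7,
            gamma_vid=2.1,
            alpha=np.array([0.3, -0.4]),
            beta=0.8,
            k=np.array([0.2, -0.1, 0.5]),
            eta_sq=1.3,
            rho_sq=0.9,
        )
        return params, data, D

    def test_matches_independent_term_by_term_oracle(self):
        params, data, D = self._setup()
        got = joint_logdensity(params, data, D, jitter_frac=0.0)

        # fully independent reconstruction with scipy distributions
        expected = 0.0
        for i in range(3):
            lin = (
                params.alpha[data.feeding_index[i]]
                + params.beta * data.eq[i]
                + params.k[i]
            )
            p = 1.0 / (1.0 + math.exp(-lin))
            for det, eff, gamma in (
                (data.lit_detected[i], data.lit_effort[i], params.gamma_lit),
                (data.vid_detected[i], data.vid_effort[i], params.gamma_vid),
            ):
                lam = 1.0 / math.exp(gamma)
                if det:
                    expected += math.log((1 - p) * lam * math.exp(-lam * eff))
                else:
                    expected += math.log(p + (1 - p) * math.exp(-lam * eff))
        K = params.eta_sq * np.exp(-params.rho_sq * D.D)
        expected += stats.multivariate_normal(np.zeros(3), K).logpdf(params.k)
        for x in (
            params.gamma_lit,
            params.gamma_vid,
            params.alpha[0],
            params.alpha[1],
            params.beta,
        ):
            expected += stats.norm.logpdf(x)
        expected += stats.expon(scale=2.0).logpdf(params.eta_sq)
        expected += stats.expon(scale=2.0).logpdf(params.rho_sq)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_prior_terms_closed_form_at_zero(self):
        # all Gaussians at 0, k = 0: the density is exactly the sum of the
        # standard-normal and Exponential(0.5) log-pdfs plus the MVN normal
        # constant, since every likelihood factor is evaluated at p = 1/2
        params, data, D = self._setup()
        params.alpha = np.zeros(2)
        params.beta = 0.0
        params.gamma_lit = params.gamma_vid = 0.0
        params.k = np.zeros(3)
        got = joint_logdensity(params, data, D, jitter_frac=0.0)
        K = params.eta_sq * np.exp(-params.rho_sq * D.D)
        expected = (
            5 * stats.norm.logpdf(0.0)
            + stats.expon(scale=2.0).logpdf(params.eta_sq)
            + stats.expon(scale=2.0).logpdf(params.rho_sq)
            + stats.multivariate_normal(np.zeros(3), K).logpdf(np.zeros(3))
        )
        for i in range(3):
            for det, eff in (
                (data.lit_detected[i], data.lit_effort[i]),
                (data.vid_detected[i], data.vid_effort[i]),
            ):
                expected += channel_loglik(bool(det), float(eff), 0.5, 1.0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_permutation_invariance(self):
        params, data, D = self._setup()
        base = joint_logdensity(params, data, D, jitter_frac=0.0)
        perm = [2, 0, 1]
        data_p = ModelData(
            species_ids=[data.species_ids[i] for i in perm],
            feeding_index=data.feeding_index[perm],
            eq=data.eq[perm],
            lit_detected=data.lit_detected[perm],
            lit_effort=data.lit_effort[perm],
            vid_detected=data.vid_detected[perm],
            vid_effort=data.vid_effort[perm],
        )
        D_p = D.reorder(data_p.species_ids)
        params_p = ModelParameters(
            gamma_lit=params.gamma_lit,
            gamma_vid=params.gamma_vid,
            alpha=params.alpha,
            beta=params.beta,
            k=params.k[perm],
            eta_sq=params.eta_sq,
            rho_sq=params.rho_sq,
        )
        assert joint_logdensity(
            params_p, data_p, D_p, jitter_frac=0.0
        ) == pytest.approx(base, abs=1e-9)

    def test_misalignment_rejected(self):
        params, data, D = self._setup()
        bad = DistanceMatrix(tuple(reversed(D.labels)), D.D)
        with pytest.raises(ValueError):
            joint_logdensity(params, data, bad)
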