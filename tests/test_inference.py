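"""Posterior sampling, summaries and the sampler's internal fast paths."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from phylocure.inference import (
    FitConfig,
    PosteriorDraws,
    _TreeSampler,
    expected_discovery_effort,
    rank_species,
    sample_posterior,
    sum_undetected,
)
from phylocure.model import ModelData, channel_loglik
from phylocure.phylo import patristic_distances
from phylocure.simulate import SimConfig, generate_dataset


def _draws_from_p(p_by_species: dict[str, np.ndarray], extras=None) -> PosteriorDraws:
    """Hand-built PosteriorDraws for summary-operation tests."""
    cols = {f"p[{s}]": np.asarray(v, float) for s, v in p_by_species.items()}
    n = len(next(iter(cols.values())))
    df = pd.DataFrame(cols)
    for name in (
        "gamma_lit",
        "gamma_vid",
        "alpha_generalist",
        "alpha_specialist",
        "beta",
        "eta_sq",
        "rho_sq",
    ):
        df[name] = (extras or {}).get(name, np.zeros(n))
    return PosteriorDraws(
        df=df,
        species_ids=list(p_by_species),
        evidence={s: False for s in p_by_species},
        diagnostics=pd.DataFrame(),
        seed=0,
        config_echo={},
    )


class TestRankSpecies:
    def test_constant_draws(self):
        draws = _draws_from_p({"Ara macao": np.full(10, 0.2)})
        r = rank_species(draws)
        assert r.loc[0, "median"] == pytest.approx(0.8)
        assert r.loc[0, "q025"] == pytest.approx(0.8)
        assert r.loc[0, "q975"] == pytest.approx(0.8)

    def test_quantiles_match_sort_oracle(self):
        p = np.array([0.9, 0.1, 0.4, 0.7, 0.2])
        draws = _draws_from_p({"Ara macao": p})
        r = rank_species(draws).iloc[0]
        tu = np.sort(1 - p)
        for col, q in (("q025", 0.025), ("q25", 0.25), ("q75", 0.75),
                       ("q975", 0.975)):
            assert r[col] == pytest.approx(np.quantile(tu, q))
        assert r["median"] == pytest.approx(np.median(1 - p))

    def test_invariant_to_draw_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        a = rank_species(_draws_from_p({"Ara macao": p}))
        b = rank_species(_draws_from_p({"Ara macao": rng.permutation(p)}))
        pd.testing.assert_frame_equal(a, b)

    def test_sorted_descending_and_medians_inside_intervals(self):
        rng = np.random.default_rng(1)
        draws = _draws_from_p(
            {f"Genus sp{i}": rng.uniform(size=40) for i in range(6)}
        )
        r = rank_species(draws)
        assert (r["median"].diff().dropna() <= 1e-12).all()
        assert ((r["q025"] <= r["median"]) & (r["median"] <= r["q975"])).all()


class TestSumUndetected:
    def test_certain_cure_sums_to_zero(self):
        draws = _draws_from_p(
            {f"Genus sp{i}": np.ones(8) - 1e-15 for i in range(4)}
        )
        assert sum_undetected(draws)["median"] == pytest.approx(0.0, abs=1e-9)

    def test_half_probabilities(self):
        draws = _draws_from_p(
            {f"Genus sp{i}": np.full(5, 0.5) for i in range(10)}
        )
        out = sum_undetected(draws)
        assert out["median"] == pytest.approx(5.0)
        assert out["ci95_low"] == pytest.approx(5.0)

    def test_matches_per_draw_enumeration(self):
        rng = np.random.default_rng(2)
        ps = {f"Genus sp{i}": rng.uniform(size=7) for i in range(3)}
        out = sum_undetected(_draws_from_p(ps))
        manual = sum(1 - v for v in ps.values())
        assert out["median"] == pytest.approx(np.median(manual))
        np.testing.assert_allclose(np.sort(out["draws"]), np.sort(manual))

    def test_detected_species_rejected(self):
        draws = _draws_from_p({"Ara macao": np.full(5, 0.5)})
        draws.evidence["Ara macao"] = True
        with pytest.raises(ValueError):
            sum_undetected(draws, {"Ara macao"})


class TestDiscoveryEffort:
    def test_fixed_gamma(self):
        draws = _draws_from_p(
            {"Ara macao": np.full(6, 0.5)},
            extras={"gamma_lit": np.zeros(6),
                    "gamma_vid": np.full(6, np.log(100.0))},
        )
        out = expected_discovery_effort(draws)
        assert out["literature"]["median"] == pytest.approx(1.0)
        assert out["video"]["median"] == pytest.approx(100.0)

    def test_median_equivariant_under_exp(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=101)
        draws = _draws_from_p(
            {"Ara macao": np.full(101, 0.5)}, extras={"gamma_lit": g}
        )
        out = expected_discovery_effort(draws)
        assert out["literature"]["median"] == pytest.approx(
            np.exp(np.median(g))
        )


class TestFastLikelihoodPath:
    def test_matches_public_channel_loglik(self, small_synth):
        dataset, ensemble, _ = small_synth
        data = ModelData.from_dataset(dataset)
        D = patristic_distances(ensemble.trees[0]).reorder(data.species_ids)
        sampler = _TreeSampler(data, D, FitConfig())
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.uniform(0.01, 0.99, size=data.n_species)
            gamma = rng.normal()
            slow = float(
                np.sum(
                    channel_loglik(
                        data.lit_detected, data.lit_effort, p, np.exp(-gamma)
                    )
                )
            )
            assert sampler._ll_fast("lit", p, gamma) == pytest.approx(
                slow, abs=1e-9
            )


class TestSamplePosterior:
    def test_reproducible_from_seed(self, small_synth):
        dataset, ensemble, _ = small_synth
        cfg = FitConfig(n_warmup=30, n_samples=30, n_chains=1)
        a = sample_posterior(dataset, ensemble, cfg, seed=5)
        b = sample_posterior(dataset, ensemble, cfg, seed=5)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_p_draws_in_unit_interval(self, small_synth):
        dataset, ensemble, _ = small_synth
        cfg = FitConfig(n_warmup=50, n_samples=50, n_chains=1)
        draws = sample_posterior(dataset, ensemble, cfg, seed=6)
        p = draws.p_matrix()
        assert np.all(p > 0) and np.all(p < 1)
        assert len(draws.df) == 50

    def test_all_detected_at_tiny_effort_pushes_tool_use_up(self):
        # every species detected in both channels almost immediately:
        # no censoring mass, tool-use probabilities near 1
        from phylocure.data import ChannelObservation
        from dataclasses import replace

        dataset, ensemble, _ = generate_dataset(
            SimConfig(n_species=20), seed=7
        )
        recs = [
            replace(
                r,
                literature=ChannelObservation(True, 0.5),
                video=ChannelObservation(True, 0.5),
            )
            for r in dataset.records
        ]
        from phylocure.data import Dataset

        forced = Dataset(recs)
        draws = sample_posterior(
            forced, ensemble, FitConfig(n_warmup=150, n_samples=150,
                                        n_chains=1), seed=8
        )
        medians = rank_species(draws)["median"]
        assert (medians > 0.8).all()

    def test_rhat_warning_fields_present(self, small_synth):
        dataset, ensemble, _ = small_synth
        cfg = FitConfig(n_warmup=40, n_samples=40, n_chains=2)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = sample_posterior(dataset, ensemble, cfg, seed=9)
        assert set(draws.diagnostics.columns) >= {
            "parameter",
            "rhat",
            "ess_bulk",
        }
        assert draws.diagnostics["rhat"].notna().all()

    def test_roundtrip_persistence(self, small_synth, tmp_path):
        dataset, ensemble, _ = small_synth
        cfg = FitConfig(n_warmup=20, n_samples=20, n_chains=1)
        draws = sample_posterior(dataset, ensemble, cfg, seed=10)
        draws.save(tmp_path / "draws.csv", tmp_path / "meta.json")
        back = PosteriorDraws.load(tmp_path / "draws.csv", tmp_path / "meta.json")
        assert back.species_ids == draws.species_ids
        np.testing.assert_allclose(
            back.p_matrix(), draws.p_matrix(), rtol=1e-12
        )


class TestPriorPredictive:
    def test_prior_only_p_quantiles_match_direct_simulation(self, small_synth):
        # with the likelihood disabled the sampler must reproduce the
        # prior-predictive distribution of p_i, which we can also simulate
        # directly from the priors
        dataset, ensemble, _ = small_synth
        cfg = FitConfig(
            n_warmup=200, n_samples=800, n_chains=1, prior_only=True
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = sample_posterior(dataset, ensemble, cfg, seed=11)
        p_mcmc = draws.p_matrix().ravel()

        data = ModelData.from_dataset(dataset)
        D = patristic_distances(ensemble.trees[0]).reorder(data.species_ids)
        rng = np.random.default_rng(12)
        n_rep = 800
        p_direct = np.empty((n_rep, data.n_species))
        from phylocure.simulate import simulate_species_effects

        for r in range(n_rep):
            alpha = rng.normal(size=2)
            beta = rng.normal()
            eta_sq = rng.exponential(2.0)
            rho_sq = rng.exponential(2.0)
            k = simulate_species_effects(D, eta_sq, rho_sq, rng)
            lin = alpha[data.feeding_index] + beta * data.eq + k
            p_direct[r] = expit(lin)
        # the prior on p is symmetric about 1/2 (all location parameters
        # are symmetric about 0), so the medians have an exact oracle
        assert abs(np.median(p_mcmc) - 0.5) < 0.06
        assert abs(np.median(p_direct) - 0.5) < 0.06
        for q in (0.25, 0.75):
            assert abs(
                np.quantile(p_mcmc, q) - np.quantile(p_direct, q)
            ) < 0.08

        # scalar priors: autocorrelation-adjusted mean checks via ESS
        import arviz as az

        for name, mean, sd in (
            ("beta", 0.0, 1.0),
            ("alpha_generalist", 0.0, 1.0),
            ("gamma_lit", 0.0, 1.0),
            ("eta_sq", 2.0, 2.0),
            ("rho_sq", 2.0, 2.0),
        ):
            x = draws.df[name].to_numpy()
            ess = max(float(az.ess(x)), 10.0)
            assert abs(x.mean() - mean) < 4 * sd / np.sqrt(ess), name


def test_censoring_is_informative_on_separated_synthetic_data():
    # species simulated as tool users but never detected despite huge
    # effort should score below actually detected species
    cfg = SimConfig(n_species=40, budget_lit_sigma=2.0, budget_vid_sigma=2.0)
    dataset, ensemble, truth = generate_dataset(cfg, seed=13)
    draws = sample_posterior(
        dataset, ensemble, FitConfig(n_warmup=250, n_samples=250, n_chains=1),
        seed=14,
    )
    r = rank_species(draws).set_index("species")
    det = r[r["evidence"]]["median"]
    undet = r[~r["evidence"]]["median"]
    if len(det) and len(undet):
        assert det.mean() > undet.mean()
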