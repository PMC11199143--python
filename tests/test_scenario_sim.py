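import math

import numpy as np
import pytest

from traitdrift import (
    DemographyConfig,
    EmptyTraitError,
    allele_frequencies,
    build_demography,
    growth_factor,
    simulate_genotypes,
)
from traitdrift.scenario_sim import write_vcf


class TestGrowthFactor:
    def test_paper_growth_factor(self):
        # g=0.015 over 200 generations: a factor of "nearly 20"
        assert growth_factor(0.015, 200) == pytest.approx(math.exp(3))
        assert 19 < growth_factor(0.015, 200) < 21

    def test_zero_growth(self):
        assert growth_factor(0.0, 200) == 1.0

    def test_closed_form(self):
        assert growth_factor(0.01, 100) == pytest.approx(math.e)

    @pytest.mark.parametrize("g,T", [(-0.1, 10), (0.1, -10)])
    def test_negative_rejected(self, g, T):
        with pytest.raises(ValueError):
            growth_factor(g, T)


class TestDemographyConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("N0", 0),
            ("N", 0),
            ("T", -1),
            ("m", 1.5),
            ("m", -0.1),
            ("g", -0.01),
            ("genome_length_morgans", 0),
            ("genome_length_bp", 0),
            ("n_sample_ref", 0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field):
            DemographyConfig(**{field: value})

    def test_sample_size_caps(self):
        with pytest.raises(ValueError, match="n_sample_ref"):
            DemographyConfig(N0=100, n_sample_ref=101, n_sample_bot=10)
        with pytest.raises(ValueError, match="n_sample_bot"):
            DemographyConfig(N=100, n_sample_bot=101, n_sample_ref=10)
        # growth raises the present-day cap
        DemographyConfig(N=100, g=0.015, T=200, n_sample_bot=500, n_sample_ref=10)

    def test_roundtrip_dict(self):
        cfg = DemographyConfig(N=1234, m=0.01)
        assert DemographyConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="bogus"):
            DemographyConfig.from_dict({"bogus": 1})


class TestBuildDemography:
    def test_present_day_bottleneck_size_with_growth(self):
        cfg = DemographyConfig(g=0.015, T=200, N=1000, n_sample_bot=500)
        dem = build_demography(cfg)
        bot = {p.name: p for p in dem.populations}["bot"]
        assert bot.initial_size == pytest.approx(1000 * math.exp(3))
        assert bot.initial_size == pytest.approx(20_000, rel=0.01)

    def test_no_growth_size(self):
        dem = build_demography(DemographyConfig(g=0, T=200, N=1000))
        bot = {p.name: p for p in dem.populations}["bot"]
        assert bot.initial_size == 1000

    def test_no_migration_matrix_zero(self):
        dem = build_demography(DemographyConfig(m=0))
        assert np.all(np.asarray(dem.migration_matrix) == 0)

    def test_migration_backward_direction(self):
        # forward-time ref -> bot equals backward-time lineage flow bot -> ref
        dem = build_demography(DemographyConfig(m=0.05))
        names = [p.name for p in dem.populations]
        M = np.asarray(dem.migration_matrix)
        assert M[names.index("bot"), names.index("ref")] == 0.05
        assert M.sum() == 0.05

    def test_reference_sampled_at_present(self):
        # both contemporary populations must default to sampling at time 0
        dem = build_demography(DemographyConfig())
        times = {p.name: p.default_sampling_time for p in dem.populations}
        assert not times["ref"] and not times["bot"]


class TestSimulateGenotypes:
    def test_entries_and_frequencies(self, tiny_dataset):
        for X in (tiny_dataset.X_ref, tiny_dataset.X_bot):
            assert np.isin(X, (0, 1, 2)).all()
        np.testing.assert_array_equal(
            tiny_dataset.f_ref, tiny_dataset.X_ref.sum(axis=0) / (2 * tiny_dataset.n_ref)
        )
        np.testing.assert_array_equal(
            tiny_dataset.f_bot, tiny_dataset.X_bot.sum(axis=0) / (2 * tiny_dataset.n_bot)
        )
        assert np.all(tiny_dataset.f_ref > 0) and np.all(tiny_dataset.f_ref < 1)
        assert np.all(tiny_dataset.f_bot >= 0) and np.all(tiny_dataset.f_bot <= 1)

    def test_positions_strictly_increasing(self, tiny_dataset):
        assert np.all(np.diff(tiny_dataset.positions) > 0)

    def test_determinism(self, tiny_config, tiny_dataset):
        again = simulate_genotypes(tiny_config)
        np.testing.assert_array_equal(again.X_ref, tiny_dataset.X_ref)
        np.testing.assert_array_equal(again.X_bot, tiny_dataset.X_bot)
        np.testing.assert_array_equal(again.positions, tiny_dataset.positions)

    def test_empty_trait_signalled(self, tiny_config):
        with pytest.raises(EmptyTraitError):
            simulate_genotypes(tiny_config.replace(causal_mutation_rate=0.0))

    def test_panmictic_split_matches_binomial_sampling_noise(self, tiny_config):
        # T=0: both samples come from one population, so the mean squared
        # frequency difference must match f(1-f) * (1/2n_ref + 1/2n_bot)
        cfg = tiny_config.replace(T=0, n_sample_ref=50, n_sample_bot=50)
        expected_factor = 1 / 100 + 1 / 100
        ratios = []
        for seed in range(1, 201):
            ds = simulate_genotypes(cfg.replace(seed=seed))
            f = (ds.f_ref + ds.f_bot) / 2
            ok = (f > 0) & (f < 1)
            observed = np.mean((ds.f_ref[ok] - ds.f_bot[ok]) ** 2)
            analytic = np.mean(f[ok] * (1 - f[ok])) * expected_factor
            ratios.append(observed / analytic)
        assert 0.9 < np.mean(ratios) < 1.1

    def test_smaller_bottleneck_loses_more_snps(self, tiny_config):
        # drift is stronger in smaller populations
        def mean_lost(N, reps=100):
            fracs = []
            for seed in range(1, reps + 1):
                ds = simulate_genotypes(tiny_config.replace(N=N, seed=seed))
                fracs.append(np.mean((ds.f_bot == 0) | (ds.f_bot == 1)))
            return np.mean(fracs)

        assert mean_lost(200) > mean_lost(400)

    def test_loss_non_decreasing_in_split_time(self, tiny_config):
        def mean_lost(T, reps=100):
            fracs = []
            for seed in range(1, reps + 1):
                ds = simulate_genotypes(tiny_config.replace(T=T, seed=seed))
                fracs.append(np.mean(ds.f_bot == 0))
            return np.mean(fracs)

        losses = [mean_lost(T) for T in (50, 200, 500)]
        assert losses[0] <= losses[1] <= losses[2]

    def test_migration_reduces_frequency_divergence(self, tiny_config):
        def mean_divergence(m, reps=100):
            divs = []
            for seed in range(1, reps + 1):
                ds = simulate_genotypes(tiny_config.replace(m=m, seed=seed))
                divs.append(np.abs(ds.f_ref - ds.f_bot).mean())
            return np.mean(divs)

        assert mean_divergence(0.1) < mean_divergence(0.0)


class TestAlleleFrequencies:
    def test_monomorphic_columns(self):
        X = np.array([[0, 2], [0, 2], [0, 2]])
        np.testing.assert_array_equal(allele_frequencies(X), [0.0, 1.0])

    def test_half_frequency(self):
        X = np.array([[0], [1], [1], [2]])
        assert allele_frequencies(X)[0] == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            allele_frequencies(np.empty((0, 0)))

    def test_bad_entries_rejected(self):
        with pytest.raises(ValueError):
            allele_frequencies(np.array([[0, 3]]))


class TestSerialisation:
    def test_csv_roundtrip(self, tiny_dataset, tiny_config, tmp_path):
        tiny_dataset.to_csv(tmp_path, config=tiny_config)
        X_ref = np.loadtxt(tmp_path / "X_ref.csv", delimiter=",", skiprows=1)
        np.testing.assert_array_equal(X_ref, tiny_dataset.X_ref)
        import json

        sidecar = json.loads((tmp_path / "dataset.json").read_text())
        assert sidecar["L"] == tiny_dataset.L
        assert sidecar["config"]["N"] == tiny_config.N

    def test_vcf_export(self, tiny_dataset, tmp_path):
        path = tmp_path / "out.vcf"
        write_vcf(tiny_dataset, path)
        lines = path.read_text().splitlines()
        body = [l for l in lines if not l.startswith("#")]
        assert len(body) == tiny_dataset.L
        first = body[0].split("\t")
        assert first[3] == "A" and first[4] == "T"
        gts = first[9:]
        assert len(gts) == tiny_dataset.n_ref + tiny_dataset.n_bot
        counts = [gt.count("1") for gt in gts[: tiny_dataset.n_ref]]
        np.testing.assert_array_equal(counts, tiny_dataset.X_ref[:, 0])
        positions = [int(l.split("\t")[1]) for l in body]
        assert all(b > a for a, b in zip(positions, positions[1:]))
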