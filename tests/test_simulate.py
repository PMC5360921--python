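"""Synthetic census generator: affinity control, abundance decline,
determinism and schema contracts."""

import io

import numpy as np
import pandas as pd
import pytest

import antplant as ap
from antplant.simulate import (
    CensusFormatError, SimulationConfig, generate_census, read_census,
    sample_species_pools, simulate_census, validate_census, write_census,
)


def small_config(**kw):
    kw.setdefault("elevations", (700, 800, 900))
    kw.setdefault("n_plant_species", 8)
    kw.setdefault("n_ant_species", 5)
    kw.setdefault("range_width_m", 1e5)
    kw.setdefault("range_width_sigma", 0.0)
    kw.setdefault("uncertain_fraction", 0.0)
    return SimulationConfig(**kw)


class TestSpeciesPools:
    def test_gamma_zero_gives_uniform_affinities(self, rng):
        cfg = small_config(specialization_gamma=0.0)
        plants, ants = sample_species_pools(cfg, rng)
        for plant in plants:
            assert np.allclose(plant.affinity, 1.0 / cfg.n_ant_species)

    def test_affinity_is_exponentiated_renormalized_base(self, rng):
        cfg = small_config(specialization_gamma=3.0)
        plants, _ = sample_species_pools(cfg, rng)
        for plant in plants:
            expected = plant.base_affinity ** 3.0
            expected = expected / expected.sum()
            assert np.allclose(plant.affinity, expected)

    def test_large_gamma_concentrates_on_one_partner(self, rng):
        # softmax-type limit: with gamma = 50 any partner whose base weight
        # sits clearly below the top one (ratio <= 0.8 -> 0.8**50 ~ 1e-5)
        # is annihilated, leaving a single dominant entry
        cfg = small_config(specialization_gamma=50.0)
        plants, _ = sample_species_pools(cfg, rng)
        separated = 0
        for plant in plants:
            top, second = np.sort(plant.base_affinity)[-2:][::-1]
            if second / top <= 0.8:
                separated += 1
                assert plant.affinity.max() >= 0.999
        assert separated >= len(plants) // 2

    def test_pools_deterministic_under_seed(self):
        cfg = small_config()
        p1, a1 = sample_species_pools(cfg, np.random.default_rng(7))
        p2, a2 = sample_species_pools(cfg, np.random.default_rng(7))
        for s1, s2 in zip(p1 + a1, p2 + a2):
            assert s1.range_center == s2.range_center
            assert np.array_equal(s1.affinity, s2.affinity)

    @pytest.mark.parametrize("bad", [
        dict(n_plant_species=0),
        dict(n_ant_species=-1),
        dict(elevations=(800, 700)),
        dict(occupancy_curve=(0.5, 1.2, 0.4)),
        dict(specialization_gamma=-1.0),
        dict(herbivory_base_logits=(2.0, 1.0, 3.0)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            small_config(**bad)


class TestGenerateCensus:
    def test_zero_occupancy_gives_empty_networks(self, rng):
        cfg = small_config(occupancy_curve=(0.0, 0.0, 0.0))
        census = generate_census(cfg, sample_species_pools(cfg, rng), rng)
        assert (census["occupied"] == 0).all()
        assert ap.build_network(census, 700.0).is_empty

    def test_at_most_one_ant_per_record(self):
        census = simulate_census(seed=3)
        occupied = census[census["occupied"] == 1]
        assert (occupied["ant_species"] != "").all()
        unoccupied = census[census["occupied"] == 0]
        assert (unoccupied["ant_species"] == "").all()

    def test_census_byte_identical_under_seed(self, tmp_path):
        cfg = SimulationConfig()
        paths = []
        for run in range(2):
            census = simulate_census(cfg, seed=11)
            path = tmp_path / f"census{run}.csv"
            write_census(census, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_abundance_halves_per_100m(self):
        # decline 0.5 per 100 m with flat range kernels: expected totals at
        # 900 m are 1/4 of those at 700 m; Monte Carlo mean over 200 seeds
        cfg = small_config(abundance_decline_rate=0.5, plant_peak_abundance=10.0)
        totals = {700.0: 0, 900.0: 0}
        for seed in range(200):
            census = simulate_census(cfg, seed=seed)
            counts = census.groupby("elevation_m")["tree_id"].count()
            totals[700.0] += counts.get(700.0, 0)
            totals[900.0] += counts.get(900.0, 0)
        ratio = totals[900.0] / totals[700.0]
        assert abs(ratio - 0.25) < 0.02

    def test_larger_gamma_raises_mean_h2(self):
        common = dict(elevations=(700,), occupancy_curve=(0.8,),
                      n_plant_species=12, n_ant_species=6,
                      plant_peak_abundance=8.0)
        means = {}
        for gamma in (0.5, 6.0):
            cfg = small_config(specialization_gamma=gamma,
                               specialization_gamma_slope=0.0, **common)
            vals = []
            for seed in range(50):
                net = ap.build_network(simulate_census(cfg, seed=seed), 700.0)
                h2 = ap.h2_prime(net)
                if not np.isnan(h2):
                    vals.append(h2)
            means[gamma] = np.mean(vals)
        assert means[6.0] > means[0.5]

    def test_steeper_decline_leaves_fewer_top_records(self):
        counts = {}
        for rate in (0.6, 0.95):
            cfg = small_config(elevations=(700, 800, 900, 1000, 1100),
                               abundance_decline_rate=rate)
            total = 0
            for seed in range(50):
                census = simulate_census(cfg, seed=seed)
                top = census[census["elevation_m"] >= 1000.0]
                total += int((top["occupied"] == 1).sum())
            counts[rate] = total
        assert counts[0.6] < counts[0.95]

    def test_uncertain_fraction_near_nominal(self):
        cfg = SimulationConfig(uncertain_fraction=0.08)
        frac = []
        for seed in range(20):
            census = simulate_census(cfg, seed=seed)
            occ = census[census["occupied"] == 1]
            frac.append((occ["ant_species"] == "uncertain").mean())
        assert abs(np.mean(frac) - 0.08) < 0.02

    def test_no_available_ants_leaves_plants_unoccupied(self, rng):
        # single ant confined to 700 m: at 1100 m its truncated kernel is 0
        cfg = SimulationConfig(elevations=(700, 1100), n_ant_species=1,
                               n_plant_species=5, range_width_m=50.0,
                               range_width_sigma=0.0, center_beta=(1.0, 1.0),
                               center_pad_m=0.0, uncertain_fraction=0.0)
        plants, ants = sample_species_pools(cfg, rng)
        ants = [ap.SpeciesPool("A01", "ant", 700.0, 50.0, 1.0,
                               ants[0].affinity)]
        plants = [ap.SpeciesPool(p.species_id, "plant", 900.0, 1e5,
                                 p.peak_abundance, p.affinity,
                                 p.base_affinity) for p in plants]
        census = generate_census(cfg, (plants, ants), rng)
        high = census[census["elevation_m"] == 1100.0]
        assert len(high) > 0
        assert (high["occupied"] == 0).all()

    def test_empty_pools_error(self, rng):
        with pytest.raises(ValueError):
            generate_census(small_config(), ([], []), rng)


class TestCensusIO:
    def test_roundtrip(self, tmp_path):
        census = simulate_census(seed=2)
        path = tmp_path / "census.csv"
        write_census(census, path)
        back = read_census(path)
        pd.testing.assert_frame_equal(census, back, check_dtype=False)

    def test_unoccupied_with_ant_is_line_numbered_error(self, tiny_census):
        bad = tiny_census.copy()
        bad.loc[3, "ant_species"] = "A9"   # row 4 is unoccupied
        with pytest.raises(CensusFormatError, match="row 5"):
            validate_census(bad)

    def test_missing_column_rejected(self, tmp_path, tiny_census):
        path = tmp_path / "bad.csv"
        tiny_census.drop(columns=["dbh_cm"]).to_csv(path, index=False)
        with pytest.raises(CensusFormatError, match="dbh_cm"):
            read_census(path)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(specialization_gamma=1.5, seed=9)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg
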