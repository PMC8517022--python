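import numpy as np
import pytest

from bloomsat import detector, mapping, radiometry, synthetic


def _one_pop(**kw):
    defaults = dict(peak_day=60, duration_days=70, amplitude=0.95,
                    center_row=2.0, center_col=2.0, spread_cells=3.0)
    defaults.update(kw)
    return synthetic.PopulationConfig(**defaults)


class TestGenerateWorld:
    def test_no_populations_means_no_presence(self):
        cfg = synthetic.WorldConfig(grid_rows=8, grid_cols=8, seed=1)
        world = synthetic.generate_world(cfg)
        assert not world.presence.any()
        assert world.phenology.empty

    def test_same_seed_is_bit_identical(self):
        cfg = synthetic.WorldConfig(
            grid_rows=12, grid_cols=12, populations=(_one_pop(),),
            background_fraction=0.3, seed=9)
        w1 = synthetic.generate_world(cfg)
        w2 = synthetic.generate_world(cfg)
        assert np.array_equal(w1.presence, w2.presence)
        assert w1.phenology.equals(w2.phenology)
        for name in w1.covariates:
            assert np.array_equal(w1.covariates[name], w2.covariates[name])

    def test_zero_link_presence_count_in_binomial_band(self):
        # Binomial(2500, 0.1): 99% band = 250 +/- 2.576 * sqrt(250 * 0.9)
        cfg = synthetic.WorldConfig(
            grid_rows=50, grid_cols=50, populations=(_one_pop(),),
            background_fraction=0.1, covariate_link={}, seed=21)
        world = synthetic.generate_world(cfg)
        count = int(world.presence.sum())
        band = 2.576 * np.sqrt(2500 * 0.1 * 0.9)
        assert 250 - band <= count <= 250 + band

    def test_positive_link_raises_presence_in_high_covariate(self):
        cfg = synthetic.WorldConfig(
            grid_rows=40, grid_cols=40, populations=(_one_pop(),),
            background_fraction=0.15,
            covariate_link={"elevation": 2.0}, seed=3)
        world = synthetic.generate_world(cfg)
        elev = world.covariates["elevation"]
        high = elev > np.median(elev)
        assert world.presence[high].mean() > world.presence[~high].mean()

    def test_truth_rows_match_presence(self):
        cfg = synthetic.WorldConfig(
            grid_rows=15, grid_cols=15,
            populations=(_one_pop(), _one_pop(peak_day=200)),
            background_fraction=0.4, two_peak_fraction=0.5, seed=5)
        world = synthetic.generate_world(cfg)
        truth_pixels = set(world.phenology["pixel_id"])
        assert truth_pixels == set(world.pixel_ids())
        per_pixel = world.phenology.groupby("pixel_id").size()
        assert per_pixel.isin([1, 2]).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            synthetic.WorldConfig(grid_rows=0, grid_cols=5)
        with pytest.raises(ValueError):
            _one_pop(peak_day=400)
        with pytest.raises(ValueError):
            synthetic.WorldConfig(background_fraction=1.5)


class TestRenderScene:
    def test_presence_free_world_is_green_background(self):
        cfg = synthetic.WorldConfig(grid_rows=6, grid_cols=6, seed=2)
        world = synthetic.generate_world(cfg)
        scene = synthetic.render_scene(world, 60, seed=1, noise_sd=0.0)
        for b, base in enumerate(synthetic.FOREST_BASE):
            assert abs(float(scene.bands[..., b].mean()) - base) < 1
        r, g, b = (scene.bands[..., i].astype(int) for i in range(3))
        assert not ((r > g) & (b > g)).any()

    def test_peak_day_magenta_exceeds_green_by_contrast(self, small_world):
        truth = small_world.phenology.iloc[0]
        date = int(truth.peak_day)
        scene = synthetic.render_scene(small_world, date, seed=0,
                                       noise_sd=0.0)
        px = small_world.config.patch_pixels
        r0, c0 = int(truth.row) * px, int(truth.col) * px
        cell = scene.bands[r0:r0 + px, c0:c0 + px].astype(int)
        magenta = (cell[..., 0] > cell[..., 1]) \
            & (cell[..., 2] > cell[..., 1])
        assert magenta.any()
        contrast = small_world.config.magenta_contrast
        diff_r = cell[..., 0] - cell[..., 1]
        diff_b = cell[..., 2] - cell[..., 1]
        assert diff_r[magenta].min() >= contrast
        assert diff_b[magenta].min() >= contrast

    def test_full_cloud(self, small_world):
        scene = synthetic.render_scene(small_world, 60, seed=1,
                                       cloud_prob=1.0)
        assert scene.cloud_mask.all()
        assert scene.cloud_fraction == 1.0

    def test_values_in_range(self, small_world):
        scene = synthetic.render_scene(small_world, 60, seed=1)
        assert scene.bands.dtype == np.uint16
        assert scene.bands.max() <= 10000

    def test_render_inverse_color_oracle_recovers_bloom_mask(
            self, small_world):
        """On noiseless scenes the color rule recovers exactly the cells
        that are currently blooming."""
        for date in (20, 60, 100, 200):
            scene = synthetic.render_scene(small_world, date, seed=0,
                                           noise_sd=0.0, cloud_prob=0.0)
            conv = radiometry.convert_scene(scene)
            patches = radiometry.tile_scene(
                conv, core=small_world.config.patch_pixels)
            pred = np.array([detector.reference_color_detector(p.pixels)
                             for p in patches])
            grid = mapping.spatialize_predictions(
                pred, small_world.grid_shape)
            assert np.array_equal(grid.astype(bool),
                                  small_world.bloom_mask(date))


class TestSimulateObservations:
    def test_p_detect_zero_gives_no_detections(self, small_world):
        obs = synthetic.simulate_observations(
            small_world, list(range(1, 100)), p_detect=0.0, seed=1)
        assert not (obs.states == mapping.DETECTED).any()

    def test_cloud_fraction_within_3_binomial_sd(self, small_world):
        import datetime as dt
        n = 1000
        dates = [dt.date(2017, 1, 1) + dt.timedelta(days=i)
                 for i in range(n)]
        obs = synthetic.simulate_observations(
            small_world, dates, cloud_prob=0.3, seed=2)
        frac = (obs.states == mapping.CLOUD).mean()
        sd = np.sqrt(0.3 * 0.7 / (n * 100))
        assert abs(frac - 0.3) <= 3 * sd

    def test_detections_only_inside_bloom_window(self, small_world):
        obs = synthetic.simulate_observations(
            small_world, list(range(1, 366)), p_detect=1.0,
            cloud_prob=0.0, seed=3)
        truth = small_world.phenology.set_index(["row", "col"])
        det = obs.states == mapping.DETECTED
        for (r, c), rows in truth.groupby(level=[0, 1]):
            days = np.nonzero(det[:, r, c])[0] + 1
            for d in days:
                inside = False
                for _, t in rows.iterrows():
                    delta = abs((d - t.peak_day + 182.5) % 365 - 182.5)
                    inside = inside or delta <= t.duration_days / 2 + 1
                assert inside

    def test_state_counts_sum_to_dates(self, small_world):
        dates = list(range(1, 201))
        obs = synthetic.simulate_observations(small_world, dates,
                                              cloud_prob=0.2, seed=4)
        counts = obs.counts()
        total = sum(counts.values())
        assert np.all(total == len(dates))

    def test_empty_dates_rejected(self, small_world):
        with pytest.raises(ValueError):
            synthetic.simulate_observations(small_world, [], seed=1)


def test_save_load_world_roundtrip(tmp_path, small_world):
    synthetic.save_world(small_world, tmp_path)
    loaded = synthetic.load_world(tmp_path, small_world.config)
    assert np.array_equal(loaded.presence, small_world.presence)
    assert np.allclose(loaded.covariates["elevation"],
                       small_world.covariates["elevation"])
    assert len(loaded.phenology) == len(small_world.phenology)
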