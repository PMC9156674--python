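"""dNBR burn mapping, time since fire, and long-unburnt patch extraction."""

import numpy as np
import pytest

from sandsheet import fire_history as fh
from sandsheet import synthetic_data as sd


def _composite(nir, swir, year=2000, window="MAM", cell=30.0):
    nir = np.atleast_2d(np.asarray(nir, dtype=float))
    swir = np.atleast_2d(np.asarray(swir, dtype=float))
    grid = fh.GridSpec(nrows=nir.shape[0], ncols=nir.shape[1], cell_size=cell)
    return fh.SeasonalComposite(year=year, window=window, nir=nir, swir=swir, grid=grid)


class TestNbr:
    @pytest.mark.parametrize(
        "nir,swir,expected",
        [(0.5, 0.1, pytest.approx(0.6667, abs=1e-4)), (0.3, 0.3, 0.0)],
    )
    def test_band_arithmetic(self, nir, swir, expected):
        out = fh.compute_nbr(_composite([[nir]], [[swir]]))
        assert out[0, 0] == expected

    def test_zero_denominator_is_nodata(self):
        out = fh.compute_nbr(_composite([[0.0]], [[0.0]]))
        assert np.isnan(out[0, 0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _composite(np.ones((2, 2)), np.ones((2, 3)))


class TestSeasonalDnbr:
    def test_difference_and_label(self):
        pre = _composite([[0.75]], [[0.25]], window="MAM")  # NBR 0.5
        post = _composite([[0.55]], [[0.45]], window="JJA")  # NBR 0.1
        dnbr, season = fh.seasonal_dnbr(pre, post)
        assert dnbr[0, 0] == pytest.approx(0.4)
        assert season == "early"

    def test_identical_composites_zero(self):
        pre = _composite([[0.6]], [[0.2]], window="JJA")
        post = _composite([[0.6]], [[0.2]], window="SON")
        dnbr, season = fh.seasonal_dnbr(pre, post)
        assert dnbr[0, 0] == 0.0
        assert season == "late"

    def test_invalid_window_pair_rejected(self):
        with pytest.raises(ValueError):
            fh.seasonal_dnbr(_composite([[0.5]], [[0.1]], window="MAM"),
                             _composite([[0.5]], [[0.1]], window="SON"))

    def test_mismatched_years_rejected(self):
        with pytest.raises(ValueError):
            fh.seasonal_dnbr(_composite([[0.5]], [[0.1]], year=2000, window="MAM"),
                             _composite([[0.5]], [[0.1]], year=2001, window="JJA"))


class TestMeanAdjust:
    def test_hand_arithmetic(self):
        stack = {2000: np.array([[0.1]]), 2001: np.array([[0.1]]), 2002: np.array([[1.0]])}
        anoms = fh.mean_adjust(stack, "early")
        values = [a.values[0, 0] for a in anoms]
        assert values == pytest.approx([-0.3, -0.3, 0.6])

    def test_year_at_mean_gives_zero(self):
        stack = {2000: np.full((2, 2), 0.2), 2001: np.full((2, 2), 0.4)}
        anoms = fh.mean_adjust(stack, "late")
        assert np.allclose(anoms[0].values, -0.1)
        assert np.allclose(anoms[1].values, 0.1)

    def test_constant_offset_cancels(self, rng):
        base = {y: rng.normal(size=(4, 4)) for y in range(2000, 2006)}
        offset = rng.normal(size=(4, 4))
        shifted = {y: v + offset for y, v in base.items()}
        a0 = fh.mean_adjust(base, "early")
        a1 = fh.mean_adjust(shifted, "early")
        for x, y in zip(a0, a1):
            np.testing.assert_allclose(x.values, y.values, atol=1e-12)

    def test_anomalies_average_to_zero(self, rng):
        stack = {y: rng.normal(size=(3, 3)) for y in range(1995, 2001)}
        anoms = fh.mean_adjust(stack, "early")
        total = sum(a.values for a in anoms)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            fh.mean_adjust({2000: np.zeros((2, 2))}, "early")


class TestThreshold:
    def test_strictly_greater_than_cutoff(self):
        anomaly = np.array([[0.76, 0.75, -0.2]])
        mask = fh.threshold_burns(anomaly, cutoff=0.75)
        assert mask.tolist() == [[True, False, False]]

    def test_nodata_cells_unburnt(self):
        mask = fh.threshold_burns(np.array([[np.nan, 2.0]]))
        assert mask.tolist() == [[False, True]]


def _stack_from_events(burn_years, shape=(1, 1), first=1990, last=2010):
    grid = fh.GridSpec(nrows=shape[0], ncols=shape[1], cell_size=30.0)
    burns = {}
    for y in range(first, last + 1):
        for season in ("early", "late"):
            m = np.zeros(shape, dtype=bool)
            if (y, season) in burn_years or y in burn_years:
                m[:] = True
            burns[(y, season)] = m
    return fh.FireHistoryStack(burns=burns, mask=np.ones(shape, bool), grid=grid)


class TestTimeSinceFire:
    def test_years_since_most_recent_burn(self):
        stack = _stack_from_events({1999, 2004})
        tsf = fh.time_since_fire(stack, 2006)
        assert tsf.values[0, 0] == 2
        assert not tsf.censored[0, 0]

    def test_zero_in_burn_year(self):
        stack = _stack_from_events({2004})
        assert fh.time_since_fire(stack, 2004).values[0, 0] == 0

    def test_censored_carries_record_length(self):
        stack = _stack_from_events(set(), first=1990, last=2010)
        tsf = fh.time_since_fire(stack, 2006)
        assert tsf.censored[0, 0]
        assert tsf.values[0, 0] == 17  # 1990..2006 inclusive

    def test_spinup_enforced(self):
        stack = _stack_from_events({1992})
        with pytest.raises(ValueError):
            fh.time_since_fire(stack, 1993)

    def test_matches_brute_force_backward_scan(self, rng):
        """TSF equals an independent per-cell backward scan on random stacks."""
        shape = (20, 20)
        grid = fh.GridSpec(nrows=20, ncols=20, cell_size=30.0)
        for _ in range(200):
            years = range(1990, 2001)
            burns = {
                (y, s): rng.random(shape) < 0.15
                for y in years
                for s in ("early", "late")
            }
            stack = fh.FireHistoryStack(burns=burns, mask=np.ones(shape, bool), grid=grid)
            q = int(rng.integers(1995, 2001))
            tsf = fh.time_since_fire(stack, q)
            for idx in [(0, 0), (7, 13), (19, 19), tuple(rng.integers(0, 20, 2))]:
                expected = None
                for y in range(q, 1989, -1):
                    if burns[(y, "early")][idx] or burns[(y, "late")][idx]:
                        expected = q - y
                        break
                if expected is None:
                    assert tsf.censored[idx]
                    assert tsf.values[idx] == q - 1990 + 1
                else:
                    assert tsf.values[idx] == expected


def _flood_fill_patches(eligible, connectivity):
    """Independent brute-force connected components."""
    visited = np.zeros_like(eligible, dtype=bool)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    sizes = []
    rows, cols = eligible.shape
    for r in range(rows):
        for c in range(cols):
            if eligible[r, c] and not visited[r, c]:
                size, frontier = 0, [(r, c)]
                visited[r, c] = True
                while frontier:
                    rr, cc = frontier.pop()
                    size += 1
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and eligible[nr, nc] and not visited[nr, nc]:
                            visited[nr, nc] = True
                            frontier.append((nr, nc))
                sizes.append(size)
    return sorted(sizes)


class TestPatches:
    def _tsf(self, values):
        values = np.asarray(values)
        return fh.TsfGrid(year=2010, values=values, censored=np.zeros_like(values, bool))

    def test_full_grid_single_patch(self):
        grid = fh.GridSpec(nrows=3, ncols=3, cell_size=30.0)
        ps = fh.long_unburnt_patches(self._tsf(np.full((3, 3), 10)), np.ones((3, 3), bool), grid)
        assert len(ps.patches) == 1
        assert ps.patches[0].area_ha == pytest.approx(0.81)

    @pytest.mark.parametrize("connectivity,n_expected", [(4, 13), (8, 1)])
    def test_checkerboard_against_flood_fill(self, connectivity, n_expected):
        values = np.zeros((5, 5), int)
        values[::2, ::2] = 10
        values[1::2, 1::2] = 10
        grid = fh.GridSpec(nrows=5, ncols=5, cell_size=30.0)
        ps = fh.long_unburnt_patches(self._tsf(values), np.ones((5, 5), bool), grid,
                                     connectivity=connectivity)
        oracle = _flood_fill_patches(values > 5, connectivity)
        assert sorted(p.cell_count for p in ps.patches) == oracle
        assert len(ps.patches) == n_expected

    def test_random_grids_match_flood_fill_oracle(self, rng):
        grid = fh.GridSpec(nrows=20, ncols=20, cell_size=30.0)
        for _ in range(200):
            values = (rng.random((20, 20)) < 0.5).astype(int) * 10
            conn = int(rng.choice([4, 8]))
            ps = fh.long_unburnt_patches(self._tsf(values), np.ones((20, 20), bool), grid,
                                         connectivity=conn)
            assert sorted(p.cell_count for p in ps.patches) == _flood_fill_patches(values > 5, conn)

    def test_patch_area_conservation(self, rng):
        grid = fh.GridSpec(nrows=15, ncols=15, cell_size=30.0)
        values = (rng.random((15, 15)) < 0.4).astype(int) * 10
        mask = rng.random((15, 15)) < 0.9
        ps = fh.long_unburnt_patches(self._tsf(values), mask, grid)
        n_eligible = int(((values > 5) & mask).sum())
        assert ps.total_area_ha == pytest.approx(n_eligible * grid.cell_area_ha)

    def test_empty_mask_rejected(self):
        grid = fh.GridSpec(nrows=3, ncols=3, cell_size=30.0)
        with pytest.raises(ValueError):
            fh.long_unburnt_patches(self._tsf(np.full((3, 3), 10)), np.zeros((3, 3), bool), grid)


class TestRegimeSummary:
    def test_union_semantics_when_seasons_coincide(self):
        shape = (2, 2)
        grid = fh.GridSpec(nrows=2, ncols=2, cell_size=30.0)
        burns = {
            (y, s): np.ones(shape, bool) if y == 1995 else np.zeros(shape, bool)
            for y in range(1990, 1997)
            for s in ("early", "late")
        }
        stack = fh.FireHistoryStack(burns=burns, mask=np.ones(shape, bool), grid=grid)
        row = fh.summarize_regime(stack).set_index("year").loc[1995]
        assert row["p_early"] == 1.0 and row["p_late"] == 1.0 and row["p_total"] == 1.0

    def test_no_burns_censored_at_record_length(self):
        stack = _stack_from_events(set(), first=1990, last=2000)
        summary = fh.summarize_regime(stack).set_index("year")
        assert summary.loc[2000, "p_total"] == 0.0
        assert summary.loc[2000, "mean_tsf"] == 11  # record length 1990..2000

    def test_union_bound_on_random_stacks(self, rng):
        shape = (10, 10)
        grid = fh.GridSpec(nrows=10, ncols=10, cell_size=30.0)
        burns = {
            (y, s): rng.random(shape) < 0.3
            for y in range(1990, 2000)
            for s in ("early", "late")
        }
        stack = fh.FireHistoryStack(burns=burns, mask=np.ones(shape, bool), grid=grid)
        summary = fh.summarize_regime(stack)
        for _, row in summary.iterrows():
            assert max(row["p_early"], row["p_late"]) <= row["p_total"] + 1e-12
            assert row["p_total"] <= row["p_early"] + row["p_late"] + 1e-12


class TestEndToEnd:
    def test_noiseless_recovery_and_known_proportions(self, two_scar_scenario):
        """Mapped masks equal generator truth; 30% early + 20% late = 50% total."""
        comps, truth = sd.gen_fire_landscape(two_scar_scenario)
        mask = np.ones(two_scar_scenario.grid.shape, bool)
        stack = fh.map_fire_history(comps, mask)
        for key, tm in truth.items():
            np.testing.assert_array_equal(stack.burns[key], tm, err_msg=str(key))
        row = fh.summarize_regime(stack).set_index("year").loc[2005]
        assert row["p_early"] == pytest.approx(0.30)
        assert row["p_late"] == pytest.approx(0.20)
        assert row["p_total"] == pytest.approx(0.50)

    def test_raw_thresholding_config(self, two_scar_scenario):
        comps, truth = sd.gen_fire_landscape(two_scar_scenario)
        mask = np.ones(two_scar_scenario.grid.shape, bool)
        stack = fh.map_fire_history(comps, mask, threshold_on="raw")
        np.testing.assert_array_equal(stack.burns[(2005, "early")], truth[(2005, "early")])


class TestRasterIO:
    def test_ascii_grid_round_trip(self, rng, tmp_path):
        grid = fh.GridSpec(nrows=5, ncols=7, cell_size=30.0, origin_x=100.0, origin_y=400.0)
        arr = rng.normal(size=(5, 7))
        arr[2, 3] = np.nan
        path = tmp_path / "grid.asc"
        fh.write_ascii_grid(str(path), arr, grid)
        back, grid2 = fh.read_ascii_grid(str(path))
        np.testing.assert_allclose(back, arr, rtol=1e-5, equal_nan=True)
        assert grid2.shape == grid.shape
        assert grid2.cell_size == grid.cell_size

    def test_geojson_mask_center_point_rule(self, tmp_path):
        import json

        grid = fh.GridSpec(nrows=4, ncols=4, cell_size=10.0, origin_y=40.0)
        # polygon covering the left half: centers at x=5,15 inside, 25,35 outside
        gj = {
            "type": "Polygon",
            "coordinates": [[[0, 0], [20, 0], [20, 40], [0, 40], [0, 0]]],
        }
        path = tmp_path / "mask.geojson"
        path.write_text(json.dumps(gj))
        mask = fh.read_geojson_mask(str(path), grid)
        assert mask[:, :2].all() and not mask[:, 2:].any()
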