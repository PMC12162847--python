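"""Landscape construction, normalizations, zones and NRZ audit."""

import numpy as np
import pytest

from copmap.io import HET, HOM_A, CrossoverCall, PopulationCalls
from copmap.landscape import (
    call_zones,
    co_landscape,
    compare_tracks,
    fold_change_track,
    merge_cop,
    normalize_per_chromosome,
    normalize_per_genome,
    nrz_audit,
)
from copmap.layout import GenomeLayout
from copmap.tracks import WindowedTrack


def pop_from_positions(positions, n_gametes=10, genotype="g", sex="female",
                       chrom="c1"):
    """Population with one call per position, round-robin over gametes."""
    ids = [f"s{i}" for i in range(n_gametes)]
    calls = [
        CrossoverCall(ids[i % n_gametes], chrom, int(p) - 1, int(p) + 1, HOM_A, HET)
        for i, p in enumerate(positions)
    ]
    return PopulationCalls(genotype, sex, ids, calls)


@pytest.fixture
def flat_layout():
    return GenomeLayout([("c1", 5_000_000), ("c2", 3_000_000)],
                        nrz={"c1": (2_000_000, 2_500_000)})


class TestLandscape:
    def test_empty_population_gives_zero_track(self, flat_layout):
        track = co_landscape(pop_from_positions([]), flat_layout)
        assert track.flat_values().sum() == 0

    def test_midpoint_increments_every_covering_window(self, flat_layout):
        track = co_landscape(pop_from_positions([1_025_000]), flat_layout,
                             window=1_000_000, step=50_000)
        hit = np.flatnonzero(track.values["c1"] > 0)
        # windows with start in (25_000, 1_025_000]: starts 50k..1000k
        assert len(hit) == 20
        np.testing.assert_array_equal(
            track.starts["c1"][hit], np.arange(50_000, 1_050_000, 50_000)
        )

    def test_doubling_calls_doubles_values(self, flat_layout):
        single = pop_from_positions([500_000, 900_000])
        double = pop_from_positions([500_000, 900_000] * 2)
        a = co_landscape(single, flat_layout)
        b = co_landscape(double, flat_layout)
        np.testing.assert_allclose(b.flat_values(), 2 * a.flat_values())

    def test_nonoverlapping_windows_conserve_total(self, flat_layout):
        pop = pop_from_positions(list(range(100_000, 4_900_000, 170_000)))
        track = co_landscape(pop, flat_layout, window=100_000, step=100_000)
        assert track.values["c1"].sum() * pop.n_gametes == pytest.approx(
            len(pop.calls)
        )


class TestNormalization:
    def _track(self, flat_layout):
        pop = pop_from_positions(list(range(200_000, 4_500_000, 330_000)))
        return co_landscape(pop, flat_layout, window=500_000, step=250_000)

    @pytest.mark.filterwarnings("ignore:c2")
    def test_per_chromosome_sums_to_one(self, flat_layout):
        norm = normalize_per_chromosome(self._track(flat_layout))
        assert norm.values["c1"].sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.filterwarnings("ignore:c2")
    def test_scale_invariance(self, flat_layout):
        t = self._track(flat_layout)
        scaled = t.copy_with({c: v * 7 for c, v in t.values.items()}, t.normalization)
        np.testing.assert_allclose(
            normalize_per_chromosome(t).values["c1"],
            normalize_per_chromosome(scaled).values["c1"],
        )

    def test_all_zero_chromosome_warns(self, flat_layout):
        t = self._track(flat_layout)
        with pytest.warns(UserWarning, match="all-zero"):
            norm = normalize_per_chromosome(t)
        assert norm.values["c2"].sum() == 0

    def test_per_genome_mean_is_one(self, flat_layout):
        pop = pop_from_positions(list(range(100_000, 2_900_000, 130_000)), chrom="c2")
        track = co_landscape(pop, flat_layout, window=300_000, step=50_000)
        norm = normalize_per_genome(track)
        assert norm.flat_values().mean() == pytest.approx(1.0, abs=1e-9)


class TestMergeCop:
    def test_self_merge_keeps_rate(self, flat_layout):
        pop = pop_from_positions([500_000, 1_700_000, 4_000_000])
        one = merge_cop([pop], flat_layout)
        two = merge_cop([pop, pop], flat_layout)
        np.testing.assert_allclose(one.flat_values(), two.flat_values())

    def test_equal_n_disjoint_sets_average(self, flat_layout):
        a = pop_from_positions([500_000], n_gametes=10)
        b = pop_from_positions([4_000_000], n_gametes=10)
        merged = merge_cop([a, b], flat_layout)
        ra = co_landscape(a, flat_layout, 300_000, 50_000)
        rb = co_landscape(b, flat_layout, 300_000, 50_000)
        np.testing.assert_allclose(
            merged.flat_values(), (ra.flat_values() + rb.flat_values()) / 2
        )

    def test_relative_output_averages_one(self, flat_layout):
        pop = pop_from_positions(list(range(200_000, 4_800_000, 170_000)))
        track = merge_cop([pop], flat_layout, per_genome_relative=True)
        assert track.flat_values().mean() == pytest.approx(1.0, abs=1e-9)


class TestZones:
    def _fold_tracks(self, n_genotypes=5, n_windows=40, hot_at=None):
        tracks = {}
        for g in range(n_genotypes):
            v = np.ones(n_windows)
            if hot_at is not None and g < hot_at[1]:
                v[hot_at[0]] = 10.0
            tracks[f"g{g}"] = WindowedTrack(
                100_000, 100_000,
                {"c1": np.arange(n_windows) * 100_000}, {"c1": v},
            )
        return tracks

    def test_uniform_fold_change_gives_no_zones(self):
        zones = call_zones(self._fold_tracks(), "g0")
        assert len(zones) == 0

    def test_shared_hot_window_becomes_one_zone(self):
        # anchor + 3 others exceed 2x their median at window 7
        zones = call_zones(self._fold_tracks(hot_at=(7, 4)), "g0")
        assert len(zones) == 1
        z = zones.zones[0]
        assert (z.chromosome, z.start, z.end) == ("c1", 700_000, 800_000)

    def test_insufficient_support_gives_no_zone(self):
        zones = call_zones(self._fold_tracks(hot_at=(7, 3)), "g0")
        assert len(zones) == 0

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            call_zones(self._fold_tracks(), "nope")

    def test_wt_zero_windows_stay_finite(self):
        wt = WindowedTrack(100_000, 100_000, {"c1": np.arange(5) * 100_000},
                           {"c1": np.array([0.0, 1.0, 2.0, 0.0, 1.0])})
        mut = wt.copy_with({"c1": np.array([5.0, 5.0, 5.0, 5.0, 5.0])}, "per_gamete")
        fc = fold_change_track(mut, wt)
        assert np.all(np.isfinite(fc.values["c1"]))


class TestNRZ:
    def test_straddling_interval_not_counted(self, flat_layout):
        ids = ["s0"]
        inside = CrossoverCall("s0", "c1", 2_100_000, 2_200_000, HOM_A, HET)
        straddle = CrossoverCall("s0", "c1", 1_900_000, 2_100_000, HET, HOM_A)
        pop = PopulationCalls("g", "female", ids, [inside, straddle])
        table = nrz_audit([pop], flat_layout)
        assert table.loc[0, "nrz_co_count"] == 1
        assert table.loc[0, "total_co_count"] == 2

    def test_totals_conserved(self, flat_layout):
        pop = pop_from_positions(list(range(100_000, 4_900_000, 230_000)))
        table = nrz_audit([pop], flat_layout)
        assert table.loc[0, "total_co_count"] == len(pop.calls)


class TestCompareTracks:
    def _track(self, values):
        return WindowedTrack(100_000, 100_000,
                             {"c1": np.arange(len(values)) * 100_000},
                             {"c1": np.asarray(values, dtype=float)})

    def test_self_correlation_is_one(self, rng):
        t = self._track(rng.random(50))
        assert compare_tracks(t, t) == pytest.approx(1.0)

    def test_negation_is_minus_one(self, rng):
        v = rng.random(50)
        assert compare_tracks(self._track(v), self._track(-v)) == pytest.approx(-1.0)

    def test_shuffle_decorrelates(self, rng):
        v = rng.random(500)
        shuffled = rng.permutation(v)
        assert abs(compare_tracks(self._track(v), self._track(shuffled))) < 0.1

    def test_windowing_mismatch_rejected(self, rng):
        a = self._track(rng.random(10))
        b = WindowedTrack(200_000, 200_000, {"c1": np.arange(10) * 200_000},
                          {"c1": rng.random(10)})
        with pytest.raises(ValueError, match="windowing"):
            compare_tracks(a, b)
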