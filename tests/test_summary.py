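"""HPDI, KDE mode, peaks, pooling, and the Table-1-style report."""
import math

import numpy as np
import pandas as pd
import pytest

import isowash as iw
from isowash.errors import EmptyGroupError, InsufficientSamplesError, ValidationError


def brute_force_hpdi(draws, mass):
    """Independent oracle: scan every contiguous window of sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    m = math.ceil(mass * n)
    best = None
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + m - 1])
    return best[1], best[2]


class TestHPDI:
    def test_degenerate_distribution(self):
        interval = iw.hpdi(np.full(100, 3.7))
        assert (interval.lower, interval.upper, interval.mode) == (3.7, 3.7, 3.7)

    def test_evenly_spaced_lowest_index_tie_break(self):
        interval = iw.hpdi(np.arange(100.0), mass=0.85)
        assert (interval.lower, interval.upper) == (0.0, 84.0)

    def test_too_few_draws(self):
        with pytest.raises(InsufficientSamplesError):
            iw.hpdi(np.arange(10.0))

    def test_invalid_mass(self):
        with pytest.raises(ValidationError):
            iw.hpdi(np.arange(100.0), mass=1.5)

    @pytest.mark.parametrize("dist", ["normal", "exponential", "bimodal", "uniform"])
    @pytest.mark.parametrize("n", [50, 333, 5000])
    def test_matches_brute_force_oracle(self, dist, n, rng):
        if dist == "normal":
            x = rng.normal(0, 1, n)
        elif dist == "exponential":
            x = rng.exponential(1.0, n)
        elif dist == "uniform":
            x = rng.uniform(-5, 5, n)
        else:
            x = np.concatenate([rng.normal(-25, 0.5, n // 2), rng.normal(-15, 0.5, n - n // 2)])
        interval = iw.hpdi(x, 0.85)
        assert (interval.lower, interval.upper) == brute_force_hpdi(x, 0.85)

    def test_width_nondecreasing_in_mass(self, rng):
        x = rng.normal(0, 1, 2000)
        widths = [iw.hpdi(x, m).width for m in (0.5, 0.7, 0.85, 0.95)]
        assert widths == sorted(widths)

    def test_mode_inside_interval(self, rng):
        x = np.concatenate([rng.normal(-25, 0.5, 1500), rng.normal(-15, 0.5, 500)])
        interval = iw.hpdi(x, 0.5)
        assert interval.lower <= interval.mode <= interval.upper


class TestMode:
    def test_common_value(self):
        assert iw.mode_estimate(np.full(50, -19.0)) == -19.0

    def test_normal_mode(self, rng):
        x = rng.normal(5, 1, 10_000)
        assert iw.mode_estimate(x) == pytest.approx(5.0, abs=0.1)

    def test_bimodal_mode_lands_on_a_component(self, rng):
        x = np.concatenate([rng.normal(-25, 0.5, 5000), rng.normal(-15, 0.5, 5000)])
        mode = iw.mode_estimate(x)
        assert min(abs(mode + 25), abs(mode + 15)) < 0.3

    def test_peaks_detect_both_components(self, rng):
        x = np.concatenate([rng.normal(-25, 0.5, 5000), rng.normal(-15, 0.5, 5000)])
        peaks = iw.kde_peaks(x)
        assert len(peaks) == 2
        assert iw.is_multimodal(x)
        assert not iw.is_multimodal(rng.normal(0, 1, 5000))


class TestPool:
    def test_count_conservation(self, small_fit):
        _, _, samples = small_fit
        pooled = iw.pool(samples, "d13c_0", group_by=("species",))
        per_bird = samples.n_chains * samples.n_draws
        for key, pp in pooled.items():
            n_birds = (samples.meta["species"] == key[0]).sum()
            assert pp.draws.size == n_birds * per_bird
            assert pp.draws.size == sum(pp.bird_counts.values())

    def test_single_species_one_group(self, small_fit):
        _, _, samples = small_fit
        pooled = iw.pool(samples, "d13c_inf", group_by=("species", "year"))
        assert all(key[1] == 2010 for key in pooled)

    def test_envelope_property(self, small_fit):
        _, _, samples = small_fit
        pooled = iw.pool(samples, "d13c_inf", group_by=("species",))
        for key, pp in pooled.items():
            birds = samples.meta.loc[samples.meta["species"] == key[0], "bird_id"]
            lo = min(samples.bird_draws(b, "d13c_inf").min() for b in birds)
            hi = max(samples.bird_draws(b, "d13c_inf").max() for b in birds)
            assert pp.draws.min() >= lo and pp.draws.max() <= hi

    def test_empty_expected_group_raises(self, small_fit):
        _, _, samples = small_fit
        with pytest.raises(EmptyGroupError, match="2018"):
            iw.pool(
                samples,
                "d13c_0",
                group_by=("species", "year"),
                expected_groups=[("rufous", 2018)],
            )

    def test_pooling_order_invariance(self, small_fit):
        """Permuting birds changes neither the pooled HPDI nor the mode."""
        _, _, samples = small_fit
        pooled = iw.pool(samples, "d13c_0", ("species",))
        key = next(iter(pooled))
        draws = pooled[key].draws
        perm = np.random.default_rng(1).permutation(draws)
        a, b = iw.hpdi(draws), iw.hpdi(perm)
        assert (a.lower, a.upper, a.mode) == (b.lower, b.upper, b.mode)


class TestTable1Report:
    def test_row_set_complete(self, small_fit):
        _, _, samples = small_fit
        table = iw.summarize_table1(samples)
        for species in ("broad_tailed", "rufous"):
            params = set(table.loc[table["species"] == species, "parameter"])
            assert params == {"tau_min", "d13c_0", "d13c_inf"}

    def test_tau_row_identical_across_species(self, small_fit):
        _, _, samples = small_fit
        table = iw.summarize_table1(samples)
        tau_rows = table[table["parameter"] == "tau_min"]
        assert tau_rows["mode"].nunique() == 1
        assert tau_rows["hpdi_lower"].nunique() == 1
        assert tau_rows["hpdi_upper"].nunique() == 1

    def test_convergence_flag_attached(self, small_fit):
        _, _, samples = small_fit
        table = iw.summarize_table1(samples)
        assert table["converged"].dtype == bool
        assert table["converged"].nunique() == 1

    def test_peaks_table_rounded_to_permil(self, small_fit):
        _, _, samples = small_fit
        peaks = iw.peaks_table(samples)
        assert set(peaks.columns) == {"species", "parameter", "peak"}
        assert np.allclose(peaks["peak"], peaks["peak"].round(0))
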