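"""Reporter extraction, normalization, presence filtering, differential
statistics and the CV metric."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stageglyco import chem, quant
from stageglyco.quant import ChannelDesign
from stageglyco.simulate import default_design, plant_effects
from conftest import make_spectrum


@pytest.fixture
def design():
    return default_design()


@pytest.fixture
def paired_design():
    groups = {}
    pairs = {}
    channels = list(chem.TMT10_CHANNELS)
    tumor = ["127N", "128N", "129N", "130N"]
    normal = ["127C", "128C", "129C", "130C"]
    for t, n in zip(tumor, normal):
        groups[t] = "tumor"
        groups[n] = "normal"
        pairs[t] = n
    return ChannelDesign(channels=tuple(channels), reference="126", groups=groups, pairs=pairs)


class TestChannelDesign:
    def test_reference_must_be_a_channel(self):
        with pytest.raises(ValueError):
            ChannelDesign(reference="140")

    def test_reference_cannot_be_grouped(self):
        with pytest.raises(ValueError):
            ChannelDesign(reference="126", groups={"126": "tumor"})


class TestExtractReporters:
    def test_all_ten_reporters_found(self, design):
        mz = sorted(chem.tmt10_reporter_mz().values())
        s = make_spectrum(mz, np.arange(1, 11, dtype=float))
        values = quant.extract_reporters(s, design)
        assert all(v is not None for v in values.values())

    def test_no_low_mass_peaks_all_missing(self, design):
        s = make_spectrum([500.0, 900.0], [10.0, 10.0])
        values = quant.extract_reporters(s, design)
        assert all(v is None for v in values.values())

    def test_nearer_of_two_in_tolerance_peaks_chosen(self, design):
        target = chem.tmt10_reporter_mz()["126"]
        s = make_spectrum([target - 8e-4, target + 4e-4], [10.0, 20.0], )
        values = quant.extract_reporters(s, design, tol_ppm=10.0)
        assert values["126"] == 20.0


class TestNormalize:
    def _matrix(self, design, values):
        return pd.DataFrame(values, columns=list(design.channels))

    def test_channels_equal_to_reference_give_zero(self, design):
        m = self._matrix(design, np.full((5, 10), 100.0))
        norm = quant.normalize(m, design)
        np.testing.assert_allclose(norm.to_numpy(), 0.0)

    def test_doubled_channel_centered_back_to_zero(self, design):
        vals = np.full((4, 10), 100.0)
        j = list(design.channels).index("129N")
        vals[:, j] = 200.0  # 2x reference in every row
        norm = quant.normalize(self._matrix(design, vals), design)
        np.testing.assert_allclose(norm["129N"], 0.0, atol=1e-12)

    def test_per_channel_median_zero(self, design):
        rng = np.random.default_rng(2)
        m = self._matrix(design, rng.lognormal(10, 1, (50, 10)))
        norm = quant.normalize(m, design)
        np.testing.assert_allclose(norm.median(axis=0), 0.0, atol=1e-12)

    def test_idempotent_up_to_relog(self, design):
        rng = np.random.default_rng(3)
        m = self._matrix(design, rng.lognormal(10, 1, (30, 10)))
        once = quant.normalize(m, design)
        again = quant.normalize(2.0**once, design)
        np.testing.assert_allclose(once.to_numpy(), again.to_numpy(), atol=1e-9)

    def test_bad_reference_row_all_missing(self, design):
        vals = np.full((2, 10), 100.0)
        vals[1, 0] = 0.0  # reference channel is first
        norm = quant.normalize(self._matrix(design, vals), design)
        assert norm.iloc[1].isna().all()


class TestPresenceFilter:
    def _row(self, design, n_present):
        cols = list(design.channels)
        row = {c: np.nan for c in cols}
        for c in design.sample_channels[:n_present]:
            row[c] = 1.0
        row[design.reference] = 1.0
        return row

    def test_fully_present_kept_two_thirds_dropped(self, design):
        n_sample = len(design.sample_channels)  # 9 non-reference channels
        m = pd.DataFrame([self._row(design, n_sample), self._row(design, 6)])
        kept = quant.presence_filter(m, design, fraction=0.75)
        assert list(kept.index) == [0]

    def test_zero_fraction_keeps_any_observed_row(self, design):
        m = pd.DataFrame([self._row(design, 1), self._row(design, 0)])
        kept = quant.presence_filter(m, design, fraction=0.0)
        assert list(kept.index) == [0]


def brute_force_bh(pvals):
    """Oracle: sort, p*m/rank, cumulative min from the largest p."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestDifferentialUnpaired:
    def test_identical_groups_not_significant(self, design):
        m = pd.DataFrame(np.zeros((3, 10)), columns=list(design.channels))
        res = quant.differential_unpaired(quant.normalize(2.0**m, design), design)
        assert (res["direction"] == "ns").all()
        np.testing.assert_allclose(res["median_log2_fc"], 0.0)

    def test_planted_twofold_shift_recovered_in_noiseless_limit(self, design):
        # log2 matrix with tumor channels shifted by exactly +1, no noise
        vals = pd.DataFrame(0.0, index=range(5), columns=list(design.channels))
        for ch in design.group_channels("tumor"):
            vals[ch] = 1.0
        res = quant.differential_unpaired(vals, design)
        np.testing.assert_allclose(res["median_log2_fc"], 1.0, atol=1e-12)

    def test_minority_planted_effects_survive_normalization(self, design):
        effects = np.zeros(200)
        effects[:20] = 1.0
        matrix = plant_effects(200, design, effects, sigma=0.0, seed=1)
        norm = quant.normalize(matrix, design)
        res = quant.differential_unpaired(norm, design)
        np.testing.assert_allclose(res["median_log2_fc"][:20], 1.0, atol=0.05)

    def test_row_with_insufficient_group_reported_untested(self, design):
        vals = pd.DataFrame(np.full((1, 10), 1.0), columns=list(design.channels))
        vals.loc[0, ["129C", "130N", "130C"]] = np.nan  # one tumor value left
        res = quant.differential_unpaired(vals, design)
        assert res.iloc[0]["direction"] == "untested"

    @given(seed=st.integers(0, 500), n=st.integers(3, 40))
    @settings(derandomize=True, max_examples=40)
    def test_bh_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        pvals = rng.uniform(0, 1, n)
        got = quant._bh_adjust(pvals.copy())
        np.testing.assert_allclose(got, brute_force_bh(pvals), atol=1e-12)

    def test_type_one_error_controlled_under_null(self, design):
        matrix = plant_effects(300, design, np.zeros(300), sigma=0.25, seed=9)
        norm = quant.normalize(matrix, design)
        res = quant.differential_unpaired(norm, design, fdr_level=0.01)
        assert (res["direction"] != "ns").mean() <= 0.02


class TestDifferentialPaired:
    def _matrix(self, paired_design, diffs_log2, sigma, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for d in diffs_log2:
            row = {}
            base = 10.0
            for t, n in paired_design.pairs.items():
                row[n] = base + rng.normal(0, sigma)
                row[t] = row[n] + d + rng.normal(0, sigma)
            row[paired_design.reference] = base
            rows.append(row)
        return pd.DataFrame(rows, columns=list(paired_design.channels))

    def test_all_zero_differences_give_p_one(self, paired_design):
        m = self._matrix(paired_design, [0.0], sigma=0.0)
        res = quant.differential_paired(m, paired_design)
        assert res.iloc[0]["p_value"] == 1.0
        assert res.iloc[0]["median_log2_fc"] == 0.0

    def test_constant_unit_shift_with_tiny_noise_significant_up(self, paired_design):
        m = self._matrix(paired_design, [1.0] * 5, sigma=0.01, seed=4)
        res = quant.differential_paired(m, paired_design)
        assert (res["direction"] == "up").all()

    def test_closed_form_paired_t(self, paired_design):
        # 4 pairs with differences d_i: t = mean/ (sd/sqrt(n))
        m = self._matrix(paired_design, [0.5], sigma=0.2, seed=8)
        res = quant.differential_paired(m, paired_design)
        diffs = []
        for t_ch, n_ch in paired_design.pairs.items():
            diffs.append(m.iloc[0][t_ch] - m.iloc[0][n_ch])
        diffs = np.array(diffs)
        from scipy import stats as sps

        expected = sps.ttest_1samp(diffs, 0.0).pvalue
        assert res.iloc[0]["p_value"] == pytest.approx(expected)

    def test_incomplete_pair_dropped(self, paired_design):
        m = self._matrix(paired_design, [1.0], sigma=0.01, seed=5)
        m.loc[0, "127C"] = np.nan  # breaks the 127N/127C pair
        res = quant.differential_paired(m, paired_design)
        assert np.isfinite(res.iloc[0]["p_value"])  # still 3 complete pairs

    def test_fewer_than_two_pairs_untested(self, paired_design):
        m = self._matrix(paired_design, [1.0], sigma=0.0)
        for t_ch in list(paired_design.pairs)[1:]:
            m.loc[0, t_ch] = np.nan
        res = quant.differential_paired(m, paired_design)
        assert res.iloc[0]["direction"] == "untested"


class TestCV:
    def test_constant_values_zero_percent(self):
        assert quant.cv([5.0, 5.0, 5.0]) == 0.0

    def test_nine_ten_eleven_gives_ten_percent(self):
        assert quant.cv([9.0, 10.0, 11.0]) == pytest.approx(10.0)

    def test_scale_invariance(self):
        vals = [3.0, 4.0, 5.5, 6.0]
        assert quant.cv([7.3 * v for v in vals]) == pytest.approx(quant.cv(vals))

    def test_single_value_undefined(self):
        assert np.isnan(quant.cv([4.2]))
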