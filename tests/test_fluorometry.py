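"""Crosstalk factors and the corrected FRET output statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

from aptafret.errors import DegenerateInputError, MissingDataError
from aptafret.fluorometry import (
    ChannelSet,
    CrosstalkFactors,
    IntensityTable,
    acceptor_direct,
    donor_leak,
    factors_from_table,
    fret_output,
    fret_replicates,
)
from aptafret.synthetic import gen_intensity_table


def _donor_only(leak_reading, donor_reading, ch):
    return IntensityTable.from_records(
        [
            ("donor_only", ch.ex_donor, ch.em_acceptor, leak_reading),
            ("donor_only", ch.ex_donor, ch.em_donor, donor_reading),
        ]
    )


class TestDonorLeak:
    @pytest.mark.parametrize(
        "leak,donor,expected", [(0.0, 100.0, 0.0), (5.0, 100.0, 0.05)]
    )
    def test_direct_ratio(self, channels, leak, donor, expected):
        assert donor_leak(_donor_only(leak, donor, channels), channels) == expected

    def test_gaussian_window_integrals_match_quadrature_oracle(self, channels):
        # donor emission Gaussian centred 505 nm (sigma 20); plate-reader
        # readings emulated as integrals over 10 nm windows at 505 and 620
        mu, sigma = 505.0, 20.0

        def window_integral(centre):
            z = lambda x: (x - mu) / (sigma * np.sqrt(2.0))
            return 0.5 * (erf(z(centre + 5)) - erf(z(centre - 5)))

        reading_em_d = window_integral(channels.em_donor)
        reading_em_a = window_integral(channels.em_acceptor)
        table = _donor_only(reading_em_a, reading_em_d, channels)
        # independent fine-grid quadrature oracle
        grid = np.linspace(300.0, 800.0, 2_000_001)
        pdf = np.exp(-0.5 * ((grid - mu) / sigma) ** 2)

        def quad(centre):
            m = np.abs(grid - centre) <= 5.0
            return np.trapezoid(pdf[m], grid[m])

        oracle = quad(channels.em_acceptor) / quad(channels.em_donor)
        assert donor_leak(table, channels) == pytest.approx(oracle, rel=1e-6)

    def test_zero_denominator_raises(self, channels):
        with pytest.raises(DegenerateInputError):
            donor_leak(_donor_only(1.0, 0.0, channels), channels)

    def test_missing_channel_raises(self, channels):
        table = IntensityTable.from_records(
            [("donor_only", channels.ex_donor, channels.em_donor, 10.0)]
        )
        with pytest.raises(MissingDataError):
            donor_leak(table, channels)


class TestAcceptorDirect:
    @pytest.mark.parametrize(
        "cross,direct,expected", [(0.0, 200.0, 0.0), (2.0, 200.0, 0.01)]
    )
    def test_direct_ratio(self, channels, cross, direct, expected):
        table = IntensityTable.from_records(
            [
                ("acceptor_only", channels.ex_donor, channels.em_acceptor, cross),
                ("acceptor_only", channels.ex_acceptor, channels.em_acceptor, direct),
            ]
        )
        assert acceptor_direct(table, channels) == expected

    def test_gaussian_excitation_matches_closed_form(self, channels):
        # acceptor excitation Gaussian centred 585 (sigma 25): the ratio
        # of excitation at 460 vs 585 nm has a closed form
        mu, sigma = 585.0, 25.0
        value = lambda x: np.exp(-0.5 * ((x - mu) / sigma) ** 2)
        table = IntensityTable.from_records(
            [
                ("acceptor_only", channels.ex_donor, channels.em_acceptor,
                 value(channels.ex_donor)),
                ("acceptor_only", channels.ex_acceptor, channels.em_acceptor,
                 value(channels.ex_acceptor)),
            ]
        )
        expected = np.exp(-0.5 * ((460.0 - 585.0) / 25.0) ** 2)
        assert acceptor_direct(table, channels) == pytest.approx(expected, rel=1e-12)


class TestFretOutput:
    def test_signal_fully_explained_by_crosstalk_gives_zero(self, channels, factors):
        i_aa, i_dd = 100.0, 63.0
        i_da = factors.acceptor_direct * i_aa + factors.donor_leak * i_dd
        table = IntensityTable.from_records(
            [
                ("double", channels.ex_donor, channels.em_acceptor, i_da),
                ("double", channels.ex_acceptor, channels.em_acceptor, i_aa),
                ("double", channels.ex_donor, channels.em_donor, i_dd),
            ]
        )
        assert fret_output(table, factors, channels).fret == pytest.approx(0.0)

    def test_equal_corrected_channels_give_half(self, channels):
        table = IntensityTable.from_records(
            [
                ("double", channels.ex_donor, channels.em_acceptor, 42.0),
                ("double", channels.ex_acceptor, channels.em_acceptor, 999.0),
                ("double", channels.ex_donor, channels.em_donor, 42.0),
            ]
        )
        zero = CrosstalkFactors(0.0, 0.0)
        assert fret_output(table, zero, channels).fret == pytest.approx(0.5)

    def test_forward_model_construction(self, double_table, factors, channels):
        result = fret_output(double_table, factors, channels)
        assert result.fret == pytest.approx(0.37)
        assert not result.negative_flag

    def test_negative_numerator_flagged_not_clamped(self, channels, factors):
        table = IntensityTable.from_records(
            [
                ("double", channels.ex_donor, channels.em_acceptor, 1.0),
                ("double", channels.ex_acceptor, channels.em_acceptor, 100.0),
                ("double", channels.ex_donor, channels.em_donor, 63.0),
            ]
        )
        result = fret_output(table, factors, channels)
        assert result.fret < 0
        assert result.negative_flag

    def test_monotone_in_transfer_channel(self, channels, factors):
        def output(i_da):
            table = IntensityTable.from_records(
                [
                    ("double", channels.ex_donor, channels.em_acceptor, i_da),
                    ("double", channels.ex_acceptor, channels.em_acceptor, 100.0),
                    ("double", channels.ex_donor, channels.em_donor, 63.0),
                ]
            )
            return fret_output(table, factors, channels).fret

        values = [output(i) for i in (30.0, 60.0, 90.0, 140.0)]
        assert values == sorted(values)
        assert all(v <= 1.0 for v in values)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        # the statistic is homogeneous of degree 0 in the intensities
        ch = ChannelSet()
        factors = CrosstalkFactors(0.05, 0.2)
        i_aa, i_dd = 100.0, 63.0
        i_da = 37.0 + 0.2 * i_aa + 0.05 * i_dd
        table = IntensityTable.from_records(
            [
                ("double", ch.ex_donor, ch.em_acceptor, i_da),
                ("double", ch.ex_acceptor, ch.em_acceptor, i_aa),
                ("double", ch.ex_donor, ch.em_donor, i_dd),
            ]
        )
        base = fret_output(table, factors, ch).fret
        scaled = fret_output(table.scaled(scale), factors, ch).fret
        assert scaled == pytest.approx(base, rel=1e-9)


class TestFretReplicates:
    def test_identical_replicates(self, double_table, factors, channels):
        result = fret_replicates([double_table] * 3, factors, channels)
        assert result.fret == pytest.approx(0.37)
        assert result.sd == pytest.approx(0.0, abs=1e-12)
        assert len(result.per_replicate) == 3

    def test_textbook_sample_sd(self, channels):
        # replicates engineered to produce outputs 0.36, 0.37, 0.38
        zero = CrosstalkFactors(0.0, 0.0)
        tables = []
        for target in (0.36, 0.37, 0.38):
            i_dd = 100.0
            i_da = target * i_dd / (1.0 - target)
            tables.append(
                IntensityTable.from_records(
                    [
                        ("double", channels.ex_donor, channels.em_acceptor, i_da),
                        ("double", channels.ex_acceptor, channels.em_acceptor, 1.0),
                        ("double", channels.ex_donor, channels.em_donor, i_dd),
                    ]
                )
            )
        result = fret_replicates(tables, zero, channels)
        assert result.fret == pytest.approx(0.37)
        assert result.sd == pytest.approx(0.01, rel=1e-9)

    def test_noisy_replicates_recover_truth(self):
        # 3 replicates, 1% multiplicative noise around a true value of 0.30
        table, truth = gen_intensity_table(
            true_sensitized=30.0, true_donor_em=70.0, noise_sd=0.01,
            n_replicates=3, seed=11,
        )
        factors = CrosstalkFactors(**truth.factors)
        result = fret_replicates(table, factors)
        assert result.fret == pytest.approx(0.30, abs=3 * 0.01 / np.sqrt(3))

    def test_empty_list_raises(self, factors):
        with pytest.raises(MissingDataError):
            fret_replicates([], factors)

    def test_single_replicate_sd_zero(self, double_table, factors, channels):
        result = fret_replicates([double_table], factors, channels)
        assert result.sd == 0.0


def test_factors_measured_from_single_labelled_rows(channels):
    table, truth = gen_intensity_table(seed=0)
    measured = factors_from_table(table, channels)
    assert measured.donor_leak == pytest.approx(truth.factors["donor_leak"])
    assert measured.acceptor_direct == pytest.approx(truth.factors["acceptor_direct"])
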