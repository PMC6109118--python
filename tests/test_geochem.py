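"""Unit and property tests for the geochemistry domain types and arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfoc.geochem import (
    GeochemError,
    Lithology,
    MissingFieldError,
    Moiety,
    Profile,
    ProfileValidationError,
    Sample,
    TocClass,
    carbonate_free,
    molar_sc,
    propagate_sc_sd,
    read_profile,
    toc_class,
    write_profile,
)


class TestMolarSC:
    @pytest.mark.parametrize(
        "s_wt, c_wt, expected",
        [
            (32.06, 12.011, 1.0),  # one mole of each per 100 g
            (0.0, 2.0, 0.0),
            (0.32, 2.40, (0.32 / 32.06) / (2.40 / 12.011)),  # ~0.0500
        ],
    )
    def test_values(self, s_wt, c_wt, expected):
        assert molar_sc(s_wt, c_wt) == pytest.approx(expected, rel=1e-12)

    def test_hand_computed_ratio_is_five_percent(self):
        assert molar_sc(0.32, 2.40) == pytest.approx(0.0500, abs=5e-4)

    @pytest.mark.parametrize("c_wt", [0.0, -1.0])
    def test_nonpositive_carbon_rejected(self, c_wt):
        with pytest.raises(GeochemError):
            molar_sc(0.1, c_wt)

    def test_negative_sulfur_rejected(self):
        with pytest.raises(GeochemError):
            molar_sc(-0.1, 1.0)

    @given(
        s=st.floats(0.001, 50),
        c=st.floats(0.001, 50),
        k=st.floats(0.01, 100),
    )
    @settings(max_examples=100, derandomize=True)
    def test_homogeneity_under_common_rescaling(self, s, c, k):
        assert molar_sc(k * s, k * c) == pytest.approx(molar_sc(s, c), rel=1e-9)


class TestCarbonateFree:
    @pytest.mark.parametrize(
        "value, carbonate, expected",
        [(0.5, 75.0, 2.0), (3.0, 0.0, 3.0), (0.2, 60.0, 0.5)],
    )
    def test_values(self, value, carbonate, expected):
        assert carbonate_free(value, carbonate) == pytest.approx(expected)

    @pytest.mark.parametrize("carbonate", [100.0, 120.0, -5.0])
    def test_domain_errors(self, carbonate):
        with pytest.raises(GeochemError):
            carbonate_free(1.0, carbonate)

    @given(carb=st.lists(st.floats(0, 99.0), min_size=2, max_size=10))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_carbonate(self, carb):
        vals = [carbonate_free(1.0, c) for c in sorted(carb)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestPropagateSD:
    def test_no_uncertainty(self):
        assert propagate_sc_sd(1.0, 0.0, 1.0, 0.0) == 0.0

    def test_single_term_is_relative_sd(self):
        sd = propagate_sc_sd(1.0, 0.1, 1.0, 0.0)
        ratio = molar_sc(1.0, 1.0)
        assert sd / ratio == pytest.approx(0.10)

    def test_quadrature(self):
        sd = propagate_sc_sd(0.32, 0.016, 2.40, 0.12)
        ratio = molar_sc(0.32, 2.40)
        assert sd / ratio == pytest.approx(math.sqrt(0.05**2 + 0.05**2), rel=1e-9)

    def test_zero_mean_nonzero_sd_rejected(self):
        with pytest.raises(GeochemError):
            propagate_sc_sd(0.0, 0.1, 1.0, 0.1)


class TestTocClass:
    @pytest.mark.parametrize(
        "toc, expected",
        [(3.1, TocClass.RICH), (1.0, TocClass.LEAN), (0.2, TocClass.LEAN)],
    )
    def test_threshold_is_strict(self, toc, expected):
        assert toc_class(toc) is expected
        sample = Sample(height=1.0, toc=toc, carbonate=10.0)
        assert toc_class(sample) is expected

    def test_custom_threshold(self):
        assert toc_class(1.5, threshold=2.0) is TocClass.LEAN


class TestSampleInvariants:
    def test_toc_carbonate_budget(self):
        with pytest.raises(GeochemError):
            Sample(height=0.0, toc=60.0, carbonate=50.0)

    def test_carbonate_at_100_rejected(self):
        with pytest.raises(GeochemError):
            Sample(height=0.0, toc=0.0, carbonate=100.0)

    def test_speciation_renormalized_with_raw_sum_kept(self):
        # fitted fractional abundances commonly over-close; ingest renormalizes
        s = Sample(
            height=0.0,
            toc=2.0,
            carbonate=30.0,
            speciation={
                Moiety.MONOSULFIDE: 0.57,
                Moiety.AROMATIC: 0.32,
                Moiety.DISULFIDE: 0.17,
                Moiety.SULFONATE: 0.08,
                Moiety.SULFOXIDE: 0.03,
            },
        )
        assert sum(s.speciation.values()) == pytest.approx(1.0, abs=1e-9)
        assert s.speciation_raw_sum == pytest.approx(1.17)
        assert s.speciation[Moiety.MONOSULFIDE] == pytest.approx(0.57 / 1.17)

    def test_wildly_unclosed_speciation_rejected(self):
        with pytest.raises(GeochemError):
            Sample(height=0.0, toc=1.0, carbonate=0.0,
                   speciation={Moiety.MONOSULFIDE: 0.3})

    def test_missing_s_org_raises_named_error(self):
        s = Sample(height=0.0, toc=1.0, carbonate=0.0)
        with pytest.raises(MissingFieldError):
            _ = s.sc


class TestProfileIO:
    def _tiny(self):
        return Profile(
            samples=[
                Sample(4.0, Lithology.MARL, toc=0.8, carbonate=60.0, s_org=0.04),
                Sample(12.5, Lithology.SHALE, toc=3.1, carbonate=40.0, s_org=0.42,
                       d34s=-30.0),
                Sample(22.6, Lithology.LIMESTONE, toc=0.2, carbonate=85.0),
            ]
        )

    def test_read_three_row_fixture(self, tmp_path):
        path = tmp_path / "p.csv"
        write_profile(self._tiny(), path)
        profile = read_profile(path)
        assert len(profile) == 3
        assert list(profile.heights) == [4.0, 12.5, 22.6]
        assert profile.samples[2].s_org is None  # missing stays missing

    def test_round_trip_identity(self, tmp_path, default_profile):
        path = tmp_path / "p.csv"
        write_profile(default_profile, path)
        again = read_profile(path)
        assert default_profile.to_dataframe().equals(again.to_dataframe())

    def test_non_monotone_heights_rejected(self):
        with pytest.raises(ProfileValidationError, match="row"):
            Profile(samples=[
                Sample(2.0, toc=1.0, carbonate=0.0),
                Sample(1.0, toc=1.0, carbonate=0.0),
            ])

    def test_unknown_column_warns(self, tmp_path):
        path = tmp_path / "p.csv"
        write_profile(self._tiny(), path)
        text = path.read_text().splitlines()
        text[0] += ",mystery"
        text[1] += ",1.0"
        text[2] += ",2.0"
        text[3] += ",3.0"
        path.write_text("\n".join(text))
        with pytest.warns(UserWarning, match="mystery"):
            read_profile(path)

    def test_invalid_row_rejected_on_read(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "height_m,lithology,toc_wt_pct,carbonate_wt_pct\n1.0,shale,0.5,100\n"
        )
        with pytest.raises(GeochemError):
            read_profile(path)
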