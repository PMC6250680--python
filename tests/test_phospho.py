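"""Reporter-ion quantification: filtering, bias correction, ratio chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phosplice.phospho import (
    filter_peptides,
    fragment_site_quantity,
    normalize_channels,
    peptide_ratio,
    protein_site_ratio,
    site_differential_test,
)
from phosplice.simulate import PhosphoSimConfig, simulate_phospho

from conftest import make_reporter_matrix


class TestFilterPeptides:
    def test_all_rows_pass_unchanged(self):
        m = make_reporter_matrix([[10, 10], [20, 20]])
        out = filter_peptides(m, min_intensity=0.0)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_unlabeled_and_shared_rows_removed(self):
        m = make_reporter_matrix(
            [[10, 10], [20, 20], [30, 30]],
            has_itraq_label=[False, True, True],
            shared_spectrum=[False, True, False],
        )
        out = filter_peptides(m, min_intensity=0.0)
        assert list(out.data["peptide"]) == ["pep2"]

    def test_confidence_threshold_is_strict(self):
        m = make_reporter_matrix(
            [[10, 10], [20, 20]], confidence=[0.95, 0.951]
        )
        out = filter_peptides(m, min_intensity=0.0, min_confidence=0.95)
        assert list(out.data["peptide"]) == ["pep1"]

    def test_low_intensity_rows_removed(self):
        m = make_reporter_matrix([[1, 2], [100, 200]])
        out = filter_peptides(m, min_intensity=50.0)
        assert list(out.data["peptide"]) == ["pep1"]


class TestNormalizeChannels:
    def test_equal_totals_unchanged(self):
        m = make_reporter_matrix([[1, 2], [2, 1]])
        out = normalize_channels(m)
        np.testing.assert_allclose(out.intensities.to_numpy(), m.intensities.to_numpy())

    def test_totals_equal_grand_mean(self):
        m = make_reporter_matrix([[1, 2], [1, 2]])
        out = normalize_channels(m)
        np.testing.assert_allclose(out.intensities.sum(axis=0), [3.0, 3.0])

    def test_column_sums_equalized_on_random_matrix(self):
        rng = np.random.default_rng(5)
        m = make_reporter_matrix(rng.lognormal(size=(20, 4)), case_channels=2)
        out = normalize_channels(m)
        sums = out.intensities.sum(axis=0).to_numpy()
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        m = make_reporter_matrix(rng.lognormal(size=(10, 3)))
        once = normalize_channels(m)
        twice = normalize_channels(once)
        np.testing.assert_allclose(
            twice.intensities.to_numpy(), once.intensities.to_numpy(), rtol=1e-12
        )

    def test_zero_total_channel_rejected(self):
        m = make_reporter_matrix([[1, 0], [1, 0]])
        with pytest.raises(ValueError):
            normalize_channels(m)


class TestRatioChain:
    @pytest.mark.parametrize(
        "x,expected", [([5, 5, 5], 5.0), ([4, 9], 6.0), ([2, 4, 8], 4.0)]
    )
    def test_fragment_geometric_mean(self, x, expected):
        assert fragment_site_quantity(x) == pytest.approx(expected)

    def test_fragment_quantity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fragment_site_quantity([1.0, 0.0])
        with pytest.raises(ValueError):
            fragment_site_quantity([])

    @given(st.lists(st.floats(1e-3, 1e6), min_size=1, max_size=10))
    def test_fragment_quantity_between_min_and_max(self, x):
        q = fragment_site_quantity(x)
        assert min(x) * (1 - 1e-9) <= q <= max(x) * (1 + 1e-9)

    @pytest.mark.parametrize(
        "case,ctrl,expected",
        [([2, 2], [1, 1], 2.0), ([1, 4], [1, 1], 2.0), ([3, 7], [3, 7], 1.0)],
    )
    def test_peptide_ratio(self, case, ctrl, expected):
        assert peptide_ratio(case, ctrl) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ratios,weights,expected",
        [
            ([2, 2], [5, 1], 2.0),
            ([1, 4], None, 2.0),
            ([1, 4], [3, 1], 2**0.5),
        ],
    )
    def test_protein_site_ratio(self, ratios, weights, expected):
        assert protein_site_ratio(ratios, weights) == pytest.approx(expected)

    def test_protein_site_ratio_rejects_zero_weights(self):
        with pytest.raises(ValueError):
            protein_site_ratio([1, 2], [0, 0])

    def test_ratios_scale_invariant(self):
        case, ctrl = [2.0, 8.0], [1.0, 4.0]
        base = peptide_ratio(case, ctrl)
        scaled = peptide_ratio([x * 1e3 for x in case], [x * 1e3 for x in ctrl])
        assert scaled == pytest.approx(base, rel=1e-12)


class TestSiteDifferentialTest:
    def test_identical_groups_not_significant(self):
        m = make_reporter_matrix(
            np.tile([[100.0, 100.0, 100.0, 100.0]], (4, 1)), case_channels=2
        )
        res = site_differential_test(m, normalize=False)
        assert res["p"].iloc[0] == 1.0
        assert not res["significant"].any()

    def test_channel_bias_corrected_under_null(self):
        """Planted channel biases, no real effects: bias correction recovers
        near-zero log ratios and a calibrated type-I rate."""
        cfg = PhosphoSimConfig(
            n_proteins=400,
            channel_bias=(1.5, 0.7, 1.2, 0.8, 1.1, 0.9),
            log_noise_sd=0.1,
            seed=11,
        )
        res = site_differential_test(simulate_phospho(cfg), normalize=True)
        assert abs(res["log2_ratio"].mean()) < 0.05
        assert res["significant"].mean() <= 0.05

    def test_uncorrected_bias_distorts_ratios(self):
        cfg = PhosphoSimConfig(
            n_proteins=50,
            channel_bias=(2.0, 2.0, 2.0, 1.0, 1.0, 1.0),
            log_noise_sd=0.05,
            seed=12,
        )
        res = site_differential_test(simulate_phospho(cfg), normalize=False)
        assert res["log2_ratio"].mean() == pytest.approx(1.0, abs=0.1)

    def test_planted_effect_recovered(self):
        # small family: Welch at n=3/3 has a p floor near 1e-3, so two true
        # signals among many nulls cannot clear BH at q < 0.05
        cfg = PhosphoSimConfig(
            n_proteins=20,
            spiked_sites=(("P0000", "S1", 1.5), ("P0001", "S1", -1.0)),
            log_noise_sd=0.1,
            seed=13,
        )
        res = site_differential_test(simulate_phospho(cfg), normalize=False)
        res = res.set_index("protein")
        assert res.loc["P0000", "log2_ratio"] == pytest.approx(1.5, abs=0.25)
        assert res.loc["P0001", "log2_ratio"] == pytest.approx(-1.0, abs=0.25)
        assert res.loc["P0000", "significant"] and res.loc["P0001", "significant"]
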