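import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logit
from scipy.stats import norm

from lepirisk.dose_response import (
    BUTTERFLY_LOGIT_SLOPE,
    LC50_BT176_MOTH,
    LC50_MON810_BUTTERFLY,
    LC50_MON810_MOTH,
    MON810_FOLD,
    PROBIT_SLOPE,
    DoseResponseModel,
    logit_approximation,
    rescale_lc50,
    species_model,
)

EDGE_DOSE = 10.0**2.346  # U. dioica crop-edge deposition, grains cm^-2
CROP_DOSE = 2.7 * EDGE_DOSE


class TestRescaleLC50:
    @pytest.mark.parametrize(
        "lc50, fold, expected",
        [
            (186.8, 31.0, 5790.8),  # butterfly Bt176 -> MON810 (rounded to 5800 in use)
            (42.0, 1.0, 42.0),  # identity fold
            (113.1, 31.0, 3506.1),  # moth product; published value is 3626
        ],
    )
    def test_product(self, lc50, fold, expected):
        assert rescale_lc50(lc50, fold) == pytest.approx(expected)

    def test_published_moth_lc50_differs_from_product(self):
        """The published moth LC50 (3626) is not the 31-fold product (3506.1);
        the package adopts the published constant and keeps the rescaling
        transparent rather than silently reconciling the two."""
        assert rescale_lc50(LC50_BT176_MOTH, MON810_FOLD) == pytest.approx(3506.1)
        assert LC50_MON810_MOTH == 3626.0

    @pytest.mark.parametrize("lc50, fold", [(-1.0, 31.0), (0.0, 31.0), (10.0, 0.0), (10.0, -2.0)])
    def test_non_positive_inputs_rejected(self, lc50, fold):
        with pytest.raises(ValueError):
            rescale_lc50(lc50, fold)


class TestMortality:
    @pytest.mark.parametrize("link", ["logit", "probit"])
    def test_half_mortality_at_lc50(self, link):
        model = DoseResponseModel(lc50=500.0, slope=2.0, link=link)
        assert model.mortality(500.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("link", ["logit", "probit"])
    def test_zero_dose_gives_zero(self, link):
        model = DoseResponseModel(lc50=500.0, slope=2.0, link=link)
        assert model.mortality(0.0) == 0.0

    def test_butterfly_edge_anchor(self):
        """The calibrated butterfly model reproduces the crop-edge mortality 0.0292."""
        model = species_model("inachis_io")
        assert model.mortality(EDGE_DOSE) == pytest.approx(0.0292, abs=1e-6)

    def test_vectorised_evaluation(self):
        model = species_model("inachis_io")
        doses = np.array([0.0, EDGE_DOSE, model.lc50])
        p = model.mortality(doses)
        assert p.shape == (3,)
        assert p[0] == 0.0 and p[2] == pytest.approx(0.5)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            species_model("inachis_io").mortality(-1.0)

    @given(
        lc50=st.floats(1.0, 1e5),
        slope=st.floats(0.1, 10.0),
        link=st.sampled_from(["logit", "probit"]),
        log_doses=st.lists(st.integers(-30, 70), min_size=2, max_size=10, unique=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_dose(self, lc50, slope, link, log_doses):
        model = DoseResponseModel(lc50=lc50, slope=slope, link=link)
        doses = 10.0 ** (np.sort(np.asarray(log_doses)) / 10.0)
        p = model.mortality(doses)
        assert np.all(np.diff(p) >= 0)
        # strict increase wherever the response is not float-saturated at 0 or 1
        interior = (p[:-1] > 1e-12) & (p[1:] < 1.0 - 1e-12)
        assert np.all(np.diff(p)[interior] > 0)


class TestLogitCalibration:
    def test_edge_anchor_slope(self):
        model = logit_approximation(PROBIT_SLOPE, EDGE_DOSE, 0.0292, 5800.0)
        assert model.slope == pytest.approx(2.472, abs=2e-3)
        assert model.link == "logit"

    def test_unit_log_distance_gives_logit_of_p(self):
        # anchor at lc50 x 10 (unit log10 distance): slope equals logit(anchor_p)
        model = logit_approximation(1.0, 5000.0, 0.9, 500.0)
        assert model.slope == pytest.approx(float(logit(0.9)))

    def test_within_crop_anchor_agrees(self):
        """Slopes recovered from the crop-edge (0.0292) and within-crop (0.0805)
        anchors agree to <0.1% relative — the internal consistency on which
        the calibration rests."""
        s_edge = logit_approximation(PROBIT_SLOPE, EDGE_DOSE, 0.0292, 5800.0).slope
        s_crop = logit_approximation(PROBIT_SLOPE, CROP_DOSE, 0.0805, 5800.0).slope
        assert s_crop == pytest.approx(2.470, abs=2e-3)
        assert abs(s_edge - s_crop) / s_edge < 1e-3

    def test_anchor_at_lc50_is_inconsistent(self):
        with pytest.raises(ValueError):
            logit_approximation(PROBIT_SLOPE, 500.0, 0.1, 500.0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_degenerate_anchor_probability_rejected(self, p):
        with pytest.raises(ValueError):
            logit_approximation(PROBIT_SLOPE, 100.0, p, 500.0)

    def test_probit_and_logit_links_nearly_coincide(self):
        """With the standard slope conversion (logistic(x) ~ Phi(x/1.702)) the
        probit and calibrated logit links agree to |dp| < 0.01 over the
        field-relevant dose range 10-1000 grains cm^-2."""
        logit_model = species_model("inachis_io")
        probit_model = DoseResponseModel(
            logit_model.lc50, logit_model.slope / 1.702, link="probit"
        )
        doses = np.linspace(10.0, 1000.0, 2000)
        dp = np.abs(logit_model.mortality(doses) - probit_model.mortality(doses))
        assert dp.max() < 0.01


class TestSpeciesPresets:
    def test_shared_butterfly_model(self):
        assert species_model("inachis_io") == species_model("vanessa_atalanta")
        assert species_model("inachis_io").lc50 == LC50_MON810_BUTTERFLY

    def test_moth_preset_uses_published_lc50_and_shared_slope(self):
        moth = species_model("plutella_xylostella")
        assert moth.lc50 == LC50_MON810_MOTH
        assert moth.slope == BUTTERFLY_LOGIT_SLOPE

    def test_unknown_species(self):
        with pytest.raises(KeyError):
            species_model("danaus_plexippus")

    def test_steep_probit_slope_sensitivity_variant(self):
        """The steep literature probit slope (>5) collapses within-crop
        mortality by orders of magnitude relative to the worst-case default."""
        steep = species_model("inachis_io", probit_slope=5.0)
        assert steep.link == "probit"
        assert steep.mortality(CROP_DOSE) < 1e-6
        assert species_model("inachis_io").mortality(CROP_DOSE) > 0.05
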