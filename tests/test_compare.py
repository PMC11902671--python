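"""Reference volumes, truncated cones, equivalent diameters, Bland-Altman."""
import numpy as np
import pytest

from segmetry.anthro import AnthropometricTable
from segmetry.compare import (
    SegmentResult, bland_altman, delta_d, deltas, equivalent_diameter,
    v_cone, v_ref,
)


@pytest.fixture(scope="module")
def table():
    return AnthropometricTable.default()


class TestVRef:
    def test_mass_fraction_over_density(self):
        import pandas as pd
        t = AnthropometricTable(pd.DataFrame(
            {"segment": ["thigh"], "mass_fraction": [0.10],
             "density_kgm3": [1000.0], "length_fraction": [0.25]}))
        assert v_ref(t, 70.0, "left_thigh") == pytest.approx(0.007)

    def test_missing_segment(self, table):
        with pytest.raises(KeyError):
            v_ref(table, 70.0, "tail")

    def test_default_table_entries_valid(self, table):
        for label in ("head", "left_arm", "right_foot", "thorax"):
            v = v_ref(table, 70.0, label)
            assert 0 < v < 0.05  # plausible m^3 for a 70 kg adult


class TestVCone:
    def test_cylinder_degenerate_case(self):
        r = 0.05
        O = 2 * np.pi * r
        assert v_cone(0.4, O, O) == pytest.approx(np.pi * r ** 2 * 0.4, rel=1e-12)

    def test_hand_computed_value(self):
        # L=0.4, O_p=0.40, O_d=0.20: r_p = 0.0636620, r_d = 0.0318310
        assert v_cone(0.4, 0.40, 0.20) == pytest.approx(0.028 / (3 * np.pi), abs=1e-9)

    def test_symmetric_in_end_circumferences(self):
        assert v_cone(0.37, 0.41, 0.23) == v_cone(0.37, 0.23, 0.41)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            v_cone(0.0, 0.4, 0.2)


class TestEquivalentDiameter:
    def test_inverts_cylinder_volume(self):
        assert equivalent_diameter(np.pi * 0.05 ** 2 * 0.4, 0.4) == pytest.approx(0.10)

    def test_quadrupled_volume_doubles_diameter(self):
        d1 = equivalent_diameter(0.002, 0.4)
        d2 = equivalent_diameter(0.008, 0.4)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_roundtrip_exact(self):
        rng = np.random.default_rng(0)
        for V, L in rng.uniform(0.01, 1.0, (50, 2)):
            D = equivalent_diameter(V, L)
            assert np.pi * D ** 2 * L / 4 == pytest.approx(V, rel=1e-12)


class TestDeltaD:
    def test_equal_diameters_vanish(self):
        assert delta_d(0.1, 0.4, 0.1, 0.4, 1.7) == 0.0

    def test_hand_computed(self):
        # Dhat_scan = 0.11/0.40 = 0.275, Dhat_ref = 0.25, /H = 0.0147059
        assert delta_d(0.11, 0.40, 0.10, 0.40, 1.70) == pytest.approx(
            0.025 / 1.70, rel=1e-9)

    def test_wider_scanner_segment_is_positive(self):
        assert delta_d(0.12, 0.4, 0.10, 0.4, 1.7) > 0

    def test_scan_length_normalization_switch(self):
        a = delta_d(0.11, 0.35, 0.10, 0.40, 1.7, dhat_scan_uses_manual_length=True)
        b = delta_d(0.11, 0.35, 0.10, 0.40, 1.7, dhat_scan_uses_manual_length=False)
        assert b > a  # shorter scan length -> larger normalized diameter


class TestDeltas:
    def test_identity_suite(self):
        """Every delta vanishes when scanner output equals the references."""
        res = SegmentResult(label="left_thigh", V_scan=0.006, L_scan=0.42,
                            M_scan=6.0, V_ref=0.006, V_cone=0.006,
                            L_ref=0.42, L_manual=0.42)
        out = deltas(res, H=1.7, body_mass=70.0)
        assert out.dV_scan_ref == pytest.approx(0.0, abs=1e-15)
        assert out.dV_scan_cone == pytest.approx(0.0, abs=1e-15)
        assert out.dL_scan_ref == pytest.approx(0.0, abs=1e-15)
        assert out.dD == pytest.approx(0.0, abs=1e-12)

    def test_length_delta_normalized_by_height(self):
        res = SegmentResult(label="x", V_scan=0.005, L_scan=0.40, L_manual=0.42)
        out = deltas(res, H=1.70)
        assert out.dL_scan_manual == pytest.approx(-0.02 / 1.70)

    def test_mass_normalized_in_percent(self):
        res = SegmentResult(label="x", V_scan=0.005, M_scan=7.0)
        assert deltas(res, 1.7, body_mass=70.0).M_norm_pct == pytest.approx(10.0)

    def test_invalid_height(self):
        with pytest.raises(ValueError):
            deltas(SegmentResult(label="x", V_scan=0.005), H=0.0)


class TestBlandAltman:
    def test_identical_pairs(self):
        ba = bland_altman([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert ba.mean_diff == 0.0
        assert ba.loa_high - ba.loa_low == 0.0

    def test_constant_offset(self):
        ba = bland_altman([(1.5, 1.0), (2.5, 2.0), (3.5, 3.0)])
        assert ba.mean_diff == pytest.approx(0.5)
        assert ba.sd == pytest.approx(0.0, abs=1e-15)

    def test_sampling_theory_oracle(self):
        """Normal differences (mu=0.5, sd=1, n=1e4): the limits of agreement
        land at 0.5 +/- 1.96 within 3 standard errors."""
        rng = np.random.default_rng(42)
        n = 10_000
        base = rng.normal(10, 2, n)
        pairs = np.column_stack([base + rng.normal(0.5, 1.0, n), base])
        ba = bland_altman(pairs)
        se_loa = np.sqrt(3.0 / n)  # SE of mean +/- 1.96 sd for unit sd
        assert abs(ba.loa_high - (0.5 + 1.96)) < 3 * se_loa
        assert abs(ba.loa_low - (0.5 - 1.96)) < 3 * se_loa

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])


def test_table_validation():
    import pandas as pd
    with pytest.raises(ValueError, match="densities"):
        AnthropometricTable(pd.DataFrame(
            {"segment": ["x"], "mass_fraction": [0.1],
             "density_kgm3": [300.0], "length_fraction": [0.2]}))
    with pytest.raises(ValueError, match="fractions"):
        AnthropometricTable(pd.DataFrame(
            {"segment": ["x"], "mass_fraction": [1.5],
             "density_kgm3": [1000.0], "length_fraction": [0.2]}))


def test_density_fallback_is_1000():
    import pandas as pd
    t = AnthropometricTable(pd.DataFrame(
        {"segment": ["thigh"], "mass_fraction": [0.1],
         "density_kgm3": [np.nan], "length_fraction": [0.2]}))
    assert t.density("left_thigh") == 1000.0


def test_plot_helpers_write_figures(tmp_path):
    import matplotlib
    import pandas as pd

    from segmetry.plots import bland_altman_plot, segment_boxplot

    rng = np.random.default_rng(0)
    ba = bland_altman(np.column_stack([rng.normal(10, 1, 40),
                                       rng.normal(10, 1, 40)]))
    bland_altman_plot(ba, title="agreement", out_path=tmp_path / "ba.png")
    df = pd.DataFrame({"label": ["left_arm"] * 5 + ["right_arm"] * 5,
                       "dD": rng.normal(0, 0.01, 10)})
    segment_boxplot(df, "dD", out_path=tmp_path / "box.png")
    assert (tmp_path / "ba.png").stat().st_size > 0
    assert (tmp_path / "box.png").stat().st_size > 0
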