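import numpy as np
import pytest

from lumpedear import (
    CONDITION_MATRIX,
    Stimulus,
    TransferFunction,
    apply_perturbation,
    assemble_matrices,
    condition_matrix_frame,
    crossover,
    find_resonances,
    first_crossover,
    get_builtin,
    parameter_ratio_report,
    resonances_to_json,
    run_condition_matrix,
    simulate,
    solve_response,
    transfer,
)
from lumpedear.analysis import DB_FLOOR
from lumpedear.solver import FrequencyResponse


def _synthetic_response(f, V, stimulus=None, params=None):
    """FrequencyResponse with prescribed node velocities (for closed forms)."""
    f = np.asarray(f, dtype=float)
    w = 2 * np.pi * f[:, None]
    V = np.asarray(V, dtype=complex)
    return FrequencyResponse(
        frequencies=f, X=V / (1j * w), V=V,
        stimulus=stimulus or Stimulus("BC", 1.0),
        params=params or get_builtin("fitted"),
    )


class TestTransfer:
    def test_identical_motion_hits_db_floor(self, grid):
        V = np.ones((len(grid), 6), dtype=complex)
        tf = transfer(_synthetic_response(grid, V), "X3", "relative")
        assert np.all(tf.ratio == 0)
        assert np.all(tf.magnitude_db == DB_FLOOR)

    def test_double_speed_node_is_zero_db(self, grid):
        V = np.ones((len(grid), 6), dtype=complex)
        V[:, 3] = 2.0
        tf = transfer(_synthetic_response(grid, V), "X3", "relative")
        np.testing.assert_allclose(tf.ratio, 1.0)
        np.testing.assert_allclose(tf.magnitude_db, 0.0, atol=1e-12)
        np.testing.assert_allclose(tf.phase_cycles, 0.0, atol=1e-12)

    def test_umbo_rides_skull_at_low_frequency(self, bc_response):
        tf = transfer(bc_response, "X3", "relative")
        assert tf.magnitude_db[0] < -40.0  # 100 Hz: far below 0 dB

    def test_absolute_equals_relative_plus_one(self, bc_response):
        for node in ("X3", "X5"):
            rel = transfer(bc_response, node, "relative")
            ab = transfer(bc_response, node, "absolute")
            np.testing.assert_array_equal(ab.ratio, rel.ratio + 1.0)

    def test_node_guard(self, bc_response):
        with pytest.raises(ValueError, match="any_node"):
            transfer(bc_response, "X2", "relative")
        tf = transfer(bc_response, "X2", "relative", any_node=True)
        assert tf.node == "X2"

    def test_ac_kind_requires_ac_stimulus(self, bc_response, fitted):
        with pytest.raises(ValueError, match="AC"):
            transfer(bc_response, "X3", "ac")
        resp = simulate(fitted, Stimulus("AC", 2.0))
        tf = transfer(resp, "X3", "ac")
        np.testing.assert_allclose(tf.ratio, resp.V[:, 3] / 2.0)


class TestResonances:
    def test_single_dof_oscillator_peak(self):
        """One-mass oscillator: peak within 1% of its 1 kHz resonance."""
        m, f0 = 1.0, 1000.0
        k = (2 * np.pi * f0) ** 2 * m
        c = 2 * 0.01 * np.sqrt(k * m)  # zeta = 1%
        f = np.geomspace(100, 10000, 512)
        w = 2 * np.pi * f
        H = 1.0 / (k - m * w**2 + 1j * w * c)
        tf = TransferFunction(f, H, kind="relative", node="X3")
        rep = find_resonances(tf)
        assert len(rep.peaks) == 1
        assert rep.peaks[0][0] == pytest.approx(f0, rel=0.01)

    def test_monotone_curve_has_no_extrema(self):
        f = np.geomspace(100, 10000, 128)
        tf = TransferFunction(f, (f / 100.0).astype(complex), "relative", "X3")
        rep = find_resonances(tf)
        assert rep.peaks == () and rep.dips == ()

    def test_umbo_first_resonance_near_2khz(self, bc_response):
        tf = transfer(bc_response, "X3", "relative")
        peaks = find_resonances(tf).peaks
        assert peaks and 1500.0 <= peaks[0][0] <= 2500.0

    def test_grid_too_coarse(self):
        f = np.geomspace(100, 1000, 8)
        tf = TransferFunction(f, np.ones(8, complex), "relative", "X3")
        with pytest.raises(ValueError, match="16"):
            find_resonances(tf)


class TestCrossover:
    def test_identical_curves_never_cross(self, bc_response):
        tf = transfer(bc_response, "X5", "relative")
        assert crossover(tf, tf) == []

    def test_linear_difference_crosses_at_analytic_root(self):
        f = np.geomspace(100, 10000, 256)
        # magnitudes straight lines in log-f crossing at exactly 1 kHz
        a = 10 ** ((np.log10(f) - 3.0) / 20)       # +1 dB per decade through 0 at 1 kHz
        b = 10 ** (-(np.log10(f) - 3.0) / 20)
        tfa = TransferFunction(f, a.astype(complex), "relative", "X5")
        tfb = TransferFunction(f, b.astype(complex), "relative", "X5")
        roots = crossover(tfa, tfb)
        assert len(roots) == 1
        assert roots[0] == pytest.approx(1000.0, rel=1e-9)

    def test_grid_mismatch_rejected(self, bc_response, fitted):
        tf = transfer(bc_response, "X5", "relative")
        other = simulate(fitted, frequencies=np.geomspace(100, 10000, 64))
        with pytest.raises(ValueError, match="grid"):
            crossover(tf, transfer(other, "X5", "relative"))

    def test_malleus_glued_crossover_near_2p5_khz(self, fitted, grid, bc_response):
        p = apply_perturbation(fitted, "malleus_glued")
        glued = solve_response(assemble_matrices(p), Stimulus("BC", 1.0), grid, p)
        fx = first_crossover(
            transfer(glued, "X5", "relative"), transfer(bc_response, "X5", "relative")
        )
        assert fx is not None and fx == pytest.approx(2500.0, rel=0.25)


@pytest.fixture(scope="module")
def results(fitted, grid):
    return run_condition_matrix(fitted, grid)


class TestConditionMatrix:
    def test_runs_all_twelve_protocol_curves(self, results):
        assert len(results) == 12
        assert sum(r.node == "X3" for r in results) == 5
        assert sum(r.node == "X5" for r in results) == 7

    def test_joint_cut_hardly_moves_the_umbo(self, results):
        by = {(r.node, r.chain): r for r in results}
        normal = by[("X3", ("normal",))].relative.magnitude_db
        cut = by[("X3", ("is_joint_cut",))].relative.magnitude_db
        assert np.max(np.abs(cut - normal)) < 3.0

    def test_stapes_glued_suppresses_stapes_everywhere(self, results):
        by = {(r.node, r.chain): r for r in results}
        normal = by[("X5", ("normal",))].relative.magnitude_db
        glued = by[("X5", ("stapes_glued",))].relative.magnitude_db
        assert np.all(glued < normal)

    def test_eardrum_mass_lowers_first_umbo_resonance(self, results):
        by = {(r.node, r.chain): r for r in results}
        f_normal = by[("X3", ("normal",))].resonances.peaks[0][0]
        f_loaded = by[("X3", ("mass_100mg_umbo",))].resonances.peaks[0][0]
        assert f_loaded < f_normal

    def test_absolute_identity_holds_for_every_curve(self, results):
        for r in results:
            np.testing.assert_array_equal(
                r.absolute.ratio, r.relative.ratio + 1.0
            )

    def test_long_format_frame(self, results, grid):
        df = condition_matrix_frame(results)
        assert set(df.columns) == {
            "condition", "node", "kind", "frequency_Hz", "magnitude_db",
            "phase_cycles",
        }
        assert len(df) == 2 * 12 * len(grid)
        assert df.groupby(["condition", "node", "kind"]).ngroups == 24

    def test_resonance_json(self, results, tmp_path):
        import json

        path = tmp_path / "res.json"
        out = resonances_to_json(results, path)
        assert json.loads(path.read_text()) == out
        assert len(out) == 12
        normal = [o for o in out if o["condition"] == "normal" and o["node"] == "X3"]
        assert normal[0]["crossovers_vs_normal"] == []
        assert normal[0]["peaks"][0]["f_hz"] == pytest.approx(2234.0, rel=0.01)


class TestJointCutVariants:
    def test_drained_cochlea_under_both_renderings(self, fitted, grid, results):
        """The joint-cut rendering shifts the drained-cochlea stapes peak.

        Printed rule (K8:=0): resonance near 1.7 kHz; literal rule
        (K6:=0): resonance near 2.5 kHz.  Under neither rendering does
        the drained curve cross the normal stapes curve above 200 Hz.
        """
        normal = next(
            r for r in results if r.node == "X5" and r.chain == ("normal",)
        ).relative
        peaks = {}
        for variant in ("k8", "k6"):
            res = run_condition_matrix(fitted, grid, isjc_variant=variant)
            drained = next(
                r for r in res
                if r.node == "X5" and r.chain == ("is_joint_cut", "cochlea_drained")
            )
            assert len(drained.resonances.peaks) == 1
            peaks[variant] = drained.resonances.peaks[0][0]
            assert first_crossover(drained.relative, normal) is None
        assert peaks["k8"] == pytest.approx(1690.0, rel=0.02)
        assert peaks["k6"] == pytest.approx(2465.0, rel=0.02)


class TestUnadjustedParameterSets:
    @pytest.mark.parametrize("name", ["rosowski_merchant_1995", "feng_gan_2004"])
    def test_rise_then_plateau(self, name, grid):
        """Adopted-model simulations rise below 1 kHz, then flatten.

        The magnitude climbs monotonically over 100-800 Hz and varies less
        over 3-10 kHz than it rose over 0.1-1 kHz, for both the umbo and
        the stapes relative-velocity curves.
        """
        p = get_builtin(name)
        resp = simulate(p, frequencies=grid)
        for node in ("X3", "X5"):
            mag = transfer(resp, node, "relative").magnitude_db
            low = (grid >= 100) & (grid <= 800)
            assert np.all(np.diff(mag[low]) > 0)
            rise = mag[np.argmin(np.abs(grid - 1000))] - mag[0]
            high = (grid >= 3000) & (grid <= 10000)
            variation = mag[high].max() - mag[high].min()
            assert variation < rise


class TestParameterRatios:
    def test_fitted_eardrum_mass_is_five_times_typical(self, fitted):
        df = parameter_ratio_report(fitted, get_builtin("feng_gan_2004"))
        assert df.loc["M2", "ratio"] == pytest.approx(5.0, abs=1e-12)

    def test_identity_ratios(self, fitted):
        df = parameter_ratio_report(fitted, fitted)
        defined = df["ratio"].dropna()
        assert np.allclose(defined, 1.0)

    def test_zero_reference_marked_undefined(self, fitted):
        rm = get_builtin("rosowski_merchant_1995")
        df = parameter_ratio_report(fitted, rm)
        assert np.isnan(df.loc["Km_t", "ratio"])
        assert df.loc["Km_t", "note"] == "undefined ratio"
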