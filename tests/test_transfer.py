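"""Transferability RMSE matrices and their summaries."""

import numpy as np
import pytest

from stericfit.decomposition import PairEnergyCurve
from stericfit.fitting import BuckinghamFit, fit_repulsive
from stericfit.transfer import (
    TransferMatrix,
    build_matrix,
    export_heatmap,
    pooled_fraction_below,
    read_matrix_csv,
    summarize_matrix,
    transfer_rmse,
)

R27 = 2.0 + 0.1 * np.arange(27)


def curve_from(A, B, mol, atom="C"):
    e = A * np.exp(-B * R27)
    return PairEnergyCurve(
        molecule_id=mol, atom_pair=(f"{atom}1", f"{atom}1"),
        separations=R27, e_def=e, e_ct=np.zeros_like(e), e_st=e,
    )


def fits_and_curves(params, atom="C"):
    curves = {m: curve_from(A, B, m, atom) for m, (A, B) in params.items()}
    fits = {
        m: fit_repulsive(c.separations, c.e_def, energy_kind="deformation")
        for m, c in curves.items()
    }
    return fits, curves


class TestTransferRMSE:
    def test_exact_transfer_is_zero(self):
        fits, curves = fits_and_curves({"x": (5e4, 2.5), "y": (5e4, 2.5)})
        c = curves["y"]
        assert transfer_rmse(fits["x"], c.separations, c.e_def) < 1e-8

    def test_self_transfer_equals_fit_rmse(self):
        rng = np.random.default_rng(2)
        e = 5e4 * np.exp(-2.5 * R27) + rng.normal(0, 0.5, R27.size)
        fit = fit_repulsive(R27, e)
        assert transfer_rmse(fit, R27, e) == pytest.approx(fit.rmse, abs=1e-12)

    def test_formula_matches_hand_computation(self):
        fit = BuckinghamFit(A=1000.0, B=1.0, rmse=0.0, n_points=3, fit_range=(1, 3))
        r = np.array([1.0, 2.0])
        e = np.array([400.0, 100.0])
        pred = 1000.0 * np.exp(-r)
        expected = np.sqrt(np.mean((e - pred) ** 2))
        assert transfer_rmse(fit, r, e) == pytest.approx(expected, rel=1e-12)


class TestBuildMatrix:
    def test_diagonal_identity_and_asymmetry(self):
        # noisy curves: each fit differs from its data, so RMSE(X->Y) is
        # generally != RMSE(Y->X), while the diagonal stays the fit RMSE
        rng = np.random.default_rng(5)
        curves = {}
        for i in range(6):
            A, B = rng.uniform(2e4, 1e5), rng.uniform(2.0, 2.8)
            e = A * np.exp(-B * R27) + rng.normal(0, 2.0, R27.size)
            curves[f"m{i}"] = PairEnergyCurve(
                molecule_id=f"m{i}", atom_pair=("C1", "C1"),
                separations=R27, e_def=e, e_ct=np.zeros_like(e), e_st=e,
            )
        fits = {
            m: fit_repulsive(c.separations, c.e_def, energy_kind="deformation")
            for m, c in curves.items()
        }
        m = build_matrix(fits, curves, "deformation", "C")
        for i, mol in enumerate(m.molecules):
            assert m.values[i, i] == pytest.approx(fits[mol].rmse, abs=1e-9)
        assert not np.allclose(m.values, m.values.T)

    def test_identical_parameters_give_zero_matrix(self):
        fits, curves = fits_and_curves({"a": (5e4, 2.5), "b": (5e4, 2.5)})
        m = build_matrix(fits, curves, "deformation", "C")
        assert np.all(m.values < 1e-8)

    def test_pathological_molecules_excluded(self):
        fits, curves = fits_and_curves({"a": (5e4, 2.5), "b": (4e4, 2.4), "c": (3e4, 2.3)})
        fits["b"] = BuckinghamFit(
            A=float("nan"), B=float("nan"), rmse=float("nan"), n_points=27,
            fit_range=(2.0, 4.6), converged=False, pathology="negative_energy",
        )
        m = build_matrix(fits, curves, "deformation", "C")
        assert m.molecules == ("a", "c")
        assert m.excluded == ("b",)

    def test_monotone_degradation_with_parameter_distance(self):
        """For fixed B, transfer RMSE grows with |A_X - A_Y|."""
        ladder = {f"m{i}": (3e4 + 1e4 * i, 2.5) for i in range(5)}
        fits, curves = fits_and_curves(ladder)
        m = build_matrix(fits, curves, "deformation", "C")
        row = m.values[0]  # transfers from the smallest A
        assert all(np.diff(row) > 0)

    def test_no_valid_fits_raises(self):
        fits, curves = fits_and_curves({"a": (5e4, 2.5)})
        fits["a"] = BuckinghamFit(
            A=float("nan"), B=float("nan"), rmse=float("nan"), n_points=27,
            fit_range=(2.0, 4.6), converged=False, pathology="failed",
        )
        with pytest.raises(ValueError, match="no non-pathological"):
            build_matrix(fits, curves, "deformation", "C")


class TestSummaries:
    def hand_matrix(self):
        return TransferMatrix(
            molecules=("a", "b"),
            values=np.array([[1.0, 3.0], [5.0, 2.0]]),
            energy_kind="deformation",
            atom_type="C",
        )

    def test_hand_built_2x2_both_conventions(self):
        m = self.hand_matrix()
        off = summarize_matrix(m, threshold=4.0, include_diagonal=False)
        # off-diagonal entries are 3 and 5
        assert off.average == pytest.approx(4.0)
        assert off.minimum == 3.0 and off.maximum == 5.0
        assert off.pct_below_threshold == pytest.approx(50.0)
        alle = summarize_matrix(m, threshold=4.0, include_diagonal=True)
        # all entries: 1, 3, 5, 2
        assert alle.average == pytest.approx(11.0 / 4.0)
        assert alle.minimum == 1.0 and alle.maximum == 5.0
        assert alle.pct_below_threshold == pytest.approx(75.0)

    def test_zero_matrix_summary(self):
        m = TransferMatrix(("a", "b"), np.zeros((2, 2)), "steric", "O")
        s = summarize_matrix(m, include_diagonal=True)
        assert (s.average, s.minimum, s.maximum) == (0.0, 0.0, 0.0)
        assert s.pct_below_threshold == 100.0

    def test_fraction_invariant_to_molecule_ordering(self):
        rng = np.random.default_rng(8)
        params = {f"m{i}": (rng.uniform(2e4, 1e5), rng.uniform(2.0, 2.8)) for i in range(5)}
        fits, curves = fits_and_curves(params)
        m1 = build_matrix(fits, curves, "deformation", "C", molecule_order=sorted(params))
        m2 = build_matrix(
            fits, curves, "deformation", "C", molecule_order=sorted(params, reverse=True)
        )
        s1 = summarize_matrix(m1)
        s2 = summarize_matrix(m2)
        assert s1.pct_below_threshold == s2.pct_below_threshold
        assert s1.average == pytest.approx(s2.average)

    def test_pooled_fraction(self):
        m1 = self.hand_matrix()  # off-diag 3, 5
        m2 = TransferMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]), "s", "O")
        assert pooled_fraction_below([m1, m2], 4.0) == pytest.approx(75.0)


class TestExport:
    def test_csv_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(1)
        params = {f"m{i}": (rng.uniform(2e4, 1e5), rng.uniform(2.0, 2.8)) for i in range(4)}
        fits, curves = fits_and_curves(params)
        m = build_matrix(fits, curves, "steric", "C")
        p = tmp_path / "matrix.csv"
        export_heatmap(m, p)
        back = read_matrix_csv(p)
        assert back.molecules == m.molecules
        assert back.energy_kind == "steric" and back.atom_type == "C"
        np.testing.assert_allclose(back.values, m.values, rtol=1e-12)

    def test_heatmap_image_written(self, tmp_path):
        fits, curves = fits_and_curves({"a": (5e4, 2.5), "b": (4e4, 2.4)})
        m = build_matrix(fits, curves, "deformation", "C")
        export_heatmap(m, tmp_path / "m.csv", tmp_path / "m.png")
        assert (tmp_path / "m.png").stat().st_size > 0

    def test_excluded_annotation_round_trip(self, tmp_path):
        m = TransferMatrix(("a",), np.zeros((1, 1)), "deformation", "C", excluded=("z",))
        export_heatmap(m, tmp_path / "m.csv")
        assert read_matrix_csv(tmp_path / "m.csv").excluded == ("z",)
        clean = TransferMatrix(("a",), np.zeros((1, 1)), "deformation", "C")
        export_heatmap(clean, tmp_path / "c.csv")
        assert "excluded" not in (tmp_path / "c.csv").read_text()
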