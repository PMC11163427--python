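"""Face-to-face dimer scan construction."""

import math

import numpy as np
import pytest

from stericfit.geometry import (
    GeometryError,
    OverlapError,
    ScanSpec,
    build_dimer_scan,
    carbonyl_plane_normal,
    formaldehyde,
    rotate_methyl_to_max_separation,
)
from stericfit.iqa_io import MonomerGeometry


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestPlaneNormal:
    def test_planar_formaldehyde_normal_is_z(self):
        n = carbonyl_plane_normal(formaldehyde())
        assert abs(n[2]) == pytest.approx(1.0, abs=1e-12)
        assert n[0] == pytest.approx(0.0, abs=1e-12)

    def test_equivariance_under_rotation(self):
        geom = formaldehyde()
        R = random_rotation(4)
        rotated = MonomerGeometry(
            "rot", geom.elements, geom.coords @ R.T, 0, 1, plane_atoms=[0, 1, 2, 3]
        )
        n0 = carbonyl_plane_normal(geom)
        n1 = carbonyl_plane_normal(rotated)
        # equal up to sign
        assert min(np.linalg.norm(n1 - R @ n0), np.linalg.norm(n1 + R @ n0)) < 1e-10

    def test_pyramidalized_geometry_matches_svd_oracle(self):
        # slightly non-planar toy carbonyl
        coords = np.array(
            [[0, 0, 0.05], [0, 1.2, -0.02], [0.9, -0.6, 0.01], [-0.9, -0.6, -0.03]]
        )
        geom = MonomerGeometry("toy", ["C", "O", "H", "H"], coords, 0, 1,
                               plane_atoms=[0, 1, 2, 3])
        n = carbonyl_plane_normal(geom)
        centered = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        oracle = vt[2] / np.linalg.norm(vt[2])
        assert min(np.linalg.norm(n - oracle), np.linalg.norm(n + oracle)) < 1e-12

    def test_collinear_atoms_rejected(self):
        coords = [[0, 0, 0], [0, 1.2, 0], [0, 2.4, 0], [0, -1.2, 0]]
        geom = MonomerGeometry("lin", ["C", "O", "X", "X"], coords,
                               plane_atoms=[0, 1, 2, 3])
        with pytest.raises(GeometryError, match="collinear"):
            carbonyl_plane_normal(geom)


class TestDimerScan:
    def test_frame_count_for_canonical_grid(self):
        spec = ScanSpec(r_min=2.0, r_max=4.6, step=0.1)
        frames = build_dimer_scan(formaldehyde(), spec)
        assert len(frames) == 27

    def test_separations_exact_by_index(self):
        spec = ScanSpec(r_min=2.0, r_max=4.6, step=0.1)
        np.testing.assert_allclose(
            spec.separations, [2.0 + 0.1 * k for k in range(27)], rtol=0, atol=1e-15
        )

    def test_carbon_carbon_distance_exact(self):
        geom = formaldehyde()
        frames = build_dimer_scan(geom, ScanSpec())
        n = geom.n_atoms
        for k, frame in enumerate(frames):
            r_nominal = 2.0 + 0.1 * k
            d = np.linalg.norm(frame.coords[0] - frame.coords[n + 0])
            assert abs(d - r_nominal) < 1e-10

    def test_internal_geometry_rigid(self):
        geom = formaldehyde()
        co = np.linalg.norm(geom.coords[0] - geom.coords[1])
        for frame in build_dimer_scan(geom, ScanSpec()):
            n = geom.n_atoms
            for off in (0, n):
                d = np.linalg.norm(frame.coords[off] - frame.coords[off + 1])
                assert d == pytest.approx(co, abs=1e-12)

    def test_scan_equivariant_under_rigid_motion(self):
        geom = formaldehyde()
        R = random_rotation(9)
        t = np.array([1.0, -2.0, 0.5])
        moved = MonomerGeometry(
            "moved", geom.elements, geom.coords @ R.T + t, 0, 1, plane_atoms=[0, 1, 2, 3]
        )
        f0 = build_dimer_scan(geom, ScanSpec(r_max=2.2))
        f1 = build_dimer_scan(moved, ScanSpec(r_max=2.2))
        for a, b in zip(f0, f1):
            direct = a.coords @ R.T + t
            # normals are defined up to sign: accept the mirror-started scan too
            n = geom.n_atoms
            flipped = np.vstack([a.coords[:n], 2 * a.coords[:n] - a.coords[n:]]) @ R.T + t
            err = min(
                np.abs(direct - b.coords).max(), np.abs(flipped - b.coords).max()
            )
            assert err < 1e-10

    def test_overlap_error_names_atoms(self):
        # bulky substituents 2.05 A out of the plane collide with the other
        # monomer's carbonyl carbon at r = 2.0 (whichever normal sign is used)
        coords = [
            [0, 0, 0], [0, 1.205, 0], [0.9, -0.6, 0],
            [0, -0.4, 2.05], [0, -0.4, -2.05],
        ]
        geom = MonomerGeometry("bulky", ["C", "O", "H", "H", "H"], coords, 0, 1,
                               plane_atoms=[0, 1, 2])
        with pytest.raises(OverlapError, match="H[45]"):
            build_dimer_scan(geom, ScanSpec(r_min=2.0, r_max=2.0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ScanSpec(r_min=0.0)
        with pytest.raises(ValueError):
            ScanSpec(r_min=3.0, r_max=2.0)


def ethanal_like():
    """Toy acetaldehyde: carbonyl plus a methyl group (idealized bond lengths)."""
    ch = 1.09
    # methyl C at (0, -1.5, 0); hydrogens tetrahedral-ish around it
    coords = [
        [0.0, 0.0, 0.0],  # C1 carbonyl
        [0.0, 1.205, 0.0],  # O
        [0.95, -0.55, 0.0],  # H on carbonyl C
        [0.0, -1.5, 0.0],  # C2 methyl carbon
        [0.0, -1.95, ch * 0.94],  # H (eclipsing the scan axis)
        [ch * 0.82, -1.95, -ch * 0.47],  # H
        [-ch * 0.82, -1.95, -ch * 0.47],  # H
    ]
    return MonomerGeometry(
        "ethanal", ["C", "O", "H", "C", "H", "H", "H"], coords, 0, 1,
        plane_atoms=[0, 1, 2, 3]
    )


class TestMethylRotation:
    def make_dimer(self):
        geom = ethanal_like()
        return build_dimer_scan(geom, ScanSpec(r_min=2.0, r_max=2.0))[0]

    def test_objective_maximized_over_grid_oracle(self):
        dimer = self.make_dimer()
        out = rotate_methyl_to_max_separation(dimer, 3, (4, 5, 6), attached_atom=0)
        n = 7
        hs = [4, 5, 6]

        def objective(frame):
            return sum(
                np.linalg.norm(frame.coords[h + n] - frame.coords[h]) for h in hs
            )

        best = objective(out)
        # brute-force oracle on a coarser independent grid
        from stericfit.geometry import _rotate_about_axis

        axis = dimer.coords[3 + n] - dimer.coords[0 + n]
        for ang in np.deg2rad(np.arange(0, 360, 5.0)):
            trial = dimer.coords.copy()
            trial[[h + n for h in hs]] = _rotate_about_axis(
                dimer.coords[[h + n for h in hs]], dimer.coords[3 + n], axis, float(ang)
            )
            trial_frame = MonomerGeometry("t", dimer.elements, trial, 0, 1)
            assert objective(trial_frame) <= best + 1e-9

    def test_eclipsed_methyls_improved(self):
        dimer = self.make_dimer()
        n = 7
        before = sum(
            np.linalg.norm(dimer.coords[h + n] - dimer.coords[h]) for h in (4, 5, 6)
        )
        out = rotate_methyl_to_max_separation(dimer, 3, (4, 5, 6), attached_atom=0)
        after = sum(
            np.linalg.norm(out.coords[h + n] - out.coords[h]) for h in (4, 5, 6)
        )
        assert after > before

    def test_non_methyl_input_rejected(self):
        dimer = self.make_dimer()
        with pytest.raises(ValueError, match="not a carbon"):
            rotate_methyl_to_max_separation(dimer, 1, (4, 5, 6), attached_atom=0)

    def test_untouched_atoms_preserved(self):
        dimer = self.make_dimer()
        out = rotate_methyl_to_max_separation(dimer, 3, (4, 5, 6), attached_atom=0)
        n = 7
        moved = [h + 7 for h in (4, 5, 6)]
        keep = [i for i in range(14) if i not in moved]
        np.testing.assert_array_equal(out.coords[keep], dimer.coords[keep])
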