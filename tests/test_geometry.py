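"""Lattice generation, inversion, and STL round trips."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from scaffoldnet import (LatticeSpec, default_library, invert_lattice,
                         make_implicit_cell, make_strut_grid, porosity,
                         read_stl, sample_field, write_stl)
from scaffoldnet.errors import InvalidSpecError, STLFormatError
from scaffoldnet.geometry import (CUBE_EDGE_MM, mesh_from_spec,
                                  strut_grid_solid_fraction)

L = CUBE_EDGE_MM


class TestStrutGrid:
    def test_full_cube_degenerate(self):
        """strut_width == period == L yields the solid calibration cube."""
        mesh = make_strut_grid(L, L, resolution=32)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(L**3, rel=0.05)
        grid = sample_field(LatticeSpec("strut_grid",
                                        {"period": L, "strut_width": L}), (16, 16, 10))
        assert porosity(grid) == 0.0

    def test_invalid_width_rejected(self):
        with pytest.raises(InvalidSpecError):
            make_strut_grid(2.5, 2.6)
        with pytest.raises(InvalidSpecError):
            make_strut_grid(2.5, -0.1)
        with pytest.raises(InvalidSpecError):
            make_strut_grid(6.0, 0.5)  # period beyond the cube

    def test_porosity_matches_inclusion_exclusion(self):
        """Voxelized porosity agrees with the closed-form strut volume.

        The closed form 3a^2 - 2a^3 is itself cross-checked by
        Monte-Carlo point sampling of the indicator field.
        """
        period, width = 2.5, 0.5
        frac = strut_grid_solid_fraction(period, width)
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, L, size=(200_000, 3))
        spec = LatticeSpec("strut_grid", {"period": period, "strut_width": width})
        from scaffoldnet.geometry import evaluate_field
        mc = evaluate_field(spec, pts).mean()
        assert mc == pytest.approx(frac, abs=0.005)

        mesh = make_strut_grid(period, width)
        # mesh volume fraction within a voxel-surface band of the closed form
        h = L / 100
        surface_tol = mesh.area * h / L**3
        assert abs(mesh.volume / L**3 - frac) <= surface_tol


class TestImplicitCell:
    def test_midpoint_level_is_half_solid(self):
        """At the symmetric level 0 the gyroid field splits ~50/50."""
        grid = sample_field(LatticeSpec("implicit_surface",
                                        {"level": 0.0, "periods": 1}),
                            (64, 64, 64))
        assert grid.mean() == pytest.approx(0.5, abs=0.02)

    def test_solid_fraction_scale_invariant_in_periods(self):
        specs = [LatticeSpec("implicit_surface", {"level": 0.4, "periods": p})
                 for p in (1, 2)]
        f1, f2 = (sample_field(s, (96, 96, 96)).mean() for s in specs)
        assert f1 == pytest.approx(f2, abs=0.01)

    def test_degenerate_level_rejected(self):
        with pytest.raises(InvalidSpecError):
            make_implicit_cell(1.5)
        with pytest.raises(InvalidSpecError):
            make_implicit_cell(-2.0)

    def test_mesh_watertight(self):
        assert make_implicit_cell(0.0, resolution=48).is_watertight


class TestInvertLattice:
    def test_all_material_to_all_void(self):
        g = np.ones((8, 8, 5), np.uint8)
        assert porosity(invert_lattice(g)) == 100.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_involution_and_porosity_complement(self, seed):
        """invert o invert = id and porosity maps p -> 100 - p exactly."""
        g = np.random.default_rng(seed).integers(0, 2, (16, 16, 10)).astype(np.uint8)
        inv = invert_lattice(g)
        assert np.array_equal(invert_lattice(inv), g)
        assert porosity(g) + porosity(inv) == pytest.approx(100.0, abs=1e-12)

    def test_complementary_pair_porosities(self):
        """A 35.2 % porous grid inverts to 64.8 %, like paired lattices."""
        g = np.zeros(1000, np.uint8)
        g[:648] = 1  # 64.8 % material -> porosity 35.2 %
        g = g.reshape(10, 10, 10)
        assert porosity(g) == pytest.approx(35.2)
        assert porosity(invert_lattice(g)) == pytest.approx(64.8)


class TestLibrary:
    def test_library_sizes_and_disjoint_names(self):
        train, test = default_library()
        assert len(train) == 20 and len(test) == 8
        names = [s.name for s in train + test]
        assert len(set(names)) == len(names)

    def test_porosity_span_covers_10_to_90(self):
        train, _ = default_library()
        pors = [porosity(sample_field(s, (32, 32, 20))) for s in train]
        assert min(pors) <= 10.0 and max(pors) >= 90.0

    @pytest.mark.parametrize("index", [0, 9, 14, 19])
    def test_sample_meshes_watertight(self, index):
        train, _ = default_library()
        mesh = mesh_from_spec(train[index], resolution=48)
        assert mesh.is_watertight


class TestSTLRoundTrip:
    def test_binary_round_trip_preserves_triangles(self, tmp_path, unit_cube_mesh):
        path = tmp_path / "cube.stl"
        write_stl(unit_cube_mesh, path)
        back = read_stl(path)
        assert len(back.faces) == len(unit_cube_mesh.faces) == 12
        assert back.volume == pytest.approx(unit_cube_mesh.volume, rel=1e-6)

    def test_ascii_dialect_detection(self, tmp_path, unit_cube_mesh):
        apath = tmp_path / "cube_ascii.stl"
        with open(apath, "wb") as fh:
            fh.write(trimesh.exchange.stl.export_stl_ascii(unit_cube_mesh)
                     .encode())
        bpath = tmp_path / "cube_bin.stl"
        write_stl(unit_cube_mesh, bpath)
        a, b = read_stl(apath), read_stl(bpath)
        assert len(a.faces) == len(b.faces)
        assert a.volume == pytest.approx(b.volume, rel=1e-6)

    def test_truncated_file_names_byte_offset(self, tmp_path, unit_cube_mesh):
        path = tmp_path / "cube.stl"
        write_stl(unit_cube_mesh, path)
        data = path.read_bytes()
        bad = tmp_path / "trunc.stl"
        bad.write_bytes(data[:-37])
        with pytest.raises(STLFormatError, match=rf"byte offset {len(data) - 37}"):
            read_stl(bad)
        tiny = tmp_path / "tiny.stl"
        tiny.write_bytes(b"\x00" * 40)
        with pytest.raises(STLFormatError, match="byte offset 40"):
            read_stl(tiny)
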