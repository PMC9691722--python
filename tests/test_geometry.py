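"""Docking descriptors, contacts, SASA and CDR3 statistics."""

import math

import numpy as np
import pytest

from tcrspec.errors import InvalidParameterError, StructureError
from tcrspec.geometry import (
    ChainAnnotation,
    StructureComplex,
    cdr3_extract,
    com_angle,
    contacts,
    crossing_angle,
    docking_geometry,
    load_structure,
    loop_length_stats,
    normal_tail_percent,
    polar_coordinates,
    sasa,
)
from tcrspec.synth import GeometryFixtureSpec, gen_geometry_fixture, write_structure


def random_rotation(rng):
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


class TestFixtureAngles:
    def test_orthogonal_construction(self):
        cx, _ = gen_geometry_fixture(GeometryFixtureSpec(crossing_angle=90.0))
        assert crossing_angle(cx) == pytest.approx(90.0, abs=1e-6)

    def test_forty_five_degrees(self):
        cx, _ = gen_geometry_fixture(GeometryFixtureSpec(crossing_angle=45.0))
        assert crossing_angle(cx) == pytest.approx(45.0, abs=0.5)

    def test_com_angle_from_construction(self):
        cx, _ = gen_geometry_fixture(GeometryFixtureSpec(com_angle=99.0))
        assert com_angle(cx) == pytest.approx(99.0, abs=0.5)

    def test_com_equals_crossing_when_axes_parallel(self):
        cx, _ = gen_geometry_fixture(
            GeometryFixtureSpec(crossing_angle=70.0, com_angle=70.0)
        )
        assert com_angle(cx) == pytest.approx(crossing_angle(cx), abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_targets_recovered(self, seed):
        rng = np.random.default_rng(200 + seed)
        spec = GeometryFixtureSpec(
            seed=seed,
            crossing_angle=float(rng.uniform(10.0, 170.0)),
            com_angle=float(rng.uniform(10.0, 170.0)),
            theta=float(rng.uniform(-170.0, 170.0)),
            phi=float(rng.uniform(2.0, 80.0)),
            r=float(rng.uniform(20.0, 40.0)),
        )
        cx, targets = gen_geometry_fixture(spec)
        geo = docking_geometry(cx)
        assert geo.crossing_angle == pytest.approx(targets["crossing_angle"], abs=0.5)
        assert geo.com_angle == pytest.approx(targets["com_angle"], abs=0.5)
        assert geo.theta == pytest.approx(targets["theta"], abs=0.5)
        assert geo.phi == pytest.approx(targets["phi"], abs=0.5)
        assert geo.r == pytest.approx(targets["r"], abs=0.1)


class TestPolarCoordinates:
    def test_tcr_directly_overhead(self):
        cx, _ = gen_geometry_fixture(GeometryFixtureSpec(phi=0.0, r=30.0))
        theta, phi, r = polar_coordinates(cx)
        assert phi == pytest.approx(0.0, abs=1e-6)
        assert r == pytest.approx(30.0, abs=1e-6)

    def test_displacement_along_peptide_axis_gives_zero_azimuth(self):
        cx, _ = gen_geometry_fixture(GeometryFixtureSpec(theta=0.0, phi=45.0))
        theta, _, _ = polar_coordinates(cx)
        assert theta == pytest.approx(0.0, abs=1e-6)

    def test_rigid_transform_invariance(self):
        cx, _ = gen_geometry_fixture(GeometryFixtureSpec(seed=5))
        ref = docking_geometry(cx)
        rng = np.random.default_rng(17)
        for _ in range(5):
            moved = cx.transformed(random_rotation(rng), rng.uniform(-50, 50, 3))
            geo = docking_geometry(moved)
            assert geo.crossing_angle == pytest.approx(ref.crossing_angle, abs=1e-6)
            assert geo.com_angle == pytest.approx(ref.com_angle, abs=1e-6)
            assert geo.theta == pytest.approx(ref.theta, abs=1e-6)
            assert geo.phi == pytest.approx(ref.phi, abs=1e-6)
            assert geo.r == pytest.approx(ref.r, abs=1e-6)


class TestStructureIO:
    def test_pdb_roundtrip_preserves_atoms(self, tmp_path):
        cx, _ = gen_geometry_fixture(GeometryFixtureSpec(seed=3))
        path = tmp_path / "fixture.pdb"
        write_structure(cx, path)
        back = load_structure(path, cx.annotation)
        assert len(back) == len(cx)
        np.testing.assert_allclose(back.coords, cx.coords, atol=1.5e-3)

    def test_pdb_and_mmcif_agree(self, tmp_path):
        cx, _ = gen_geometry_fixture(GeometryFixtureSpec(seed=3))
        pdb, cif = tmp_path / "f.pdb", tmp_path / "f.cif"
        write_structure(cx, pdb)
        write_structure(cx, cif)
        a = load_structure(pdb, cx.annotation)
        b = load_structure(cif, cx.annotation)
        np.testing.assert_allclose(a.coords, b.coords, atol=1.5e-3)
        geo_a, geo_b = docking_geometry(a), docking_geometry(b)
        assert geo_a.crossing_angle == pytest.approx(geo_b.crossing_angle, abs=0.01)

    def test_only_first_model_kept(self, tmp_path):
        pdb_text = (
            "MODEL        1\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00 20.00           C\n"
            "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 20.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      3  CA  GLY A   1      99.000  99.000  99.000  1.00 20.00           C\n"
            "ENDMDL\nEND\n"
        )
        path = tmp_path / "two_models.pdb"
        path.write_text(pdb_text)
        ann = ChainAnnotation(tcr_alpha="A", tcr_beta="A", mhc_heavy="A",
                              peptide="A", v_domain_ranges={"A": (1, 2)})
        cx = load_structure(path, ann)
        assert len(cx) == 2
        assert cx.coords.max() < 10.0

    def test_missing_annotated_chain_rejected(self, tmp_path):
        cx, _ = gen_geometry_fixture(GeometryFixtureSpec(seed=3))
        path = tmp_path / "fixture.pdb"
        write_structure(cx, path)
        bad = ChainAnnotation(tcr_alpha="Z", tcr_beta="B", mhc_heavy="M", peptide="P")
        with pytest.raises(StructureError, match="tcr_alpha"):
            load_structure(path, bad)


def _cloud_complex(rng, n_a=250, n_b=250, spread=15.0):
    n = n_a + n_b
    coords = rng.uniform(-spread, spread, size=(n, 3))
    return StructureComplex(
        coords=coords,
        elements=np.array(["C"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        res_numbers=np.arange(1, n + 1),
        res_names=np.array(["ALA"] * n, dtype=object),
        chain_ids=np.array(["A"] * n_a + ["B"] * n_b, dtype=object),
        annotation=ChainAnnotation(tcr_alpha="A", tcr_beta="B", mhc_heavy="A",
                                   peptide="B"),
    )


class TestContacts:
    @pytest.mark.parametrize("distance, expected", [(3.9, 1), (4.1, 0)])
    def test_cutoff_boundary(self, distance, expected):
        cx = _cloud_complex(np.random.default_rng(0), 1, 1)
        cx.coords[0] = (0.0, 0.0, 0.0)
        cx.coords[1] = (distance, 0.0, 0.0)
        table = contacts(cx, cx.chain_ids == "A", cx.chain_ids == "B", cutoff=4.0)
        assert table.n_atom_pairs == expected

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(8)
        cx = _cloud_complex(rng)
        ma, mb = cx.chain_ids == "A", cx.chain_ids == "B"
        table = contacts(cx, ma, mb, cutoff=4.0)
        # O(n^2) oracle
        d = np.linalg.norm(
            cx.coords[ma][:, None, :] - cx.coords[mb][None, :, :], axis=-1
        )
        assert table.n_atom_pairs == int((d <= 4.0).sum())

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(9)
        cx = _cloud_complex(rng)
        ma, mb = cx.chain_ids == "A", cx.chain_ids == "B"
        small = contacts(cx, ma, mb, cutoff=3.5)
        large = contacts(cx, ma, mb, cutoff=4.0)
        keys_small = set(map(tuple, small.pairs.iloc[:, :6].to_numpy()))
        keys_large = set(map(tuple, large.pairs.iloc[:, :6].to_numpy()))
        assert keys_small <= keys_large
        assert small.n_atom_pairs <= large.n_atom_pairs

    def test_overlapping_groups_rejected(self):
        cx = _cloud_complex(np.random.default_rng(0), 5, 5)
        mask = np.ones(len(cx), dtype=bool)
        with pytest.raises(InvalidParameterError):
            contacts(cx, mask, mask)


def _atoms_complex(coords, elements):
    n = len(coords)
    return StructureComplex(
        coords=np.asarray(coords, dtype=float),
        elements=np.array(elements, dtype=object),
        atom_names=np.array(["X"] * n, dtype=object),
        res_numbers=np.arange(1, n + 1),
        res_names=np.array(["UNK"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        annotation=ChainAnnotation(tcr_alpha="A", tcr_beta="A", mhc_heavy="A",
                                   peptide="A"),
    )


class TestSasa:
    def test_isolated_atom_closed_form(self):
        # selenium: vdW 1.9 A, probe 1.4 A -> 4*pi*(3.3)^2
        cx = _atoms_complex([[0.0, 0.0, 0.0]], ["SE"])
        area = sasa(cx)["area_A2"].iloc[0]
        assert area == pytest.approx(4.0 * math.pi * 3.3**2, rel=1e-9)

    def test_distant_atoms_additive(self):
        cx = _atoms_complex([[0, 0, 0], [50, 0, 0]], ["C", "C"])
        areas = sasa(cx)["area_A2"]
        single = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert areas.sum() == pytest.approx(2 * single, rel=1e-9)

    def test_caged_atom_is_buried(self):
        from tcrspec.geometry import _sphere_points

        cage = 2.0 * _sphere_points(80)
        cx = _atoms_complex(
            np.vstack([[0.0, 0.0, 0.0], cage]), ["C"] * 81
        )
        df = sasa(cx)
        center = df[df.res_number == 1]["area_A2"].iloc[0]
        assert center == pytest.approx(0.0, abs=1e-9)

    def test_point_density_convergence(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(-4, 4, size=(20, 3))
        cx = _atoms_complex(coords, ["C"] * 20)
        coarse = sasa(cx, n_points=240)["area_A2"].sum()
        fine = sasa(cx, n_points=960)["area_A2"].sum()
        assert abs(coarse - fine) / fine < 0.02

    def test_unknown_element_rejected(self):
        cx = _atoms_complex([[0.0, 0.0, 0.0]], ["QQ"])
        with pytest.raises(StructureError, match="QQ"):
            sasa(cx)


class TestCdr3:
    def test_motif_rule_extracts_inclusive_loop(self):
        seq = "MDTEVKCQSPAC" + "ASSLGTDTQY" + "FGPGTRLTVT"
        loop, length = cdr3_extract(seq)
        assert loop == "CASSLGTDTQYF"
        assert length == 12

    def test_missing_motif_raises(self):
        with pytest.raises(InvalidParameterError, match="supply explicit"):
            cdr3_extract("MKTAYIVCQDPAKLMC")

    def test_explicit_boundaries_override(self):
        seq = "AAAACBBBBBFCCCC"
        loop, length = cdr3_extract(seq, boundaries=(4, 10))
        assert loop == "CBBBBBF"
        assert length == 7

    def test_planted_loop_roundtrip(self):
        planted = "CASSPGLAGEYEQYF"
        scaffold = "MGVTQCPRYLIK" + planted + "FGSGTRLTVL"
        # note: the planted loop's own F is followed by FGSG; the motif F is
        # the first [FW]G.G hit, which is the J-region one
        loop, length = cdr3_extract(scaffold)
        assert loop.startswith("CASS")
        assert loop.endswith("F")
        assert length == len(planted) + 1  # includes the J-region F


class TestLoopLengthStats:
    def test_query_at_mean_gives_half_tail(self):
        stats = loop_length_stats([12, 14, 16, 12, 14, 16], 14)
        assert stats.z_score == pytest.approx(0.0)
        assert stats.normal_tail_percent == pytest.approx(50.0)

    def test_outlier_loop_tail(self):
        # published repertoire scale: mean 13.9, SD 1.9, query 20
        tail = normal_tail_percent(13.9, 1.9, 20)
        assert (20 - 13.9) / 1.9 == pytest.approx(3.2105, abs=1e-3)
        assert tail == pytest.approx(0.066, abs=0.01)
        assert tail < 1.0

    def test_degenerate_sample_flagged(self):
        stats = loop_length_stats([14, 14, 14], 20)
        assert stats.degenerate
        assert stats.normal_tail_percent == 0.0

    def test_empirical_tail_counted(self):
        stats = loop_length_stats([10, 12, 14, 20, 22], 20)
        assert stats.empirical_tail_percent == pytest.approx(40.0)
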