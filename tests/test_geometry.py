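"""Mesh construction: volumes, region tagging, patches, probe lines."""

import logging

import numpy as np
import pytest

from lnchemosim import ConfigurationError, GeometryParams, RegionId, \
    build_mesh, probe_lines
from lnchemosim.geometry import PATCHES
from lnchemosim.analysis import sample_field


def quarter_sphere_volume(radius):
    return np.pi * radius ** 3 / 3.0


def mc_region_fractions(params: GeometryParams, n=400_000, seed=7):
    """Independent Monte-Carlo oracle for region volumes from the CSG
    definition (sphere + shell + follicle spheres + polar medulla cap)."""
    rng = np.random.default_rng(seed)
    R = params.radius
    pts = rng.uniform(-R, R, (n, 3))
    pts[:, :2] = np.abs(pts[:, :2])          # quarter domain x, y >= 0
    r = np.linalg.norm(pts, axis=1)
    keep = r < R
    pts, r = pts[keep], r[keep]
    th = np.arccos(pts[:, 2] / r)
    reg = np.full(len(pts), int(RegionId.TCELL_AREA))
    reg[r >= params.floor_radius] = int(RegionId.SCS)
    par = r < params.floor_radius
    reg[par & (th >= np.radians(params.medulla_polar_deg))] = \
        int(RegionId.MEDULLA)
    for c in params.follicle_centers():
        d = np.linalg.norm(pts - c, axis=1)
        reg[par & (d < params.follicle_radius)] = int(RegionId.BFOLLICLE)
    vq = quarter_sphere_volume(R)
    return {rid: (reg == int(rid)).mean() * vq
            for rid in (RegionId.SCS, RegionId.BFOLLICLE,
                        RegionId.TCELL_AREA, RegionId.MEDULLA)}


class TestVolumes:
    def test_node_volume_is_exact(self, mesh_default):
        """The spherical-metric cell volumes sum to the analytic quarter-node
        volume (vessel stubs excluded) to round-off."""
        in_node = np.linalg.norm(mesh_default.centroid, axis=1) \
            < mesh_default.params.radius
        total = mesh_default.volume[in_node].sum()
        assert total == pytest.approx(
            quarter_sphere_volume(mesh_default.params.radius), rel=1e-12)

    def test_scs_shell_volume_analytic(self, mesh_default):
        p = mesh_default.params
        shell = (np.pi / 3.0) * (p.radius ** 3 - p.floor_radius ** 3)
        assert mesh_default.region_volume(RegionId.SCS) == pytest.approx(
            shell, rel=1e-9)

    def test_region_volumes_match_mc_oracle(self, mesh_default):
        oracle = mc_region_fractions(mesh_default.params)
        for rid, v_mc in oracle.items():
            v = mesh_default.region_volume(rid)
            assert v == pytest.approx(v_mc, rel=0.03), rid.name

    def test_region_volumes_converge_under_refinement(self, config):
        coarse = build_mesh(config.geometry, 3.0)
        fine = build_mesh(config.geometry, 6.0)
        for rid in (RegionId.SCS, RegionId.BFOLLICLE, RegionId.TCELL_AREA,
                    RegionId.MEDULLA):
            assert fine.region_volume(rid) == pytest.approx(
                coarse.region_volume(rid), rel=0.01), rid.name


class TestTopology:
    def test_interior_faces_are_conforming(self, mesh_lowres):
        m = mesh_lowres
        assert np.all(m.face_owner != m.face_neigh)
        assert np.all(m.face_area >= 0)
        assert np.all(m.face_dist > 0)

    def test_every_boundary_face_has_one_patch(self, mesh_lowres):
        assert np.all((mesh_lowres.bnd_patch >= 0)
                      & (mesh_lowres.bnd_patch < len(PATCHES)))

    def test_symmetry_patches_lie_on_coordinate_planes(self, mesh_lowres):
        m = mesh_lowres
        x_faces = m.patch_faces("SYMMETRY_X")
        y_faces = m.patch_faces("SYMMETRY_Y")
        assert len(x_faces) and len(y_faces)
        assert np.allclose(m.bnd_pos[x_faces][:, 0], 0.0, atol=1e-9)
        assert np.allclose(m.bnd_pos[y_faces][:, 1], 0.0, atol=1e-9)

    def test_path_from_inlet_to_outlet(self, mesh_lowres):
        """Lymph can percolate cell-to-cell from the afferent inlet through
        SCS and medulla to the efferent outlet."""
        m = mesh_lowres
        start = set(m.bnd_cell[m.patch_faces("AFFERENT_INLET")])
        goal = set(m.bnd_cell[m.patch_faces("EFFERENT_OUTLET")])
        adj = m.adjacency()
        seen = set(start)
        stack = list(start)
        while stack:
            c = stack.pop()
            for nb in adj[c]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        assert goal & seen
        regions_crossed = {RegionId(m.region[c]) for c in seen}
        assert RegionId.SCS in regions_crossed
        assert RegionId.MEDULLA in regions_crossed

    def test_follicles_touch_only_scs_and_tcell_area(self, mesh_lowres):
        m = mesh_lowres
        bf = int(RegionId.BFOLLICLE)
        allowed = {bf, int(RegionId.SCS), int(RegionId.TCELL_AREA)}
        for o, n in zip(m.face_owner, m.face_neigh):
            if m.region[o] == bf or m.region[n] == bf:
                assert m.region[o] in allowed and m.region[n] in allowed


class TestProbeLines:
    def test_lines_start_on_ceiling_and_point_inward(self, mesh_default):
        for line in probe_lines(mesh_default):
            assert np.linalg.norm(line.start) == pytest.approx(
                mesh_default.params.radius)
            assert np.dot(line.direction, line.start) < 0
            assert line.length >= 400

    def test_ifr_line_first_10um_in_scs(self, mesh_default):
        line = {l.name: l for l in probe_lines(mesh_default)}["IFR_ARROW"]
        region = sample_field(mesh_default,
                              mesh_default.region.astype(float),
                              line.points[line.positions < 9.0])
        assert np.allclose(region, int(RegionId.SCS))

    def test_bftc_line_crosses_border_at_expected_depth(self, mesh_default):
        m = mesh_default
        line = {l.name: l for l in probe_lines(m)}["BFTC_ARROW"]
        # nearest-cell region along the line (no interpolation smoothing)
        pts = line.points
        r = np.linalg.norm(pts, axis=1)
        regions = []
        for p_, rr in zip(pts, r):
            d2 = np.sum((m.centroid - p_) ** 2, axis=1)
            regions.append(m.region[np.argmin(d2)])
        regions = np.array(regions)
        bf = line.positions[regions == int(RegionId.BFOLLICLE)]
        assert len(bf)
        expected = m.params.scs_thickness + m.params.bf_tc_border_depth
        assert abs(bf.max() - expected) < 15.0   # within ~1 cell
        # exactly one BF -> TC transition
        trans = np.flatnonzero(
            (regions[:-1] == int(RegionId.BFOLLICLE))
            & (regions[1:] == int(RegionId.TCELL_AREA)))
        assert len(trans) == 1

    def test_no_follicles_drops_bftc_line(self, caplog):
        params = GeometryParams(n_follicles_per_quarter=0)
        mesh = build_mesh(params, 2.0)
        with caplog.at_level(logging.WARNING):
            lines = probe_lines(mesh)
        assert [l.name for l in lines] == ["IFR_ARROW"]
        assert any("BFTC" in rec.message for rec in caplog.records)


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(node_diameter=-1),
        dict(scs_thickness=200.0),
        dict(bf_tc_border_depth=600.0),
        dict(follicle_radius=250.0),                  # exceeds border depth
        dict(follicle_polar_deg=100.0),               # overlaps medulla
        dict(follicle_azimuth_deg=(0.0, 10.0)),       # follicles overlap
    ])
    def test_infeasible_geometry_raises(self, kwargs):
        with pytest.raises(ConfigurationError):
            build_mesh(GeometryParams(**kwargs), 2.0)

    def test_resolution_floor(self):
        with pytest.raises(ConfigurationError):
            build_mesh(GeometryParams(), 1.0)
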