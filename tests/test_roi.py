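"""ROI binning, volume weighting and grouped summaries."""

import numpy as np
import pandas as pd
import pytest

from arraystrain.fem import StrainField
from arraystrain.meshing import box_mesh
from arraystrain.roi import (
    ROIError,
    electrode_strain_table,
    group_strains,
    max_strain,
    roi_profile,
    volume_weighted_average,
)


def make_field(mesh, fn):
    """Strain field whose von Mises values follow fn(points)."""
    vm = fn(mesh.points)
    n = mesh.n_nodes
    return StrainField(hencky=np.zeros((n, 3, 3)), von_mises=vm,
                       valid=np.ones(n, bool))


@pytest.fixture(scope="module")
def dense_mesh():
    # 120 um cube around the origin; ~2.6 um nodal spacing with midsides
    return box_mesh([-60, -60, -60], [60, 60, 60], 23)


def test_constant_field_every_bin_mean_is_constant(dense_mesh):
    f = make_field(dense_mesh, lambda p: np.full(len(p), 0.37))
    prof = roi_profile(dense_mesh, f, [0, 0, 0], radius=50.0)
    ok = prof.bin_counts > 0
    assert np.allclose(prof.bin_means[ok], 0.37)
    assert volume_weighted_average(prof) == pytest.approx(0.37)
    assert max_strain(dense_mesh, f, [0, 0, 0]) == pytest.approx(0.37)


def test_linear_radial_field_bins_increase(dense_mesh):
    f = make_field(dense_mesh,
                   lambda p: np.linalg.norm(p, axis=1) / 50.0)
    prof = roi_profile(dense_mesh, f, [0, 0, 0], radius=50.0)
    means = prof.bin_means[prof.bin_counts > 0]
    assert np.all(np.diff(means) > 0)


def test_volume_weighted_average_of_linear_radial_field(dense_mesh):
    # int r * r^2 dr / int r^2 dr = 3R/4 -> eps = (3R/4)/50 = 0.75 at R = 50
    f = make_field(dense_mesh,
                   lambda p: np.linalg.norm(p, axis=1) / 50.0)
    prof = roi_profile(dense_mesh, f, [0, 0, 0], radius=50.0)
    assert volume_weighted_average(prof) == pytest.approx(0.75, rel=0.02)


def test_bin_edges_cover_exactly_0_to_50():
    mesh = box_mesh([-60, -60, -60], [60, 60, 60], 8)
    f = make_field(mesh, lambda p: np.ones(len(p)))
    prof = roi_profile(mesh, f, [0, 0, 0], radius=50.0, bin_width=2.5)
    assert prof.n_bins == 20
    assert prof.bin_edges[0] == 0.0
    assert prof.bin_edges[-1] == pytest.approx(50.0)
    # shell volumes are the ideal spherical shells
    v = (4 * np.pi / 3) * (prof.bin_edges[1:] ** 3 - prof.bin_edges[:-1] ** 3)
    assert np.allclose(prof.shell_volumes, v)


def test_bin_refinement_consistency(dense_mesh):
    """Halving the bin width changes the volume-weighted average by < 1%
    for a smooth field."""
    f = make_field(dense_mesh,
                   lambda p: 0.1 + np.linalg.norm(p, axis=1) ** 2 / 2500.0)
    a1 = volume_weighted_average(
        roi_profile(dense_mesh, f, [0, 0, 0], radius=50.0, bin_width=2.5))
    a2 = volume_weighted_average(
        roi_profile(dense_mesh, f, [0, 0, 0], radius=50.0, bin_width=1.25))
    assert a2 == pytest.approx(a1, rel=0.01)


def test_max_strain_matches_brute_force(dense_mesh):
    rng = np.random.default_rng(0)
    vals = rng.random(dense_mesh.n_nodes)
    f = StrainField(hencky=np.zeros((dense_mesh.n_nodes, 3, 3)),
                    von_mises=vals, valid=np.ones(dense_mesh.n_nodes, bool))
    tip = np.array([5.0, -3.0, 2.0])
    d = np.linalg.norm(dense_mesh.points - tip, axis=1)
    expect = vals[d <= 50.0].max()
    assert max_strain(dense_mesh, f, tip) == pytest.approx(expect)


def test_planted_spike_node_is_the_max(dense_mesh):
    vals = np.full(dense_mesh.n_nodes, 0.01)
    vals[1234] = 5.0
    f = StrainField(hencky=np.zeros((dense_mesh.n_nodes, 3, 3)),
                    von_mises=vals, valid=np.ones(dense_mesh.n_nodes, bool))
    tip = dense_mesh.points[1234]
    assert max_strain(dense_mesh, f, tip) == pytest.approx(5.0)


def test_empty_roi_raises():
    mesh = box_mesh([0, 0, 0], [10, 10, 10], 2)
    f = make_field(mesh, lambda p: np.ones(len(p)))
    with pytest.raises(ROIError):
        roi_profile(mesh, f, [500.0, 500.0, 500.0], radius=50.0)
    with pytest.raises(ROIError):
        max_strain(mesh, f, [500.0, 500.0, 500.0])


def test_truncated_roi_flagged():
    mesh = box_mesh([0, 0, 0], [60, 60, 60], 6)
    f = make_field(mesh, lambda p: np.ones(len(p)))
    with pytest.warns(UserWarning):
        prof = roi_profile(mesh, f, [5.0, 30.0, 30.0], radius=50.0,
                           domain_bounds=([0, 0, 0], [60, 60, 60]))
    assert prof.truncated


def test_single_nonempty_bin_average_is_that_bin():
    mesh = box_mesh([-60, -60, -60], [60, 60, 60], 6)
    f = make_field(mesh, lambda p: np.full(len(p), 2.0))
    prof = roi_profile(mesh, f, [0, 0, 0], radius=50.0, bin_width=2.5)
    # keep only one bin artificially
    prof.bin_counts[:] = 0
    prof.bin_counts[7] = 4
    prof.bin_means[:] = np.nan
    prof.bin_means[7] = 1.25
    assert volume_weighted_average(prof) == pytest.approx(1.25)


def test_group_strains_trivial_and_planted():
    table = pd.DataFrame({
        "electrode_id": np.arange(16),
        "ring_label": np.repeat([1, 2], 8),
        "is_corner": [False] * 12 + [True] * 4,
        "dist_center": np.linspace(0, 100, 16),
        "avg_strain": np.repeat([1.0, 2.0], 8),
    })
    g = group_strains(table, mode="ring")
    by = {r["group"]: r for _, r in g.iterrows()}
    assert by["ring1"]["mean"] == pytest.approx(1.0)
    assert by["ring1"]["sd"] == pytest.approx(0.0)
    assert by["corner"]["n"] == 4
    # planted strains equal to ring labels are recovered exactly
    table2 = table.assign(avg_strain=table["ring_label"].astype(float))
    g2 = group_strains(table2.assign(is_corner=False), mode="ring")
    for _, row in g2.iterrows():
        assert row["mean"] == pytest.approx(float(row["group"][-1]))


def test_ring_mode_group_count_10x10():
    table = pd.DataFrame({
        "electrode_id": np.arange(100),
        "ring_label": __import__("arraystrain.geometry", fromlist=["ring_labels"]
                                 ).ring_labels(10, 10),
        "is_corner": __import__("arraystrain.geometry", fromlist=["corner_mask"]
                                ).corner_mask(10, 10),
        "dist_center": np.ones(100),
        "avg_strain": np.random.default_rng(1).random(100),
    })
    g = group_strains(table, mode="ring")
    assert len(g) == 6  # 5 rings + corner


def test_radial_distance_mode():
    table = pd.DataFrame({
        "electrode_id": np.arange(20),
        "ring_label": np.ones(20, int),
        "is_corner": False,
        "dist_center": np.linspace(0, 99, 20),
        "avg_strain": np.linspace(0, 1, 20),
    })
    g = group_strains(table, mode="radial_distance", n_distance_bins=4)
    assert len(g) == 4
    assert g["n"].sum() == 20
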