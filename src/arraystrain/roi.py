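"""Per-electrode strain summaries in the 50 um recording volume.

A sphere of radius 50 um around each electrode tip approximates the volume
from which single units can be recorded.  Nodal von Mises strains are
averaged in 2.5 um radial bins from the tip, and the bin means are weighted
by the ideal spherical-shell volumes to obtain a mesh-density-unbiased
average strain; the maximum is the largest nodal strain in the sphere.
Bins are half-open [r_lo, r_hi); only tissue nodes enter the ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import StrainField
from .geometry import ElectrodeLayout
from .meshing import Mesh

__all__ = [
    "ROIProfile",
    "roi_profile",
    "volume_weighted_average",
    "max_strain",
    "electrode_strain_table",
    "group_strains",
    "ROIError",
]


class ROIError(ValueError):
    """Raised for empty or invalid regions of interest."""


@dataclass
class ROIProfile:
    """Radially binned strain profile around one electrode tip."""

    electrode_id: int
    bin_edges: np.ndarray  # (n_bins + 1,)
    bin_means: np.ndarray  # (n_bins,), NaN where empty
    bin_counts: np.ndarray  # (n_bins,)
    shell_volumes: np.ndarray  # (n_bins,), ideal (4pi/3)(r_out^3 - r_in^3)
    truncated: bool = False  # ROI sphere extends outside the tissue block

    @property
    def n_bins(self) -> int:
        return len(self.bin_means)


def _roi_nodes(mesh: Mesh, strain: StrainField, tip: np.ndarray,
               radius: float) -> tuple[np.ndarray, np.ndarray]:
    """(distances, von Mises values) of valid tissue nodes within radius."""
    pts = mesh.points
    d = np.linalg.norm(pts - np.asarray(tip, dtype=float), axis=1)
    sel = (d <= radius) & strain.valid
    return d[sel], strain.von_mises[sel]


def roi_profile(mesh: Mesh, strain: StrainField, tip, electrode_id: int = 0,
                radius: float = 50.0, bin_width: float = 2.5,
                domain_bounds: tuple | None = None) -> ROIProfile:
    """Bin nodal strains by distance from the tip (half-open bins).

    Raises :class:`ROIError` when no node lies within ``radius``; warns and
    flags truncation when the sphere extends outside the tissue block.
    """
    tip = np.asarray(tip, dtype=float)
    n_bins = int(round(radius / bin_width))
    if abs(n_bins * bin_width - radius) > 1e-9:
        raise ROIError("radius must be an integer multiple of bin_width")
    d, vm = _roi_nodes(mesh, strain, tip, radius)
    if len(d) == 0:
        raise ROIError(f"no strain nodes within {radius} um of tip "
                       f"{tip.tolist()}")
    edges = bin_width * np.arange(n_bins + 1)
    idx = np.minimum((d / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vm, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    shells = (4.0 * np.pi / 3.0) * (edges[1:] ** 3 - edges[:-1] ** 3)
    truncated = False
    if domain_bounds is not None:
        lo, hi = (np.asarray(b, dtype=float) for b in domain_bounds)
        if np.any(tip - radius < lo) or np.any(tip + radius > hi):
            truncated = True
            warnings.warn(
                f"ROI sphere at {tip.tolist()} extends outside the tissue "
                "block; shell volumes are not truncation-corrected",
                stacklevel=2)
    return ROIProfile(electrode_id=electrode_id, bin_edges=edges,
                      bin_means=means, bin_counts=counts,
                      shell_volumes=shells, truncated=truncated)


def volume_weighted_average(profile: ROIProfile) -> float:
    """Shell-volume-weighted mean of the bin means over non-empty bins."""
    ok = profile.bin_counts > 0
    if not np.any(ok):
        raise ROIError("all ROI bins are empty")
    w = profile.shell_volumes[ok]
    return float(np.sum(profile.bin_means[ok] * w) / np.sum(w))


def max_strain(mesh: Mesh, strain: StrainField, tip,
               radius: float = 50.0) -> float:
    """Largest nodal von Mises strain within the ROI sphere."""
    d, vm = _roi_nodes(mesh, strain, tip, radius)
    if len(d) == 0:
        raise ROIError("empty ROI")
    return float(vm.max())


def profiles_to_frame(profiles: list[ROIProfile]) -> pd.DataFrame:
    """Long-format table: electrode, bin_lo, bin_hi, mean, n."""
    rows = []
    for p in profiles:
        for k in range(p.n_bins):
            rows.append({
                "electrode_id": p.electrode_id,
                "bin_lo": p.bin_edges[k],
                "bin_hi": p.bin_edges[k + 1],
                "mean": p.bin_means[k],
                "n": int(p.bin_counts[k]),
            })
    return pd.DataFrame(rows)


def electrode_strain_table(mesh: Mesh, strain: StrainField,
                           layout: ElectrodeLayout,
                           radius: float = 50.0,
                           bin_width: float = 2.5) -> pd.DataFrame:
    """Per-electrode ROI summary joined with the layout table.

    Columns: the layout columns plus avg_strain (volume-weighted),
    max_strain, roi_truncated.
    """
    lo = mesh.points.min(axis=0)
    hi = mesh.points.max(axis=0)
    tips = layout.table[["tip_x", "tip_y", "tip_z"]].to_numpy()
    avg = np.empty(len(tips))
    mx = np.empty(len(tips))
    trunc = np.zeros(len(tips), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, tip in enumerate(tips):
            prof = roi_profile(mesh, strain, tip, electrode_id=i,
                               radius=radius, bin_width=bin_width,
                               domain_bounds=(lo, hi))
            avg[i] = volume_weighted_average(prof)
            mx[i] = max_strain(mesh, strain, tip, radius)
            trunc[i] = prof.truncated
    out = layout.table.copy()
    out["avg_strain"] = avg
    out["max_strain"] = mx
    out["roi_truncated"] = trunc
    out["group3"] = layout.group3().to_numpy()
    return out


def group_strains(table: pd.DataFrame, mode: str = "ring",
                  value: str = "avg_strain",
                  n_distance_bins: int = 5) -> pd.DataFrame:
    """Grouped strain summary by concentric ring or distance from center.

    ``ring`` groups by ring label with corners split out; ``radial_distance``
    bins the tip distance from the array center into ``n_distance_bins``
    equal-width bins.  Returns group label, n, mean, sd and the member
    electrode ids (a list column feeding the ANOVA stage).
    """
    t = table.copy()
    if mode == "ring":
        lab = np.where(t["is_corner"], "corner",
                       "ring" + t["ring_label"].astype(str))
    elif mode == "radial_distance":
        d = t["dist_center"].to_numpy()
        edges = np.linspace(0.0, d.max() + 1e-9, n_distance_bins + 1)
        lab = np.array([f"d{k}" for k in
                        np.clip(np.digitize(d, edges) - 1, 0,
                                n_distance_bins - 1)])
    else:
        raise ValueError("mode must be 'ring' or 'radial_distance'")
    t["group"] = lab
    rows = []
    for g, sub in t.groupby("group", sort=True):
        rows.append({
            "group": g,
            "n": len(sub),
            "mean": float(sub[value].mean()),
            "sd": float(sub[value].std(ddof=1)) if len(sub) > 1 else 0.0,
            "members": sub["electrode_id"].tolist(),
            "values": sub[value].tolist(),
        })
    return pd.DataFrame(rows)
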