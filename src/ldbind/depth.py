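"""Residue-wise membrane penetration-depth probability maps.

The penetration depth of residue i at frame t is |z_i(t) - z_center(t)|,
the absolute distance of the residue's heavy-atom centre of geometry from
the membrane centre (leaflets folded together by the absolute value, since a
symmetric patch can be approached from either side).  Per-residue depth
histograms are normalised by their own maximum, P_i(z) / P_i(max), so every
residue row peaks at exactly 1 and rows are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MembraneGeometry, Trajectory, select_atoms

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1.0
DEFAULT_Z_MAX = 60.0


def residue_depth_series(
    traj: Trajectory,
    residue_index: int,
    geometry: MembraneGeometry,
    use_calpha: bool = False,
) -> np.ndarray:
    """Per-frame |z_cog - center_z| of one residue (heavy-atom centre of
    geometry by default; ``use_calpha`` restricts to the CA atom)."""
    top = traj.topology
    idx = select_atoms(top, role="protein", residue_index=residue_index,
                       is_heavy=True)
    if use_calpha:
        idx = idx[top.atom_name[idx] == "CA"]
    if idx.size == 0:
        raise ValueError(f"residue {residue_index} has no heavy atoms")
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        out[k] = abs(frame.coords[idx, 2].mean() - geometry.center_z[k])
    return out


def depth_histogram(
    series: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    z_max: float = DEFAULT_Z_MAX,
) -> np.ndarray:
    """Occupancy counts over half-open bins [k w, (k+1) w) up to z_max.

    Depths >= z_max are clipped into the last bin with a logged warning.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty depth series")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(np.ceil(z_max / bin_width))
    idx = np.floor(series / bin_width).astype(int)
    n_clipped = int((idx >= n_bins).sum())
    if n_clipped:
        logger.warning("%d depth value(s) >= %.1f A clipped into the last bin",
                       n_clipped, z_max)
        idx = np.minimum(idx, n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(float)


def relative_probability(counts: np.ndarray) -> np.ndarray:
    """Row(s) of counts divided by the row maximum: P(z) / P(max) in [0, 1]."""
    counts = np.asarray(counts, dtype=float)
    m = counts.max(axis=-1, keepdims=True)
    if np.any(m <= 0):
        raise ValueError("all-zero count row cannot be normalised")
    return counts / m


@dataclass
class DepthMap:
    """Per-residue depth histograms and their max-normalised relative rows."""

    residue_ids: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray     # (n_residues, n_bins)
    relative: np.ndarray   # rows in [0, 1], each with maximum exactly 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def modal_depth(self) -> np.ndarray:
        """Depth (bin centre) of the most occupied bin per residue."""
        return self.bin_centers[np.argmax(self.counts, axis=1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.relative, index=self.residue_ids,
                            columns=np.round(self.bin_centers, 2))


def depth_map(
    traj: Trajectory,
    geometry: MembraneGeometry,
    bin_width: float = DEFAULT_BIN_WIDTH,
    z_max: float = DEFAULT_Z_MAX,
    use_calpha: bool = False,
) -> DepthMap:
    """Depth histograms for every protein residue, max-normalised per row."""
    residue_ids = traj.topology.protein_residue_ids()
    if residue_ids.size == 0:
        raise ValueError("trajectory contains no protein residues")
    rows = [depth_histogram(
        residue_depth_series(traj, int(r), geometry, use_calpha=use_calpha),
        bin_width, z_max) for r in residue_ids]
    counts = np.vstack(rows)
    n_bins = counts.shape[1]
    edges = np.arange(n_bins + 1) * bin_width
    return DepthMap(residue_ids, edges, counts, relative_probability(counts))
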