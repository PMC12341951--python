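"""Per-residue protein-membrane contact numbers and bound-state detection.

The contact number of residue i at frame t is

    C_i(t) = sum over heavy-atom pairs (a in residue i, b in membrane)
             with d_ab <= 5 A of  1 / (1 + exp(5 (d_ab - 4)))

with d in A and the minimum-image convention applied in x, y.  Pairs beyond
the 5 A prefilter contribute exactly zero (the kernel is < 0.007 there, a
truncation of < 0.7% per pair).  A residue is in a *bound conformation* at
frame t when C_i(t) > 25 (strict); per-residue averages are taken over bound
frames only and reported as a cumulative sum over residue index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Topology, Trajectory, select_atoms
from .roles import MEMBRANE_ROLES

DEFAULT_CUTOFF = 5.0
DEFAULT_THRESHOLD = 25.0


def contact_kernel(d) -> np.ndarray | float:
    """Distance-weighted contact function 1 / (1 + e^{5 (d - 4)}), d in A."""
    d = np.asarray(d, dtype=float)
    out = 1.0 / (1.0 + np.exp(np.clip(5.0 * (d - 4.0), -500, 500)))
    return float(out) if out.ndim == 0 else out


def _pair_distances_xy_periodic(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) distance matrix, minimum image in x and y."""
    d = a[:, None, :] - b[None, :, :]
    for axis in (0, 1):
        L = box[axis]
        d[..., axis] -= L * np.round(d[..., axis] / L)
    return np.sqrt((d ** 2).sum(axis=-1))


def residue_contact_series(
    traj: Trajectory,
    residue_index: int,
    membrane_selection: np.ndarray | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """Per-frame contact number C_i(t) of one protein residue."""
    top = traj.topology
    res_idx = select_atoms(top, role="protein", residue_index=residue_index,
                           is_heavy=True)
    if res_idx.size == 0:
        raise ValueError(f"residue {residue_index} has no protein heavy atoms")
    mem_idx = _membrane_selection(top, membrane_selection)
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        a, b = _z_prefilter(frame.coords, res_idx, mem_idx, cutoff)
        if a.size == 0 or b.size == 0:
            out[k] = 0.0
            continue
        d = _pair_distances_xy_periodic(frame.coords[a], frame.coords[b],
                                        frame.box)
        within = d <= cutoff
        out[k] = contact_kernel(d[within]).sum() if within.any() else 0.0
    return out


def _z_prefilter(coords: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray,
                 cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Cheap z-interval screen: keep only atoms whose z lies within ``cutoff``
    of the other selection's z-range (z is not periodic, so this is exact)."""
    za, zb = coords[a_idx, 2], coords[b_idx, 2]
    a = a_idx[(za >= zb.min() - cutoff) & (za <= zb.max() + cutoff)]
    if a.size == 0:
        return a, b_idx[:0]
    za = coords[a, 2]
    b = b_idx[(zb >= za.min() - cutoff) & (zb <= za.max() + cutoff)]
    return a, b


def _membrane_selection(top: Topology, membrane_selection) -> np.ndarray:
    if membrane_selection is None:
        membrane_selection = select_atoms(top, role=MEMBRANE_ROLES, is_heavy=True)
    membrane_selection = np.asarray(membrane_selection, dtype=int)
    if membrane_selection.size == 0:
        raise ValueError("empty membrane selection")
    return membrane_selection


def bound_frames(series: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean bound-conformation mask: strictly C > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return np.asarray(series) > threshold


@dataclass
class ContactProfile:
    """Residue x frame contact numbers with bound masks and cumulative profile."""

    residue_ids: np.ndarray
    per_frame: np.ndarray          # (n_residues, n_frames)
    threshold: float
    bound_mask: np.ndarray = None  # type: ignore[assignment]
    avg_bound: np.ndarray = None   # type: ignore[assignment]
    cumulative: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bound_mask = bound_frames(self.per_frame, self.threshold)
        n_bound = self.bound_mask.sum(axis=1)
        sums = np.where(self.bound_mask, self.per_frame, 0.0).sum(axis=1)
        # average over bound frames only; a never-bound residue contributes 0
        self.avg_bound = np.divide(sums, n_bound, out=np.zeros_like(sums),
                                   where=n_bound > 0)
        self.cumulative = np.cumsum(self.avg_bound)

    @property
    def first_binding_frame(self) -> int | None:
        """First frame where any residue is bound (a convenience statistic)."""
        any_bound = self.bound_mask.any(axis=0)
        hits = np.flatnonzero(any_bound)
        return int(hits[0]) if hits.size else None

    def bound_residues(self) -> np.ndarray:
        """Residues bound in at least one frame."""
        return self.residue_ids[self.bound_mask.any(axis=1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residue_ids,
            "avg_bound": self.avg_bound,
            "cumulative": self.cumulative,
        })


def contact_profile(
    traj: Trajectory,
    membrane_selection: np.ndarray | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    threshold: float = DEFAULT_THRESHOLD,
) -> ContactProfile:
    """Contact numbers for every protein residue over every frame."""
    top = traj.topology
    mem_idx = _membrane_selection(top, membrane_selection)
    residue_ids = top.protein_residue_ids()
    prot_idx = select_atoms(top, role="protein", is_heavy=True)
    n_res = residue_ids.size
    per_frame = np.zeros((n_res, traj.n_frames))
    res_pos = {r: i for i, r in enumerate(residue_ids)}
    for k, frame in enumerate(traj.frames):
        a, b = _z_prefilter(frame.coords, prot_idx, mem_idx, cutoff)
        if a.size == 0 or b.size == 0:
            continue
        d = _pair_distances_xy_periodic(frame.coords[a], frame.coords[b],
                                        frame.box)
        contrib = np.where(d <= cutoff, contact_kernel(d), 0.0).sum(axis=1)
        res_a = top.residue_index[a]
        for r, c in zip(res_a, contrib):
            per_frame[res_pos[r], k] += c
    return ContactProfile(residue_ids, per_frame, threshold)


def cumulative_profile(avg_bound: np.ndarray) -> np.ndarray:
    """Running sum of per-residue bound-average contact numbers."""
    return np.cumsum(np.asarray(avg_bound, dtype=float))


def contacts_per_frame_table(profile: ContactProfile) -> pd.DataFrame:
    """Long-format (frame, residue, C) table for TSV export."""
    n_res, n_frames = profile.per_frame.shape
    return pd.DataFrame({
        "frame": np.repeat(np.arange(n_frames), n_res),
        "residue": np.tile(profile.residue_ids, n_frames),
        "contact_number": profile.per_frame.T.ravel(),
    })
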