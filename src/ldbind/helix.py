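"""Amphipathic-helix analytics.

Helical-wheel projection (100 deg per residue), Wimley-White interfacial
hydrophobicity sums, Eisenberg-style hydrophobic moment, point mutations,
backbone phi/psi dihedrals and helicity classification against the canonical
alpha-helical angles (-57, -47) deg.

The embedded scale is the Wimley-White water-to-POPC-interface free energy
of transfer per residue (kcal/mol); by its sign convention negative values
are hydrophobic (favourable partitioning into the membrane interface).
Charged-form values are used for Asp/Glu/Lys/Arg and neutral His.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Frame, Topology

#: Wimley & White interfacial scale, kcal/mol (water -> POPC interface)
WW_INTERFACE: dict[str, float] = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}

WHEEL_STEP = 100.0  # deg per residue of an ideal alpha-helix

CANONICAL_PHI = -57.0
CANONICAL_PSI = -47.0


def ww_scores(sequence: str) -> np.ndarray:
    """Per-residue Wimley-White interface values for a sequence window."""
    bad = sorted({c for c in sequence if c not in WW_INTERFACE})
    if bad:
        raise ValueError(f"nonstandard amino-acid letter(s): {bad}")
    return np.array([WW_INTERFACE[c] for c in sequence])


def ww_sum(sequence: str) -> float:
    """Sum of interface-scale values over a window (kcal/mol); empty -> 0.
    Negative sums indicate a hydrophobic (interface-favourable) window."""
    if not sequence:
        return 0.0
    return float(ww_scores(sequence).sum())


# ---------------------------------------------------------------------------
# mutations

_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution in conventional XnY notation (e.g. F159I)."""

    wt_residue: str
    position: int     # 1-based, full-protein numbering
    new_residue: str

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        m = _MUT_RE.match(text.strip().upper())
        if not m:
            raise ValueError(f"cannot parse mutation {text!r} (expected e.g. F159I)")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.new_residue}"

    def inverse(self) -> "MutationSpec":
        return MutationSpec(self.new_residue, self.position, self.wt_residue)

    @property
    def ww_delta(self) -> float:
        """Change in any window's WW sum caused by this substitution
        (independent of the surrounding sequence)."""
        return WW_INTERFACE[self.new_residue] - WW_INTERFACE[self.wt_residue]


def apply_mutations(
    sequence: str,
    mutations: list[MutationSpec | str],
    offset: int = 1,
) -> str:
    """Apply point mutations to a sequence; ``offset`` is the full-protein
    index of the sequence's first residue.  Order-independent for
    non-overlapping positions; a wild-type mismatch raises."""
    specs = [MutationSpec.parse(m) if isinstance(m, str) else m for m in mutations]
    chars = list(sequence)
    for spec in specs:
        i = spec.position - offset
        if not 0 <= i < len(chars):
            raise ValueError(f"mutation {spec}: position outside the sequence")
        if chars[i] != spec.wt_residue:
            raise ValueError(
                f"mutation {spec}: expected {spec.wt_residue} at position "
                f"{spec.position}, found {chars[i]}"
            )
        chars[i] = spec.new_residue
    return "".join(chars)


# ---------------------------------------------------------------------------
# helical wheel and hydrophobic moment

def wheel_angles(n_residues: int, start_angle: float = 0.0) -> np.ndarray:
    """Wheel angle of each residue: (k * 100) mod 360 degrees."""
    return (start_angle + WHEEL_STEP * np.arange(n_residues)) % 360.0


def hydrophobic_moment(
    sequence: str,
    scale: dict[str, float] | None = None,
    delta: float = WHEEL_STEP,
) -> tuple[float, float]:
    """Hydrophobic moment of a helix window: (magnitude, direction in deg).

    Per-residue hydrophobicities (negated Wimley-White values by default, so
    hydrophobic residues point positive) are summed as vectors at successive
    wheel angles of ``delta`` degrees.  The direction marks the centre of the
    hydrophobic face.
    """
    if len(sequence) < 3:
        raise ValueError("window must have length >= 3")
    if scale is None:
        h = -ww_scores(sequence)
    else:
        h = np.array([scale[c] for c in sequence])
    ang = np.deg2rad((delta * np.arange(len(sequence))) % 360.0)
    vx = float((h * np.cos(ang)).sum())
    vy = float((h * np.sin(ang)).sum())
    magnitude = float(np.hypot(vx, vy))
    direction = float(np.degrees(np.arctan2(vy, vx)) % 360.0)
    return magnitude, direction


def face_partition(sequence: str) -> list[str]:
    """Label each residue hydrophobic (negative WW value) or hydrophilic."""
    return ["hydrophobic" if WW_INTERFACE[c] < 0 else "hydrophilic"
            for c in sequence]


# ---------------------------------------------------------------------------
# backbone dihedrals and helicity

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign, range (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang) if ang > -180.0 else 180.0


def backbone_dihedrals(
    topology: Topology,
    frame: Frame,
    residue_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """phi/psi per protein residue (degrees; NaN where neighbours/atoms are
    missing).  phi(i) = C(i-1)-N-CA-C, psi(i) = N-CA-C-N(i+1)."""
    pos: dict[tuple[int, str], np.ndarray] = {}
    for i, a in enumerate(topology.atoms):
        if a.role == "protein" and a.atom_name in ("N", "CA", "C"):
            pos[(a.residue_index, a.atom_name)] = frame.coords[i]
    residues = sorted({r for r, _ in pos})
    if residue_range is not None:
        lo, hi = residue_range
        residues = [r for r in residues if lo <= r <= hi]
    rows = []
    for r in residues:
        phi = psi = np.nan
        try:
            phi = dihedral(pos[(r - 1, "C")], pos[(r, "N")], pos[(r, "CA")],
                           pos[(r, "C")])
        except KeyError:
            pass
        try:
            psi = dihedral(pos[(r, "N")], pos[(r, "CA")], pos[(r, "C")],
                           pos[(r + 1, "N")])
        except KeyError:
            pass
        rows.append((r, phi, psi))
    return pd.DataFrame(rows, columns=["residue", "phi", "psi"]).set_index("residue")


def _circular_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def helicity_classify(
    phi: float, psi: float, tolerance: float = 30.0
) -> tuple[bool, str]:
    """Classify one (phi, psi) pair.

    Helical iff both angles lie within ``tolerance`` (circular, boundary
    inclusive) of the canonical (-57, -47).  The region label comes from a
    declared rectangle set: allowed alpha phi in [-100, -30], psi in
    [-80, -5]; marginal is its 20-degree dilation; otherwise outside.
    """
    if np.isnan(phi) or np.isnan(psi):
        return False, "undefined"
    helical = (_circular_diff(phi, CANONICAL_PHI) <= tolerance
               and _circular_diff(psi, CANONICAL_PSI) <= tolerance)
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        region = "allowed"
    elif -120.0 <= phi <= -10.0 and -100.0 <= psi <= 15.0:
        region = "marginal"
    else:
        region = "outside"
    return helical, region


# ---------------------------------------------------------------------------
# annotation assembly

@dataclass
class HelixAnnotation:
    """Full per-residue report for one helix window."""

    start: int
    end: int
    sequence: str
    wheel_angle: np.ndarray
    ww_scores: np.ndarray
    ww_sum: float
    moment_magnitude: float
    moment_direction: float
    face: list[str]
    phi: np.ndarray | None = None
    psi: np.ndarray | None = None
    helical: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "residue": np.arange(self.start, self.end + 1),
            "aa": list(self.sequence),
            "wheel_angle": self.wheel_angle,
            "ww": self.ww_scores,
            "face": self.face,
        })
        if self.phi is not None:
            df["phi"] = self.phi
            df["psi"] = self.psi
            df["helical"] = self.helical
        return df.set_index("residue")


def annotate_helix(
    sequence: str,
    start: int,
    end: int,
    structure: tuple[Topology, Frame] | None = None,
    mutations: list[MutationSpec | str] | None = None,
    seq_offset: int = 1,
    tolerance: float = 30.0,
) -> HelixAnnotation:
    """Annotate the helix window [start, end] (full-protein 1-based, inclusive)
    of ``sequence`` whose first letter is full-protein residue ``seq_offset``.
    Optional ``structure`` adds phi/psi and per-residue helicity calls."""
    if mutations:
        sequence = apply_mutations(sequence, mutations, offset=seq_offset)
    lo, hi = start - seq_offset, end - seq_offset + 1
    if lo < 0 or hi > len(sequence) or lo >= hi:
        raise ValueError("window outside the sequence")
    window = sequence[lo:hi]
    scores = ww_scores(window)
    mag, direction = hydrophobic_moment(window)
    ann = HelixAnnotation(
        start=start, end=end, sequence=window,
        wheel_angle=wheel_angles(len(window)),
        ww_scores=scores, ww_sum=float(scores.sum()),
        moment_magnitude=mag, moment_direction=direction,
        face=face_partition(window),
    )
    if structure is not None:
        top, frame = structure
        table = backbone_dihedrals(top, frame, residue_range=(start, end))
        table = table.reindex(np.arange(start, end + 1))
        ann.phi = table["phi"].to_numpy()
        ann.psi = table["psi"].to_numpy()
        ann.helical = np.array([
            helicity_classify(p, s, tolerance)[0]
            for p, s in zip(ann.phi, ann.psi)
        ])
    return ann
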