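"""Atom role categories and the table-driven role assignment used at parse time.

Every analysis in this package keys off a coarse per-atom *role* rather than
chemistry: protein atoms, lipid headgroup / glycerol / acyl-chain atoms, core
neutral lipid (wax-ester or TAG) atoms, and solvent.  Roles are assigned from
residue and atom names through a :class:`RoleMap`, which ships with defaults
for the synthetic bead naming scheme and for common real-system names, and is
user-extensible for arbitrary force-field naming conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

PROTEIN = "protein"
LIPID_HEAD = "lipid_head"
LIPID_GLYCEROL = "lipid_glycerol"
LIPID_CHAIN = "lipid_chain"
CORE_NEUTRAL = "core_neutral"
SOLVENT = "solvent"

ROLES = (PROTEIN, LIPID_HEAD, LIPID_GLYCEROL, LIPID_CHAIN, CORE_NEUTRAL, SOLVENT)

#: roles counted as membrane material (lipids plus the neutral-lipid core)
MEMBRANE_ROLES = frozenset({LIPID_HEAD, LIPID_GLYCEROL, LIPID_CHAIN, CORE_NEUTRAL})

AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-variant names
    "HSD", "HSE", "HSP", "ASH", "GLH", "LYN", "CYX",
}

#: phospholipid residue names (synthetic headgroup codes)
PHOSPHOLIPIDS = {"PC", "PE", "PI", "PG", "PA", "PS"}

#: neutral-lipid core residue names
CORE_RESIDUES = {"WE", "TAG", "TRIO"}

SOLVENT_RESIDUES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "SPC"}


@dataclass
class RoleMap:
    """Residue/atom-name -> role mapping.

    ``residue_roles`` maps a residue name directly to a role (used for protein,
    core-neutral and solvent residues).  Residues listed in ``lipid_residues``
    are phospholipids whose atoms are sub-classified by atom-name prefix via
    ``lipid_atom_prefixes`` (first matching prefix wins; default chain).
    Unknown residue names fall back to ``solvent`` with a logged warning.
    """

    residue_roles: dict[str, str] = field(default_factory=dict)
    lipid_residues: set[str] = field(default_factory=set)
    lipid_atom_prefixes: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "RoleMap":
        residue_roles = {name: PROTEIN for name in AMINO3}
        residue_roles.update({name: CORE_NEUTRAL for name in CORE_RESIDUES})
        residue_roles.update({name: SOLVENT for name in SOLVENT_RESIDUES})
        return cls(
            residue_roles=residue_roles,
            lipid_residues=set(PHOSPHOLIPIDS),
            lipid_atom_prefixes={"PH": LIPID_HEAD, "P": LIPID_HEAD,
                                 "GL": LIPID_GLYCEROL, "C": LIPID_CHAIN},
        )

    def assign(self, residue_name: str, atom_name: str) -> str:
        resn = residue_name.strip().upper()
        if resn in self.lipid_residues:
            name = atom_name.strip().upper()
            for prefix, role in self.lipid_atom_prefixes.items():
                if name.startswith(prefix):
                    return role
            return LIPID_CHAIN
        role = self.residue_roles.get(resn)
        if role is None:
            logger.warning("unknown residue name %r: assigning role 'solvent'", residue_name)
            return SOLVENT
        return role
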