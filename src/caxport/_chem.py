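"""Internal-coordinate residue templates and side-chain rebuilding.

Each supported residue type is built from a fixed backbone stub (N, CA, C, O,
CB) plus side-chain atoms placed by natural-extension (NeRF) rules whose
torsions are the chi angles.  The same rules are used both to construct the
synthetic scaffold and to rebuild side chains while the ensemble sampler
varies chi torsions, so the two stay exactly consistent.

Atom names follow PDB conventions (ND1/ND2, OD1/OD2, OE1/OE2, NE2, OG).
Greek-letter selectors used in the field's prose map onto these via
:data:`ATOM_NAME_ALIASES`.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .structure import Atom, nerf_place

__all__ = [
    "SUPPORTED_RESIDUES",
    "N_CHI",
    "SECONDARY_ATOM",
    "ATOM_NAME_ALIASES",
    "build_residue",
    "rebuild_sidechain",
    "measure_chi",
    "anchor_frame",
    "frame_from",
    "phosphate_template",
]

# Side-chain placement rules: atom -> (ref atoms a,b,c; bond; angle; chi index
# or None for a fixed torsion; torsion offset in degrees).
_SIDECHAIN_RULES: dict[str, list[tuple[str, tuple[str, str, str], float, float, int | None, float]]] = {
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 0, 0.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 114.0, 1, 0.0),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.5, 2, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.5, 2, 180.0),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 0, 0.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 114.0, 1, 0.0),
        ("OE1", ("CB", "CG", "CD"), 1.23, 121.0, 2, 0.0),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.5, 2, 180.0),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 0, 0.0),
        ("OD1", ("CA", "CB", "CG"), 1.23, 121.0, 1, 0.0),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.5, 1, 180.0),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 0, 0.0),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.5, 1, 0.0),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.5, 1, 180.0),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.50, 114.0, 0, 0.0),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.5, 1, 0.0),
        ("CD2", ("CA", "CB", "CG"), 1.36, 131.0, 1, 180.0),
        ("CE1", ("CD2", "CG", "ND1"), 1.32, 109.0, None, 180.0),
        ("NE2", ("ND1", "CG", "CD2"), 1.37, 107.0, None, 180.0),
    ],
    "SER": [
        ("OG", ("N", "CA", "CB"), 1.42, 110.5, 0, 0.0),
    ],
    "GLY": [],
}

SUPPORTED_RESIDUES = frozenset(_SIDECHAIN_RULES)
N_CHI = {t: max((r[4] + 1 for r in rules if r[4] is not None), default=0)
         for t, rules in _SIDECHAIN_RULES.items()}

# The "second" functional atom of each side chain, used when a neighbouring
# residue is positioned relative to it (e.g. an amide N accepting an H-bond).
SECONDARY_ATOM = {
    "GLU": "OE2", "ASP": "OD2", "ASN": "ND2", "GLN": "NE2",
    "HIS": "NE2", "SER": "OG", "GLY": "O",
}

# Prose selectors -> PDB atom names (per residue type).  "Ndelta" of His is
# ND1, but for Asn the side-chain nitrogen is ND2; serine has no CG, its
# gamma heavy atom is OG.
ATOM_NAME_ALIASES: dict[str, Mapping[str, str]] = {
    "HIS": {"ND": "ND1", "NDELTA": "ND1"},
    "ASN": {"ND": "ND2", "NDELTA": "ND2", "OD": "OD1", "ODELTA": "OD1"},
    "GLN": {"OE": "OE1", "OEPSILON": "OE1"},
    "SER": {"CG": "OG", "OGAMMA": "OG"},
}

_DEFAULT_CHI = {
    "GLU": (180.0, 180.0, 0.0),
    "GLN": (180.0, 180.0, 0.0),
    "ASN": (180.0, 0.0),
    "ASP": (180.0, 0.0),
    "HIS": (180.0, 90.0),
    "SER": (180.0,),
    "GLY": (),
}


def _backbone_stub() -> dict[str, np.ndarray]:
    """Fixed local backbone: CA at the origin, N along -x, C in the xy plane."""
    ca = np.zeros(3)
    n = np.array([-1.458, 0.0, 0.0])
    c = 1.525 * np.array([math.cos(math.radians(69.0)), math.sin(math.radians(69.0)), 0.0])
    o = nerf_place(n, ca, c, 1.231, 120.1, 120.0)
    cb = nerf_place(c, n, ca, 1.530, 110.5, 122.5)
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def build_residue(type3: str, chi: tuple[float, ...] | None = None) -> dict[str, np.ndarray]:
    """Return atom-name -> position for one residue in its local frame."""
    if type3 not in _SIDECHAIN_RULES:
        raise ValueError(f"unsupported residue type {type3!r}")
    if chi is None:
        chi = _DEFAULT_CHI[type3]
    pos = _backbone_stub()
    if type3 == "GLY":
        pos.pop("CB")
        return pos
    for name, (a, b, c), bond, angle, ci, off in _SIDECHAIN_RULES[type3]:
        tors = off if ci is None else chi[ci] + off
        pos[name] = nerf_place(pos[a], pos[b], pos[c], bond, angle, tors)
    return pos


def rebuild_sidechain(
    pos: dict[str, np.ndarray], type3: str, chi: np.ndarray
) -> dict[str, np.ndarray]:
    """Recompute side-chain atoms (beyond CB) from frozen backbone and chi."""
    out = {}
    for name, (a, b, c), bond, angle, ci, off in _SIDECHAIN_RULES[type3]:
        src = {**pos, **out}
        tors = off if ci is None else float(chi[ci]) + off
        out[name] = nerf_place(src[a], src[b], src[c], bond, angle, tors)
    return out


def measure_chi(pos: dict[str, np.ndarray], type3: str) -> np.ndarray:
    """Read chi torsions back from coordinates (inverse of rebuild)."""
    from .structure import dihedral_angle

    chi = np.zeros(N_CHI[type3])
    for name, (a, b, c), _bond, _angle, ci, off in _SIDECHAIN_RULES[type3]:
        if ci is not None and off == 0.0:
            chi[ci] = dihedral_angle(pos[a], pos[b], pos[c], pos[name])
    return chi


# -- rigid placement -------------------------------------------------------


def frame_from(x_dir: np.ndarray, normal_hint: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame with the given x axis; columns x,y,z."""
    x = np.asarray(x_dir, dtype=float)
    x = x / np.linalg.norm(x)
    z = np.cross(x, np.asarray(normal_hint, dtype=float))
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise ValueError("normal hint parallel to x direction")
    z /= nz
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def anchor_frame(pos: dict[str, np.ndarray], type3: str) -> tuple[np.ndarray, np.ndarray]:
    """(origin, 3x3 frame) anchored on the residue's functional group.

    The frame's x axis points from the anchor origin toward the site the
    functional group contacts (for carboxylates: along the O-O bisector).
    """
    if type3 in ("GLU", "ASP"):
        cd = pos["CD" if type3 == "GLU" else "CG"]
        o1 = pos["OE1" if type3 == "GLU" else "OD1"]
        o2 = pos["OE2" if type3 == "GLU" else "OD2"]
        x = 0.5 * (o1 + o2) - cd
        n = np.cross(o1 - cd, o2 - cd)
        return cd, frame_from(x, n)
    if type3 == "ASN":
        cg = pos["CG"]
        x = pos["OD1"] - cg
        n = np.cross(pos["OD1"] - cg, pos["ND2"] - cg)
        return cg, frame_from(x, n)
    if type3 == "GLN":
        oe1 = pos["OE1"]
        x = pos["CD"] - oe1
        n = np.cross(pos["CD"] - oe1, pos["NE2"] - oe1)
        return oe1, frame_from(x, n)
    if type3 == "HIS":
        nd1 = pos["ND1"]
        x = pos["CG"] - nd1
        n = np.cross(pos["CG"] - nd1, pos["CE1"] - nd1)
        return nd1, frame_from(x, n)
    if type3 == "SER":
        og = pos["OG"]
        x = pos["CB"] - og
        n = np.cross(pos["CB"] - og, pos["CA"] - og)
        return og, frame_from(x, n)
    if type3 == "GLY":
        o = pos["O"]
        x = pos["C"] - o
        n = np.cross(pos["C"] - o, pos["CA"] - o)
        return o, frame_from(x, n)
    raise ValueError(f"unsupported residue type {type3!r}")


def transform_positions(
    pos: dict[str, np.ndarray],
    origin_local: np.ndarray,
    frame_local: np.ndarray,
    origin_target: np.ndarray,
    frame_target: np.ndarray,
) -> dict[str, np.ndarray]:
    rot = frame_target @ frame_local.T
    return {k: rot @ (v - origin_local) + origin_target for k, v in pos.items()}


def phosphate_template(bond: float = 1.55) -> dict[str, np.ndarray]:
    """Dihydrogen phosphate heavy atoms, P at the origin, O1 along -z."""
    s = math.sqrt(8.0) / 3.0
    dirs = {
        "O1": np.array([0.0, 0.0, -1.0]),
        "O2": np.array([s, 0.0, 1.0 / 3.0]),
        "O3": np.array([-s / 2.0, s * math.sqrt(3.0) / 2.0, 1.0 / 3.0]),
        "O4": np.array([-s / 2.0, -s * math.sqrt(3.0) / 2.0, 1.0 / 3.0]),
    }
    out = {"P": np.zeros(3)}
    out.update({k: bond * v for k, v in dirs.items()})
    return out


def residue_atoms(
    type3: str,
    number: int,
    chain: str,
    pos: dict[str, np.ndarray],
) -> list[Atom]:
    order = ["N", "CA", "C", "O", "CB"] + [r[0] for r in _SIDECHAIN_RULES[type3]]
    return [
        Atom(name=nm, element=nm[0], residue_name=type3, residue_number=number,
             chain=chain, pos=pos[nm])
        for nm in order if nm in pos
    ]
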