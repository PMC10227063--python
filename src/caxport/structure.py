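"""Shared structural currency: atoms, structures, geometry primitives, PDB I/O.

A :class:`StructureModel` is the in-memory representation used by the
binding-site survey, the restraint sampler and the ensemble analysis.  It is
deliberately light-weight -- a flat list of atoms plus optional metadata
(resolution, per-chain sequences) -- and converts to/from ``gemmi``
structures for file I/O so that real PDB/mmCIF entries and in-repo fixtures
go through a single parse path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "ParseError",
    "parse_structure",
    "write_pdb",
    "nerf_place",
    "dihedral_angle",
    "THREE_TO_ONE",
]

# Standard amino acids; used to build one-letter chain sequences.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class ParseError(ValueError):
    """Raised when a structure file cannot be turned into a StructureModel."""


@dataclass
class Atom:
    """One atom: identity plus Cartesian coordinates in Angstrom."""

    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    pos: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")

    def copy(self) -> "Atom":
        return replace(self, pos=self.pos.copy())


@dataclass
class StructureModel:
    """A parsed structure: atom list, optional resolution, chain sequences."""

    atoms: list[Atom]
    resolution: float | None = None
    chain_sequences: dict[str, str] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.residue_number, a.residue_name, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in {self.source_id!r}")
            seen.add(key)

    # -- accessors ---------------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float).reshape(-1, 3)

    def atom(self, residue_number: int, name: str, chain: str | None = None) -> Atom:
        """Return the unique atom with this residue number and atom name."""
        hits = [
            a for a in self.atoms
            if a.residue_number == residue_number and a.name == name
            and (chain is None or a.chain == chain)
        ]
        if len(hits) != 1:
            raise KeyError(
                f"selector {residue_number}:{name} resolves to {len(hits)} atoms"
            )
        return hits[0]

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Group atoms by (chain, residue number, residue name), file order."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.residue_number, a.residue_name), []).append(a)
        return out

    def copy(self) -> "StructureModel":
        return StructureModel(
            atoms=[a.copy() for a in self.atoms],
            resolution=self.resolution,
            chain_sequences=dict(self.chain_sequences),
            source_id=self.source_id,
        )

    def derive_chain_sequences(self) -> dict[str, str]:
        """One-letter sequences from standard amino-acid residues, by chain."""
        seqs: dict[str, str] = {}
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.residue_name not in THREE_TO_ONE:
                continue
            key = (a.chain, a.residue_number)
            if key in seen:
                continue
            seen.add(key)
            seqs[a.chain] = seqs.get(a.chain, "") + THREE_TO_ONE[a.residue_name]
        return seqs


# -- geometry primitives ---------------------------------------------------


def nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom D from internal coordinates relative to A, B, C.

    ``bond`` is |C-D|, ``angle_deg`` the B-C-D angle and ``dihedral_deg`` the
    A-B-C-D torsion (natural extension reference frame).
    """
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    # scalar 3-vector math: this primitive is hot in the ensemble sampler
    b2x, b2y, b2z = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    ln = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    b2x, b2y, b2z = b2x / ln, b2y / ln, b2z / ln
    b1x, b1y, b1z = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = b1y * b2z - b1z * b2y
    ny = b1z * b2x - b1x * b2z
    nz = b1x * b2y - b1y * b2x
    ln = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / ln, ny / ln, nz / ln
    mx = ny * b2z - nz * b2y
    my = nz * b2x - nx * b2z
    mz = nx * b2y - ny * b2x
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = -math.cos(phi), -math.sin(phi)
    dx = bond * (-ct * b2x + st * cp * mx + st * sp * nx)
    dy = bond * (-ct * b2y + st * cp * my + st * sp * ny)
    dz = bond * (-ct * b2z + st * cp * mz + st * sp * nz)
    return np.array([c[0] + dx, c[1] + dy, c[2] + dz])


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0x, b0y, b0z = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
    b1x, b1y, b1z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b2x, b2y, b2z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    ln = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    b1x, b1y, b1z = b1x / ln, b1y / ln, b1z / ln
    d0 = b0x * b1x + b0y * b1y + b0z * b1z
    vx, vy, vz = b0x - d0 * b1x, b0y - d0 * b1y, b0z - d0 * b1z
    d2 = b2x * b1x + b2y * b1y + b2z * b1z
    wx, wy, wz = b2x - d2 * b1x, b2y - d2 * b1y, b2z - d2 * b1z
    x = vx * wx + vy * wy + vz * wz
    cx = b1y * vz - b1z * vy
    cy = b1z * vx - b1x * vz
    cz = b1x * vy - b1y * vx
    y = cx * wx + cy * wy + cz * wz
    return math.degrees(math.atan2(y, x))


# -- file I/O --------------------------------------------------------------


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    if model.resolution is not None:
        st.resolution = model.resolution
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int, str], gemmi.Residue] = {}
    for a in model.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
            md.add_chain(ch)
            ch = md[len(md) - 1]
            chains[a.chain] = ch
        rkey = (a.chain, a.residue_number, a.residue_name)
        res = residues.get(rkey)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.het else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
            residues[rkey] = res
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.pos)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        res.add_atom(at)
    st.add_model(md)
    return st


def write_pdb(model: StructureModel, path: str | Path) -> Path:
    """Write a StructureModel as a PDB file (REMARK 2 carries the resolution)."""
    path = Path(path)
    st = _to_gemmi(model)
    st.setup_entities()
    body = st.make_pdb_string()
    header = ""
    if model.resolution is not None and "REMARK   2 RESOLUTION" not in body:
        header = (
            f"REMARK   2\nREMARK   2 RESOLUTION. {model.resolution:7.2f} ANGSTROMS.\n"
        )
    path.write_text(header + body)
    return path


def write_multi_model_pdb(models: Sequence[StructureModel], path: str | Path) -> Path:
    """Write an ensemble as a multi-MODEL PDB file."""
    path = Path(path)
    chunks = []
    for i, m in enumerate(models, start=1):
        body = _to_gemmi(m).make_pdb_string()
        lines = [ln for ln in body.splitlines() if ln.startswith(("ATOM", "HETATM", "TER"))]
        chunks.append(f"MODEL     {i:4d}\n" + "\n".join(lines) + "\nENDMDL")
    path.write_text("\n".join(chunks) + "\nEND\n")
    return path


def parse_models(file: str | Path) -> list[StructureModel]:
    """Parse all MODEL records of a (multi-model) PDB/mmCIF file."""
    path = Path(file)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    out = []
    for md in st:
        atoms = []
        for chain in md:
            for res in chain:
                for at in res:
                    atoms.append(Atom(
                        name=at.name, element=at.element.name,
                        residue_name=res.name.strip(), residue_number=res.seqid.num,
                        chain=chain.name,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ, b_factor=at.b_iso,
                        het=(res.het_flag == "H")))
        if atoms:
            model = StructureModel(atoms=atoms, source_id=f"{path.stem}:{md.num}")
            model.chain_sequences = model.derive_chain_sequences()
            out.append(model)
    if not out:
        raise ParseError(f"no atoms found in {path.name}")
    return out


def parse_structure(file: str | Path) -> StructureModel:
    """Parse a PDB or mmCIF file into a StructureModel.

    Resolution is taken from REMARK 2 (PDB) or the refinement category
    (mmCIF) when present; HETATM entities (ions, ligands) are retained.
    """
    path = Path(file)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError variants
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                for at in res:
                    atoms.append(
                        Atom(
                            name=at.name,
                            element=at.element.name,
                            residue_name=res.name.strip(),
                            residue_number=res.seqid.num,
                            chain=chain.name,
                            pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=at.occ,
                            b_factor=at.b_iso,
                            het=(res.het_flag == "H"),
                        )
                    )
    if not atoms:
        raise ParseError(f"no atoms found in {path.name}")
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    model = StructureModel(
        atoms=atoms, resolution=resolution, source_id=path.stem
    )
    model.chain_sequences = model.derive_chain_sequences()
    return model
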