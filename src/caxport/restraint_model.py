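"""Binding-site restraint ledger and restraint-satisfying ensemble sampling.

The default ledger encodes ten geometric restraints describing concurrent
Ca2+ / dihydrogen-phosphate recognition at the antiporter's central site:

* r1-r4: flat-bottom upper-distance restraints (harmonic beyond 2.6 A,
  deviation 0.1 A) from Ca2+ to the four carboxylate oxygens of E72/E255,
  to the nearest phosphate oxygen, to the G68 backbone carbonyl, and to the
  N69 side-chain carbonyl.  Together these fix a Ca2+ coordination number
  of 7.
* r5-r9: two-sided harmonic distance targets tying the phosphorus atom to
  H256 Nd1 (3.9 A), N252 Cg (4.5 A) and S278 Og (4.5 A; ledger alias for a
  "Cg" that serine does not have), plus the polar-network distances
  Q281 Oe1 - N69 Nd2 (3.2 A) and N252 Cg - N99 Cg (4.2 A).
* r10: planarity of each Ca2+/carboxylate chelate, expressed as the
  dihedral over (Ca, Oe1, Oe2, Cd) restrained to 0 deg with a 20 deg
  deviation; in this atom ordering an in-plane bi-dentate pose reads 0 deg.

Models are generated by simulated annealing over the side-chain chi
torsions of the nine site residues plus rigid-body Ca2+ and phosphate
placement, with the backbone frozen.  A model is accepted when every
restraint term (and the auxiliary steric / coordination-exclusion terms
that keep the chemistry plausible) deviates by at most three sigmas.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import _chem
from .structure import Atom, StructureModel, THREE_TO_ONE, dihedral_angle

__all__ = [
    "Restraint",
    "RestraintSet",
    "SiteModel",
    "build_default_restraints",
    "restraint_energy",
    "sample_ensemble",
    "coordination_count",
    "parse_selector",
    "resolve_selector",
]

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Auxiliary scoring constants: soft-sphere contact radius between heavy
#: atoms of different residues, and the Ca2+ exclusion radius for O/N atoms
#: that are not designated coordination partners.
STERIC_RADIUS = 2.7
STERIC_SIGMA = 0.1
CA_EXCLUSION_RADIUS = 3.2
CA_EXCLUSION_SIGMA = 0.1


# -- selectors -------------------------------------------------------------


def parse_selector(sel: str) -> tuple[str, int | None, str]:
    """Parse "E72:OE1" -> ("E", 72, "OE1"); "ion:CA" -> ("ion", None, "CA")."""
    if ":" not in sel:
        raise ValueError(f"bad selector {sel!r}; expected 'E72:OE1' or 'ion:CA'")
    head, atom = sel.split(":", 1)
    if head == "ion":
        return "ion", None, atom
    letter = head[0].upper()
    if letter not in ONE_TO_THREE or not head[1:].isdigit():
        raise ValueError(f"bad residue selector {head!r}")
    return letter, int(head[1:]), atom.upper()


def resolve_selector(model: StructureModel, sel: str) -> Atom:
    """Resolve a selector to exactly one atom, applying atom-name aliases."""
    kind, resnum, atom_name = parse_selector(sel)
    if kind == "ion":
        if atom_name == "CA":
            hits = [a for a in model.atoms if a.residue_name == "CA" and a.element == "Ca"]
        elif atom_name == "P":
            hits = [a for a in model.atoms if a.element == "P"]
        else:
            raise KeyError(f"unknown ion selector {sel!r}")
        if len(hits) != 1:
            raise KeyError(f"selector {sel!r} resolves to {len(hits)} atoms")
        return hits[0]
    res_atoms = [a for a in model.atoms if a.residue_number == resnum
                 and a.residue_name in THREE_TO_ONE]
    if not res_atoms:
        raise KeyError(f"selector {sel!r}: residue {resnum} not in scaffold")
    type3 = res_atoms[0].residue_name
    name = _chem.ATOM_NAME_ALIASES.get(type3, {}).get(atom_name, atom_name)
    hits = [a for a in res_atoms if a.name == name]
    if len(hits) != 1:
        raise KeyError(f"selector {sel!r} (atom {name}) resolves to {len(hits)} atoms")
    return hits[0]


# -- restraint records -----------------------------------------------------

KINDS = ("flat_bottom_upper_distance", "target_distance", "planarity_dihedral")


@dataclass
class Restraint:
    """One logical restraint; may expand to several scalar terms."""

    id: str
    kind: str
    terms: list[tuple[tuple[str, ...], float, float]]  # (selectors, target, sigma)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        for selectors, _target, sigma in self.terms:
            if sigma <= 0:
                raise ValueError(f"{self.id}: deviation must be positive")
            n = 4 if self.kind == "planarity_dihedral" else 2
            if len(selectors) != n:
                raise ValueError(f"{self.id}: expected {n} selectors per term")


@dataclass
class RestraintSet:
    """Ordered ledger of logical restraints."""

    restraints: list[Restraint] = field(default_factory=list)

    def scalar_terms(self) -> list[tuple[str, str, tuple[str, ...], float, float]]:
        out = []
        for r in self.restraints:
            for selectors, target, sigma in r.terms:
                out.append((r.id, r.kind, selectors, target, sigma))
        return out

    def validate(self, scaffold: StructureModel) -> None:
        for rid, _kind, selectors, _t, _s in self.scalar_terms():
            for sel in selectors:
                if sel == "ion:nearest_phosphate_O":
                    if not _phosphate_oxygens(scaffold):
                        raise KeyError(f"{rid}: no phosphate oxygens in scaffold")
                    continue
                resolve_selector(scaffold, sel)

    # -- serialization (the human-auditable ledger) ------------------------

    def to_json(self) -> str:
        payload = [
            {"id": r.id, "kind": r.kind,
             "terms": [{"selectors": list(sel), "target": t, "sigma": s}
                       for sel, t, s in r.terms]}
            for r in self.restraints
        ]
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RestraintSet":
        items = json.loads(text)
        return cls([
            Restraint(id=i["id"], kind=i["kind"],
                      terms=[(tuple(t["selectors"]), float(t["target"]),
                              float(t["sigma"])) for t in i["terms"]])
            for i in items
        ])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RestraintSet":
        return cls.from_json(Path(path).read_text())


def _phosphate_oxygens(model: StructureModel) -> list[Atom]:
    p = [a for a in model.atoms if a.element == "P"]
    if not p:
        return []
    return [a for a in model.atoms
            if a.residue_number == p[0].residue_number and a.element == "O"]


def build_default_restraints(
    scaffold: StructureModel, target_sigma: float = 0.1
) -> RestraintSet:
    """The default ten-restraint ledger for the wild-type site residues.

    ``target_sigma`` sets the deviation of the two-sided distance targets
    r5-r9 (their flat-bottom analogues r1-r4 always use 0.1 A).
    """
    fb, td, pl = KINDS
    rs = RestraintSet([
        Restraint("r1", fb, [
            (("ion:CA", "E72:OE1"), 2.6, 0.1),
            (("ion:CA", "E72:OE2"), 2.6, 0.1),
            (("ion:CA", "E255:OE1"), 2.6, 0.1),
            (("ion:CA", "E255:OE2"), 2.6, 0.1),
        ]),
        Restraint("r2", fb, [(("ion:CA", "ion:nearest_phosphate_O"), 2.6, 0.1)]),
        Restraint("r3", fb, [(("ion:CA", "G68:O"), 2.6, 0.1)]),
        Restraint("r4", fb, [(("ion:CA", "N69:OD1"), 2.6, 0.1)]),
        Restraint("r5", td, [(("ion:P", "H256:ND1"), 3.9, target_sigma)]),
        Restraint("r6", td, [(("ion:P", "N252:CG"), 4.5, target_sigma)]),
        Restraint("r7", td, [(("ion:P", "S278:OG"), 4.5, target_sigma)]),
        Restraint("r8", td, [(("Q281:OE1", "N69:ND2"), 3.2, target_sigma)]),
        Restraint("r9", td, [(("N252:CG", "N99:CG"), 4.2, target_sigma)]),
        Restraint("r10", pl, [
            (("ion:CA", "E72:OE1", "E72:OE2", "E72:CD"), 0.0, 20.0),
            (("ion:CA", "E255:OE1", "E255:OE2", "E255:CD"), 0.0, 20.0),
        ]),
    ])
    rs.validate(scaffold)
    return rs


# -- energy ----------------------------------------------------------------


@dataclass
class SiteModel:
    """One restraint-satisfying configuration of the site."""

    structure: StructureModel
    score: float
    per_restraint: pd.DataFrame

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("restraint pseudo-energy must be non-negative")


def _angular_difference(theta: float, target: float) -> float:
    """Minimal absolute angular difference in degrees."""
    d = (theta - target + 180.0) % 360.0 - 180.0
    return abs(d)


def restraint_energy(
    model: StructureModel | SiteModel, rs: RestraintSet
) -> tuple[float, pd.DataFrame]:
    """Total restraint pseudo-energy and the per-term violation table.

    Flat-bottom terms cost 0 up to the target distance and
    ((d - target)/sigma)^2 / 2 beyond it; two-sided targets and dihedrals
    cost (deviation/sigma)^2 / 2 everywhere.
    """
    structure = model.structure if isinstance(model, SiteModel) else model
    rows = []
    total = 0.0
    pho_o = _phosphate_oxygens(structure)
    for rid, kind, selectors, target, sigma in rs.scalar_terms():
        if kind == "planarity_dihedral":
            pts = [resolve_selector(structure, s).pos for s in selectors]
            theta = dihedral_angle(*pts)
            dev = _angular_difference(theta, target) / sigma
            value = theta
        else:
            if selectors[1] == "ion:nearest_phosphate_O":
                a = resolve_selector(structure, selectors[0]).pos
                value = min(float(np.linalg.norm(a - o.pos)) for o in pho_o)
            else:
                a = resolve_selector(structure, selectors[0]).pos
                b = resolve_selector(structure, selectors[1]).pos
                value = float(np.linalg.norm(a - b))
            if kind == "flat_bottom_upper_distance":
                dev = max(0.0, value - target) / sigma
            else:
                dev = abs(value - target) / sigma
        energy = 0.5 * dev * dev
        total += energy
        rows.append({"restraint": rid, "kind": kind,
                     "selectors": "|".join(selectors), "value": value,
                     "target": target, "sigma": sigma,
                     "deviation_sigma": dev, "energy": energy})
    return total, pd.DataFrame(rows)


def coordination_count(
    model: StructureModel | SiteModel, center: str = "ion:CA", cutoff: float = 3.0
) -> tuple[int, list[tuple[str, float]]]:
    """Unique O/N atoms within ``cutoff`` of the center ion, with partners."""
    structure = model.structure if isinstance(model, SiteModel) else model
    ion = resolve_selector(structure, center)
    partners = []
    for a in structure.atoms:
        if a is ion or a.element not in ("O", "N"):
            continue
        d = float(np.linalg.norm(a.pos - ion.pos))
        if d <= cutoff:
            partners.append((f"{a.residue_name}{a.residue_number}:{a.name}", d))
    partners.sort(key=lambda t: t[1])
    return len(partners), partners


# -- ensemble sampler ------------------------------------------------------


class _Sampler:
    """Indexed state for fast annealing on one scaffold + restraint set."""

    def __init__(self, scaffold: StructureModel, rs: RestraintSet):
        rs.validate(scaffold)
        self.scaffold = scaffold
        self.rs = rs
        self.atoms = [a.copy() for a in scaffold.atoms]
        self.index = {(a.residue_number, a.name): i for i, a in enumerate(self.atoms)}
        self.X0 = np.array([a.pos for a in self.atoms])

        # variable residues: chi-bearing protein side chains
        self.residues: list[tuple[int, str, np.ndarray]] = []  # (resnum, type3, chi0)
        for (chain, num, name3), res_atoms in scaffold.residues().items():
            if name3 in _chem.SUPPORTED_RESIDUES and _chem.N_CHI[name3] > 0:
                pos = {a.name: a.pos for a in res_atoms}
                self.residues.append((num, name3, _chem.measure_chi(pos, name3)))

        # ions
        ca_atom = resolve_selector(scaffold, "ion:CA")
        p_atom = resolve_selector(scaffold, "ion:P")
        self.ca_idx = self.index[(ca_atom.residue_number, ca_atom.name)]
        self.p_resnum = p_atom.residue_number
        self.p_idx = self.index[(self.p_resnum, p_atom.name)]
        self.pho_idx = [i for i, a in enumerate(self.atoms)
                        if a.residue_number == self.p_resnum]
        self.pho_local = self.X0[self.pho_idx] - self.X0[self.p_idx]
        self.pho_o_idx = np.array([i for i in self.pho_idx
                                   if self.atoms[i].element == "O"])

        self._index_terms()
        self._index_aux()

    def _resolve_idx(self, sel: str) -> int:
        a = resolve_selector(self.scaffold, sel)
        return self.index[(a.residue_number, a.name)]

    def _index_terms(self) -> None:
        pairs, nearest, dihedrals = [], [], []
        self.term_meta = []
        for rid, kind, selectors, target, sigma in self.rs.scalar_terms():
            if kind == "planarity_dihedral":
                dihedrals.append(([self._resolve_idx(s) for s in selectors],
                                  target, sigma))
                self.term_meta.append((rid, kind, selectors, target, sigma))
            elif selectors[1] == "ion:nearest_phosphate_O":
                nearest.append((self._resolve_idx(selectors[0]), target, sigma))
                self.term_meta.append((rid, kind, selectors, target, sigma))
            else:
                i = self._resolve_idx(selectors[0])
                j = self._resolve_idx(selectors[1])
                pairs.append((i, j, target, sigma,
                              kind == "flat_bottom_upper_distance"))
                self.term_meta.append((rid, kind, selectors, target, sigma))
        self.pair_i = np.array([p[0] for p in pairs], dtype=int)
        self.pair_j = np.array([p[1] for p in pairs], dtype=int)
        self.pair_target = np.array([p[2] for p in pairs])
        self.pair_sigma = np.array([p[3] for p in pairs])
        self.pair_flat = np.array([p[4] for p in pairs], dtype=bool)
        self.nearest_terms = nearest
        self.dihedral_terms = dihedrals
        self.restrained_pairs = {frozenset((p[0], p[1])) for p in pairs}

    def _index_aux(self) -> None:
        # steric soft-sphere pairs between heavy atoms of different residues
        # (the Ca2+ ion is excluded; its contacts are handled separately)
        heavy = [i for i, a in enumerate(self.atoms)
                 if a.element != "H" and i != self.ca_idx]
        si, sj = [], []
        for ii, i in enumerate(heavy):
            for j in heavy[ii + 1:]:
                if self.atoms[i].residue_number == self.atoms[j].residue_number:
                    continue
                if frozenset((i, j)) in self.restrained_pairs:
                    continue
                si.append(i)
                sj.append(j)
        self.steric_i = np.array(si, dtype=int)
        self.steric_j = np.array(sj, dtype=int)

        # O/N atoms that are not designated Ca2+ coordination partners must
        # stay out of the coordination shell (this is what makes the ledger
        # "imply" a coordination number of exactly 7)
        designated = {j for i, j, f in zip(self.pair_i, self.pair_j, self.pair_flat)
                      if f and i == self.ca_idx}
        self.excl_idx = np.array([
            i for i, a in enumerate(self.atoms)
            if a.element in ("O", "N") and i not in designated
            and i not in set(self.pho_o_idx)
        ], dtype=int)

        # single concatenated distance pass: restraint pairs, Ca-phosphate
        # oxygens, Ca-exclusion candidates, steric pairs
        np_pair = self.pair_i.size
        n_pho = self.pho_o_idx.size
        n_excl = self.excl_idx.size
        ca_rep_p = np.full(n_pho, self.ca_idx, dtype=int)
        ca_rep_e = np.full(n_excl, self.ca_idx, dtype=int)
        self.all_i = np.concatenate([self.pair_i, ca_rep_p, ca_rep_e, self.steric_i])
        self.all_j = np.concatenate([self.pair_j, self.pho_o_idx, self.excl_idx,
                                     self.steric_j])
        self.s_pair = slice(0, np_pair)
        self.s_pho = slice(np_pair, np_pair + n_pho)
        self.s_excl = slice(np_pair + n_pho, np_pair + n_pho + n_excl)
        self.s_ster = slice(np_pair + n_pho + n_excl, self.all_i.size)
        self._excl_r2 = CA_EXCLUSION_RADIUS**2
        self._ster_r2 = STERIC_RADIUS**2

    # -- energy ------------------------------------------------------------

    def _eval(self, X: np.ndarray) -> tuple[float, float]:
        """(total pseudo-energy, worst auxiliary violation in sigmas)."""
        diff = X[self.all_i] - X[self.all_j]
        d2 = np.einsum("ij,ij->i", diff, diff)

        d = np.sqrt(d2[self.s_pair])
        dev = np.where(self.pair_flat,
                       np.maximum(0.0, d - self.pair_target),
                       np.abs(d - self.pair_target)) / self.pair_sigma
        e = 0.5 * float(dev @ dev)

        # nearest phosphate oxygen: flat-bottom pull; the remaining oxygens
        # are kept out of the Ca2+ coordination shell
        pho_d = np.sqrt(np.sort(d2[self.s_pho]))
        aux_max = 0.0
        for _i, target, sigma in self.nearest_terms:
            e += 0.5 * (max(0.0, pho_d[0] - target) / sigma) ** 2
        if pho_d.size > 1 and pho_d[1] < CA_EXCLUSION_RADIUS:
            v = (CA_EXCLUSION_RADIUS - pho_d[1:]) / CA_EXCLUSION_SIGMA
            v = np.maximum(v, 0.0)
            e += 0.5 * float(v @ v)
            aux_max = float(v.max())

        for idx4, target, sigma in self.dihedral_terms:
            theta = dihedral_angle(X[idx4[0]], X[idx4[1]], X[idx4[2]], X[idx4[3]])
            e += 0.5 * (_angular_difference(theta, target) / sigma) ** 2

        de2 = d2[self.s_excl]
        if de2.size and de2.min() < self._excl_r2:
            v = (CA_EXCLUSION_RADIUS - np.sqrt(de2[de2 < self._excl_r2])) \
                / CA_EXCLUSION_SIGMA
            e += 0.5 * float(v @ v)
            aux_max = max(aux_max, float(v.max()))

        ds2 = d2[self.s_ster]
        if ds2.size and ds2.min() < self._ster_r2:
            v = (STERIC_RADIUS - np.sqrt(ds2[ds2 < self._ster_r2])) / STERIC_SIGMA
            e += 0.5 * float(v @ v)
            aux_max = max(aux_max, float(v.max()))
        return e, aux_max

    def energy(self, X: np.ndarray) -> float:
        return self._eval(X)[0]

    def max_aux_violation(self, X: np.ndarray) -> float:
        return self._eval(X)[1]

    # -- state <-> coordinates ---------------------------------------------

    def _residue_backbone(self, num: int) -> dict[str, np.ndarray]:
        return {a.name: self.X0[self.index[(num, a.name)]]
                for a in self.atoms
                if a.residue_number == num and a.name in ("N", "CA", "C", "O", "CB")}

    def _apply_residue(self, X: np.ndarray, ridx: int, chi: np.ndarray) -> None:
        num, type3, _chi0 = self.residues[ridx]
        side = _chem.rebuild_sidechain(self._backbones[ridx], type3, chi)
        for name, xyz in side.items():
            X[self.index[(num, name)]] = xyz

    def _apply_ions(self, X: np.ndarray, state: dict) -> None:
        X[self.ca_idx] = state["ca"]
        rot = Rotation.from_rotvec(state["rotvec"]).as_matrix()
        X[self.pho_idx] = state["p"] + self.pho_local @ rot.T

    def build_coords(self, state: dict) -> np.ndarray:
        if not hasattr(self, "_backbones"):
            self._backbones = [self._residue_backbone(num)
                               for (num, _t, _c) in self.residues]
        X = self.X0.copy()
        for ridx, chi in enumerate(state["chi"]):
            self._apply_residue(X, ridx, chi)
        self._apply_ions(X, state)
        return X

    def initial_state(self, rng: np.random.Generator) -> dict:
        return {
            "chi": [chi0 + rng.normal(0.0, 12.0, size=chi0.size)
                    for (_n, _t, chi0) in self.residues],
            "ca": self.X0[self.ca_idx] + rng.normal(0.0, 0.15, size=3),
            "p": self.X0[self.p_idx] + rng.normal(0.0, 0.15, size=3),
            "rotvec": rng.normal(0.0, 0.08, size=3),
        }

    def anneal(
        self, rng: np.random.Generator,
        n_steps: int = 200, t_start: float = 10.0, t_end: float = 0.01,
    ) -> tuple[np.ndarray, dict]:
        state = self.initial_state(rng)
        X = self.build_coords(state)
        e = self.energy(X)
        chi_map = [(ridx, k) for ridx, (_n, _t, c) in enumerate(self.residues)
                   for k in range(c.size)]
        n_chi_dof = len(chi_map)
        n_dof = n_chi_dof + 3  # chi angles + ca + p translation + p rotation
        decay = (t_end / t_start) ** (1.0 / max(n_steps - 1, 1))
        temp = t_start
        for _step in range(n_steps):
            scale = max(math.sqrt(temp / t_start), 0.05)
            choices = rng.integers(0, n_dof, size=n_dof)
            for choice in choices:
                Xn = X.copy()
                undo = None
                if choice < n_chi_dof:
                    ridx, k = chi_map[choice]
                    chi = state["chi"][ridx]
                    old = chi[k]
                    chi[k] = old + rng.normal(0.0, 10.0 * scale)
                    self._apply_residue(Xn, ridx, chi)
                    undo = ("chi", ridx, k, old)
                elif choice == n_chi_dof:
                    old = state["ca"]
                    state["ca"] = old + rng.normal(0.0, 0.08 * scale, 3)
                    Xn[self.ca_idx] = state["ca"]
                    undo = ("ca", old)
                elif choice == n_chi_dof + 1:
                    old = state["p"]
                    state["p"] = old + rng.normal(0.0, 0.08 * scale, 3)
                    self._apply_ions(Xn, state)
                    undo = ("p", old)
                else:
                    old = state["rotvec"]
                    state["rotvec"] = old + rng.normal(0.0, 0.05 * scale, 3)
                    self._apply_ions(Xn, state)
                    undo = ("rotvec", old)
                en = self.energy(Xn)
                if en <= e or rng.random() < math.exp(-(en - e) / temp):
                    X, e = Xn, en
                elif undo[0] == "chi":
                    state["chi"][undo[1]][undo[2]] = undo[3]
                else:
                    state[undo[0]] = undo[1]
            temp *= decay
        return X, state

    def to_site_model(self, X: np.ndarray) -> SiteModel:
        structure = self.scaffold.copy()
        for a, xyz in zip(structure.atoms, X):
            a.pos = xyz.copy()
        score, table = restraint_energy(structure, self.rs)
        return SiteModel(structure=structure, score=score, per_restraint=table)


def sample_ensemble(
    scaffold: StructureModel,
    rs: RestraintSet,
    n_models: int,
    seed: int = 0,
    max_violation_sigma: float = 3.0,
    n_steps: int = 200,
    restart_budget: int | None = None,
) -> list[SiteModel]:
    """Generate restraint-satisfying site models by annealed restarts.

    Each restart perturbs the scaffold configuration, anneals the restraint
    pseudo-energy from T=10 to T=0.01 score units over ``n_steps`` sweeps,
    and accepts the end point if every restraint term and every auxiliary
    steric/exclusion term deviates by at most ``max_violation_sigma``
    sigmas.  Restarts are independently seeded, so the ensemble is a pure
    function of (scaffold, restraints, n_models, seed, budget).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    sampler = _Sampler(scaffold, rs)
    if restart_budget is None:
        restart_budget = 3 * n_models
    models: list[SiteModel] = []
    root = np.random.SeedSequence([seed, 0xC0B0])
    for restart, child in enumerate(root.spawn(restart_budget)):
        if len(models) >= n_models:
            break
        rng = np.random.default_rng(child)
        X, _state = sampler.anneal(rng, n_steps=n_steps)
        model = sampler.to_site_model(X)
        worst = float(model.per_restraint["deviation_sigma"].max())
        worst = max(worst, sampler.max_aux_violation(X))
        if worst <= max_violation_sigma:
            models.append(model)
    if len(models) < n_models:
        warnings.warn(
            f"restart budget exhausted: {len(models)}/{n_models} models accepted",
            RuntimeWarning, stacklevel=2,
        )
    return models
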