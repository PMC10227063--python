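"""Synthetic inputs with known ground truth for every pipeline stage.

The module produces (i) an idealized binding-site scaffold carrying the nine
site residues of the YfkE alpha-repeats (G68, N69, E72, N99, N252, E255,
H256, S278, Q281) together with one Ca2+ ion and one dihydrogen phosphate,
(ii) a set of mini-PDB survey fixtures with machine-readable truth labels,
and (iii) simulated assay datasets -- initial-rate tables, coupled uptake
time courses, one-site calorimetric isotherms, luminescence decays and
Gaussian alchemical work samples -- whose generating parameters are known
exactly, so each downstream fitter can be validated by round-trip recovery.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import _chem
from .protonation_fep import FepDataset, FepWindow
from .structure import Atom, StructureModel, write_pdb

__all__ = [
    "SITE_RESIDUES",
    "ScaffoldSpec",
    "TransportSimConfig",
    "ItcSimConfig",
    "FepSimConfig",
    "build_scaffold",
    "plant_survey_fixtures",
    "gen_initial_rates",
    "gen_transport_timecourse",
    "gen_paired_rates",
    "gen_itc_isotherm",
    "gen_lret_decay",
    "gen_fep_samples",
]

#: Residue numbers and wild-type identities of the binding-site positions.
SITE_RESIDUES: dict[int, str] = {
    68: "GLY", 69: "ASN", 72: "GLU", 99: "ASN", 252: "ASN",
    255: "GLU", 256: "HIS", 278: "SER", 281: "GLN",
}

CA_RESNUM = 401
PHOSPHATE_RESNUM = 402
PHOSPHATE_RESNAME = "2HP"


# -- configuration types ---------------------------------------------------


class ScaffoldSpec(BaseModel):
    """Residue identities and geometric seeds for the synthetic scaffold."""

    residue_types: dict[int, str] = Field(default_factory=lambda: dict(SITE_RESIDUES))
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ca_o_distance: float = 2.50       # Ca-carboxylate oxygen contact, Angstrom
    ca_contact_distance: float = 2.40  # Ca-carbonyl/amide oxygen contact
    ca_phosphate_o: float = 2.45       # Ca to nearest phosphate oxygen

    @model_validator(mode="after")
    def _check(self) -> "ScaffoldSpec":
        missing = set(SITE_RESIDUES) - set(self.residue_types)
        if missing:
            raise ValueError(f"scaffold spec missing site positions: {sorted(missing)}")
        extra = set(self.residue_types) - set(SITE_RESIDUES)
        if extra:
            raise ValueError(f"unknown site positions: {sorted(extra)}")
        for num, t3 in self.residue_types.items():
            if t3 not in _chem.SUPPORTED_RESIDUES:
                raise ValueError(f"invalid residue identity {t3!r} at position {num}")
        if not all(math.isfinite(v) for v in self.origin):
            raise ValueError("origin must be finite")
        for d in (self.ca_o_distance, self.ca_contact_distance, self.ca_phosphate_o):
            if not 1.5 < d < 8.0:
                raise ValueError("ion contact distances must be plausible (1.5-8 A)")
        return self


class TransportSimConfig(BaseModel):
    """Parameters of the vesicle-uptake simulator."""

    mode: str = "co_transport"
    km_ca: float = 69.0          # uM
    vmax_ca: float = 4.2         # umol/min/g
    km_pi: float = 4.9           # mM
    coupling_ratio: float = 1.0
    noise_cv: float = 0.05
    saturation_rate: float = 0.15  # 1/min, free amplitude parameter
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TransportSimConfig":
        modes = {"low_flux", "co_transport", "control_empty", "cccp", "edta"}
        if self.mode not in modes:
            raise ValueError(f"mode must be one of {sorted(modes)}")
        if self.km_ca <= 0 or self.vmax_ca <= 0 or self.km_pi <= 0:
            raise ValueError("km and vmax must be positive")
        if not 0.0 <= self.noise_cv <= 0.5:
            raise ValueError("noise_cv must be in [0, 0.5]")
        if self.coupling_ratio <= 0:
            raise ValueError("coupling_ratio must be positive")
        return self


class ItcSimConfig(BaseModel):
    """Parameters of the one-site calorimetric titration simulator."""

    kd: float                    # M
    delta_h: float = -8.0        # kcal/mol
    n_sites: float = 1.0
    cell_conc: float = 5e-6      # M
    syringe_conc: float = 1e-4   # M
    injection_volume: float = 10e-6  # L
    n_injections: int = 25
    cell_volume: float = 1.4e-3  # L
    noise_sd: float = 0.05       # ucal
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ItcSimConfig":
        if min(self.kd, self.cell_conc, self.syringe_conc,
               self.injection_volume, self.cell_volume) <= 0:
            raise ValueError("kd, concentrations and volumes must be positive")
        if self.n_injections < 5:
            raise ValueError("need at least 5 injections")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return self


class FepSimConfig(BaseModel):
    """Parameters of the Gaussian alchemical-work simulator."""

    n_windows: int = 40
    samples_per_window: int = 1000
    true_dg_per_window: float = 0.1  # kT
    work_sd: float = 1.0             # kT
    equil_fraction: float = 0.2
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FepSimConfig":
        if self.n_windows < 1:
            raise ValueError("need at least one window")
        if self.samples_per_window < 3:
            raise ValueError("need at least 3 samples per window")
        if self.work_sd < 0:
            raise ValueError("work_sd must be non-negative")
        if not 0.0 <= self.equil_fraction < 0.9:
            raise ValueError("equil_fraction must be in [0, 0.9)")
        return self


# -- scaffold construction -------------------------------------------------

# Outward unit directions of each site position relative to its reference
# point (the Ca2+ ion, the phosphorus atom, or a previously placed atom).
def _unit(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    return a / np.linalg.norm(a)


_DIRECTIONS = {
    68: _unit((0.0, 0.766, -0.643)),
    69: _unit((0.0, -0.766, -0.643)),
    72: np.array([1.0, 0.0, 0.0]),
    255: np.array([-1.0, 0.0, 0.0]),
    256: _unit((0.6, 0.8, 0.0)),
    252: _unit((-0.6, 0.8, 0.0)),
    99: _unit((-0.8126, 0.1552, 0.5618)),
    278: _unit((0.3, -0.8, 0.5)),
    281: _unit((-0.4928, -0.0583, 0.8682)),
}

# Plane-orientation hints (arbitrary but fixed; chosen so that the placed
# residue bodies radiate away from the site without steric overlap).
_NORMAL_HINTS = {
    68: (1.0, 0.0, 0.0),
    69: (1.0, 0.0, 0.0),
    72: (0.0, 0.0, 1.0),
    255: (0.0, 0.0, 1.0),
    256: (-0.7071, -0.7071, 0.0),
    252: (0.0, 0.0, 1.0),
    99: (0.0, 0.0, 1.0),
    278: (1.0, 0.0, 0.0),
    281: (1.0, 0.0, 0.0),
}

# Distance from the reference point to the functional contact atom.
_P_CONTACTS = {256: 3.9, 252: 4.5, 278: 4.5}

# Side-chain orientation overrides (frame x axis) for the CG-anchored
# placements, pointing their amide groups into open space.
_ORIENTS: dict[int, np.ndarray] = {
    252: _unit((-0.0742, -0.4224, 0.9034)),
    99: _unit((0.684, -0.3001, 0.6649)),
}


def _place_residue(
    type3: str,
    number: int,
    contact_point: np.ndarray,
    outward: np.ndarray,
    normal_hint: np.ndarray,
    ca_pos: np.ndarray | None = None,
    ca_o_distance: float = 2.5,
    origin_at_contact: bool = False,
    orient: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Rigidly place a residue template so its functional group hits a target.

    For carboxylates the target is a symmetric bi-dentate pose around the
    Ca2+ ion (both oxygens at ``ca_o_distance``); for the other types the
    primary functional atom is put at ``contact_point`` with the side chain
    body extending along ``outward``.
    """
    pos = _chem.build_residue(type3)
    origin_local, frame_local = _chem.anchor_frame(pos, type3)
    if type3 in ("GLU", "ASP") and ca_pos is not None:
        c_name = "CD" if type3 == "GLU" else "CG"
        o_name = "OE1" if type3 == "GLU" else "OD1"
        bisector = frame_local[:, 0]
        r_co = np.linalg.norm(pos[o_name] - pos[c_name])
        proj = float(np.dot(pos[o_name] - pos[c_name], bisector))
        perp = math.sqrt(max(r_co**2 - proj**2, 0.0))
        d_c = proj + math.sqrt(max(ca_o_distance**2 - perp**2, 0.0))
        origin_target = ca_pos + d_c * outward
        frame_target = _chem.frame_from(-outward, normal_hint)
    elif type3 == "ASN":
        # anchor origin is CG; by default the contact point is the OD1
        # oxygen one bond further in, unless CG itself is the restrained atom
        bond = 0.0 if origin_at_contact else np.linalg.norm(pos["OD1"] - pos["CG"])
        origin_target = contact_point + bond * outward
        x_dir = -outward if orient is None else orient
        frame_target = _chem.frame_from(x_dir, normal_hint)
    else:
        origin_target = contact_point
        frame_target = _chem.frame_from(outward, normal_hint)
    return _chem.transform_positions(pos, origin_local, frame_local,
                                     origin_target, frame_target)


def build_scaffold(spec: ScaffoldSpec | None = None) -> StructureModel:
    """Build the synthetic binding-site scaffold.

    The construction is deterministic: residues are placed rigidly around
    seeded Ca2+ and phosphate positions so that, for the wild-type residue
    set, the full default restraint ledger is satisfied exactly.  Backbone
    fidelity to any particular crystal structure is not claimed -- only the
    inter-residue geometry needed for the restraints to be satisfiable.
    """
    spec = spec or ScaffoldSpec()
    origin = np.asarray(spec.origin, dtype=float)
    ca_pos = origin.copy()

    # phosphate: nearest oxygen toward Ca along +z
    ptmpl = _chem.phosphate_template()
    bond = np.linalg.norm(ptmpl["O1"] - ptmpl["P"])
    o1_target = ca_pos + np.array([0.0, 0.0, spec.ca_phosphate_o])
    frame_t = _chem.frame_from((0.0, 0.0, 1.0), (1.0, 0.0, 0.0))
    frame_l = _chem.frame_from(ptmpl["P"] - ptmpl["O1"], (1.0, 0.0, 0.0))
    ppos = _chem.transform_positions(ptmpl, ptmpl["O1"], frame_l, o1_target, frame_t)
    p_pos = ppos["P"]

    placed: dict[int, dict[str, np.ndarray]] = {}
    order = [68, 69, 72, 255, 256, 252, 278, 99, 281]
    for num in order:
        t3 = spec.residue_types[num]
        outward = _DIRECTIONS[num]
        hint = np.asarray(_NORMAL_HINTS[num], dtype=float)
        if num in (72, 255):
            contact = ca_pos + spec.ca_o_distance * outward
            pos = _place_residue(t3, num, contact, outward, hint,
                                 ca_pos=ca_pos, ca_o_distance=spec.ca_o_distance)
        elif num in (68, 69):
            contact = ca_pos + spec.ca_contact_distance * outward
            pos = _place_residue(t3, num, contact, outward, hint)
        elif num in _P_CONTACTS:
            contact = p_pos + _P_CONTACTS[num] * outward
            # for N252 the restrained atom is CG itself, not its oxygen
            pos = _place_residue(t3, num, contact, outward, hint,
                                 origin_at_contact=(num == 252),
                                 orient=_ORIENTS.get(num))
        elif num == 99:
            anchor252 = placed[252].get("CG", placed[252][
                _chem.SECONDARY_ATOM[spec.residue_types[252]]])
            contact = anchor252 + 4.2 * outward
            pos = _place_residue(t3, num, contact, outward, hint,
                                 origin_at_contact=True,
                                 orient=_ORIENTS.get(num))
        elif num == 281:
            t69 = spec.residue_types[69]
            sec69 = placed[69][_chem.SECONDARY_ATOM[t69]]
            contact = sec69 + 3.2 * outward
            pos = _place_residue(t3, num, contact, outward, hint)
        else:  # pragma: no cover - exhaustive above
            raise AssertionError(num)
        placed[num] = pos

    atoms: list[Atom] = []
    for num in sorted(placed):
        atoms.extend(_chem.residue_atoms(spec.residue_types[num], num, "A", placed[num]))
    atoms.append(Atom(name="CA", element="Ca", residue_name="CA",
                      residue_number=CA_RESNUM, chain="A", pos=ca_pos, het=True))
    for name in ("P", "O1", "O2", "O3", "O4"):
        atoms.append(Atom(name=name, element=name[0], residue_name=PHOSPHATE_RESNAME,
                          residue_number=PHOSPHATE_RESNUM, chain="A",
                          pos=ppos[name], het=True))
    model = StructureModel(atoms=atoms, source_id="synthetic-scaffold")
    model.chain_sequences = model.derive_chain_sequences()
    return model


# -- survey fixtures -------------------------------------------------------

# A second, sequence-divergent positive: same geometry engine, different
# residue identities (still 2 acidic + 1 His around the shared site).
_VARIANT_POSITIVE = {
    68: "SER", 69: "ASN", 72: "ASP", 99: "GLN", 252: "GLN",
    255: "ASP", 256: "HIS", 278: "GLY", 281: "ASN",
}


def plant_survey_fixtures(out_dir: str | Path, seed: int) -> tuple[list[Path], pd.DataFrame]:
    """Write mini-PDB survey fixtures plus a machine-readable truth table.

    Produces two true positives (co-bound Ca/phosphate site, 2 acidic + 1
    His flanking, resolution better than 3 A) and four negatives, each
    failing exactly one selection criterion: ion-pair distance, flanking
    motif, resolution, or sequence redundancy with an accepted positive.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    entries: list[tuple[str, StructureModel, float, str, str]] = []

    pos_a = build_scaffold()
    entries.append(("fix_pos_a", pos_a, 1.8, "accept", ""))

    pos_b = build_scaffold(ScaffoldSpec(residue_types=_VARIANT_POSITIVE))
    entries.append(("fix_pos_b", pos_b, 2.2, "accept", ""))

    # distance decoy: phosphate (and its His partner) shifted away from Ca
    neg_dist = build_scaffold()
    shift = np.array([0.0, 0.0, 2.6])
    for a in neg_dist.atoms:
        if a.residue_number in (PHOSPHATE_RESNUM, 256):
            a.pos = a.pos + shift
    entries.append(("fix_neg_distance", neg_dist, 2.0, "reject", "distance"))

    # motif decoy: histidine replaced, everything else intact
    no_his = dict(SITE_RESIDUES)
    no_his[256] = "SER"
    neg_motif = build_scaffold(ScaffoldSpec(residue_types=no_his))
    entries.append(("fix_neg_motif", neg_motif, 2.0, "reject", "motif"))

    # resolution decoy: a genuine site, but the structure is too coarse
    neg_res = build_scaffold()
    entries.append(("fix_neg_resolution", neg_res, 3.5, "reject", "resolution"))

    # redundancy decoy: jittered copy of the first positive (identity 1.0)
    neg_dup = build_scaffold()
    for a in neg_dup.atoms:
        a.pos = a.pos + rng.normal(0.0, 0.05, size=3)
    entries.append(("fix_neg_redundant", neg_dup, 2.5, "reject", "redundancy"))

    paths: list[Path] = []
    rows = []
    for name, model, resolution, label, reason in entries:
        model.resolution = resolution
        model.source_id = name
        path = write_pdb(model, out_dir / f"{name}.pdb")
        paths.append(path)
        rows.append({"file": path.name, "source_id": name, "label": label,
                     "reason": reason, "resolution": resolution})
    truth = pd.DataFrame(rows)
    (out_dir / "truth.json").write_text(json.dumps(rows, indent=1))
    return paths, truth


# -- assay generators ------------------------------------------------------


def gen_initial_rates(
    km: float,
    vmax: float,
    conc_grid: Sequence[float],
    noise_cv: float = 0.05,
    n_rep: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Michaelis-Menten initial rates with multiplicative Gaussian noise.

    v = vmax * S / (km + S) * (1 + eps), eps ~ Normal(0, noise_cv).
    Columns: conc, replicate, rate.
    """
    if km <= 0 or vmax <= 0:
        raise ValueError("km and vmax must be positive")
    conc = np.asarray(list(conc_grid), dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration grid")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_rep):
        v = vmax * conc / (km + conc)
        if noise_cv > 0:
            v = v * (1.0 + rng.normal(0.0, noise_cv, size=conc.size))
        rows.append(pd.DataFrame({"conc": conc, "replicate": rep, "rate": v}))
    return pd.concat(rows, ignore_index=True)


def _uptake_curve(v0: float, k: float, times: np.ndarray) -> np.ndarray:
    """Saturating uptake with initial slope v0: U(t) = (v0/k)(1 - e^{-kt})."""
    return (v0 / k) * (1.0 - np.exp(-k * times))


def gen_transport_timecourse(
    config: TransportSimConfig,
    times: Sequence[float],
    ca_conc: float,
    pi_conc: float,
) -> pd.DataFrame:
    """Paired Ca2+ / Pi uptake time courses for one assay mode.

    In ``co_transport`` mode the expected Pi uptake is coupling_ratio times
    the Ca uptake at every time point.  ``control_empty`` and ``cccp``
    (protonophore) modes transport nothing -- readings are pure baseline
    noise around zero -- and in ``edta`` mode (Ca2+ chelated) uptake is
    identically zero.  Columns: time, ca_uptake, pi_uptake.
    """
    t = np.asarray(list(times), dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted and non-negative")
    if ca_conc < 0 or pi_conc < 0:
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(config.seed)
    k = config.saturation_rate
    v0_ca = config.vmax_ca * ca_conc / (config.km_ca + ca_conc)

    if config.mode == "edta":
        ca_u = np.zeros_like(t)
        pi_u = np.zeros_like(t)
    elif config.mode in ("control_empty", "cccp"):
        floor = 0.02 * config.vmax_ca / k
        ca_u = rng.normal(0.0, config.noise_cv * floor + 1e-12, size=t.size)
        pi_u = rng.normal(0.0, config.noise_cv * floor + 1e-12, size=t.size)
    else:
        ca_u = _uptake_curve(v0_ca, k, t)
        if config.mode == "co_transport":
            pi_u = config.coupling_ratio * ca_u
        else:  # low_flux: no phosphate co-substrate
            pi_u = np.zeros_like(t)
        if config.noise_cv > 0:
            ca_u = ca_u * (1.0 + rng.normal(0.0, config.noise_cv, size=t.size))
            if config.mode == "co_transport":
                pi_u = pi_u * (1.0 + rng.normal(0.0, config.noise_cv, size=t.size))
    return pd.DataFrame({"time": t, "ca_uptake": ca_u, "pi_uptake": pi_u})


def gen_paired_rates(
    config: TransportSimConfig,
    times: Sequence[float],
    ca_conc: float,
    pi_conc: float,
    n_rep: int = 4,
) -> pd.DataFrame:
    """Matched per-time-point Ca and Pi transport rates (co-transport design).

    Instantaneous rates v(t) = v0 e^{-kt} with independent multiplicative
    noise on each channel; expected Pi/Ca ratio equals the coupling ratio.
    Columns: time, replicate, ca_rate, pi_rate.
    """
    t = np.asarray(list(times), dtype=float)
    rng = np.random.default_rng(config.seed)
    v0 = config.vmax_ca * ca_conc / (config.km_ca + ca_conc)
    base = v0 * np.exp(-config.saturation_rate * t)
    rows = []
    for rep in range(n_rep):
        ca = base.copy()
        pi = config.coupling_ratio * base
        if config.noise_cv > 0:
            ca = ca * (1.0 + rng.normal(0.0, config.noise_cv, size=t.size))
            pi = pi * (1.0 + rng.normal(0.0, config.noise_cv, size=t.size))
        rows.append(pd.DataFrame({"time": t, "replicate": rep,
                                  "ca_rate": ca, "pi_rate": pi}))
    return pd.concat(rows, ignore_index=True)


def gen_itc_isotherm(config: ItcSimConfig) -> pd.DataFrame:
    """Simulated injection heats for a one-site titration.

    The noiseless heats come from the same single-site binding model used by
    the fitter (quadratic 1:1 equilibrium with per-injection dilution
    bookkeeping); Gaussian noise in ucal is added on top.  Columns:
    injection, heat_ucal.  A ``low_saturation`` flag is set in ``attrs``
    when the syringe load cannot approach saturation.
    """
    from .assay_analysis import one_site_heats

    heats = one_site_heats(
        kd=config.kd, delta_h=config.delta_h, n_sites=config.n_sites,
        cell_conc=config.cell_conc, syringe_conc=config.syringe_conc,
        injection_volume=config.injection_volume,
        n_injections=config.n_injections, cell_volume=config.cell_volume,
    )
    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        heats = heats + rng.normal(0.0, config.noise_sd, size=heats.size)
    df = pd.DataFrame({"injection": np.arange(1, config.n_injections + 1),
                       "heat_ucal": heats})
    df.attrs["config"] = config.model_dump()
    df.attrs["low_saturation"] = bool(
        config.syringe_conc <= config.cell_conc * config.n_sites / 10.0
    )
    return df


def gen_lret_decay(
    tau: float,
    n_points: int = 200,
    noise_sd: float = 0.01,
    seed: int = 0,
    t_max_lifetimes: float = 5.0,
) -> pd.DataFrame:
    """Single-exponential luminescence decay y(t) = exp(-t/tau) + noise.

    ``noise_sd`` is expressed as a fraction of the unit amplitude and is
    added as Gaussian noise, the way photon-counting baselines err.  The
    time grid spans ``t_max_lifetimes`` lifetimes (>= 3).  Columns: t, y.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if t_max_lifetimes < 3:
        raise ValueError("trace must span at least 3 lifetimes")
    t = np.linspace(0.0, t_max_lifetimes * tau, n_points)
    y = np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"t": t, "y": y})


def gen_fep_samples(config: FepSimConfig) -> FepDataset:
    """Gaussian per-window work samples with known analytic ground truth.

    For Gaussian dU ~ Normal(mu, sd^2), exponential averaging gives exactly
    dG = mu - sd^2/2 (kT); the generator therefore draws each window with
    mu = true_dg_per_window + sd^2/2 so the per-window ground truth is
    ``true_dg_per_window``.  The reverse-direction windows are generated
    independently with negated ground truth, and the first
    ``equil_fraction`` of samples in every window is flagged as
    equilibration.
    """
    rng = np.random.default_rng(config.seed)
    mu_f = config.true_dg_per_window + 0.5 * config.work_sd**2
    mu_r = -config.true_dg_per_window + 0.5 * config.work_sd**2
    n_eq = math.ceil(config.equil_fraction * config.samples_per_window)
    windows: list[FepWindow] = []
    for direction, mu in (("forward", mu_f), ("reverse", mu_r)):
        for w in range(config.n_windows):
            samples = rng.normal(mu, config.work_sd, size=config.samples_per_window)
            mask = np.zeros(config.samples_per_window, dtype=bool)
            mask[:n_eq] = True
            windows.append(FepWindow(lambda_index=w, direction=direction,
                                     samples=samples, equil_mask=mask))
    ds = FepDataset(windows=windows, site_label="synthetic")
    return ds
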