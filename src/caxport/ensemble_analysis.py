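"""Ensemble clustering by pairwise RMSD and voxel occupancy mapping.

The RMSD selection mirrors the site atoms used to compare binding-site
models: all non-hydrogen atoms of residues N69, E72, N99, N252, E255, H256,
S278 and Q281, plus the Ca2+ and phosphate ions.  Models share a frozen
backbone frame, so RMSD is computed directly without superposition.
Clustering is leader-style in model-index order with the founding model as
representative; occupancy grids report, per voxel, the fraction of models
that place at least one selected atom center inside the voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .restraint_model import SiteModel
from .structure import StructureModel

__all__ = [
    "RmsdSelection",
    "EnsembleClustering",
    "OccupancyGrid",
    "pairwise_rmsd",
    "cluster_ensemble",
    "cluster_statistics",
    "occupancy_map",
    "write_opendx",
]

DEFAULT_RMSD_RESIDUES = frozenset({69, 72, 99, 252, 255, 256, 278, 281})


def _structure(m: StructureModel | SiteModel) -> StructureModel:
    return m.structure if isinstance(m, SiteModel) else m


@dataclass(frozen=True)
class RmsdSelection:
    """Which atoms enter the pairwise RMSD (hydrogens always excluded)."""

    residues: frozenset[int] = DEFAULT_RMSD_RESIDUES
    include_ions: bool = True

    def __post_init__(self) -> None:
        if not self.residues and not self.include_ions:
            raise ValueError("selection must not be empty")

    def atom_keys(self, model: StructureModel | SiteModel) -> list[tuple[int, str]]:
        s = _structure(model)
        keys = []
        for a in s.atoms:
            if a.element == "H":
                continue
            if a.het or a.residue_name in ("CA", "2HP", "PO4", "PI", "H2P"):
                if self.include_ions:
                    keys.append((a.residue_number, a.name))
            elif a.residue_number in self.residues:
                keys.append((a.residue_number, a.name))
        return sorted(keys)

    def coords(self, model: StructureModel | SiteModel) -> np.ndarray:
        s = _structure(model)
        index = {(a.residue_number, a.name): a.pos for a in s.atoms}
        keys = self.atom_keys(model)
        if not keys:
            raise ValueError("selection matches no atoms")
        return np.array([index[k] for k in keys])


def pairwise_rmsd(
    a: StructureModel | SiteModel,
    b: StructureModel | SiteModel,
    sel: RmsdSelection | None = None,
) -> float:
    """Direct (no-superposition) RMSD over the selected atoms, in Angstrom."""
    sel = sel or RmsdSelection()
    ka, kb = sel.atom_keys(a), sel.atom_keys(b)
    if ka != kb:
        raise ValueError("models have mismatched atom selections")
    xa, xb = sel.coords(a), sel.coords(b)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


@dataclass
class EnsembleClustering:
    """Leader-clustering result over a model ensemble."""

    n_models: int
    threshold: float
    assignments: np.ndarray          # model index -> cluster id
    populations: np.ndarray          # cluster id -> member count
    representatives: np.ndarray      # cluster id -> founding model index

    def __post_init__(self) -> None:
        if int(self.populations.sum()) != self.n_models:
            raise ValueError("cluster populations must sum to n_models")

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.populations, kind="stable")
        return pd.DataFrame({
            "cluster": order,
            "population": self.populations[order],
            "fraction": self.populations[order] / self.n_models,
            "representative": self.representatives[order],
        })


def cluster_ensemble(
    models: Sequence[StructureModel | SiteModel],
    sel: RmsdSelection | None = None,
    threshold: float = 0.6,
) -> EnsembleClustering:
    """Leader clustering in model-index order.

    A model joins the first existing cluster whose representative (the
    founding model) is within ``threshold`` RMSD; otherwise it founds a new
    cluster.  Deterministic for a fixed model order.
    """
    if not models:
        raise ValueError("need at least one model")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    sel = sel or RmsdSelection()
    coords = [sel.coords(m) for m in models]
    keys0 = sel.atom_keys(models[0])
    for m in models[1:]:
        if sel.atom_keys(m) != keys0:
            raise ValueError("models have mismatched atom selections")
    reps: list[int] = []
    assignments = np.empty(len(models), dtype=int)
    for i, x in enumerate(coords):
        for cid, rep in enumerate(reps):
            rmsd = float(np.sqrt(np.mean(np.sum((x - coords[rep]) ** 2, axis=1))))
            if rmsd <= threshold:
                assignments[i] = cid
                break
        else:
            assignments[i] = len(reps)
            reps.append(i)
    populations = np.bincount(assignments, minlength=len(reps))
    return EnsembleClustering(
        n_models=len(models), threshold=threshold, assignments=assignments,
        populations=populations, representatives=np.array(reps, dtype=int),
    )


def cluster_statistics(c: EnsembleClustering, min_size: int = 10) -> dict[str, float]:
    """Summary of clusters larger than ``min_size`` and their coverage."""
    big = c.populations > min_size
    return {
        "n_clusters": int(c.populations.size),
        "n_clusters_above_min": int(big.sum()),
        "coverage_above_min": float(c.populations[big].sum() / c.n_models),
        "top_cluster_fraction": float(c.populations.max() / c.n_models),
    }


@dataclass
class OccupancyGrid:
    """Per-voxel fraction of models occupying the voxel."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # 3-D array in [0, 1]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("occupancy values must lie in [0, 1]")

    def contour(self, level: float = 0.85) -> np.ndarray:
        """Boolean mask of voxels with occupancy >= level."""
        return self.values >= level

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        idx = np.argwhere(mask if mask is not None else np.ones_like(self.values, bool))
        return self.origin + (idx + 0.5) * self.spacing


def occupancy_map(
    models: Sequence[StructureModel | SiteModel],
    sel: RmsdSelection | Sequence[tuple[int, str]] | None = None,
    spacing: float = 0.5,
    origin: np.ndarray | None = None,
) -> OccupancyGrid:
    """Fraction of models placing >=1 selected atom center in each voxel.

    ``sel`` may be an RmsdSelection or an explicit list of
    (residue_number, atom_name) keys (e.g. just the Ca2+ ion).
    """
    if not models:
        raise ValueError("need at least one model")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if sel is None or isinstance(sel, RmsdSelection):
        selection = sel or RmsdSelection()
        per_model = [selection.coords(m) for m in models]
    else:
        keys = list(sel)
        per_model = []
        for m in models:
            s = _structure(m)
            index = {(a.residue_number, a.name): a.pos for a in s.atoms}
            per_model.append(np.array([index[k] for k in keys]))
    allx = np.vstack(per_model)
    if origin is None:
        origin = np.floor(allx.min(axis=0) / spacing) * spacing - spacing
    origin = np.asarray(origin, dtype=float)
    shape = np.ceil((allx.max(axis=0) - origin) / spacing).astype(int) + 1
    counts = np.zeros(shape, dtype=int)
    for x in per_model:
        vox = np.floor((x - origin) / spacing).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            raise ValueError("grid origin does not cover all ensemble atoms")
        uniq = np.unique(vox, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return OccupancyGrid(origin=origin, spacing=spacing,
                         values=counts / len(models))


def write_opendx(grid: OccupancyGrid, path: str | Path) -> Path:
    """Write an occupancy grid in OpenDX scalar-field format."""
    path = Path(path)
    nx, ny, nz = grid.values.shape
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.4f} {:.4f} {:.4f}".format(*grid.origin),
        f"delta {grid.spacing:.4f} 0 0",
        f"delta 0 {grid.spacing:.4f} 0",
        f"delta 0 0 {grid.spacing:.4f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.ravel(order="C")
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6f}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "occupancy" class field')
    path.write_text("\n".join(lines) + "\n")
    return path
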