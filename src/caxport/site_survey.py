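"""Geometric survey for shared Ca2+/phosphate binding sites.

Implements the four-stage selection used to scan crystal structures for a
co-bound calcium/phosphate site like the one in the CAX antiporter YfkE:

1. resolution 3.0 A or better;
2. one Ca2+ and one phosphate entity bound in a common site, i.e. the
   minimum over atom pairs of the Ca-to-phosphate distance is <= 3.2 A;
3. the site is flanked by at least two acidic side chains and one
   histidine (side-chain functional atoms within the flank cutoff of
   either ion);
4. non-redundancy: global sequence identity below 70% to any previously
   accepted structure, iterating structures in ascending-resolution order.

Each rejection is annotated with the first failing criterion, so decoy
fixtures that fail exactly one stage are classified unambiguously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from .structure import Atom, ParseError, StructureModel, parse_structure

__all__ = [
    "CoBoundSite",
    "SurveyCriteria",
    "SurveyReport",
    "parse_structure",
    "find_co_bound_sites",
    "motif_check",
    "pairwise_identity",
    "run_survey",
]

#: Side-chain functional atoms considered when listing flanking residues.
FLANK_FUNCTIONAL_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2"),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
}

ACIDIC = frozenset({"ASP", "GLU"})

_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SurveyCriteria:
    """Thresholds of the four selection stages."""

    max_resolution: float = 3.0
    max_ion_distance: float = 3.2
    identity_threshold: float = 0.70
    n_acidic: int = 2
    n_histidine: int = 1
    flank_cutoff: float = 4.5
    phosphate_codes: frozenset[str] = frozenset({"PO4", "2HP", "PI", "H2P"})

    def __post_init__(self) -> None:
        if min(self.max_resolution, self.max_ion_distance, self.flank_cutoff) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass
class CoBoundSite:
    """A Ca2+/phosphate pair bound in a common site."""

    ca_atom: Atom
    phosphate_atoms: list[Atom]
    min_ion_distance: float
    flanking_residues: list[tuple[str, int, float]]  # (residue name, number, distance)

    def __post_init__(self) -> None:
        if self.min_ion_distance < 0:
            raise ValueError("distance must be non-negative")
        self.flanking_residues = sorted(self.flanking_residues, key=lambda t: t[2])


def find_co_bound_sites(
    s: StructureModel, criteria: SurveyCriteria | None = None
) -> list[CoBoundSite]:
    """All Ca/phosphate entity pairs whose closest approach is within bounds.

    The ion-pair distance is the minimum over (Ca atom, phosphate non-H
    atom) pairs; flanking residues are those with a side-chain functional
    atom within ``flank_cutoff`` of either ion.
    """
    criteria = criteria or SurveyCriteria()
    ca_ions = [a for a in s.atoms if a.residue_name == "CA" and a.element == "Ca"]
    pho_groups: dict[tuple[str, int], list[Atom]] = {}
    for a in s.atoms:
        if a.residue_name in criteria.phosphate_codes and a.element != "H":
            pho_groups.setdefault((a.chain, a.residue_number), []).append(a)
    sites = []
    for ca in ca_ions:
        for _key, group in sorted(pho_groups.items()):
            dmin = min(float(np.linalg.norm(ca.pos - a.pos)) for a in group)
            if dmin > criteria.max_ion_distance:
                continue
            flanking = []
            for (chain, num, name3), res_atoms in s.residues().items():
                fnames = FLANK_FUNCTIONAL_ATOMS.get(name3)
                if not fnames:
                    continue
                targets = [ca.pos] + [a.pos for a in group]
                dists = [float(np.linalg.norm(a.pos - t))
                         for a in res_atoms if a.name in fnames for t in targets]
                if dists and min(dists) <= criteria.flank_cutoff:
                    flanking.append((name3, num, min(dists)))
            sites.append(CoBoundSite(ca_atom=ca, phosphate_atoms=list(group),
                                     min_ion_distance=dmin,
                                     flanking_residues=flanking))
    return sites


def motif_check(site: CoBoundSite, criteria: SurveyCriteria | None = None) -> bool:
    """True iff the flanking list has >=2 acidic residues and >=1 histidine."""
    criteria = criteria or SurveyCriteria()
    within = [(name3, num) for name3, num, d in site.flanking_residues
              if d <= criteria.flank_cutoff]
    n_acidic = sum(1 for name3, _ in within if name3 in ACIDIC)
    n_his = sum(1 for name3, _ in within if name3 == "HIS")
    return n_acidic >= criteria.n_acidic and n_his >= criteria.n_histidine


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Needleman-Wunsch with match +1, mismatch 0, gap open -5, gap extend -1;
    identity is the number of identical aligned positions divided by the
    alignment length excluding terminal-gap columns.  Symmetric by
    construction of the scoring scheme.
    """
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("sequences must be non-empty")
        bad = set(seq.upper()) - _AA_LETTERS
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    cols = [i for i in range(len(ga)) if ga[i] != "-" and gb[i] != "-"]
    first, last = cols[0], cols[-1]
    n_ident = sum(1 for i in range(first, last + 1) if ga[i] == gb[i] and ga[i] != "-")
    length = last - first + 1
    return n_ident / length


@dataclass
class SurveyReport:
    """Accepted hits with their sites, and per-file rejection reasons."""

    accepted: list[tuple[StructureModel, list[CoBoundSite]]] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)  # source_id -> reason
    parse_failures: dict[str, str] = field(default_factory=dict)

    @property
    def accepted_ids(self) -> list[str]:
        return [m.source_id for m, _ in self.accepted]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, sites in self.accepted:
            best = min(sites, key=lambda s: s.min_ion_distance)
            rows.append({"source_id": m.source_id, "status": "accept", "reason": "",
                         "resolution": m.resolution, "n_sites": len(sites),
                         "min_ion_distance": best.min_ion_distance})
        for sid, reason in self.rejected.items():
            rows.append({"source_id": sid, "status": "reject", "reason": reason,
                         "resolution": None, "n_sites": 0,
                         "min_ion_distance": None})
        for sid, msg in self.parse_failures.items():
            rows.append({"source_id": sid, "status": "error", "reason": msg,
                         "resolution": None, "n_sites": 0,
                         "min_ion_distance": None})
        return pd.DataFrame(rows)

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            detail = {
                "accepted": [
                    {"source_id": m.source_id, "resolution": m.resolution,
                     "sites": [{
                         "min_ion_distance": s.min_ion_distance,
                         "flanking": [list(f) for f in s.flanking_residues],
                     } for s in sites]}
                    for m, sites in self.accepted
                ],
                "rejected": self.rejected,
                "parse_failures": self.parse_failures,
            }
            Path(json_path).write_text(json.dumps(detail, indent=1))


def _best_chain_identity(a: StructureModel, b: StructureModel) -> float:
    best = 0.0
    for sa in a.chain_sequences.values():
        for sb in b.chain_sequences.values():
            if sa and sb:
                best = max(best, pairwise_identity(sa, sb))
    return best


def run_survey(
    files: list[str | Path], criteria: SurveyCriteria | None = None
) -> SurveyReport:
    """Run the four-stage selection over a set of structure files.

    Files are processed in ascending-resolution (then source-id) order so
    the greedy redundancy filter is deterministic; each rejection records
    the first failing criterion.
    """
    if not files:
        raise ValueError("need at least one file")
    criteria = criteria or SurveyCriteria()
    report = SurveyReport()
    models: list[StructureModel] = []
    for f in files:
        try:
            models.append(parse_structure(f))
        except ParseError as exc:
            report.parse_failures[Path(f).stem] = str(exc)
    models.sort(key=lambda m: (m.resolution if m.resolution is not None
                               else float("inf"), m.source_id))
    for m in models:
        if m.resolution is None or m.resolution > criteria.max_resolution:
            report.rejected[m.source_id] = "resolution"
            continue
        sites = find_co_bound_sites(m, criteria)
        if not sites:
            report.rejected[m.source_id] = "distance"
            continue
        good = [s for s in sites if motif_check(s, criteria)]
        if not good:
            report.rejected[m.source_id] = "motif"
            continue
        if any(_best_chain_identity(m, prev) >= criteria.identity_threshold
               for prev, _ in report.accepted):
            report.rejected[m.source_id] = "redundancy"
            continue
        report.accepted.append((m, good))
    return report
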