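"""Docking-result filtering against pocket specifications.

Candidate off-targets are structurally validated by docking a ligand into
biologically relevant pockets (e.g. the BH3/BH4 homology domains of the
Bcl-2 apoptosis regulators).  This module does not run a docking engine:
it parses pocket tables (candidate, structure, chain, semicolon-separated
residue positions), extracts heavy-atom pocket coordinates from PDB files,
computes ligand-pocket minimum distances, and applies the positive-call
filter — binding free energy strictly below -6 kcal/mol AND minimum
distance strictly below 5 angstrom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

ENERGY_CUT = -6.0   # kcal/mol, strict
DIST_CUT = 5.0      # angstrom, strict


@dataclass(frozen=True)
class PocketSpec:
    """One docking pocket: residue positions (PDB author numbering)."""

    candidate: str
    uniprot: str
    pdb_id: str
    chain: str
    residue_positions: tuple
    pocket_type: str = ""

    def __post_init__(self):
        if len(self.pdb_id) != 4:
            raise ValidationError(f"PDB id must be 4 characters: {self.pdb_id!r}")
        if not self.residue_positions:
            raise ValidationError("pocket has no residue positions")
        object.__setattr__(self, "residue_positions",
                           tuple(sorted(set(self.residue_positions))))

    @property
    def label(self) -> str:
        return f"{self.pdb_id}:{self.chain}:{self.pocket_type}"


@dataclass(frozen=True)
class DockingPose:
    ligand_id: str
    pocket_label: str
    binding_energy: float   # kcal/mol
    min_distance: float | None = None  # angstrom

    def __post_init__(self):
        if self.min_distance is not None and self.min_distance < 0:
            raise ValidationError("min_distance must be >= 0")


@dataclass
class CandidateReport:
    candidate: str
    best_pose_per_pocket: dict  # pocket label -> DockingPose or None
    validated: bool


def parse_pocket_table(path) -> list[PocketSpec]:
    """Read a pocket CSV/TSV with semicolon-separated residue lists.

    Columns: candidate, uniprot, pdb_id, chain, residues, pocket_type.
    Non-integer residue tokens raise with their row.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"candidate", "uniprot", "pdb_id", "chain", "residues",
                "pocket_type"}
    if not required <= set(df.columns):
        raise ValidationError(f"pocket table needs columns {sorted(required)}")
    specs = []
    for i, row in df.iterrows():
        toks = [t for t in str(row["residues"]).split(";") if t.strip()]
        try:
            positions = tuple(int(t) for t in toks)
        except ValueError as exc:
            raise ValidationError(
                f"row {i + 2}, column 'residues': non-integer token "
                f"({exc})") from exc
        specs.append(PocketSpec(row["candidate"], row["uniprot"],
                                row["pdb_id"], row["chain"], positions,
                                row["pocket_type"]))
    return specs


def write_pocket_table(path, specs) -> None:
    pd.DataFrame(
        [(s.candidate, s.uniprot, s.pdb_id, s.chain,
          ";".join(str(p) for p in s.residue_positions), s.pocket_type)
         for s in specs],
        columns=["candidate", "uniprot", "pdb_id", "chain", "residues",
                 "pocket_type"],
    ).to_csv(path, index=False)


def extract_pocket_coords(pdb_path, pocket: PocketSpec):
    """Heavy-atom coordinates (angstrom) of the pocket residues.

    Alternate locations keep the highest-occupancy conformer; hydrogens
    are excluded.  Returns (Nx3 array, missing residue list); raises when
    no listed residue resolves on the requested chain.
    """
    from Bio.PDB import PDBParser
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(pocket.pdb_id,
                                                        pdb_path)
    model = next(structure.get_models())
    if pocket.chain not in [c.id for c in model]:
        raise InputError(
            f"chain {pocket.chain!r} absent from {pdb_path}")
    chain = model[pocket.chain]
    wanted = set(pocket.residue_positions)
    coords, found = [], set()
    for residue in chain:
        resseq = residue.id[1]
        if resseq not in wanted:
            continue
        # only explicitly listed insertion codes are distinct residues;
        # the plain position matches any icode
        found.add(resseq)
        best_by_atom: dict[str, tuple] = {}
        for atom in residue.get_unpacked_list():
            if (atom.element or "").upper() == "H":
                continue
            occ = atom.get_occupancy() or 0.0
            prev = best_by_atom.get(atom.get_name())
            if prev is None or occ > prev[0]:
                best_by_atom[atom.get_name()] = (occ, atom.get_coord())
        coords.extend(c for _, c in best_by_atom.values())
    missing = sorted(wanted - found)
    if not found:
        raise InputError(
            f"no pocket residues resolved in {pdb_path} chain {pocket.chain}")
    if missing:
        logger.warning("pocket %s: %d residues missing from structure: %s",
                       pocket.label, len(missing), missing)
    return np.asarray(coords, dtype=float), missing


def min_distance(ligand_coords, pocket_coords,
                 mode: str = "min_heavy_atom") -> float:
    """Ligand-pocket distance in angstrom.

    ``min_heavy_atom`` (default) is the minimum pairwise Euclidean
    distance between the two point sets; ``centroid`` measures between
    the centroids instead (less conservative; kept for comparison).
    """
    ligand_coords = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    pocket_coords = np.atleast_2d(np.asarray(pocket_coords, dtype=float))
    if ligand_coords.size == 0 or pocket_coords.size == 0:
        raise ValidationError("coordinate sets must be non-empty")
    if mode == "min_heavy_atom":
        return float(cdist(ligand_coords, pocket_coords).min())
    if mode == "centroid":
        return float(np.linalg.norm(ligand_coords.mean(axis=0)
                                    - pocket_coords.mean(axis=0)))
    raise ValueError(f"unknown distance mode {mode!r}")


def classify_pose(pose: DockingPose, energy_cut: float = ENERGY_CUT,
                  dist_cut: float = DIST_CUT) -> bool:
    """Positive iff binding energy < cut AND distance < cut (both strict)."""
    if pose.min_distance is None:
        raise ValidationError(
            f"pose {pose.ligand_id}/{pose.pocket_label} has no distance")
    return pose.binding_energy < energy_cut and pose.min_distance < dist_cut


def summarize_candidates(poses, pockets, energy_cut: float = ENERGY_CUT,
                         dist_cut: float = DIST_CUT) -> list[CandidateReport]:
    """Per-candidate best positive pose per pocket and validation flag.

    A candidate is validated when at least one pocket has at least one
    positive pose; the best pose is the lowest-energy positive one.
    Poses referencing unknown pockets raise.
    """
    by_label = {p.label: p for p in pockets}
    candidates: dict[str, dict] = {
        p.candidate: {s.label: None for s in pockets if s.candidate == p.candidate}
        for p in pockets}
    for pose in poses:
        if pose.pocket_label not in by_label:
            raise InputError(f"pose references unknown pocket "
                             f"{pose.pocket_label!r}")
        if not classify_pose(pose, energy_cut, dist_cut):
            continue
        cand = by_label[pose.pocket_label].candidate
        best = candidates[cand][pose.pocket_label]
        if best is None or pose.binding_energy < best.binding_energy:
            candidates[cand][pose.pocket_label] = pose
    return [CandidateReport(cand,
                            best_pose_per_pocket=pockets_map,
                            validated=any(v is not None
                                          for v in pockets_map.values()))
            for cand, pockets_map in sorted(candidates.items())]


def read_pose_table(path) -> list[DockingPose]:
    """Pose CSV: ligand_id, pocket_label, binding_energy, min_distance."""
    df = pd.read_csv(path)
    required = {"ligand_id", "pocket_label", "binding_energy"}
    if not required <= set(df.columns):
        raise ValidationError(f"pose table needs columns {sorted(required)}")
    poses = []
    for r in df.itertuples(index=False):
        dist = getattr(r, "min_distance", None)
        dist = None if dist is None or pd.isna(dist) else float(dist)
        poses.append(DockingPose(str(r.ligand_id), str(r.pocket_label),
                                 float(r.binding_energy), dist))
    return poses


def write_candidate_reports(path, reports) -> None:
    rows = []
    for rep in reports:
        for label, pose in rep.best_pose_per_pocket.items():
            rows.append((rep.candidate, label, rep.validated,
                         pose.binding_energy if pose else float("nan"),
                         pose.min_distance if pose else float("nan"),
                         pose.ligand_id if pose else ""))
    pd.DataFrame(rows, columns=["candidate", "pocket", "validated",
                                "best_energy", "best_distance",
                                "ligand"]).to_csv(path, sep="\t", index=False)
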