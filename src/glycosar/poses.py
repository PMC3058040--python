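"""Geometric filtering of docked peptide poses against a reference pose.

Docked poses sharing one fixed receptor frame are compared to the reference
pose by backbone RMSD without superposition; optional rigid (Kabsch)
superposition is available for frame-independent comparisons. The two-stage
culling scheme keeps poses with RMSD strictly below a pre-minimization
threshold (default 3.0 A), expects externally minimized coordinates for the
survivors, and then applies a stricter post-minimization threshold (default
1.5 A) to select the poses passed on to rescoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PoseRecord",
    "BACKBONE_ROLES",
    "truncate_fragment",
    "backbone_rmsd",
    "two_stage_filter",
    "read_poses_pdb",
    "write_pose_pdb",
]

#: Default backbone atom roles used in RMSD: all backbone carbons plus the
#: amide nitrogen. The carbonyl O can be added via the ``atom_roles`` argument.
BACKBONE_ROLES = frozenset({"N", "CA", "C"})


@dataclass
class PoseRecord:
    """Coordinates of one peptide pose.

    ``atoms`` is a DataFrame with columns (resi, role, x, y, z); ``stage``
    tags whether the pose comes from docking or from energy minimization.
    """

    peptide_id: str
    atoms: pd.DataFrame
    stage: str = "docked"

    def __post_init__(self) -> None:
        need = {"resi", "role", "x", "y", "z"}
        missing = need - set(self.atoms.columns)
        if missing:
            raise ValueError(f"pose {self.peptide_id}: missing atom columns {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"pose {self.peptide_id}: non-finite coordinates")

    def residue_range(self) -> tuple[int, int]:
        r = self.atoms["resi"].to_numpy()
        return int(r.min()), int(r.max())

    def coords(self, roles=None) -> pd.DataFrame:
        """Atoms sorted deterministically by (resi, role), optionally filtered."""
        df = self.atoms
        if roles is not None:
            df = df[df["role"].isin(set(roles))]
        return df.sort_values(["resi", "role"], kind="stable").reset_index(drop=True)


def truncate_fragment(pose: PoseRecord, first: int, last: int) -> PoseRecord:
    """Keep only atoms whose residue index lies in the closed interval."""
    lo, hi = pose.residue_range()
    if first > last or first < lo or last > hi:
        raise ValueError(
            f"truncation [{first},{last}] outside pose range [{lo},{hi}]"
        )
    kept = pose.atoms[(pose.atoms["resi"] >= first) & (pose.atoms["resi"] <= last)]
    if kept.empty:
        raise ValueError(f"truncation [{first},{last}] leaves no atoms")
    return PoseRecord(pose.peptide_id, kept.reset_index(drop=True), pose.stage)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotate+translate P onto Q (least squares); returns transformed P."""
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return (R @ Pc.T).T + Q.mean(axis=0)


def backbone_rmsd(
    pose: PoseRecord,
    reference: PoseRecord,
    atom_roles=BACKBONE_ROLES,
    superpose: bool = False,
) -> float:
    """Backbone RMSD between a pose and the reference, in Angstrom.

    Atoms are matched by (residue index, role); a mismatch in the matched
    sets is an error. With ``superpose`` the pose is first rigidly fitted
    onto the reference (Kabsch); by default poses are compared in the shared
    receptor frame.
    """
    a = pose.coords(atom_roles)
    b = reference.coords(atom_roles)
    ka = list(zip(a["resi"], a["role"]))
    kb = list(zip(b["resi"], b["role"]))
    if ka != kb:
        missing = sorted(set(ka) ^ set(kb))
        raise ValueError(f"atom mismatch between poses: {missing[:10]}")
    if not ka:
        raise ValueError("no atoms with the requested roles")
    P = a[["x", "y", "z"]].to_numpy(dtype=float)
    Q = b[["x", "y", "z"]].to_numpy(dtype=float)
    if superpose:
        P = _kabsch(P, Q)
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


@dataclass
class FilterReport:
    """Per-peptide RMSD values and survival through the two-stage filter."""

    table: pd.DataFrame
    pre_threshold: float
    post_threshold: float

    @property
    def stage1_survivors(self) -> list[str]:
        t = self.table
        return list(t.index[t["pass_stage1"]])

    @property
    def survivors(self) -> list[str]:
        t = self.table
        return list(t.index[t["pass_stage2"] == True])  # noqa: E712 (None-safe)


def two_stage_filter(
    docked: dict[str, PoseRecord],
    minimized: dict[str, PoseRecord],
    reference: PoseRecord,
    pre_threshold: float = 3.0,
    post_threshold: float = 1.5,
    atom_roles=BACKBONE_ROLES,
    reuse_docked: bool = False,
) -> FilterReport:
    """Two-threshold geometric culling of docked poses.

    Stage 1 keeps poses with RMSD(docked, reference) strictly below
    ``pre_threshold``; those are expected to have externally minimized
    coordinates, and stage 2 keeps peptides whose minimized pose has RMSD
    strictly below ``post_threshold``. Boundary values are culled. A stage-1
    survivor without a minimized pose is an error unless ``reuse_docked`` is
    set, in which case the docked coordinates are reused.
    """
    rows = {}
    for pid, pose in docked.items():
        r1 = backbone_rmsd(pose, reference, atom_roles)
        pass1 = r1 < pre_threshold
        r2, pass2 = np.nan, None
        if pass1:
            mpose = minimized.get(pid)
            if mpose is None:
                if not reuse_docked:
                    raise ValueError(
                        f"stage-1 survivor {pid!r} has no minimized pose "
                        "(pass reuse_docked=True to reuse docked coordinates)"
                    )
                mpose = pose
            r2 = backbone_rmsd(mpose, reference, atom_roles)
            pass2 = r2 < post_threshold
        rows[pid] = {
            "rmsd_docked": r1,
            "pass_stage1": pass1,
            "rmsd_minimized": r2,
            "pass_stage2": pass2,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return FilterReport(table, pre_threshold, post_threshold)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_poses_pdb(path, stage: str = "docked") -> dict[str, PoseRecord]:
    """Read poses from a PDB file, one pose per MODEL (or one per file).

    The peptide id is taken from the MODEL serial (``model_<n>``) unless a
    preceding ``REMARK peptide <id>`` names it.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    names = {}
    with open(path) as fh:
        model_no = 0
        for line in fh:
            if line.startswith("MODEL"):
                model_no = int(line.split()[1])
            elif line.startswith("REMARK peptide"):
                names[model_no] = line.split()[2]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    out = {}
    for model in structure:
        rows = []
        for chain in model:
            for res in chain:
                for atom in res:
                    x, y, z = atom.coord
                    rows.append(
                        {
                            "resi": res.id[1],
                            "role": atom.get_name(),
                            "x": float(x),
                            "y": float(y),
                            "z": float(z),
                        }
                    )
        pid = names.get(model.serial_num, names.get(0, f"model_{model.serial_num}"))
        if len(structure) == 1 and 0 in names:
            pid = names[0]
        out[pid] = PoseRecord(pid, pd.DataFrame(rows), stage)
    return out


def write_pose_pdb(poses, path) -> None:
    """Write poses as a multi-MODEL PDB file readable by read_poses_pdb."""
    items = poses.items() if isinstance(poses, dict) else [(p.peptide_id, p) for p in poses]
    with open(path, "w") as fh:
        for n, (pid, pose) in enumerate(items, start=1):
            fh.write(f"MODEL     {n:4d}\n")
            fh.write(f"REMARK peptide {pid}\n")
            serial = 1
            for _, a in pose.coords().iterrows():
                role = str(a["role"])[:4]
                fh.write(
                    f"ATOM  {serial:5d} {role:^4s} GLY A{int(a['resi']):4d}    "
                    f"{a['x']:8.3f}{a['y']:8.3f}{a['z']:8.3f}  1.00  0.00\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
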