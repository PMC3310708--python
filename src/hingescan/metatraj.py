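"""Meta-trajectories: one joint trajectory of corresponding residues.

To compare the internal dynamics of homologous proteins, each trajectory is
reduced to a shared set of corresponding residues (an externally produced
structure-alignment table, e.g. from flexible alignment) and the reduced
frames are concatenated into a single "meta-trajectory".  Downstream
analyses are either superposition-free (distance fluctuations) or superpose
internally (rigid-domain and axis fits), so the absolute reference frames of
the sources never matter and no re-superposition happens at build time.

Per-frame provenance (protein tag, ligand state, original frame index) is
carried along so any fit can be reported per source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory_io import CalphaTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "CorrespondenceTable",
    "MetaTrajectory",
    "load_correspondence",
    "write_correspondence",
    "build_metatrajectory",
    "per_source_fit_report",
]

_COLUMNS = ["group_id", "protein_tag", "chain", "resid"]


@dataclass
class CorrespondenceTable:
    """Validated residue-correspondence table.

    Each row maps an alignment column (``group_id``) to one residue of one
    protein.  Only complete columns (covering every protein tag present) are
    kept; within one protein a residue belongs to at most one group.
    """

    frame: pd.DataFrame

    @property
    def group_ids(self) -> np.ndarray:
        return np.sort(self.frame["group_id"].unique())

    @property
    def protein_tags(self) -> list[str]:
        return sorted(self.frame["protein_tag"].unique())

    @staticmethod
    def from_rows(rows: Sequence[tuple[int, str, str, int]]) -> "CorrespondenceTable":
        df = pd.DataFrame(rows, columns=_COLUMNS)
        return CorrespondenceTable._validate(df)

    @staticmethod
    def _validate(df: pd.DataFrame) -> "CorrespondenceTable":
        dup = df.duplicated(subset=["protein_tag", "chain", "resid"], keep=False)
        if dup.any():
            rows = (df.index[dup] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"duplicate (protein, residue) entries at rows {rows}")
        tags = set(df["protein_tag"])
        complete = df.groupby("group_id")["protein_tag"].nunique() == len(tags)
        incomplete = complete.index[~complete]
        if len(incomplete):
            logger.warning("dropping %d incomplete correspondence group(s)", len(incomplete))
            df = df[~df["group_id"].isin(incomplete)]
        if df.empty:
            raise ValueError("no complete correspondence groups")
        return CorrespondenceTable(frame=df.reset_index(drop=True))

    def lookup(self, protein_tag: str) -> pd.DataFrame:
        """Rows of one protein, ordered by group_id."""
        sub = self.frame[self.frame["protein_tag"] == protein_tag]
        return sub.sort_values("group_id").reset_index(drop=True)


def load_correspondence(path: str | Path) -> CorrespondenceTable:
    """Read a TSV with header ``group_id protein_tag chain resid``."""
    df = pd.read_csv(path, sep="\t", dtype={"group_id": int, "protein_tag": str, "chain": str, "resid": int})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"correspondence TSV missing column(s) {missing}")
    return CorrespondenceTable._validate(df[_COLUMNS])


def write_correspondence(table: CorrespondenceTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


@dataclass
class MetaTrajectory:
    """A CalphaTrajectory over alignment groups, plus per-frame provenance."""

    trajectory: CalphaTrajectory
    frame_provenance: pd.DataFrame  # columns: protein_tag, ligand_state, source_frame

    def __post_init__(self) -> None:
        if len(self.frame_provenance) != self.trajectory.n_frames:
            raise ValueError("provenance must have one row per frame")

    def save_provenance(self, path: str | Path) -> None:
        self.frame_provenance.to_csv(path, sep="\t", index=False)


def build_metatrajectory(
    trajs: Sequence[tuple[CalphaTrajectory, str, str]], table: CorrespondenceTable
) -> MetaTrajectory:
    """Concatenate trajectories reduced to the corresponding residues.

    ``trajs`` holds (trajectory, protein_tag, ligand_state) triples; frames
    are concatenated in input order; the residue axis is ordered by group_id.
    """
    tags_present = {tag for _t, tag, _l in trajs}
    missing = set(table.protein_tags) - tags_present
    if missing:
        raise ValueError(f"no trajectory provided for table protein tag(s) {sorted(missing)}")

    group_ids = table.group_ids
    blocks, prov_rows = [], []
    for traj, tag, ligand in trajs:
        rows = table.lookup(tag)
        key_to_idx = {
            (chain, num): i for i, (_tag, chain, num, _name) in enumerate(traj.residue_ids)
        }
        indices = []
        for _, row in rows.iterrows():
            key = (row["chain"], int(row["resid"]))
            if key not in key_to_idx:
                raise ValueError(
                    f"residue chain={key[0]} resid={key[1]} of protein {tag!r} "
                    "referenced in table but absent in trajectory"
                )
            indices.append(key_to_idx[key])
        blocks.append(traj.coords[:, indices, :])
        for f in range(traj.n_frames):
            prov_rows.append((tag, ligand, f))

    coords = np.concatenate(blocks, axis=0)
    residue_ids = [("meta", "A", int(g) + 1, "GRP") for g in group_ids]
    meta = CalphaTrajectory(
        coords=coords,
        residue_ids=residue_ids,
        source="meta(" + ", ".join(f"{tag}:{lig}" for _t, tag, lig in trajs) + ")",
    )
    prov = pd.DataFrame(prov_rows, columns=["protein_tag", "ligand_state", "source_frame"])
    return MetaTrajectory(trajectory=meta, frame_provenance=prov)


def per_source_fit_report(
    meta: MetaTrajectory, per_frame_rmsd: np.ndarray, threshold: float = 4.0
) -> pd.DataFrame:
    """Group a per-frame fit RMSD series by source.

    Returns one row per (protein_tag, ligand_state) plus an ``overall`` row,
    with mean and max RMSD and the fraction of frames at or below
    ``threshold`` (A).
    """
    per_frame_rmsd = np.asarray(per_frame_rmsd, dtype=float)
    if len(per_frame_rmsd) != meta.trajectory.n_frames:
        raise ValueError("per_frame_rmsd length does not match the meta-trajectory")
    df = meta.frame_provenance.copy()
    df["rmsd"] = per_frame_rmsd
    rows = []
    for (tag, lig), sub in df.groupby(["protein_tag", "ligand_state"], sort=False):
        rows.append(
            {
                "protein_tag": tag,
                "ligand_state": lig,
                "n_frames": len(sub),
                "mean_rmsd": sub["rmsd"].mean(),
                "max_rmsd": sub["rmsd"].max(),
                f"fraction_le_{threshold:g}A": (sub["rmsd"] <= threshold).mean(),
            }
        )
    rows.append(
        {
            "protein_tag": "overall",
            "ligand_state": "",
            "n_frames": len(df),
            "mean_rmsd": df["rmsd"].mean(),
            "max_rmsd": df["rmsd"].max(),
            f"fraction_le_{threshold:g}A": (df["rmsd"] <= threshold).mean(),
        }
    )
    return pd.DataFrame(rows)
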