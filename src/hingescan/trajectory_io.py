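"""Read, write, select and validate C-alpha trajectories.

The universal carrier is :class:`CalphaTrajectory`: an (frames x residues x 3)
coordinate array in Angstroms plus per-residue identity labels.  Sources are
multi-model PDB files, or a binary trajectory (XTC/DCD/TRR) with a PDB/GRO
topology; parsing is delegated to :mod:`mdtraj` and coordinates are converted
from its internal nanometres to Angstroms at load time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NM_TO_ANGSTROM = 10.0

__all__ = ["CalphaTrajectory", "AtomSelection", "load_trajectory", "write_trajectory"]


@dataclass
class CalphaTrajectory:
    """A C-alpha coordinate trajectory.

    Attributes
    ----------
    coords : (n_frames, n_residues, 3) float array, Angstroms.
    residue_ids : list of (protein_tag, chain_id, residue_number, residue_name)
        tuples, one per residue, aligned with the residue axis.  Residue
        numbers are 1-based as in the source file.
    frame_times : optional per-frame times in ns, strictly increasing.
    source : provenance string (file paths or generator description).
    """

    coords: np.ndarray
    residue_ids: list[tuple[str, str, int, str]]
    frame_times: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, residues, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] < 2:
            raise ValueError("trajectory needs at least two residues")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if len(self.residue_ids) != self.coords.shape[1]:
            raise ValueError("residue_ids length must equal the residue axis")
        keys = [(t, c, n) for (t, c, n, _name) in self.residue_ids]
        if len(set(keys)) != len(keys):
            raise ValueError("(protein_tag, chain_id, residue_number) triples must be unique")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.n_frames:
                raise ValueError("frame_times length must equal frame count")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def subset(self, indices: Sequence[int], source_suffix: str = "") -> "CalphaTrajectory":
        """New trajectory restricted to the given residue indices (0-based)."""
        idx = np.asarray(indices, dtype=int)
        return CalphaTrajectory(
            coords=self.coords[:, idx, :].copy(),
            residue_ids=[self.residue_ids[i] for i in idx],
            frame_times=None if self.frame_times is None else self.frame_times.copy(),
            source=self.source + source_suffix,
        )

    def frame_slice(self, first: int, last: int) -> "CalphaTrajectory":
        """Frames ``first..last`` inclusive (0-based)."""
        if not (0 <= first <= last < self.n_frames):
            raise ValueError(f"frame range ({first}, {last}) outside trajectory of {self.n_frames} frames")
        return CalphaTrajectory(
            coords=self.coords[first : last + 1].copy(),
            residue_ids=list(self.residue_ids),
            frame_times=None if self.frame_times is None else self.frame_times[first : last + 1].copy(),
            source=self.source + f"[frames {first}:{last}]",
        )


@dataclass
class AtomSelection:
    """A residue selection, resolved against a trajectory.

    The expression grammar is ``tag:<protein_tag> chain:<id> resid:<a>-<b>
    name:<resname>`` terms joined by whitespace (AND) and ``|`` (OR); a bare
    ``resid:<a>`` selects a single residue number.
    """

    expression: str
    resolved_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @staticmethod
    def resolve(expression: str, traj: CalphaTrajectory) -> "AtomSelection":
        mask = _evaluate_expression(expression, traj.residue_ids)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"selection {expression!r} matches no residues")
        return AtomSelection(expression=expression, resolved_indices=idx)


_TERM_RE = re.compile(r"^(tag|chain|resid|name):(.+)$")


def _evaluate_expression(expression: str, residue_ids: list[tuple[str, str, int, str]]) -> np.ndarray:
    n = len(residue_ids)
    result = np.zeros(n, dtype=bool)
    for clause in expression.split("|"):
        clause = clause.strip()
        if not clause:
            raise ValueError("empty OR-clause in selection expression")
        mask = np.ones(n, dtype=bool)
        for term in clause.split():
            m = _TERM_RE.match(term)
            if m is None:
                raise ValueError(f"bad selection term {term!r}")
            key, value = m.group(1), m.group(2)
            if key == "tag":
                mask &= np.array([t == value for (t, _c, _n, _na) in residue_ids])
            elif key == "chain":
                mask &= np.array([c == value for (_t, c, _n, _na) in residue_ids])
            elif key == "name":
                mask &= np.array([na == value for (_t, _c, _n, na) in residue_ids])
            else:  # resid
                if "-" in value:
                    a, b = value.split("-", 1)
                    lo, hi = int(a), int(b)
                else:
                    lo = hi = int(value)
                mask &= np.array([lo <= num <= hi for (_t, _c, num, _na) in residue_ids])
        result |= mask
    return result


def load_trajectory(
    structure_path: str | Path,
    trajectory_path: str | Path | None = None,
    selection: str | None = None,
    protein_tag: str | None = None,
) -> CalphaTrajectory:
    """Load a C-alpha trajectory from a structure file (+ optional trajectory).

    A multi-model PDB alone yields one frame per MODEL.  With
    ``trajectory_path`` (XTC/DCD/TRR), the structure acts as topology and must
    match the trajectory atom count.  Residues lacking a C-alpha are dropped
    with a warning.  Output coordinates are Angstroms; residues are ordered by
    (chain, residue number); ``selection`` is applied after the C-alpha
    reduction.
    """
    import mdtraj

    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FileNotFoundError(structure_path)
    tag = protein_tag if protein_tag is not None else structure_path.stem

    if trajectory_path is None:
        traj = mdtraj.load(str(structure_path))
        source = str(structure_path)
    else:
        trajectory_path = Path(trajectory_path)
        if not trajectory_path.exists():
            raise FileNotFoundError(trajectory_path)
        top = mdtraj.load_topology(str(structure_path))
        try:
            traj = mdtraj.load(str(trajectory_path), top=top)
        except Exception as exc:  # mdtraj raises various types on atom mismatch
            raise ValueError(f"trajectory/topology mismatch: {exc}") from exc
        source = f"{trajectory_path} (top: {structure_path})"
    if traj.n_frames == 0:
        raise ValueError(f"{source}: zero frames")

    # C-alpha reduction; warn about residues missing a CA.
    ca_indices = []
    residue_ids = []
    n_dropped = 0
    for res in traj.topology.residues:
        ca = [a.index for a in res.atoms if a.name == "CA"]
        if not ca:
            if not res.is_water:
                n_dropped += 1
            continue
        chain_id = res.chain.chain_id or chr(ord("A") + res.chain.index % 26)
        ca_indices.append(ca[0])
        residue_ids.append((tag, chain_id, int(res.resSeq), res.name))
    if n_dropped:
        logger.warning("%s: dropped %d residue(s) without a C-alpha atom", source, n_dropped)
    if len(ca_indices) < 2:
        raise ValueError(f"{source}: fewer than two residues with C-alpha atoms")

    order = sorted(range(len(ca_indices)), key=lambda i: (residue_ids[i][1], residue_ids[i][2]))
    ca_indices = [ca_indices[i] for i in order]
    residue_ids = [residue_ids[i] for i in order]

    coords = traj.xyz[:, ca_indices, :].astype(float) * NM_TO_ANGSTROM

    frame_times = None
    if trajectory_path is not None and traj.time is not None:
        times_ns = np.asarray(traj.time, dtype=float) / 1000.0  # mdtraj: ps
        if len(times_ns) == traj.n_frames and np.all(np.diff(times_ns) > 0):
            frame_times = times_ns

    out = CalphaTrajectory(coords=coords, residue_ids=residue_ids, frame_times=frame_times, source=source)
    if selection is not None:
        sel = AtomSelection.resolve(selection, out)
        out = out.subset(sel.resolved_indices, source_suffix=f"[{selection}]")
    return out


def write_trajectory(traj: CalphaTrajectory, path: str | Path) -> None:
    """Write a multi-model PDB with one MODEL per frame, C-alpha atoms only.

    Chain identifiers and 1-based residue numbers are preserved; coordinates
    are written at PDB precision (1e-3 A).
    """
    path = Path(path)
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for i, (_tag, chain, resnum, resname) in enumerate(traj.residue_ids):
            x, y, z = traj.coords[f, i]
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname[:3]:>3s} {chain[:1]}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {'C':>2s}"
            )
            serial += 1
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
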