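"""In-memory trajectory container and GRO/XTC round-trip.

Analyses in this package operate on a light array-backed container rather
than on file handles: frame times in ns, coordinates in nm wrapped into an
orthorhombic periodic box, and per-particle labels (bead name, residue id,
residue/species name, receptor flag).  :func:`write_trajectory` and
:func:`load_trajectory` convert to and from standard GRO topology + XTC
frames through MDAnalysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Trajectory",
    "RECEPTOR_RESNAME",
    "minimum_image",
    "minimum_image_distance",
    "molecule_com",
    "write_trajectory",
    "slice_frames",
    "load_trajectory",
]

#: residue name labelling receptor beads in written topologies
RECEPTOR_RESNAME = "REC"


@dataclass
class Trajectory:
    """Frames of a coarse-grained membrane system.

    Attributes
    ----------
    frame_times_ns : (n_frames,) float array
    coords_nm : (n_frames, n_particles, 3) float array, wrapped into the box
    box_nm : (n_frames, 3) float array, orthorhombic box lengths
    names : (n_particles,) bead names
    resids : (n_particles,) int residue ids (one residue per lipid molecule
        and per receptor residue)
    resnames : (n_particles,) residue names; lipid species name for lipids,
        ``REC`` for receptor beads
    """

    frame_times_ns: np.ndarray
    coords_nm: np.ndarray
    box_nm: np.ndarray
    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times_ns = np.asarray(self.frame_times_ns, dtype=float)
        self.coords_nm = np.asarray(self.coords_nm)
        self.box_nm = np.asarray(self.box_nm, dtype=float)
        self.names = np.asarray(self.names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        nf, npart, _ = self.coords_nm.shape
        if len(self.frame_times_ns) != nf or self.box_nm.shape != (nf, 3):
            raise ValueError("frame_times/box shape mismatch with coords")
        if not (len(self.names) == len(self.resids) == len(self.resnames) == npart):
            raise ValueError("per-particle label length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords_nm.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords_nm.shape[1]

    @property
    def stride_ns(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.frame_times_ns[1] - self.frame_times_ns[0])

    @property
    def is_receptor(self) -> np.ndarray:
        return self.resnames == RECEPTOR_RESNAME

    def receptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_receptor)

    def species_molecules(self, species: str) -> np.ndarray:
        """Sorted residue ids of all molecules of one lipid species."""
        return np.unique(self.resids[self.resnames == species])

    def lipid_species(self) -> list[str]:
        return sorted(set(self.resnames[~self.is_receptor]))

    def time_window(self, begin_ns: float | None, end_ns: float | None) -> np.ndarray:
        """Frame indices with begin <= t <= end (None = unbounded)."""
        t = self.frame_times_ns
        mask = np.ones(len(t), dtype=bool)
        if begin_ns is not None:
            mask &= t >= begin_ns
        if end_ns is not None:
            mask &= t <= end_ns
        return np.flatnonzero(mask)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary image of an orthorhombic box."""
    # equivalent to delta - box * round(delta / box); floor is markedly
    # cheaper than banker's rounding on large arrays
    return delta - box * np.floor(delta / box + 0.5)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance between broadcastable point arrays."""
    d = minimum_image(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), box)
    return np.sqrt((d * d).sum(axis=-1))


def molecule_com(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Centre of mass of one molecule's beads under periodic wrapping.

    Beads are equal-weight (coarse-grained convention).  The molecule is
    unwrapped about its first bead before averaging so molecules straddling
    a box face get a physical COM, then the COM is wrapped back.

    Parameters
    ----------
    coords : (..., n_beads, 3) bead positions in nm
    box : (3,) or broadcastable box lengths
    """
    coords = np.asarray(coords, dtype=float)
    ref = coords[..., :1, :]
    unwrapped = ref + minimum_image(coords - ref, box)
    com = unwrapped.mean(axis=-2)
    return np.mod(com, box)


def write_trajectory(
    traj: Trajectory,
    topology_path: str | Path,
    frames_path: str | Path | None = None,
) -> None:
    """Write topology as GRO (frame 0) and, optionally, all frames as XTC.

    Coordinates are converted nm -> Angstrom for MDAnalysis; both formats
    store positions at 0.001 nm precision, so a read-back agrees with the
    in-memory coordinates to that tolerance.  With ``frames_path=None``
    only the GRO snapshot of frame 0 is written (single-frame export).
    """
    import MDAnalysis as mda

    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    resids = traj.resids
    uniq, first_idx, resindex = np.unique(resids, return_index=True, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=traj.n_particles,
        n_residues=len(uniq),
        atom_resindex=resindex,
        n_segments=1,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(traj.names))
    u.add_TopologyAttr("resnames", list(traj.resnames[first_idx]))
    u.add_TopologyAttr("resids", list(uniq))

    coords_A = np.asarray(traj.coords_nm, dtype=np.float32) * 10.0
    dims = np.hstack(
        [traj.box_nm * 10.0, np.full((traj.n_frames, 3), 90.0)]
    ).astype(np.float32)
    u.load_new(coords_A, format=mda.coordinates.memory.MemoryReader, dimensions=dims)
    u.trajectory[0]
    u.atoms.write(str(topology_path))
    if frames_path is None:
        return
    with mda.Writer(str(frames_path), traj.n_particles) as writer:
        for i, _ in enumerate(u.trajectory):
            u.trajectory.ts.time = traj.frame_times_ns[i] * 1e3  # ps
            writer.write(u.atoms)


def slice_frames(traj: Trajectory, start: int, stop: int | None = None) -> Trajectory:
    """A new trajectory holding frames [start, stop) with shared labels."""
    stop = start + 1 if stop is None else stop
    return Trajectory(
        frame_times_ns=traj.frame_times_ns[start:stop],
        coords_nm=traj.coords_nm[start:stop],
        box_nm=traj.box_nm[start:stop],
        names=traj.names,
        resids=traj.resids,
        resnames=traj.resnames,
    )


def load_trajectory(
    topology_path: str | Path,
    frames_path: str | Path | None = None,
    frame_stride_ns: float | None = None,
) -> Trajectory:
    """Load a GRO (+ optional XTC) back into the array container.

    Receptor beads are recognised by the ``REC`` residue name; all other
    residues are lipids whose resname is the species name.  Frame times are
    taken from the trajectory (ps -> ns) unless `frame_stride_ns` overrides
    them.
    """
    import MDAnalysis as mda

    u = (
        mda.Universe(str(topology_path), str(frames_path))
        if frames_path is not None
        else mda.Universe(str(topology_path))
    )
    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(u.atoms), 3), dtype=np.float32)
    box = np.empty((n_frames, 3))
    times = np.empty(n_frames)
    for i, ts in enumerate(u.trajectory):
        coords[i] = ts.positions / 10.0
        box[i] = ts.dimensions[:3] / 10.0
        times[i] = ts.time / 1e3
    if frame_stride_ns is not None:
        times = np.arange(n_frames) * frame_stride_ns
    return Trajectory(
        frame_times_ns=times,
        coords_nm=coords,
        box_nm=box,
        names=u.atoms.names.astype(object),
        resids=u.atoms.resids.astype(int),
        resnames=u.atoms.resnames.astype(object),
    )
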