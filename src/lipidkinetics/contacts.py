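"""Dual-cutoff lipid-residue contact detection and occupancy analysis.

A continuous lipid-residue contact starts when the lipid's centre of mass
comes closer than a tight lower cutoff (default 0.55 nm) to the residue's
centre of mass, and ends only when it moves beyond a looser upper cutoff
(default 1.4 nm).  The hysteresis suppresses boundary rattling, so the
distribution of contact durations reflects genuine unbinding rather than
threshold noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajectory import Trajectory, minimum_image

__all__ = [
    "ContactEvent",
    "DurationProfile",
    "OccupancySeries",
    "NoPlateauError",
    "DEFAULT_LOWER_CUTOFF_NM",
    "DEFAULT_UPPER_CUTOFF_NM",
    "DEFAULT_SHELL_RADIUS_NM",
    "lipid_com_series",
    "receptor_residue_com_series",
    "com_distance_series",
    "detect_contact_events",
    "detect_species_contacts",
    "residue_duration_profile",
    "first_shell_series",
    "estimate_equilibration",
]

DEFAULT_LOWER_CUTOFF_NM = 0.55
DEFAULT_UPPER_CUTOFF_NM = 1.4
DEFAULT_SHELL_RADIUS_NM = 1.0


class NoPlateauError(RuntimeError):
    """The occupancy series never settles onto a plateau."""


@dataclass(frozen=True)
class ContactEvent:
    """One continuous dual-cutoff contact between a lipid and a residue."""

    lipid_id: int
    residue_id: int
    species: str
    t_start_ns: float
    t_end_ns: float
    censored: bool = False

    @property
    def duration_ns(self) -> float:
        return self.t_end_ns - self.t_start_ns


@dataclass
class DurationProfile:
    """Per-residue, per-species contact-duration statistics.

    ``table`` holds mean duration (uncensored events), event counts and
    censored counts keyed by (residue_id, species); ``durations`` keeps the
    raw uncensored duration samples for downstream kinetic fits.  When
    events from several independent repeats are pooled, ``per_repeat``
    additionally carries the per-repeat means.
    """

    table: pd.DataFrame
    durations: dict[tuple[int, str], np.ndarray]
    per_repeat: pd.DataFrame | None = None

    def mean_duration(self, residue_id: int, species: str | None = None) -> float:
        sub = self.table[self.table.residue_id == residue_id]
        if species is not None:
            sub = sub[sub.species == species]
        if sub.empty or sub.n_events.sum() == 0:
            return 0.0
        w = sub.n_events.to_numpy()
        return float((sub.mean_duration_ns.to_numpy() * w).sum() / w.sum())

    def residue_ids(self) -> np.ndarray:
        return np.unique(self.table.residue_id.to_numpy())


@dataclass
class OccupancySeries:
    """Per-frame first-shell occupancy of one species."""

    species: str
    times_ns: np.ndarray
    counts: np.ndarray
    shell_radius_nm: float
    equilibration_time_ns: float | None = None
    analysis_window_ns: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# centre-of-mass machinery

def lipid_com_series(
    traj: Trajectory, species: str | None = None, resids: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """COM time series of lipid molecules.

    Returns ``(coms, molecule_resids)`` with ``coms`` of shape
    (n_frames, n_molecules, 3).  Beads are equal-weight; each molecule is
    unwrapped about its first bead before averaging (minimum image).
    """
    mask = ~traj.is_receptor
    if species is not None:
        mask &= traj.resnames == species
    if resids is not None:
        mask &= np.isin(traj.resids, np.asarray(resids))
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("lipid selection resolves to zero particles")
    return _grouped_com(traj, idx)


def receptor_residue_com_series(
    traj: Trajectory, resids: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """COM time series of receptor residues; shape (n_frames, n_residues, 3)."""
    mask = traj.is_receptor
    if resids is not None:
        mask &= np.isin(traj.resids, np.asarray(resids))
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("residue selection resolves to zero particles")
    return _grouped_com(traj, idx)


def _grouped_com(traj: Trajectory, particle_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    resids = traj.resids[particle_idx]
    uniq = np.unique(resids)
    box = traj.box_nm[:, None, :]
    coms = np.empty((traj.n_frames, len(uniq), 3))
    # group molecules by bead count so each group is one vectorized pass
    by_count: dict[int, list[int]] = {}
    members: dict[int, np.ndarray] = {}
    for m, rid in enumerate(uniq):
        beads = particle_idx[resids == rid]
        members[m] = beads
        by_count.setdefault(len(beads), []).append(m)
    for n_beads, group in by_count.items():
        gather = np.stack([members[m] for m in group])  # (n_mol, n_beads)
        pts = traj.coords_nm[:, gather.ravel(), :].reshape(
            traj.n_frames, len(group), n_beads, 3
        ).astype(float)
        ref = pts[:, :, :1, :]
        unwrapped = ref + minimum_image(pts - ref, traj.box_nm[:, None, None, :])
        coms[:, group, :] = np.mod(unwrapped.mean(axis=2), box)
    return coms, uniq


def com_distance_series(
    traj: Trajectory,
    lipid_selection: str | Sequence[int],
    residue_selection: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-image COM-COM distances, per frame, lipid and residue.

    ``lipid_selection`` is a species name or an explicit list of lipid
    residue ids; ``residue_selection`` restricts the receptor residues
    (default: all).  Returns ``(distances, lipid_resids, residue_resids)``
    with distances of shape (n_frames, n_lipids, n_residues).
    """
    if isinstance(lipid_selection, str):
        lip_coms, lip_ids = lipid_com_series(traj, species=lipid_selection)
    else:
        lip_coms, lip_ids = lipid_com_series(traj, resids=lipid_selection)
    res_coms, res_ids = receptor_residue_com_series(traj, residue_selection)
    delta = lip_coms[:, :, None, :] - res_coms[:, None, :, :]
    delta = minimum_image(delta, traj.box_nm[:, None, None, :])
    return np.sqrt((delta * delta).sum(axis=-1)), lip_ids, res_ids


# ---------------------------------------------------------------------------
# the dual-cutoff automaton

def detect_contact_events(
    distances_nm: np.ndarray,
    frame_times_ns: np.ndarray,
    lower: float = DEFAULT_LOWER_CUTOFF_NM,
    upper: float = DEFAULT_UPPER_CUTOFF_NM,
    lipid_id: int = -1,
    residue_id: int = -1,
    species: str = "",
) -> list[ContactEvent]:
    """Run the two-threshold automaton on one distance time series.

    An event opens at the first frame with d < lower, stays open while
    d <= upper, and closes at the first frame with d > upper; its duration
    is t_close - t_open.  An event still open at the end of the trajectory
    is closed at the final frame time and flagged censored.
    """
    if lower >= upper:
        raise ValueError("require lower < upper cutoff")
    d = np.asarray(distances_nm, dtype=float)
    t = np.asarray(frame_times_ns, dtype=float)
    if d.shape != t.shape:
        raise ValueError("distance and time series must have equal length")
    if len(t) > 2:
        strides = np.diff(t)
        if not np.allclose(strides, strides[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform frame stride; resample first")

    below = np.flatnonzero(d < lower)
    above = np.flatnonzero(d > upper)
    events: list[ContactEvent] = []
    pos = 0
    n = len(d)
    while True:
        k = np.searchsorted(below, pos)
        if k == len(below):
            break
        open_frame = below[k]
        j = np.searchsorted(above, open_frame)
        if j == len(above):
            events.append(
                ContactEvent(
                    lipid_id, residue_id, species,
                    float(t[open_frame]), float(t[n - 1]), censored=True,
                )
            )
            break
        close_frame = above[j]
        events.append(
            ContactEvent(
                lipid_id, residue_id, species,
                float(t[open_frame]), float(t[close_frame]), censored=False,
            )
        )
        pos = close_frame + 1
    return events


def detect_species_contacts(
    traj: Trajectory,
    species: str,
    residue_selection: Sequence[int] | None = None,
    lower: float = DEFAULT_LOWER_CUTOFF_NM,
    upper: float = DEFAULT_UPPER_CUTOFF_NM,
    begin_ns: float | None = None,
    end_ns: float | None = None,
    chunk_lipids: int = 16,
) -> list[ContactEvent]:
    """Detect all dual-cutoff contacts of one species against the receptor.

    Contacts are sparse, so for a static receptor the per-frame neighbour
    search runs through a periodic k-d tree of residue COMs and the
    automaton is reconstructed from the sparse within-cutoff frame sets; a
    moving receptor falls back to dense chunked distance series.  Both
    paths implement the identical open-below-lower / close-above-upper
    semantics of :func:`detect_contact_events`.
    """
    frames = traj.time_window(begin_ns, end_ns)
    sub_times = traj.frame_times_ns[frames]
    lip_coms, lip_ids = lipid_com_series(traj, species=species)
    res_coms, res_ids = receptor_residue_com_series(traj, residue_selection)
    lip_coms = lip_coms[frames]
    res_coms = res_coms[frames]
    static = (
        bool(np.all(res_coms[0] == res_coms[-1]))
        and bool(np.all(traj.box_nm[frames[0]] == traj.box_nm[frames[-1]]))
    )
    if static:
        events = _sparse_contacts(
            lip_coms, res_coms[0], traj.box_nm[frames[0]], sub_times,
            lip_ids, res_ids, species, lower, upper,
        )
    else:
        events = _dense_contacts(
            lip_coms, res_coms, traj.box_nm[frames], sub_times,
            lip_ids, res_ids, species, lower, upper, chunk_lipids,
        )
    events.sort(key=lambda e: (e.lipid_id, e.residue_id, e.t_start_ns))
    return events


def _sparse_contacts(
    lip_coms, res_xyz, box, times, lip_ids, res_ids, species, lower, upper
) -> list[ContactEvent]:
    from scipy.spatial import cKDTree

    tree = cKDTree(np.mod(res_xyz, box), boxsize=box)
    n_frames, n_lip, _ = lip_coms.shape
    within: dict[tuple[int, int], list[int]] = {}
    below: dict[tuple[int, int], list[int]] = {}
    for f in range(n_frames):
        pts = np.mod(lip_coms[f], box)
        hits = tree.query_ball_point(pts, upper)
        for li, neigh in enumerate(hits):
            if not neigh:
                continue
            d = minimum_image(pts[li] - res_xyz[neigh], box)
            dist = np.sqrt((d * d).sum(axis=-1))
            for ri, dd in zip(neigh, dist):
                key = (li, ri)
                within.setdefault(key, []).append(f)
                if dd < lower:
                    below.setdefault(key, []).append(f)

    events: list[ContactEvent] = []
    last = n_frames - 1
    for key, b_frames in below.items():
        li, ri = key
        b = np.asarray(b_frames)
        w_arr = np.asarray(within[key])
        pos = 0
        while True:
            k = np.searchsorted(b, pos)
            if k == len(b):
                break
            open_f = int(b[k])
            # walk the run of consecutive within-upper frames from open_f
            j = int(np.searchsorted(w_arr, open_f))
            while j + 1 < len(w_arr) and w_arr[j + 1] == w_arr[j] + 1:
                j += 1
            run_end = int(w_arr[j])
            if run_end >= last:
                events.append(
                    ContactEvent(
                        int(lip_ids[li]), int(res_ids[ri]), species,
                        float(times[open_f]), float(times[last]), censored=True,
                    )
                )
                break
            close_f = run_end + 1
            events.append(
                ContactEvent(
                    int(lip_ids[li]), int(res_ids[ri]), species,
                    float(times[open_f]), float(times[close_f]), censored=False,
                )
            )
            pos = close_f + 1
    return events


def _dense_contacts(
    lip_coms, res_coms, box_frames, times, lip_ids, res_ids, species,
    lower, upper, chunk_lipids
) -> list[ContactEvent]:
    box = box_frames[:, None, None, :]
    events: list[ContactEvent] = []
    for start in range(0, len(lip_ids), chunk_lipids):
        sl = slice(start, min(start + chunk_lipids, len(lip_ids)))
        delta = lip_coms[:, sl, None, :] - res_coms[:, None, :, :]
        delta = minimum_image(delta, box)
        dist = np.sqrt((delta * delta).sum(axis=-1))
        hit_l, hit_r = np.nonzero((dist < lower).any(axis=0))
        for li, ri in zip(hit_l.tolist(), hit_r.tolist()):
            events.extend(
                detect_contact_events(
                    dist[:, li, ri],
                    times,
                    lower=lower,
                    upper=upper,
                    lipid_id=int(lip_ids[sl][li]),
                    residue_id=int(res_ids[ri]),
                    species=species,
                )
            )
    return events


# ---------------------------------------------------------------------------
# duration profiles

def residue_duration_profile(
    events: Iterable[ContactEvent] | Sequence[Iterable[ContactEvent]],
    repeats: bool = False,
) -> DurationProfile:
    """Aggregate contact events into a per-residue, per-species profile.

    With ``repeats=True`` the input is a sequence of event lists (one per
    independent trajectory); durations are pooled across repeats for the
    means, and per-repeat means are reported alongside.  Censored events
    are excluded from means but counted.
    """
    if repeats:
        repeat_lists = [list(ev) for ev in events]  # type: ignore[arg-type]
    else:
        repeat_lists = [list(events)]  # type: ignore[arg-type]

    durations: dict[tuple[int, str], list[float]] = {}
    censored: dict[tuple[int, str], int] = {}
    per_repeat_rows = []
    for rep, ev_list in enumerate(repeat_lists):
        rep_durs: dict[tuple[int, str], list[float]] = {}
        for e in ev_list:
            key = (e.residue_id, e.species)
            if e.censored:
                censored[key] = censored.get(key, 0) + 1
                continue
            durations.setdefault(key, []).append(e.duration_ns)
            rep_durs.setdefault(key, []).append(e.duration_ns)
        for (rid, sp), vals in rep_durs.items():
            per_repeat_rows.append(
                {
                    "repeat": rep,
                    "residue_id": rid,
                    "species": sp,
                    "mean_duration_ns": float(np.mean(vals)),
                    "n_events": len(vals),
                }
            )

    rows = []
    keys = set(durations) | set(censored)
    for rid, sp in sorted(keys, key=lambda k: (k[0], k[1])):
        vals = durations.get((rid, sp), [])
        rows.append(
            {
                "residue_id": rid,
                "species": sp,
                "mean_duration_ns": float(np.mean(vals)) if vals else np.nan,
                "n_events": len(vals),
                "n_censored": censored.get((rid, sp), 0),
            }
        )
    table = pd.DataFrame(
        rows, columns=["residue_id", "species", "mean_duration_ns", "n_events", "n_censored"]
    )
    return DurationProfile(
        table=table,
        durations={k: np.asarray(v) for k, v in durations.items()},
        per_repeat=pd.DataFrame(per_repeat_rows) if repeats else None,
    )


# ---------------------------------------------------------------------------
# first-shell occupancy and equilibration

def first_shell_series(
    traj: Trajectory,
    species: str,
    shell_radius_nm: float = DEFAULT_SHELL_RADIUS_NM,
) -> OccupancySeries:
    """Per-frame count of species molecules within the first lipid shell.

    A molecule is in the first shell when the minimum-image distance from
    its COM to the nearest receptor bead is at most ``shell_radius_nm``
    (default 1 nm, the shell boundary indicated by the surface RDFs).
    """
    if species not in traj.lipid_species():
        raise ValueError(f"species {species!r} absent from topology")
    coms, _ = lipid_com_series(traj, species=species)
    rec_idx = traj.receptor_indices()
    if len(rec_idx) == 0:
        raise ValueError("no receptor beads in trajectory")
    from scipy.spatial import cKDTree

    rec = traj.coords_nm[:, rec_idx, :].astype(float)
    counts = np.empty(traj.n_frames, dtype=int)
    # static receptors (e.g. the synthetic generator's) need only one tree
    static = bool(np.all(rec[0] == rec[-1])) and bool(
        np.all(traj.box_nm[0] == traj.box_nm[-1])
    )
    tree = cKDTree(np.mod(rec[0], traj.box_nm[0]), boxsize=traj.box_nm[0]) if static else None
    for f in range(traj.n_frames):
        box = traj.box_nm[f]
        t = tree if tree is not None else cKDTree(np.mod(rec[f], box), boxsize=box)
        dmin, _ = t.query(np.mod(coms[f], box))
        counts[f] = int((dmin <= shell_radius_nm).sum())
    return OccupancySeries(
        species=species,
        times_ns=traj.frame_times_ns.copy(),
        counts=counts,
        shell_radius_nm=shell_radius_nm,
    )


def estimate_equilibration(
    occupancy: OccupancySeries,
    tolerance: float = 2.0,
    n_blocks: int = 20,
) -> float:
    """Earliest time after which block-averaged occupancy is stationary.

    The series is split into ``n_blocks`` equal blocks; the reference mean
    and SD are taken from the final half of the blocks.  The equilibration
    time is the start of the earliest block from which every later block
    mean stays within ``tolerance`` x SD of the reference mean.  The
    plateau must cover at least the final quarter of the trajectory,
    otherwise :class:`NoPlateauError` is raised.  The estimate is stored on
    the series along with the default analysis window (equilibration to
    end of trajectory).
    """
    counts = np.asarray(occupancy.counts, dtype=float)
    if len(counts) < n_blocks or n_blocks < 4:
        raise ValueError("series too short: need at least n_blocks >= 4 windows")
    edges = np.linspace(0, len(counts), n_blocks + 1).astype(int)
    block_means = np.array(
        [counts[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    )
    ref = block_means[n_blocks // 2 :]
    ref_mean = ref.mean()
    ref_sd = max(ref.std(ddof=1), 1e-12)
    latest_start = n_blocks - max(2, n_blocks // 4)
    for i in range(latest_start + 1):
        if np.all(np.abs(block_means[i:] - ref_mean) <= tolerance * ref_sd):
            t_eq = float(occupancy.times_ns[edges[i]])
            occupancy.equilibration_time_ns = t_eq
            occupancy.analysis_window_ns = (t_eq, float(occupancy.times_ns[-1]))
            return t_eq
    raise NoPlateauError(
        f"no plateau within {tolerance} x SD covering the final quarter "
        f"(species {occupancy.species})"
    )
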