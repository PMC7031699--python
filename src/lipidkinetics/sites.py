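"""Lipid binding-site identification, pose scoring and lipid interplay.

Binding sites are delineated from per-residue contact-duration profiles:
residues whose mean duration clears a threshold become nodes, residues
within an adjacency radius are connected, and connected components of two
or more residues are reported as sites ranked by their hottest residue.
Bound poses at a site are ranked by a bead-density score, and the coupling
between two co-habiting species is quantified by the Pearson correlation
of their per-repeat mean interaction durations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import DurationProfile, lipid_com_series
from .synthetic import ReceptorModel
from .trajectory import Trajectory, minimum_image

__all__ = [
    "LipidBindingSite",
    "PoseScore",
    "UndefinedCorrelationError",
    "identify_sites",
    "score_poses",
    "representative_pose",
    "duration_pcc",
    "interplay_matrix",
    "classify_interplay",
]

DEFAULT_ADJACENCY_RADIUS_NM = 0.8
DEFAULT_INCLUSION_RADIUS_NM = 1.0
DEFAULT_VOXEL_NM = 0.1
#: |PCC| above which an interplay is annotated synergistic/competing
INTERPLAY_ANNOTATION_THRESHOLD = 0.5


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance input)."""


@dataclass
class LipidBindingSite:
    """A contiguous patch of high-duration residues."""

    site_id: str
    residues: tuple[int, ...]
    species: str  # dominant species by mean duration
    max_duration_ns: float
    mean_duration_ns: float
    n_events: int
    k_off_per_us: float | None = None


@dataclass(frozen=True)
class PoseScore:
    frame: int
    lipid_id: int
    score: float
    rank: int


def identify_sites(
    profile: DurationProfile,
    receptor: ReceptorModel,
    duration_threshold_ns: float | None = None,
    adjacency_radius_nm: float = DEFAULT_ADJACENCY_RADIUS_NM,
    min_size: int = 2,
) -> list[LipidBindingSite]:
    """Delineate binding sites from a duration profile.

    Residues whose mean duration (maximum over species) reaches the
    threshold form graph nodes; edges connect residues whose COMs lie
    within ``adjacency_radius_nm``; connected components with at least
    ``min_size`` members become sites, ranked by maximal member duration.
    The default threshold is 3x the median positive residue duration, a
    scale-free choice that separates designed hotspots from diffusive
    rattling contacts.
    """
    tab = profile.table[profile.table.n_events > 0]
    if tab.empty:
        return []
    per_residue = tab.groupby("residue_id").mean_duration_ns.max()
    if duration_threshold_ns is None:
        positive = per_residue[per_residue > 0]
        if positive.empty:
            return []
        duration_threshold_ns = 3.0 * float(positive.median())
    hot = per_residue[per_residue >= duration_threshold_ns]
    if hot.empty:
        return []

    known = set(int(r) for r in receptor.residue_ids)
    nodes = [int(r) for r in hot.index if int(r) in known]
    coords = {r: receptor.residue_com(r) for r in nodes}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if np.linalg.norm(coords[a] - coords[b]) <= adjacency_radius_nm:
                g.add_edge(a, b)

    components = [sorted(c) for c in nx.connected_components(g) if len(c) >= min_size]
    components.sort(key=lambda c: -max(hot[r] for r in c))
    sites = []
    for i, members in enumerate(components, start=1):
        sub = tab[tab.residue_id.isin(members)]
        by_species = sub.groupby("species").mean_duration_ns.max()
        dominant = str(by_species.idxmax())
        sites.append(
            LipidBindingSite(
                site_id=f"S{i}",
                residues=tuple(int(m) for m in members),
                species=dominant,
                max_duration_ns=float(sub.mean_duration_ns.max()),
                mean_duration_ns=float(
                    (sub.mean_duration_ns * sub.n_events).sum() / sub.n_events.sum()
                ),
                n_events=int(sub.n_events.sum()),
            )
        )
    return sites


def score_poses(
    traj: Trajectory,
    site: LipidBindingSite,
    species: str,
    receptor: ReceptorModel | None = None,
    basic_residues: Sequence[int] | None = None,
    inclusion_radius_nm: float = DEFAULT_INCLUSION_RADIUS_NM,
    voxel_nm: float = DEFAULT_VOXEL_NM,
    margin_nm: float = 1.0,
    mode: str = "all",
) -> list[PoseScore]:
    """Rank bound poses of a species at a site by bead-density score.

    Bound frames are those where the lipid COM lies within
    ``inclusion_radius_nm`` of the site's basic residues -- of every basic
    residue with ``mode="all"`` (the literal reading), or of at least one
    with ``mode="any"`` (useful for wide sites where the intersection is
    empty).  For each lipid bead index a 3D voxel density is accumulated
    over the selected poses; a pose's score is the sum over its beads of
    the density at each bead's voxel.  Poses are returned ranked, ties
    broken by (frame, lipid) index.

    The trajectory is assumed receptor-fixed (the synthetic generator's
    receptor is static; externally loaded trajectories should be aligned
    to the receptor beforehand).
    """
    if basic_residues is None:
        if receptor is None:
            raise ValueError("supply basic_residues or a receptor model")
        basic_residues = sorted(set(site.residues) & receptor.basic_residues)
        if not basic_residues:
            basic_residues = list(site.residues)
    basic_residues = list(basic_residues)

    from .contacts import receptor_residue_com_series

    res_coms, _ = receptor_residue_com_series(traj, basic_residues)
    basic_xyz = res_coms[0]  # static receptor
    coms, lip_ids = lipid_com_series(traj, species=species)

    delta = coms[:, :, None, :] - basic_xyz[None, None, :, :]
    delta = minimum_image(delta, traj.box_nm[:, None, None, :])
    dist = np.sqrt((delta * delta).sum(axis=-1))  # (frames, lipids, basics)
    within = (
        (dist <= inclusion_radius_nm).all(axis=2)
        if mode == "all"
        else (dist <= inclusion_radius_nm).any(axis=2)
    )
    frames_idx, lipids_idx = np.nonzero(within)
    if len(frames_idx) == 0:
        raise ValueError("no bound frames at this site")

    # gather bead positions of each selected pose
    bead_lists = {
        int(rid): np.flatnonzero(traj.resids == rid) for rid in lip_ids
    }
    n_beads = len(next(iter(bead_lists.values())))
    poses = np.empty((len(frames_idx), n_beads, 3))
    for p, (f, li) in enumerate(zip(frames_idx, lipids_idx)):
        poses[p] = traj.coords_nm[f, bead_lists[int(lip_ids[li])], :]

    lo = poses.reshape(-1, 3).min(axis=0) - margin_nm
    hi = poses.reshape(-1, 3).max(axis=0) + margin_nm
    shape = np.maximum(np.ceil((hi - lo) / voxel_nm).astype(int), 1)
    vox = np.clip(((poses - lo) / voxel_nm).astype(int), 0, shape - 1)

    scores = np.zeros(len(frames_idx))
    norm = 1.0 / (len(frames_idx) * voxel_nm**3)
    for b in range(n_beads):
        flat = np.ravel_multi_index(vox[:, b, :].T, shape)
        counts = np.bincount(flat, minlength=int(np.prod(shape)))
        scores += counts[flat] * norm

    order = sorted(
        range(len(scores)),
        key=lambda p: (-scores[p], int(frames_idx[p]), int(lip_ids[lipids_idx[p]])),
    )
    return [
        PoseScore(
            frame=int(frames_idx[p]),
            lipid_id=int(lip_ids[lipids_idx[p]]),
            score=float(scores[p]),
            rank=r + 1,
        )
        for r, p in enumerate(order)
    ]


def representative_pose(scores: Sequence[PoseScore]) -> int:
    """Frame id of the highest-scoring pose (ties: lower frame index)."""
    if not scores:
        raise ValueError("empty score list")
    best = min(scores, key=lambda s: (s.rank, s.frame))
    return best.frame


def duration_pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of per-repeat mean interaction durations.

    Computed directly as sum((x_i - xbar)(y_i - ybar)) /
    sqrt(sum((x_i - xbar)^2) sum((y_i - ybar)^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("require two equal-length 1D vectors of length >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float((dx * dx).sum()))
    sy = math.sqrt(float((dy * dy).sum()))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance in an input vector")
    return float((dx * dy).sum() / (sx * sy))


def interplay_matrix(per_repeat_means: pd.DataFrame) -> pd.DataFrame:
    """Pairwise duration PCC between species.

    ``per_repeat_means`` is species x repeat (rows: species, columns:
    repeat index).  Pairs with zero variance are reported as NaN; the
    diagonal is 1 where defined.
    """
    species = list(per_repeat_means.index)
    out = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
    for i, a in enumerate(species):
        for b in species[i:]:
            try:
                v = duration_pcc(
                    per_repeat_means.loc[a].to_numpy(),
                    per_repeat_means.loc[b].to_numpy(),
                )
            except UndefinedCorrelationError:
                v = np.nan
            out.loc[a, b] = v
            out.loc[b, a] = v
    return out


def classify_interplay(
    pcc: float, threshold: float = INTERPLAY_ANNOTATION_THRESHOLD
) -> str:
    """Annotate a duration correlation: synergistic, competing or neutral."""
    if not np.isfinite(pcc):
        return "undefined"
    if pcc >= threshold:
        return "synergistic"
    if pcc <= -threshold:
        return "competing"
    return "neutral"
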