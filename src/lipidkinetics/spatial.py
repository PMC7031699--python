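"""Spatial lipid statistics: surface RDFs, 2D density maps, Voronoi APL.

All three analyses are leaflet-aware and periodic.  The surface radial
distribution function measures lipid centre-of-mass distances to the
nearest receptor bead and normalizes each distance shell by a Monte-Carlo
estimate of its accessible in-plane area, so g(r) -> 1 in the bulk around
an irregular protein cross-section.  Area per lipid comes from a 2D Voronoi
tessellation of per-leaflet representative beads plus the receptor beads
projected into the leaflet's z-slab, with periodic boundaries handled by
3x3 image tiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

from .composition import MembraneComposition
from .contacts import lipid_com_series
from .trajectory import Trajectory, minimum_image

__all__ = [
    "SurfaceRDF",
    "DensityMap2D",
    "VoronoiAPL",
    "assign_leaflets",
    "representative_points",
    "surface_rdf",
    "density_map_2d",
    "voronoi_apl",
]


@dataclass
class SurfaceRDF:
    """Receptor-surface-referenced radial distribution function."""

    species: str
    bin_edges_nm: np.ndarray
    g: np.ndarray
    n_frames: int
    bulk_density_per_nm2: float
    shell_area_nm2: np.ndarray  # MC-estimated accessible area per shell

    @property
    def bin_centers_nm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_nm[:-1] + self.bin_edges_nm[1:])

    def first_shell_value(self, shell_radius_nm: float = 1.0) -> float:
        """Peak g(r) within the first lipid shell (r <= shell radius)."""
        mask = self.bin_centers_nm <= shell_radius_nm
        return float(self.g[mask].max()) if mask.any() else 0.0


@dataclass
class DensityMap2D:
    """Time-averaged in-plane number density of one species in one leaflet."""

    species: str
    leaflet: str
    x_edges_nm: np.ndarray
    y_edges_nm: np.ndarray
    density_per_nm2: np.ndarray  # (nx, ny)
    n_frames: int

    @property
    def bin_area_nm2(self) -> float:
        return float(
            (self.x_edges_nm[1] - self.x_edges_nm[0])
            * (self.y_edges_nm[1] - self.y_edges_nm[0])
        )

    def molecule_frames(self) -> float:
        """Total molecule-frame count: integral x bin area x frames."""
        return float(self.density_per_nm2.sum() * self.bin_area_nm2 * self.n_frames)


@dataclass
class VoronoiAPL:
    """Per-lipid Voronoi cell areas for one frame."""

    frame: int
    areas_nm2: dict[int, float]  # lipid resid -> cell area
    receptor_area_nm2: dict[str, float]  # per leaflet, summed receptor cells
    per_species: pd.DataFrame  # leaflet, species, mean, sd, n
    box_area_nm2: float

    def total_area(self, leaflet_of: dict[int, str]) -> dict[str, float]:
        totals = dict(self.receptor_area_nm2)
        for rid, area in self.areas_nm2.items():
            lf = leaflet_of[rid]
            totals[lf] = totals.get(lf, 0.0) + area
        return totals


# ---------------------------------------------------------------------------
# leaflet assignment

def _head_bead_index(traj: Trajectory, beads: np.ndarray) -> int:
    names = traj.names[beads]
    for head in ("PO4", "ROH"):
        hit = np.flatnonzero(names == head)
        if len(hit):
            return int(beads[hit[0]])
    return int(beads[0])


def _representative_bead_indices(
    traj: Trajectory, composition: MembraneComposition, beads: np.ndarray, species: str
) -> np.ndarray:
    rule_names = composition.species[species].representative_bead_names()
    names = traj.names[beads]
    idx = [beads[np.flatnonzero(names == nm)] for nm in rule_names]
    if any(len(i) == 0 for i in idx):
        raise ValueError(
            f"representative bead rule for {species} not resolvable "
            f"(need beads {rule_names}, have {sorted(set(names))})"
        )
    return np.array([int(i[0]) for i in idx])


def assign_leaflets(
    traj: Trajectory, composition: MembraneComposition
) -> tuple[np.ndarray, np.ndarray]:
    """Per-molecule, per-frame leaflet labels.

    The instantaneous membrane midplane is the median z of all lipid
    representative beads; a molecule is labelled by the sign of its
    head-group bead z relative to the midplane.  Cholesterol (a flip-flop
    capable sterol) is re-evaluated every frame; every other species keeps
    its frame-0 label.

    Returns ``(labels, molecule_resids)`` with labels of shape
    (n_frames, n_molecules) holding "upper"/"lower".
    """
    lipid_resids = np.unique(traj.resids[~traj.is_receptor])
    if len(lipid_resids) == 0:
        raise ValueError("no lipid molecules in trajectory")
    head_idx = np.empty(len(lipid_resids), dtype=int)
    rep_idx: list[np.ndarray] = []
    is_sterol = np.zeros(len(lipid_resids), dtype=bool)
    for m, rid in enumerate(lipid_resids):
        beads = np.flatnonzero(traj.resids == rid)
        species = str(traj.resnames[beads[0]])
        head_idx[m] = _head_bead_index(traj, beads)
        rep_idx.append(_representative_bead_indices(traj, composition, beads, species))
        is_sterol[m] = composition.species[species].lipid_class == "sterol"

    rep_flat = np.concatenate(rep_idx)
    rep_z = traj.coords_nm[:, rep_flat, 2].astype(float)
    midplane = np.median(rep_z, axis=1)  # (n_frames,)
    head_z = traj.coords_nm[:, head_idx, 2].astype(float)
    rel = head_z - midplane[:, None]
    if np.all(np.abs(rel) < 1e-9):
        raise ValueError("degenerate geometry: all head beads on the midplane")

    above = rel > 0
    labels = np.where(above, "upper", "lower").astype(object)
    # non-sterol species keep their frame-0 assignment
    frozen = ~is_sterol
    labels[:, frozen] = labels[0, frozen]
    return labels, lipid_resids


def representative_points(
    traj: Trajectory,
    composition: MembraneComposition,
    frame: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Representative-bead xy positions of all lipids in one frame.

    Glycerophospholipids and phosphoinositides reduce to the GL1/GL2
    midpoint, sphingolipids and glycolipids to the AM1/AM2 midpoint,
    sterols to the ROH bead.  Returns (points_xy, molecule_resids, species).
    """
    lipid_resids = np.unique(traj.resids[~traj.is_receptor])
    pts = np.empty((len(lipid_resids), 2))
    species = np.empty(len(lipid_resids), dtype=object)
    box = traj.box_nm[frame]
    for m, rid in enumerate(lipid_resids):
        beads = np.flatnonzero(traj.resids == rid)
        sp = str(traj.resnames[beads[0]])
        species[m] = sp
        idx = _representative_bead_indices(traj, composition, beads, sp)
        coords = traj.coords_nm[frame, idx, :].astype(float)
        ref = coords[:1]
        unwrapped = ref + minimum_image(coords - ref, box)
        pts[m] = np.mod(unwrapped.mean(axis=0), box)[:2]
    return pts, lipid_resids, species


# ---------------------------------------------------------------------------
# surface RDF

def surface_rdf(
    traj: Trajectory,
    species: str,
    composition: MembraneComposition,
    bin_width_nm: float = 0.1,
    r_max_nm: float | None = None,
    n_mc_samples: int = 100_000,
    seed: int = 0,
    begin_ns: float | None = None,
    end_ns: float | None = None,
) -> SurfaceRDF:
    """Radial distribution of lipid COMs around the receptor surface.

    The distance of a molecule to the receptor is the minimum-image
    distance from its COM to the nearest receptor bead.  Each distance
    shell is normalized by its accessible in-plane area, estimated by
    Monte-Carlo sampling of the same distance metric over the leaflet
    plane, times the bulk (area-averaged) density of the species in that
    leaflet, so a homogeneously distributed species gives g(r) = 1.

    The receptor is taken from frame 0 (static-receptor convention; align
    external trajectories first).
    """
    if species not in traj.lipid_species():
        raise ValueError(f"species {species!r} absent from topology")
    box = traj.box_nm[0]
    if r_max_nm is None:
        r_max_nm = min(box[0], box[1]) / 2.0 - 0.5
    if r_max_nm >= min(box[0], box[1]) / 2.0:
        raise ValueError("r_max must be below half the smallest box edge")
    frames = traj.time_window(begin_ns, end_ns)

    from scipy.spatial import cKDTree

    rec = np.mod(traj.coords_nm[0, traj.receptor_indices(), :].astype(float), box)
    rec_tree = cKDTree(rec, boxsize=box)
    coms, mol_ids = lipid_com_series(traj, species=species)
    labels, lab_ids = assign_leaflets(traj, composition)
    col = {rid: i for i, rid in enumerate(lab_ids)}
    mol_cols = np.array([col[rid] for rid in mol_ids])

    edges = np.arange(0.0, r_max_nm + bin_width_nm, bin_width_nm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    obs = np.zeros(len(centers))
    exp = np.zeros(len(centers))
    rng = np.random.default_rng(seed)

    for leaflet in ("upper", "lower"):
        sel_frames_counts = 0.0
        leaflet_hist = np.zeros(len(centers))
        z_values = []
        for chunk_start in range(0, len(frames), 200):
            chunk = frames[chunk_start : chunk_start + 200]
            in_leaf = labels[np.ix_(chunk, mol_cols)] == leaflet  # (chunk, mols)
            if not in_leaf.any():
                continue
            pts = coms[chunk][in_leaf]  # flattens selected molecule-frames
            z_values.append(pts[:, 2].mean())
            dmin, _ = rec_tree.query(np.mod(pts, box))
            leaflet_hist += np.histogram(dmin, bins=edges)[0]
            # bulk density over the region the histogram actually covers:
            # molecules beyond r_max (box corners) enter neither side
            sel_frames_counts += int((dmin <= edges[-1]).sum())
        if sel_frames_counts == 0:
            continue
        # MC accessible-area estimate at the leaflet's mean COM plane
        z_plane = float(np.mean(z_values))
        samples = np.column_stack(
            [
                rng.uniform(0, box[0], n_mc_samples),
                rng.uniform(0, box[1], n_mc_samples),
                np.full(n_mc_samples, z_plane),
            ]
        )
        dmin, _ = rec_tree.query(np.mod(samples, box))
        mc_hist = np.histogram(dmin, bins=edges)[0]
        shell_area = mc_hist / n_mc_samples * box[0] * box[1]
        accessible_total = (dmin <= edges[-1]).mean() * box[0] * box[1]
        mean_n = sel_frames_counts / len(frames)
        bulk = mean_n / accessible_total
        obs += leaflet_hist / len(frames)
        exp += bulk * shell_area

    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(exp > 0, obs / exp, 0.0)
    total_mols = len(mol_ids)
    return SurfaceRDF(
        species=species,
        bin_edges_nm=edges,
        g=g,
        n_frames=len(frames),
        bulk_density_per_nm2=total_mols / (box[0] * box[1]),
        shell_area_nm2=exp,
    )


# ---------------------------------------------------------------------------
# 2D density maps

def density_map_2d(
    traj: Trajectory,
    species: str,
    leaflet: str,
    composition: MembraneComposition,
    grid_spacing_nm: float = 0.3,
    begin_ns: float | None = None,
    end_ns: float | None = None,
) -> DensityMap2D:
    """Time-averaged in-plane number density of one species in one leaflet.

    COM xy positions are accumulated on a regular grid over the analysis
    window; the counts are normalized per frame and per bin area, so the
    integral of the map times the frame count recovers the counted
    molecule-frames exactly.
    """
    frames = traj.time_window(begin_ns, end_ns)
    if len(frames) == 0:
        raise ValueError("empty analysis window")
    box = traj.box_nm[0]
    nx = max(int(round(box[0] / grid_spacing_nm)), 1)
    ny = max(int(round(box[1] / grid_spacing_nm)), 1)
    x_edges = np.linspace(0, box[0], nx + 1)
    y_edges = np.linspace(0, box[1], ny + 1)

    coms, mol_ids = lipid_com_series(traj, species=species)
    labels, lab_ids = assign_leaflets(traj, composition)
    col = {rid: i for i, rid in enumerate(lab_ids)}
    mol_cols = np.array([col[rid] for rid in mol_ids])

    hist = np.zeros((nx, ny))
    for f in frames:
        sel = labels[f, mol_cols] == leaflet
        if not sel.any():
            continue
        pts = coms[f][sel]
        hist += np.histogram2d(pts[:, 0], pts[:, 1], bins=(x_edges, y_edges))[0]
    bin_area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    return DensityMap2D(
        species=species,
        leaflet=leaflet,
        x_edges_nm=x_edges,
        y_edges_nm=y_edges,
        density_per_nm2=hist / (len(frames) * bin_area),
        n_frames=len(frames),
    )


# ---------------------------------------------------------------------------
# Voronoi area per lipid

def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a convex polygon, vertices sorted by angle."""
    c = vertices.mean(axis=0)
    order = np.argsort(np.arctan2(vertices[:, 1] - c[1], vertices[:, 0] - c[0]))
    v = vertices[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _periodic_voronoi_areas(points: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Voronoi cell areas of points in a periodic 2D box (3x3 image tiling).

    Exact as long as no cell spans half the box, which holds for membrane
    densities; degenerate cells raise.
    """
    n = len(points)
    if n < 3:
        raise ValueError("fewer than 3 generating points in leaflet")
    shifts = np.array(
        [[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1) if not (i == 0 and j == 0)]
    )
    tiled = np.vstack([points] + [points + s * box_xy for s in shifts])
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise ValueError("unbounded Voronoi cell: cell spans half the box")
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


def voronoi_apl(
    traj: Trajectory,
    composition: MembraneComposition,
    frame: int = 0,
    leaflet_z_slab_nm: float = 2.0,
) -> VoronoiAPL:
    """Area per lipid by periodic 2D Voronoi tessellation of one frame.

    Per leaflet, the generating points are the lipids' representative beads
    (glycerol midpoint / sphingosine midpoint / hydroxyl bead) plus the xy
    projections of receptor beads lying between the bilayer midplane and
    that leaflet's midplane (``leaflet_z_slab_nm`` from the bilayer
    midplane).  A lipid's APL is its cell area; receptor cell areas are
    summed separately.  Lipid plus receptor cell areas tile the box
    exactly.
    """
    box = traj.box_nm[frame]
    box_xy = box[:2]
    pts, resids, species = representative_points(traj, composition, frame)
    labels, lab_ids = assign_leaflets(traj, composition)
    col = {rid: i for i, rid in enumerate(lab_ids)}
    frame_labels = np.array([labels[frame, col[rid]] for rid in resids], dtype=object)

    rep_flat = []
    for rid in resids:
        beads = np.flatnonzero(traj.resids == rid)
        sp = str(traj.resnames[beads[0]])
        rep_flat.append(_representative_bead_indices(traj, composition, beads, sp))
    midplane = float(
        np.median(traj.coords_nm[frame, np.concatenate(rep_flat), 2].astype(float))
    )

    rec_idx = traj.receptor_indices()
    rec_xyz = traj.coords_nm[frame, rec_idx, :].astype(float) if len(rec_idx) else np.zeros((0, 3))

    areas: dict[int, float] = {}
    receptor_area: dict[str, float] = {}
    rows = []
    for leaflet in ("upper", "lower"):
        sel = frame_labels == leaflet
        lipid_pts = pts[sel]
        lipid_rids = resids[sel]
        lipid_sp = species[sel]
        if len(rec_xyz):
            rel_z = rec_xyz[:, 2] - midplane
            in_slab = (
                (rel_z >= 0) & (rel_z <= leaflet_z_slab_nm)
                if leaflet == "upper"
                else (rel_z <= 0) & (rel_z >= -leaflet_z_slab_nm)
            )
            # stacked beads of a vertical helix project to one xy point;
            # deduplicate so no zero-area twin cells are generated
            rec_pts = np.unique(np.round(rec_xyz[in_slab, :2], 6), axis=0)
        else:
            rec_pts = np.zeros((0, 2))
        all_pts = np.vstack([lipid_pts, rec_pts])
        cell_areas = _periodic_voronoi_areas(all_pts, box_xy)
        for rid, a in zip(lipid_rids, cell_areas[: len(lipid_rids)]):
            areas[int(rid)] = float(a)
        receptor_area[leaflet] = float(cell_areas[len(lipid_rids):].sum())
        for sp in sorted(set(lipid_sp)):
            vals = cell_areas[: len(lipid_rids)][lipid_sp == sp]
            rows.append(
                {
                    "leaflet": leaflet,
                    "species": sp,
                    "mean_apl_nm2": float(vals.mean()),
                    "sd_apl_nm2": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }
            )
    return VoronoiAPL(
        frame=frame,
        areas_nm2=areas,
        receptor_area_nm2=receptor_area,
        per_species=pd.DataFrame(rows),
        box_area_nm2=float(box_xy[0] * box_xy[1]),
    )
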