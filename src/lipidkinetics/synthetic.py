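"""Synthetic coarse-grained membrane trajectories with known binding kinetics.

The generator stands in for multi-microsecond CG-MD data: a static
multi-helix receptor bead model spans an asymmetric bilayer, lipids diffuse
laterally as 2D Brownian walkers, and designated binding sites capture
eligible lipids with first-order hazards.  Residence times are drawn
exactly from an exponential distribution with the site's true dissociation
rate, so every downstream statistic (dual-cutoff durations, k_off fits,
site maps) can be validated against a ground-truth event ledger.

This is a statistical emulator, not a physical simulator: there are no
forces, no thermostat, and no lipid internal dynamics beyond a centre of
mass plus fixed representative-bead offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import MembraneComposition, SystemConfig, realize_counts
from .trajectory import RECEPTOR_RESNAME, Trajectory

__all__ = [
    "ReceptorModel",
    "BindingSiteSpec",
    "GroundTruthLedger",
    "build_helix_bundle_receptor",
    "build_seven_helix_receptor",
    "design_site",
    "designed_member_residues",
    "simulate_membrane_trajectory",
    "ledger_to_reference_durations",
]

#: leaflet midplanes sit at +/- this distance from the bilayer midplane (nm)
LEAFLET_Z_NM = 2.0
#: head-group bead offset above the molecule COM (nm)
HEAD_OFFSET_NM = 0.3
#: bound-lipid tether: per-frame Gaussian jitter, truncated in radius
TETHER_SIGMA_NM = 0.10
TETHER_MAX_NM = 0.25
#: displacement distance from the anchor applied on unbinding (nm)
EJECT_DISTANCE_NM = 1.6
#: unbound lipids may not diffuse closer than this to a site anchor, so a
#: contact below the lower cutoff always corresponds to a ledger binding
#: (0.55 lower cutoff + 0.25 tether radius + margin)
UNBOUND_KEEPOUT_NM = 0.85
#: default per-species lateral diffusion coefficient (nm^2/ns), CG-regime
DEFAULT_DIFFUSION = 2e-2


@dataclass
class ReceptorModel:
    """Static receptor bead model.

    One or more beads per residue; residue ids unique and contiguous.
    Coordinates are receptor-local, centred on the origin with the
    transmembrane axis along z; the simulator translates the model to the
    box centre.
    """

    residue_ids: np.ndarray
    bead_positions: list[np.ndarray]  # one (n_beads, 3) array per residue
    basic_residues: set[int] = field(default_factory=set)
    helix_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if len(np.unique(self.residue_ids)) != len(self.residue_ids):
            raise ValueError("residue ids must be unique")
        if len(self.bead_positions) != len(self.residue_ids):
            raise ValueError("one bead array required per residue")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def residue_com(self, resid: int) -> np.ndarray:
        i = int(np.flatnonzero(self.residue_ids == resid)[0])
        return np.asarray(self.bead_positions[i], dtype=float).mean(axis=0)

    def all_beads(self) -> tuple[np.ndarray, np.ndarray]:
        """(bead coordinates, per-bead residue id), concatenated."""
        coords = np.concatenate([np.atleast_2d(b) for b in self.bead_positions])
        resids = np.concatenate(
            [
                np.full(len(np.atleast_2d(b)), rid)
                for rid, b in zip(self.residue_ids, self.bead_positions)
            ]
        )
        return coords.astype(float), resids.astype(int)

    def max_radius_xy(self) -> float:
        coords, _ = self.all_beads()
        return float(np.sqrt((coords[:, :2] ** 2).sum(axis=1)).max())


@dataclass
class BindingSiteSpec:
    """A designed lipid binding site with known Markovian kinetics."""

    site_id: str
    anchor_residues: tuple[int, ...]
    anchor_point_xy: tuple[float, float]  # receptor-local nm
    capture_radius_nm: float
    species: str
    k_on_per_us: float
    k_off_true_per_us: float
    leaflet: str  # "upper" | "lower"

    def __post_init__(self) -> None:
        if self.k_on_per_us <= 0 or self.k_off_true_per_us <= 0:
            raise ValueError("rates must be positive")
        if not self.anchor_residues:
            raise ValueError("anchor residue set must be non-empty")
        if self.leaflet not in ("upper", "lower"):
            raise ValueError("leaflet must be 'upper' or 'lower'")


@dataclass
class GroundTruthLedger:
    """Exact binding/unbinding transitions: the oracle for event detection.

    Times are in microseconds.  ``t_on`` is the frame time at which the
    lipid was first rendered bound; ``t_off`` is the exact exponential
    unbinding time (the rendered displacement happens at the first frame at
    or after it, i.e. within one stride).
    """

    events: list[tuple[int, str, float, float]] = field(default_factory=list)

    def record(self, lipid_id: int, site_id: str, t_on_us: float, t_off_us: float) -> None:
        if t_off_us <= t_on_us:
            raise ValueError("t_off must exceed t_on")
        self.events.append((int(lipid_id), str(site_id), float(t_on_us), float(t_off_us)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events, columns=["lipid_id", "site_id", "t_on_us", "t_off_us"]
        )

    def to_csv(self, path: str | Path) -> None:
        # %.17g preserves float64 exactly across the round trip
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruthLedger":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            events=[
                (int(r.lipid_id), str(r.site_id), float(r.t_on_us), float(r.t_off_us))
                for r in df.itertuples()
            ]
        )


def ledger_to_reference_durations(ledger: GroundTruthLedger) -> dict[str, np.ndarray]:
    """Residence-time samples (t_off - t_on, in us) grouped by site."""
    out: dict[str, list[float]] = {}
    for _, site_id, t_on, t_off in ledger.events:
        out.setdefault(site_id, []).append(t_off - t_on)
    return {k: np.asarray(v) for k, v in out.items()}


def build_helix_bundle_receptor(
    n_helices: int = 7,
    residues_per_helix: int = 13,
    ring_radius_nm: float = 1.5,
    z_span_nm: float = 4.2,
    basic_residues: set[int] | None = None,
) -> ReceptorModel:
    """An idealised transmembrane helix bundle, one bead per residue.

    Helices are vertical bead stacks evenly placed on a ring; residues are
    numbered contiguously helix by helix, from the lower (cytoplasmic) end
    upward.  The default is a GPCR-like seven-helix bundle.
    """
    residue_ids = []
    beads = []
    spans = {}
    rid = 1
    zs = np.linspace(-z_span_nm / 2, z_span_nm / 2, residues_per_helix)
    for h in range(n_helices):
        theta = 2 * math.pi * h / n_helices
        x, y = ring_radius_nm * math.cos(theta), ring_radius_nm * math.sin(theta)
        start = rid
        for z in zs:
            residue_ids.append(rid)
            beads.append(np.array([[x, y, z]]))
            rid += 1
        spans[f"TM{h + 1}"] = (start, rid - 1)
    return ReceptorModel(
        residue_ids=np.array(residue_ids),
        bead_positions=beads,
        basic_residues=set(basic_residues or ()),
        helix_spans=spans,
    )


def design_site(
    receptor: ReceptorModel,
    helix: str,
    leaflet: str,
    species: str,
    site_id: str,
    k_on_per_us: float,
    k_off_true_per_us: float,
    capture_radius_nm: float = 1.2,
) -> BindingSiteSpec:
    """Place a binding site at the membrane-facing end of one helix.

    The two residues of the helix closest to the leaflet midplane z-level
    become the anchors; a lipid tethered at their centroid stays within the
    contact lower cutoff of both.
    """
    lo, hi = receptor.helix_spans[helix]
    rids = [r for r in receptor.residue_ids if lo <= r <= hi]
    target_z = LEAFLET_Z_NM if leaflet == "upper" else -LEAFLET_Z_NM
    rids.sort(key=lambda r: abs(receptor.residue_com(r)[2] - target_z))
    anchors = tuple(int(r) for r in sorted(rids[:2]))
    centroid = np.mean([receptor.residue_com(r) for r in anchors], axis=0)
    return BindingSiteSpec(
        site_id=site_id,
        anchor_residues=anchors,
        anchor_point_xy=(float(centroid[0]), float(centroid[1])),
        capture_radius_nm=capture_radius_nm,
        species=species,
        k_on_per_us=k_on_per_us,
        k_off_true_per_us=k_off_true_per_us,
        leaflet=leaflet,
    )


def designed_member_residues(
    receptor: ReceptorModel,
    site: BindingSiteSpec,
    lower_cutoff_nm: float = 0.55,
) -> set[int]:
    """Residues a tethered lipid can open a dual-cutoff contact with.

    Geometric ground truth for site-recovery tests: a bound lipid's COM
    stays within ``TETHER_MAX_NM`` of the anchor centroid, so a residue can
    start a contact iff its COM lies within lower_cutoff + TETHER_MAX of
    that centroid.
    """
    centroid = np.mean([receptor.residue_com(r) for r in site.anchor_residues], axis=0)
    reach = lower_cutoff_nm + TETHER_MAX_NM
    members = set()
    for rid in receptor.residue_ids:
        if np.linalg.norm(receptor.residue_com(int(rid)) - centroid) < reach:
            members.add(int(rid))
    return members


# ---------------------------------------------------------------------------
# bead templates

_CLASS_BEADS = {
    "glycerophospholipid": (("PO4", "GL1", "GL2"), "glycerol"),
    "phosphoinositide": (("PO4", "GL1", "GL2"), "glycerol"),
    "sphingolipid": (("PO4", "AM1", "AM2"), "sphingosine"),
    "glycolipid": (("PO4", "AM1", "AM2"), "sphingosine"),
    "sterol": (("ROH",), "sterol"),
}


def _bead_template(lipid_class: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Bead names and COM-relative offsets (upper-leaflet orientation)."""
    names, kind = _CLASS_BEADS[lipid_class]
    if kind == "sterol":
        return names, np.zeros((1, 3))
    # head bead above the COM, backbone pair below; offsets sum to zero
    offsets = np.array(
        [
            [0.0, 0.0, HEAD_OFFSET_NM],
            [0.15, 0.0, -HEAD_OFFSET_NM / 2],
            [-0.15, 0.0, -HEAD_OFFSET_NM / 2],
        ]
    )
    return names, offsets


def simulate_membrane_trajectory(
    composition: MembraneComposition,
    receptor: ReceptorModel,
    sites: list[BindingSiteSpec],
    cfg: SystemConfig,
    n_upper: int | None = None,
    n_lower: int | None = None,
    diffusion_nm2_per_ns: dict[str, float] | None = None,
    chol_flip_hazard_per_us: float = 0.1,
    area_per_lipid_nm2: float = 0.65,
) -> tuple[Trajectory, GroundTruthLedger]:
    """Generate a membrane trajectory with ground-truth binding events.

    Unbound lipids perform 2D Brownian steps with periodic wrapping and a
    hard cylindrical exclusion around the receptor; an unbound lipid of the
    right species and leaflet within a free site's capture radius binds
    with hazard k_on per us; a bound lipid is tethered at the site's anchor
    centroid and unbinds at an exactly exponential time with hazard
    k_off_true, after which it is displaced beyond the analysis upper
    cutoff within one frame.  Unbound cholesterol flips leaflet with a
    small constant hazard.  Identical seed and configuration give a
    bit-identical trajectory.

    Returns the rendered :class:`Trajectory` and the exact event ledger.
    """
    from .composition import validate_composition

    violations = validate_composition(composition)
    if violations:
        raise ValueError(f"invalid composition: {violations}")
    for s in sites:
        if not set(s.anchor_residues) <= set(int(r) for r in receptor.residue_ids):
            raise ValueError(f"site {s.site_id} anchors unknown residues")

    bx, by, bz = cfg.box_nm
    box3 = np.array([bx, by, bz])
    centre = np.array([bx / 2, by / 2, bz / 2])
    r_receptor = receptor.max_radius_xy()
    if r_receptor + 1.0 > min(bx, by) / 2:
        raise ValueError("box too small for receptor")
    exclusion_radius = max(r_receptor - 0.4, 0.0)

    if n_upper is None:
        n_upper = max(int((bx * by - math.pi * r_receptor**2) / area_per_lipid_nm2), 1)
    if n_lower is None:
        n_lower = n_upper
    if n_upper > 0 and n_lower > 0:
        counts = realize_counts(composition, n_upper, n_lower)
    else:  # zero-lipid degenerate case: receptor-only frames
        counts = {
            "upper": realize_counts(composition, max(n_upper, 1), 1)["upper"]
            if n_upper > 0
            else {},
            "lower": realize_counts(composition, 1, max(n_lower, 1))["lower"]
            if n_lower > 0
            else {},
        }

    rng = np.random.default_rng(cfg.seed)
    dt_ns = cfg.frame_stride_ns
    dt_us = dt_ns * 1e-3
    n_frames = cfg.n_frames
    times_ns = np.arange(n_frames) * dt_ns

    # --- receptor particles (static) ------------------------------------
    rec_coords, rec_bead_resids = receptor.all_beads()
    rec_coords = rec_coords + centre
    n_rec = len(rec_coords)

    # --- lipid bookkeeping ----------------------------------------------
    lipid_species: list[str] = []
    lipid_leaflet: list[int] = []  # +1 upper, -1 lower
    for leaflet_name, sign in (("upper", 1), ("lower", -1)):
        for name in sorted(counts[leaflet_name]):
            lipid_species += [name] * counts[leaflet_name][name]
            lipid_leaflet += [sign] * counts[leaflet_name][name]
    n_lipids = len(lipid_species)
    leaflet_sign = np.array(lipid_leaflet, dtype=float)
    species_arr = np.array(lipid_species, dtype=object)

    for s in sites:
        eligible = np.sum(
            (species_arr == s.species)
            & (leaflet_sign == (1 if s.leaflet == "upper" else -1))
        )
        if eligible < 1:
            raise ValueError(
                f"site {s.site_id}: no {s.species} lipid in {s.leaflet} leaflet"
            )

    diffusion = dict(diffusion_nm2_per_ns or {})
    sigma_step = np.array(
        [
            math.sqrt(2.0 * diffusion.get(sp, DEFAULT_DIFFUSION) * dt_ns)
            for sp in lipid_species
        ]
    )

    # bead layout: one template per lipid class, z-mirrored in the lower leaflet
    bead_owner: list[int] = []
    bead_names: list[str] = []
    bead_offsets: list[np.ndarray] = []
    for i, sp_name in enumerate(lipid_species):
        names, offsets = _bead_template(composition.species[sp_name].lipid_class)
        offsets = offsets * np.array([1.0, 1.0, leaflet_sign[i]])
        for nm, off in zip(names, offsets):
            bead_owner.append(i)
            bead_names.append(nm)
            bead_offsets.append(off)
    bead_owner_arr = np.array(bead_owner, dtype=int)
    bead_offsets_arr = np.array(bead_offsets) if bead_offsets else np.zeros((0, 3))
    n_lipid_beads = len(bead_owner)

    # --- site state -------------------------------------------------------
    site_anchor_xyz = []
    for s in sites:
        cen = np.mean([receptor.residue_com(r) for r in s.anchor_residues], axis=0)
        site_anchor_xyz.append(cen + centre)
        if s.capture_radius_nm <= UNBOUND_KEEPOUT_NM:
            raise ValueError(
                f"site {s.site_id}: capture radius must exceed the unbound "
                f"keep-out distance ({UNBOUND_KEEPOUT_NM} nm)"
            )
    site_anchor_xyz = np.array(site_anchor_xyz).reshape(len(sites), 3)

    def outside_keepout(cand_xy: np.ndarray, cand_z: np.ndarray) -> np.ndarray:
        """True where a position keeps clear of every site's anchor pocket."""
        ok = np.ones(len(cand_xy), dtype=bool)
        for a in site_anchor_xyz:
            d2 = cand_xy - a[:2]
            d2 -= np.array([bx, by]) * np.round(d2 / [bx, by])
            dist = np.sqrt((d2 * d2).sum(axis=1) + (cand_z - a[2]) ** 2)
            ok &= dist >= UNBOUND_KEEPOUT_NM
        return ok

    # --- initial placement ----------------------------------------------
    z = centre[2] + leaflet_sign * LEAFLET_Z_NM
    xy = np.empty((n_lipids, 2))
    free = np.arange(n_lipids)
    while len(free):
        cand = rng.uniform(0, [bx, by], size=(len(free), 2))
        ok = np.linalg.norm(cand - centre[:2], axis=1) >= exclusion_radius + 0.2
        ok &= outside_keepout(cand, z[free])
        xy[free[ok]] = cand[ok]
        free = free[~ok]
    site_occupant = np.full(len(sites), -1, dtype=int)
    lipid_site = np.full(n_lipids, -1, dtype=int)  # -1 = unbound
    unbind_time_us = np.full(n_lipids, np.inf)
    bind_start_us = np.full(n_lipids, np.nan)
    site_capture_p = np.array([1.0 - math.exp(-s.k_on_per_us * dt_us) for s in sites])
    flip_p = 1.0 - math.exp(-chol_flip_hazard_per_us * dt_us)
    is_chol = np.array(
        [composition.species[sp].lipid_class == "sterol" for sp in lipid_species]
    )

    ledger = GroundTruthLedger()
    coords = np.empty((n_frames, n_rec + n_lipid_beads, 3), dtype=np.float32)

    lipid_pos = np.empty((n_lipids, 3))
    for f in range(n_frames):
        t_us = times_ns[f] * 1e-3

        # scheduled unbinding: displace beyond the upper cutoff this frame
        due = np.flatnonzero(unbind_time_us <= t_us)
        just_ejected = np.zeros(n_lipids, dtype=bool)
        just_ejected[due] = True
        for i in due:
            s_idx = lipid_site[i]
            s = sites[s_idx]
            ledger.record(i, s.site_id, bind_start_us[i], unbind_time_us[i])
            z[i] = centre[2] + leaflet_sign[i] * LEAFLET_Z_NM
            # displace beyond the upper cutoff; resample the direction until
            # the landing point is legal (outside the receptor core and every
            # site's keep-out pocket, including neighbouring sites')
            for _ in range(200):
                theta = rng.uniform(0, 2 * math.pi)
                cand = np.mod(
                    site_anchor_xyz[s_idx, :2]
                    + EJECT_DISTANCE_NM * np.array([math.cos(theta), math.sin(theta)]),
                    [bx, by],
                )
                d_core = cand - centre[:2]
                if (
                    np.linalg.norm(d_core) >= exclusion_radius
                    and outside_keepout(cand[None, :], z[i : i + 1])[0]
                ):
                    break
            xy[i] = cand
            site_occupant[s_idx] = -1
            lipid_site[i] = -1
            unbind_time_us[i] = np.inf

        # diffusion of unbound lipids with receptor hard-core exclusion;
        # lipids ejected this frame are rendered at the displaced position
        # (beyond the upper cutoff) so the contact unambiguously closes
        unbound = (lipid_site < 0) & ~just_ejected
        if f > 0 and unbound.any():
            idx = np.flatnonzero(unbound)
            step = rng.normal(size=(len(idx), 2)) * sigma_step[idx, None]
            trial = np.mod(xy[idx] + step, [bx, by])
            d = trial - centre[:2]
            d -= np.array([bx, by]) * np.round(d / [bx, by])
            ok = np.sqrt((d * d).sum(axis=1)) >= exclusion_radius
            ok &= outside_keepout(trial, z[idx])
            moved = idx[ok]
            xy[moved] = trial[ok]
            # cholesterol leaflet flip (unbound only)
            if flip_p > 0:
                chol_idx = idx[is_chol[idx]]
                flips = chol_idx[rng.random(len(chol_idx)) < flip_p]
                leaflet_sign[flips] *= -1.0
                z[flips] = centre[2] + leaflet_sign[flips] * LEAFLET_Z_NM

        # binding attempts at free sites
        for s_idx, s in enumerate(sites):
            if site_occupant[s_idx] >= 0:
                continue
            want_sign = 1.0 if s.leaflet == "upper" else -1.0
            cand = np.flatnonzero(
                (lipid_site < 0)
                & ~just_ejected
                & (species_arr == s.species)
                & (leaflet_sign == want_sign)
            )
            if len(cand) == 0:
                continue
            d = xy[cand] - site_anchor_xyz[s_idx, :2]
            d -= np.array([bx, by]) * np.round(d / [bx, by])
            near = cand[np.sqrt((d * d).sum(axis=1)) <= s.capture_radius_nm]
            if len(near) == 0:
                continue
            hit = near[rng.random(len(near)) < site_capture_p[s_idx]]
            if len(hit) == 0:
                continue
            i = int(rng.choice(hit))
            site_occupant[s_idx] = i
            lipid_site[i] = s_idx
            bind_start_us[i] = t_us
            unbind_time_us[i] = t_us + rng.exponential(1.0 / s.k_off_true_per_us)

        # render: tethered positions for bound lipids, base plane otherwise
        lipid_pos[:, 0] = xy[:, 0]
        lipid_pos[:, 1] = xy[:, 1]
        lipid_pos[:, 2] = z
        bound = np.flatnonzero(lipid_site >= 0)
        for i in bound:
            jit = rng.normal(scale=TETHER_SIGMA_NM, size=3)
            norm = np.linalg.norm(jit)
            if norm > TETHER_MAX_NM:
                jit *= TETHER_MAX_NM / norm
            lipid_pos[i] = site_anchor_xyz[lipid_site[i]] + jit

        frame = coords[f]
        frame[:n_rec] = rec_coords
        if n_lipid_beads:
            frame[n_rec:] = lipid_pos[bead_owner_arr] + bead_offsets_arr
        np.mod(frame, box3, out=frame)

    # close censored events at trajectory end for the ledger? ledger keeps
    # only completed transitions; still-bound lipids are censored and the
    # dual-cutoff detector flags them, so they are intentionally omitted.

    names = ["BB"] * n_rec + bead_names
    resids = list(rec_bead_resids) + [
        int(receptor.residue_ids.max()) + 1 + i for i in bead_owner
    ]
    resnames = [RECEPTOR_RESNAME] * n_rec + [lipid_species[i] for i in bead_owner]
    traj = Trajectory(
        frame_times_ns=times_ns,
        coords_nm=coords,
        box_nm=np.tile(box3, (n_frames, 1)),
        names=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
    )
    return traj, ledger


def lipid_resid_for_index(receptor: ReceptorModel, lipid_index: int) -> int:
    """Map a ledger lipid index to the residue id used in the trajectory."""
    return int(receptor.residue_ids.max()) + 1 + lipid_index


def make_ideal_gas_trajectory(
    receptor: ReceptorModel,
    species: str,
    lipid_class: str,
    n_molecules: int,
    n_frames: int,
    box_nm: tuple[float, float, float] = (14.0, 14.0, 10.0),
    leaflet: str = "upper",
    seed: int = 0,
) -> Trajectory:
    """Homogeneous reference system: fresh uniform positions every frame.

    Molecules of one species are placed uniformly over the leaflet plane
    with no interactions or exclusion, around a static receptor.  This is
    the null model against which the surface RDF normalization is
    validated: the expected g(r) is exactly 1 at all distances.
    """
    rng = np.random.default_rng(seed)
    bx, by, bz = box_nm
    centre = np.array([bx / 2, by / 2, bz / 2])
    rec_coords, rec_bead_resids = receptor.all_beads()
    rec_coords = rec_coords + centre
    n_rec = len(rec_coords)
    sign = 1.0 if leaflet == "upper" else -1.0
    z_plane = centre[2] + sign * LEAFLET_Z_NM

    bead_names, offsets = _bead_template(lipid_class)
    offsets = offsets * np.array([1.0, 1.0, sign])
    nb = len(bead_names)
    coords = np.empty((n_frames, n_rec + nb * n_molecules, 3), dtype=np.float32)
    coords[:, :n_rec] = rec_coords
    for f in range(n_frames):
        xy = rng.uniform(0, [bx, by], size=(n_molecules, 2))
        com = np.column_stack([xy, np.full(n_molecules, z_plane)])
        coords[f, n_rec:] = np.repeat(com, nb, axis=0) + np.tile(offsets, (n_molecules, 1))
    np.mod(coords, np.array(box_nm, dtype=np.float32), out=coords)

    names = ["BB"] * n_rec + list(bead_names) * n_molecules
    base = int(receptor.residue_ids.max()) + 1
    resids = list(rec_bead_resids) + [base + m for m in range(n_molecules) for _ in range(nb)]
    resnames = [RECEPTOR_RESNAME] * n_rec + [species] * (nb * n_molecules)
    return Trajectory(
        frame_times_ns=np.arange(n_frames, dtype=float),
        coords_nm=coords,
        box_nm=np.tile(box_nm, (n_frames, 1)),
        names=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
    )


def build_seven_helix_receptor(**kwargs) -> ReceptorModel:
    """The GPCR-like seven-helix default of :func:`build_helix_bundle_receptor`."""
    return build_helix_bundle_receptor(**kwargs)
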