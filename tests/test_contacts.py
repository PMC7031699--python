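"""Dual-cutoff contact detection, COM machinery, occupancy, equilibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lipidkinetics as lk
from lipidkinetics.contacts import (
    NoPlateauError,
    OccupancySeries,
    detect_contact_events,
    estimate_equilibration,
    first_shell_series,
    lipid_com_series,
    residue_duration_profile,
)
from lipidkinetics.trajectory import Trajectory, minimum_image_distance


def brute_force_events(d, lower, upper):
    """Independent two-state automaton, one frame at a time."""
    events, state, start = [], "out", None
    for i, x in enumerate(d):
        if state == "out" and x < lower:
            state, start = "in", i
        elif state == "in" and x > upper:
            events.append((start, i, False))
            state = "out"
    if state == "in":
        events.append((start, len(d) - 1, True))
    return events


def single_bead_trajectory(positions, box=(10.0, 10.0, 10.0)):
    """Two single-bead residues (one lipid, one receptor) at given positions."""
    positions = np.asarray(positions, dtype=float)  # (frames, 2, 3)
    n = len(positions)
    return Trajectory(
        frame_times_ns=np.arange(n, dtype=float),
        coords_nm=positions,
        box_nm=np.tile(box, (n, 1)),
        names=np.array(["PO4", "BB"], dtype=object),
        resids=np.array([10, 1]),
        resnames=np.array(["POPC", "REC"], dtype=object),
    )


class TestComDistances:
    def test_plain_distance_without_wrap(self):
        traj = single_bead_trajectory([[[1.0, 1.0, 5.0], [1.3, 1.0, 5.0]]])
        d, lips, res = lk.com_distance_series(traj, [10], [1])
        assert d[0, 0, 0] == pytest.approx(0.3)

    def test_minimum_image_across_boundary(self):
        traj = single_bead_trajectory([[[0.1, 5.0, 5.0], [9.9, 5.0, 5.0]]])
        d, *_ = lk.com_distance_series(traj, [10], [1])
        assert d[0, 0, 0] == pytest.approx(0.2)

    def test_multibead_com_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        box = np.array([8.0, 9.0, 10.0])
        n_frames, n_beads = 5, 4
        lipid = rng.uniform(0, 1, size=(n_frames, n_beads, 3)) * 0.6
        origin = rng.uniform(0, box, size=(n_frames, 1, 3))
        lipid = np.mod(lipid + origin, box)  # compact molecule, may straddle faces
        residue = rng.uniform(0, box, size=(n_frames, 1, 3))
        coords = np.concatenate([lipid, residue], axis=1)
        traj = Trajectory(
            frame_times_ns=np.arange(n_frames, dtype=float),
            coords_nm=coords,
            box_nm=np.tile(box, (n_frames, 1)),
            names=np.array(["PO4", "GL1", "GL2", "C1", "BB"], dtype=object),
            resids=np.array([10, 10, 10, 10, 1]),
            resnames=np.array(["POPC"] * 4 + ["REC"], dtype=object),
        )
        d, *_ = lk.com_distance_series(traj, [10], [1])
        for f in range(n_frames):
            ref = lipid[f, 0]
            disp = lipid[f] - ref
            disp -= box * np.round(disp / box)
            com = np.mod(ref + disp.mean(axis=0), box)
            expected = minimum_image_distance(com, residue[f, 0], box)
            assert d[f, 0, 0] == pytest.approx(float(expected), abs=1e-9)

    def test_empty_selection_raises(self, kinetic_sim):
        traj, *_ = kinetic_sim
        with pytest.raises(ValueError, match="zero particles"):
            lipid_com_series(traj, species="NOPE")


class TestDualCutoffAutomaton:
    def test_spec_trace_opens_below_lower_closes_above_upper(self):
        d = [0.60, 0.50, 0.80, 1.00, 1.50]
        events = detect_contact_events(d, np.arange(5.0))
        assert len(events) == 1
        e = events[0]
        assert (e.t_start_ns, e.t_end_ns, e.duration_ns) == (1.0, 4.0, 3.0)
        assert not e.censored

    def test_never_below_lower_gives_no_events(self):
        d = np.full(50, 0.56)
        assert detect_contact_events(d, np.arange(50.0)) == []

    def test_intermediate_excursion_does_not_terminate(self):
        # 1.20 <= upper cutoff, so the contact survives the excursion
        d = [0.50, 1.20, 0.50, 1.50]
        events = detect_contact_events(d, np.arange(4.0))
        assert len(events) == 1
        assert events[0].duration_ns == pytest.approx(3.0)

    def test_open_event_at_end_is_censored(self):
        d = [0.50, 0.60, 0.70]
        events = detect_contact_events(d, np.arange(3.0))
        assert len(events) == 1
        assert events[0].censored
        assert events[0].t_end_ns == 2.0

    def test_requires_lower_below_upper(self):
        with pytest.raises(ValueError):
            detect_contact_events([0.5], [0.0], lower=1.4, upper=0.55)

    def test_non_uniform_stride_rejected(self):
        with pytest.raises(ValueError, match="stride"):
            detect_contact_events([0.5, 0.6, 0.7], [0.0, 1.0, 3.0])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.1, 2.0), min_size=1, max_size=80))
    def test_matches_brute_force_automaton(self, d):
        t = np.arange(len(d), dtype=float)
        got = [
            (int(e.t_start_ns), int(e.t_end_ns), e.censored)
            for e in detect_contact_events(d, t)
        ]
        assert got == brute_force_events(d, 0.55, 1.4)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0.1, 2.0), min_size=2, max_size=60),
        st.floats(0.6, 1.4),
    )
    def test_event_count_non_increasing_in_upper_cutoff(self, d, upper):
        """Tightening the upper cutoff toward the lower one never merges
        events: counts can only grow or stay as the cutoff loosens."""
        t = np.arange(len(d), dtype=float)
        tight = detect_contact_events(d, t, lower=0.55, upper=upper)
        loose = detect_contact_events(d, t, lower=0.55, upper=1.4)
        assert len(loose) <= len(tight)


class TestDurationProfile:
    def test_single_event_mean_and_count(self):
        e = lk.ContactEvent(1, 7, "PIP2", 0.0, 3.0)
        profile = residue_duration_profile([e])
        row = profile.table.iloc[0]
        assert row.mean_duration_ns == 3.0 and row.n_events == 1

    def test_mean_of_two_durations(self):
        events = [
            lk.ContactEvent(1, 7, "PIP2", 0.0, 2.0),
            lk.ContactEvent(2, 7, "PIP2", 5.0, 9.0),
        ]
        profile = residue_duration_profile(events)
        assert profile.table.iloc[0].mean_duration_ns == pytest.approx(3.0)

    def test_censored_events_counted_but_excluded_from_mean(self):
        events = [
            lk.ContactEvent(1, 7, "PIP2", 0.0, 2.0),
            lk.ContactEvent(2, 7, "PIP2", 5.0, 50.0, censored=True),
        ]
        profile = residue_duration_profile(events)
        row = profile.table.iloc[0]
        assert row.mean_duration_ns == 2.0
        assert row.n_events == 1 and row.n_censored == 1

    def test_per_repeat_means_emitted_when_pooling(self):
        rep0 = [lk.ContactEvent(1, 7, "PIP2", 0.0, 2.0)]
        rep1 = [lk.ContactEvent(1, 7, "PIP2", 0.0, 4.0)]
        profile = residue_duration_profile([rep0, rep1], repeats=True)
        assert profile.table.iloc[0].mean_duration_ns == pytest.approx(3.0)
        assert sorted(profile.per_repeat.mean_duration_ns) == [2.0, 4.0]

    def test_profile_maximum_on_anchor_residues(self, kinetic_sim, receptor):
        traj, _, site, _ = kinetic_sim
        events = lk.detect_species_contacts(traj, "PIP2")
        profile = residue_duration_profile(events)
        sub = profile.table[profile.table.species == "PIP2"]
        best = int(sub.loc[sub.mean_duration_ns.idxmax()].residue_id)
        member = lk.designed_member_residues(receptor, site)
        assert best in member


class TestFirstShellAndEquilibration:
    def test_constructed_frame_counts_molecules_in_shell(self, composition, receptor):
        cfg = lk.SystemConfig(
            box_nm=(12, 12, 10), frame_stride_ns=2.0, total_time_us=0.01, seed=0
        )
        traj, _ = lk.simulate_membrane_trajectory(
            composition, receptor, [], cfg, n_upper=60, n_lower=60
        )
        occ = first_shell_series(traj, "POPC")
        # recompute frame 0 by hand
        coms, _ = lipid_com_series(traj, species="POPC")
        rec = traj.coords_nm[0, traj.receptor_indices(), :].astype(float)
        dmin = np.array([
            minimum_image_distance(c, rec, traj.box_nm[0]).min() for c in coms[0]
        ])
        assert occ.counts[0] == (dmin <= 1.0).sum()

    def test_absent_species_rejected(self, quiet_membrane):
        with pytest.raises(ValueError, match="absent"):
            first_shell_series(quiet_membrane, "XXX")

    def test_stationary_series_equilibrates_immediately(self):
        rng = np.random.default_rng(4)
        occ = OccupancySeries(
            species="GM3",
            times_ns=np.arange(2000.0),
            counts=rng.poisson(10, size=2000),
            shell_radius_nm=1.0,
        )
        t_eq = estimate_equilibration(occ, tolerance=3.0)
        assert t_eq == 0.0
        assert occ.analysis_window_ns == (0.0, 1999.0)

    def test_step_series_located_at_step(self):
        """Occupancy jumping from 5 to 15 at 3 us on an 8 us span is detected
        near 3 us, and the analysis window becomes (t_eq, 8 us)."""
        rng = np.random.default_rng(5)
        times = np.arange(0, 8000.0, 10.0)  # ns
        counts = np.where(
            times < 3000.0, rng.poisson(5, len(times)), rng.poisson(15, len(times))
        )
        occ = OccupancySeries("PIP2", times, counts, 1.0)
        t_eq = estimate_equilibration(occ, tolerance=2.0, n_blocks=20)
        assert 2800.0 <= t_eq <= 3400.0
        assert occ.analysis_window_ns[1] == times[-1]

    def test_monotone_drift_has_no_plateau(self):
        times = np.arange(0, 2000.0, 10.0)
        occ = OccupancySeries("CHOL", times, np.linspace(0, 40, len(times)), 1.0)
        with pytest.raises(NoPlateauError):
            estimate_equilibration(occ, tolerance=1.0, n_blocks=20)

    def test_series_too_short_rejected(self):
        occ = OccupancySeries("GM3", np.arange(5.0), np.ones(5), 1.0)
        with pytest.raises(ValueError, match="too short"):
            estimate_equilibration(occ, n_blocks=20)
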