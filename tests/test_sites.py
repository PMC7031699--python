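"""Binding-site identification, pose scoring and interplay correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

import lipidkinetics as lk
from lipidkinetics.contacts import residue_duration_profile
from lipidkinetics.sites import (
    UndefinedCorrelationError,
    classify_interplay,
    duration_pcc,
    interplay_matrix,
)


def profile_from_means(mean_by_residue, species="PIP2", n_events=50):
    """Synthesize a duration profile with prescribed per-residue means."""
    events = []
    for rid, mean in mean_by_residue.items():
        t = 0.0
        for _ in range(n_events):
            events.append(lk.ContactEvent(1, rid, species, t, t + mean))
            t += mean + 5.0
    return residue_duration_profile(events)


class TestIdentifySites:
    def test_flat_zero_profile_gives_no_sites(self, receptor):
        profile = residue_duration_profile([])
        assert lk.identify_sites(profile, receptor) == []

    def test_two_separated_hot_clusters_give_two_sites(self, receptor):
        # TM1 spans residues 1-13 (bottom to top), TM4 spans 40-52
        hot = {1: 300.0, 2: 310.0, 40: 280.0, 41: 290.0}
        cold = {r: 5.0 for r in (20, 25, 30, 60, 70, 80)}
        profile = profile_from_means({**hot, **cold})
        sites = lk.identify_sites(profile, receptor)
        assert len(sites) == 2
        members = sorted(tuple(s.residues) for s in sites)
        assert members == [(1, 2), (40, 41)]

    def test_sites_ranked_by_hottest_member(self, receptor):
        profile = profile_from_means(
            {1: 100.0, 2: 110.0, 40: 280.0, 41: 290.0, 20: 1.0, 25: 1.0, 30: 1.0}
        )
        sites = lk.identify_sites(profile, receptor, duration_threshold_ns=50.0)
        assert sites[0].residues == (40, 41)
        assert sites[0].max_duration_ns >= sites[1].max_duration_ns

    def test_isolated_hot_residue_dropped_by_min_size(self, receptor):
        profile = profile_from_means({1: 300.0, 20: 1.0, 25: 1.0, 30: 1.0})
        assert lk.identify_sites(profile, receptor) == []

    def test_explicit_threshold_excluding_everything_returns_empty(self, receptor):
        profile = profile_from_means({1: 10.0, 2: 12.0})
        assert lk.identify_sites(profile, receptor, duration_threshold_ns=1e6) == []

    def test_dominant_species_reported(self, receptor):
        strong = profile_from_means({1: 300.0, 2: 310.0}, species="GM3")
        weak = profile_from_means({1: 30.0, 2: 20.0}, species="CHOL")
        merged = residue_duration_profile([])
        merged.table = pd.concat([strong.table, weak.table], ignore_index=True)
        merged.durations = {**strong.durations, **weak.durations}
        sites = lk.identify_sites(merged, receptor, duration_threshold_ns=100.0)
        assert sites[0].species == "GM3"


@pytest.fixture(scope="module")
def scored_system(composition, receptor):
    site = lk.design_site(
        receptor, "TM3", "lower", "PIP2", "S1",
        k_on_per_us=1000.0, k_off_true_per_us=8.0, capture_radius_nm=1.5,
    )
    cfg = lk.SystemConfig(
        box_nm=(12, 12, 10), frame_stride_ns=2.0, total_time_us=4.0, seed=21
    )
    traj, _ = lk.simulate_membrane_trajectory(
        composition, receptor, [site], cfg, n_upper=20, n_lower=120
    )
    lsite = lk.LipidBindingSite(
        site_id="S1", residues=site.anchor_residues, species="PIP2",
        max_duration_ns=0, mean_duration_ns=0, n_events=0,
    )
    scores = lk.score_poses(
        traj, lsite, "PIP2", basic_residues=list(site.anchor_residues)
    )
    return traj, lsite, site, scores


class TestPoseScoring:
    def test_scores_finite_and_ranked(self, scored_system):
        *_, scores = scored_system
        assert all(np.isfinite(s.score) for s in scores)
        ranked = [s.score for s in scores]
        assert ranked == sorted(ranked, reverse=True)
        assert [s.rank for s in scores] == list(range(1, len(scores) + 1))

    def test_representative_pose_is_brute_force_argmax(self, scored_system):
        *_, scores = scored_system
        best = lk.representative_pose(scores)
        top = max(scores, key=lambda s: (s.score, -s.frame))
        assert best == top.frame

    def test_mode_pose_outscores_tail_pose(self, composition, receptor):
        """A pose at the bead-density mode scores higher than an outlier."""
        site = lk.design_site(
            receptor, "TM3", "lower", "PIP2", "S1",
            k_on_per_us=1000.0, k_off_true_per_us=8.0, capture_radius_nm=1.5,
        )
        cfg = lk.SystemConfig(
            box_nm=(12, 12, 10), frame_stride_ns=2.0, total_time_us=4.0, seed=22
        )
        traj, _ = lk.simulate_membrane_trajectory(
            composition, receptor, [site], cfg, n_upper=20, n_lower=120
        )
        lsite = lk.LipidBindingSite(
            site_id="S1", residues=site.anchor_residues, species="PIP2",
            max_duration_ns=0, mean_duration_ns=0, n_events=0,
        )
        scores = lk.score_poses(
            traj, lsite, "PIP2", basic_residues=list(site.anchor_residues)
        )
        # bottom-ranked pose is geometrically farther from the dense tether
        # cloud than the top pose
        anchor = np.mean([receptor.residue_com(r) for r in site.anchor_residues], axis=0)
        anchor = anchor + np.array([6.0, 6.0, 5.0])
        from lipidkinetics.contacts import lipid_com_series

        coms, ids = lipid_com_series(traj, species="PIP2")
        col = {rid: i for i, rid in enumerate(ids)}
        def dist(s):
            return np.linalg.norm(coms[s.frame, col[s.lipid_id]] - anchor)
        assert dist(scores[0]) < dist(scores[-1])

    def test_scores_invariant_under_frame_permutation(self, scored_system):
        """Reversing the frame order permutes pose labels but leaves the
        score multiset unchanged (the density sees the same poses)."""
        traj, lsite, site, scores = scored_system
        from lipidkinetics.trajectory import Trajectory

        reversed_traj = Trajectory(
            frame_times_ns=traj.frame_times_ns,
            coords_nm=traj.coords_nm[::-1],
            box_nm=traj.box_nm,
            names=traj.names,
            resids=traj.resids,
            resnames=traj.resnames,
        )
        rev = lk.score_poses(
            reversed_traj, lsite, "PIP2", basic_residues=list(site.anchor_residues)
        )
        assert np.allclose(
            sorted(s.score for s in scores), sorted(s.score for s in rev)
        )

    def test_no_bound_frames_rejected(self, scored_system):
        traj, lsite, site, _ = scored_system
        with pytest.raises(ValueError, match="no bound frames"):
            lk.score_poses(traj, lsite, "PIP2",
                           basic_residues=list(site.anchor_residues),
                           inclusion_radius_nm=1e-6)

    def test_empty_score_list_rejected(self):
        with pytest.raises(ValueError):
            lk.representative_pose([])

    def test_tie_broken_by_lower_frame(self):
        scores = [
            lk.PoseScore(frame=9, lipid_id=1, score=1.0, rank=1),
            lk.PoseScore(frame=3, lipid_id=1, score=1.0, rank=1),
        ]
        assert lk.representative_pose(scores) == 3


class TestDurationPcc:
    def test_identical_vectors_give_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert duration_pcc(x, x) == pytest.approx(1.0)

    def test_negated_vector_gives_minus_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert duration_pcc(x, -x) == pytest.approx(-1.0)

    def test_matches_printed_formula_brute_force(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=10), rng.normal(size=10)
        num = sum((a - x.mean()) * (b - y.mean()) for a, b in zip(x, y))
        den = np.sqrt(
            sum((a - x.mean()) ** 2 for a in x) * sum((b - y.mean()) ** 2 for b in y)
        )
        assert duration_pcc(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            duration_pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            duration_pcc([1.0, 2.0], [1.0, 2.0])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=10, unique=True),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    def test_affine_invariance(self, x, scale, shift):
        assume(np.ptp(x) > 1e-3)  # avoid underflow-degenerate inputs
        y = np.linspace(0.0, 1.0, len(x))
        base = duration_pcc(x, y)
        rescaled = duration_pcc(np.asarray(x) * scale + shift, y)
        assert rescaled == pytest.approx(base, abs=1e-9)
        assert -1.0 - 1e-12 <= base <= 1.0 + 1e-12

    def test_interplay_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(3, 10)), index=["GM3", "CHOL", "PIP2"])
        mat = interplay_matrix(df)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)
        assert (mat.values >= -1 - 1e-12).all() and (mat.values <= 1 + 1e-12).all()

    def test_interplay_classification(self):
        assert classify_interplay(0.8) == "synergistic"
        assert classify_interplay(-0.6) == "competing"
        assert classify_interplay(0.2) == "neutral"
        assert classify_interplay(float("nan")) == "undefined"
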