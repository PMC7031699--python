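"""Generate a synthetic trajectory and detect lipid-residue contacts.

A PIP2 binding site with a known dissociation rate (8 events per us) is
placed on the cytoplasmic end of one helix; the dual-cutoff detector (open
below 0.55 nm, close above 1.4 nm) then recovers the binding events from
the rendered coordinates alone, and the per-residue duration profile shows
the site's anchor residues as the hotspot.
"""

import lipidkinetics as lk

comp = lk.build_default_composition()
receptor = lk.build_seven_helix_receptor()
site = lk.design_site(
    receptor, "TM1", "lower", "PIP2", "demo-site",
    k_on_per_us=1000.0, k_off_true_per_us=8.0, capture_radius_nm=1.5,
)
cfg = lk.SystemConfig(
    box_nm=(12.0, 12.0, 10.0), frame_stride_ns=2.0, total_time_us=10.0, seed=3
)
traj, ledger = lk.simulate_membrane_trajectory(
    comp, receptor, [site], cfg, n_upper=20, n_lower=120
)
print(f"trajectory: {traj.n_frames} frames, {traj.n_particles} beads")
print(f"ground truth: {len(ledger.events)} binding events at the site")

events = lk.detect_species_contacts(traj, "PIP2")
profile = lk.residue_duration_profile(events)
top = profile.table.sort_values("mean_duration_ns", ascending=False).head(4)
print("\nhottest residues by mean contact duration (ns):")
print(top.to_string(index=False))
print("\nsite anchors:", site.anchor_residues,
      "(the hotspot maxima should sit on or next to these)")
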