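"""Topological features of one epoch's embedded point cloud.

The 500 samples of a 2-s, 8-channel epoch are points in R^8; the
Vietoris-Rips persistence diagram of that cloud summarises how the
brain's trajectory loops through channel space. A coherent
post-stimulus oscillation traces a large clean loop (long-lived
1-cycle); degraded coherence collapses it toward a noise cloud.
"""

from eegtda import (StudyConfig, SubjectProfile, build_point_cloud,
                    compute_features, generate_recording,
                    preprocess_recording, rips_diagram)

config = StudyConfig(n_sessions=1, master_seed=3)
for group, severity in [("healthy", 0.0), ("mci", 1.0)]:
    profile = SubjectProfile(subject_id=f"sub-{group}", group=group,
                             severity=severity, moca=28 if group == "healthy"
                             else 15, age_years=70.0)
    epochs = preprocess_recording(generate_recording(profile, config))
    epoch = epochs.epochs[0].data
    diagram = rips_diagram(build_point_cloud(epoch))
    feats = compute_features(diagram)
    print(f"{group:8s} total_cycles={feats.total_cycles:3d} "
          f"max_cycles={feats.max_cycles:3d} "
          f"max_persistence={feats.max_persistence:6.2f} "
          f"npe={feats.npe:.3f} max_ratio={feats.max_persistence_ratio:.2f}")
print("The healthy epoch's dominant cycle persists far longer: its "
      "coherent burst traces a larger loop in channel space.")
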