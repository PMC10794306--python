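"""Generate a small synthetic oddball-EEG study and inspect its design.

Each participant completes 8 oddball sessions of 9 stimulus displays
(1 cue + 8 stream images, half reminiscent / half contemporary), giving
72 stimulus-locked responses; MoCA scores follow the cohort label
(healthy >= 26, impaired < 26).
"""

from eegtda import StudyConfig, generate_study

config = StudyConfig(n_subjects=4, n_mci=2, master_seed=1)
study = generate_study(config)

print(f"subjects: {len(study)}, events/subject: {config.events_per_subject}")
for profile, rec in study:
    roles = rec.events["role"].value_counts().to_dict()
    print(f"  {profile.subject_id}: group={profile.group:8s} "
          f"moca={profile.moca:2d} severity={profile.severity:.2f} "
          f"events={roles}")
print("Each row is one participant; severity drives both the MoCA score "
      "and how degraded the post-stimulus oscillatory bursts are.")
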