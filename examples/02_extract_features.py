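"""Preprocess a recording and extract the full-body kinematic features.

Synthesizes one TUG session, runs the preprocessing chain (gap filling,
hip-centering, Z-normalization, 4-s windows with 1-s overlap) and prints
the spectral features that separate the motor subtypes: the freezing
index and dominant frequency of wrist and shank channels.
"""

from pdkin import extract_window_features, generate_cohort, synthesize_session
from pdkin.mocap import preprocess

cohort = generate_cohort(n_participants=4, td_fraction=0.5,
                         fog_fraction_within_pigd=1.0, seed=3)

for participant in cohort:
    rec, truth = synthesize_session(participant, "tug", duration=40.0, seed=3)
    windows = preprocess(rec, window_s=4.0, overlap_s=1.0)
    fv = extract_window_features(windows[4]).to_series()
    label = participant.phenotype.subtype_label
    print(f"{participant.participant_id} ({label}, FOG {participant.fog_score}) "
          f"- {len(windows)} windows of {windows[0].n_frames} frames")
    for name in ("fi-L.Shank_Z", "domfreq-L.Wrist_X", "variance-R.Wrist_Y",
                 "wav-L.Thigh_Z"):
        print(f"    {name:22s} = {fv[name]:8.3f}")

# Feature names follow "<feature>-<Marker>_<axis>". TD participants show a
# 4-6 Hz dominant frequency on the wrist channels (resting tremor); PIGD
# freezers accumulate 3-8 Hz freeze-band power, raising the freezing index
# (fi) on shank/heel channels during trembling episodes.
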