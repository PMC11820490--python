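"""Generate one synthetic V-cut trial and detect its four CODs.

The generator places a heel strike of the non-cutting foot 18 frames before
each braking trough and a toe off of the cutting foot 10 frames after; the
detector should recover exactly those frames.
"""

from codseg import DetectionParams, SyntheticSpec, detect_cods, generate_trial

syn = generate_trial(SyntheticSpec(seed=42))
result = detect_cods(syn.trial, DetectionParams())

print(f"trial {syn.trial.trial_id}: {syn.trial.n_frames} frames "
      f"at {syn.trial.frame_rate:g} Hz")
print("cod  minimum    IF    FF  cutting-foot  status      truth(IF,FF)")
for ev, truth in zip(result.events, syn.truth.events):
    print(f"{ev.cod_index:>3}  {ev.minimum_frame:>7}  {ev.if_frame:>4}  "
          f"{ev.ff_frame:>4}  {ev.ffc_side.value:>12}  {ev.status.value:<10}  "
          f"({truth.if_frame}, {truth.ff_frame})")

# Each row is one change of direction: the velocity minimum anchoring it,
# the detected initial frame (penultimate-contact heel strike) and final
# frame (final-contact toe off), which should equal the ground truth.
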