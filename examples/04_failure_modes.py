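"""Reproduce the two documented misdetection scenarios.

Both stem from the velocity minimum drifting away from the foot-contact
events it anchors: (a) the true heel strike falls outside the search
region, so IF is wrong or missing; (b) the minimum occurs after the true
toe off, so the detector latches the *next* toe off and FF is late.
"""

from codseg import detect_cods, match_events
from codseg.synthetic import FailureMode, make_failure_fixture

for mode in FailureMode:
    syn = make_failure_fixture(mode)
    pairs = match_events(detect_cods(syn.trial), syn.truth)
    print(f"\n{mode.value}:")
    for p in pairs:
        wrong = [k for k in ("IF", "FF") if p.diff(k) != 0]
        note = f"  <- {'/'.join(wrong)} deviate(s) from truth" if wrong else ""
        print(f"  COD {p.cod_index}: auto IF/FF = {p.auto_if}/{p.auto_ff}, "
              f"truth = {p.manual_if}/{p.manual_ff}{note}")

# Only the engineered COD deviates from truth; the other three stay exact.
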