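"""Parse a keystroke log into linguistically labeled pause events.

A small typing script (two sentences, a deletion, an edit operation) is
rendered as a time-stamped keystroke stream, then parsed back: every
positive inter-event latency becomes one pause event labeled with the
boundary class at which it occurred.
"""

from collections import Counter

import pausemix as pm
from pausemix.synthetic import generate_keystroke_log, lognormal_sampler

plan = [
    ("word", "pauses"), ("space",), ("word", "tell"), ("space",), ("word", "stories"),
    ("punct", "."), ("space",),
    ("word", "realy"), ("backspace", 2), ("word", "lly"), ("space",), ("word", "true"),
    ("edit", "cursor_move"), ("word", "ones"), ("punct", "."),
]
stream, planted = generate_keystroke_log(plan, lognormal_sampler(mu=5.3, sigma=0.6), seed=3)
pauses = pm.extract_pauses(stream)

print(f"keystroke events: {len(stream)}, pause events: {len(pauses)}")
print("pauses per context:", dict(Counter(p.context for p in pauses)))
print("round trip exact:", sorted(pauses) == sorted(planted))
# WithinWord dominates (one pause per letter); the deletion produced
# Single/MultipleBackspace plus a resume-after-deletion (BackSpace) pause,
# and the cursor move produced an Edit pause.
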