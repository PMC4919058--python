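"""Classify single stem pair changes into the compensatory taxonomy.

Builds a handful of pair-state transitions and prints the verdict for each:
HCBC (one base changed, pairing kept), FCBC type I/II (both bases changed,
pairing kept, orientation preserved/flipped), or mismatch gain/resolution.
"""

from cloverleaf import classify_transition, make_pair_state

TRANSITIONS = [
    ("A", "T", "G", "T"),  # wobble-mediated hemi-compensatory change
    ("A", "T", "G", "C"),  # full compensation, orientation preserved
    ("T", "A", "A", "T"),  # full compensation, orientation flipped
    ("G", "T", "T", "A"),  # flip with a wobble endpoint
    ("A", "T", "A", "A"),  # pairing lost
    ("A", "A", "A", "T"),  # pairing restored
]

for f5, f3, t5, t3 in TRANSITIONS:
    a, b = make_pair_state(f5, f3), make_pair_state(t5, t3)
    v = classify_transition(a, b)
    extra = f" type {v.fcbc_type.value}" if v.fcbc_type.value != "absent" else ""
    print(f"{a} -> {b}: {v.kind.value}{extra} (changed side: {v.changed_side.value})")

print()
print("Each line reads ancestral state -> derived state; '-' is Watson-Crick,")
print("'.' the G/T wobble, '|' a mismatch. Only FCBCs carry a type.")
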