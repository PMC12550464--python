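"""Classify substitution pairs into the convergence taxonomy.

Each event is a pair of substitutions, one per focal branch. Depending on
the grouping scheme, a pair is exclusive state convergence (same derived
residue, no class change), property-and-state convergence (same derived
residue with a class change on both branches), exclusive property
convergence (different derived residues in one shared class), or none.
"""

import caap

events = [
    ("R", "H", "R", "H"),   # both become H: basic residue, no class change
    ("R", "D", "R", "D"),   # both become acidic D: class change on both
    ("R", "D", "R", "E"),   # D and E differ but share the acidic class
    ("P", "R", "P", "H"),   # R/H share the basic class; P is elsewhere
    ("A", "A", "A", "A"),   # no substitution at all
]

for name in ("US", "GS1", "GS4"):
    scheme = caap.load_scheme(name)
    print(f"\n{name} ({scheme.n_classes} classes)")
    for anc_a, der_a, anc_b, der_b in events:
        kind = caap.classify_event(
            caap.PairEvent(anc_a, der_a, anc_b, der_b), scheme
        )
        print(f"  {anc_a}->{der_a} | {anc_b}->{der_b}: {kind.value}")

# Under US (20 singleton classes) property convergence collapses onto state
# convergence, so R->D | R->E is only convergent once residues are grouped.
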