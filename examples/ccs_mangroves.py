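"""Conserved-site convergence (CCS) with a role-swapped negative control.

The CCS rule keeps only sites where the outgroup and every background taxon
carry the identical residue, then asks whether at least two focal taxa share
a physicochemical class different from that background residue's class. No
tree or ancestral reconstruction is involved. The negative control swaps the
focal and background sets.
"""

import numpy as np

import caap
from caap.lineage import Lineage, LineageRoleConfig

roles = LineageRoleConfig(
    lineages=[Lineage("mangrove", frozenset(["Avi", "Rhi", "Son"]), frozenset())],
    background=frozenset(["Ses", "Pop", "Euc"]),
    outgroup="Ory",
)

taxa = ["Avi", "Rhi", "Son", "Ses", "Pop", "Euc", "Ory"]
# site 1: conserved K background, two mangroves acidic (D, E) -> convergent
# site 2: conserved K background, mangrove K/K/R -> within-class, not counted
# site 3: background not unanimous -> not conserved, excluded
cols = {
    "Avi": "DKD", "Rhi": "EKK", "Son": "KRK",
    "Ses": "KKK", "Pop": "KKR", "Euc": "KKK", "Ory": "KKK",
}
aln = caap.ProteinAlignment("demo", taxa, np.array([list(cols[t]) for t in taxa]))

scheme = caap.load_scheme("GS4")   # fine-grained: acidic {D,E}, basic {K,R,H}
calls, count = caap.ccs_detect(aln, roles, scheme)
print(f"focal direction: {count} convergent site(s)")
for call in calls:
    print(f"  site {call.site}: background {call.background_state}, "
          f"focal taxa {sorted(call.convergent_taxa)} share class "
          f"{call.derived_class}")

control_calls, control_count = caap.ccs_detect(aln, roles, scheme, control=True)
print(f"control direction (roles swapped): {control_count} site(s)")

# Only site 1 counts: a conserved basic background with two focal taxa
# arriving in the acidic class. The within-class K->R change and the
# non-conserved column are rejected by the rule itself.
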