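"""Independent reference implementations used as oracles in the tests.

These deliberately avoid the package's class-aggregated fast paths: the
expectation oracle enumerates all 400 ordered derived-state pairs through
the public event classifier, and the state-convergence reference works
directly on residues with no recoding machinery.
"""

import numpy as np

from caap.grouping import GroupingScheme
from caap.io import AMINO_ACIDS


def convergence_indicator(scheme: GroupingScheme) -> np.ndarray:
    """conv[x1, x2, y1, y2] = 1 iff (x1->y1, x2->y2) is property convergence."""
    cls = scheme.class_index
    x1 = np.arange(20)[:, None, None, None]
    x2 = np.arange(20)[None, :, None, None]
    y1 = np.arange(20)[None, None, :, None]
    y2 = np.arange(20)[None, None, None, :]
    return (
        (cls[y1] == cls[y2]) & (cls[y1] != cls[x1]) & (cls[y2] != cls[x2])
    ).astype(float)


def enumerate_E_site(qa, qb, Pa, Pb, scheme) -> float:
    """Exhaustive expectation: sum over all parent and derived pairs."""
    conv = convergence_indicator(scheme)
    joint = (
        qa[:, None, None, None]
        * qb[None, :, None, None]
        * Pa[:, None, :, None]
        * Pb[None, :, None, :]
    )
    return float((joint * conv).sum())


def direct_state_convergence_O(anc_a, der_a, anc_b, der_b) -> int:
    """Residue-level state convergence count, no recoding."""
    hits = (der_a == der_b) & (der_a != anc_a) & (der_b != anc_b)
    return int(hits.sum())


def direct_state_convergence_E(qa_sites, qb_sites, Ps_a, Ps_b, w) -> float:
    """Residue-level expectation: both branches substitute to one shared
    residue different from both ancestors, summed per site over rate
    categories. Mirrors the class machinery's contraction order so the US
    comparison is exact at the bit level.
    """
    k = len(Ps_a)
    e_sites = 0.0
    for m in range(k):
        Pa, Pb = Ps_a[m], Ps_b[m]
        M = np.zeros((20, 20))
        for y in range(20):
            u = Pa[:, y].copy()
            u[y] = 0.0
            v = Pb[:, y].copy()
            v[y] = 0.0
            M += np.outer(u, v)
        e_sites = e_sites + w[:, m] * ((qa_sites @ M) * qb_sites).sum(axis=1)
    return e_sites


def ccs_state_reference(aln, roles):
    """Residue-identity implementation of conserved-site convergence."""
    enc = aln.encoded()
    idx = {t: i for i, t in enumerate(aln.taxa)}
    bg_rows = [idx[t] for t in sorted(roles.background)] + [idx[roles.outgroup]]
    focal = sorted(roles.focal_taxa)
    sites = []
    for s in range(aln.n_sites):
        bg_states = {int(enc[r, s]) for r in bg_rows}
        if len(bg_states) != 1:
            continue
        bg = bg_states.pop()
        from collections import Counter

        counts = Counter(
            int(enc[idx[t], s]) for t in focal if int(enc[idx[t], s]) != bg
        )
        if any(n >= 2 for n in counts.values()):
            sites.append(s + 1)
    return sites
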