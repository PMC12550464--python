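"""The R-statistic engine: observed vs expected convergent sites per gene.

For a pair of phylogenetically independent branches, O counts the alignment
sites whose per-branch substitutions (ancestral states from marginal ASR,
derived states from ASR or the observed leaf) form a property-convergence
event under the chosen grouping scheme. E sums, over sites and rate
categories, the model probability that both branches independently change
class and land in the same class, conditioned on the ancestral states (point
reconstructions or full posteriors). R = O/E, with a one-sided Poisson tail
test of O > E.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import poisson

from caap.grouping import EventClass, GroupingScheme, PairEvent, classify_event
from caap.io import AMINO_ACIDS, DiscardAlignment, ProteinAlignment, filter_sites
from caap.model import (
    AncestralReconstruction,
    RateModel,
    SubstitutionModel,
    build_model,
    discrete_gamma,
    estimate_alpha,
    marginal_asr,
)
from caap.tree import Node, PhyloTree, TreeError


#: Default convention for the neutral expectation E. "posterior" and
#: "conditional" apply forward transition probabilities from
#: posterior-weighted or ML point ancestors: a genuine a-priori expectation,
#: the convention a test of excess convergence requires. "joint" multiplies
#: the two branches' empirical-Bayes substitution-type probabilities (joint
#: parent/child endpoint posteriors); it tracks the shrinkage of
#: reconstruction-based counting and is useful as a calibration diagnostic,
#: but it conditions on the observed derived states — real convergent
#: signal inflates it alongside O — so it must not be used to test O > E.
DEFAULT_E_MODE = "posterior"


class BranchResolutionError(ValueError):
    pass


class SkipGene(Exception):
    """A gene cannot support the requested branch pair; carry the reason."""


@dataclass(frozen=True)
class BranchPair:
    """Two independent branches hypothesised to carry convergent change.

    Branches are addressed by their child node (name, id or ``mrca:`` spec)
    on the species tree; neither may be ancestral to the other.
    """

    branch_a: Union[str, int]
    branch_b: Union[str, int]
    label: str = "BP"

    def resolve(self, tree: PhyloTree) -> tuple[Node, Node]:
        a = tree.resolve_branch(self.branch_a)
        b = tree.resolve_branch(self.branch_b)
        if a is b:
            raise BranchResolutionError(f"{self.label}: branches are identical")
        if tree.is_ancestor(a, b) or tree.is_ancestor(b, a):
            raise BranchResolutionError(
                f"{self.label}: branches are nested, convergence is ill-defined"
            )
        if a.parent is None or b.parent is None:
            raise BranchResolutionError(f"{self.label}: the root is not a branch")
        return a, b


def transfer_branch(
    species_tree: PhyloTree, species_node: Node, gene_tree: PhyloTree
) -> Node:
    """Find the gene-tree branch corresponding to a species-tree branch.

    The species branch is identified by its subtended clade; the matching
    gene branch subtends exactly that clade intersected with the gene's
    taxa. Raises :class:`SkipGene` when the clade is absent.
    """
    clade = species_tree.clade_taxa(species_node)
    gene_taxa = set(gene_tree.taxa)
    target = frozenset(clade & gene_taxa)
    if not target:
        raise SkipGene(f"clade {sorted(clade)[:3]}... absent from gene")
    for node in gene_tree.postorder():
        if gene_tree.clade_taxa(node) == target:
            if node.parent is None:
                raise SkipGene("branch collapsed into the gene-tree root")
            return node
    raise SkipGene("clade is not monophyletic in the pruned gene tree")


def resolve_pair_on_gene_tree(
    pair: BranchPair, species_tree: PhyloTree, gene_tree: PhyloTree
) -> tuple[Node, Node]:
    sa, sb = pair.resolve(species_tree)
    a = transfer_branch(species_tree, sa, gene_tree)
    b = transfer_branch(species_tree, sb, gene_tree)
    if a is b:
        raise SkipGene(f"{pair.label}: branches coincide after pruning")
    if gene_tree.is_ancestor(a, b) or gene_tree.is_ancestor(b, a):
        raise SkipGene(f"{pair.label}: branches nested after pruning")
    return a, b


# ---------------------------------------------------------------------------
# Branch states


def branch_states(
    asr: AncestralReconstruction,
    tree: PhyloTree,
    branch: Node,
    aln: ProteinAlignment,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (ancestral state, derived state, ancestral posterior).

    The derived state is the observed leaf residue on a terminal branch and
    the reconstructed ML state otherwise; the ancestral state is always the
    parent's ML reconstruction, returned with its full posterior.
    """
    parent = branch.parent
    if parent is None:
        raise BranchResolutionError("the root subtends no branch")
    anc = asr.ml_states[parent.id]
    anc_post = asr.posteriors[parent.id]
    if branch.is_leaf:
        der = aln.encoded()[aln.taxa.index(branch.name)]
    else:
        der = asr.ml_states[branch.id]
    return anc, der, anc_post


# ---------------------------------------------------------------------------
# Observed convergence


@dataclass(frozen=True)
class SiteConvergenceEvent:
    gene_id: str
    site: int            # 1-based, filtered coordinates
    site_orig: int       # 1-based, unfiltered coordinates
    pair_label: str
    anc_a: str
    der_a: str
    anc_b: str
    der_b: str
    anc_class_a: int
    der_class_a: int
    anc_class_b: int
    der_class_b: int
    event_class: EventClass


def observed_O(
    asr: AncestralReconstruction,
    tree: PhyloTree,
    pair_nodes: tuple[Node, Node],
    scheme: GroupingScheme,
    aln: ProteinAlignment,
    pair_label: str = "BP",
) -> tuple[int, list[SiteConvergenceEvent]]:
    """Count property-convergent sites between the two branches.

    Under the ungrouped scheme this reduces exactly to state convergence.
    """
    a, b = pair_nodes
    anc_a, der_a, _ = branch_states(asr, tree, a, aln)
    anc_b, der_b, _ = branch_states(asr, tree, b, aln)
    cls = scheme.class_index
    ca_anc, ca_der = cls[anc_a], cls[der_a]
    cb_anc, cb_der = cls[anc_b], cls[der_b]
    prop = (ca_der == cb_der) & (ca_der != ca_anc) & (cb_der != cb_anc)
    state = (der_a == der_b) & (der_a != anc_a) & (der_b != anc_b)
    events = []
    aas = AMINO_ACIDS
    for s in np.nonzero(prop)[0]:
        events.append(
            SiteConvergenceEvent(
                gene_id=aln.gene_id,
                site=int(s) + 1,
                site_orig=aln.site_map[int(s)],
                pair_label=pair_label,
                anc_a=aas[anc_a[s]],
                der_a=aas[der_a[s]],
                anc_b=aas[anc_b[s]],
                der_b=aas[der_b[s]],
                anc_class_a=int(ca_anc[s]),
                der_class_a=int(ca_der[s]),
                anc_class_b=int(cb_anc[s]),
                der_class_b=int(cb_der[s]),
                event_class=(
                    EventClass.STATE_AND_PROPERTY if state[s] else EventClass.EXCLUSIVE_PROPERTY
                ),
            )
        )
    return int(prop.sum()), events


# ---------------------------------------------------------------------------
# Expected convergence


def pair_convergence_matrix(
    Pa: np.ndarray, Pb: np.ndarray, scheme: GroupingScheme
) -> np.ndarray:
    """M[x1, x2] = P(both branches change class and land in one shared class).

    Entry (x1, x2) sums, over every class c different from the classes of
    both ancestral states, the product of the two branches' aggregate
    probabilities of arriving anywhere inside c.
    """
    C = scheme.membership_matrix
    A = Pa @ C
    B = Pb @ C
    cls = scheme.class_index
    M = np.zeros((20, 20))
    for c in range(scheme.n_classes):
        u = A[:, c].copy()
        u[cls == c] = 0.0
        v = B[:, c].copy()
        v[cls == c] = 0.0
        M += np.outer(u, v)
    return M


def expected_E_site(
    parent_a,
    parent_b,
    t_a: float,
    t_b: float,
    rates: RateModel,
    site_weights,
    model: SubstitutionModel,
    scheme: GroupingScheme,
) -> float:
    """Expected number of property-convergence events at one site.

    ``parent_a``/``parent_b`` are ancestral-state distributions: a residue
    letter, a state index (point mass), or a length-20 posterior vector.
    ``site_weights`` are the posterior weights of the rate categories at
    this site and must sum to 1.
    """
    if t_a < 0 or t_b < 0:
        raise ValueError("branch lengths must be non-negative")
    qa = _as_distribution(parent_a)
    qb = _as_distribution(parent_b)
    w = np.asarray(site_weights, float)
    if w.shape != (rates.k,):
        raise ValueError("site_weights length must match rate categories")
    e = 0.0
    for m, r in enumerate(rates.rates):
        M = pair_convergence_matrix(
            model.transition_matrix(t_a * r), model.transition_matrix(t_b * r), scheme
        )
        e += w[m] * float(qa @ M @ qb)
    return e


def _as_distribution(parent) -> np.ndarray:
    if isinstance(parent, str):
        q = np.zeros(20)
        q[AMINO_ACIDS.index(parent)] = 1.0
        return q
    if np.isscalar(parent):
        q = np.zeros(20)
        q[int(parent)] = 1.0
        return q
    q = np.asarray(parent, float)
    if q.shape != (20,):
        raise ValueError("parent distribution must have length 20")
    return q


def expected_E_gene(
    asr: AncestralReconstruction,
    tree: PhyloTree,
    pair_nodes: tuple[Node, Node],
    model: SubstitutionModel,
    rates: RateModel,
    scheme: GroupingScheme,
    mode: str = DEFAULT_E_MODE,
    aln: Optional[ProteinAlignment] = None,
) -> tuple[float, np.ndarray]:
    """Gene-level E: the sum of site-wise convergence expectations.

    ``mode='posterior'`` weights ancestral states by their full marginal
    posteriors and ``'conditional'`` conditions on the ML point
    reconstructions; both then apply the model's forward transition
    probabilities over the branch. ``'joint'`` instead multiplies the two
    branches' empirical-Bayes substitution-type probabilities (joint
    parent/child endpoint posteriors, which requires ``aln``): the expected
    number of convergence events among the reconstructed substitutions
    themselves, the convention of the original state-convergence studies.
    """
    a, b = pair_nodes
    if mode == "joint":
        if aln is None:
            raise ValueError("joint mode needs the alignment")
        from caap.model import edge_joint_posteriors

        joints = edge_joint_posteriors(aln, asr.tree, model, rates, [a, b])
        return expected_E_from_joints(joints[a.id], joints[b.id], scheme)
    w = asr.rate_weights
    if w.shape[1] != rates.k:
        raise ValueError("rate model does not match the reconstruction's categories")
    Ms = [
        pair_convergence_matrix(
            model.transition_matrix(a.length * r),
            model.transition_matrix(b.length * r),
            scheme,
        )
        for r in rates.rates
    ]
    if mode == "posterior":
        qa = asr.posteriors[a.parent.id]
        qb = asr.posteriors[b.parent.id]
        e_sites = sum(w[:, m] * ((qa @ Ms[m]) * qb).sum(axis=1) for m in range(rates.k))
    elif mode == "conditional":
        xa = asr.ml_states[a.parent.id]
        xb = asr.ml_states[b.parent.id]
        e_sites = sum(w[:, m] * Ms[m][xa, xb] for m in range(rates.k))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    e_sites = np.asarray(e_sites)
    return float(e_sites.sum()), e_sites


def expected_E_from_joints(
    Ja: np.ndarray, Jb: np.ndarray, scheme: GroupingScheme
) -> tuple[float, np.ndarray]:
    """E from precomputed joint endpoint posteriors of the two branches.

    Per site and class c, each branch contributes the posterior probability
    that it carried a substitution from outside c into c; the two branches'
    contributions multiply and classes sum.
    """
    cls = scheme.class_index
    c_idx = np.arange(scheme.n_classes)
    x_ok = (cls[:, None] != c_idx[None, :]).astype(float)  # parent outside c
    y_in = (cls[:, None] == c_idx[None, :]).astype(float)  # child inside c
    A = np.einsum("sxy,xc,yc->sc", Ja, x_ok, y_in)
    B = np.einsum("sxy,xc,yc->sc", Jb, x_ok, y_in)
    e_sites = (A * B).sum(axis=1)
    return float(e_sites.sum()), e_sites


def poisson_test(O: int, E: float) -> float:
    """One-sided upper tail P(X >= O) for X ~ Poisson(E)."""
    if O < 0 or E < 0:
        raise ValueError("O and E must be non-negative")
    if O == 0:
        return 1.0
    if E == 0:
        return 0.0
    return float(poisson.sf(O - 1, E))


# ---------------------------------------------------------------------------
# Per-gene result and the batch scan


@dataclass
class GeneConvergenceResult:
    gene_id: str
    scheme: str
    pair_label: str
    O: int
    E: float
    R: Optional[float]
    p: float
    n_sites: int
    status: str = "ok"
    events: list[SiteConvergenceEvent] = field(default_factory=list)


def gene_convergence(
    aln: ProteinAlignment,
    tree: PhyloTree,
    pair_nodes: tuple[Node, Node],
    scheme: GroupingScheme,
    model: SubstitutionModel,
    rates: RateModel,
    asr: AncestralReconstruction,
    mode: str = DEFAULT_E_MODE,
    pair_label: str = "BP",
    joints=None,
) -> GeneConvergenceResult:
    O, events = observed_O(asr, tree, pair_nodes, scheme, aln, pair_label)
    if mode == "joint" and joints is not None:
        a, b = pair_nodes
        E, _ = expected_E_from_joints(joints[a.id], joints[b.id], scheme)
    else:
        E, _ = expected_E_gene(asr, tree, pair_nodes, model, rates, scheme, mode,
                               aln=aln)
    R = O / E if E > 0 else None
    return GeneConvergenceResult(
        gene_id=aln.gene_id,
        scheme=scheme.name,
        pair_label=pair_label,
        O=O,
        E=E,
        R=R,
        p=poisson_test(O, E),
        n_sites=aln.n_sites,
        events=events,
    )


DEFAULT_ALPHA_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


def scan_genes(
    alignments: Iterable[ProteinAlignment],
    species_tree: PhyloTree,
    pairs: Sequence[BranchPair],
    schemes: Sequence[GroupingScheme],
    matrix: str = "LG",
    frequencies_mode: str = "gene",
    alpha: Optional[float] = None,
    k: int = 4,
    mode: str = DEFAULT_E_MODE,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    prefiltered: bool = False,
    log=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the R-statistic pipeline over a batch of genes.

    Returns the per-gene result table, the site-event table, and the
    four gene sets of interest per scheme and pair: (1) significant excess
    convergence R > 1 with p < 0.05, (2) any observed convergence O > 0,
    (3) R(GS) > R(US), (4) O(GS) > O(US). Per-gene failures are recorded in
    the status column and never abort the scan.
    """
    rows, event_rows = [], []
    for aln in alignments:
        try:
            results = _scan_one(
                aln, species_tree, pairs, schemes, matrix, frequencies_mode,
                alpha, k, mode, alpha_grid, prefiltered,
            )
        except DiscardAlignment as exc:
            if log:
                log.info("discarding %s: %s", aln.gene_id, exc)
            for pair in pairs:
                for scheme in schemes:
                    rows.append(
                        (aln.gene_id, scheme.name, pair.label, 0, 0.0, np.nan,
                         np.nan, 0, "discarded")
                    )
            continue
        for res in results:
            rows.append(
                (res.gene_id, res.scheme, res.pair_label, res.O, res.E,
                 res.R if res.R is not None else np.nan, res.p, res.n_sites,
                 res.status)
            )
            for ev in res.events:
                for branch, anc, der, anc_c, der_c in (
                    ("a", ev.anc_a, ev.der_a, ev.anc_class_a, ev.der_class_a),
                    ("b", ev.anc_b, ev.der_b, ev.anc_class_b, ev.der_class_b),
                ):
                    event_rows.append(
                        (ev.gene_id, ev.site, ev.site_orig, res.scheme,
                         ev.pair_label, branch, anc, der, anc_c, der_c,
                         ev.event_class.value)
                    )
    results_df = pd.DataFrame(
        rows,
        columns=["gene_id", "scheme", "branch_pair", "O", "E", "R", "p_poisson",
                 "n_sites", "status"],
    )
    events_df = pd.DataFrame(
        event_rows,
        columns=["gene_id", "site", "site_orig", "scheme", "branch_pair",
                 "branch", "anc", "der", "anc_class", "der_class",
                 "event_class"],
    )
    return results_df, events_df, summarise_gene_sets(results_df)


def _scan_one(
    aln, species_tree, pairs, schemes, matrix, frequencies_mode, alpha, k,
    mode, alpha_grid, prefiltered,
):
    faln = aln if prefiltered else filter_sites(aln)
    usable = [t for t in faln.taxa if t in set(species_tree.taxa)]
    if len(usable) < 3:
        return [
            GeneConvergenceResult(faln.gene_id, s.name, p.label, 0, 0.0, None,
                                  np.nan, faln.n_sites, "skipped:too-few-taxa")
            for p in pairs for s in schemes
        ]
    faln = faln.subset_taxa(usable)
    gene_tree = species_tree.prune_to(usable)
    model = build_model(matrix, frequencies_mode, faln)
    if alpha is None:
        alpha = estimate_alpha(faln, gene_tree, model, alpha_grid, k)
    rates = discrete_gamma(alpha, k)
    asr = marginal_asr(faln, gene_tree, model, rates)
    out = []
    for pair in pairs:
        try:
            nodes = resolve_pair_on_gene_tree(pair, species_tree, gene_tree)
        except (SkipGene, BranchResolutionError, TreeError) as exc:
            out.extend(
                GeneConvergenceResult(faln.gene_id, s.name, pair.label, 0, 0.0,
                                      None, np.nan, faln.n_sites,
                                      f"skipped:{exc}")
                for s in schemes
            )
            continue
        joints = None
        if mode == "joint":
            from caap.model import edge_joint_posteriors

            joints = edge_joint_posteriors(faln, gene_tree, model, rates,
                                           list(nodes))
        for scheme in schemes:
            out.append(
                gene_convergence(faln, gene_tree, nodes, scheme, model, rates,
                                 asr, mode, pair.label, joints=joints)
            )
    return out


def summarise_gene_sets(results: pd.DataFrame) -> dict:
    """The four gene sets of interest, keyed by (pair label, scheme name)."""
    ok = results[results["status"] == "ok"]
    out = {}
    for (pair, scheme), grp in ok.groupby(["branch_pair", "scheme"]):
        sig = grp[(grp["R"] > 1) & (grp["p_poisson"] < 0.05)]["gene_id"]
        obs = grp[grp["O"] > 0]["gene_id"]
        entry = {
            "R_gt_1": set(sig),
            "O_gt_0": set(obs),
        }
        if scheme != "US":
            us = ok[(ok["branch_pair"] == pair) & (ok["scheme"] == "US")]
            merged = grp.merge(us, on="gene_id", suffixes=("", "_us"))
            entry["R_gs_gt_us"] = set(
                merged[merged["R"].fillna(-np.inf) > merged["R_us"].fillna(-np.inf)]["gene_id"]
            )
            entry["O_gs_gt_us"] = set(merged[merged["O"] > merged["O_us"]]["gene_id"])
        out[(pair, scheme)] = entry
    return out
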