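"""Empirical reversible substitution models, likelihoods and marginal ASR.

The rate matrix is built from a published exchangeability matrix S and
equilibrium frequencies pi as q_ij = S_ij pi_j, normalised to one expected
substitution per unit branch length. Because the chain is reversible, P(t) =
exp(Qt) is computed through a symmetric eigendecomposition done once per
model. Among-site rate variation uses the usual discrete-gamma construction
with equal-probability categories.

Marginal ancestral reconstruction combines, per site and rate category, the
"up" conditional likelihood of the subtree below a node with the "down"
likelihood of the rest of the data, weighting categories by their site
posterior; the reported ancestral state is the argmax of the resulting
marginal posterior (ties broken alphabetically and recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from caap.io import AMINO_ACIDS, ProteinAlignment
from caap.tree import Node, PhyloTree

FREQ_FLOOR = 1e-6

_BUILTIN_MATRICES = {"LG": "lg.dat", "JTT": "jtt.dat", "WAG": "wag.dat"}


class ModelError(ValueError):
    pass


def read_paml_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PAML-layout .dat file: 19 lower-triangle rows then frequencies."""
    values = [float(tok) for tok in text.split()]
    if len(values) < 210:
        raise ModelError("matrix file too short")
    S = np.zeros((20, 20))
    pos = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = values[pos]
            pos += 1
    freqs = np.array(values[pos : pos + 20])
    return S, freqs


@dataclass
class SubstitutionModel:
    """Reversible 20-state model: exchangeabilities, frequencies, Q, P(t)."""

    name: str
    exchangeabilities: np.ndarray  # symmetric, zero diagonal
    frequencies: np.ndarray        # strictly positive, sums to 1

    Q: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, float)
        pi = np.asarray(self.frequencies, float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ModelError("exchangeability matrix must be symmetric 20x20")
        if pi.shape != (20,) or (pi <= 0).any():
            raise ModelError("frequencies must be 20 positive values")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(20)] = -Q.sum(axis=1)
        mu = -np.dot(pi, np.diag(Q))
        Q /= mu
        self.exchangeabilities = S
        self.frequencies = pi
        self.Q = Q
        # Symmetric decomposition: B = D Q D^-1 with D = diag(sqrt(pi)).
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        eigval, V = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = eigval
        self._left = V / d[:, None]          # U such that Q = U diag(l) W
        self._right = V.T * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, P(0) = I."""
        if t < 0:
            raise ModelError(f"negative branch length {t}")
        if t == 0:
            return np.eye(20)
        P = (self._left * np.exp(self._eigval * t)[None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def build_model(
    name: str = "LG",
    frequencies_mode: str = "empirical",
    aln: Optional[ProteinAlignment] = None,
) -> SubstitutionModel:
    """Build a substitution model from a shipped empirical matrix.

    ``frequencies_mode='empirical'`` uses the frequencies published with the
    matrix; ``'gene'`` replaces them with the observed residue proportions of
    the supplied (already filtered) alignment, floored at 1e-6 and
    renormalised so rare residues never get zero probability.
    """
    key = name.upper()
    if key not in _BUILTIN_MATRICES:
        raise ModelError(f"unknown matrix {name!r}; available: LG, JTT, WAG")
    text = (
        resources.files("caap").joinpath("data/matrices", _BUILTIN_MATRICES[key])
    ).read_text()
    S, freqs = read_paml_dat(text)
    if frequencies_mode == "gene":
        if aln is None:
            raise ModelError("gene-frequency mode needs an alignment")
        freqs = gene_frequencies(aln)
    elif frequencies_mode != "empirical":
        raise ModelError(f"unknown frequencies_mode {frequencies_mode!r}")
    return SubstitutionModel(key, S, freqs)


def gene_frequencies(aln: ProteinAlignment) -> np.ndarray:
    """Observed residue proportions over all cells, floored and renormalised."""
    counts = np.zeros(20)
    states, n = np.unique(aln.encoded(), return_counts=True)
    counts[states] = n
    freqs = counts / counts.sum()
    freqs = np.maximum(freqs, FREQ_FLOOR)
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# Discrete gamma rates


@dataclass(frozen=True)
class RateModel:
    """Discrete-gamma rate categories with equal prior weight 1/k, mean 1."""

    alpha: float
    k: int
    rates: tuple

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)


def discrete_gamma(alpha: float, k: int, convention: str = "mean") -> RateModel:
    """Discretise Gamma(shape=alpha, mean=1) into k equal-probability bins.

    ``convention='mean'`` gives each category the mean of its bin (computed
    with the regularised incomplete gamma function); ``'median'`` uses the
    bin median rescaled to overall mean 1.
    """
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    if k < 1:
        raise ModelError("need at least one rate category")
    if k == 1:
        return RateModel(alpha, 1, (1.0,))
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    if convention == "mean":
        # Mean of Gamma(a, 1/a) over [lo, hi] with bin mass 1/k:
        # k * [I(a+1, a*hi) - I(a+1, a*lo)] where I is the regularised
        # lower incomplete gamma.
        cum = gammainc(alpha + 1.0, alpha * edges)
        rates = k * np.diff(cum)
    elif convention == "median":
        mids = gamma_dist.ppf((np.arange(k) + 0.5) / k, a=alpha, scale=1.0 / alpha)
        rates = mids / mids.mean()
    else:
        raise ModelError(f"unknown discretisation convention {convention!r}")
    rates = np.sort(rates)
    return RateModel(alpha, k, tuple(float(r) for r in rates))


# ---------------------------------------------------------------------------
# Pruning likelihood and marginal ASR


def _leaf_states(aln: ProteinAlignment, tree: PhyloTree) -> dict[int, np.ndarray]:
    """Map leaf node id -> per-site state indices."""
    enc = aln.encoded()
    out = {}
    for leaf in tree.leaves():
        if leaf.name not in aln.taxa:
            raise ModelError(f"leaf {leaf.name!r} has no sequence")
        out[leaf.id] = enc[aln.taxa.index(leaf.name)]
    return out


def _up_messages(tree, leaf_states, n_sites, P):
    """Postorder conditional likelihoods per node, with per-site log scaling.

    Returns (up, logscale): up[node_id] is (n_sites, 20); logscale[node_id]
    is the per-site log of the factor divided out below/at that node.
    """
    n_nodes = len(list(tree.postorder()))
    up = [None] * n_nodes
    logscale = [None] * n_nodes
    for node in tree.postorder():
        if node.is_leaf:
            L = np.zeros((n_sites, 20))
            L[np.arange(n_sites), leaf_states[node.id]] = 1.0
            up[node.id] = L
            logscale[node.id] = np.zeros(n_sites)
        else:
            L = np.ones((n_sites, 20))
            sc = np.zeros(n_sites)
            for child in node.children:
                L = L * (up[child.id] @ P[child.id].T)
                sc = sc + logscale[child.id]
            m = L.max(axis=1)
            safe = np.where(m > 0, m, 1.0)
            up[node.id] = L / safe[:, None]
            with np.errstate(divide="ignore"):
                logscale[node.id] = sc + np.log(safe) + np.where(m > 0, 0.0, -np.inf)
    return up, logscale


@dataclass
class AncestralReconstruction:
    """Marginal ASR over a gene: posteriors, ML states, rate weights."""

    tree: PhyloTree
    node_ids: list[int]                 # internal node ids, postorder
    posteriors: dict[int, np.ndarray]   # node id -> (n_sites, 20)
    ml_states: dict[int, np.ndarray]    # node id -> (n_sites,) state indices
    rate_weights: np.ndarray            # (n_sites, k) posterior over categories
    site_loglik: np.ndarray
    loglik: float
    ties: list[tuple[int, int]] = field(default_factory=list)  # (node id, site)

    def ml_residues(self, node_id: int) -> np.ndarray:
        aas = np.array(list(AMINO_ACIDS))
        return aas[self.ml_states[node_id]]


def _category_up(aln, tree, model, rates):
    """Per-category up messages and root log-likelihood terms."""
    n_sites = aln.n_sites
    leaf_states = _leaf_states(aln, tree)
    pi = model.frequencies
    per_cat = []
    cat_site_loglik = np.empty((rates.k, n_sites))
    for m, r in enumerate(rates.rates):
        P = {
            node.id: model.transition_matrix(node.length * r)
            for node in tree.postorder()
            if node.parent is not None
        }
        up, logscale = _up_messages(tree, leaf_states, n_sites, P)
        with np.errstate(divide="ignore"):
            cat_site_loglik[m] = np.log(up[tree.root.id] @ pi) + logscale[tree.root.id]
        per_cat.append((P, up, logscale))
    return leaf_states, per_cat, cat_site_loglik


def prune_loglik(
    aln: ProteinAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    rates: Optional[RateModel] = None,
) -> tuple[np.ndarray, float]:
    """Per-site and total log-likelihood by postorder pruning.

    The site likelihood averages the conditional likelihood over the k
    equally probable rate categories and sums over root states weighted by
    the equilibrium frequencies.
    """
    if rates is None:
        rates = RateModel(np.inf, 1, (1.0,))
    _, _, cat_site_loglik = _category_up(aln, tree, model, rates)
    site_loglik = logsumexp(cat_site_loglik, axis=0) - np.log(rates.k)
    return site_loglik, float(site_loglik.sum())


def marginal_asr(
    aln: ProteinAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    rates: Optional[RateModel] = None,
) -> AncestralReconstruction:
    """Marginal ancestral reconstruction at every internal node.

    Per site, the posterior at a node is proportional to
    sum_m w_m * up_m(x) * down_m(x), where w_m is the posterior weight of
    rate category m given the site and the up/down factors are the
    conditional likelihoods of the data below and outside the node.
    """
    if rates is None:
        rates = RateModel(np.inf, 1, (1.0,))
    n_sites = aln.n_sites
    pi = model.frequencies
    leaf_states, per_cat, cat_site_loglik = _category_up(aln, tree, model, rates)
    site_loglik = logsumexp(cat_site_loglik, axis=0) - np.log(rates.k)
    rate_weights = np.exp(cat_site_loglik - site_loglik[None, :]).T / rates.k

    internal = [n for n in tree.postorder() if not n.is_leaf]
    n_nodes = len(list(tree.postorder()))
    # log joint P(data, state at node = x, category m), shape (k, n, 20)
    logjoint = {n.id: np.empty((rates.k, n_sites, 20)) for n in internal}
    for m in range(rates.k):
        P, up, up_ls = per_cat[m]
        down = [None] * n_nodes        # outside likelihood, scaled
        down_ls = [None] * n_nodes
        for node in tree.preorder():
            if node.parent is None:
                down[node.id] = np.tile(pi, (n_sites, 1))
                down_ls[node.id] = np.zeros(n_sites)
            else:
                parent = node.parent
                raw = down[parent.id].copy()
                sc = down_ls[parent.id].copy()
                for sib in parent.children:
                    if sib is node:
                        continue
                    raw = raw * (up[sib.id] @ P[sib.id].T)
                    sc = sc + up_ls[sib.id]
                raw = raw @ P[node.id]
                mx = raw.max(axis=1)
                safe = np.where(mx > 0, mx, 1.0)
                down[node.id] = raw / safe[:, None]
                with np.errstate(divide="ignore"):
                    down_ls[node.id] = sc + np.log(safe) + np.where(mx > 0, 0.0, -np.inf)
            if not node.is_leaf:
                with np.errstate(divide="ignore"):
                    logjoint[node.id][m] = (
                        np.log(up[node.id] * down[node.id])
                        + (up_ls[node.id] + down_ls[node.id])[:, None]
                    )

    # alpha_rank[i] = alphabetical rank of the residue with state index i
    alpha_rank = np.argsort(np.argsort(list(AMINO_ACIDS)))
    posteriors, ml_states, ties = {}, {}, []
    for node in internal:
        lj = logjoint[node.id] - np.log(rates.k)        # (k, n, 20)
        post = np.exp(lj - logsumexp(lj, axis=(0, 2))[None, :, None]).sum(axis=0)
        post /= post.sum(axis=1, keepdims=True)
        posteriors[node.id] = post
        best = post.max(axis=1)
        states = np.empty(n_sites, dtype=np.int64)
        for s in range(n_sites):
            winners = np.nonzero(post[s] == best[s])[0]
            if winners.size > 1:
                ties.append((node.id, s))
                winners = winners[np.argsort(alpha_rank[winners])]
            states[s] = winners[0]
        ml_states[node.id] = states
    return AncestralReconstruction(
        tree=tree,
        node_ids=[n.id for n in internal],
        posteriors=posteriors,
        ml_states=ml_states,
        rate_weights=rate_weights,
        site_loglik=site_loglik,
        loglik=float(site_loglik.sum()),
        ties=ties,
    )


def edge_joint_posteriors(
    aln: ProteinAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    rates: Optional[RateModel] = None,
    branches: Optional[list] = None,
) -> dict[int, np.ndarray]:
    """Joint posterior of (parent state, child state) on selected branches.

    For each requested branch (child node) returns an (n_sites, 20, 20)
    array J with J[s, x, y] = P(parent = x, child = y | data), integrating
    over rate categories. Row/column sums reproduce the marginal posteriors
    of the two endpoint nodes. These joints are the empirical-Bayes
    substitution-type probabilities: the probability that the branch carried
    an x->y substitution at the site.
    """
    if rates is None:
        rates = RateModel(np.inf, 1, (1.0,))
    n_sites = aln.n_sites
    pi = model.frequencies
    if branches is None:
        branches = [n for n in tree.postorder() if n.parent is not None]
    wanted = {n.id for n in branches}
    _, per_cat, cat_site_loglik = _category_up(aln, tree, model, rates)

    n_nodes = len(list(tree.postorder()))
    logjoint = {
        n.id: np.full((rates.k, n_sites, 20, 20), -np.inf) for n in branches
    }
    for m in range(rates.k):
        P, up, up_ls = per_cat[m]
        down = [None] * n_nodes
        down_ls = [None] * n_nodes
        for node in tree.preorder():
            if node.parent is None:
                down[node.id] = np.tile(pi, (n_sites, 1))
                down_ls[node.id] = np.zeros(n_sites)
                continue
            parent = node.parent
            half = down[parent.id].copy()
            sc = down_ls[parent.id].copy()
            for sib in parent.children:
                if sib is node:
                    continue
                half = half * (up[sib.id] @ P[sib.id].T)
                sc = sc + up_ls[sib.id]
            if node.id in wanted:
                # J ~ half(x) * P(x, y) * up_child(y)
                with np.errstate(divide="ignore"):
                    logjoint[node.id][m] = (
                        np.log(
                            half[:, :, None]
                            * P[node.id][None, :, :]
                            * up[node.id][:, None, :]
                        )
                        + (sc + up_ls[node.id])[:, None, None]
                    )
            raw = half @ P[node.id]
            mx = raw.max(axis=1)
            safe = np.where(mx > 0, mx, 1.0)
            down[node.id] = raw / safe[:, None]
            with np.errstate(divide="ignore"):
                down_ls[node.id] = sc + np.log(safe) + np.where(mx > 0, 0.0, -np.inf)

    out = {}
    for node_id, lj in logjoint.items():
        lj = lj - np.log(rates.k)
        norm = logsumexp(lj, axis=(0, 2, 3))
        post = np.exp(lj - norm[None, :, None, None]).sum(axis=0)
        post /= post.sum(axis=(1, 2), keepdims=True)
        out[node_id] = post
    return out


def estimate_alpha(
    aln: ProteinAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    grid,
    k: int = 4,
) -> float:
    """Gamma shape maximising the pruning log-likelihood over a grid."""
    grid = list(grid)
    if not grid:
        raise ModelError("empty alpha grid")
    best_alpha, best_ll = None, -np.inf
    for alpha in grid:
        _, ll = prune_loglik(aln, tree, model, discrete_gamma(alpha, k))
        if ll > best_ll:
            best_alpha, best_ll = alpha, ll
    return best_alpha
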