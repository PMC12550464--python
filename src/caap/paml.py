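"""Parser for PAML ``rst`` marginal ancestral-reconstruction output.

Reads the numbered tree and the per-site "Prob of best state at each node"
block that codeml writes for marginal reconstruction, and reconciles codeml's
node numbering (leaves 1..n in tree order, internals n+1..2n-1) with a
:class:`~caap.tree.PhyloTree` by matching subtended leaf sets. The result can
stand in for the native reconstruction anywhere an
:class:`~caap.model.AncestralReconstruction` is accepted, which allows exact
replication of analyses whose reconstruction step was run in PAML.
"""

from __future__ import annotations

import re

import numpy as np

from caap.io import AA_INDEX
from caap.model import AncestralReconstruction
from caap.tree import PhyloTree


class RstParseError(ValueError):
    pass


class RstReconcileError(RstParseError):
    pass


_NUMBERED_LEAF = re.compile(r"(\d+)_([^\s,():;]+)")


def _parse_numbered_tree(line: str) -> tuple[dict[int, str], dict[int, frozenset]]:
    """Map leaf numbers to taxa and internal numbers to leaf-name sets."""
    leaf_names = {int(num): name for num, name in _NUMBERED_LEAF.findall(line)}
    if not leaf_names:
        raise RstParseError("numbered tree line contains no '<number>_<taxon>' leaves")
    # Parse the nesting to collect, for each internal node number (the label
    # after a closing parenthesis), the set of leaf names beneath it.
    clades: dict[int, frozenset] = {}
    stack: list[list[str]] = []
    i = 0
    while i < len(line):
        ch = line[i]
        if ch == "(":
            stack.append([])
            i += 1
        elif ch == ")":
            members = stack.pop()
            i += 1
            m = re.match(r"\s*(\d+)", line[i:])
            if m:
                clades[int(m.group(1))] = frozenset(members)
                i += m.end()
            if stack:
                stack[-1].extend(members)
        else:
            m = _NUMBERED_LEAF.match(line, i)
            if m:
                name = m.group(2)
                if stack:
                    stack[-1].append(name)
                i = m.end()
            else:
                i += 1
    if not clades:
        raise RstParseError("no numbered internal nodes found in tree line")
    return leaf_names, clades


_STATE_PROB = re.compile(r"([A-Z])\(([0-9.]+)\)")


def parse_paml_rst(path, tree: PhyloTree) -> AncestralReconstruction:
    """Read marginal ancestral states and posteriors from an ``rst`` file.

    Only the best-state-per-node block is parsed; the stored posterior mass
    is concentrated on the reported state (codeml prints the winning
    probability only). Rate-category weights default to a single category.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    tree_line = None
    site_block_start = None
    for idx, line in enumerate(lines):
        if tree_line is None and _NUMBERED_LEAF.search(line) and line.count("(") >= 1:
            tree_line = line
        if "Prob of best state at each node" in line:
            site_block_start = idx + 1
    if tree_line is None:
        raise RstParseError(f"{path}: no numbered tree found")
    if site_block_start is None:
        raise RstParseError(f"{path}: no marginal reconstruction block found")

    leaf_names, clades = _parse_numbered_tree(tree_line)
    n_leaves = len(leaf_names)

    # Reconcile codeml node numbers with tree node ids via leaf sets.
    tree_clades = {
        tree.clade_taxa(node): node.id
        for node in tree.postorder()
        if not node.is_leaf
    }
    number_to_id: dict[int, int] = {}
    unmatched = []
    for number, members in clades.items():
        if members in tree_clades:
            number_to_id[number] = tree_clades[members]
        else:
            unmatched.append(number)
    if unmatched:
        raise RstReconcileError(
            f"{path}: codeml nodes {sorted(unmatched)} have no matching clade "
            "in the supplied tree"
        )

    internal_numbers = sorted(clades)
    site_states: list[list[int]] = []
    site_probs: list[list[float]] = []
    for line in lines[site_block_start:]:
        stripped = line.strip()
        if not stripped:
            if site_states:
                break
            continue
        if not stripped[0].isdigit():
            continue
        pairs = _STATE_PROB.findall(stripped)
        if len(pairs) < len(internal_numbers):
            raise RstParseError(
                f"{path}: site line has {len(pairs)} reconstructed states, "
                f"expected {len(internal_numbers)}"
            )
        pairs = pairs[-len(internal_numbers):]
        try:
            site_states.append([AA_INDEX[aa] for aa, _ in pairs])
        except KeyError as exc:
            raise RstParseError(f"{path}: non-canonical state {exc}") from None
        site_probs.append([float(p) for _, p in pairs])
    if not site_states:
        raise RstParseError(f"{path}: marginal reconstruction block is empty")

    states = np.asarray(site_states)          # (n_sites, n_internal)
    probs = np.asarray(site_probs)
    n_sites = states.shape[0]

    posteriors, ml_states = {}, {}
    for col, number in enumerate(internal_numbers):
        node_id = number_to_id[number]
        ml = states[:, col]
        post = np.full((n_sites, 20), 0.0)
        best = probs[:, col]
        # Winning probability on the reported state; remainder spread evenly.
        post[:] = ((1.0 - best) / 19.0)[:, None]
        post[np.arange(n_sites), ml] = best
        posteriors[node_id] = post
        ml_states[node_id] = ml

    return AncestralReconstruction(
        tree=tree,
        node_ids=sorted(ml_states),
        posteriors=posteriors,
        ml_states=ml_states,
        rate_weights=np.ones((n_sites, 1)),
        site_loglik=np.zeros(n_sites),
        loglik=0.0,
    )
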