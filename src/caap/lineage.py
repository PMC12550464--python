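"""Lineage-based convergence detection without the R statistic.

Two engines:

* MRCA comparison (after the marine-mammal state-convergence approach): a
  focal lineage is "changed" at a site when its focal taxa all carry one
  class that differs from the class of the reconstructed most recent common
  ancestor of the focal taxa and their nearest sister species; a site is
  convergent when two or more lineages changed to the same derived class.

* CCS (convergence at conservative sites, after the mangrove study): among
  sites where the outgroup and every background taxon carry the identical
  residue, a site is convergent when at least two focal taxa share one
  class that differs from the class of the background residue. No tree or
  reconstruction is needed.

Both engines run at residue level under the ungrouped scheme, reproducing
the original state-based methods exactly, and support negative-control role
swaps as plain configuration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from caap.grouping import GroupingScheme
from caap.io import AMINO_ACIDS, CompositionRule, ConfigError, ProteinAlignment
from caap.model import AncestralReconstruction
from caap.tree import PhyloTree


@dataclass(frozen=True)
class Lineage:
    """One focal lineage: its focal taxa and their nearest sister taxa."""

    name: str
    focal: frozenset
    sister: frozenset


@dataclass
class LineageRoleConfig:
    """Taxon roles for the MRCA and CCS engines.

    Role sets must be pairwise disjoint; every named taxon must resolve
    against the configured species list (when one is given).
    """

    lineages: list[Lineage] = field(default_factory=list)
    background: frozenset = frozenset()
    outgroup: Optional[str] = None

    def __post_init__(self):
        sets = [lin.focal for lin in self.lineages]
        sets.append(frozenset(self.background))
        if self.outgroup:
            sets.append(frozenset([self.outgroup]))
        seen: set[str] = set()
        for s in sets:
            if seen & set(s):
                raise ConfigError(f"overlapping role sets: {sorted(seen & set(s))}")
            seen |= set(s)

    @property
    def focal_taxa(self) -> frozenset:
        out: set[str] = set()
        for lin in self.lineages:
            out |= set(lin.focal)
        return frozenset(out)

    def validate(self, known_taxa: Sequence[str]) -> None:
        known = set(known_taxa)
        named = set(self.focal_taxa) | set(self.background)
        for lin in self.lineages:
            named |= set(lin.sister)
        if self.outgroup:
            named.add(self.outgroup)
        unknown = named - known
        if unknown:
            raise ConfigError(f"roles name unknown taxa: {sorted(unknown)}")

    def composition_rule(self, engine: str) -> CompositionRule:
        """Minimum-count requirements a gene must meet for an engine."""
        if engine == "mrca":
            reqs = []
            for lin in self.lineages:
                reqs.append((f"{lin.name}:focal", lin.focal, len(lin.focal)))
                reqs.append((f"{lin.name}:sister", lin.sister, 1))
            return CompositionRule(reqs)
        if engine == "ccs":
            taxa = self.focal_taxa | self.background | frozenset(
                [self.outgroup] if self.outgroup else []
            )
            return CompositionRule([("ccs:all", frozenset(taxa), len(taxa))])
        raise ConfigError(f"unknown engine {engine!r}")

    def swapped(self) -> "LineageRoleConfig":
        """Exchange focal and background roles (CCS negative control)."""
        return LineageRoleConfig(
            lineages=[Lineage("control", frozenset(self.background), frozenset())],
            background=self.focal_taxa,
            outgroup=self.outgroup,
        )


class GeneSkipped(Exception):
    pass


# ---------------------------------------------------------------------------
# MRCA-comparison engine


@dataclass(frozen=True)
class LineageChange:
    lineage: str
    mrca_state: str
    mrca_class: int
    derived_class: Optional[int]   # None when focal taxa disagree in class
    changed: bool


@dataclass(frozen=True)
class FooteSiteCall:
    gene_id: str
    site: int
    site_orig: int
    changes: tuple[LineageChange, ...]
    shared_lineages: frozenset     # changed lineages sharing the derived class
    shared_class: int


def foote_detect(
    aln: ProteinAlignment,
    tree: PhyloTree,
    asr: AncestralReconstruction,
    roles: LineageRoleConfig,
    scheme: GroupingScheme,
    agreement: str = "strict",
) -> tuple[list[FooteSiteCall], dict[frozenset, int]]:
    """Site calls and per-lineage-combination tallies by MRCA comparison.

    ``agreement='strict'`` requires every focal taxon of a lineage to carry
    the same derived class; ``'any'`` lets a single focal taxon carry the
    change. Tally keys are frozensets of lineage names (every subset of size
    >= 2); a site increments a combination when all its lineages changed to
    one shared class, so two-lineage tallies contain the three-lineage one.
    """
    if agreement not in ("strict", "any"):
        raise ConfigError(f"unknown agreement mode {agreement!r}")
    enc = aln.encoded()
    cls = scheme.class_index
    taxa_idx = {t: i for i, t in enumerate(aln.taxa)}
    lineage_rows: dict[str, list[int]] = {}
    mrca_nodes: dict[str, int] = {}
    for lin in roles.lineages:
        missing = (set(lin.focal) | set(lin.sister)) - set(aln.taxa)
        if missing:
            raise GeneSkipped(f"{lin.name}: taxa absent: {sorted(missing)}")
        lineage_rows[lin.name] = [taxa_idx[t] for t in sorted(lin.focal)]
        mrca_nodes[lin.name] = tree.mrca(set(lin.focal) | set(lin.sister)).id

    calls: list[FooteSiteCall] = []
    names = [lin.name for lin in roles.lineages]
    tallies: dict[frozenset, int] = {}
    for r in range(2, len(names) + 1):
        from itertools import combinations

        for combo in combinations(names, r):
            tallies[frozenset(combo)] = 0

    for s in range(aln.n_sites):
        changes = []
        derived: dict[str, int] = {}
        for lin in roles.lineages:
            mrca_state = int(asr.ml_states[mrca_nodes[lin.name]][s])
            mrca_class = int(cls[mrca_state])
            focal_classes = {int(cls[enc[i, s]]) for i in lineage_rows[lin.name]}
            if agreement == "strict":
                agreed = focal_classes.pop() if len(focal_classes) == 1 else None
            else:
                non_anc = focal_classes - {mrca_class}
                agreed = min(non_anc) if len(non_anc) == 1 else None
            changed = agreed is not None and agreed != mrca_class
            changes.append(
                LineageChange(lin.name, AMINO_ACIDS[mrca_state], mrca_class,
                              agreed, changed)
            )
            if changed:
                derived[lin.name] = agreed
        if len(derived) < 2:
            continue
        by_class: dict[int, set] = {}
        for name, c in derived.items():
            by_class.setdefault(c, set()).add(name)
        sharing = {c: members for c, members in by_class.items() if len(members) >= 2}
        if not sharing:
            continue
        best_class = max(sharing, key=lambda c: (len(sharing[c]), -c))
        calls.append(
            FooteSiteCall(
                gene_id=aln.gene_id,
                site=s + 1,
                site_orig=aln.site_map[s],
                changes=tuple(changes),
                shared_lineages=frozenset(sharing[best_class]),
                shared_class=best_class,
            )
        )
        for combo in tallies:
            if any(combo <= members for members in sharing.values()):
                tallies[combo] += 1
    return calls, tallies


# ---------------------------------------------------------------------------
# CCS engine


@dataclass(frozen=True)
class CCSSiteCall:
    gene_id: str
    site: int
    site_orig: int
    background_state: str
    convergent_taxa: frozenset
    derived_class: int
    conserved: bool


def ccs_detect(
    aln: ProteinAlignment,
    roles: LineageRoleConfig,
    scheme: GroupingScheme,
    control: bool = False,
) -> tuple[list[CCSSiteCall], int]:
    """Convergence at conservative sites.

    Conservation is defined at residue level: the outgroup and every
    background taxon must carry the identical residue. Convergence then
    requires at least two focal taxa sharing one class different from the
    class of the conserved background residue. ``control=True`` swaps the
    focal and background roles, the negative-control configuration.
    """
    if control:
        roles = roles.swapped()
    if roles.outgroup is None:
        raise ConfigError("CCS requires an outgroup taxon")
    needed = roles.focal_taxa | roles.background | {roles.outgroup}
    missing = needed - set(aln.taxa)
    if missing:
        raise GeneSkipped(f"taxa absent: {sorted(missing)}")
    enc = aln.encoded()
    idx = {t: i for i, t in enumerate(aln.taxa)}
    bg_rows = [idx[t] for t in sorted(roles.background)] + [idx[roles.outgroup]]
    focal = sorted(roles.focal_taxa)
    focal_rows = [idx[t] for t in focal]
    cls = scheme.class_index

    calls: list[CCSSiteCall] = []
    bg = enc[bg_rows]
    conserved_mask = (bg == bg[0]).all(axis=0)
    for s in np.nonzero(conserved_mask)[0]:
        bg_state = int(bg[0, s])
        bg_class = int(cls[bg_state])
        focal_classes = cls[enc[focal_rows, s]]
        counts = Counter(int(c) for c in focal_classes if int(c) != bg_class)
        shared = {c: n for c, n in counts.items() if n >= 2}
        if not shared:
            continue
        best = max(shared, key=lambda c: (shared[c], -c))
        taxa = frozenset(
            t for t, c in zip(focal, focal_classes) if int(c) == best
        )
        calls.append(
            CCSSiteCall(
                gene_id=aln.gene_id,
                site=int(s) + 1,
                site_orig=aln.site_map[int(s)],
                background_state=AMINO_ACIDS[bg_state],
                convergent_taxa=taxa,
                derived_class=best,
                conserved=True,
            )
        )
    return calls, len(calls)


def compare_scheme_counts(
    counts: pd.DataFrame, direction: str = "focal"
) -> dict[str, set]:
    """Genes whose convergent-site count increased under each grouped scheme.

    ``counts`` has columns gene_id, scheme, direction, count; the result
    maps each non-US scheme to {gene : count(GS) > count(US)} within the
    requested direction (focal detection or the role-swapped control).
    """
    sub = counts[counts["direction"] == direction]
    us = sub[sub["scheme"] == "US"].set_index("gene_id")["count"]
    out: dict[str, set] = {}
    for scheme, grp in sub[sub["scheme"] != "US"].groupby("scheme"):
        merged = grp.set_index("gene_id")["count"]
        common = merged.index.intersection(us.index)
        out[scheme] = set(common[merged.loc[common] > us.loc[common]])
    return out
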