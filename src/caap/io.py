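"""Alignment I/O, site filtering, taxon-composition rules and result tables.

The unit of analysis is one FASTA file of aligned one-to-one orthologous
protein sequences per gene. Before any convergence detection, every column
containing a gap or an ambiguous residue is removed, and alignments left
with fewer than two columns are discarded.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Characters that disqualify a column: alignment gaps, ambiguity codes,
#: the non-canonical residues selenocysteine/pyrrolysine, stops and unknowns.
AMBIGUOUS_CHARS = frozenset("-.XBZJUO*?")


class AlignmentError(ValueError):
    pass


class MalformedAlignmentError(AlignmentError):
    pass


class DuplicateTaxonError(AlignmentError):
    pass


class EmptyInputError(AlignmentError):
    pass


class DiscardAlignment(Exception):
    """Raised when an alignment retains fewer than two usable columns."""


@dataclass
class ProteinAlignment:
    """A residue matrix (rows = taxa, columns = sites) for one gene.

    ``site_map`` maps each retained column (1-based) to its 1-based index in
    the unfiltered alignment; it is the identity straight after reading.
    """

    gene_id: str
    taxa: list[str]
    residues: np.ndarray  # (n_taxa, n_sites) of single characters
    site_map: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype="U1")
        if self.residues.ndim != 2:
            raise MalformedAlignmentError("residue matrix must be 2-D")
        if len(self.taxa) != self.residues.shape[0]:
            raise MalformedAlignmentError("taxa/row count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateTaxonError(f"duplicate taxon in {self.gene_id}")
        if not self.site_map:
            self.site_map = list(range(1, self.residues.shape[1] + 1))
        if len(self.site_map) != self.residues.shape[1]:
            raise MalformedAlignmentError("site_map/column count mismatch")

    @property
    def n_taxa(self) -> int:
        return self.residues.shape[0]

    @property
    def n_sites(self) -> int:
        return self.residues.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.residues[self.taxa.index(taxon)]

    def encoded(self) -> np.ndarray:
        """Residues as integer state indices (canonical residues only)."""
        flat = np.array([AA_INDEX[c] for c in self.residues.ravel()], dtype=np.int8)
        return flat.reshape(self.residues.shape)

    def subset_taxa(self, taxa: Sequence[str]) -> "ProteinAlignment":
        rows = [self.taxa.index(t) for t in taxa]
        return ProteinAlignment(
            self.gene_id, list(taxa), self.residues[rows], list(self.site_map)
        )


def read_alignment(path, gene_id: Optional[str] = None) -> ProteinAlignment:
    """Read an aligned FASTA file; residues are upper-cased, order preserved."""
    if gene_id is None:
        gene_id = str(path).rsplit("/", 1)[-1].split(".")[0]
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise DuplicateTaxonError(f"{path}: duplicate record headers")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise MalformedAlignmentError(
            f"{path}: records of unequal length {sorted(lengths)}"
        )
    if lengths == {0}:
        raise EmptyInputError(f"{path}: zero-length records")
    mat = np.array([list(str(r.seq).upper()) for r in records], dtype="U1")
    return ProteinAlignment(gene_id, names, mat)


def filter_sites(aln: ProteinAlignment) -> ProteinAlignment:
    """Drop every column containing a gap or any non-canonical character.

    Raises :class:`DiscardAlignment` when fewer than two columns survive, the
    signal that the gene is unusable for convergence counting.
    """
    canonical = np.isin(aln.residues, list(AMINO_ACIDS))
    keep = canonical.all(axis=0)
    surviving = np.nonzero(keep)[0]
    if surviving.size < 2:
        raise DiscardAlignment(
            f"{aln.gene_id}: {surviving.size} site(s) left after filtering"
        )
    site_map = [aln.site_map[j] for j in surviving]
    return ProteinAlignment(aln.gene_id, list(aln.taxa), aln.residues[:, surviving], site_map)


# ---------------------------------------------------------------------------
# Taxon composition rules


class ConfigError(ValueError):
    pass


@dataclass
class CompositionRule:
    """Minimum-count requirements on named taxon groups.

    Each entry is ``(label, taxa, min_count)``: the alignment must contain at
    least ``min_count`` members of ``taxa``.
    """

    requirements: list[tuple[str, frozenset, int]] = field(default_factory=list)

    def validate(self, known_taxa: Sequence[str]) -> None:
        known = set(known_taxa)
        for label, taxa, _ in self.requirements:
            unknown = set(taxa) - known
            if unknown:
                raise ConfigError(
                    f"rule {label!r} references unknown taxa: {sorted(unknown)}"
                )


def check_taxon_composition(aln: ProteinAlignment, rule: CompositionRule) -> bool:
    """True iff the alignment satisfies every minimum-count requirement."""
    present = set(aln.taxa)
    return all(
        len(present & set(taxa)) >= min_count
        for _, taxa, min_count in rule.requirements
    )


# ---------------------------------------------------------------------------
# Result tables

RESULT_COLUMNS = [
    "gene_id", "scheme", "branch_pair", "O", "E", "R", "p_poisson", "n_sites", "status",
]

EVENT_COLUMNS = [
    "gene_id", "site", "site_orig", "branch", "anc", "der", "anc_class", "der_class",
    "event_class",
]


def provenance_header(seed=None, config: Optional[dict] = None) -> str:
    """Header comment lines stamped on every output table."""
    from caap import __version__

    parts = [f"# caap {__version__}"]
    if config is not None:
        blob = ";".join(f"{k}={config[k]}" for k in sorted(config))
        digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
        parts.append(f"# config_hash {digest}")
    if seed is not None:
        parts.append(f"# seed {seed}")
    return "\n".join(parts) + "\n"


def write_results(results: pd.DataFrame, path, seed=None, config=None) -> None:
    """Write a result table as TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        results.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
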