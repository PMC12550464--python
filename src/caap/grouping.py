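"""Amino-acid grouping schemes and the substitution-pair event taxonomy.

A grouping scheme partitions the 20 canonical residues into physicochemical
classes. Convergence of a pair of substitutions (one per focal branch) is
classified as:

* ``exclusive_state``      — same derived residue on both branches, but no
  class change (e.g. R→H twice when R and H share the basic class);
* ``state_and_property``   — same derived residue and both branches changed
  class, arriving in the same class (e.g. R→D twice);
* ``exclusive_property``   — different derived residues in one shared class,
  both branches having changed class (e.g. R→D and R→E);
* ``none``                 — anything else.

"Property convergence" means ``state_and_property`` or ``exclusive_property``.
Under the ungrouped scheme (US, 20 singleton classes) property convergence
coincides exactly with state convergence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Union

import numpy as np

from caap.io import AMINO_ACIDS, AA_INDEX


class SchemeError(ValueError):
    pass


@dataclass(frozen=True)
class GroupingScheme:
    """An ordered partition of the 20 canonical residues into classes."""

    name: str
    classes: tuple[tuple[str, frozenset], ...]  # (label, residue set)

    def __post_init__(self):
        seen: set[str] = set()
        for label, members in self.classes:
            if not members:
                raise SchemeError(f"{self.name}: empty class {label!r}")
            for aa in members:
                if aa not in AA_INDEX:
                    raise SchemeError(f"{self.name}: unknown residue {aa!r}")
                if aa in seen:
                    raise SchemeError(f"{self.name}: residue {aa!r} duplicated")
                seen.add(aa)
        missing = set(AMINO_ACIDS) - seen
        if missing:
            raise SchemeError(f"{self.name}: residues missing: {sorted(missing)}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_sizes(self) -> list[int]:
        return [len(m) for _, m in self.classes]

    def class_of(self, residue: str) -> int:
        """Class index of a canonical residue."""
        try:
            return self._lookup()[AA_INDEX[residue]]
        except KeyError:
            raise SchemeError(f"non-canonical residue {residue!r}") from None

    def _lookup(self) -> np.ndarray:
        try:
            return self._cached_lookup
        except AttributeError:
            lut = np.empty(20, dtype=np.int64)
            for ci, (_, members) in enumerate(self.classes):
                for aa in members:
                    lut[AA_INDEX[aa]] = ci
            object.__setattr__(self, "_cached_lookup", lut)
            return lut

    @property
    def class_index(self) -> np.ndarray:
        """Length-20 vector mapping residue state index -> class index."""
        return self._lookup()

    @property
    def membership_matrix(self) -> np.ndarray:
        """20 x n_classes 0/1 indicator matrix (residue i in class c)."""
        m = np.zeros((20, self.n_classes))
        m[np.arange(20), self._lookup()] = 1.0
        return m

    def members(self, class_index: int) -> frozenset:
        return self.classes[class_index][1]


def ungrouped_scheme() -> GroupingScheme:
    """US: twenty singleton classes, one per residue."""
    return GroupingScheme(
        "US", tuple((aa, frozenset(aa)) for aa in AMINO_ACIDS)
    )


_BUILTIN_FILES = {f"GS{i}": f"gs{i}.txt" for i in range(5)}


def _parse_scheme_text(name: str, text: str) -> GroupingScheme:
    classes = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().upper()
        if not line:
            continue
        if len(set(line)) != len(line):
            raise SchemeError(f"{name}: residue repeated within class {line!r}")
        classes.append((line, frozenset(line)))
    if not classes:
        raise SchemeError(f"{name}: no classes defined")
    return GroupingScheme(name, tuple(classes))


def load_scheme(source: Union[str, "os.PathLike"]) -> GroupingScheme:
    """Load a grouping scheme by built-in name (US, GS0..GS4) or file path.

    Scheme files are plain text, one class per line as concatenated residue
    letters, with ``#`` comments.
    """
    key = str(source).upper()
    if key == "US":
        return ungrouped_scheme()
    if key in _BUILTIN_FILES:
        text = (
            resources.files("caap").joinpath("data/schemes", _BUILTIN_FILES[key])
        ).read_text()
        return _parse_scheme_text(key, text)
    with open(source) as fh:
        text = fh.read()
    name = str(source).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return _parse_scheme_text(name, text)


def recode(residue: str, scheme: GroupingScheme) -> int:
    """Class index of a residue under a scheme."""
    return scheme.class_of(residue)


def recode_column(column: Iterable[str], scheme: GroupingScheme) -> np.ndarray:
    """Class-index vector for an alignment column."""
    return np.array([scheme.class_of(c) for c in column], dtype=np.int64)


def make_random_scheme(
    template: GroupingScheme, seed: int, name: str = "shuffled"
) -> GroupingScheme:
    """Shuffle the 20 residues between the template's classes.

    A uniformly random permutation of the residues is dealt back into classes
    of the template's sizes, giving a size-preserving randomised control
    partition. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    residues = list(AMINO_ACIDS)
    rng.shuffle(residues)
    classes = []
    pos = 0
    for size in template.class_sizes:
        members = residues[pos : pos + size]
        classes.append(("".join(sorted(members)), frozenset(members)))
        pos += size
    return GroupingScheme(name, tuple(classes))


# ---------------------------------------------------------------------------
# Event classification


class EventClass(enum.Enum):
    NONE = "none"
    EXCLUSIVE_STATE = "exclusive_state"
    STATE_AND_PROPERTY = "state_and_property"
    EXCLUSIVE_PROPERTY = "exclusive_property"

    def is_property_convergence(self) -> bool:
        return self in (EventClass.STATE_AND_PROPERTY, EventClass.EXCLUSIVE_PROPERTY)


@dataclass(frozen=True)
class PairEvent:
    """Ancestral→derived residues for a pair of branches at one site."""

    anc_a: str
    der_a: str
    anc_b: str
    der_b: str

    def __post_init__(self):
        for aa in (self.anc_a, self.der_a, self.anc_b, self.der_b):
            if aa not in AA_INDEX:
                raise SchemeError(f"non-canonical residue {aa!r} in event")


def classify_event(event: PairEvent, scheme: GroupingScheme) -> EventClass:
    """Classify a pair of per-branch substitutions at one site.

    State convergence: both derived residues identical and each differs from
    its own ancestor. Property convergence: both derived classes identical
    and each differs from its own ancestral class.
    """
    state = (
        event.der_a == event.der_b
        and event.der_a != event.anc_a
        and event.der_b != event.anc_b
    )
    ca, cb = scheme.class_of(event.der_a), scheme.class_of(event.der_b)
    prop = (
        ca == cb
        and ca != scheme.class_of(event.anc_a)
        and cb != scheme.class_of(event.anc_b)
    )
    if state and prop:
        return EventClass.STATE_AND_PROPERTY
    if state:
        return EventClass.EXCLUSIVE_STATE
    if prop:
        return EventClass.EXCLUSIVE_PROPERTY
    return EventClass.NONE
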