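"""Site-level topology for coarse-grained transporter models.

A :class:`SiteModel` plays the role a residue/atom topology plays in an
atomistic package: every interaction site (a C-alpha bead, a charged-group
bead, a tracer particle) carries a name, a structural domain label, an
optional helix label and a set of functional tags. Selections over these
fields use a small boolean mini-grammar (``"tag:acidic and domain:I"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Functional tags a site may carry.  ``gate_cyt``/``gate_mat`` mark the
#: cytoplasmic- and matrix-gate rings, ``acidic``/``basic`` the charged
#: groups of the matrix salt-bridge motif, ``tracer`` marks solvent
#: surrogate particles.
ALLOWED_TAGS = frozenset(
    {"gate_cyt", "gate_mat", "acidic", "basic", "hydrophobic", "tracer"}
)


class SelectionError(ValueError):
    """Raised for syntactically or semantically invalid selection strings."""


@dataclass(frozen=True)
class Site:
    """One interaction site."""

    site_id: int
    name: str
    domain: str
    helix: str | None = None
    group_tags: frozenset[str] = frozenset()
    mass: float = 1.0

    def __post_init__(self) -> None:
        bad = set(self.group_tags) - ALLOWED_TAGS
        if bad:
            raise ValueError(f"unknown group tags {sorted(bad)}")
        if self.mass <= 0:
            raise ValueError("site mass must be positive")


@dataclass
class SiteModel:
    """Ordered collection of sites; site_ids are contiguous from 0."""

    sites: list[Site] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, s in enumerate(self.sites):
            if s.site_id != i:
                raise ValueError(
                    f"site_ids must be contiguous from 0; site {i} has id {s.site_id}"
                )

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __getitem__(self, i: int) -> Site:
        return self.sites[i]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sites]

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.sites], dtype=float)

    def with_sites_appended(self, new_sites: Iterable[Site]) -> "SiteModel":
        """Return a new SiteModel with extra sites renumbered after the last."""
        sites = list(self.sites)
        for s in new_sites:
            sites.append(
                Site(
                    site_id=len(sites),
                    name=s.name,
                    domain=s.domain,
                    helix=s.helix,
                    group_tags=s.group_tags,
                    mass=s.mass,
                )
            )
        return SiteModel(sites)

    def indices_with_tag(self, tag: str) -> np.ndarray:
        if tag not in ALLOWED_TAGS:
            raise SelectionError(f"unknown tag {tag!r}")
        return np.array(
            [s.site_id for s in self.sites if tag in s.group_tags], dtype=int
        )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sites": [
                {
                    "site_id": s.site_id,
                    "name": s.name,
                    "domain": s.domain,
                    "helix": s.helix,
                    "group_tags": sorted(s.group_tags),
                    "mass": s.mass,
                }
                for s in self.sites
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteModel":
        return cls(
            [
                Site(
                    site_id=e["site_id"],
                    name=e["name"],
                    domain=e["domain"],
                    helix=e.get("helix"),
                    group_tags=frozenset(e.get("group_tags", ())),
                    mass=e.get("mass", 1.0),
                )
                for e in d["sites"]
            ]
        )


# ---------------------------------------------------------------------------
# Selection mini-grammar
#
#   expr    := term ("or" term)*
#   term    := factor ("and" factor)*
#   factor  := "not" factor | "(" expr ")" | atom
#   atom    := field ":" value        field in {name, domain, helix, tag}
#
# Values support a trailing/leading "*" glob.  Matching is case-sensitive.
# ---------------------------------------------------------------------------

_FIELDS = ("name", "domain", "helix", "tag")


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    token = ""
    for ch in expression:
        if ch in "()":
            if token:
                out.append(token)
                token = ""
            out.append(ch)
        elif ch.isspace():
            if token:
                out.append(token)
                token = ""
        else:
            token += ch
    if token:
        out.append(token)
    return out


def _match_value(actual: str | None, pattern: str) -> bool:
    if actual is None:
        return False
    if pattern == "*":
        return True
    if pattern.endswith("*"):
        return actual.startswith(pattern[:-1])
    if pattern.startswith("*"):
        return actual.endswith(pattern[1:])
    return actual == pattern


class _Parser:
    def __init__(self, tokens: list[str], topology: SiteModel):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens near {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.atom()

    def atom(self) -> np.ndarray:
        tok = self.next()
        if ":" not in tok:
            raise SelectionError(f"expected field:value, got {tok!r}")
        fieldname, _, value = tok.partition(":")
        if fieldname not in _FIELDS:
            raise SelectionError(
                f"unknown selection field {fieldname!r}; use one of {_FIELDS}"
            )
        if not value:
            raise SelectionError(f"empty value in {tok!r}")
        sites = self.top.sites
        if fieldname == "tag":
            if "*" not in value and value not in ALLOWED_TAGS:
                raise SelectionError(f"unknown tag {value!r}")
            return np.array(
                [any(_match_value(t, value) for t in s.group_tags) for s in sites],
                dtype=bool,
            )
        getter = {
            "name": lambda s: s.name,
            "domain": lambda s: s.domain,
            "helix": lambda s: s.helix,
        }[fieldname]
        return np.array(
            [_match_value(getter(s), value) for s in sites], dtype=bool
        )


def select(topology: SiteModel, expression: str) -> np.ndarray:
    """Evaluate a selection expression, returning ascending site indices.

    Parameters
    ----------
    topology
        The topology to select over.
    expression
        Boolean expression over ``name:``, ``domain:``, ``helix:`` and
        ``tag:`` atoms combined with ``and``/``or``/``not`` and parentheses.

    Returns
    -------
    numpy.ndarray of int
        Sorted, deterministic site indices.  May be empty.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology).parse()
    return np.flatnonzero(mask)


def resolve_selection(
    topology: SiteModel, selection: str | Sequence[int] | np.ndarray | None
) -> np.ndarray:
    """Normalize a selection (string, index sequence, or None=all) to indices."""
    if selection is None:
        return np.arange(topology.n_sites)
    if isinstance(selection, str):
        return select(topology, selection)
    idx = np.asarray(selection, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= topology.n_sites):
        raise SelectionError("selection indices out of range")
    return np.unique(idx)
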