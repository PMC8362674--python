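"""Cocktail / expert-system engine for formalized vegetation classification.

Formal definitions are boolean formulas (AND/OR/NOT) over three condition
types evaluated on one relevé at a time:

* ``TC(group) > t``  — combined (total) cover of a species group's members,
  combined under the independence formula, exceeds ``t`` percent;
* ``SC(group) > t``  — the highest cover of any single member exceeds ``t``;
* ``COV(taxon) > t`` — the cover of one particular species exceeds ``t``;
* ``SOC(group)``     — a sociological species group is "present": at least
  half its members (rounded up, overridable per group) occur.

Definitions hang on the nodes of a class -> alliance -> association tree and
classification is unequivocal: a relevé is assigned at a rank only if
exactly one definition of that rank matches; on a multi-match the relevé
falls back to the deepest rank with a unique match and the conflict is
recorded.  A relevé assigned to an association is also counted in the
parent alliance and the class.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .releve_io import Releve, ReleveTable, combine_covers, name_key

__all__ = [
    "SpeciesGroup",
    "GroupRegistry",
    "FormalDefinition",
    "Syntaxon",
    "SyntaxonHierarchy",
    "ClassificationResult",
    "DefinitionError",
    "classify",
    "classify_table",
    "default_hierarchy",
    "load_groups",
    "max_single_cover",
    "parse_definition",
    "sociological_presence",
    "total_cover",
]

RANKS = ("class", "alliance", "association")


class DefinitionError(ValueError):
    """Bad group definitions or formula syntax."""


@dataclass(frozen=True)
class SpeciesGroup:
    """A named species list of kind TC (total cover), SC (highest single
    cover) or SOC (sociological presence)."""

    name: str
    kind: str  # "TC" | "SC" | "SOC"
    members: tuple[str, ...]
    min_members: int | None = None  # SOC only; default ceil(|members| / 2)

    def __post_init__(self) -> None:
        if self.kind not in ("TC", "SC", "SOC"):
            raise DefinitionError(f"group {self.name!r}: unknown kind {self.kind!r}")
        if not self.members:
            raise DefinitionError(f"group {self.name!r}: no members")
        keys = [name_key(m) for m in self.members]
        if len(set(keys)) != len(keys):
            raise DefinitionError(f"group {self.name!r}: duplicate members")

    @property
    def member_keys(self) -> frozenset[str]:
        return frozenset(name_key(m) for m in self.members)


class GroupRegistry:
    """Case-insensitive lookup of species groups by name."""

    def __init__(self, groups: Iterable[SpeciesGroup] = ()) -> None:
        self._groups: dict[str, SpeciesGroup] = {}
        for g in groups:
            key = name_key(g.name)
            if key in self._groups:
                raise DefinitionError(f"duplicate group name {g.name!r}")
            self._groups[key] = g

    def __getitem__(self, name: str) -> SpeciesGroup:
        try:
            return self._groups[name_key(name)]
        except KeyError:
            raise DefinitionError(f"unknown species group {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name_key(name) in self._groups

    def __iter__(self):
        return iter(self._groups.values())

    def __len__(self) -> int:
        return len(self._groups)


def load_groups(path: str | Path | None = None) -> GroupRegistry:
    """Load species groups from YAML (packaged groups when *path* is None)."""
    if path is None:
        text = (resources.files("vegclass.data") / "species_groups.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    groups = [
        SpeciesGroup(
            name=entry["name"],
            kind=entry["kind"],
            members=tuple(entry["members"]),
            min_members=entry.get("min_members"),
        )
        for entry in raw["groups"]
    ]
    return GroupRegistry(groups)


# --------------------------------------------------------------------------
# Group operators


def _covers(releve: Releve) -> dict[str, float]:
    """Layer-combined cover per taxon matching key, cached on the relevé."""
    cache = getattr(releve, "_cover_cache", None)
    if cache is None:
        cache = {name_key(t): c for t, c in releve.species_covers().items()}
        releve.__dict__["_cover_cache"] = cache
    return cache


def total_cover(releve: Releve, group: SpeciesGroup) -> float:
    """Combined cover (percent) of a #TC group's members present."""
    covers = _covers(releve)
    present = [covers[k] for k in group.member_keys if k in covers]
    return 100.0 * combine_covers(present) if present else 0.0


def max_single_cover(releve: Releve, group: SpeciesGroup) -> float:
    """Highest single-member cover (percent) of an #SC group, 0 if none."""
    covers = _covers(releve)
    present = [covers[k] for k in group.member_keys if k in covers]
    return 100.0 * max(present) if present else 0.0


def sociological_presence(
    releve: Releve, group: SpeciesGroup, min_members: int | None = None
) -> bool:
    """True iff at least *min_members* members occur (default: half the
    group, rounded up)."""
    if min_members is None:
        min_members = (
            group.min_members
            if group.min_members is not None
            else math.ceil(len(group.members) / 2)
        )
    covers = _covers(releve)
    count = sum(1 for k in group.member_keys if k in covers)
    return count >= min_members


# --------------------------------------------------------------------------
# Formula AST


@dataclass(frozen=True)
class _Node:
    def evaluate(self, releve: Releve) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class GroupCover(_Node):
    group: SpeciesGroup
    op: str  # ">" | ">="
    threshold: float

    def evaluate(self, releve: Releve) -> bool:
        value = (
            total_cover(releve, self.group)
            if self.group.kind == "TC"
            else max_single_cover(releve, self.group)
        )
        return value > self.threshold if self.op == ">" else value >= self.threshold


@dataclass(frozen=True)
class SpeciesCover(_Node):
    taxon: str
    op: str
    threshold: float

    def evaluate(self, releve: Releve) -> bool:
        value = 100.0 * _covers(releve).get(name_key(self.taxon), 0.0)
        return value > self.threshold if self.op == ">" else value >= self.threshold


@dataclass(frozen=True)
class GroupPresence(_Node):
    group: SpeciesGroup
    min_members: int | None = None

    def evaluate(self, releve: Releve) -> bool:
        return sociological_presence(releve, self.group, self.min_members)


@dataclass(frozen=True)
class Not(_Node):
    child: _Node

    def evaluate(self, releve: Releve) -> bool:
        return not self.child.evaluate(releve)


@dataclass(frozen=True)
class And(_Node):
    children: tuple[_Node, ...]

    def evaluate(self, releve: Releve) -> bool:
        return all(c.evaluate(releve) for c in self.children)


@dataclass(frozen=True)
class Or(_Node):
    children: tuple[_Node, ...]

    def evaluate(self, releve: Releve) -> bool:
        return any(c.evaluate(releve) for c in self.children)


@dataclass(frozen=True)
class FormalDefinition:
    """A parsed membership formula."""

    text: str
    root: _Node

    def evaluate(self, releve: Releve) -> bool:
        return self.root.evaluate(releve)


# --------------------------------------------------------------------------
# Parser
#
# expr  := or ; or := and ("OR" and)* ; and := unary ("AND" unary)*
# unary := "NOT" unary | "(" expr ")" | atom
# atom  := ("TC"|"SC") "(" name ")" cmp number
#        | "COV" "(" name ")" cmp number
#        | "SOC" "(" name ")"
# Names may contain spaces and run to the closing parenthesis.

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<kw>AND|OR|NOT)\b|(?P<func>TC|SC|COV|SOC)\s*\((?P<name>[^()]*)\)"
    r"|(?P<op>>=|>)|(?P<num>\d+(?:\.\d+)?)|(?P<lpar>\()|(?P<rpar>\)))",
    re.IGNORECASE,
)


def _tokenize(text: str) -> list[tuple[str, object, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        if text[pos:].strip() == "":
            break
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise DefinitionError(f"syntax error at position {pos}: {text[pos:pos+20]!r}")
        if m.group("kw"):
            tokens.append((m.group("kw").upper(), None, m.start()))
        elif m.group("func"):
            tokens.append(
                ("FUNC", (m.group("func").upper(), m.group("name").strip()), m.start())
            )
        elif m.group("op"):
            tokens.append(("CMP", m.group("op"), m.start()))
        elif m.group("num"):
            tokens.append(("NUM", float(m.group("num")), m.start()))
        elif m.group("lpar"):
            tokens.append(("LPAR", None, m.start()))
        else:
            tokens.append(("RPAR", None, m.start()))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list, groups: GroupRegistry) -> None:
        self.tokens = tokens
        self.groups = groups
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self) -> tuple:
        if self.i >= len(self.tokens):
            raise DefinitionError("unexpected end of formula")
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expr(self) -> _Node:
        children = [self.and_()]
        while self.peek() == "OR":
            self.next()
            children.append(self.and_())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def and_(self) -> _Node:
        children = [self.unary()]
        while self.peek() == "AND":
            self.next()
            children.append(self.unary())
        return children[0] if len(children) == 1 else And(tuple(children))

    def unary(self) -> _Node:
        kind = self.peek()
        if kind == "NOT":
            self.next()
            return Not(self.unary())
        if kind == "LPAR":
            self.next()
            node = self.expr()
            tok = self.next()
            if tok[0] != "RPAR":
                raise DefinitionError(f"expected ')' at position {tok[2]}")
            return node
        return self.atom()

    def atom(self) -> _Node:
        kind, value, pos = self.next()
        if kind != "FUNC":
            raise DefinitionError(f"expected a condition at position {pos}")
        func, name = value
        if func == "SOC":
            return GroupPresence(self._group(name, ("SOC",)))
        op_tok = self.next()
        if op_tok[0] != "CMP":
            raise DefinitionError(f"expected '>' or '>=' at position {op_tok[2]}")
        num_tok = self.next()
        if num_tok[0] != "NUM":
            raise DefinitionError(f"expected a threshold at position {num_tok[2]}")
        threshold = num_tok[1]
        if not 0.0 <= threshold <= 100.0:
            raise DefinitionError(f"threshold {threshold} outside [0, 100]")
        if func == "COV":
            return SpeciesCover(name, op_tok[1], threshold)
        return GroupCover(self._group(name, (func,)), op_tok[1], threshold)

    def _group(self, name: str, kinds: tuple[str, ...]) -> SpeciesGroup:
        group = self.groups[name]
        if group.kind not in kinds:
            raise DefinitionError(
                f"group {name!r} has kind {group.kind}, expected {'/'.join(kinds)}"
            )
        return group


def parse_definition(text: str, groups: GroupRegistry) -> FormalDefinition:
    """Parse a formula string against a group registry."""
    parser = _Parser(_tokenize(text), groups)
    root = parser.expr()
    if parser.i != len(parser.tokens):
        tok = parser.tokens[parser.i]
        raise DefinitionError(f"trailing input at position {tok[2]}")
    return FormalDefinition(text=text, root=root)


# --------------------------------------------------------------------------
# Hierarchy and classification


@dataclass(frozen=True)
class Syntaxon:
    name: str
    rank: str
    parent: str | None
    definition: FormalDefinition | None


class SyntaxonHierarchy:
    """Rooted class -> alliance -> association tree with formal definitions."""

    def __init__(self, nodes: Iterable[Syntaxon]) -> None:
        self.nodes: dict[str, Syntaxon] = {}
        for node in nodes:
            if node.rank not in RANKS:
                raise DefinitionError(f"{node.name!r}: unknown rank {node.rank!r}")
            if node.name in self.nodes:
                raise DefinitionError(f"duplicate syntaxon name {node.name!r}")
            self.nodes[node.name] = node
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0].rank != "class":
            raise DefinitionError("hierarchy must have exactly one class root")
        self.root = roots[0]
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise DefinitionError(
                    f"{node.name!r}: unknown parent {node.parent!r}"
                )

    def at_rank(self, rank: str) -> list[Syntaxon]:
        """Nodes of a rank, name-sorted for deterministic evaluation."""
        return sorted(
            (n for n in self.nodes.values() if n.rank == rank),
            key=lambda n: n.name,
        )

    def ancestors(self, name: str) -> list[Syntaxon]:
        out, node = [], self.nodes[name]
        while node.parent is not None:
            node = self.nodes[node.parent]
            out.append(node)
        return out

    @classmethod
    def from_yaml(
        cls, path: str | Path | None = None, groups: GroupRegistry | None = None
    ) -> "SyntaxonHierarchy":
        """Load a definition file (packaged reconstructed set when None)."""
        if path is None:
            text = (resources.files("vegclass.data") / "definitions.yaml").read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if groups is None:
            gf = raw.get("groups_file")
            if gf is not None and path is not None:
                groups = load_groups(Path(path).parent / gf)
            else:
                groups = load_groups()
        nodes = []
        for entry in raw["syntaxa"]:
            formula = entry.get("formula")
            nodes.append(
                Syntaxon(
                    name=entry["name"],
                    rank=entry["rank"],
                    parent=entry.get("parent"),
                    definition=(
                        parse_definition(formula, groups) if formula else None
                    ),
                )
            )
        return cls(nodes)


def default_hierarchy() -> SyntaxonHierarchy:
    """The packaged, reconstructed expert-system definition set."""
    return SyntaxonHierarchy.from_yaml()


@dataclass(frozen=True)
class ClassificationResult:
    """Per-plot assignment at each rank; unassigned ranks are None."""

    plot_id: str
    klass: str | None = None
    alliance: str | None = None
    association: str | None = None
    conflict: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.association is not None and self.alliance is None:
            raise DefinitionError("association assigned without alliance")
        if self.alliance is not None and self.klass is None:
            raise DefinitionError("alliance assigned without class")

    @property
    def deepest(self) -> str | None:
        return self.association or self.alliance or self.klass


def classify(releve: Releve, hierarchy: SyntaxonHierarchy) -> ClassificationResult:
    """Unequivocally classify one relevé against the hierarchy.

    Association definitions are evaluated first; exactly one match assigns
    the association and its ancestors.  Zero matches fall through to the
    alliance rank, then the class.  Two or more matches at a rank record a
    conflict and also fall through (the deepest rank with a unique match
    wins).
    """
    conflict: tuple[str, ...] = ()
    for rank in ("association", "alliance"):
        matches = [
            n for n in hierarchy.at_rank(rank)
            if n.definition is not None and n.definition.evaluate(releve)
        ]
        if len(matches) == 1:
            node = matches[0]
            anc = {a.rank: a.name for a in hierarchy.ancestors(node.name)}
            return ClassificationResult(
                plot_id=releve.plot_id,
                klass=anc.get("class", node.name if node.rank == "class" else None),
                alliance=(
                    node.name if rank == "alliance" else anc.get("alliance")
                ),
                association=node.name if rank == "association" else None,
                conflict=conflict,
            )
        if len(matches) > 1 and not conflict:
            conflict = tuple(n.name for n in matches)
    root = hierarchy.root
    if root.definition is not None and root.definition.evaluate(releve):
        return ClassificationResult(
            plot_id=releve.plot_id, klass=root.name, conflict=conflict
        )
    return ClassificationResult(plot_id=releve.plot_id, conflict=conflict)


def classify_table(
    table: ReleveTable, hierarchy: SyntaxonHierarchy
) -> tuple[list[ClassificationResult], dict]:
    """Classify every plot; return results plus summary counts.

    The summary mirrors the usual reporting style: per-node totals (a relevé
    assigned to an association also counts for its alliance and the class)
    and per-rank exclusive counts (association-level, alliance-only,
    class-only, unassigned).
    """
    results = [classify(rel, hierarchy) for rel in table]
    by_node = {name: 0 for name in hierarchy.nodes}
    by_rank = {
        "association": 0,
        "alliance_only": 0,
        "class_only": 0,
        "unassigned": 0,
        "conflicts": 0,
    }
    for res in results:
        for name in (res.klass, res.alliance, res.association):
            if name is not None:
                by_node[name] += 1
        if res.association is not None:
            by_rank["association"] += 1
        elif res.alliance is not None:
            by_rank["alliance_only"] += 1
        elif res.klass is not None:
            by_rank["class_only"] += 1
        else:
            by_rank["unassigned"] += 1
        if res.conflict:
            by_rank["conflicts"] += 1
    return results, {"by_node": by_node, "by_rank": by_rank}
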