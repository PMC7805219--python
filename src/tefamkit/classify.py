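"""Unranked TE classification tree with path-string semantics.

A classification is the ';'-joined concatenation of node names along the
path from the root — e.g. ``Interspersed_Repeat;Unknown``.  Node names may
repeat in different subtrees (labels are reusable), so resolution always
uses the full path; a partial path (prefix of a longer one) resolves to the
corresponding internal node, allowing partial classifications.  The tree is
deliberately unranked: no class/order/family levels exist anywhere in the
API or serialization.

Cross-system aliases map nodes to the RepeatMasker, Repbase, Wicker-et-al.
and Curcio-Derbyshire labels where an equivalent exists.  The shipped tree
is a curated skeleton spanning the major eukaryotic TE divisions (class I
LTR/LINE/SINE/..., class II cut-and-paste / rolling-circle /
self-synthesizing, plus non-TE categories); users can load their own.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

from .errors import FormatError, LookupFailure, ParameterError

SUPPORTED_SYSTEMS = ("repeatmasker", "repbase", "wicker", "curcio_derbyshire")
_NAME_RE = re.compile(r"^[^\s;]+$")


@dataclass
class ClassificationNode:
    """One node of the classification tree."""

    name: str
    parent: Optional["ClassificationNode"] = None
    aliases: dict[str, str] = field(default_factory=dict)
    children: list["ClassificationNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name and not _NAME_RE.match(self.name):
            raise FormatError(
                f"illegal node name {self.name!r}: no whitespace or ';' allowed"
            )
        for system in self.aliases:
            if system not in SUPPORTED_SYSTEMS:
                raise FormatError(f"unknown classification system {system!r}")

    @property
    def path(self) -> str:
        """Full ';'-joined path from the root (empty for the virtual root)."""
        parts = []
        node = self
        while node is not None and node.name:
            parts.append(node.name)
            node = node.parent
        return ";".join(reversed(parts))

    def walk(self) -> Iterator["ClassificationNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def __repr__(self) -> str:
        return f"ClassificationNode({self.path!r})"


class ClassificationTree:
    """The tree plus path resolution and cross-system mapping."""

    def __init__(self, root: ClassificationNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[int] = set()
        for node in self.root.walk():
            if id(node) in seen:
                raise FormatError("classification tree contains a cycle")
            seen.add(id(node))
            names = [c.name for c in node.children]
            dupes = {n for n in names if names.count(n) > 1}
            if dupes:
                raise FormatError(
                    f"duplicate sibling names {sorted(dupes)} under "
                    f"{node.path or '<root>'!r}"
                )

    def resolve(self, path: str) -> ClassificationNode:
        """Resolve a full or partial ';'-path; '' resolves to the virtual root."""
        node = self.root
        if path == "":
            return node
        walked = []
        for name in path.split(";"):
            nxt = next((c for c in node.children if c.name == name), None)
            if nxt is None:
                prefix = ";".join(walked)
                raise LookupFailure(
                    f"cannot resolve {path!r}; nearest valid prefix: {prefix!r}"
                )
            walked.append(name)
            node = nxt
        return node

    def map_label(self, node: ClassificationNode, system: str) -> Optional[str]:
        """The equivalent label in another classification system, or None."""
        if system not in SUPPORTED_SYSTEMS:
            raise ParameterError(
                f"unknown system {system!r}; supported: {SUPPORTED_SYSTEMS}"
            )
        return node.aliases.get(system)

    def find_by_alias(self, label: str, system: str) -> list[ClassificationNode]:
        """All nodes whose alias in ``system`` equals ``label``."""
        if system not in SUPPORTED_SYSTEMS:
            raise ParameterError(f"unknown system {system!r}")
        return [n for n in self.root.walk() if n.aliases.get(system) == label]

    def nodes(self) -> list[ClassificationNode]:
        return list(self.root.walk())

    def __len__(self) -> int:
        return sum(1 for _ in self.root.walk()) - 1  # virtual root excluded


def _build(spec: dict, parent: Optional[ClassificationNode]) -> ClassificationNode:
    node = ClassificationNode(
        name=spec.get("name", ""),
        parent=parent,
        aliases=dict(spec.get("aliases", {})),
    )
    for child_spec in spec.get("children", []):
        node.children.append(_build(child_spec, node))
    return node


def load_tree(config=None) -> ClassificationTree:
    """Load a classification tree from a JSON config (or the shipped default).

    The config is a nested ``{"name": ..., "aliases": {...}, "children":
    [...]}`` structure under a virtual root with an empty name.  Duplicate
    sibling names and alias systems outside the supported four are rejected.
    """
    if config is None:
        text = resources.files("tefamkit.data").joinpath("classification.json").read_text()
    else:
        text = Path(config).read_text()
    try:
        spec = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"classification config is not valid JSON: {exc}") from exc
    root = _build(spec, None)
    if root.name:
        # allow configs whose top node is a real category: wrap in virtual root
        virtual = ClassificationNode(name="")
        virtual.children = [root]
        root.parent = virtual
        root = virtual
    return ClassificationTree(root)
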