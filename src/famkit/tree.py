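"""Phylogenetic tree container and Newick serialization.

The tree type is deliberately small: parent/child links, optional branch
lengths, optional integer bootstrap support on internal edges.  The Newick
parser is a recursive-descent scanner that reports the character offset of
any syntax error; internal-node labels that look like integers are stored as
bootstrap support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from .errors import NewickParseError, PhyloError


@dataclass
class TreeNode:
    """One node of a (rooted representation of a) phylogenetic tree."""

    label: Optional[str] = None
    length: Optional[float] = None
    support: Optional[int] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = field(default=None, repr=False, compare=False)

    # -- construction -----------------------------------------------------
    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    # -- traversal --------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> Optional["TreeNode"]:
        for node in self.walk():
            if node.label == label:
                return node
        return None

    def copy(self) -> "TreeNode":
        node = TreeNode(label=self.label, length=self.length, support=self.support)
        for child in self.children:
            node.add_child(child.copy())
        return node

    # -- comparison -------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, as the side excluding the
        lexicographically smallest leaf (canonical for unrooted comparison)."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path-length matrix (sum of branch lengths)."""
        import itertools

        dists: dict[tuple[str, str], float] = {}

        def depths(node, acc):
            out = {}
            if node.is_leaf:
                out[node.label] = acc
            for c in node.children:
                out.update(depths(c, acc + (c.length or 0.0)))
            return out

        for node in self.walk():
            for c1, c2 in itertools.combinations(node.children, 2):
                d1 = depths(c1, c1.length or 0.0)
                d2 = depths(c2, c2.length or 0.0)
                for a, da in d1.items():
                    for b, db in d2.items():
                        key = (a, b) if a < b else (b, a)
                        dists[key] = da + db
        return dists

    # -- rendering --------------------------------------------------------
    def to_newick(self) -> str:
        return _serialize(self) + ";"

    def ascii(self) -> str:
        """Plain-text rendering for logs."""
        lines: list[str] = []

        def draw(node: TreeNode, prefix: str, is_last: bool):
            connector = "" if node.parent is None else ("`-- " if is_last else "|-- ")
            label = node.label or ""
            if node.support is not None:
                label = f"{label}[{node.support}]" if label else f"[{node.support}]"
            lines.append(prefix + connector + (label or "+"))
            child_prefix = prefix if node.parent is None else (
                prefix + ("    " if is_last else "|   "))
            for i, child in enumerate(node.children):
                draw(child, child_prefix, i == len(node.children) - 1)

        draw(self, "", True)
        return "\n".join(lines)


def _serialize(node: TreeNode) -> str:
    if node.is_leaf:
        body = node.label or ""
    else:
        body = "(" + ",".join(_serialize(c) for c in node.children) + ")"
        if node.support is not None:
            body += str(node.support)
        elif node.label:
            body += node.label
    if node.length is not None:
        body += f":{node.length:.6f}"
    return body


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def next(self) -> str:
        c = self.peek()
        self.pos += 1
        return c

    def skip_ws(self):
        # note: peek() returns "" at end of input, and "" is a substring of
        # any string — the explicit truthiness check prevents an infinite loop
        while self.peek() and self.peek() in " \t\r\n":
            self.pos += 1

    def fail(self, message: str):
        raise NewickParseError(message, self.pos)


_LABEL_END = set("(),:;")


def parse_newick(text: str) -> TreeNode:
    """Parse one Newick tree; raises :class:`NewickParseError` with the
    character offset of the first problem."""
    sc = _Scanner(text)
    sc.skip_ws()
    if not sc.peek():
        sc.fail("empty Newick string")
    root = _parse_subtree(sc)
    sc.skip_ws()
    if sc.peek() != ";":
        sc.fail("expected ';' at end of tree")
    sc.next()
    return root


def _parse_subtree(sc: _Scanner) -> TreeNode:
    sc.skip_ws()
    node = TreeNode()
    if sc.peek() == "(":
        sc.next()
        while True:
            node.add_child(_parse_subtree(sc))
            sc.skip_ws()
            c = sc.peek()
            if c == ",":
                sc.next()
                continue
            if c == ")":
                sc.next()
                break
            sc.fail("expected ',' or ')'")
        label = _parse_label(sc)
        if label:
            if label.isdigit():
                node.support = int(label)
            else:
                node.label = label
    else:
        label = _parse_label(sc)
        if not label:
            sc.fail("expected a leaf label")
        node.label = label
    sc.skip_ws()
    if sc.peek() == ":":
        sc.next()
        node.length = _parse_number(sc)
    return node


def _parse_label(sc: _Scanner) -> str:
    sc.skip_ws()
    start = sc.pos
    while sc.peek() and sc.peek() not in _LABEL_END and sc.peek() not in " \t\r\n":
        sc.next()
    return sc.text[start:sc.pos]


def _parse_number(sc: _Scanner) -> float:
    sc.skip_ws()
    start = sc.pos
    while sc.peek() and (sc.peek().isdigit() or sc.peek() in "+-.eE"):
        sc.next()
    token = sc.text[start:sc.pos]
    try:
        return float(token)
    except ValueError:
        sc.pos = start
        sc.fail(f"invalid branch length {token!r}")


def read_newick(path) -> TreeNode:
    text = Path(path).read_text()
    return parse_newick(text)


def write_newick(tree: TreeNode, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
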