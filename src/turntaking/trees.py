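"""Penn-style bracketed parse trees: parsing, serialization, and the two
syntactic complexity measures (tree height, clause count).

A tree is an ordered labeled tree whose category nodes are
:class:`TreeNode` objects; terminal word strings are plain ``str`` leaves,
so ``(S (NP (PRP I)))`` is S → NP → PRP → "I" with three category nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Union

__all__ = ["TreeNode", "TreeParseError", "parse_bracketed_tree", "tree_to_string",
           "tree_height", "count_clauses"]


class TreeParseError(ValueError):
    """Malformed bracketing; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass
class TreeNode:
    label: str
    children: List[Union["TreeNode", str]] = field(default_factory=list)

    def category_children(self) -> List["TreeNode"]:
        return [c for c in self.children if isinstance(c, TreeNode)]

    def terminals(self) -> List[str]:
        out: List[str] = []
        for c in self.children:
            if isinstance(c, str):
                out.append(c)
            else:
                out.extend(c.terminals())
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TreeNode):
            return NotImplemented
        return self.label == other.label and self.children == other.children


def parse_bracketed_tree(text: str) -> TreeNode:
    """Parse one S-expression like ``(S (NP (PRP I)) (VP (VBP agree)))``.

    Raises :class:`TreeParseError` with a character offset on unbalanced
    or malformed input.
    """
    stack: List[TreeNode] = []
    root: TreeNode | None = None
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "(":
            j = i + 1
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            label = text[i + 1:j]
            if not label:
                raise TreeParseError("empty node label", i)
            node = TreeNode(label)
            if stack:
                stack[-1].children.append(node)
            elif root is not None:
                raise TreeParseError("multiple top-level trees", i)
            stack.append(node)
            i = j
        elif ch == ")":
            if not stack:
                raise TreeParseError("unbalanced ')'", i)
            node = stack.pop()
            if not stack:
                root = node
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            if not stack:
                raise TreeParseError("terminal outside brackets", i)
            stack[-1].children.append(text[i:j])
            i = j
    if stack:
        raise TreeParseError("unbalanced '(': tree not closed", n)
    if root is None:
        raise TreeParseError("empty input", 0)
    return root


def tree_to_string(node: TreeNode) -> str:
    """Serialize back to single-line bracketed form (inverse of the parser)."""
    parts = [tree_to_string(c) if isinstance(c, TreeNode) else c for c in node.children]
    if parts:
        return "(" + node.label + " " + " ".join(parts) + ")"
    return "(" + node.label + ")"


def _max_category_path(node: TreeNode) -> int:
    """Node count on the deepest root-to-leaf path through category nodes."""
    kids = node.category_children()
    if not kids:
        return 1
    return 1 + max(_max_category_path(c) for c in kids)


def tree_height(node: TreeNode) -> int:
    """Maximum number of nodes between the root and any tip.

    Terminal word strings are not counted; the root itself is excluded
    except for a single-node tree, so ``(S)`` has height 1 and
    ``(S (NP (PRP I)))`` has height 2 (NP, PRP).
    """
    return max(1, _max_category_path(node) - 1)


def count_clauses(node: TreeNode, label: str = "S") -> int:
    """Number of nodes with the exact label ``S`` (clause nodes)."""
    n = 1 if node.label == label else 0
    return n + sum(count_clauses(c, label) for c in node.category_children())
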