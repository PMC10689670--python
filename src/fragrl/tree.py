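"""Similarity-driven balanced binary tree over a fragment library.

Trees are built bottom-up in strict rounds: within each round the two most
similar trees are merged (inter-tree similarity = the maximum pairwise
fragment similarity between their member sets) until at most one unpaired
tree remains, which is promoted unchanged to the next round.  Rounds repeat
until a single tree spans the library, so the tree stays balanced to within
one level.

Each fragment's code is its root-to-leaf path: a left branch appends ``"1"``,
a right branch ``"0"``.  Similar fragments end up as near siblings and share
code prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fragmentation import FragmentLibrary, SimilarityMatrix

__all__ = ["TreeNode", "FragmentTree", "DecodeError", "build_balanced_tree",
           "encode_fragment", "decode_code"]

_TOL = 1e-12  # similarity comparison tolerance before tie-breaking


class DecodeError(KeyError):
    pass


@dataclass
class TreeNode:
    node_id: int
    fragment_ref: int | None = None          # leaves only
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    member_set: frozenset[int] = field(default_factory=frozenset)

    @property
    def is_leaf(self) -> bool:
        return self.fragment_ref is not None

    def to_json(self) -> dict:
        if self.is_leaf:
            return {"id": self.node_id, "fragment": self.fragment_ref}
        return {
            "id": self.node_id,
            "left": self.left.to_json(),
            "right": self.right.to_json(),
        }


@dataclass
class FragmentTree:
    root: TreeNode
    codes: dict[int, str]

    def to_json(self) -> dict:
        return {"root": self.root.to_json(),
                "codes": {str(k): v for k, v in self.codes.items()}}

    @classmethod
    def from_json(cls, obj: dict) -> "FragmentTree":
        counter = [0]

        def parse(rec: dict) -> TreeNode:
            counter[0] += 1
            if "fragment" in rec:
                return TreeNode(rec["id"], fragment_ref=rec["fragment"],
                                member_set=frozenset({rec["fragment"]}))
            left, right = parse(rec["left"]), parse(rec["right"])
            return TreeNode(rec["id"], left=left, right=right,
                            member_set=left.member_set | right.member_set)

        return cls(root=parse(obj["root"]),
                   codes={int(k): v for k, v in obj["codes"].items()})

    @property
    def code_length(self) -> int:
        """Length of the longest code (0 for a single-leaf tree)."""
        return max((len(c) for c in self.codes.values()), default=0)


def build_balanced_tree(lib: FragmentLibrary, sim: SimilarityMatrix) -> FragmentTree:
    """Greedy round-based pairing of the most similar trees.

    Deterministic: similarities equal within 1e-12 are tie-broken by the
    lexicographically smallest (min member index, max member index) pair; on a
    merge the operand containing the smaller minimum library index becomes the
    left child.
    """
    n = len(lib)
    if n == 0:
        raise ValueError("empty library")
    if len(sim) != n:
        raise ValueError(f"similarity matrix is {len(sim)}x{len(sim)}, library has {n}")

    next_id = [0]

    def new_node(**kw) -> TreeNode:
        node = TreeNode(next_id[0], **kw)
        next_id[0] += 1
        return node

    forest = [new_node(fragment_ref=i, member_set=frozenset({i})) for i in range(n)]

    def tree_sim(a: TreeNode, b: TreeNode) -> float:
        return max(sim.values[i, j] for i in a.member_set for j in b.member_set)

    def tie_key(a: TreeNode, b: TreeNode) -> tuple[int, int]:
        ma, mb = min(a.member_set), min(b.member_set)
        return (min(ma, mb), max(ma, mb))

    while len(forest) > 1:
        unpaired = list(forest)
        merged: list[TreeNode] = []
        while len(unpaired) >= 2:
            best = None
            for i in range(len(unpaired)):
                for j in range(i + 1, len(unpaired)):
                    s = tree_sim(unpaired[i], unpaired[j])
                    key = tie_key(unpaired[i], unpaired[j])
                    if best is None or s > best[0] + _TOL or (
                        abs(s - best[0]) <= _TOL and key < best[1]
                    ):
                        best = (s, key, i, j)
            _, _, i, j = best
            a, b = unpaired[i], unpaired[j]
            if min(b.member_set) < min(a.member_set):
                a, b = b, a
            node = new_node(left=a, right=b, member_set=a.member_set | b.member_set)
            merged.append(node)
            for k in sorted((i, j), reverse=True):
                unpaired.pop(k)
        if unpaired:  # odd leftover: promote the tree with the lowest min index
            merged.append(min(unpaired, key=lambda t: min(t.member_set)))
        forest = merged

    root = forest[0]
    codes: dict[int, str] = {}

    def walk(node: TreeNode, prefix: str):
        if node.is_leaf:
            codes[node.fragment_ref] = prefix
            return
        walk(node.left, prefix + "1")
        walk(node.right, prefix + "0")

    walk(root, "")
    return FragmentTree(root=root, codes=codes)


def encode_fragment(tree: FragmentTree, frag_index: int) -> str:
    try:
        return tree.codes[frag_index]
    except KeyError:
        raise DecodeError(f"fragment index {frag_index} has no code") from None


def decode_code(tree: FragmentTree, code: str) -> int:
    """Walk the code from the root; errors if it stops early or walks off."""
    node = tree.root
    for bit in code:
        if node.is_leaf:
            raise DecodeError(f"code {code!r} walks past a leaf")
        node = node.left if bit == "1" else node.right
    if not node.is_leaf:
        raise DecodeError(f"code {code!r} stops at an internal node")
    return node.fragment_ref
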