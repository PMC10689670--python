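"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem


def max_common_connected_atoms(smiles1: str, smiles2: str) -> int:
    """Heavy-atom count of the maximum common connected subgraph.

    McGregor-style exhaustive growth of an atom correspondence: atoms match on
    element only, and every newly added pair must be joined to the current
    mapping by a bond present in BOTH molecules (bond order ignored).  This is
    the atom-maximal MCS definition.
    """
    m1 = Chem.MolFromSmiles(smiles1)
    m2 = Chem.MolFromSmiles(smiles2)

    def graph(m):
        els = [a.GetSymbol() for a in m.GetAtoms()]
        adj = {i: set() for i in range(m.GetNumAtoms())}
        for b in m.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            adj[i].add(j)
            adj[j].add(i)
        return els, adj

    els1, adj1 = graph(m1)
    els2, adj2 = graph(m2)
    n1, n2 = len(els1), len(els2)
    best = 0
    seen: set[frozenset] = set()

    def extend(mapping: dict[int, int]):
        nonlocal best
        key = frozenset(mapping.items())
        if key in seen:
            return
        seen.add(key)
        best = max(best, len(mapping))
        if len(mapping) == min(n1, n2):
            return
        used2 = set(mapping.values())
        for u1, u2 in mapping.items():
            for a1 in adj1[u1]:
                if a1 in mapping:
                    continue
                for a2 in adj2[u2]:
                    if a2 in used2 or els1[a1] != els2[a2]:
                        continue
                    mapping[a1] = a2
                    extend(mapping)
                    del mapping[a1]

    for a1 in range(n1):
        for a2 in range(n2):
            if els1[a1] == els2[a2]:
                extend({a1: a2})
    return best


def intdiv_bruteforce(fps, p: int) -> float:
    """Double-loop internal diversity over explicit fingerprint pairs."""
    from rdkit import DataStructs

    n = len(fps)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += DataStructs.TanimotoSimilarity(fps[i], fps[j]) ** p
    return 1.0 - (total / n**2) ** (1.0 / p)


def gate_bruteforce(profile_dict: dict, ranges_dict: dict) -> bool:
    """Independent per-bound check of the property gate."""
    for key, (lo, hi) in ranges_dict.items():
        v = profile_dict.get(key)
        if v is None or v < lo or v > hi:
            return False
    return True


def transformer_block_oracle(x, WQ, WK, WV, WO, W1, b1, W2, b2,
                             ln1_g, ln1_b, ln2_g, ln2_b, d_p):
    """Step-by-step single-head encoder block in plain NumPy."""

    def softmax_rows(a):
        e = np.exp(a - a.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    def layernorm(a, g, b, eps=1e-6):
        mu = a.mean(axis=-1, keepdims=True)
        var = ((a - mu) ** 2).mean(axis=-1, keepdims=True)
        return (a - mu) / np.sqrt(var + eps) * g + b

    Q, K, V = x @ WQ, x @ WK, x @ WV
    A = softmax_rows(Q @ K.T / np.sqrt(d_p)) @ V
    mh = A @ WO
    h = layernorm(x + mh, ln1_g, ln1_b)
    ffn = np.maximum(0.0, h @ W1 + b1) @ W2 + b2
    return layernorm(h + ffn, ln2_g, ln2_b)


def frechet_1d(mu1, var1, mu2, var2) -> float:
    """Scalar closed form: (mu1-mu2)^2 + v1 + v2 - 2 sqrt(v1 v2)."""
    return (mu1 - mu2) ** 2 + var1 + var2 - 2.0 * np.sqrt(var1 * var2)
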