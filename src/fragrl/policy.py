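"""Transformer-DNN actor and critic over fragment-decomposed molecule states.

A state is embedded as two token sequences: every fragment (code embedding +
position embedding) and the scaffold subset (ring/linker positions only).
Each sequence runs through its own small transformer encoder; the mean-pooled
features are concatenated and fed to a feed-forward trunk with three heads:

* position head  - which fragment position to replace,
* replacement head - which library fragment to put there (per position),
* value head     - the critic's scalar state value.

Replacement candidates whose attachment-point count cannot host the bonds at
the chosen position get exactly zero probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .assembly import MoleculeState
from .fragmentation import FragmentLibrary
from .nn import Adam, Tensor, concat, layer_norm, relu, softmax
from .tree import FragmentTree

__all__ = [
    "TransformerParams",
    "EncodedFeatures",
    "ActionDistribution",
    "CriticValue",
    "embed_state",
    "transformer_encode",
    "actor_forward",
    "critic_forward",
    "sample_action",
    "DegenerateStateError",
]

_PAD = 2  # code-bit vocabulary: 0, 1, pad


class DegenerateStateError(ValueError):
    """State offers no replaceable position."""


@dataclass
class EncodedFeatures:
    fragment_features: Tensor          # (l1, d_f)
    scaffold_features: Tensor | None   # (l2, d_f) or None when no scaffold tokens
    attention: list[np.ndarray]        # last block's per-head attention weights


@dataclass
class ActionDistribution:
    """Joint distribution over (position, replacement fragment)."""

    position_t: Tensor                 # (n_positions,)
    replacement_t: Tensor              # (n_positions, lib_size)

    @property
    def position_probs(self) -> np.ndarray:
        return self.position_t.data

    @property
    def replacement_probs(self) -> np.ndarray:
        return self.replacement_t.data

    def log_prob(self, position: int, fragment: int) -> Tensor:
        return (self.position_t[position]).log() + (
            self.replacement_t[position, fragment]
        ).log()

    def entropy(self) -> Tensor:
        """H(position) + sum_i p_i H(replacement | i), with 0 log 0 = 0."""
        eps = 1e-12
        p = self.position_t
        h_pos = -(p * (p + eps).log()).sum()
        r = self.replacement_t
        h_rep_rows = -(r * (r + eps).log()).sum(axis=1)
        return h_pos + (p * h_rep_rows).sum()


@dataclass
class CriticValue:
    value: float
    tensor: Tensor


class TransformerParams:
    """Hyperparameters plus the flat parameter store for actor and critic."""

    def __init__(
        self,
        lib_size: int,
        code_len: int,
        heads: int = 4,
        blocks: int = 2,
        d_f: int = 64,
        d_p: int = 16,
        head_layers: tuple[int, ...] = (128, 64),
        max_positions: int = 32,
        seed: int = 0,
    ):
        self.lib_size = lib_size
        self.code_len = max(code_len, 1)
        self.H = heads
        self.L = blocks
        self.d_f = d_f
        self.d_p = d_p
        self.head_layers = tuple(head_layers)
        self.max_positions = max_positions
        self.seed = seed
        self.params: dict[str, Tensor] = {}
        self._init(np.random.default_rng(seed))

    def _add(self, name: str, array: np.ndarray):
        self.params[name] = Tensor(array, requires_grad=True)

    def _init(self, rng):
        d_f, d_p, H = self.d_f, self.d_p, self.H

        def glorot(*shape):
            scale = np.sqrt(2.0 / (shape[-2] + shape[-1])) if len(shape) >= 2 else 0.1
            return rng.normal(0.0, scale, size=shape)

        for enc in ("frag", "scaf"):
            self._add(f"{enc}.code_emb", rng.normal(0, 0.1, (self.code_len, 3, d_f)))
            self._add(f"{enc}.pos_emb", rng.normal(0, 0.1, (self.max_positions, d_f)))
            for l in range(self.L):
                p = f"{enc}.block{l}"
                for h in range(H):
                    self._add(f"{p}.head{h}.WQ", glorot(d_f, d_p))
                    self._add(f"{p}.head{h}.WK", glorot(d_f, d_p))
                    self._add(f"{p}.head{h}.WV", glorot(d_f, d_p))
                self._add(f"{p}.WO", glorot(H * d_p, d_f))
                self._add(f"{p}.ln1.g", np.ones(d_f))
                self._add(f"{p}.ln1.b", np.zeros(d_f))
                self._add(f"{p}.W1", glorot(d_f, 4 * d_f))
                self._add(f"{p}.b1", np.zeros(4 * d_f))
                self._add(f"{p}.W2", glorot(4 * d_f, d_f))
                self._add(f"{p}.b2", np.zeros(d_f))
                self._add(f"{p}.ln2.g", np.ones(d_f))
                self._add(f"{p}.ln2.b", np.zeros(d_f))
        # DNN trunk on concat(mean frag, mean scaffold)
        widths = (2 * d_f,) + self.head_layers
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            self._add(f"trunk.W{i}", glorot(a, b))
            self._add(f"trunk.b{i}", np.zeros(b))
        top = widths[-1]
        self._add("pos_head.w", glorot(d_f, 1))
        self._add("pos_head.ctx", glorot(top, 1))
        self._add("rep_head.W", glorot(d_f, self.lib_size))
        self._add("rep_head.b", np.zeros(self.lib_size))
        self._add("critic.w", glorot(top, 1))
        self._add("critic.b", np.zeros(1))

    # -- persistence --------------------------------------------------------

    def hyperparams(self) -> dict:
        return {
            "lib_size": self.lib_size,
            "code_len": self.code_len,
            "heads": self.H,
            "blocks": self.L,
            "d_f": self.d_f,
            "d_p": self.d_p,
            "head_layers": list(self.head_layers),
            "max_positions": self.max_positions,
            "seed": self.seed,
        }

    @staticmethod
    def _npz_path(path: str) -> str:
        path = str(path)
        return path if path.endswith(".npz") else path + ".npz"

    def save(self, path: str):
        npz = self._npz_path(path)
        np.savez(npz, **{k: t.data for k, t in self.params.items()})
        with open(npz + ".json", "w") as fh:
            json.dump(self.hyperparams(), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "TransformerParams":
        npz = cls._npz_path(path)
        with open(npz + ".json") as fh:
            hp = json.load(fh)
        hp["head_layers"] = tuple(hp["head_layers"])
        obj = cls(**hp)
        arrays = np.load(npz)
        for k in obj.params:
            obj.params[k].data = arrays[k]
        return obj

    def make_optimizer(self, lr_actor: float, lr_critic: float) -> Adam:
        return Adam(self.params, lr=lr_actor, lr_overrides={"critic.": lr_critic})


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------


def _pad_code(code: str, code_len: int) -> np.ndarray:
    bits = [int(c) for c in code[:code_len]]
    return np.array(bits + [_PAD] * (code_len - len(bits)), dtype=int)


def embed_state(
    state: MoleculeState, tree: FragmentTree, params: TransformerParams
) -> tuple[Tensor, Tensor | None]:
    """Token sequences for the fragment-level and scaffold-level encoders."""
    n = len(state.fragments)
    if n > params.max_positions:
        raise ValueError(f"state has {n} fragments; max_positions={params.max_positions}")
    seqs = {}
    for enc, positions in (
        ("frag", range(n)),
        ("scaf", [i for i in range(n) if state.scaffold_mask[i]]),
    ):
        toks = []
        code_emb = params.params[f"{enc}.code_emb"]
        pos_emb = params.params[f"{enc}.pos_emb"]
        for i in positions:
            frag_idx = state.fragments[i]
            if frag_idx not in tree.codes:
                raise KeyError(f"fragment {frag_idx} has no tree code")
            bits = _pad_code(tree.codes[frag_idx], params.code_len)
            tok = code_emb[np.arange(params.code_len), bits].sum(axis=0) + pos_emb[i]
            toks.append(tok.reshape(1, -1))
        seqs[enc] = concat(toks, axis=0) if toks else None
    return seqs["frag"], seqs["scaf"]


def transformer_encode(
    tokens: Tensor, params: TransformerParams, encoder: str = "frag"
) -> EncodedFeatures:
    """Stack of multi-head attention + FFN blocks with residuals and layer norm."""
    if tokens is None or tokens.shape[0] == 0:
        raise ValueError("empty token sequence")
    x = tokens
    attention: list[np.ndarray] = []
    scale = 1.0 / np.sqrt(params.d_p)
    P = params.params
    for l in range(params.L):
        p = f"{encoder}.block{l}"
        heads = []
        attention = []
        for h in range(params.H):
            Q = x @ P[f"{p}.head{h}.WQ"]
            K = x @ P[f"{p}.head{h}.WK"]
            V = x @ P[f"{p}.head{h}.WV"]
            weights = softmax(Q @ K.T * scale, axis=-1)
            attention.append(weights.data.copy())
            heads.append(weights @ V)
        mh = concat(heads, axis=1) @ P[f"{p}.WO"]
        x = layer_norm(x + mh, P[f"{p}.ln1.g"], P[f"{p}.ln1.b"])
        ffn = relu(x @ P[f"{p}.W1"] + P[f"{p}.b1"]) @ P[f"{p}.W2"] + P[f"{p}.b2"]
        x = layer_norm(x + ffn, P[f"{p}.ln2.g"], P[f"{p}.ln2.b"])
    return EncodedFeatures(fragment_features=x, scaffold_features=None,
                           attention=attention)


def _trunk(params: TransformerParams, pooled: Tensor) -> Tensor:
    h = pooled
    for i in range(len(params.head_layers)):
        h = relu(h @ params.params[f"trunk.W{i}"] + params.params[f"trunk.b{i}"])
    return h


def _encode_both(state, tree, params):
    frag_toks, scaf_toks = embed_state(state, tree, params)
    enc_f = transformer_encode(frag_toks, params, "frag")
    feats_f = enc_f.fragment_features
    if scaf_toks is not None:
        feats_s = transformer_encode(scaf_toks, params, "scaf").fragment_features
        pooled_s = feats_s.mean(axis=0)
    else:
        pooled_s = Tensor(np.zeros(params.d_f))
    pooled = concat([feats_f.mean(axis=0), pooled_s], axis=0).reshape(1, -1)
    return feats_f, _trunk(params, pooled)


def arity_mask(state: MoleculeState, lib: FragmentLibrary) -> np.ndarray:
    """mask[i, f] = 1 if library fragment f can host position i's bonds."""
    arities = np.array([f.n_attachments for f in lib])
    mask = np.zeros((len(state.fragments), len(lib)))
    for i in range(len(state.fragments)):
        need = len(state.bonds_at(i))
        mask[i] = (arities >= need).astype(float)
    return mask


def actor_forward(
    state: MoleculeState,
    tree: FragmentTree,
    params: TransformerParams,
    lib: FragmentLibrary,
) -> ActionDistribution:
    if len(state.fragments) == 0:
        raise DegenerateStateError("state has no fragments")
    feats_f, trunk = _encode_both(state, tree, params)
    P = params.params
    pos_logits = (feats_f @ P["pos_head.w"]).reshape(-1) + (
        trunk @ P["pos_head.ctx"]
    ).reshape(-1)
    pos_probs = softmax(pos_logits.reshape(1, -1), axis=-1).reshape(-1)
    rep_logits = feats_f @ P["rep_head.W"] + P["rep_head.b"]
    mask = arity_mask(state, lib)
    # -1e9 drives masked logits to exactly zero probability after softmax
    rep_probs = softmax(rep_logits + Tensor((mask - 1.0) * 1e9), axis=-1)
    return ActionDistribution(position_t=pos_probs, replacement_t=rep_probs)


def critic_forward(
    state: MoleculeState, tree: FragmentTree, params: TransformerParams
) -> CriticValue:
    _, trunk = _encode_both(state, tree, params)
    v = (trunk @ params.params["critic.w"] + params.params["critic.b"]).reshape(())
    return CriticValue(value=float(v.data), tensor=v)


def sample_action(
    dist: ActionDistribution, rng: np.random.Generator
) -> tuple[int, int]:
    pos = int(rng.choice(len(dist.position_probs), p=_renorm(dist.position_probs)))
    frag = int(rng.choice(dist.replacement_probs.shape[1],
                          p=_renorm(dist.replacement_probs[pos])))
    return pos, frag


def _renorm(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, None)
    return p / p.sum()
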