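"""Generation-quality metrics.

validity / uniqueness / novelty over canonical structures, internal diversity

    IntDiv_p(G) = 1 - ( |G|^-2  sum_{m1,m2 in GxG} T(m1,m2)^p )^(1/p)

(power-mean reading, self-pairs included, T = Morgan-fingerprint Tanimoto),
cosine scaffold-frequency similarity over Bemis-Murcko frameworks, and the
Frechet distance between Gaussian moment summaries of feature activations

    d^2 = ||mu_G - mu_R||^2 + Tr(S_G + S_R - 2 (S_G S_R)^{1/2}).

The feature extractor is pluggable; the default is a folded Morgan-count
descriptor, a documented stand-in for learned network activations, so absolute
distance values are not comparable with published numbers that use those.
SA (synthetic accessibility, 1 easy .. 10 hard) and QED come from their
standard published implementations.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, DataStructs, QED
from rdkit.Chem import rdFingerprintGenerator

from .assembly import bemis_murcko_scaffold, check_validity, canonical_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "GenerationMetrics",
    "MorganCountFeaturizer",
    "validity_fraction",
    "uniqueness_fraction",
    "novelty_fraction",
    "internal_diversity",
    "scaffold_similarity",
    "frechet_distance",
    "sa_score",
    "qed_score",
    "evaluate_generation",
]


@dataclass
class GenerationMetrics:
    validity: float
    uniqueness: float
    novelty: float
    intdiv_p: dict[int, float]
    scaff_sim: float
    fcd: float

    def to_json(self) -> dict:
        return {
            "schema_version": 1,
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "intdiv": {str(p): v for p, v in self.intdiv_p.items()},
            "scaff_sim": self.scaff_sim,
            "fcd": self.fcd,
        }


def validity_fraction(gen: list[str]) -> float:
    if not gen:
        raise ValueError("empty molecule list")
    return sum(check_validity(s) for s in gen) / len(gen)


def _canonical_set(smiles: list[str]) -> list[str]:
    return [canonical_smiles(s) for s in smiles]


def uniqueness_fraction(gen_valid: list[str]) -> float:
    if not gen_valid:
        raise ValueError("empty molecule list")
    canon = _canonical_set(gen_valid)
    return len(set(canon)) / len(canon)


def novelty_fraction(gen_valid: list[str], training: list[str]) -> float:
    if not gen_valid:
        raise ValueError("empty molecule list")
    train_set = set(_canonical_set(training))
    canon = _canonical_set(gen_valid)
    return sum(c not in train_set for c in canon) / len(canon)


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _fingerprints(smiles: list[str]):
    return [_FP_GEN.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]


def internal_diversity(gen_valid: list[str], p: int = 1) -> float:
    """1 - p-th root of the mean of T^p over all ordered pairs incl. self."""
    if not gen_valid:
        raise ValueError("empty molecule list")
    fps = _fingerprints(gen_valid)
    n = len(fps)
    total = 0.0
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps)
        total += float(np.sum(np.asarray(sims) ** p))
    return 1.0 - (total / n**2) ** (1.0 / p)


def scaffold_similarity(gen: list[str], ref: list[str]) -> float:
    """Cosine similarity of Bemis-Murcko scaffold frequency vectors."""
    if not gen or not ref:
        raise ValueError("both sets must be non-empty")
    counts_g: dict[str, int] = {}
    counts_r: dict[str, int] = {}
    for smiles, counts in ((gen, counts_g), (ref, counts_r)):
        for s in smiles:
            scaf = bemis_murcko_scaffold(s)
            if scaf:
                counts[scaf] = counts.get(scaf, 0) + 1
    scaffolds = sorted(set(counts_g) | set(counts_r))
    if not scaffolds:
        logger.warning("both sets are scaffold-free; scaffold similarity := 0")
        return 0.0
    g = np.array([counts_g.get(s, 0) for s in scaffolds], dtype=float)
    r = np.array([counts_r.get(s, 0) for s in scaffolds], dtype=float)
    denom = np.linalg.norm(g) * np.linalg.norm(r)
    if denom == 0:
        return 0.0
    return float(g @ r / denom)


def frechet_distance(feats_g: np.ndarray, feats_r: np.ndarray) -> float:
    """Frechet distance between Gaussian summaries of two feature sets.

    The cross term Tr((S_G S_R)^1/2) is evaluated through the symmetric
    product  S_G^1/2 S_R S_G^1/2  whose eigenvalues are clipped at zero.
    """
    feats_g = np.asarray(feats_g, dtype=float)
    feats_r = np.asarray(feats_r, dtype=float)
    if not (np.all(np.isfinite(feats_g)) and np.all(np.isfinite(feats_r))):
        raise ValueError("non-finite features")
    if feats_g.shape[0] < 2 or feats_r.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors per set")
    mu_g, mu_r = feats_g.mean(axis=0), feats_r.mean(axis=0)
    sig_g = np.cov(feats_g, rowvar=False)
    sig_r = np.cov(feats_r, rowvar=False)
    sig_g = np.atleast_2d(sig_g)
    sig_r = np.atleast_2d(sig_r)

    def psd_sqrt(m: np.ndarray) -> np.ndarray:
        vals, vecs = np.linalg.eigh((m + m.T) / 2)
        vals = np.clip(vals, 0.0, None)
        return (vecs * np.sqrt(vals)) @ vecs.T

    root_g = psd_sqrt(sig_g)
    cross = psd_sqrt(root_g @ sig_r @ root_g)
    d2 = float(
        np.sum((mu_g - mu_r) ** 2)
        + np.trace(sig_g) + np.trace(sig_r) - 2.0 * np.trace(cross)
    )
    return max(d2, 0.0)


class MorganCountFeaturizer:
    """Deterministic stand-in feature extractor: folded Morgan counts."""

    def __init__(self, width: int = 64, radius: int = 2):
        self.width = width
        self.radius = radius

    def __call__(self, smiles: str) -> np.ndarray:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"invalid molecule: {smiles!r}")
        counts = np.zeros(self.width)
        info: dict = {}
        AllChem.GetMorganFingerprint(mol, self.radius, bitInfo=info)
        for bit, matches in info.items():
            counts[bit % self.width] += len(matches)
        return counts

    def batch(self, smiles: list[str]) -> np.ndarray:
        return np.stack([self(s) for s in smiles])


_sascorer = None


def _load_sascorer():
    global _sascorer
    if _sascorer is None:
        import os

        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer  # noqa: PLC0415

        _sascorer = sascorer
    return _sascorer


def sa_score(smiles: str) -> float:
    """Synthetic-accessibility score in [1, 10]; lower = easier."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    return float(_load_sascorer().calculateScore(mol))


def qed_score(smiles: str) -> float:
    """Drug-likeness desirability in [0, 1]."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    return float(QED.qed(mol))


def evaluate_generation(
    gen: list[str],
    ref: list[str],
    p_values: tuple[int, ...] = (1, 2),
    featurizer=None,
) -> GenerationMetrics:
    """Full metric record for a generated set against a reference set."""
    featurizer = featurizer or MorganCountFeaturizer()
    valid = [s for s in gen if check_validity(s)]
    validity = validity_fraction(gen)
    if not valid:
        return GenerationMetrics(validity, 0.0, 0.0,
                                 {p: 0.0 for p in p_values}, 0.0, float("inf"))
    uniq = uniqueness_fraction(valid)
    nov = novelty_fraction(valid, ref)
    intdiv = {p: internal_diversity(valid, p) for p in p_values}
    scaff = scaffold_similarity(valid, ref)
    if len(valid) >= 2 and len(ref) >= 2:
        fcd = frechet_distance(featurizer.batch(valid), featurizer.batch(ref))
    else:
        fcd = float("nan")
    return GenerationMetrics(validity, uniq, nov, intdiv, scaff, fcd)
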