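"""Multi-objective reward: property gate, toxic-group screen, activity classifier.

The gate checks, with inclusive bounds, that every tracked property lies in its
configured range (defaults: MW 200-500 Da, logP 1.5-5.5, TPSA 40-120 A^2, at
most 2 toxicophore alerts).  Bioactivity is predicted by a classic perceptron
over three docking-derived features: docking score, heavy-atom count and their
ratio.

Note on ligand efficiency (LE): it is defined here as ``-score/heavy_atoms``
(more positive = better), the negation of the perceptron's ratio feature.  It
enters the gate only when docking is enabled and an LE range is configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .assembly import check_validity

__all__ = [
    "PropertyProfile",
    "PropertyRanges",
    "DockingFeatures",
    "ActivityClassifier",
    "RewardComponents",
    "RewardWeights",
    "DEFAULT_TOXICOPHORES",
    "compute_properties",
    "toxicophore_count",
    "property_gate",
    "docking_features",
    "train_perceptron",
    "total_reward",
]

# Small structural-alert screen (nitro, nitroso, azo, acyl halide, aldehyde,
# epoxide/aziridine, hydrazine, isocyanate).  Configurable; any SMARTS list
# can be supplied instead.
DEFAULT_TOXICOPHORES: tuple[str, ...] = (
    "[N+](=O)[O-]",
    "[NX2]=[OX1]",
    "N=N",
    "C(=O)[F,Cl,Br,I]",
    "[CX3H1](=O)[#6]",
    "C1OC1",
    "C1NC1",
    "[NX3][NX3]",
    "N=C=O",
)


@dataclass
class PropertyProfile:
    E: int                      # validity indicator {0, 1}
    MW: float | None = None
    logP: float | None = None
    PSA: float | None = None
    T: int | None = None        # toxicophore alert count
    LE: float | None = None     # ligand efficiency, set when docking is enabled

    def value(self, key: str):
        return getattr(self, key)


@dataclass
class PropertyRanges:
    """Inclusive [lower, upper] bound per property key."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "E": (1, 1),
            "MW": (200.0, 500.0),
            "logP": (1.5, 5.5),
            "PSA": (40.0, 120.0),
            "T": (0, 2),
        }
    )

    def __post_init__(self):
        for k, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"range for {k} has lower > upper: {lo} > {hi}")

    def in_range(self, key: str, value) -> bool:
        lo, hi = self.ranges[key]
        return value is not None and lo <= value <= hi


def _compiled_screen(screen) -> list:
    patterns = []
    for s in screen:
        patt = Chem.MolFromSmarts(s)
        if patt is None:
            raise ValueError(f"invalid substructure pattern: {s!r}")
        patterns.append(patt)
    return patterns


def toxicophore_count(smiles: str, screen=DEFAULT_TOXICOPHORES) -> int:
    """Number of distinct screen patterns matched (not match multiplicity)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    return sum(1 for patt in _compiled_screen(screen) if mol.HasSubstructMatch(patt))


def compute_properties(smiles: str, screen=DEFAULT_TOXICOPHORES) -> PropertyProfile:
    """Standard descriptor panel; E=0 and all else unset for invalid input."""
    if not check_validity(smiles):
        return PropertyProfile(E=0)
    mol = Chem.MolFromSmiles(smiles)
    return PropertyProfile(
        E=1,
        MW=Descriptors.MolWt(mol),
        logP=Crippen.MolLogP(mol),
        PSA=Descriptors.TPSA(mol),
        T=toxicophore_count(smiles, screen),
    )


def property_gate(profile: PropertyProfile, ranges: PropertyRanges) -> bool:
    """True iff every configured property is inside its inclusive bounds."""
    return all(profile.E == 1 and ranges.in_range(k, profile.value(k))
               for k in ranges.ranges)


# ---------------------------------------------------------------------------
# docking features and perceptron activity classifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DockingFeatures:
    score: float
    heavy_atoms: int
    ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([self.score, self.heavy_atoms, self.ratio], dtype=float)


def docking_features(score: float, heavy_atoms: int) -> DockingFeatures:
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return DockingFeatures(score=score, heavy_atoms=heavy_atoms,
                           ratio=score / heavy_atoms)


@dataclass
class ActivityClassifier:
    """Linear threshold unit: active iff w . z + b > 0 on standardized features."""

    weights: np.ndarray
    bias: float
    mean: np.ndarray
    std: np.ndarray

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    def predict(self, feats: DockingFeatures) -> bool:
        z = self._standardize(feats.as_array())
        return float(z @ self.weights + self.bias) > 0.0


def train_perceptron(
    samples: list[tuple[DockingFeatures, bool]],
    epochs: int = 100,
    learning_rate: float = 1.0,
    seed: int = 0,
) -> ActivityClassifier:
    """Classic perceptron on standardized features; deterministic under seed."""
    labels = {bool(lbl) for _, lbl in samples}
    if labels != {True, False}:
        raise ValueError("need both active and inactive samples")
    X = np.stack([f.as_array() for f, _ in samples])
    y = np.array([1.0 if lbl else -1.0 for _, lbl in samples])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 0.01, size=Z.shape[1])
    b = 0.0
    order = np.arange(len(y))
    for _ in range(epochs):
        rng.shuffle(order)
        mistakes = 0
        for i in order:
            if y[i] * (Z[i] @ w + b) <= 0:
                w = w + learning_rate * y[i] * Z[i]
                b = b + learning_rate * y[i]
                mistakes += 1
        if mistakes == 0:
            break
    return ActivityClassifier(weights=w, bias=b, mean=mean, std=std)


# ---------------------------------------------------------------------------
# reward composition
# ---------------------------------------------------------------------------


@dataclass
class RewardWeights:
    validity: float = 0.1
    per_property: float = 0.15
    gate: float = 0.2
    activity: float = 0.3


@dataclass
class RewardComponents:
    validity_reward: float
    property_reward: float
    activity_reward: float
    total: float
    gate_pass: bool


def total_reward(
    smiles: str,
    ranges: PropertyRanges | None = None,
    weights: RewardWeights | None = None,
    classifier: ActivityClassifier | None = None,
    feats: DockingFeatures | None = None,
    screen=DEFAULT_TOXICOPHORES,
    use_property_optimization: bool = True,
) -> RewardComponents:
    """Compose the per-molecule reward.

    Invalid molecules score exactly 0.  With ``use_property_optimization``
    off, only the validity term remains (ablation switch).  The activity term
    requires both a trained classifier and docking features.
    """
    ranges = ranges or PropertyRanges()
    weights = weights or RewardWeights()
    profile = compute_properties(smiles, screen)
    if profile.E == 0:
        return RewardComponents(0.0, 0.0, 0.0, 0.0, False)
    validity_reward = weights.validity
    property_reward = 0.0
    activity_reward = 0.0
    gate = False
    if use_property_optimization:
        gate = property_gate(profile, ranges)
        n_satisfied = sum(
            1 for k in ranges.ranges if ranges.in_range(k, profile.value(k))
        )
        property_reward = weights.per_property * n_satisfied
        if gate:
            property_reward += weights.gate
        if classifier is not None and feats is not None and classifier.predict(feats):
            activity_reward = weights.activity
    total = validity_reward + property_reward + activity_reward
    return RewardComponents(
        validity_reward=validity_reward,
        property_reward=property_reward,
        activity_reward=activity_reward,
        total=total,
        gate_pass=gate,
    )
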