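"""Physicochemical peptide descriptors and margin-based function classification.

Ten sequence-computable descriptors are used: length, average molecular
weight, net charge at pH 7 (Henderson-Hasselbalch over ionizable groups),
mean Kyte-Doolittle hydropathy, hydrogen-bond donor and acceptor counts,
N-H/O-H hydrogen counts (NHOH), nitrogen+oxygen atom counts (NO), aromatic
residue fraction and branched-chain (I/L/V) residue fraction.  Counts come
from fixed per-residue atom/group tables for the neutral peptide form
(free N-terminal amine, free C-terminal carboxylic acid).

Classification standardizes the descriptors, reduces them by PCA, and fits
a linear maximum-margin (support-vector) model; the data set is split 30%
training / 70% validation by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .synth import AMINO_ACIDS

__all__ = [
    "DESCRIPTOR_NAMES",
    "StandardizationParams",
    "ClassifierModel",
    "compute_descriptors",
    "describe_peptides",
    "standardize",
    "apply_standardization",
    "fit_classifier",
    "predict",
]

WATER_DA = 18.02

#: Average masses of the free amino acids (Da).
RESIDUE_MASS = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "E": 147.13, "Q": 146.15, "G": 75.07, "H": 155.15, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "E": -3.5, "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Side-chain heavy-atom and hydrogen tables (neutral form):
# (N atoms, O atoms, N-H/O-H hydrogens, donor atoms bearing >=1 H).
# The cysteine thiol counts as a donor (S-H) but not toward NHOH, which is
# an N-H/O-H hydrogen count only.
_SIDE_CHAIN = {
    "A": (0, 0, 0, 0), "R": (3, 0, 4, 3), "N": (1, 1, 2, 1),
    "D": (0, 2, 1, 1), "C": (0, 0, 0, 1), "E": (0, 2, 1, 1),
    "Q": (1, 1, 2, 1), "G": (0, 0, 0, 0), "H": (2, 0, 1, 1),
    "I": (0, 0, 0, 0), "L": (0, 0, 0, 0), "K": (1, 0, 2, 1),
    "M": (0, 0, 0, 0), "F": (0, 0, 0, 0), "P": (0, 0, 0, 0),
    "S": (0, 1, 1, 1), "T": (0, 1, 1, 1), "W": (1, 0, 1, 1),
    "Y": (0, 1, 1, 1), "V": (0, 0, 0, 0),
}

# side-chain pKa values (standard set) and termini
_PKA_POSITIVE = {"K": 10.53, "R": 12.48, "H": 6.0}
_PKA_NEGATIVE = {"D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.07}
_PKA_NTERM = 9.0
_PKA_CTERM = 2.0

_AROMATIC = set("FWY")
_BCAA = set("ILV")

DESCRIPTOR_NAMES = (
    "length", "mol_weight", "net_charge_ph7", "hydropathy_mean",
    "hbond_donors", "hbond_acceptors", "nhoh_count", "no_count",
    "aromatic_frac", "bcaa_frac",
)


def net_charge(sequence: str, ph: float = 7.0) -> float:
    """Net charge from Henderson-Hasselbalch partial protonation."""
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    for aa in sequence:
        if aa in _PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE[aa]))
        elif aa in _PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE[aa] - ph))
    return charge


def compute_descriptors(sequence: str) -> dict[str, float]:
    """Descriptor vector of a peptide sequence (length >= 2).

    Backbone bookkeeping: every residue contributes one amide/amine N and
    one carbonyl O; the C-terminus adds one hydroxyl O.  Amide N-H
    hydrogens exist for every backbone N not supplied by proline; the free
    N-terminal amine carries two hydrogens (one if the first residue is
    proline).  Acceptors are counted as all N+O atoms (Lipinski NO
    convention); donors as N/O atoms bearing at least one hydrogen.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("peptide length must be >= 2")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")

    mass = sum(RESIDUE_MASS[aa] for aa in sequence) - (n - 1) * WATER_DA
    sc = np.array([_SIDE_CHAIN[aa] for aa in sequence])
    sc_n, sc_o, sc_nhoh, sc_donor = sc.sum(axis=0)

    no_count = int(sc_n + sc_o) + n + n + 1  # backbone N, carbonyl O, C-term OH

    n_pro_internal = sum(1 for aa in sequence[1:] if aa == "P")
    nterm_h = 1 if sequence[0] == "P" else 2
    nhoh = int(sc_nhoh) + nterm_h + (n - 1 - n_pro_internal) + 1  # + C-term OH

    amide_donors = sum(1 for aa in sequence[1:] if aa != "P")
    donors = int(sc_donor) + 1 + amide_donors + 1  # N-term N + amide NHs + C-term OH

    return {
        "length": float(n),
        "mol_weight": float(mass),
        "net_charge_ph7": net_charge(sequence),
        "hydropathy_mean": float(np.mean([KYTE_DOOLITTLE[aa] for aa in sequence])),
        "hbond_donors": float(donors),
        "hbond_acceptors": float(no_count),
        "nhoh_count": float(nhoh),
        "no_count": float(no_count),
        "aromatic_frac": sum(aa in _AROMATIC for aa in sequence) / n,
        "bcaa_frac": sum(aa in _BCAA for aa in sequence) / n,
    }


def describe_peptides(peptides) -> pd.DataFrame:
    """Descriptor table (peptides x descriptors), indexed by sequence."""
    rows = {}
    for pep in peptides:
        try:
            rows[pep] = compute_descriptors(pep)
        except ValueError as exc:
            raise ValueError(f"peptide {pep!r}: {exc}") from exc
    return pd.DataFrame.from_dict(rows, orient="index")[list(DESCRIPTOR_NAMES)]


@dataclass
class StandardizationParams:
    feature_names: list
    means: np.ndarray
    sds: np.ndarray
    dropped: list = field(default_factory=list)


def standardize(train: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Zero-mean unit-SD scaling fit on training data.

    Constant features are dropped and recorded in the returned params.
    Apply once; re-applying to already standardized data rescales again.
    """
    if len(train) < 2:
        raise ValueError("standardize requires >= 2 rows")
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=0)
    kept = sds[sds > 0].index.tolist()
    dropped = [c for c in train.columns if c not in kept]
    if not kept:
        raise ValueError("all features are constant")
    params = StandardizationParams(
        feature_names=kept,
        means=means[kept].to_numpy(),
        sds=sds[kept].to_numpy(),
        dropped=dropped,
    )
    return apply_standardization(train, params), params


def apply_standardization(data: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    return (data[params.feature_names] - params.means) / params.sds


@dataclass
class ClassifierModel:
    """Linear max-margin classifier over standardized PCA scores.

    ``weights`` and ``bias`` act on the PCA scores; a decision score >= 0
    maps to ``positive_class`` (ties at the boundary break positive).
    """

    params: StandardizationParams
    pca_components: np.ndarray
    weights: np.ndarray
    bias: float
    classes: list
    positive_class: str
    split_ratio: float
    seed: int

    def decision_scores(self, descriptors: pd.DataFrame) -> np.ndarray:
        X = apply_standardization(descriptors, self.params).to_numpy(float)
        scores = X @ self.pca_components.T
        return scores @ self.weights + self.bias

    def to_json(self) -> str:
        payload = {
            "feature_names": self.params.feature_names,
            "means": self.params.means.tolist(),
            "sds": self.params.sds.tolist(),
            "dropped": self.params.dropped,
            "pca_components": self.pca_components.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "classes": self.classes,
            "positive_class": self.positive_class,
            "split_ratio": self.split_ratio,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        params = StandardizationParams(
            feature_names=d["feature_names"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            dropped=d["dropped"],
        )
        return cls(
            params=params,
            pca_components=np.asarray(d["pca_components"]),
            weights=np.asarray(d["weights"]),
            bias=float(d["bias"]),
            classes=d["classes"],
            positive_class=d["positive_class"],
            split_ratio=float(d["split_ratio"]),
            seed=int(d["seed"]),
        )


def fit_classifier(
    descriptors: pd.DataFrame,
    labels,
    split_ratio: float = 0.3,
    var_target: float = 0.8,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[ClassifierModel, dict]:
    """Fit the peptide-function classifier with a stratified random split.

    ``split_ratio`` is the training fraction (0.3 = 30% train / 70%
    validation).  Returns the model and validation metrics (accuracy,
    sensitivity, specificity; sensitivity is recall of the positive class).
    """
    y = pd.Series(list(labels))
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if y.value_counts().min() < 5:
        raise ValueError("each class needs >= 5 members")
    if not 0 < split_ratio < 1:
        raise ValueError("split_ratio must be in (0, 1)")

    X_train, X_val, y_train, y_val = train_test_split(
        descriptors, y, train_size=split_ratio, stratify=y, random_state=seed
    )
    Xs_train, params = standardize(X_train)
    n_comp = min(Xs_train.shape[0] - 1, Xs_train.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(Xs_train.to_numpy(float))
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = min(int(np.searchsorted(cum, var_target) + 1), n_comp)
    components = pca.components_[:n_keep]
    svc = SVC(kernel="linear", C=C)
    svc.fit(scores[:, :n_keep], y_train)
    # sklearn orders classes_ sorted; decision > 0 maps to classes_[1]
    positive_class = str(svc.classes_[1])
    model = ClassifierModel(
        params=params,
        pca_components=components,
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        classes=[str(c) for c in svc.classes_],
        positive_class=positive_class,
        split_ratio=split_ratio,
        seed=seed,
    )
    metrics = _binary_metrics(y_val.to_numpy(), predict(model, X_val)["label"].to_numpy(),
                              positive_class, classes)
    return model, metrics


def _binary_metrics(y_true, y_pred, positive_class, classes) -> dict:
    negative_class = next(c for c in classes if c != positive_class)
    pos = y_true == positive_class
    neg = y_true == negative_class
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "sensitivity": float(np.mean(y_pred[pos] == positive_class)) if pos.any() else math.nan,
        "specificity": float(np.mean(y_pred[neg] == negative_class)) if neg.any() else math.nan,
        "n_validation": int(len(y_true)),
    }


def predict(model: ClassifierModel, peptides_or_descriptors) -> pd.DataFrame:
    """Predict function labels with margin scores.

    Accepts a descriptor DataFrame or an iterable of peptide sequences.
    A margin score of exactly zero is assigned the positive class.
    """
    if isinstance(peptides_or_descriptors, pd.DataFrame):
        desc = peptides_or_descriptors
    else:
        desc = describe_peptides(peptides_or_descriptors)
    scores = model.decision_scores(desc)
    negative = next(c for c in model.classes if c != model.positive_class)
    labels = np.where(scores >= 0, model.positive_class, negative)
    return pd.DataFrame({"label": labels, "margin": scores}, index=desc.index)
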