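"""In silico gastrointestinal digestion and peptidome-based protein clustering.

A protein sequence is cleaved by rule tables describing each protease's
specificity over the P1 residue (immediately N-terminal of the scissile
bond) and the P1' residue (immediately C-terminal): the bond after a P1
residue is cut unless the P1' residue blocks it.  Six gastrointestinal
enzymes are registered: pepsin, trypsin, alpha-chymotrypsin, pancreatic
elastase, prolyl oligopeptidase and thimet oligopeptidase.

The peptide repertoire (multiset of released peptides with counts) is the
protein's "enzymatic fingerprint".  Per enzyme, pooled peptides are grouped
into a small number of sequence-composition categories; the per-protein
category counts form a feature matrix on which proteins are clustered
(standardize -> PCA -> k-means).  Repertoires are compared by weighted
Jaccard similarity (sum of elementwise minima over sum of maxima of the
count vectors).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .synth import AMINO_ACIDS

__all__ = [
    "EnzymeRule",
    "DigestionResult",
    "PeptidomeFeatureMatrix",
    "ClusterResult",
    "DEFAULT_REGISTRY",
    "default_registry",
    "load_registry",
    "cleave",
    "digest_gi",
    "categorize_peptides",
    "build_feature_matrix",
    "cluster_proteins",
    "repertoire_similarity",
]

_ALPHABET = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage specificity of one protease.

    The bond C-terminal of any residue in ``p1`` is cut unless the following
    residue is in ``p1_block``.  ``min_distance_from_ends`` suppresses sites
    too close to either terminus (used for the oligopeptidase rules, which
    act away from chain ends in this simplified model).
    """

    name: str
    p1: frozenset
    p1_block: frozenset = frozenset()
    min_distance_from_ends: int = 1

    def __post_init__(self) -> None:
        aas = set(AMINO_ACIDS)
        if not set(self.p1) <= aas or not set(self.p1_block) <= aas:
            raise ValueError(f"rule {self.name!r}: residue sets must be standard amino acids")
        if self.min_distance_from_ends < 1:
            raise ValueError("min_distance_from_ends must be >= 1")

    def cuts_after(self, sequence: str, i: int) -> bool:
        """True if the bond after 1-based position ``i`` is cleaved."""
        n = len(sequence)
        if i < self.min_distance_from_ends or i > n - self.min_distance_from_ends:
            return False
        if sequence[i - 1] not in self.p1:
            return False
        return sequence[i] not in self.p1_block


def _r(name, p1, block="", ends=1) -> EnzymeRule:
    return EnzymeRule(name=name, p1=frozenset(p1), p1_block=frozenset(block),
                      min_distance_from_ends=ends)


#: Simplified PeptideCutter-style specificities.  Users can substitute
#: stricter Keil rules via :func:`load_registry`.
DEFAULT_REGISTRY: dict[str, EnzymeRule] = {
    r.name: r
    for r in (
        _r("pepsin", "FLWY", "P"),             # pH > 2 preference, simplified
        _r("trypsin", "KR", "P"),
        _r("alpha-chymotrypsin", "FYW", "P"),  # high-specificity rule
        _r("pancreatic-elastase", "AVSGLI", "P"),
        _r("prolyl-oligopeptidase", "P", "P"),
        _r("thimet-oligopeptidase", "FLIV", "", ends=2),  # internal sites only
    )
}

_GASTRIC = ("pepsin",)
_PANCREATIC = ("trypsin", "alpha-chymotrypsin", "pancreatic-elastase",
               "prolyl-oligopeptidase", "thimet-oligopeptidase")


def default_registry() -> dict[str, EnzymeRule]:
    return dict(DEFAULT_REGISTRY)


def load_registry(path) -> dict[str, EnzymeRule]:
    """Load an enzyme rule registry from a YAML file.

    Schema: a mapping of enzyme name to ``{p1: "KR", p1_block: "P",
    min_distance_from_ends: 1}``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    registry = {}
    for name, entry in raw.items():
        registry[name] = _r(
            name,
            entry.get("p1", ""),
            entry.get("p1_block", ""),
            entry.get("min_distance_from_ends", 1),
        )
    return registry


@dataclass
class DigestionResult:
    """Peptide repertoire released from one protein.

    ``peptides`` maps (enzyme, sequence) -> count after length filtering;
    ``spans`` records every base fragment (enzyme, sequence, start, end)
    with 1-based inclusive coordinates on the parent, before filtering, so
    that span-ordered fragments reconstruct the parent.
    """

    protein_id: str
    enzymes: tuple
    peptides: Counter = field(default_factory=Counter)
    spans: list = field(default_factory=list)

    def counts(self) -> Counter:
        """Counts pooled over enzymes: sequence -> count."""
        pooled: Counter = Counter()
        for (_, seq), c in self.peptides.items():
            pooled[seq] += c
        return pooled

    def total_peptides(self) -> int:
        return sum(self.peptides.values())


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - _ALPHABET
    if bad:
        raise ValueError(f"illegal residues in sequence: {sorted(bad)}")


def _cut_positions(sequence: str, rules) -> list[int]:
    """Sorted 1-based positions i such that the bond after residue i is cut
    by at least one rule.  X never forms a cleavage site."""
    n = len(sequence)
    out = []
    for i in range(1, n):
        if sequence[i - 1] == "X" or sequence[i] == "X":
            continue
        if any(rule.cuts_after(sequence, i) for rule in rules):
            out.append(i)
    return out


def _fragments(sequence: str, cuts: list[int]) -> list[tuple[str, int, int]]:
    bounds = [0] + cuts + [len(sequence)]
    return [
        (sequence[a:b], a + 1, b)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def cleave(
    sequence: str,
    rule: EnzymeRule,
    missed_cleavages: int = 0,
    min_length: int = 2,
    protein_id: str = "protein",
) -> DigestionResult:
    """Digest a sequence with a single enzyme rule.

    Fragments shorter than ``min_length`` are dropped from the repertoire
    but kept in span bookkeeping.  With ``missed_cleavages`` = m, every
    concatenation of up to m+1 adjacent base fragments is added to the
    repertoire as well.
    """
    _validate_sequence(sequence)
    cuts = _cut_positions(sequence, [rule])
    base = _fragments(sequence, cuts)
    result = DigestionResult(protein_id=protein_id, enzymes=(rule.name,))
    result.spans = [(rule.name, frag, s, e) for frag, s, e in base]
    for m in range(missed_cleavages + 1):
        for j in range(len(base) - m):
            merged = "".join(f for f, _, _ in base[j : j + m + 1])
            if len(merged) >= min_length:
                result.peptides[(rule.name, merged)] += 1
    return result


def digest_gi(
    sequence: str,
    registry: dict[str, EnzymeRule] | None = None,
    mode: str = "sequential",
    missed_cleavages: int = 0,
    min_length: int = 2,
    protein_id: str = "protein",
) -> DigestionResult:
    """Digest a protein with the full gastrointestinal enzyme panel.

    sequential
        Gastric phase first (pepsin on the intact protein), then the five
        pancreatic/oligopeptidase rules act jointly on the gastric
        fragments; the final fragments carry a single ``gi`` provenance.
    independent
        Each enzyme digests the intact protein separately; repertoires are
        concatenated with per-enzyme provenance.
    """
    _validate_sequence(sequence)
    if registry is None:
        registry = DEFAULT_REGISTRY
    if not registry:
        raise ValueError("empty enzyme registry")
    missing = {n for n in _GASTRIC + _PANCREATIC} - set(registry)
    if missing:
        raise ValueError(f"registry missing enzymes: {sorted(missing)}")

    if mode == "independent":
        result = DigestionResult(protein_id=protein_id, enzymes=tuple(sorted(registry)))
        for name in sorted(registry):
            sub = cleave(sequence, registry[name], missed_cleavages, min_length, protein_id)
            result.peptides.update(sub.peptides)
            result.spans.extend(sub.spans)
        return result

    if mode != "sequential":
        raise ValueError(f"unknown digestion mode {mode!r}")

    gastric_rules = [registry[n] for n in _GASTRIC]
    pancreatic_rules = [registry[n] for n in _PANCREATIC]
    gastric_cuts = _cut_positions(sequence, gastric_rules)
    result = DigestionResult(protein_id=protein_id, enzymes=("gi",))
    for frag, start, _ in _fragments(sequence, gastric_cuts):
        sub_cuts = _cut_positions(frag, pancreatic_rules)
        base = _fragments(frag, sub_cuts)
        shifted = [(p, start + s - 1, start + e - 1) for p, s, e in base]
        result.spans.extend(("gi", p, s, e) for p, s, e in shifted)
        for m in range(missed_cleavages + 1):
            for j in range(len(base) - m):
                merged = "".join(f for f, _, _ in base[j : j + m + 1])
                if len(merged) >= min_length:
                    result.peptides[("gi", merged)] += 1
    return result


# ---------------------------------------------------------------------------
# categorization and clustering
# ---------------------------------------------------------------------------

_DIPEPTIDES = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=2)]
_DIPEPTIDE_INDEX = {d: i for i, d in enumerate(_DIPEPTIDES)}


def _dimer_embedding(peptides: list[str]) -> np.ndarray:
    """Length-normalized 2-mer composition vectors (400-dim)."""
    mat = np.zeros((len(peptides), 400))
    for r, pep in enumerate(peptides):
        n_dimers = len(pep) - 1
        if n_dimers < 1:
            continue
        for j in range(n_dimers):
            idx = _DIPEPTIDE_INDEX.get(pep[j : j + 2])
            if idx is not None:  # dimers containing X are skipped
                mat[r, idx] += 1.0
        mat[r] /= n_dimers
    return mat


def categorize_peptides(
    peptide_counts: Counter | dict,
    n_categories: int = 4,
    seed: int = 0,
) -> dict[str, int]:
    """Partition distinct peptides into composition categories.

    Peptides are embedded as length-normalized 2-mer composition vectors
    and grouped by count-weighted k-means.  Distinct peptides are processed
    in sorted order so the assignment is invariant to input order under a
    fixed seed.  Returns sequence -> category (0-based).
    """
    counts = dict(peptide_counts)
    distinct = sorted(counts)
    if len(distinct) < n_categories:
        raise ValueError(
            f"need at least {n_categories} distinct peptides, got {len(distinct)}"
        )
    emb = _dimer_embedding(distinct)
    weights = np.array([counts[p] for p in distinct], dtype=float)
    km = KMeans(n_clusters=n_categories, n_init=10, random_state=seed)
    labels = km.fit_predict(emb, sample_weight=weights)
    return {p: int(lab) for p, lab in zip(distinct, labels)}


@dataclass
class PeptidomeFeatureMatrix:
    """Proteins x (enzyme, category) count matrix with category definitions."""

    matrix: pd.DataFrame  # index: protein ids; columns: (enzyme, category)
    categories: dict  # enzyme -> {peptide: category}


@dataclass
class ClusterResult:
    labels: pd.Series  # per-protein cluster label, 1-based
    scores: np.ndarray  # PCA scores used for clustering
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    inertia: float
    seed: int


def build_feature_matrix(
    records,
    registry: dict[str, EnzymeRule] | None = None,
    mode: str = "independent",
    n_categories: int = 4,
    missed_cleavages: int = 0,
    min_length: int = 2,
    seed: int = 0,
) -> PeptidomeFeatureMatrix:
    """Digest every protein and build the enzyme x category feature matrix.

    ``records`` is an iterable of Biopython SeqRecords or ``(id, sequence)``
    pairs.  Per enzyme, that enzyme's peptides pooled over all proteins are
    categorized once; feature (enzyme, category) of a protein counts its
    peptides assigned to that category, so a protein's row sums to its total
    released peptide count.
    """
    pairs = []
    for rec in records:
        if isinstance(rec, tuple):
            pairs.append((rec[0], str(rec[1])))
        else:
            pairs.append((rec.id, str(rec.seq)))
    if len(pairs) < 2:
        raise ValueError("need at least 2 proteins")

    digests = {}
    for pid, seq in pairs:
        try:
            digests[pid] = digest_gi(seq, registry, mode, missed_cleavages,
                                     min_length, protein_id=pid)
        except ValueError as exc:
            raise ValueError(f"digestion failed for protein {pid!r}: {exc}") from exc

    enzymes = sorted({enz for d in digests.values() for (enz, _) in d.peptides})
    categories: dict = {}
    for enz in enzymes:
        pooled: Counter = Counter()
        for d in digests.values():
            for (e, pep), c in d.peptides.items():
                if e == enz:
                    pooled[pep] += c
        categories[enz] = categorize_peptides(pooled, n_categories, seed=seed)

    columns = [(enz, c) for enz in enzymes for c in range(n_categories)]
    data = np.zeros((len(pairs), len(columns)))
    col_index = {col: j for j, col in enumerate(columns)}
    for r, (pid, _) in enumerate(pairs):
        for (enz, pep), c in digests[pid].peptides.items():
            cat = categories[enz][pep]
            data[r, col_index[(enz, cat)]] += c
    matrix = pd.DataFrame(
        data,
        index=[pid for pid, _ in pairs],
        columns=pd.MultiIndex.from_tuples(columns, names=["enzyme", "category"]),
    )
    return PeptidomeFeatureMatrix(matrix=matrix, categories=categories)


def cluster_proteins(
    features: PeptidomeFeatureMatrix | pd.DataFrame,
    k: int,
    var_target: float = 0.8,
    seed: int = 0,
    row_normalize: bool = True,
) -> ClusterResult:
    """Cluster proteins on their peptidome category features.

    Rows are first divided by their sums (``row_normalize``) so that the
    repertoire's category composition, not the protein's size, carries the
    signal; columns are then standardized, PCA retains the fewest
    components explaining >= ``var_target`` of the variance, and k-means
    (10 restarts, best inertia) assigns labels.
    """
    mat = features.matrix if isinstance(features, PeptidomeFeatureMatrix) else features
    n = len(mat)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    X = mat.to_numpy(float)
    if row_normalize:
        sums = X.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError("protein with empty repertoire cannot be row-normalized")
        X = X / sums
    keep = X.std(axis=0) > 0
    X = StandardScaler().fit_transform(X[:, keep])
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, var_target) + 1)
    n_keep = min(n_keep, n_comp)
    scores = scores[:, :n_keep]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(scores)
    return ClusterResult(
        labels=pd.Series(labels + 1, index=mat.index, name="cluster"),
        scores=scores,
        loadings=pca.components_[:n_keep],
        explained_variance_ratio=pca.explained_variance_ratio_[:n_keep],
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
    )


def repertoire_similarity(a: DigestionResult | Counter, b: DigestionResult | Counter) -> float:
    """Weighted Jaccard similarity of two peptide repertoires.

    sum(min(count_a, count_b)) / sum(max(count_a, count_b)) over the union
    of peptide sequences; 1 for identical repertoires, 0 for disjoint ones.
    """
    ca = a.counts() if isinstance(a, DigestionResult) else Counter(a)
    cb = b.counts() if isinstance(b, DigestionResult) else Counter(b)
    if not ca and not cb:
        raise ValueError("both repertoires are empty")
    num = den = 0
    for pep in set(ca) | set(cb):
        x, y = ca.get(pep, 0), cb.get(pep, 0)
        num += min(x, y)
        den += max(x, y)
    return num / den
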