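"""Omics computations: TPM conversion, expression filtering, variance
partitioning, fuzzy c-means clustering and gene-metabolite correlation
networks.

TPM (transcripts per million) converts raw read counts ``N_i`` with gene
lengths ``L_i`` (bp) into length-normalized abundances

    TPM_i = (N_i / L_i) * 1e6 / sum_j (N_j / L_j)

per sample, so every sample column sums to one million.

Variance partitioning decomposes each gene's (log) expression over a
complete crossed tissue x individual design into tissue, individual and
residual variance components by the Henderson / ANOVA method of moments,
reported as non-negative fractions of their sum.

Fuzzy c-means is the classic alternating optimization of the weighted
within-cluster objective sum_ij u_ij^m d_ij^2 with memberships summing to
one per feature.

Correlation networks compute all gene x metabolite Spearman correlations
with tie-corrected t-approximation p-values and Benjamini-Hochberg FDR
control across all pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceDecomposition",
    "FuzzyClustering",
    "counts_to_tpm",
    "filter_and_transform",
    "variance_partition",
    "fuzzy_cmeans",
    "correlate_network",
]


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Convert a genes x samples count matrix to TPM.

    ``gene_lengths`` is in base pairs, indexed like ``counts``.  Raises if
    any sample column is all zero (its TPM would be undefined).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"gene lengths missing for {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    dead = totals[totals <= 0].index.tolist()
    if dead:
        raise ValueError(f"sample(s) with all-zero counts: {dead}")
    return rates.div(totals, axis=1) * 1e6


def filter_and_transform(
    tpm: pd.DataFrame, min_tpm: float = 1.0, min_fraction: float = 0.2
) -> pd.DataFrame:
    """Drop lowly expressed genes and log2-transform.

    Keeps genes with TPM >= ``min_tpm`` in at least ``min_fraction`` of
    samples, then returns log2(TPM + 1).
    """
    frac_expressed = (tpm >= min_tpm).mean(axis=1)
    kept = tpm[frac_expressed >= min_fraction]
    if kept.empty:
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    return np.log2(kept + 1.0)


@dataclass
class VarianceDecomposition:
    """Variance components and fractions per gene.

    ``fractions`` holds per-gene fractions (tissue, individual, residual)
    of the summed components; ``components`` the truncated per-gene
    variance-component estimates and ``raw_components`` the untruncated
    moment estimates (may be negative) used for pooled summaries.
    """

    fractions: pd.DataFrame  # columns: tissue, individual, residual
    components: pd.DataFrame  # same columns, truncated at 0
    raw_components: pd.DataFrame  # untruncated moment estimates

    def mean_fractions(self) -> pd.Series:
        """Average of the per-gene fractions.

        With few factor levels this ratio average is biased toward the
        residual; prefer :meth:`overall_fractions` as the dataset-level
        summary.
        """
        return self.fractions.mean(axis=0)

    def overall_fractions(self) -> pd.Series:
        """Pooled fractions: untruncated moment estimates summed across
        genes, truncated at zero once, then normalized.  This is the
        consistent method-of-moments aggregate (per-gene truncation before
        pooling would bias small components upward)."""
        pooled = self.raw_components.sum(axis=0).clip(lower=0.0)
        return pooled / pooled.sum()


def variance_partition(
    expression: pd.DataFrame,
    tissue,
    individual,
) -> VarianceDecomposition:
    """Partition per-gene expression variance into tissue, individual and
    residual components over a complete crossed design.

    ``expression`` is genes x samples (typically log2 TPM); ``tissue`` and
    ``individual`` are per-sample label vectors aligned with the columns.
    Components are estimated by the two-way random-effects ANOVA method of
    moments (one observation per tissue x individual cell; the interaction
    plus error forms the residual); negative component estimates are
    truncated to zero before renormalizing to fractions.
    """
    tissue = pd.Categorical(list(tissue))
    individual = pd.Categorical(list(individual))
    if len(tissue) != expression.shape[1] or len(individual) != expression.shape[1]:
        raise ValueError("label vectors must match the number of samples")
    a = len(tissue.categories)
    b = len(individual.categories)
    if a < 2 or b < 2:
        raise ValueError("need >= 2 tissues and >= 2 individuals")
    cell_counts = pd.crosstab(tissue, individual)
    if (cell_counts.to_numpy() != 1).any():
        raise ValueError(
            "variance partitioning requires a complete crossed design with "
            "exactly one sample per tissue x individual cell; observed cell "
            f"counts range {cell_counts.min().min()}..{cell_counts.max().max()}"
        )

    X = expression.to_numpy(float)  # genes x (a*b)
    t_idx = np.asarray(tissue.codes)
    i_idx = np.asarray(individual.codes)

    grand = X.mean(axis=1, keepdims=True)
    t_means = np.zeros((X.shape[0], a))
    i_means = np.zeros((X.shape[0], b))
    for t in range(a):
        t_means[:, t] = X[:, t_idx == t].mean(axis=1)
    for i in range(b):
        i_means[:, i] = X[:, i_idx == i].mean(axis=1)

    ss_t = b * ((t_means - grand) ** 2).sum(axis=1)
    ss_i = a * ((i_means - grand) ** 2).sum(axis=1)
    fitted = t_means[:, t_idx] + i_means[:, i_idx] - grand
    ss_e = ((X - fitted) ** 2).sum(axis=1)

    ms_t = ss_t / (a - 1)
    ms_i = ss_i / (b - 1)
    ms_e = ss_e / ((a - 1) * (b - 1))

    var_t = np.maximum((ms_t - ms_e) / b, 0.0)
    var_i = np.maximum((ms_i - ms_e) / a, 0.0)
    var_e = np.maximum(ms_e, 0.0)
    total = var_t + var_i + var_e
    total[total == 0] = np.nan  # constant genes: fractions undefined
    comps = np.column_stack([var_t, var_i, var_e])
    raw = np.column_stack([(ms_t - ms_e) / b, (ms_i - ms_e) / a, ms_e])
    frac = comps / total[:, None]
    cols = ["tissue", "individual", "residual"]
    return VarianceDecomposition(
        fractions=pd.DataFrame(frac, index=expression.index, columns=cols),
        components=pd.DataFrame(comps, index=expression.index, columns=cols),
        raw_components=pd.DataFrame(raw, index=expression.index, columns=cols),
    )


@dataclass
class FuzzyClustering:
    centers: np.ndarray  # c x n_samples pattern vectors
    membership: pd.DataFrame  # features x c, rows sum to 1
    m: float
    objective: float
    objective_history: list
    seed: int
    iterations: int

    def hard_labels(self) -> pd.Series:
        return self.membership.idxmax(axis=1)


def fuzzy_cmeans(
    matrix: pd.DataFrame,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    standardize_rows: bool = True,
) -> FuzzyClustering:
    """Fuzzy c-means clustering of feature rows (e.g. metabolites x samples).

    Rows are z-scored before clustering (the conventional preprocessing for
    abundance-pattern clustering) unless ``standardize_rows`` is False.
    Alternates the classic membership and center updates until the maximum
    center shift falls below ``tol``; the objective is checked to be
    non-increasing at every iteration.
    """
    X = matrix.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")
    n, _ = X.shape
    if c < 2 or c > n:
        raise ValueError(f"c must be in [2, {n}], got {c}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if standardize_rows:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError("constant rows cannot be z-scored; drop them first")
        X = (X - mu) / sd

    rng = np.random.default_rng(seed)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)

    def _objective(u, centers):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return float((u**m * d2).sum())

    centers = (u**m).T @ X / (u**m).sum(axis=0)[:, None]
    history = [_objective(u, centers)]
    for iteration in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        # exact-hit features get full membership on their nearest center
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        hit = ~np.isfinite(inv).all(axis=1)
        u = inv / inv.sum(axis=1, keepdims=True)
        if hit.any():
            u[hit] = 0.0
            u[hit, d2[hit].argmin(axis=1)] = 1.0
        if not np.allclose(u.sum(axis=1), 1.0, atol=1e-9):
            raise AssertionError("membership normalization violated")
        new_centers = (u**m).T @ X / (u**m).sum(axis=0)[:, None]
        obj = _objective(u, new_centers)
        if obj > history[-1] + 1e-8 * max(1.0, abs(history[-1])):
            raise AssertionError("fuzzy c-means objective increased")
        history.append(obj)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    membership = pd.DataFrame(
        u, index=matrix.index, columns=[f"cluster{j + 1}" for j in range(c)]
    )
    return FuzzyClustering(
        centers=centers,
        membership=membership,
        m=m,
        objective=history[-1],
        objective_history=history,
        seed=seed,
        iterations=iteration,
    )


def correlate_network(
    genes: pd.DataFrame,
    metabolites: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Spearman correlation between gene and metabolite rows.

    Both matrices are features x samples with matching columns.  Returns a
    tidy edge table (gene, metabolite, rho, p, q, significant) with
    Benjamini-Hochberg q-values over all tested pairs; constant rows are
    skipped and reported with NaN rho.
    """
    if list(genes.columns) != list(metabolites.columns):
        common = [c for c in genes.columns if c in set(metabolites.columns)]
        if len(common) < 4:
            raise ValueError("need >= 4 matched samples")
        genes = genes[common]
        metabolites = metabolites[common]
    n = genes.shape[1]
    if n < 4:
        raise ValueError("need >= 4 matched samples for rank correlation")

    G = stats.rankdata(genes.to_numpy(float), axis=1)
    M = stats.rankdata(metabolites.to_numpy(float), axis=1)
    g_ok = genes.to_numpy(float).std(axis=1) > 0
    m_ok = metabolites.to_numpy(float).std(axis=1) > 0

    Gc = G - G.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    g_norm = np.sqrt((Gc**2).sum(axis=1))
    m_norm = np.sqrt((Mc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Gc @ Mc.T) / np.outer(g_norm, m_norm)
    rho[~g_ok, :] = np.nan
    rho[:, ~m_ok] = np.nan
    rho = np.clip(rho, -1.0, 1.0)

    # two-sided p via the t approximation (tie correction enters through
    # average ranks in the Pearson-on-ranks formulation)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0

    gene_ids = np.repeat(genes.index.to_numpy(), metabolites.shape[0])
    met_ids = np.tile(metabolites.index.to_numpy(), genes.shape[0])
    edges = pd.DataFrame(
        {"gene": gene_ids, "metabolite": met_ids,
         "rho": rho.ravel(), "p": p.ravel()}
    )
    tested = edges["p"].notna()
    q = np.full(len(edges), np.nan)
    if tested.any():
        q[tested.to_numpy()] = stats.false_discovery_control(
            edges.loc[tested, "p"].to_numpy(), method="bh"
        )
    edges["q"] = q
    edges["significant"] = edges["q"] < q_threshold
    return edges
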