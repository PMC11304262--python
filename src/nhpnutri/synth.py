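"""Synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure the analysis assumes —
sex-stratified weight-for-age ratios, a depressed non-thriving subgroup,
serum-biochemistry group differences, protein families with distinct residue
compositions, separable peptide function classes, count matrices with known
tissue/individual variance fractions, and metabolite matrices with planted
cluster patterns — so that every downstream stage can be exercised and its
recovery properties tested without external data.

All generators take an explicit integer seed and are bit-reproducible.
Defaults mirror the cynomolgus-macaque reference cohort this toolkit was
built around: 857 males with weight-for-age ratio Normal(1.30, 0.34) kg/yr,
530 females Normal(1.12, 0.34), a flagged subgroup centred at WAZ -1.83,
and ages uniform on 2-10 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSpec",
    "BiochemGroupSpec",
    "ProteinFamilySpec",
    "PeptideLabelSpec",
    "OmicsSimSpec",
    "generate_cohort",
    "generate_biochem",
    "generate_proteins",
    "generate_labeled_peptides",
    "generate_omics",
    "dairy_like_frequencies",
    "legume_like_frequencies",
    "divergent_frequencies",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic screening cohort.

    Reference animals draw their weight-for-age ratio from a sex-specific
    truncated Normal (ratios must be positive); flagged (non-thriving)
    animals draw from the same family with the mean shifted to
    ``mu + flagged_waz_mean * sigma`` so their expected WAZ against the
    reference equals ``flagged_waz_mean`` by construction.
    """

    n_male: int = 857
    n_female: int = 530
    ratio_mean_male: float = 1.30  # kg/year
    ratio_sd_male: float = 0.34
    ratio_mean_female: float = 1.12
    ratio_sd_female: float = 0.34
    n_flagged_male: int = 121
    n_flagged_female: int = 128
    flagged_waz_mean: float = -1.83
    age_range: tuple[float, float] = (2.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio_sd_male <= 0 or self.ratio_sd_female <= 0:
            raise ValueError("ratio SDs must be > 0")
        if min(self.n_male, self.n_female, self.n_flagged_male, self.n_flagged_female) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_male + self.n_female + self.n_flagged_male + self.n_flagged_female == 0:
            raise ValueError("cohort is empty")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range min must be < max")
        if self.age_range[0] <= 0:
            raise ValueError("ages must be positive")


def _truncnorm_positive(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    # truncation at 0; negligible bias at mu/sigma ~ 3.8 but enforced anyway
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _truncnorm_loc_for_mean(target_mean: float, sd: float) -> float:
    """Location parameter of a positive-truncated Normal whose mean equals
    ``target_mean``.

    For reference animals (target ~3.8 SD above zero) the correction is
    negligible, but flagged groups sit only 1.5-2 SD above zero where the
    truncation would otherwise pull the realized mean visibly upward.
    """
    if target_mean <= 0:
        raise ValueError(
            f"target ratio mean {target_mean:.3g} kg/yr is not positive; "
            "flagged shift too extreme for a positive ratio distribution"
        )

    def truncated_mean(loc: float) -> float:
        a = (0.0 - loc) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    from scipy.optimize import brentq

    lo, hi = target_mean - 8.0 * sd, target_mean
    return float(brentq(lambda loc: truncated_mean(loc) - target_mean, lo, hi, xtol=1e-12))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table: one row per animal.

    Columns: ``id, sex, age_years, weight_kg, bcs, group`` where ``group``
    is ``reference`` or ``flagged``.  Weight is ratio x age; BCS is >= 2.0
    for reference animals and < 2.0 for flagged ones (the screening
    convention, not a fitted link).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    blocks = [
        ("M", "reference", spec.n_male, spec.ratio_mean_male, spec.ratio_sd_male),
        ("F", "reference", spec.n_female, spec.ratio_mean_female, spec.ratio_sd_female),
        ("M", "flagged", spec.n_flagged_male,
         spec.ratio_mean_male + spec.flagged_waz_mean * spec.ratio_sd_male, spec.ratio_sd_male),
        ("F", "flagged", spec.n_flagged_female,
         spec.ratio_mean_female + spec.flagged_waz_mean * spec.ratio_sd_female, spec.ratio_sd_female),
    ]
    idx = 0
    lo, hi = spec.age_range
    for sex, group, n, mean, sd in blocks:
        if n == 0:
            continue
        ages = rng.uniform(lo, hi, size=n)
        if group == "flagged":
            # match the truncated mean to the target so the flagged group's
            # expected WAZ equals flagged_waz_mean by construction
            mean = _truncnorm_loc_for_mean(mean, sd)
        ratios = _truncnorm_positive(rng, mean, sd, n)
        if group == "reference":
            bcs = rng.uniform(2.0, 4.0, size=n)
        else:
            bcs = rng.uniform(1.0, 2.0, size=n)
        for j in range(n):
            rows.append(
                {
                    "id": f"NHP{idx + j:05d}",
                    "sex": sex,
                    "age_years": ages[j],
                    "weight_kg": ratios[j] * ages[j],
                    "bcs": bcs[j],
                    "group": group,
                }
            )
        idx += n
    df = pd.DataFrame(rows)
    df.attrs["seed"] = spec.seed
    return df


# ---------------------------------------------------------------------------
# serum biochemistry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiochemGroupSpec:
    """Two-group serum-analyte design.

    ``analytes`` maps analyte name to ``{group: (mean, sd)}``; ``n`` maps
    group name to per-group sample size.  Defaults reproduce the reported
    normal-versus-undernourished albumin and total-protein contrasts
    (47.13 +/- 4.68 vs 27.16 +/- 6.52 g/L albumin; 72.95 +/- 7.31 vs
    62.98 +/- 6.55 g/L total protein) at the study group sizes (20 vs 60).
    """

    analytes: dict = field(default_factory=lambda: {
        "albumin_g_L": {"N-NHP": (47.13, 4.68), "U-NHP": (27.16, 6.52)},
        "total_protein_g_L": {"N-NHP": (72.95, 7.31), "U-NHP": (62.98, 6.55)},
    })
    n: dict = field(default_factory=lambda: {"N-NHP": 20, "U-NHP": 60})
    seed: int = 0

    def __post_init__(self) -> None:
        for analyte, groups in self.analytes.items():
            for g, (_, sd) in groups.items():
                if sd <= 0:
                    raise ValueError(f"sd must be > 0 for {analyte}/{g}")
        for g, n in self.n.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2")


def generate_biochem(spec: BiochemGroupSpec) -> pd.DataFrame:
    """Per-animal analyte table with columns ``id, group, <analyte>...``."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, n in spec.n.items():
        data = {"id": [f"{group}-{i:03d}" for i in range(n)], "group": group}
        for analyte, groups in spec.analytes.items():
            mean, sd = groups[group]
            data[analyte] = rng.normal(mean, sd, size=n)
        frames.append(pd.DataFrame(data))
    df = pd.concat(frames, ignore_index=True)
    df.attrs["seed"] = spec.seed
    return df


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinFamilySpec:
    """A family of random protein sequences.

    Two generation models are supported:

    independent (``template_seed`` is None)
        Residues i.i.d. from the family's 20-dimensional frequency vector
        (order ``ACDEFGHIKLMNPQRSTVWY``).  Use this for families with
        distinct dominant residues.
    homologous (``template_seed`` set)
        Each sequence is a mutated copy of an ancestral template drawn
        uniformly over residues from ``template_seed``; a fraction
        ``mutation_rate`` of positions is substituted with residues drawn
        from the family frequency vector.  Families sharing a
        ``template_seed`` (and length range / count) are homologous and
        release largely overlapping peptide repertoires, emulating related
        food proteins from different sources.
    """

    name: str
    frequencies: tuple
    length_range: tuple[int, int] = (300, 600)
    n_sequences: int = 20
    seed: int = 0
    template_seed: int | None = None
    mutation_rate: float = 0.03

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.shape != (20,):
            raise ValueError("frequencies must have length 20")
        if (freqs < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {freqs.sum()}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


def _family_sequences(spec: ProteinFamilySpec) -> list[str]:
    rng = np.random.default_rng(spec.seed)
    freqs = np.asarray(spec.frequencies, dtype=float)
    freqs = freqs / freqs.sum()
    aas = list(AMINO_ACIDS)
    lo, hi = spec.length_range
    if spec.template_seed is None:
        return [
            "".join(rng.choice(aas, size=int(rng.integers(lo, hi + 1)), p=freqs))
            for _ in range(spec.n_sequences)
        ]
    trng = np.random.default_rng(spec.template_seed)
    ancestors = [
        "".join(trng.choice(aas, size=int(trng.integers(lo, hi + 1))))
        for _ in range(spec.n_sequences)
    ]
    out = []
    for anc in ancestors:
        arr = list(anc)
        mask = rng.random(len(arr)) < spec.mutation_rate
        repl = rng.choice(aas, size=int(mask.sum()), p=freqs)
        j = 0
        for i, hit in enumerate(mask):
            if hit:
                arr[i] = repl[j]
                j += 1
        out.append("".join(arr))
    return out


def generate_proteins(specs: list[ProteinFamilySpec]):
    """Generate FASTA records for each family.

    Returns a list of Biopython ``SeqRecord`` objects; the description
    carries ``family=<name>`` for downstream label recovery.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for spec in specs:
        for i, seq in enumerate(_family_sequences(spec)):
            records.append(
                SeqRecord(
                    Seq(seq),
                    id=f"{spec.name}_{i:03d}",
                    description=f"family={spec.name}",
                )
            )
    return records


def dairy_like_frequencies() -> tuple:
    """Residue frequencies loosely shaped like a milk-protein composition
    (proline/glutamate-rich), overlapping broadly with the legume-like set."""
    base = _base_frequencies()
    base["P"] += 0.06
    base["E"] += 0.05
    base["L"] += 0.03
    return _normalize(base)


def legume_like_frequencies() -> tuple:
    """Residue frequencies loosely shaped like a seed-storage-protein
    composition (asparagine/glutamine/acidic-rich)."""
    base = _base_frequencies()
    base["N"] += 0.05
    base["Q"] += 0.05
    base["D"] += 0.04
    return _normalize(base)


def divergent_frequencies() -> tuple:
    """A deliberately divergent composition dominated by residues rare in
    the two food-protein families (used as a negative control)."""
    base = {aa: 0.005 for aa in AMINO_ACIDS}
    for aa in "HWMC":
        base[aa] = 0.22
    return _normalize(base)


def _base_frequencies() -> dict:
    # flat-ish background over the 20 residues
    return {aa: 0.05 for aa in AMINO_ACIDS}


def _normalize(d: dict) -> tuple:
    total = sum(d.values())
    return tuple(d[aa] / total for aa in AMINO_ACIDS)


# ---------------------------------------------------------------------------
# labeled peptides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideLabelSpec:
    """Two labelled peptide classes differing in residue-composition bias.

    ``bcaa_frac`` gives each class's expected fraction of branched-chain
    residues (I/L/V); ``polar_frac`` the expected fraction of polar
    N/O-bearing residues (S/T/N/Q/Y).  Remaining mass is spread over the
    other residues.  Equal biases produce an unseparable null set.
    """

    n_per_class: int = 250
    bcaa_frac: tuple[float, float] = (0.6, 0.1)
    polar_frac: tuple[float, float] = (0.2, 0.2)
    length_range: tuple[int, int] = (5, 25)
    seed: int = 0

    def __post_init__(self) -> None:
        for b, p in zip(self.bcaa_frac, self.polar_frac):
            if b < 0 or p < 0 or b + p > 1:
                raise ValueError("class biases must be non-negative and sum to <= 1")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


_BCAA = "ILV"
_POLAR = "STNQY"
_OTHER = "".join(aa for aa in AMINO_ACIDS if aa not in _BCAA + _POLAR)


def generate_labeled_peptides(spec: PeptideLabelSpec) -> pd.DataFrame:
    """Peptide table with columns ``peptide, label`` (labels ``bioactive``
    and ``other``)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cls, label in ((0, "bioactive"), (1, "other")):
        b, p = spec.bcaa_frac[cls], spec.polar_frac[cls]
        probs = np.empty(20)
        for i, aa in enumerate(AMINO_ACIDS):
            if aa in _BCAA:
                probs[i] = b / len(_BCAA)
            elif aa in _POLAR:
                probs[i] = p / len(_POLAR)
            else:
                probs[i] = (1 - b - p) / len(_OTHER)
        lo, hi = spec.length_range
        for _ in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            rows.append({
                "peptide": "".join(rng.choice(list(AMINO_ACIDS), size=length, p=probs)),
                "label": label,
            })
    df = pd.DataFrame(rows)
    df.attrs["seed"] = spec.seed
    return df


# ---------------------------------------------------------------------------
# omics matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmicsSimSpec:
    """Gene count matrix with a known tissue/individual variance split plus
    a metabolite matrix with planted cluster patterns.

    Per-gene log2 expression is grand mean + tissue effect + individual
    effect + residual, with the three components' variances in the stated
    fractions of a unit total; counts are the rounded antilog.  Metabolite
    rows follow one of ``n_clusters`` sample-axis pattern templates plus
    Normal noise.
    """

    n_genes: int = 2000
    tissues: tuple = ("liver", "muscle", "kidney", "spleen")
    individuals: tuple = ("ind1", "ind2", "ind3", "ind4", "ind5", "ind6")
    variance_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)  # tissue, individual, residual
    gene_length_range: tuple[int, int] = (300, 5000)  # bp
    n_metabolites: int = 120
    n_clusters: int = 6
    metabolite_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.variance_fractions, dtype=float)
        if (fr < 0).any() or (fr > 1).any():
            raise ValueError("variance fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if len(self.tissues) < 2 or len(self.individuals) < 2:
            raise ValueError("need >= 2 tissues and >= 2 individuals")


def _cluster_templates(n_clusters: int, n_samples: int) -> np.ndarray:
    """Smooth, mutually distinct sample-axis patterns (rising, falling,
    peaked, dipped, and phase-shifted sinusoids)."""
    t = np.linspace(0.0, 1.0, n_samples)
    templates = []
    for c in range(n_clusters):
        kind = c % 4
        phase = (c // 4) * 0.9
        if kind == 0:
            pat = 2.0 * t - 1.0 + 0.5 * np.sin(2 * np.pi * (t + phase))
        elif kind == 1:
            pat = 1.0 - 2.0 * t + 0.5 * np.sin(2 * np.pi * (t + phase))
        elif kind == 2:
            pat = np.cos(2 * np.pi * (t + phase))
        else:
            pat = -np.cos(2 * np.pi * (t + phase))
        pat = (pat - pat.mean()) / pat.std()
        templates.append(pat)
    return np.asarray(templates)


def generate_omics(spec: OmicsSimSpec):
    """Generate ``(counts, gene_lengths, sample_meta, metabolites, met_clusters)``.

    ``counts`` is a genes x samples integer DataFrame over the full crossed
    tissue x individual design; ``gene_lengths`` a Series in bp;
    ``sample_meta`` a DataFrame with ``sample_id, tissue, individual``;
    ``metabolites`` a metabolites x samples DataFrame; ``met_clusters`` the
    planted cluster label per metabolite.
    """
    rng = np.random.default_rng(spec.seed)
    f_t, f_i, f_r = spec.variance_fractions
    tissues, individuals = list(spec.tissues), list(spec.individuals)
    samples = [f"{t}_{i}" for t in tissues for i in individuals]
    meta = pd.DataFrame({
        "sample_id": samples,
        "tissue": [s.split("_")[0] for s in samples],
        "individual": [s.split("_", 1)[1] for s in samples],
    })

    grand = rng.uniform(4.0, 9.0, size=spec.n_genes)  # log2 scale
    t_eff = rng.normal(0.0, np.sqrt(f_t), size=(spec.n_genes, len(tissues)))
    i_eff = rng.normal(0.0, np.sqrt(f_i), size=(spec.n_genes, len(individuals)))
    resid = rng.normal(0.0, np.sqrt(f_r), size=(spec.n_genes, len(samples)))
    log2_expr = grand[:, None] + resid
    for j, s in enumerate(samples):
        ti = tissues.index(meta.loc[j, "tissue"])
        ii = individuals.index(meta.loc[j, "individual"])
        log2_expr[:, j] += t_eff[:, ti] + i_eff[:, ii]
    counts = np.rint(np.exp2(log2_expr)).astype(np.int64)
    gene_ids = [f"gene{g:05d}" for g in range(spec.n_genes)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    lengths = pd.Series(
        rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1,
                     size=spec.n_genes),
        index=gene_ids, name="length_bp",
    )

    templates = _cluster_templates(spec.n_clusters, len(samples))
    met_labels = rng.integers(0, spec.n_clusters, size=spec.n_metabolites)
    met = templates[met_labels] + rng.normal(0.0, spec.metabolite_noise_sd,
                                             size=(spec.n_metabolites, len(samples)))
    met_ids = [f"met{m:04d}" for m in range(spec.n_metabolites)]
    met_df = pd.DataFrame(met, index=met_ids, columns=samples)
    met_clusters = pd.Series(met_labels, index=met_ids, name="cluster")
    for df in (counts_df, met_df):
        df.attrs["seed"] = spec.seed
    return counts_df, lengths, meta, met_df, met_clusters
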