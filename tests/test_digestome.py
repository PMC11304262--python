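"""In silico digestion: cleavage rules against a brute-force oracle,
repertoire accounting, categorization and protein clustering."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score, silhouette_score

from nhpnutri.digestome import (
    DEFAULT_REGISTRY,
    EnzymeRule,
    build_feature_matrix,
    categorize_peptides,
    cleave,
    cluster_proteins,
    digest_gi,
    repertoire_similarity,
)
from nhpnutri.synth import (
    AMINO_ACIDS,
    ProteinFamilySpec,
    generate_proteins,
)

TRYPSIN = DEFAULT_REGISTRY["trypsin"]


def brute_force_fragments(sequence: str, rule: EnzymeRule) -> list[str]:
    """Independent position-scan oracle: walk the sequence, splitting after
    every residue satisfying the rule predicate."""
    fragments, current = [], []
    n = len(sequence)
    for i, aa in enumerate(sequence, start=1):
        current.append(aa)
        cut = (
            i < n
            and rule.min_distance_from_ends <= i <= n - rule.min_distance_from_ends
            and aa in rule.p1
            and aa != "X"
            and sequence[i] not in rule.p1_block
            and sequence[i] != "X"
        )
        if cut:
            fragments.append("".join(current))
            current = []
    fragments.append("".join(current))
    return fragments


class TestCleave:
    def test_trypsin_worked_example(self):
        result = cleave("MKRAG", TRYPSIN, min_length=1)
        assert result.counts() == Counter({"MK": 1, "R": 1, "AG": 1})

    def test_proline_blocks_tryptic_cut(self):
        result = cleave("MKPAG", TRYPSIN, min_length=1)
        assert result.counts() == Counter({"MKPAG": 1})

    def test_no_sites_returns_whole_sequence(self):
        for rule in DEFAULT_REGISTRY.values():
            seq = "GGGGGG" if "G" not in rule.p1 else "MMMMMM"
            assert cleave(seq, rule, min_length=1).counts() == Counter({seq: 1})

    def test_min_length_drops_short_but_keeps_spans(self):
        result = cleave("MKRAG", TRYPSIN, min_length=2)
        assert result.counts() == Counter({"MK": 1, "AG": 1})
        spans = [(s, e) for (_, _, s, e) in result.spans]
        assert spans == [(1, 2), (3, 3), (4, 5)]

    def test_missed_cleavages_add_adjacent_unions(self):
        result = cleave("MKRAG", TRYPSIN, missed_cleavages=1, min_length=1)
        assert result.counts() == Counter(
            {"MK": 1, "R": 1, "AG": 1, "MKR": 1, "RAG": 1}
        )

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            cleave("MKZ", TRYPSIN)

    def test_x_is_never_a_cleavage_site(self):
        result = cleave("MKXAG", TRYPSIN, min_length=1)
        # K is followed by X: treated as uncuttable context
        assert result.counts() == Counter({"MKXAG": 1})

    @pytest.mark.parametrize("enzyme", sorted(DEFAULT_REGISTRY))
    def test_agrees_with_brute_force_oracle(self, enzyme):
        rule = DEFAULT_REGISTRY[enzyme]
        rng = np.random.default_rng(17)
        aas = list(AMINO_ACIDS)
        for _ in range(100):
            seq = "".join(rng.choice(aas, size=int(rng.integers(5, 120))))
            got = cleave(seq, rule, min_length=1).counts()
            assert got == Counter(brute_force_fragments(seq, rule))

    @settings(derandomize=True, max_examples=60)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60))
    def test_reconstruction_invariant(self, seq):
        """Span-ordered base fragments concatenate to the parent."""
        for rule in DEFAULT_REGISTRY.values():
            result = cleave(seq, rule, min_length=1)
            ordered = sorted(result.spans, key=lambda t: t[2])
            assert "".join(frag for (_, frag, _, _) in ordered) == seq


class TestDigestGI:
    def test_no_site_sequence_single_peptide_both_modes(self):
        # M is in no enzyme's P1 set, so the chain is never cut
        for mode in ("sequential", "independent"):
            result = digest_gi("MMMMMM", mode=mode, min_length=1)
            assert set(result.counts()) == {"MMMMMM"}

    def test_independent_repertoire_is_sum_of_per_enzyme(self):
        seq = "MKRAGFLKPSTWYEAV"
        combined = digest_gi(seq, mode="independent", min_length=1)
        per_enzyme_total = sum(
            cleave(seq, rule, min_length=1).total_peptides()
            for rule in DEFAULT_REGISTRY.values()
        )
        assert combined.total_peptides() == per_enzyme_total

    def test_hand_digestion_oracle_independent(self):
        expected = Counter()
        fragments = {
            "pepsin": ["MKRAGF", "L", "K"],
            "trypsin": ["MK", "R", "AGFLK"],
            "alpha-chymotrypsin": ["MKRAGF", "LK"],
            "pancreatic-elastase": ["MKRA", "G", "FL", "K"],
            "prolyl-oligopeptidase": ["MKRAGFLK"],
            "thimet-oligopeptidase": ["MKRAGF", "LK"],
        }
        for enz, peps in fragments.items():
            for p in peps:
                expected[(enz, p)] += 1
        result = digest_gi("MKRAGFLK", mode="independent", min_length=1)
        assert result.peptides == expected

    def test_hand_digestion_oracle_sequential(self):
        # gastric: MKRAGF | L | K; joint pancreatic pass cuts MKRAGF into
        # MK | R | A | G | F; single residues survive only at min_length=1
        result = digest_gi("MKRAGFLK", mode="sequential", min_length=1)
        assert result.counts() == Counter(
            {"MK": 1, "R": 1, "A": 1, "G": 1, "F": 1, "L": 1, "K": 1}
        )
        assert digest_gi("MKRAGFLK", mode="sequential").counts() == Counter({"MK": 1})

    def test_sequential_spans_reconstruct_parent(self):
        seq = "MKRAGFLKPSTWYEAVHNQD"
        result = digest_gi(seq, mode="sequential", min_length=1)
        ordered = sorted(result.spans, key=lambda t: t[2])
        assert "".join(frag for (_, frag, _, _) in ordered) == seq

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            digest_gi("MKRAG", mode="jumbled")


class TestCategorize:
    def test_disjoint_residue_pairs_recovered(self):
        groups = {
            "AG": ["AGAG", "AGAGAG", "GAGA"],
            "KR": ["KRKR", "RKRKRK", "KRRK"],
            "FY": ["FYFY", "YFYF", "FYYF"],
            "ST": ["STST", "TSTS", "STTS"],
        }
        counts = Counter({p: 2 for peps in groups.values() for p in peps})
        assignment = categorize_peptides(counts, n_categories=4, seed=0)
        for peps in groups.values():
            assert len({assignment[p] for p in peps}) == 1
        labels = {assignment[peps[0]] for peps in groups.values()}
        assert len(labels) == 4

    def test_fewer_distinct_than_categories(self):
        with pytest.raises(ValueError, match="distinct"):
            categorize_peptides(Counter({"AAAA": 10}), n_categories=4)

    def test_input_order_invariance(self):
        peps = {f"PEP{aa}{aa}": i + 1 for i, aa in enumerate("ACDEFGHIK")}
        a = categorize_peptides(dict(sorted(peps.items())), n_categories=3, seed=1)
        b = categorize_peptides(dict(sorted(peps.items(), reverse=True)),
                                n_categories=3, seed=1)
        assert a == b


@pytest.fixture(scope="module")
def distinct_family_records():
    """Two families with disjoint dominant residues (well-separated)."""
    def freqs(dominant):
        base = {aa: 0.02 for aa in AMINO_ACIDS}
        for aa in dominant:
            base[aa] = (1.0 - 0.02 * (20 - len(dominant))) / len(dominant)
        total = sum(base.values())
        return tuple(base[aa] / total for aa in AMINO_ACIDS)

    return generate_proteins([
        ProteinFamilySpec("acid", freqs("DEST"), (300, 500), 10, seed=21),
        ProteinFamilySpec("basic", freqs("KRHQ"), (300, 500), 10, seed=22),
    ])


class TestFeatureMatrixAndClustering:
    def test_identical_proteins_identical_rows(self):
        recs = [("p1", "MKRAGFLKPSTWYEAV"), ("p2", "MKRAGFLKPSTWYEAV")]
        feat = build_feature_matrix(recs, n_categories=2, seed=0)
        assert np.allclose(feat.matrix.iloc[0], feat.matrix.iloc[1])

    def test_row_sums_equal_total_released_peptides(self, distinct_family_records):
        feat = build_feature_matrix(distinct_family_records[:4], seed=0)
        for rec in distinct_family_records[:4]:
            total = digest_gi(str(rec.seq), mode="independent").total_peptides()
            assert feat.matrix.loc[rec.id].sum() == total

    def test_families_are_separable(self, distinct_family_records):
        feat = build_feature_matrix(distinct_family_records, seed=0)
        labels = [rec.description.split("family=")[1] for rec in distinct_family_records]
        X = feat.matrix.to_numpy(float)
        X = X / X.sum(axis=1, keepdims=True)
        assert silhouette_score(X, labels) > 0.5
        result = cluster_proteins(feat, k=2, seed=0)
        assert adjusted_rand_score(labels, result.labels) >= 0.9

    def test_k_equals_n_gives_zero_inertia(self, distinct_family_records):
        feat = build_feature_matrix(distinct_family_records[:5], seed=0)
        result = cluster_proteins(feat, k=5, seed=0)
        assert result.inertia == pytest.approx(0.0, abs=1e-9)
        assert sorted(result.labels.unique()) == [1, 2, 3, 4, 5]

    def test_duplicated_proteins_co_cluster(self, distinct_family_records):
        recs = [(r.id, str(r.seq)) for r in distinct_family_records[:6]]
        doubled = recs + [(pid + "_dup", seq) for pid, seq in recs]
        feat = build_feature_matrix(doubled, seed=0)
        result = cluster_proteins(feat, k=3, seed=0)
        for pid, _ in recs:
            assert result.labels[pid] == result.labels[pid + "_dup"]

    def test_k_larger_than_n_rejected(self, distinct_family_records):
        feat = build_feature_matrix(distinct_family_records[:3], seed=0)
        with pytest.raises(ValueError):
            cluster_proteins(feat, k=4, seed=0)


class TestRepertoireSimilarity:
    def test_identity_and_disjoint(self):
        a = Counter({"AB": 2, "CD": 1})
        assert repertoire_similarity(a, a) == 1.0
        assert repertoire_similarity(a, Counter({"EF": 3})) == 0.0

    def test_worked_example(self):
        a = Counter({"AB": 2, "CD": 1})
        b = Counter({"AB": 1, "EF": 1})
        assert repertoire_similarity(a, b) == pytest.approx(0.25)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            repertoire_similarity(Counter(), Counter())

    @settings(derandomize=True, max_examples=50)
    @given(
        st.dictionaries(st.sampled_from(["AA", "AB", "BC", "CD", "DE"]),
                        st.integers(1, 9), min_size=1),
        st.dictionaries(st.sampled_from(["AA", "AB", "BC", "CD", "DE"]),
                        st.integers(1, 9), min_size=1),
    )
    def test_symmetric_and_bounded(self, a, b):
        s = repertoire_similarity(Counter(a), Counter(b))
        assert 0.0 <= s <= 1.0
        assert s == repertoire_similarity(Counter(b), Counter(a))
        assert (s == 1.0) == (a == b)


def test_load_registry_from_yaml(tmp_path):
    path = tmp_path / "rules.yaml"
    path.write_text(
        "strict-trypsin:\n  p1: KR\n  p1_block: P\n"
        "mini-elastase:\n  p1: AG\n  min_distance_from_ends: 2\n"
    )
    from nhpnutri.digestome import load_registry

    registry = load_registry(path)
    assert registry["strict-trypsin"].p1 == frozenset("KR")
    assert registry["mini-elastase"].min_distance_from_ends == 2
    result = cleave("MKRAG", registry["strict-trypsin"], min_length=1)
    assert result.counts() == Counter({"MK": 1, "R": 1, "AG": 1})
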