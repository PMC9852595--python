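import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsomics.datamodel import CpGAnnotation, GeneAnnotation, ValidationError
from rsomics.integration import (
    build_integrome,
    enrichment_fold,
    enrichment_test,
    filter_significant,
    select_candidates,
    spearman,
)


def _cpgs(positions: dict[str, tuple[str, int]], links=None) -> CpGAnnotation:
    frame = pd.DataFrame(
        {"cpg_id": list(positions),
         "chrom": [v[0] for v in positions.values()],
         "pos": [v[1] for v in positions.values()]}
    )
    links_df = pd.DataFrame(links or [], columns=["cpg_id", "gene_id", "feature_class"])
    return CpGAnnotation(frame, links_df)


def _genes(tss: dict[str, tuple[str, int]]) -> GeneAnnotation:
    return GeneAnnotation(
        pd.DataFrame(
            {"gene_id": list(tss),
             "transcript_ids": [f"{g}.t1" for g in tss],
             "chrom": [v[0] for v in tss.values()],
             "tss": [v[1] for v in tss.values()],
             "strand": ["+"] * len(tss),
             "biotype": ["protein_coding"] * len(tss)}
        )
    )


class TestBuildIntegrome:
    def test_window_boundary_is_inclusive_at_2kb(self):
        cpgs = _cpgs({"cgA": ("chr1", 8000), "cgB": ("chr1", 7999)})
        genes = _genes({"G1": ("chr1", 10_000)})
        pairs = build_integrome(cpgs, genes, window=2000)
        assert set(pairs["cpg_id"]) == {"cgA"}  # 2000 away kept, 2001 dropped
        assert (pairs["feature_class"] == "TSSoverlap2kb").all()

    def test_id_link_takes_precedence_over_coordinates(self):
        cpgs = _cpgs({"cgA": ("chr1", 9900)},
                     links=[("cgA", "G1", "TSS200")])
        genes = _genes({"G1": ("chr1", 10_000)})
        pairs = build_integrome(cpgs, genes)
        assert len(pairs) == 1
        assert pairs.iloc[0]["link_method"] == "shared_id"
        assert pairs.iloc[0]["feature_class"] == "TSS200"

    def test_matches_brute_force_all_pairs_distance_check(self):
        rng = np.random.default_rng(11)
        cpg_pos = {f"cg{i}": ("chr1", int(rng.integers(1, 50_000))) for i in range(20)}
        gene_tss = {f"G{i}": ("chr1", int(rng.integers(1, 50_000))) for i in range(5)}
        pairs = build_integrome(_cpgs(cpg_pos), _genes(gene_tss), window=2000)
        expected = {
            (c, f"{g}.t1")
            for c, (_, p) in cpg_pos.items()
            for g, (_, t) in gene_tss.items()
            if abs(p - t) <= 2000
        }
        assert set(zip(pairs["cpg_id"], pairs["target_id"])) == expected

    def test_disjoint_chromosomes_rejected(self):
        cpgs = _cpgs({"cgA": ("chr1", 100)})
        genes = _genes({"G1": ("chr2", 100)})
        with pytest.raises(ValidationError, match="chromosome"):
            build_integrome(cpgs, genes)


def _spearman_rank_oracle(x, y):
    """Brute-force mid-rank Spearman (average ties), Pearson on ranks."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = np.mean(rx), np.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSpearman:
    def test_monotone_increasing_pair_is_one(self):
        x = np.arange(12.0)
        rho, p = spearman(x, x**3 + 1)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_reversed_pair_is_minus_one(self):
        x = np.arange(12.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_brute_force_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0, 8.0, 8.0])
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0, 5.0, 8.0])
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(_spearman_rank_oracle(x, y), rel=1e-12)

    def test_large_n_p_matches_t_approximation(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman(x, y)
        t = rho * math.sqrt((30 - 2) / (1 - rho**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-12)

    def test_small_n_uses_exact_permutation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p = spearman(x, y)
        # enumerate all 720 permutations with an independent rho formula
        robs = abs(_spearman_rank_oracle(x, y))
        count = sum(
            abs(_spearman_rank_oracle(x, [y[i] for i in perm])) >= robs - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert p == pytest.approx(count / math.factorial(6), rel=1e-12)

    def test_constant_vector_returns_nan(self):
        rho, p = spearman(np.ones(12), np.arange(12.0))
        assert math.isnan(rho) and math.isnan(p)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match=">=5"):
            spearman(np.arange(4.0), np.arange(4.0))


def _assoc_frame(rows):
    return pd.DataFrame(
        rows, columns=["cpg_id", "target_id", "gene_id", "link_method",
                       "feature_class", "rho", "p"]
    )


class TestFilters:
    def test_predicate_boundaries(self):
        rows = [
            ("c1", "t1", "g1", "shared_id", "TSS200", 0.34, 0.005),   # kept
            ("c2", "t1", "g1", "shared_id", "TSS200", 0.50, 0.02),    # p too big
            ("c3", "t1", "g1", "shared_id", "TSS200", 1 / 3, 0.001),  # rho not strictly above
        ]
        kept = filter_significant(_assoc_frame(rows))
        assert list(kept["cpg_id"]) == ["c1"]

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(13)
        rows = [
            (f"c{i}", "t", "g", "shared_id", "TSS200",
             float(rng.uniform(-1, 1)), float(rng.uniform(0, 0.05)))
            for i in range(200)
        ]
        kept = filter_significant(_assoc_frame(rows), p_cut=0.01, rho_cut=1 / 3)
        expected = [r[0] for r in rows if abs(r[5]) > 1 / 3 and r[6] < 0.01]
        assert list(kept["cpg_id"]) == expected


class TestSelectCandidates:
    def test_three_negative_promoter_cpgs_make_a_candidate(self):
        rows = [(f"c{i}", "t1", "g1", "shared_id", "TSS200", -0.5, 1e-4) for i in range(3)]
        cands, gene_lists = select_candidates(_assoc_frame(rows))
        assert len(cands) == 1
        assert cands[0].direction == "negative"
        assert gene_lists["union"] == ["g1"]

    def test_two_qualifying_cpgs_are_not_enough(self):
        rows = [(f"c{i}", "t1", "g1", "shared_id", "TSS200", -0.5, 1e-4) for i in range(2)]
        cands, _ = select_candidates(_assoc_frame(rows))
        assert cands == []

    def test_gene_body_support_does_not_count(self):
        rows = [(f"c{i}", "t1", "g1", "shared_id", "Body", -0.5, 1e-4) for i in range(3)]
        cands, _ = select_candidates(_assoc_frame(rows))
        assert cands == []

    def test_candidates_nest_inside_significant_filter(self):
        rng = np.random.default_rng(14)
        rows = [
            (f"c{i}", f"t{i % 10}", f"g{i % 10}", "shared_id", "TSS200",
             float(rng.uniform(-1, 1)), float(rng.uniform(0, 0.02)))
            for i in range(300)
        ]
        frame = _assoc_frame(rows)
        cands, _ = select_candidates(frame, p_cut=0.001)
        significant = filter_significant(frame, p_cut=0.01)
        sig_pairs = set(zip(significant["cpg_id"], significant["target_id"]))
        for c in cands:
            for cpg in c.cpg_ids:
                assert (cpg, c.target_id) in sig_pairs


class TestEnrichment:
    def test_worked_example_fold(self):
        assert enrichment_fold(17, 22, 33, 90) == pytest.approx(2.107, abs=5e-4)

    def test_background_frequency_gives_unit_fold(self):
        assert enrichment_fold(10, 100, 30, 300) == pytest.approx(1.0)

    def test_zero_background_is_flagged_infinity(self):
        assert math.isinf(enrichment_fold(3, 10, 0, 100))

    def test_fisher_hand_computed_hypergeometric(self):
        assert enrichment_test([[5, 0], [0, 5]], "fisher") == pytest.approx(2 / 252, rel=1e-9)

    def test_fisher_independent_table_is_one(self):
        assert enrichment_test([[10, 10], [10, 10]], "fisher") == pytest.approx(1.0)

    def test_chi2_matches_pearson_statistic_oracle(self):
        table = np.array([[20, 10], [10, 20]])
        p = enrichment_test(table, "chi2")
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        x2 = ((table - expected) ** 2 / expected).sum()
        assert p == pytest.approx(stats.chi2.sf(x2, 1), rel=1e-12)

    def test_non_integer_cell_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            enrichment_test([[1.5, 2], [3, 4]], "fisher")
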