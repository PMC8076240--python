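import itertools

import numpy as np
import pytest

from mirhomology import GeneSetCollection, enrich, hypergeometric_test, read_gmt
from mirhomology.enrichment import write_enrichment_tsv
from oracles import hypergeom_upper_tail


def collection(**sets):
    return GeneSetCollection(
        sets={k: (f"name-{k}", frozenset(v)) for k, v in sets.items()}
    )


class TestReadGmt:
    def test_basic_parse_and_dedup(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tG1\tG2\nS2\tdesc\tg1\tG1\n")
        coll = read_gmt(p)
        assert coll.sets["S1"][1] == {"G1", "G2"}
        assert coll.sets["S2"][1] == {"G1"}  # uppercased then deduplicated

    def test_short_line_warns_and_skips(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tG1\nS2\tonlydesc\n")
        with pytest.warns(UserWarning, match="fewer than 3"):
            coll = read_gmt(p)
        assert list(coll.sets) == ["S1"]

    def test_duplicate_term_is_hard_error(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tG1\nS1\tdesc\tG2\n")
        with pytest.raises(ValueError, match="S1"):
            read_gmt(p)


class TestHypergeometricTest:
    def test_zero_overlap_gives_p_one(self):
        k, K, n, N, p = hypergeometric_test({"A", "B"}, {"C", "D"},
                                            {"A", "B", "C", "D", "E"})
        assert k == 0
        assert p == pytest.approx(1.0)

    def test_worked_case_5_over_210(self):
        universe = set(f"G{i}" for i in range(10))
        term = {f"G{i}" for i in range(5)}
        query = {f"G{i}" for i in range(4)}  # 4 draws, all in the term
        k, K, n, N, p = hypergeometric_test(query, term, universe)
        assert (k, K, n, N) == (4, 5, 4, 10)
        assert p == pytest.approx(5 / 210)
        assert hypergeom_upper_tail(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_certain_event(self):
        genes = {"A", "B", "C"}
        _, _, _, _, p = hypergeometric_test(genes, genes, genes)
        assert p == pytest.approx(1.0)

    def test_genes_outside_universe_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="outside the universe"):
            k, K, n, N, p = hypergeometric_test(
                {"A", "X"}, {"A", "B"}, {"A", "B", "C"}
            )
        assert (k, n) == (1, 1)

    def test_empty_query_after_intersection_is_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="empty"):
                hypergeometric_test({"X"}, {"A"}, {"A", "B"})

    def test_exact_against_enumeration_small_universes(self):
        for N in (5, 8):
            universe = {f"G{i}" for i in range(N)}
            for K in range(1, N + 1):
                term = {f"G{i}" for i in range(K)}
                for n in range(1, N + 1):
                    query = {f"G{i}" for i in range(N - n, N)}
                    k, K_, n_, N_, p = hypergeometric_test(query, term, universe)
                    assert p == pytest.approx(hypergeom_upper_tail(N, K_, n_, k),
                                              abs=1e-12)


class TestEnrich:
    def test_single_term_adjusted_equals_raw(self):
        coll = collection(S1=["A", "B", "C"])
        rows = enrich({"A", "B"}, coll, universe={"A", "B", "C", "D", "E"})
        assert len(rows) == 1
        assert rows[0].p_adj == pytest.approx(rows[0].p)

    def test_disjoint_terms_are_dropped_from_output(self):
        coll = collection(S1=["A"], S2=["B"])
        rows = enrich({"C"}, coll, universe={"A", "B", "C"})
        assert rows == []

    def test_bh_stepup_hand_example(self):
        """Three raw p of (0.01, 0.02, 0.03) BH-adjust to (0.03, 0.03, 0.03)."""
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert list(np.round(adj, 10)) == [0.03, 0.03, 0.03]

    def test_zero_overlap_terms_still_count_in_bh_denominator(self):
        universe = {f"G{i}" for i in range(12)}
        query = {"G0", "G1", "G2"}
        hit = ["G0", "G1", "G2", "G3"]
        coll_with_misses = collection(
            S1=hit, M1=["G8", "G9"], M2=["G10", "G11"], M3=["G8", "G11"]
        )
        coll_alone = collection(S1=hit)
        p_with = enrich(query, coll_with_misses, universe=universe)[0]
        p_alone = enrich(query, coll_alone, universe=universe)[0]
        assert p_with.p == pytest.approx(p_alone.p)
        # m = 4 tested terms vs m = 1
        assert p_with.p_adj == pytest.approx(min(1.0, p_alone.p_adj * 4))

    def test_adding_term_gene_to_query_never_raises_term_p(self):
        universe = {f"G{i}" for i in range(20)}
        term = {f"G{i}" for i in range(6)}
        coll = collection(S1=sorted(term))
        query = {"G0", "G10", "G11"}
        p_before = enrich(query, coll, universe=universe)[0].p
        p_after = enrich(query | {"G1"}, coll, universe=universe)[0].p
        assert p_after <= p_before

    def test_sorted_and_truncated(self):
        universe = {f"G{i}" for i in range(30)}
        sets = {f"S{i}": [f"G{j}" for j in range(i + 1)] for i in range(1, 8)}
        coll = collection(**sets)
        rows = enrich({"G0", "G1"}, coll, universe=universe, top=3)
        assert len(rows) == 3
        keys = [(r.p_adj, r.p, r.term_id) for r in rows]
        assert keys == sorted(keys)

    def test_tsv_export(self, tmp_path):
        coll = collection(S1=["A", "B"])
        rows = enrich({"A"}, coll, universe={"A", "B", "C", "D"})
        out = tmp_path / "enrich.tsv"
        write_enrichment_tsv(rows, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("term_id\tterm_name")
        assert len(lines) == 2
        assert lines[1].split("\t")[0] == "S1"
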