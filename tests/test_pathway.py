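from math import comb

import numpy as np
import pandas as pd
import pytest

from bmdkit.data_io import GeneAnnotation
from bmdkit.pathway import (aggregate_categories, cdc_table, compute_bepod,
                            correlate_pod, fisher_enrichment,
                            map_probes_to_genes, pathway_analysis, percentage,
                            select_enriched)


def fisher_oracle(a, b, c, d):
    """Two-tailed Fisher p by exhaustive enumeration of tables with the same
    margins, summing probabilities <= the observed table's probability."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_p(x):  # x = top-left cell
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = table_p(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_p(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def _estimates(pairs):
    return pd.DataFrame([{"probe_id": p, "bmd": v, "bmdl": v / 2, "bmdu": 2 * v}
                         for p, v in pairs])


class TestMapProbesToGenes:
    def test_multi_gene_probe_removed(self):
        est = _estimates([("pX", 1.0), ("pY", 2.0)])
        out = map_probes_to_genes(est, {"pX": {"g1", "g2"}, "pY": {"g3"}})
        assert out["gene_id"].tolist() == ["g3"]

    def test_probes_sharing_a_gene_average(self):
        est = _estimates([("p1", 2.0), ("p2", 4.0)])
        out = map_probes_to_genes(est, {"p1": {"g1"}, "p2": {"g1"}})
        assert out.loc[0, "bmd"] == pytest.approx(3.0)
        assert out.loc[0, "bmdl"] == pytest.approx(1.5)

    def test_unmapped_probe_dropped(self):
        est = _estimates([("p1", 2.0), ("p_nowhere", 4.0)])
        out = map_probes_to_genes(est, {"p1": {"g1"}})
        assert out["gene_id"].tolist() == ["g1"]

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            map_probes_to_genes(_estimates([("p", 1.0)]), {})


class TestFisherEnrichment:
    def test_two_by_two_diagonal(self):
        assert fisher_enrichment(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_balanced_table_p_one(self):
        assert fisher_enrichment(1, 1, 1, 1) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(200)
        for _ in range(500):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0:
                continue
            assert fisher_enrichment(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-10)

    def test_all_zero_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(0, 0, 0, 0)


class TestAggregation:
    @pytest.fixture()
    def annotation(self):
        return GeneAnnotation(
            probe_to_genes={f"p{i}": {f"g{i}"} for i in range(10)},
            categories={"C1": ("hit set", {"g0", "g1", "g2", "g3"}),
                        "C2": ("cold set", {"g8", "g9"})})

    def test_category_stats_hand_example(self, annotation):
        est = _estimates([("p0", 1.0), ("p1", 2.0), ("p2", 3.0), ("p3", 10.0)])
        table = aggregate_categories(map_probes_to_genes(est, annotation),
                                     annotation).set_index("category_id")
        row = table.loc["C1"]
        assert row["bmd_min"] == 1 and row["bmd_max"] == 10
        assert row["bmd_mean"] == pytest.approx(4.0)
        assert row["bmd_median"] == pytest.approx(2.5)
        assert row["genes_with_bmd"] == 4 and row["genes_total"] == 4

    def test_single_gene_category_collapses(self, annotation):
        est = _estimates([("p8", 5.0)])
        table = aggregate_categories(map_probes_to_genes(est, annotation),
                                     annotation).set_index("category_id")
        row = table.loc["C2"]
        assert row["bmd_min"] == row["bmd_max"] == row["bmd_median"] == 5.0

    def test_genes_without_bmd_excluded_from_stats(self, annotation):
        est = _estimates([("p0", 1.0), ("p1", 3.0)])
        table = aggregate_categories(map_probes_to_genes(est, annotation),
                                     annotation).set_index("category_id")
        assert table.loc["C1", "bmd_mean"] == pytest.approx(2.0)
        assert table.loc["C1", "genes_with_bmd"] == 2

    def test_enrichment_invariant_to_orderings(self, annotation):
        est = _estimates([("p0", 1.0), ("p1", 3.0), ("p8", 2.0)])
        t1 = aggregate_categories(map_probes_to_genes(est, annotation),
                                  annotation)
        shuffled = GeneAnnotation(
            probe_to_genes=dict(reversed(list(annotation.probe_to_genes.items()))),
            categories=dict(reversed(list(annotation.categories.items()))))
        t2 = aggregate_categories(
            map_probes_to_genes(est.iloc[::-1], shuffled), shuffled)
        pd.testing.assert_frame_equal(
            t1.sort_values("category_id").reset_index(drop=True),
            t2.sort_values("category_id").reset_index(drop=True))


class TestSelectionAndBepod:
    def _table(self, **over):
        row = {"category_id": "C", "name": "", "genes_total": 100,
               "genes_with_bmd": 5, "p_fisher": 0.01, "percentage": 0.05,
               "bmd_median": 3.0}
        row.update(over)
        return pd.DataFrame([row])

    def test_percentage_threshold_examples(self):
        assert percentage(3, 100) == pytest.approx(0.03)
        assert percentage(0, 10) == 0.0
        assert percentage(10, 10) == 1.0
        with pytest.raises(ValueError):
            percentage(1, 0)

    def test_single_responsive_gene_excluded(self):
        assert len(select_enriched(self._table(genes_with_bmd=1))) == 0

    def test_p_boundary_strict(self):
        assert len(select_enriched(self._table(p_fisher=0.05))) == 0
        assert len(select_enriched(self._table(p_fisher=0.049))) == 1

    def test_percentage_boundary_inclusive(self):
        assert len(select_enriched(self._table(percentage=0.03))) == 1
        assert len(select_enriched(self._table(percentage=0.029))) == 0

    def test_bepod_is_median_of_category_medians(self):
        enriched = pd.DataFrame({"category_id": list("abc"),
                                 "bmd_median": [1.0, 2.0, 9.0]})
        assert compute_bepod(enriched).bepod == pytest.approx(2.0)

    def test_bepod_even_count_uses_middle_mean(self):
        enriched = pd.DataFrame({"category_id": list("ab"),
                                 "bmd_median": [1.0, 9.0]})
        assert compute_bepod(enriched).bepod == pytest.approx(5.0)

    def test_no_enriched_category_gives_no_bepod(self):
        out = compute_bepod(pd.DataFrame(columns=["category_id", "bmd_median"]))
        assert not out.defined and out.bepod is None

    def test_bepod_scale_equivariance(self):
        ann = GeneAnnotation(
            probe_to_genes={f"p{i}": {f"g{i}"} for i in range(40)},
            categories={"C1": ("", {f"g{i}" for i in range(10)}),
                        "C2": ("", {f"g{i}" for i in range(10, 20)})})
        est = _estimates([(f"p{i}", float(i + 1)) for i in range(12)])
        _, bepod1 = pathway_analysis(est, ann)
        est10 = est.copy()
        est10[["bmd", "bmdl", "bmdu"]] *= 10.0
        _, bepod10 = pathway_analysis(est10, ann)
        assert bepod1.defined
        assert bepod10.bepod == pytest.approx(10 * bepod1.bepod)


class TestPodCorrelation:
    def test_identical_vectors(self):
        r, rmsd = correlate_pod([1, 10, 100], [1, 10, 100])
        assert r == pytest.approx(1.0) and rmsd == pytest.approx(0.0)

    def test_tenfold_offset_is_one_log_decade(self):
        b = np.array([1.0, 5.0, 20.0])
        r, rmsd = correlate_pod(b, 10 * b)
        assert r == pytest.approx(1.0)
        assert rmsd == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(201)
        b = rng.lognormal(1, 1, 20)
        p = rng.lognormal(1, 1, 20)
        r, rmsd = correlate_pod(b, p)
        lb, lp = np.log10(b), np.log10(p)
        r_oracle = (np.mean(lb * lp) - lb.mean() * lp.mean()) / (lb.std() * lp.std())
        assert r == pytest.approx(r_oracle, abs=1e-10)
        assert rmsd == pytest.approx(np.sqrt(np.mean((lb - lp) ** 2)), abs=1e-12)

    def test_nonpositive_or_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlate_pod([1.0], [2.0])
        with pytest.raises(ValueError):
            correlate_pod([1.0, -1.0], [2.0, 3.0])


class TestCdcTable:
    def test_simple_fractions(self):
        out = cdc_table([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out["cumulative_fraction"],
                                   [1 / 3, 2 / 3, 1.0])

    def test_duplicates_collapse_to_one_step(self):
        out = cdc_table([2.0, 1.0, 2.0])
        assert out["value"].tolist() == [1.0, 2.0]
        np.testing.assert_allclose(out["cumulative_fraction"], [1 / 3, 1.0])

    def test_nondecreasing_in_both_coordinates(self):
        rng = np.random.default_rng(202)
        out = cdc_table(rng.lognormal(0, 1, 200))
        assert np.all(np.diff(out["value"]) > 0)
        assert np.all(np.diff(out["cumulative_fraction"]) > 0)
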