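import math

import numpy as np
import pytest

import oracles
from litmine.assoc import hypergeom_pvalue
from litmine.enrich import (
    ContingencyTable2x2,
    GeneSet,
    build_target_contingency,
    conditional_mle_odds_ratio,
    fisher_exact,
    gsea_preranked,
    read_gmt,
    read_targets_tsv,
)


class TestContingency:
    def test_published_style_counts(self):
        disease = {f"g{i}" for i in range(2513)}
        targets = {f"g{i}" for i in range(71)} | {f"t{i}" for i in range(41)}
        table = build_target_contingency(disease, targets, 19969)
        assert (table.a, table.b, table.c, table.d) == (71, 2442, 41, 17415)

    def test_disjoint_sets(self):
        table = build_target_contingency({"a", "b"}, {"c"}, 100)
        assert table.a == 0 and table.b == 2 and table.c == 1

    def test_identical_sets(self):
        table = build_target_contingency({"a", "b"}, {"a", "b"}, 10)
        assert (table.a, table.b, table.c, table.d) == (2, 0, 0, 8)

    def test_undersized_universe_rejected(self):
        with pytest.raises(ValueError, match="universe_size"):
            build_target_contingency({"a", "b"}, {"c"}, 2)


class TestFisher:
    def test_sample_odds_ratio_cross_product(self):
        result = fisher_exact(ContingencyTable2x2(71, 2442, 41, 17415))
        assert result.sample_or == pytest.approx(1236465 / 100122, rel=1e-12)
        assert round(result.sample_or, 2) == 12.35

    def test_balanced_table(self):
        result = fisher_exact(ContingencyTable2x2(5, 5, 5, 5))
        assert result.sample_or == pytest.approx(1.0)
        assert result.cmle_or == pytest.approx(1.0, abs=1e-6)
        assert result.p_one_sided == pytest.approx(
            oracles.hypergeom_upper_tail(5, 10, 10, 20), abs=1e-12
        )

    def test_p_equals_cooccurrence_hypergeometric_tail(self):
        """Cross-module consistency: same tail probability as the co-mention test."""
        table = ContingencyTable2x2(8, 30, 12, 200)
        result = fisher_exact(table)
        assert result.p_one_sided == hypergeom_pvalue(8, 38, 20, 250)

    def test_cmle_matches_scipy_conditional_estimate(self):
        from scipy.stats.contingency import odds_ratio

        for cells in [(71, 2442, 41, 17415), (8, 30, 12, 200), (3, 7, 2, 11)]:
            ours = conditional_mle_odds_ratio(ContingencyTable2x2(*cells))
            ref = odds_ratio([cells[:2], cells[2:]], kind="conditional").statistic
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_cmle_approaches_sample_or_on_large_tables(self):
        table = ContingencyTable2x2(1500, 1000, 1200, 2000)
        result = fisher_exact(table)
        assert result.cmle_or == pytest.approx(result.sample_or, rel=1e-3)

    def test_zero_cell_boundaries(self):
        result = fisher_exact(ContingencyTable2x2(3, 0, 2, 5))
        assert not result.sample_or_defined and math.isinf(result.sample_or)
        assert math.isinf(conditional_mle_odds_ratio(ContingencyTable2x2(4, 0, 0, 6)))
        assert conditional_mle_odds_ratio(ContingencyTable2x2(0, 4, 6, 0)) == 0.0


class TestGseaPreranked:
    RANKED4 = [("g1", 4.0), ("g2", 3.0), ("g3", 2.0), ("g4", 1.0)]

    def test_top_gene_scores_plus_one(self):
        (res,) = gsea_preranked(self.RANKED4, [GeneSet("s", frozenset({"g1"}))], n_perm=50)
        assert res.es == pytest.approx(1.0)

    def test_bottom_gene_scores_minus_one(self):
        (res,) = gsea_preranked(self.RANKED4, [GeneSet("s", frozenset({"g4"}))], n_perm=50)
        assert res.es == pytest.approx(-1.0)
        assert res.nes < 0  # NES carries the ES sign

    def test_weight_zero_equals_classical_ks_statistic(self):
        genes = [f"g{i}" for i in range(20)]
        ranked = [(g, 1.0) for g in genes]
        members = set(genes[:10])
        (res,) = gsea_preranked(
            ranked, [GeneSet("top-half", frozenset(members))], weight_exponent=0.0, n_perm=20
        )
        assert res.es == pytest.approx(oracles.unweighted_ks_es(genes, members), abs=1e-12)

    def test_matches_external_implementation_on_fixture(self):
        """Dual-route check of the deterministic ES against gseapy's preranked module."""
        import warnings

        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(60)]
        metrics = np.sort(rng.gamma(2.0, size=60))[::-1]
        sets = {
            "A": list(rng.choice(genes, 8, replace=False)),
            "B": list(rng.choice(genes, 12, replace=False)),
        }
        ours = gsea_preranked(
            list(zip(genes, metrics.tolist())),
            [GeneSet(k, frozenset(v)) for k, v in sorted(sets.items())],
            weight_exponent=1.0,
            n_perm=10,
            seed=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import gseapy
            import pandas as pd

            res = gseapy.prerank(
                rnk=pd.DataFrame({"gene": genes, "score": metrics}),
                gene_sets=sets,
                permutation_num=10,
                seed=1,
                min_size=1,
                max_size=500,
                weight=1.0,
                outdir=None,
                no_plot=True,
                threads=1,
            ).res2d.set_index("Term")
        for r in ours:
            assert r.es == pytest.approx(float(res.loc[r.name, "ES"]), abs=1e-9)

    def test_deterministic_under_seed_and_stable_across_seeds(self):
        genes = [f"g{i}" for i in range(120)]
        rng = np.random.default_rng(9)
        metrics = np.sort(rng.normal(size=120))[::-1]
        ranked = list(zip(genes, metrics.tolist()))
        sets = [GeneSet("s", frozenset(genes[:15]))]
        a = gsea_preranked(ranked, sets, n_perm=1000, seed=17)
        b = gsea_preranked(ranked, sets, n_perm=1000, seed=17)
        c = gsea_preranked(ranked, sets, n_perm=1000, seed=18)
        assert a == b
        assert abs(a[0].nes - c[0].nes) < 0.1

    def test_full_coverage_set_rejected(self):
        with pytest.raises(ValueError, match="entire ranked list"):
            gsea_preranked(self.RANKED4, [GeneSet("all", frozenset({"g1", "g2", "g3", "g4"}))])

    def test_disjoint_set_not_evaluable(self):
        (res,) = gsea_preranked(self.RANKED4, [GeneSet("none", frozenset({"zz"}))], n_perm=10)
        assert not res.evaluable and math.isnan(res.es)

    def test_increasing_metric_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            gsea_preranked([("a", 1.0), ("b", 2.0)], [GeneSet("s", frozenset({"a"}))])


class TestInputs:
    def test_read_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\nsetB\t-\tg3\n")
        sets = read_gmt(path)
        assert [(s.name, sorted(s.genes)) for s in sets] == [
            ("setA", ["g1", "g2"]),
            ("setB", ["g3"]),
        ]

    def test_read_targets_by_phase(self, tmp_path):
        path = tmp_path / "targets.tsv"
        path.write_text("gene\tphase\nIL17A\tapproved\nTYK2\tphase3\nJAK1\tphase3\n")
        groups = read_targets_tsv(path)
        assert groups["approved"] == {"IL17A"}
        assert groups["phase3"] == {"TYK2", "JAK1"}

    def test_unknown_phase_rejected(self, tmp_path):
        path = tmp_path / "targets.tsv"
        path.write_text("gene\tphase\nIL17A\tphase9\n")
        with pytest.raises(ValueError, match="unknown phase"):
            read_targets_tsv(path)
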