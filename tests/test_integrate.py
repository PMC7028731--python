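import itertools

import pytest

from methcrosstalk.integrate import (
    ConcordantGene,
    GeneCall,
    ThresholdParams,
    concordance_class,
    crosstab_classes,
    select_robust_genes,
    threshold_calls,
)
from methcrosstalk.meth_io import LogFCTable


def expr_tables(values_by_gene):
    """One expression table per replicate column."""
    n = len(next(iter(values_by_gene.values())))
    return [
        LogFCTable(f"E{i}", "expression", {g: v[i] for g, v in values_by_gene.items()})
        for i in range(n)
    ]


def meth_tables(values_by_gene):
    n = len(next(iter(values_by_gene.values())))
    return [
        LogFCTable(f"M{i}", "methylation", {g: v[i] for g, v in values_by_gene.items()})
        for i in range(n)
    ]


def current_hyper(gene):
    return GeneCall(gene, "current", "methylation", 1.0, "hyper", True)


class TestThresholdCalls:
    def test_methylation_pass(self):
        t = LogFCTable("M", "methylation", {"G": 0.28})
        call = threshold_calls(t)[0]
        assert call.passes and call.status == "hyper"

    def test_expression_pass_down(self):
        t = LogFCTable("E", "expression", {"G": -2.04})
        call = threshold_calls(t)[0]
        assert call.passes and call.status == "down"
        # both readings of the |FC|>2 cut admit this gene
        call_log = threshold_calls(t, params=ThresholdParams(expr_cut_scale="log2"))[0]
        assert call_log.passes

    def test_boundary_strict(self):
        t = LogFCTable("M", "methylation", {"G": 0.1})
        assert not threshold_calls(t)[0].passes

    def test_p_value_filter(self):
        t = LogFCTable("E", "expression", {"G": -3.0})
        assert not threshold_calls(t, p_values={"G": 0.2})[0].passes
        assert threshold_calls(t, p_values={"G": 0.001})[0].passes


class TestConcordanceClass:
    @pytest.mark.parametrize(
        "meth,expr,expected",
        [
            ("hyper", "down", "hyper_down"),
            ("hypo", "up", "hypo_up"),
            ("hyper", "up", "hyper_up"),
            ("hypo", "down", "hypo_down"),
        ],
    )
    def test_total_map(self, meth, expr, expected):
        assert concordance_class(meth, expr) == expected

    def test_invalid_status_rejected(self):
        with pytest.raises(ValueError):
            concordance_class("up", "down")


class TestSelectRobustGenes:
    def test_table1_style_gene_accepted_hyper_down(self):
        # expression and methylation replicate values as printed for the
        # hypermethylated/down-regulated exemplar gene
        e = expr_tables({"SLC30A10": [-2.04, -2.87, -2.16, -2.38]})
        m = meth_tables({"SLC30A10": [0.28, 0.44, 0.25, 0.19]})
        robust = select_robust_genes([current_hyper("SLC30A10")], e, m)
        assert robust == [
            ConcordantGene("SLC30A10", "hyper_down",
                           ("E0", "E1", "E2", "E3", "M0", "M1", "M2", "M3"))
        ]

    def test_sign_conflict_excluded_at_full_support(self):
        e = expr_tables({"SLC30A10": [-2.04, -2.87, 2.5, -2.38]})
        m = meth_tables({"SLC30A10": [0.28, 0.44, 0.25, 0.19]})
        assert select_robust_genes([current_hyper("SLC30A10")], e, m) == []

    def test_hyper_up_not_functional(self):
        e = expr_tables({"G": [2.5, 2.6, 2.7, 2.8]})
        m = meth_tables({"G": [0.3, 0.3, 0.3, 0.3]})
        assert select_robust_genes([current_hyper("G")], e, m) == []

    def test_meth_direction_must_match_current_call(self):
        e = expr_tables({"G": [-2.5, -2.6]})
        m = meth_tables({"G": [-0.3, -0.3]})  # external says hypo, current hyper
        assert select_robust_genes([current_hyper("G")], e, m) == []

    def test_zero_tables_errors(self):
        with pytest.raises(ValueError):
            select_robust_genes([current_hyper("G")], [], [])

    def test_monotone_in_thresholds(self):
        e = expr_tables({"A": [-2.1, -2.2], "B": [-1.4, -1.5]})
        m = meth_tables({"A": [0.3, 0.3], "B": [0.15, 0.2]})
        current = [current_hyper("A"), current_hyper("B")]
        sizes = []
        for expr_fc in (2.0, 3.0, 5.0):
            for meth_delta in (0.1, 0.25):
                p = ThresholdParams(expr_fc=expr_fc, meth_delta=meth_delta)
                sizes.append(((expr_fc, meth_delta),
                              len(select_robust_genes(current, e, m, params=p))))
        by_key = dict(sizes)
        # raising either threshold never adds a robust gene
        assert by_key[(2.0, 0.1)] >= by_key[(3.0, 0.1)] >= by_key[(5.0, 0.1)]
        assert by_key[(2.0, 0.1)] >= by_key[(2.0, 0.25)]

    def brute_force(self, current, e_tables, m_tables, params):
        """Nested set comprehensions over genes and datasets."""
        cut = params.expr_logfc_cut
        out = []
        for c in sorted(current, key=lambda x: x.gene_id):
            g = c.gene_id
            e_pass = {
                (t.dataset_id, "down" if t.rows[g] < 0 else "up")
                for t in e_tables
                if g in t.rows and abs(t.rows[g]) > cut
            }
            m_pass = {
                (t.dataset_id, "hyper" if t.rows[g] > 0 else "hypo")
                for t in m_tables
                if g in t.rows and abs(t.rows[g]) > params.meth_delta
            }
            e_dirs = {d for _, d in e_pass}
            m_dirs = {d for _, d in m_pass}
            if len(e_dirs) != 1 or len(m_pass) < len(m_tables) or len(e_pass) < len(e_tables):
                continue
            if m_dirs != {c.status}:
                continue
            klass = f"{c.status}_{next(iter(e_dirs))}"
            if klass in ("hyper_down", "hypo_up"):
                out.append((g, klass))
        return out

    def test_oracle_equivalence_random_fixtures(self):
        import numpy as np

        rng = np.random.default_rng(21)
        params = ThresholdParams()
        for _ in range(10):
            genes = [f"G{i}" for i in range(30)]
            e = expr_tables({g: list(rng.normal(0, 2, 3)) for g in genes})
            m = meth_tables({g: list(rng.normal(0, 0.2, 3)) for g in genes})
            current = []
            for g in genes[:15]:
                lfc = 1.0 if rng.random() < 0.5 else -1.0
                current.append(
                    GeneCall(g, "current", "methylation", lfc,
                             "hyper" if lfc > 0 else "hypo", True)
                )
            got = [(g.gene_id, g.klass) for g in select_robust_genes(current, e, m, params=params)]
            assert got == self.brute_force(current, e, m, params)

    def test_recovery_on_synthetic_truth(self):
        from methcrosstalk.simulate import (
            SimConfig,
            generate_external_datasets,
            generate_methylation_cohort,
        )

        cfg = SimConfig(seed=30, external_noise_sd=0.05, dropout=0.0,
                        n_genes=50, chrom_length=1_100_000,
                        n_hyper_dmr=8, n_hypo_dmr=6, n_marker_dmr=2)
        _, truth = generate_methylation_cohort(cfg)
        e, m = generate_external_datasets(cfg, truth)
        current = [
            GeneCall(p.gene_id, "current", "methylation",
                     1.0 if p.direction == "hyper" else -1.0, p.direction, True)
            for p in truth.planted_dmrs
        ]
        got = {g.gene_id: g.klass for g in select_robust_genes(current, e, m)}
        assert got == truth.concordant_genes

    def test_no_concordant_truth_yields_nothing(self):
        from methcrosstalk.simulate import (
            SimConfig,
            generate_external_datasets,
            generate_methylation_cohort,
        )

        cfg = SimConfig(seed=31, frac_concordant=0.0, n_marker_dmr=0,
                        n_genes=50, chrom_length=1_100_000,
                        n_hyper_dmr=8, n_hypo_dmr=6)
        _, truth = generate_methylation_cohort(cfg)
        assert truth.concordant_genes == {}
        e, m = generate_external_datasets(cfg, truth)
        current = [
            GeneCall(p.gene_id, "current", "methylation",
                     1.0 if p.direction == "hyper" else -1.0, p.direction, True)
            for p in truth.planted_dmrs
        ]
        assert select_robust_genes(current, e, m) == []


class TestCrosstab:
    def test_published_class_counts_sum(self):
        genes = (
            [ConcordantGene(f"a{i}", "hyper_down") for i in range(4)]
            + [ConcordantGene(f"b{i}", "hyper_up") for i in range(2)]
            + [ConcordantGene(f"c{i}", "hypo_down") for i in range(4)]
            + [ConcordantGene(f"d{i}", "hypo_up") for i in range(4)]
        )
        counts = crosstab_classes(genes)
        assert (counts["hyper_down"], counts["hyper_up"],
                counts["hypo_down"], counts["hypo_up"]) == (4, 2, 4, 4)
        assert counts["total"] == 14

    def test_empty(self):
        counts = crosstab_classes([])
        assert counts["total"] == 0

    def test_direction_level_sum(self):
        genes = [ConcordantGene(f"h{i}", "hyper_down") for i in range(449)] + [
            ConcordantGene(f"l{i}", "hypo_up") for i in range(378)
        ]
        assert crosstab_classes(genes)["total"] == 827
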