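import itertools

import numpy as np
import pandas as pd
import pytest

import septikit as sk
from septikit.io import SeptikitError

PANEL = frozenset(sk.PANEL_GENES)


def _matrix(values: dict[str, list[float]]) -> sk.ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return sk.ExpressionMatrix(df)


class TestRatioFeature:
    def test_hand_arithmetic(self):
        m = _matrix({"A": [10.0, 12.0], "B": [9.0, 9.0]})
        feat = sk.compute_ratio_feature(m, "A", "B")
        assert feat.tolist() == [1.0, 3.0]

    def test_antisymmetry(self):
        m = _matrix({"A": [10.0, 12.0, 7.5], "B": [9.0, 9.0, 8.25]})
        ab = sk.compute_ratio_feature(m, "A", "B")
        ba = sk.compute_ratio_feature(m, "B", "A")
        np.testing.assert_allclose(ab.to_numpy(), -ba.to_numpy())

    def test_same_gene_gives_zero(self):
        m = _matrix({"A": [10.0, 12.0]})
        assert sk.compute_ratio_feature(m, "A", "A").tolist() == [0.0, 0.0]

    def test_unknown_gene_named(self, tiny_matrix):
        with pytest.raises(SeptikitError, match="NOPE"):
            sk.compute_ratio_feature(tiny_matrix, "PLAC8", "NOPE")


class TestPrefilter:
    def test_planted_gene_ranks_first(self):
        rng = np.random.default_rng(11)
        n = 60
        genes = {f"N{i:02d}": rng.normal(8, 1, n).tolist() for i in range(50)}
        case = np.zeros(n, bool); case[:30] = True
        genes["HIT"] = (rng.normal(8, 1, n) + 2.0 * case).tolist()
        m = _matrix(genes)
        labels = sk.CohortLabels(pd.DataFrame(
            {"class_label": np.where(case, "case", "control")},
            index=pd.Index(m.sample_ids, name="sample_id")))
        assert sk.prefilter_genes(m, labels, 5)[0] == "HIT"

    def test_top_n_equal_gene_count_is_identity_set(self, tiny_matrix, tiny_labels):
        got = sk.prefilter_genes(tiny_matrix, tiny_labels, 4)
        assert set(got) == set(tiny_matrix.gene_ids)

    def test_constant_matrix_falls_to_tiebreak(self, tiny_labels):
        m = _matrix({g: [5.0] * 6 for g in ("b", "a", "c")})
        assert sk.prefilter_genes(m, tiny_labels, 3) == ["a", "b", "c"]

    def test_oversized_top_n_warns_and_returns_all(self, tiny_matrix, tiny_labels):
        with pytest.warns(UserWarning, match="exceeds gene count"):
            got = sk.prefilter_genes(tiny_matrix, tiny_labels, 99)
        assert len(got) == 4


class TestScreen:
    def test_combinatorial_count(self, discovery_cohort):
        _, matrix, labels = discovery_cohort
        pool = matrix.gene_ids[:10]
        assert len(sk.screen_all_ratios(matrix, labels, pool)) == 45

    def test_planted_pair_ranks_first(self, discovery_cohort):
        _, matrix, labels = discovery_cohort
        top = sk.screen_all_ratios(matrix, labels)[0]
        assert top.genes <= PANEL
        # a planted up-gene over a planted down-gene, oriented toward cases
        up = {"PLAC8", "LAMP1"}
        high = top.gene_a if top.orientation == 1 else top.gene_b
        assert high in up

    @pytest.mark.parametrize("objective", ["binormal", "empirical"])
    def test_oriented_auc_at_least_half(self, discovery_cohort, objective):
        _, matrix, labels = discovery_cohort
        ranked = sk.screen_all_ratios(matrix, labels, matrix.gene_ids[:12],
                                      objective=objective)
        assert all(0.5 <= r.auc <= 1.0 for r in ranked)
        aucs = [r.auc for r in ranked]
        assert aucs == sorted(aucs, reverse=True)

    def test_label_swap_flips_orientation_not_auc(self, discovery_cohort):
        _, matrix, labels = discovery_cohort
        swapped = sk.CohortLabels(labels.frame.assign(
            class_label=labels.frame["class_label"].map(
                {"case": "control", "control": "case"})))
        pool = matrix.gene_ids[:8]
        a = sk.screen_all_ratios(matrix, labels, pool)
        b = sk.screen_all_ratios(matrix, swapped, pool)
        for ra, rb in zip(a, b):
            assert (ra.genes, ra.auc) == (rb.genes, pytest.approx(rb.auc))
            if ra.auc > 0.5 + 1e-9:
                assert ra.orientation == -rb.orientation

    def test_log_base_change_leaves_ranking(self, discovery_cohort):
        # base change = positive scalar multiply of every log intensity
        _, matrix, labels = discovery_cohort
        scaled = sk.ExpressionMatrix(matrix.data * np.log10(2.0))
        pool = matrix.gene_ids[:8]
        a = sk.screen_all_ratios(matrix, labels, pool, objective="empirical")
        b = sk.screen_all_ratios(scaled, labels, pool, objective="empirical")
        assert [(r.genes, round(r.auc, 12)) for r in a] == \
               [(r.genes, round(r.auc, 12)) for r in b]

    def test_null_permutation_top_auc_moderate(self):
        rng = np.random.default_rng(5)
        n = 60
        m = _matrix({f"g{i:02d}": rng.normal(8, 1, n).tolist() for i in range(20)})
        tops = []
        for s in range(20):
            perm = np.random.default_rng(s).permutation(n)
            lab = np.where(perm < 30, "case", "control")
            labels = sk.CohortLabels(pd.DataFrame(
                {"class_label": lab}, index=pd.Index(m.sample_ids, name="sample_id")))
            tops.append(sk.screen_all_ratios(m, labels, objective="empirical")[0].auc)
        assert 0.5 <= float(np.median(tops)) <= 0.75


class TestGreedy:
    def test_recovers_planted_signature(self, discovery_cohort):
        _, matrix, labels = discovery_cohort
        clf = sk.discover(matrix, labels, prefilter_top=20)
        assert clf.gene_set == PANEL
        assert clf.training_auc >= clf.ratio_1.auc

    def test_matches_exhaustive_pair_search(self, discovery_cohort):
        """Greedy equals brute force over all disjoint ratio pairs on a small pool."""
        _, matrix, labels = discovery_cohort
        pool = sorted(PANEL) + ["GENE0001", "GENE0002", "GENE0003", "GENE0004"]
        ranked = sk.screen_all_ratios(matrix, labels, pool, objective="empirical")
        clf = sk.greedy_pair_search(matrix, labels, ranked,
                                    pool_k=len(ranked) - 1, objective="empirical")

        known = labels.known_status()
        case = known.case_mask(matrix.sample_ids)
        seed = ranked[0]

        def auc_of(feature):
            vals = feature.to_numpy()
            return sk.mann_whitney_auc(vals[case], vals[~case])

        best = None
        for partner in ranked[1:]:
            if partner.genes & seed.genes:
                continue
            combined = seed.values(matrix) + partner.values(matrix)
            a = auc_of(combined)
            if best is None or a > best[0]:
                best = (a, partner.genes)
        assert clf.training_auc == pytest.approx(best[0])
        assert clf.ratio_2.genes == best[1]

    def test_no_admissible_partner_degenerates(self, tiny_matrix, tiny_labels):
        # the only candidate in the pool shares a gene with the seed
        ranked = [sk.RatioFeature("PLAC8", "PLA2G7", 1, 0.9),
                  sk.RatioFeature("PLA2G7", "LAMP1", 1, 0.8)]
        with pytest.warns(UserWarning, match="single-ratio"):
            clf = sk.greedy_pair_search(tiny_matrix, tiny_labels, ranked, pool_k=1)
        assert clf.ratio_2 is None
        assert clf.training_auc == 0.9

    def test_selection_optimism_shrinks_with_n(self):
        """On pure-noise data the top training AUC exceeds 0.5 but decays with n."""
        def top_auc(n_per_class, seed):
            rng = np.random.default_rng(seed)
            m = _matrix({f"g{i:02d}": rng.normal(8, 1, 2 * n_per_class).tolist()
                         for i in range(12)})
            lab = ["case"] * n_per_class + ["control"] * n_per_class
            labels = sk.CohortLabels(pd.DataFrame(
                {"class_label": lab}, index=pd.Index(m.sample_ids, name="sample_id")))
            return sk.screen_all_ratios(m, labels, objective="empirical")[0].auc

        small = np.mean([top_auc(15, 100 + s) for s in range(15)])
        large = np.mean([top_auc(150, 200 + s) for s in range(15)])
        assert small > large > 0.5
        assert small - 0.5 > 2 * (large - 0.5)  # optimism gap shrinks


class TestApplyClassifier:
    def test_canonical_hand_arithmetic(self):
        m = _matrix({"PLAC8": [12.0], "PLA2G7": [10.0], "LAMP1": [11.0], "CEACAM4": [9.0]})
        score = sk.apply_classifier(sk.septicyte_classifier(), m)
        assert score.tolist() == [4.0]

    def test_equal_genes_score_zero(self):
        m = _matrix({g: [10.0] for g in sk.PANEL_GENES})
        assert sk.apply_classifier(sk.septicyte_classifier(), m).tolist() == [0.0]

    def test_per_sample_shift_invariance(self, tiny_matrix):
        clf = sk.septicyte_classifier()
        base = sk.apply_classifier(clf, tiny_matrix)
        shifted = sk.ExpressionMatrix(tiny_matrix.data + 3.7)
        np.testing.assert_allclose(
            sk.apply_classifier(clf, shifted).to_numpy(), base.to_numpy(), atol=1e-12)

    def test_missing_gene_errors(self, tiny_matrix):
        m = sk.ExpressionMatrix(tiny_matrix.data.drop(index="LAMP1"))
        with pytest.raises(SeptikitError, match="LAMP1"):
            sk.apply_classifier(sk.septicyte_classifier(), m)


class TestDifferentialExpression:
    @pytest.mark.parametrize("ix, iy, included", [
        (150.0, 400.0, True),    # fold 2.67, both > 100
        (90.0, 400.0, False),    # one signal <= 100
        (200.0, 200.0, False),   # fold 1.0
        (400.0, 150.0, True),    # direction-symmetric
    ])
    def test_rules(self, ix, iy, included):
        df = pd.DataFrame({"x": [ix], "y": [iy]}, index=["g"])
        m = sk.ExpressionMatrix(df, scale="linear")
        got = sk.differential_expression_filter(m, "x", "y")
        assert (got == ["g"]) == included

    def test_accepts_log2_input(self):
        df = np.log2(pd.DataFrame({"x": [150.0, 90.0], "y": [400.0, 400.0]},
                                  index=["g1", "g2"]))
        m = sk.ExpressionMatrix(df, scale="log2")
        assert sk.differential_expression_filter(m, "x", "y") == ["g1"]
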