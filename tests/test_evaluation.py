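"""Consistency, recall, indirect auditing, and association statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phenoseverity.annotation import Characteristic, Frequency
from phenoseverity.evaluation import (
    chance_consistency,
    class_score_concordance,
    congenital_by_branch,
    consistency_rates,
    depth_consistency_association,
    flag_indirect,
    metric_correlations,
    reassign_indirect,
    true_positive_rate,
)
from phenoseverity.scoring import classify_severity, score_all

from conftest import build_ontology, make_record, make_set

C = Characteristic


class TestConsistency:
    def test_identical_replicates_consistent_under_both(self):
        rep = consistency_rates(make_set(
            make_record(replicate=1, death="always"),
            make_record(replicate=2, death="always"),
        ))
        assert rep.lenient_rate[C.DEATH] == 1.0
        assert rep.stringent_rate[C.DEATH] == 1.0

    def test_always_often_is_lenient_only(self):
        rep = consistency_rates(make_set(
            make_record(replicate=1, death="always"),
            make_record(replicate=2, death="often"),
        ))
        assert rep.lenient_rate[C.DEATH] == 1.0
        assert rep.stringent_rate[C.DEATH] == 0.0

    def test_cross_group_pair_is_inconsistent(self):
        rep = consistency_rates(make_set(
            make_record(replicate=1, death="rarely"),
            make_record(replicate=2, death="often"),
        ))
        assert rep.lenient_rate[C.DEATH] == 0.0

    def test_three_replicates_require_all_to_agree(self):
        rep = consistency_rates(make_set(
            make_record(replicate=1, death="always"),
            make_record(replicate=2, death="always"),
            make_record(replicate=3, death="rarely"),
        ))
        assert rep.lenient_rate[C.DEATH] == 0.0
        assert rep.stringent_rate[C.DEATH] == 0.0

    def test_no_duplicates_is_an_error(self):
        with pytest.raises(ValueError, match="replicates"):
            consistency_rates(make_set(make_record()))

    def test_stringent_never_exceeds_lenient(self):
        rng = np.random.default_rng(11)
        records = []
        for i in range(60):
            for rep in (1, 2):
                words = {
                    c.value: Frequency(rng.integers(4)).word for c in C
                }
                records.append(
                    make_record(phenotype=f"HP:{i:07d}", replicate=rep, **words)
                )
        report = consistency_rates(make_set(*records))
        for c in C:
            assert report.stringent_rate[c] <= report.lenient_rate[c]


class TestChanceConsistency:
    def test_pair_values_exact(self):
        assert chance_consistency(2, "lenient") == 0.5
        assert chance_consistency(2, "stringent") == 0.25

    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize("metric", ["lenient", "stringent"])
    def test_matches_enumeration_of_uniform_draws(self, k, metric):
        group = (lambda f: f // 2) if metric == "lenient" else (lambda f: f)
        hits = sum(
            1
            for draw in itertools.product(range(4), repeat=k)
            if len({group(f) for f in draw}) == 1
        )
        assert chance_consistency(k, metric) == pytest.approx(hits / 4**k)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            chance_consistency(1, "lenient")


class TestRecall:
    def test_all_truth_members_always_gives_one(self):
        truth = {C.CANCER: {"HP:0000001", "HP:0000002"}}
        aset = make_set(
            make_record(phenotype="HP:0000001", cancer="always"),
            make_record(phenotype="HP:0000002", cancer="often"),
        )
        rep = true_positive_rate(aset, truth)
        assert rep.recall[C.CANCER] == 1.0

    def test_counting_oracle_seven_of_eight(self):
        ids = [f"HP:{i:07d}" for i in range(8)]
        records = [
            make_record(phenotype=t, cancer="often" if i < 7 else "rarely")
            for i, t in enumerate(ids)
        ]
        rep = true_positive_rate(make_set(*records), {C.CANCER: set(ids)})
        assert rep.n_truth[C.CANCER] == 8
        assert rep.n_hit[C.CANCER] == 7
        assert rep.recall[C.CANCER] == 0.875

    def test_absent_truth_members_excluded_from_denominator(self):
        truth = {C.CANCER: {"HP:0000001", "HP:0000099"}}
        rep = true_positive_rate(
            make_set(make_record(phenotype="HP:0000001", cancer="always")), truth
        )
        assert rep.n_truth[C.CANCER] == 1

    def test_empty_denominator_is_nan_not_zero(self):
        rep = true_positive_rate(
            make_set(make_record(phenotype="HP:0000001")), {C.CANCER: {"HP:0000099"}}
        )
        assert math.isnan(rep.recall[C.CANCER])

    def test_first_replicate_used_by_default(self):
        aset = make_set(
            make_record(phenotype="HP:0000001", replicate=1, cancer="never"),
            make_record(phenotype="HP:0000001", replicate=2, cancer="always"),
        )
        rep = true_positive_rate(aset, {C.CANCER: {"HP:0000001"}})
        assert rep.recall[C.CANCER] == 0.0


class TestIndirectAudit:
    def test_example_justification_is_flagged(self):
        rec = make_record(justifications={
            C.CANCER: "Obesity does not directly cause cancer, although it is a risk factor"
        })
        flags = flag_indirect(make_set(rec))
        assert len(flags) == 1
        assert flags[0].characteristic == C.CANCER
        assert flags[0].matched_pattern == "does not directly"

    def test_plain_direct_justification_not_flagged(self):
        rec = make_record(justifications={C.IMPAIRED_MOBILITY: "directly causes paralysis"})
        assert flag_indirect(make_set(rec)) == []

    def test_empty_justification_not_flagged(self):
        rec = make_record(justifications={c: "" for c in C})
        assert flag_indirect(make_set(rec)) == []

    def test_no_flags_reassignment_is_identity(self):
        aset = make_set(make_record(death="always"))
        out = reassign_indirect(aset, [])
        assert out.records[0].annotations == aset.records[0].annotations

    def test_flagged_always_to_never_drops_nss_by_weighted_share(self):
        rec = make_record(
            death="always",
            justifications={C.DEATH: "it indirectly causes death via complications"},
        )
        aset = make_set(rec)
        flags = flag_indirect(aset)
        before = score_all(aset)["nss"].iloc[0]
        after = score_all(reassign_indirect(aset, flags))["nss"].iloc[0]
        assert before - after == pytest.approx(100 * 18 / 99)

    def test_reassignment_never_raises_nss_or_class(self):
        rng = np.random.default_rng(5)
        records = []
        for i in range(80):
            words, justs = {}, {}
            for c in C:
                f = Frequency(rng.integers(4))
                words[c.value] = f.word
                justs[c] = (
                    "this one indirectly contributes" if rng.random() < 0.4 else "direct cause"
                )
            records.append(
                make_record(phenotype=f"HP:{i:07d}", justifications=justs, **words)
            )
        aset = make_set(*records)
        out = reassign_indirect(aset, flag_indirect(aset))
        before, after = score_all(aset), score_all(out)
        assert (after["nss"] <= before["nss"] + 1e-12).all()
        for b, a in zip(aset.records, out.records):
            assert classify_severity(a) <= classify_severity(b)


class TestCorrelations:
    def test_diagonal_is_one_and_matrix_symmetric(self):
        aset = make_set(
            make_record(phenotype="HP:0000001", death="always", cancer="always"),
            make_record(phenotype="HP:0000002", death="often", cancer="rarely"),
            make_record(phenotype="HP:0000003", death="never", cancer="often"),
            make_record(phenotype="HP:0000004", death="rarely", cancer="never"),
        )
        corr = metric_correlations(score_all(aset))
        assert np.allclose(np.diag(corr.values), 1.0)
        assert np.allclose(corr.values, corr.values.T, equal_nan=True)

    def test_constant_column_is_nan_not_zero(self):
        aset = make_set(
            make_record(phenotype="HP:0000001", death="always"),
            make_record(phenotype="HP:0000002", death="often"),
            make_record(phenotype="HP:0000003", death="never"),
        )
        corr = metric_correlations(score_all(aset))
        assert math.isnan(corr.loc["cancer", "death"])  # cancer constant 'never'

    def test_matches_textbook_pearson_formula(self):
        death = [3, 2, 0, 1, 3]
        cancer = [3, 1, 0, 2, 2]
        records = [
            make_record(
                phenotype=f"HP:{i:07d}",
                death=Frequency(d).word,
                cancer=Frequency(k).word,
            )
            for i, (d, k) in enumerate(zip(death, cancer))
        ]
        corr = metric_correlations(score_all(make_set(*records)))
        x, y = np.array(death, float), np.array(cancer, float)
        n = len(x)
        r_hand = (
            (n * (x * y).sum() - x.sum() * y.sum())
            / math.sqrt(n * (x**2).sum() - x.sum() ** 2)
            / math.sqrt(n * (y**2).sum() - y.sum() ** 2)
        )
        assert corr.loc["death", "cancer"] == pytest.approx(r_hand, abs=1e-12)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            metric_correlations(score_all(make_set(make_record(), make_record(phenotype="HP:2"))))


class TestCongenitalByBranch:
    @pytest.fixture
    def two_branch_ontology(self):
        return build_ontology(
            {
                "HP:0000002": ["HP:0000001"],
                "HP:0000003": ["HP:0000001"],
                "HP:0000004": ["HP:0000002"],
                "HP:0000005": ["HP:0000002"],
                "HP:0000006": ["HP:0000003"],
                "HP:0000007": ["HP:0000002", "HP:0000003"],
            },
            names={"HP:0000001": "Phenotypic abnormality",
                   "HP:0000002": "Branch A", "HP:0000003": "Branch B"},
        )

    def test_all_always_branch(self, two_branch_ontology):
        aset = make_set(
            make_record(phenotype="HP:0000004", congenital_onset="always"),
            make_record(phenotype="HP:0000005", congenital_onset="always"),
        )
        df = congenital_by_branch(aset, two_branch_ontology)
        row = df[df["branch_id"] == "HP:0000002"].iloc[0]
        assert (row["always"], row["often"], row["rarely"], row["never"]) == (1.0, 0, 0, 0)

    def test_proportions_sum_to_one_and_sorted_by_always(self, two_branch_ontology):
        aset = make_set(
            make_record(phenotype="HP:0000004", congenital_onset="always"),
            make_record(phenotype="HP:0000005", congenital_onset="never"),
            make_record(phenotype="HP:0000006", congenital_onset="always"),
        )
        df = congenital_by_branch(aset, two_branch_ontology)
        sums = df[["never", "rarely", "often", "always"]].sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert list(df["always"]) == sorted(df["always"], reverse=True)

    def test_multi_branch_phenotype_counted_in_each(self, two_branch_ontology):
        aset = make_set(make_record(phenotype="HP:0000007", congenital_onset="often"))
        df = congenital_by_branch(aset, two_branch_ontology)
        assert set(df["branch_id"]) == {"HP:0000002", "HP:0000003"}
        assert (df["n"] == 1).all()


class TestDepthConsistency:
    def _chain_ontology(self, n_levels=4, per_level=12):
        edges, names = {}, {"HP:0000001": "Phenotypic abnormality"}
        edges["HP:0000002"] = ["HP:0000001"]
        names["HP:0000002"] = "Branch"
        counter = 3
        parents_at_level = {1: "HP:0000002"}
        for level in range(2, n_levels + 1):
            tid = f"HP:{counter:07d}"
            counter += 1
            edges[tid] = [parents_at_level[level - 1]]
            parents_at_level[level] = tid
        leaves = []
        for level in range(1, n_levels + 1):
            for _ in range(per_level):
                tid = f"HP:{counter:07d}"
                counter += 1
                edges[tid] = [parents_at_level[level]]
                leaves.append((tid, level + 1))
        return build_ontology(edges, names=names), leaves

    def test_null_case_rho_near_zero(self):
        ont, leaves = self._chain_ontology()
        rng = np.random.default_rng(21)
        records = []
        for tid, _level in leaves:
            for rep in (1, 2):
                words = {c.value: Frequency(rng.integers(4)).word for c in C}
                records.append(make_record(phenotype=tid, replicate=rep, **words))
        out = depth_consistency_association(make_set(*records), ont)
        # consistency is independent of depth by construction
        assert abs(out["spearman_rho"]) < 0.35
        assert out["n"] == len(leaves)

    def test_perfectly_separated_table_gives_cramers_v_one(self):
        ont, leaves = self._chain_ontology(n_levels=2, per_level=10)
        records = []
        for tid, level in leaves:
            consistent = level == 2  # shallow leaves consistent, deep not
            for rep in (1, 2):
                word = "always" if consistent or rep == 1 else "never"
                records.append(
                    make_record(phenotype=tid, replicate=rep, default=Frequency.from_word(word))
                )
        out = depth_consistency_association(make_set(*records), ont)
        assert out["cramers_v"] == pytest.approx(1.0)

    def test_chi_square_matches_textbook_formula(self):
        # hand-built 3x2 table via scipy-free arithmetic
        table = np.array([[10, 2], [6, 6], [2, 10]], dtype=float)
        row, col = table.sum(1, keepdims=True), table.sum(0, keepdims=True)
        expected = row @ col / table.sum()
        chi2_hand = (((table - expected) ** 2) / expected).sum()
        from scipy.stats import chi2_contingency

        chi2, _, _, _ = chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(chi2_hand)

    def test_single_depth_level_is_degenerate(self):
        ont = build_ontology(
            {"HP:0000002": ["HP:0000001"], "HP:0000003": ["HP:0000002"]},
            names={"HP:0000001": "Phenotypic abnormality"},
        )
        aset = make_set(
            make_record(phenotype="HP:0000003", replicate=1),
            make_record(phenotype="HP:0000003", replicate=2),
        )
        with pytest.raises(ValueError, match="depth"):
            depth_consistency_association(aset, ont)


class TestClassScoreConcordance:
    def test_hand_computed_omega_squared(self):
        # 12 records, 3 classes x 4; ANOVA table computed by hand below
        groups = {
            "Mild": [0.0, 2.0, 1.0, 1.0],
            "Moderate": [20.0, 22.0, 21.0, 21.0],
            "Severe": [40.0, 42.0, 41.0, 41.0],
        }
        df = pd.DataFrame(
            [
                {"severity_class": cls, "nss": v}
                for cls, values in groups.items()
                for v in values
            ]
        )
        values = [v for vs in groups.values() for v in vs]
        grand = sum(values) / len(values)
        ss_b = sum(len(vs) * (sum(vs) / len(vs) - grand) ** 2 for vs in groups.values())
        ss_w = sum((v - sum(vs) / len(vs)) ** 2 for vs in groups.values() for v in vs)
        ms_w = ss_w / (12 - 3)
        omega_hand = (ss_b - 2 * ms_w) / (ss_b + ss_w + ms_w)
        out = class_score_concordance(df)
        assert out["omega_squared_partial"] == pytest.approx(omega_hand, abs=1e-10)
        assert out["p_value"] < 1e-9

    def test_identical_within_distinct_between_approaches_one(self):
        df = pd.DataFrame(
            {"severity_class": ["Mild"] * 5 + ["Severe"] * 5, "nss": [0.0] * 5 + [50.0] * 5}
        )
        out = class_score_concordance(df)
        assert out["omega_squared_partial"] == pytest.approx(1.0)
        assert out["p_value"] == 0.0

    def test_identical_distributions_give_near_zero(self):
        rng = np.random.default_rng(3)
        values = rng.normal(50, 10, size=400)
        df = pd.DataFrame(
            {"severity_class": ["Mild", "Severe"] * 200, "nss": values}
        )
        out = class_score_concordance(df)
        assert abs(out["omega_squared_partial"]) < 0.05

    def test_single_class_rejected(self):
        df = pd.DataFrame({"severity_class": ["Mild"] * 4, "nss": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            class_score_concordance(df)
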