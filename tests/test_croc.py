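"""Rare-variant collapsing: MAF split, pseudo-common growth, CROC fits."""

import numpy as np
import pytest

from crocpred import (
    GenotypeDataset,
    InvalidArgumentError,
    SimulationConfig,
    assign_scores,
    build_collapsing_plan,
    collapse_burden,
    collapse_indicator,
    compute_auc,
    estimate_lr_table,
    fit_croc,
    fit_froc,
    grow_pseudo_variant,
    materialize_pseudo_variants,
    predict,
    simulate_dataset,
    simulate_from_truth,
    split_by_maf,
)
from crocpred.io import dumps_document, model_to_document

from conftest import make_random_dataset


def dataset_with_maf(maf_values, n=40, seed=0):
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, maf_values, size=(n, len(maf_values))).astype(np.int8)
    phen = rng.integers(0, 2, n).astype(np.int8)
    phen[:2] = [1, 0]
    data = GenotypeDataset(
        geno, phen, [f"v{i}" for i in range(len(maf_values))]
    )
    data.maf = np.asarray(maf_values, dtype=float)  # pin the intended MAFs
    return data


def rare_dataset(carrier_matrix, phenotype):
    """Dataset of 0/1 rare-carrier columns from explicit carrier lists."""
    geno = np.asarray(carrier_matrix, dtype=np.int8)
    return GenotypeDataset(
        geno, np.asarray(phenotype, dtype=np.int8),
        [f"r{i}" for i in range(geno.shape[1])],
    )


class TestSplitByMaf:
    def test_threshold_partition(self):
        data = dataset_with_maf([0.2, 0.005, 0.0007])
        common, rare = split_by_maf(data, 0.01)
        assert common == [0] and rare == [1, 2]

    def test_boundary_and_strictness(self):
        data = dataset_with_maf([0.2, 0.01, 0.005])
        common, rare = split_by_maf(data, 0.01)
        assert 1 in common  # MAF exactly at threshold counts as common
        common, rare = split_by_maf(data, 0.5)
        assert common == [] and sorted(rare) == [0, 1, 2]

    def test_invalid_threshold(self):
        data = dataset_with_maf([0.2])
        for bad in (0.0, -0.1, 0.6):
            with pytest.raises(InvalidArgumentError):
                split_by_maf(data, bad)


class TestCollapseCodings:
    def test_indicator_union_of_carriers(self):
        # six individuals, one carrier each at distinct variants of a
        # 3-variant group -> exactly three carriers of the pseudo-variant
        geno = np.zeros((6, 4), dtype=np.int8)
        geno[0, 0] = 1
        geno[1, 1] = 2
        geno[2, 2] = 1
        geno[3, 3] = 2  # outside the group
        data = rare_dataset(geno, [1, 1, 1, 0, 0, 0])
        col = collapse_indicator(data, [0, 1, 2])
        assert col.tolist() == [1, 1, 1, 0, 0, 0]
        assert col.sum() == 3

    def test_burden_counts_clip_at_two(self):
        geno = np.array([[1, 1, 1], [2, 2, 0], [0, 0, 0]], dtype=np.int8)
        data = rare_dataset(geno, [1, 0, 1])
        assert collapse_burden(data, [0, 1, 2]).tolist() == [2, 2, 0]

    def test_empty_group_rejected(self):
        data = rare_dataset(np.zeros((4, 2), dtype=np.int8) + [[1, 0]], [1, 0, 1, 0])
        with pytest.raises(InvalidArgumentError):
            collapse_indicator(data, [])


class TestGrowPseudoVariant:
    def test_distinct_case_carriers_are_absorbed(self):
        """Two rare risk variants carried by distinct cases collapse into one
        pseudo-variant whose AUC beats each single variant's."""
        n = 20
        geno = np.zeros((n, 3), dtype=np.int8)
        phen = np.array([1] * 8 + [0] * 12, dtype=np.int8)
        geno[0, 0] = 1  # case-only carrier of r0
        geno[1, 1] = 1  # a different case carries r1
        geno[10, 2] = 1  # r2 is carried by a control
        data = rare_dataset(geno, phen)
        group, aucs = grow_pseudo_variant(data, [0, 1, 2])
        assert set(group[:2]) == {0, 1}
        singles = []
        for v in (0, 1):
            col = collapse_indicator(data, [v])
            d1 = GenotypeDataset(col[:, None], phen, ["p"])
            t = estimate_lr_table(d1, [0])
            singles.append(compute_auc(assign_scores(t, d1), phen).auc)
        assert aucs[1] > max(singles)

    def test_singleton_pool(self, rng):
        data = make_random_dataset(rng, n=30, m=3)
        group, aucs = grow_pseudo_variant(data, [2])
        assert group == [2]
        assert len(aucs) == 1

    def test_auc_sequence_strictly_increases_after_seed(self, rng):
        for _ in range(20):
            n = 60
            geno = (rng.random((n, 8)) < 0.05).astype(np.int8)
            phen = rng.integers(0, 2, n).astype(np.int8)
            phen[:2] = [1, 0]
            data = rare_dataset(geno, phen)
            _, aucs = grow_pseudo_variant(data, list(range(8)))
            assert (np.diff(aucs) > 0).all()

    def test_matches_brute_force_greedy_oracle(self, rng):
        """On <=6 rares the greedy group equals an independent brute-force
        greedy re-implementation built on the LR-table AUC route."""
        for _ in range(15):
            n = 40
            geno = (rng.random((n, 6)) < 0.08).astype(np.int8)
            phen = rng.integers(0, 2, n).astype(np.int8)
            phen[:2] = [1, 0]
            data = rare_dataset(geno, phen)

            def table_auc(members):
                col = collapse_indicator(data, members)
                d1 = GenotypeDataset(col[:, None], phen, ["p"])
                t = estimate_lr_table(d1, [0])
                return compute_auc(assign_scores(t, d1), phen).auc

            expected, cur, remaining = [], -np.inf, list(range(6))
            while remaining:
                scored = [(table_auc(expected + [r]), r) for r in remaining]
                best_auc = max(a for a, _ in scored)
                best = min(r for a, r in scored if a == best_auc)
                if expected and best_auc <= cur:
                    break
                expected.append(best)
                remaining.remove(best)
                cur = best_auc
            group, _ = grow_pseudo_variant(data, list(range(6)))
            assert group == expected

    def test_null_pseudo_variant_has_no_heldout_signal(self):
        """Groups grown on phenotype-independent rares show AUC ~ 0.5 on an
        independent replicate (training AUC is inflated by construction)."""
        heldout = []
        for r in range(40):
            config = SimulationConfig(
                n_cases=60, n_controls=140, n_common=0, n_rare=30,
                causal_common=0, causal_rare=0, seed=61000 + r,
            )
            train = simulate_dataset(config)
            test = simulate_from_truth(train.truth, 60, 140, 71000 + r)
            group, aucs = grow_pseudo_variant(train, list(range(30)))
            assert aucs[-1] >= 0.5
            col = collapse_indicator(test, group)
            d1 = GenotypeDataset(col[:, None], test.phenotype, ["p"])
            t = estimate_lr_table(
                GenotypeDataset(
                    collapse_indicator(train, group)[:, None],
                    train.phenotype, ["p"],
                ),
                [0],
            )
            heldout.append(compute_auc(assign_scores(t, d1), test.phenotype).auc)
        mean = np.mean(heldout)
        se = np.std(heldout, ddof=1) / np.sqrt(len(heldout))
        assert abs(mean - 0.5) < 3 * se + 0.01


class TestBuildCollapsingPlan:
    def test_empty_rare_set_gives_empty_plan(self, rng):
        data = make_random_dataset(rng)
        plan = build_collapsing_plan(data, [])
        assert plan.n_groups == 0

    def test_plan_partitions_rare_set(self, rng):
        for _ in range(15):
            n, m = 50, 12
            geno = (rng.random((n, m)) < 0.06).astype(np.int8)
            phen = rng.integers(0, 2, n).astype(np.int8)
            phen[:2] = [1, 0]
            data = rare_dataset(geno, phen)
            rares = list(range(m))
            plan = build_collapsing_plan(data, rares)
            flat = [i for g in plan.groups for i in g]
            assert sorted(flat) == rares  # disjoint and exhaustive
            assert all(len(g) > 0 for g in plan.groups)

    def test_carrier_frequency_union_monotone(self, rng):
        n, m = 60, 8
        geno = (rng.random((n, m)) < 0.07).astype(np.int8)
        phen = rng.integers(0, 2, n).astype(np.int8)
        phen[:2] = [1, 0]
        data = rare_dataset(geno, phen)
        plan = build_collapsing_plan(data, list(range(m)))
        for group in plan.groups:
            union_freq = collapse_indicator(data, group).mean()
            for v in group:
                assert union_freq >= collapse_indicator(data, [v]).mean()

    def test_opposite_direction_clusters_stay_separate(self):
        """Risk-enriched and protective rares land in different groups when
        merging them would lower the AUC (bidirectional effects)."""
        n = 40
        phen = np.array([1] * 16 + [0] * 24, dtype=np.int8)
        geno = np.zeros((n, 4), dtype=np.int8)
        geno[0, 0] = 1
        geno[1, 1] = 1  # r0, r1 carried by distinct cases
        geno[20, 2] = 1
        geno[21, 3] = 1  # r2, r3 carried by distinct controls
        data = rare_dataset(geno, phen)
        plan = build_collapsing_plan(data, [0, 1, 2, 3])
        assert plan.n_groups >= 2
        risk = {0, 1}
        protective = {2, 3}
        for g in plan.groups:
            gs = set(g)
            assert not (gs & risk and gs & protective)


class TestFitCroc:
    def test_reduces_to_froc_without_rares(self):
        config = SimulationConfig(
            n_cases=50, n_controls=100, n_common=12, n_rare=0,
            causal_common=3, causal_rare=0, seed=99,
        )
        data = simulate_dataset(config)
        croc = fit_croc(data, 5, seed=7)
        froc = fit_froc(data, None, 5, seed=7)
        assert dumps_document(model_to_document(croc)) == dumps_document(
            model_to_document(froc)
        )

    def test_predict_two_path_equivalence(self):
        """Scoring raw genotypes through the model's plan equals scoring
        pre-collapsed genotypes directly."""
        config = SimulationConfig(
            n_cases=60, n_controls=140, n_common=10, n_rare=40,
            causal_common=2, causal_rare=8, seed=17,
        )
        train = simulate_dataset(config)
        test = simulate_from_truth(train.truth, 60, 140, 18)
        model = fit_croc(train, 5, seed=3)
        via_plan = predict(model, test)
        pre = materialize_pseudo_variants(test, model.collapsing_plan)
        direct = assign_scores(model.lr_table, pre)
        assert np.array_equal(via_plan, direct)

    def test_model_carries_plan_and_pseudo_ids(self):
        config = SimulationConfig(
            n_cases=60, n_controls=140, n_common=5, n_rare=30,
            causal_common=0, causal_rare=10, effect_rare=3.0, seed=5,
        )
        data = simulate_dataset(config)
        model = fit_croc(data, 5, seed=11)
        assert model.collapsing_plan is not None
        assert model.config["method"] == "croc"
        plan_vids = {v for g in model.collapsing_plan.group_variant_ids for v in g}
        assert plan_vids <= set(data.variant_ids)
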