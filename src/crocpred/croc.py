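"""Collapsing ROC (CROC): multistage collapsing of rare variants.

Rare variants (MAF below a threshold, default 0.01) are greedily grouped
into *pseudo-common variants*: a group's indicator column is 1 for any
individual carrying a minor allele at any member variant (the Li-and-Leal
carrier coding). A group is grown one rare variant at a time, always adding
the variant that raises the pseudo-variant's LR-ordered AUC the most, and
stops growing when no addition increases the AUC. The procedure repeats on
the leftover rare variants until none remain, so the resulting plan is a
partition of the rare set; risk-increasing and protective variants end up
in separate groups because mixing directions lowers a group's AUC. Forward
selection (FROC) then searches common and pseudo-common variants together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_LR_CAP,
    DEFAULT_MAF_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_UNSEEN_LR,
    GenotypeDataset,
    InvalidArgumentError,
    SchemaMismatchError,
    _auc_from_group_counts,
    _lr_from_counts,
)
from .froc import (
    CV_FIXED_PATH,
    CV_NESTED,
    DEFAULT_FOLDS,
    DEFAULT_MAX_MODEL_SIZE,
    RiskModel,
    fit_froc,
)

logger = logging.getLogger("crocpred")

CODING_INDICATOR = "indicator"
CODING_BURDEN = "burden"
PSEUDO_ID_PREFIX = "PCV"


@dataclass
class CollapsingPlan:
    """Ordered disjoint groups of rare variants, one pseudo-common variant each.

    ``groups`` holds build-time column indices (``None`` for a plan reloaded
    from disk); ``group_variant_ids`` is the portable representation used to
    re-apply the plan to new data.
    """

    group_variant_ids: list[list[str]]
    group_ids: list[str]
    per_group_auc: list[float]
    maf_threshold: float
    coding: str = CODING_INDICATOR
    groups: list[list[int]] | None = None

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)


def split_by_maf(
    data: GenotypeDataset, threshold: float = DEFAULT_MAF_THRESHOLD
) -> tuple[list[int], list[int]]:
    """Partition variant indices into common and rare by strict MAF cutoff.

    A variant is rare when its MAF is strictly below ``threshold``; a MAF
    exactly at the threshold is common.
    """
    if not (0.0 < threshold <= 0.5):
        raise InvalidArgumentError("maf threshold must lie in (0, 0.5]")
    rare = np.flatnonzero(data.maf < threshold)
    common = np.flatnonzero(data.maf >= threshold)
    return common.tolist(), rare.tolist()


def collapse_indicator(data: GenotypeDataset, group) -> np.ndarray:
    """Carrier indicator of a rare-variant group (1 if any minor allele)."""
    group = list(group)
    if not group:
        raise InvalidArgumentError("collapsing group must be non-empty")
    return (data.genotypes[:, group] > 0).any(axis=1).astype(np.int8)


def collapse_burden(data: GenotypeDataset, group) -> np.ndarray:
    """Minor-allele count over a group, clipped to 2 to stay in {0,1,2}."""
    group = list(group)
    if not group:
        raise InvalidArgumentError("collapsing group must be non-empty")
    counts = np.clip(data.genotypes[:, group], 0, None).sum(axis=1)
    return np.minimum(counts, 2).astype(np.int8)


def _collapse_column(data, group, coding):
    if coding == CODING_INDICATOR:
        return collapse_indicator(data, group)
    if coding == CODING_BURDEN:
        return collapse_burden(data, group)
    raise InvalidArgumentError(f"unknown collapse coding: {coding}")


def _binary_group_aucs(a1, b1, n_cases, n_controls, pseudocount, lr_cap):
    """LR-ordered AUC of carrier/non-carrier splits, vectorized.

    Uses the same smoothed-LR expressions as ``_lr_from_counts`` (with
    ``M = 2`` observed groups, or 1 when a split is empty) so the result is
    float-for-float identical to the LR-table route.
    """
    a1 = np.asarray(a1, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    a0 = n_cases - a1
    b0 = n_controls - b1
    both = ((a1 + b1) > 0) & ((a0 + b0) > 0)
    m = np.where(both, 2.0, 1.0)
    if pseudocount > 0:
        lr1 = ((a1 + pseudocount) / (n_cases + pseudocount * m)) / (
            (b1 + pseudocount) / (n_controls + pseudocount * m)
        )
        lr0 = ((a0 + pseudocount) / (n_cases + pseudocount * m)) / (
            (b0 + pseudocount) / (n_controls + pseudocount * m)
        )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            raw1 = (a1 / n_cases) / (b1 / n_controls)
            raw0 = (a0 / n_cases) / (b0 / n_controls)
        lr1 = np.where(a1 == 0, 1.0 / lr_cap, np.where(b1 == 0, lr_cap, raw1))
        lr0 = np.where(a0 == 0, 1.0 / lr_cap, np.where(b0 == 0, lr_cap, raw0))
    denom = n_cases * n_controls
    auc_above = (a0 * 0.5 * b0 + a1 * (b0 + 0.5 * b1)) / denom
    auc_below = (a1 * 0.5 * b1 + a0 * (b1 + 0.5 * b0)) / denom
    auc = np.where(lr1 > lr0, auc_above, np.where(lr1 < lr0, auc_below, 0.5))
    return np.where(both, auc, 0.5)


def _column_auc(data, column, pseudocount, lr_cap):
    """LR-ordered AUC of a single (possibly multi-valued) pseudo column."""
    uniq, inv = np.unique(column, return_inverse=True)
    case = data.case_mask
    a = np.bincount(inv[case], minlength=len(uniq))
    b = np.bincount(inv[~case], minlength=len(uniq))
    lr = _lr_from_counts(a, b, data.n_cases, data.n_controls, pseudocount, lr_cap)
    return _auc_from_group_counts(a, b, lr, data.n_cases, data.n_controls)


def grow_pseudo_variant(
    data: GenotypeDataset,
    available_rares,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    epsilon: float = 0.0,
    lr_cap: float = DEFAULT_LR_CAP,
    coding: str = CODING_INDICATOR,
) -> tuple[list[int], np.ndarray]:
    """Grow one pseudo-common variant greedily from the available rares.

    The group is seeded with the rare variant whose single-variant
    pseudo-column has the highest LR-ordered AUC (ties to the lowest
    index); each subsequent step absorbs the rare variant that raises the
    collapsed column's AUC the most, stopping when the best improvement is
    ``<= epsilon``. Returns the group (in addition order) and the AUC after
    each step — strictly increasing after the seed.
    """
    rares = sorted(set(int(r) for r in available_rares))
    if not rares:
        raise InvalidArgumentError("available_rares must be non-empty")
    if any(r < 0 or r >= data.n_variants for r in rares):
        raise InvalidArgumentError("rare variant index out of range")

    case = data.case_mask
    n_d, n_c = data.n_cases, data.n_controls
    group: list[int] = []
    aucs: list[float] = []
    if coding == CODING_INDICATOR:
        carriers = data.genotypes[:, rares] > 0  # (n, R)
        current = np.zeros(data.n_individuals, dtype=bool)
        remaining = list(range(len(rares)))
        cur_auc = 0.5
        while remaining:
            cand = current[:, None] | carriers[:, remaining]
            a1 = cand[case].sum(axis=0)
            b1 = cand[~case].sum(axis=0)
            cand_auc = _binary_group_aucs(a1, b1, n_d, n_c, pseudocount, lr_cap)
            j = int(np.argmax(cand_auc))  # first max -> lowest index
            best = float(cand_auc[j])
            if group and best - cur_auc <= epsilon:
                break
            group.append(rares[remaining[j]])
            aucs.append(best)
            current = current | carriers[:, remaining[j]]
            del remaining[j]
            cur_auc = best
    else:
        remaining = list(rares)
        cur_auc = 0.5
        while remaining:
            best, best_auc = -1, -np.inf
            for r in remaining:
                col = _collapse_column(data, group + [r], coding)
                auc = _column_auc(data, col, pseudocount, lr_cap)
                if auc > best_auc:
                    best, best_auc = r, auc
            if group and best_auc - cur_auc <= epsilon:
                break
            group.append(best)
            aucs.append(float(best_auc))
            remaining.remove(best)
            cur_auc = best_auc
    return group, np.asarray(aucs)


def build_collapsing_plan(
    data: GenotypeDataset,
    rare_indices,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    epsilon: float = 0.0,
    lr_cap: float = DEFAULT_LR_CAP,
    coding: str = CODING_INDICATOR,
) -> CollapsingPlan:
    """Multistage collapsing: partition all rares into pseudo-common groups.

    Repeatedly grows one pseudo-common variant from the not-yet-collapsed
    rares and removes it, until no rare variant remains. Every rare index
    ends up in exactly one group; groups that never rise above AUC 0.5 are
    still emitted (downstream forward selection is what discards them).
    """
    remaining = sorted(set(int(r) for r in rare_indices))
    groups: list[list[int]] = []
    per_group_auc: list[float] = []
    while remaining:
        group, aucs = grow_pseudo_variant(
            data, remaining, pseudocount, epsilon, lr_cap, coding
        )
        groups.append(group)
        per_group_auc.append(float(aucs[-1]))
        remaining = [r for r in remaining if r not in set(group)]
    return CollapsingPlan(
        group_variant_ids=[[data.variant_ids[i] for i in g] for g in groups],
        group_ids=[f"{PSEUDO_ID_PREFIX}{k + 1}" for k in range(len(groups))],
        per_group_auc=per_group_auc,
        maf_threshold=maf_threshold,
        coding=coding,
        groups=groups,
    )


def materialize_pseudo_variants(
    data: GenotypeDataset,
    plan: CollapsingPlan,
    coding: str | None = None,
) -> GenotypeDataset:
    """Apply a collapsing plan to raw genotypes.

    Returns a dataset whose columns are the variants *not* covered by the
    plan (in their original order) followed by one pseudo-common column per
    group, resolved by variant ID so the plan ports across files.
    """
    coding = coding or plan.coding
    index = data.variant_index()
    missing = [
        v for g in plan.group_variant_ids for v in g if v not in index
    ]
    if missing:
        raise SchemaMismatchError(
            f"collapsing plan variants absent from dataset: {missing[:10]}"
        )
    group_cols = [[index[v] for v in g] for g in plan.group_variant_ids]
    covered = {c for g in group_cols for c in g}
    kept = [i for i in range(data.n_variants) if i not in covered]
    pseudo = [
        _collapse_column(data, cols, coding) for cols in group_cols
    ]
    genotypes = np.column_stack(
        [data.genotypes[:, kept]] + [p[:, None] for p in pseudo]
    ) if pseudo else data.genotypes[:, kept]
    return GenotypeDataset(
        genotypes=genotypes.astype(data.genotypes.dtype, copy=False),
        phenotype=data.phenotype,
        variant_ids=[data.variant_ids[i] for i in kept] + list(plan.group_ids),
        sample_ids=data.sample_ids,
    )


def fit_croc(
    data: GenotypeDataset,
    folds: int = DEFAULT_FOLDS,
    *,
    seed: int,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    epsilon: float = 0.0,
    max_model_size: int = DEFAULT_MAX_MODEL_SIZE,
    cv_mode: str = CV_FIXED_PATH,
    unseen_lr: float = DEFAULT_UNSEEN_LR,
    lr_cap: float = DEFAULT_LR_CAP,
    coding: str = CODING_INDICATOR,
) -> RiskModel:
    """Fit a CROC risk model.

    Splits variants at ``maf_threshold``, builds a collapsing plan on the
    rares, materializes pseudo-common columns, and runs FROC forward
    selection over common + pseudo-common candidates. With no rare variants
    the fit reduces exactly to :func:`fit_froc`. By default the plan is
    built once on the full training data and held fixed inside
    cross-validation; ``cv_mode="nested"`` rebuilds it per fold.
    """
    common, rare = split_by_maf(data, maf_threshold)
    if not rare:
        logger.info("no rare variants below MAF %g; CROC reduces to FROC",
                    maf_threshold)
        return fit_froc(
            data, None, folds, seed=seed, pseudocount=pseudocount,
            epsilon=epsilon, max_model_size=max_model_size, cv_mode=cv_mode,
            unseen_lr=unseen_lr, lr_cap=lr_cap,
        )
    plan = build_collapsing_plan(
        data, rare, maf_threshold, pseudocount, epsilon, lr_cap, coding
    )
    logger.info(
        "collapsed %d rare variants into %d pseudo-common variants",
        len(rare), plan.n_groups,
    )
    augmented = materialize_pseudo_variants(data, plan, coding)

    fold_transform = None
    if cv_mode == CV_NESTED:
        def fold_transform(tr_rows, te_rows):
            raw_tr = data.take_samples(tr_rows)
            raw_te = data.take_samples(te_rows)
            _, fold_rare = split_by_maf(raw_tr, maf_threshold)
            if not fold_rare:
                return raw_tr, raw_te, list(range(raw_tr.n_variants))
            fold_plan = build_collapsing_plan(
                raw_tr, fold_rare, maf_threshold, pseudocount, epsilon,
                lr_cap, coding,
            )
            tr_aug = materialize_pseudo_variants(raw_tr, fold_plan, coding)
            te_aug = materialize_pseudo_variants(raw_te, fold_plan, coding)
            return tr_aug, te_aug, list(range(tr_aug.n_variants))

    model = fit_froc(
        augmented, None, folds, seed=seed, pseudocount=pseudocount,
        epsilon=epsilon, max_model_size=max_model_size, cv_mode=cv_mode,
        unseen_lr=unseen_lr, lr_cap=lr_cap,
        _fold_transform=fold_transform,
        _extra_config={
            "method": "croc",
            "maf_threshold": maf_threshold,
            "collapse_coding": coding,
        },
    )
    model.collapsing_plan = plan
    return model
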