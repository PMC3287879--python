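"""Forward ROC (FROC): greedy forward selection of loci by LR-ordered AUC.

Starting from the null model, each step adds the candidate locus whose
addition yields the largest training AUC (likelihood-ratio ordered), until
no addition increases accuracy. Ten-fold stratified cross-validation over
the resulting model path picks the model size with the best mean held-out
AUC; the final LR table is refit on the full training sample at that size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import (
    DEFAULT_LR_CAP,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_UNSEEN_LR,
    GROUP_EXPLOSION_WARN,
    GenotypeDataset,
    InvalidArgumentError,
    LRTable,
    assign_scores,
    compute_auc,
    estimate_lr_table,
    _auc_from_group_counts,
    _lr_from_counts,
)

logger = logging.getLogger("crocpred")

DEFAULT_FOLDS: int = 10
DEFAULT_MAX_MODEL_SIZE: int = 20
CV_FIXED_PATH = "fixed-path"
CV_NESTED = "nested"


@dataclass
class SelectionStep:
    locus: int  # column index in the fitted matrix
    locus_id: str
    training_auc: float
    cv_auc: float | None = None


@dataclass
class SelectionTrace:
    """The forward path: one step per added locus, plus the CV choice."""

    steps: list[SelectionStep]
    chosen_size: int


@dataclass
class RiskModel:
    """A fitted LR risk predictor.

    ``loci`` are the identifiers of the selected predictors (variant IDs
    and/or pseudo-common variant IDs); ``collapsing_plan`` is present only
    for CROC fits and lets :func:`predict` materialize pseudo-common
    variants from raw genotypes.
    """

    loci: list[str]
    lr_table: LRTable
    trace: SelectionTrace
    config: dict
    collapsing_plan: object | None = None
    loci_indices: list[int] | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Candidate scanning
# ---------------------------------------------------------------------------


def _scan_candidates(gplus, gid, case_mask, cands, n_cases, n_controls,
                     pseudocount, lr_cap):
    """Training AUC of adding each candidate to the current grouping.

    ``gplus`` is the genotype matrix shifted by +1 (codes 0..3, missing 0);
    ``gid`` the current group id per individual. Returns the best candidate
    (ties to the lowest column index), its AUC, and its group codes.
    """
    best_locus = -1
    best_auc = -np.inf
    best_code = None
    base = 4 * gid
    ctrl_mask = ~case_mask
    for c in cands:
        code = base + gplus[:, c]
        uniq, inv = np.unique(code, return_inverse=True)
        a = np.bincount(inv[case_mask], minlength=len(uniq))
        b = np.bincount(inv[ctrl_mask], minlength=len(uniq))
        lr = _lr_from_counts(a, b, n_cases, n_controls, pseudocount, lr_cap)
        auc = _auc_from_group_counts(a, b, lr, n_cases, n_controls)
        if auc > best_auc:
            best_locus, best_auc, best_code = c, auc, code
    return best_locus, best_auc, best_code


def forward_step(
    data: GenotypeDataset,
    current_loci,
    candidates,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    lr_cap: float = DEFAULT_LR_CAP,
) -> tuple[int, float]:
    """One forward-selection step.

    Returns the candidate locus whose addition to ``current_loci`` maximizes
    the training AUC of the LR-ordered scores, with ties broken toward the
    lowest column index, together with that AUC.
    """
    current = list(current_loci)
    cands = sorted(set(candidates))
    if not cands:
        raise InvalidArgumentError("candidate list must be non-empty")
    if set(cands) & set(current):
        raise InvalidArgumentError("candidates must be disjoint from current loci")
    if any(c < 0 or c >= data.n_variants for c in cands + current):
        raise InvalidArgumentError("locus index out of range")

    gplus = (data.genotypes + 1).astype(np.int64)
    if current:
        _, gid = np.unique(
            data.genotypes[:, current], axis=0, return_inverse=True
        )
        gid = gid.astype(np.int64)
    else:
        gid = np.zeros(data.n_individuals, dtype=np.int64)
    best, auc, _ = _scan_candidates(
        gplus, gid, data.case_mask, cands, data.n_cases, data.n_controls,
        pseudocount, lr_cap,
    )
    return best, float(auc)


def _build_forward_path(data, candidates, pseudocount, epsilon,
                        max_model_size, lr_cap):
    """Greedy path of loci with their training AUCs (seed step always kept)."""
    gplus = (data.genotypes + 1).astype(np.int64)
    gid = np.zeros(data.n_individuals, dtype=np.int64)
    case_mask = data.case_mask
    remaining = sorted(set(candidates))
    path: list[int] = []
    aucs: list[float] = []
    last = 0.5
    while remaining and len(path) < max_model_size:
        best, auc, code = _scan_candidates(
            gplus, gid, case_mask, remaining, data.n_cases, data.n_controls,
            pseudocount, lr_cap,
        )
        if path and auc - last <= epsilon:
            break
        path.append(best)
        aucs.append(float(auc))
        remaining.remove(best)
        uniq, gid = np.unique(code, return_inverse=True)
        gid = gid.astype(np.int64)
        if len(uniq) > GROUP_EXPLOSION_WARN:
            logger.warning(
                "forward path reached %d observed genotype groups at size %d",
                len(uniq), len(path),
            )
        last = auc
    return path, aucs


def _heldout_aucs_along_path(train: GenotypeDataset, test: GenotypeDataset,
                             path, pseudocount, lr_cap, unseen_lr):
    """Held-out AUC after each prefix of ``path``, refitting LR tables on
    ``train``. Incremental group encoding; exact match of the
    estimate_lr_table / assign_scores / compute_auc route."""
    gplus_tr = (train.genotypes + 1).astype(np.int64)
    gplus_te = (test.genotypes + 1).astype(np.int64)
    gid_tr = np.zeros(train.n_individuals, dtype=np.int64)
    gid_te = np.zeros(test.n_individuals, dtype=np.int64)
    seen_te = np.ones(test.n_individuals, dtype=bool)
    case_tr = train.case_mask
    out = []
    for locus in path:
        code_tr = 4 * gid_tr + gplus_tr[:, locus]
        uniq, inv = np.unique(code_tr, return_inverse=True)
        a = np.bincount(inv[case_tr], minlength=len(uniq))
        b = np.bincount(inv[~case_tr], minlength=len(uniq))
        lr = _lr_from_counts(
            a, b, train.n_cases, train.n_controls, pseudocount, lr_cap
        )
        code_te = 4 * gid_te + gplus_te[:, locus]
        pos = np.searchsorted(uniq, code_te).clip(max=len(uniq) - 1)
        ok = seen_te & (uniq[pos] == code_te)
        scores = np.where(ok, lr[pos], unseen_lr)
        out.append(compute_auc(scores, test.phenotype).auc)
        gid_tr = inv.astype(np.int64)
        gid_te = np.where(ok, pos, 0)
        seen_te = ok
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_froc(
    data: GenotypeDataset,
    candidates=None,
    folds: int = DEFAULT_FOLDS,
    *,
    seed: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    epsilon: float = 0.0,
    max_model_size: int = DEFAULT_MAX_MODEL_SIZE,
    cv_mode: str = CV_FIXED_PATH,
    unseen_lr: float = DEFAULT_UNSEEN_LR,
    lr_cap: float = DEFAULT_LR_CAP,
    _fold_transform=None,
    _extra_config: dict | None = None,
) -> RiskModel:
    """Fit a FROC risk model.

    Builds the greedy forward path on the full sample, evaluates every path
    prefix by stratified ``folds``-fold cross-validation (LR tables refit on
    each fold's training part; the path itself is fixed unless
    ``cv_mode="nested"``, which re-runs selection inside each fold), picks
    the prefix size with the highest mean held-out AUC (ties to the smaller
    size), and refits the LR table on all data at that size.

    ``seed`` drives the shuffled fold assignment and is recorded in the
    model's config snapshot.
    """
    if candidates is None:
        candidates = range(data.n_variants)
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise InvalidArgumentError("candidate list must be non-empty")
    if folds < 2:
        raise InvalidArgumentError("folds must be >= 2")
    if folds > min(data.n_cases, data.n_controls):
        raise InvalidArgumentError(
            f"folds={folds} exceeds the smaller class count "
            f"({min(data.n_cases, data.n_controls)})"
        )
    if cv_mode not in (CV_FIXED_PATH, CV_NESTED):
        raise InvalidArgumentError(f"unknown cv_mode: {cv_mode}")

    path, train_aucs = _build_forward_path(
        data, candidates, pseudocount, epsilon, max_model_size, lr_cap
    )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dummy = np.zeros(data.n_individuals)
    cv = np.full((len(path), folds), np.nan)
    for f, (tr_rows, te_rows) in enumerate(skf.split(dummy, data.phenotype)):
        if _fold_transform is not None:
            tr_ds, te_ds, fold_cands = _fold_transform(tr_rows, te_rows)
        else:
            tr_ds = data.take_samples(tr_rows)
            te_ds = data.take_samples(te_rows)
            fold_cands = candidates
        if cv_mode == CV_NESTED:
            fold_path, _ = _build_forward_path(
                tr_ds, fold_cands, pseudocount, epsilon, max_model_size, lr_cap
            )
        else:
            fold_path = path
        fold_aucs = _heldout_aucs_along_path(
            tr_ds, te_ds, fold_path, pseudocount, lr_cap, unseen_lr
        )
        for s in range(len(path)):
            # shorter fold paths contribute their largest fitted model
            cv[s, f] = fold_aucs[min(s, len(fold_aucs) - 1)]

    cv_mean = cv.mean(axis=1)
    chosen = 1
    for s in range(2, len(path) + 1):
        if cv_mean[s - 1] > cv_mean[chosen - 1]:
            chosen = s

    steps = [
        SelectionStep(
            locus=int(l),
            locus_id=data.variant_ids[l],
            training_auc=train_aucs[i],
            cv_auc=float(cv_mean[i]),
        )
        for i, l in enumerate(path)
    ]
    trace = SelectionTrace(steps=steps, chosen_size=chosen)
    final_loci = path[:chosen]
    table = estimate_lr_table(data, final_loci, pseudocount, lr_cap)
    config = {
        "method": "froc",
        "folds": folds,
        "seed": int(seed),
        "pseudocount": pseudocount,
        "epsilon": epsilon,
        "max_model_size": max_model_size,
        "cv_mode": cv_mode,
        "unseen_lr": unseen_lr,
        "lr_cap": lr_cap,
    }
    if _extra_config:
        config.update(_extra_config)
    logger.info(
        "fit %s: path length %d, chosen size %d, training AUC %.4f, "
        "mean CV AUC %.4f",
        config["method"], len(path), chosen, train_aucs[chosen - 1],
        cv_mean[chosen - 1],
    )
    return RiskModel(
        loci=[data.variant_ids[l] for l in final_loci],
        lr_table=table,
        trace=trace,
        config=config,
        collapsing_plan=None,
        loci_indices=[int(l) for l in final_loci],
    )


def predict(model: RiskModel, data: GenotypeDataset) -> np.ndarray:
    """LR score per individual in ``data`` under a fitted model.

    For CROC models the collapsing plan is first applied to the raw
    genotypes so pseudo-common variant columns exist; unseen genotype tuples
    receive the model's configured neutral LR.
    """
    if model.collapsing_plan is not None:
        from .croc import materialize_pseudo_variants

        data = materialize_pseudo_variants(
            data,
            model.collapsing_plan,
            coding=model.config.get("collapse_coding", "indicator"),
        )
    return assign_scores(
        model.lr_table, data, unseen_lr=model.config.get("unseen_lr", 1.0)
    )
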