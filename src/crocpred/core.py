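"""Likelihood-ratio risk scores and optimal ROC/AUC machinery.

The risk score for a multilocus genotype ``G`` is its likelihood ratio

    LR(G) = P(G | case) / P(G | control),

estimated from genotype-group frequencies in a case-control sample. Ranking
individuals by LR yields the ROC curve with the highest attainable AUC for
the chosen loci, so the AUC of the LR-ordered scores is the natural accuracy
measure for a set of predictors. The AUC itself is the Mann-Whitney
probability that a random case outscores a random control, with ties
counting one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger("crocpred")

# Genotype codes: minor-allele counts; MISSING is the designated sentinel for
# no-call genotypes (treated as its own category when grouping).
MISSING: int = -1
GENOTYPE_CODES = (0, 1, 2)

DEFAULT_PSEUDOCOUNT: float = 0.5
DEFAULT_LR_CAP: float = 1e6
DEFAULT_UNSEEN_LR: float = 1.0
DEFAULT_MAF_THRESHOLD: float = 0.01
GROUP_EXPLOSION_WARN: int = 2 ** 12


class CrocpredError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CrocpredError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateDataError(CrocpredError, ValueError):
    """The sample cannot support the computation (e.g. a single class)."""


class SchemaMismatchError(CrocpredError, ValueError):
    """A model refers to loci that the supplied dataset does not contain."""


class AlignmentError(CrocpredError, ValueError):
    """Sample identifiers of genotype and phenotype sources do not align."""


class UnsupportedRecordError(CrocpredError, ValueError):
    """An input record (e.g. a multiallelic VCF site) is not supported."""


class SimulationTimeoutError(CrocpredError, RuntimeError):
    """Rejection sampling failed to reach the requested case/control counts."""


# ---------------------------------------------------------------------------
# GenotypeDataset
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """A biallelic genotype matrix with a binary case/control phenotype.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_variants)`` integer matrix of minor-allele
        counts in ``{0, 1, 2}``; missing genotypes are coded ``-1``.
    phenotype
        Length-``n_individuals`` vector with 1 = case, 0 = control.
    variant_ids
        One identifier per variant column.
    sample_ids
        Optional identifiers per individual.
    maf
        Per-variant minor allele frequency; recomputed from the genotypes
        when omitted.
    truth
        Optional generative ground truth attached by the simulator.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    variant_ids: list[str]
    sample_ids: list[str] | None = None
    maf: np.ndarray | None = None
    truth: object | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotype = np.asarray(self.phenotype)
        if self.genotypes.ndim != 2:
            raise InvalidArgumentError("genotypes must be a 2-D matrix")
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise InvalidArgumentError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} genotype rows"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            raise InvalidArgumentError("phenotype must be coded 0/1")
        if len(self.variant_ids) != m:
            raise InvalidArgumentError("variant_ids length != n_variants")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise InvalidArgumentError("sample_ids length != n_individuals")
        valid = np.isin(self.genotypes, (MISSING,) + GENOTYPE_CODES)
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise InvalidArgumentError(f"invalid genotype codes: {bad.tolist()}")
        if self.n_cases == 0 or self.n_controls == 0:
            raise DegenerateDataError(
                "dataset must contain at least one case and one control"
            )
        if self.maf is None:
            self.maf = compute_maf(self.genotypes)
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.maf.shape != (m,):
                raise InvalidArgumentError("maf length != n_variants")

    # -- basic shape accessors ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == 1

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variant_ids)}

    def take_samples(self, rows: np.ndarray) -> "GenotypeDataset":
        """Row subset (e.g. a cross-validation fold)."""
        rows = np.asarray(rows)
        return GenotypeDataset(
            genotypes=self.genotypes[rows],
            phenotype=self.phenotype[rows],
            variant_ids=list(self.variant_ids),
            sample_ids=(
                [self.sample_ids[i] for i in rows] if self.sample_ids else None
            ),
        )

    def take_variants(self, cols) -> "GenotypeDataset":
        """Column subset (e.g. the common-variant block)."""
        cols = np.asarray(cols, dtype=int)
        return GenotypeDataset(
            genotypes=self.genotypes[:, cols],
            phenotype=self.phenotype,
            variant_ids=[self.variant_ids[i] for i in cols],
            sample_ids=self.sample_ids,
            maf=None if self.maf is None else self.maf[cols],
        )


def compute_maf(genotypes: np.ndarray) -> np.ndarray:
    """Pooled-sample minor allele frequency per variant (missing excluded)."""
    g = np.asarray(genotypes)
    observed = g != MISSING
    counts = np.where(observed, g, 0).sum(axis=0)
    denom = 2 * observed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(denom > 0, counts / np.maximum(denom, 1), 0.0)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# LRTable
# ---------------------------------------------------------------------------


@dataclass
class LRTable:
    """Estimated likelihood ratio for every observed multilocus genotype.

    ``groups`` holds the ``M`` observed genotype tuples over the ``K``
    selected loci (one row each); ``lr[g]`` is the smoothed case/control
    frequency ratio of group ``g``.
    """

    loci_ids: tuple[str, ...]
    groups: np.ndarray  # (M, K) genotype codes
    case_counts: np.ndarray
    control_counts: np.ndarray
    lr: np.ndarray
    pseudocount: float
    lr_cap: float
    n_cases: int
    n_controls: int

    @property
    def n_groups(self) -> int:
        return len(self.lr)

    @property
    def case_freq(self) -> np.ndarray:
        """Raw (unsmoothed) genotype-group frequencies among cases."""
        return self.case_counts / self.n_cases

    @property
    def control_freq(self) -> np.ndarray:
        return self.control_counts / self.n_controls

    @cached_property
    def _lookup(self) -> dict[tuple[int, ...], float]:
        return {
            tuple(int(x) for x in row): float(v)
            for row, v in zip(self.groups, self.lr)
        }

    def lr_of(self, genotype: tuple[int, ...], unseen_lr: float) -> float:
        return self._lookup.get(tuple(int(x) for x in genotype), unseen_lr)


def _lr_from_counts(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    n_cases: int,
    n_controls: int,
    pseudocount: float,
    lr_cap: float,
) -> np.ndarray:
    """Smoothed frequency-ratio LR for genotype groups.

    With a positive pseudocount ``c`` and ``M`` observed groups the group LR is
    ``((a+c)/(N_D+cM)) / ((b+c)/(N_D̄+cM))``.  With ``c = 0`` the raw ratio is
    used, capped at ``lr_cap`` when the control count is zero (and floored at
    ``1/lr_cap`` when the case count is zero) so LRs stay positive and finite.
    """
    a = np.asarray(case_counts, dtype=float)
    b = np.asarray(control_counts, dtype=float)
    m = len(a)
    if pseudocount > 0:
        num = (a + pseudocount) / (n_cases + pseudocount * m)
        den = (b + pseudocount) / (n_controls + pseudocount * m)
        return num / den
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (a / n_cases) / (b / n_controls)
    lr = np.where(b == 0, lr_cap, raw)
    return np.where(a == 0, 1.0 / lr_cap, lr)


def estimate_lr_table(
    data: GenotypeDataset,
    loci,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    lr_cap: float = DEFAULT_LR_CAP,
) -> LRTable:
    """Estimate the LR for every multilocus genotype observed at ``loci``.

    Parameters
    ----------
    data
        Training sample with at least one case and one control.
    loci
        Non-empty list of variant column indices.
    pseudocount
        Haldane-style smoothing added per group and class; ``0`` switches to
        the raw ratio with the ``lr_cap`` guard.
    """
    loci = list(loci)
    if not loci:
        raise InvalidArgumentError("loci list must be non-empty")
    if any(l < 0 or l >= data.n_variants for l in loci):
        raise InvalidArgumentError(f"locus index out of range: {loci}")
    if pseudocount < 0:
        raise InvalidArgumentError("pseudocount must be non-negative")

    sub = data.genotypes[:, loci]
    groups, inverse = np.unique(sub, axis=0, return_inverse=True)
    m = len(groups)
    case = data.case_mask
    a = np.bincount(inverse[case], minlength=m)
    b = np.bincount(inverse[~case], minlength=m)
    lr = _lr_from_counts(a, b, data.n_cases, data.n_controls, pseudocount, lr_cap)
    return LRTable(
        loci_ids=tuple(data.variant_ids[l] for l in loci),
        groups=groups,
        case_counts=a,
        control_counts=b,
        lr=lr,
        pseudocount=pseudocount,
        lr_cap=lr_cap,
        n_cases=data.n_cases,
        n_controls=data.n_controls,
    )


def assign_scores(
    table: LRTable,
    data: GenotypeDataset,
    unseen_lr: float = DEFAULT_UNSEEN_LR,
) -> np.ndarray:
    """LR score per individual: the table LR of their multilocus genotype.

    Genotype tuples never observed at training time receive ``unseen_lr``
    (default 1.0, i.e. uninformative evidence).
    """
    index = data.variant_index()
    missing = [v for v in table.loci_ids if v not in index]
    if missing:
        raise SchemaMismatchError(
            f"model loci absent from dataset: {missing}"
        )
    cols = [index[v] for v in table.loci_ids]
    sub = data.genotypes[:, cols]
    return np.array(
        [table.lr_of(tuple(row), unseen_lr) for row in sub], dtype=float
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    """An ROC curve and its area.

    ``curve_points`` are ``(1 - specificity, sensitivity)`` pairs swept over
    decreasing score thresholds, starting at (0, 0) and ending at (1, 1);
    ``auc`` is the Mann-Whitney statistic (ties count one half), which equals
    the trapezoidal area under the curve.
    """

    auc: float
    curve_points: np.ndarray = field(repr=False)


def compute_auc(scores, phenotype) -> ROCResult:
    """Mann-Whitney AUC of ``scores`` against a binary phenotype.

    ``AUC = (1 / (N_D N_D̄)) Σ ψ(s_case, s_control)`` over all case-control
    pairs, with the kernel ``ψ = 1`` if the case outscores the control,
    ``0.5`` on ties and ``0`` otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype)
    if scores.shape != phenotype.shape:
        raise InvalidArgumentError("scores and phenotype lengths differ")
    case = phenotype == 1
    n_case = int(case.sum())
    n_ctrl = int(len(phenotype) - n_case)
    if n_case == 0 or n_ctrl == 0:
        raise DegenerateDataError("need at least one case and one control")

    # Rank-sum form of the pairwise kernel sum; midranks implement psi = 0.5.
    ranks = rankdata(scores)
    kernel_sum = ranks[case].sum() - n_case * (n_case + 1) / 2.0
    auc = kernel_sum / (n_case * n_ctrl)

    case_sorted = np.sort(scores[case])
    ctrl_sorted = np.sort(scores[~case])
    thresholds = np.unique(scores)[::-1]
    tpr = 1.0 - np.searchsorted(case_sorted, thresholds, side="left") / n_case
    fpr = 1.0 - np.searchsorted(ctrl_sorted, thresholds, side="left") / n_ctrl
    curve = np.vstack([np.zeros((1, 2)), np.column_stack([fpr, tpr])])
    return ROCResult(auc=float(auc), curve_points=curve)


def _auc_from_group_counts(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    lr: np.ndarray,
    n_cases: int,
    n_controls: int,
) -> float:
    """AUC of LR-ordered genotype groups, from group counts alone.

    Groups with exactly equal LR are merged (their members tie). Equivalent
    to ``compute_auc(assign_scores(...))`` on the same sample but O(M log M).
    """
    uniq, inv = np.unique(lr, return_inverse=True)  # ascending LR
    a = np.bincount(inv, weights=case_counts, minlength=len(uniq))
    b = np.bincount(inv, weights=control_counts, minlength=len(uniq))
    below = np.cumsum(b) - b  # controls in strictly lower-LR groups
    kernel_sum = float((a * (below + 0.5 * b)).sum())
    return kernel_sum / (n_cases * n_controls)
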