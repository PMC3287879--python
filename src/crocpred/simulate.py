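"""Synthetic case-control genotype data with common and rare variants.

Emulates a mini-exome candidate-gene panel: a few hundred individuals, a
minority of common variants and a majority of rare ones (MAF < 0.01), a
small causal subset, and a binary phenotype. Genotypes are independent
Hardy-Weinberg draws (no linkage disequilibrium); disease status follows a
logistic liability on the causal minor-allele counts; case and control
quotas are filled by rejection sampling, so the sample is ascertained the
way a case-control study is. The generative truth (per-variant MAF, causal
set, effect sizes, intercept) travels with the dataset so recovery and
calibration experiments can check against it, and independent replicates
can be drawn from the same truth for train/test evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import GenotypeDataset, InvalidArgumentError, SimulationTimeoutError

# Defaults mirror the GAW17 candidate-gene panel shape: 697 individuals with
# 209 cases, 533 SNPs of which 400 are rare (MAF < 0.01), pooled MAF spanning
# roughly 0.0007-0.45.
DEFAULT_N_CASES = 209
DEFAULT_N_CONTROLS = 488
DEFAULT_N_COMMON = 133
DEFAULT_N_RARE = 400
DEFAULT_MAF_COMMON = (0.05, 0.45)
DEFAULT_MAF_RARE = (0.0007, 0.01)
DEFAULT_EFFECT_COMMON = math.log(1.5)
DEFAULT_EFFECT_RARE = 2.0  # log-odds per minor allele, OR ~ 7.4
DEFAULT_PREVALENCE = 0.3  # 209 / 697

_MAX_DRAW_FACTOR = 2000  # rejection-sampling guard


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic case-control study.

    ``causal_common`` / ``causal_rare`` may be counts (causal loci drawn at
    random within the block) or explicit block-local index sequences.
    ``effect_sizes`` optionally overrides the per-causal-variant log-odds
    (commons first, then rares; negative values give protective alleles).
    ``causal_common_maf_range`` / ``causal_rare_maf_range`` optionally place
    the causal variants in a specific frequency band of their block.
    """

    n_cases: int = DEFAULT_N_CASES
    n_controls: int = DEFAULT_N_CONTROLS
    n_common: int = DEFAULT_N_COMMON
    n_rare: int = DEFAULT_N_RARE
    maf_common_range: tuple[float, float] = DEFAULT_MAF_COMMON
    maf_rare_range: tuple[float, float] = DEFAULT_MAF_RARE
    causal_common: object = 5
    causal_rare: object = 15
    effect_common: float = DEFAULT_EFFECT_COMMON
    effect_rare: float = DEFAULT_EFFECT_RARE
    effect_sizes: np.ndarray | None = None
    causal_common_maf_range: tuple[float, float] | None = None
    causal_rare_maf_range: tuple[float, float] | None = None
    baseline_prevalence: float = DEFAULT_PREVALENCE
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise InvalidArgumentError("case and control counts must be positive")
        if self.n_common < 0 or self.n_rare < 0 or self.n_common + self.n_rare == 0:
            raise InvalidArgumentError("need at least one variant")
        for lo, hi in filter(None, (self.maf_common_range, self.maf_rare_range,
                                    self.causal_common_maf_range,
                                    self.causal_rare_maf_range)):
            if not (0.0 < lo <= hi < 0.5):
                raise InvalidArgumentError(f"MAF range ({lo}, {hi}) not in (0, 0.5)")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise InvalidArgumentError("baseline_prevalence must be in (0, 1)")


@dataclass
class SimulationTruth:
    """The generative ground truth behind a simulated dataset."""

    maf: np.ndarray
    causal_indices: np.ndarray
    betas: np.ndarray
    alpha: float
    n_common: int
    n_rare: int
    variant_ids: list[str] = field(repr=False)

    @property
    def causal_common_indices(self) -> np.ndarray:
        return self.causal_indices[self.causal_indices < self.n_common]

    @property
    def causal_rare_indices(self) -> np.ndarray:
        return self.causal_indices[self.causal_indices >= self.n_common]

    def to_dict(self) -> dict:
        return {
            "maf": self.maf.tolist(),
            "causal_indices": self.causal_indices.tolist(),
            "betas": self.betas.tolist(),
            "alpha": self.alpha,
            "n_common": self.n_common,
            "n_rare": self.n_rare,
            "variant_ids": self.variant_ids,
        }


def _resolve_causal(spec, block_size, rng) -> np.ndarray:
    """Block-local causal indices from a count or an explicit sequence."""
    if isinstance(spec, (int, np.integer)):
        if spec < 0 or spec > block_size:
            raise InvalidArgumentError(
                f"causal count {spec} outside block of size {block_size}"
            )
        return np.sort(rng.choice(block_size, size=int(spec), replace=False))
    idx = np.asarray(sorted(int(i) for i in spec), dtype=int)
    if len(idx) and (idx.min() < 0 or idx.max() >= block_size):
        raise InvalidArgumentError("explicit causal index outside block")
    return idx


def build_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw the generative truth (MAFs, causal loci, effects) for a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    maf_common = rng.uniform(*config.maf_common_range, size=config.n_common)
    maf_rare = rng.uniform(*config.maf_rare_range, size=config.n_rare)
    causal_c = _resolve_causal(config.causal_common, config.n_common, rng)
    causal_r = _resolve_causal(config.causal_rare, config.n_rare, rng)
    if config.causal_common_maf_range is not None and len(causal_c):
        maf_common[causal_c] = rng.uniform(
            *config.causal_common_maf_range, size=len(causal_c)
        )
    if config.causal_rare_maf_range is not None and len(causal_r):
        maf_rare[causal_r] = rng.uniform(
            *config.causal_rare_maf_range, size=len(causal_r)
        )
    maf = np.concatenate([maf_common, maf_rare])
    causal = np.concatenate([causal_c, config.n_common + causal_r])
    if config.effect_sizes is not None:
        betas = np.asarray(config.effect_sizes, dtype=float)
        if betas.shape != causal.shape:
            raise InvalidArgumentError(
                f"effect_sizes length {len(betas)} != number of causal "
                f"variants {len(causal)}"
            )
    else:
        betas = np.concatenate([
            np.full(len(causal_c), config.effect_common),
            np.full(len(causal_r), config.effect_rare),
        ])
    # Center the liability so the population prevalence stays at baseline
    # when every causal genotype sits at its expected value.
    alpha = float(
        logit(config.baseline_prevalence) - (betas * 2.0 * maf[causal]).sum()
    )
    width_c = max(3, len(str(max(config.n_common, 1))))
    width_r = max(3, len(str(max(config.n_rare, 1))))
    variant_ids = [f"C{i + 1:0{width_c}d}" for i in range(config.n_common)] + [
        f"R{i + 1:0{width_r}d}" for i in range(config.n_rare)
    ]
    return SimulationTruth(
        maf=maf,
        causal_indices=causal,
        betas=betas,
        alpha=alpha,
        n_common=config.n_common,
        n_rare=config.n_rare,
        variant_ids=variant_ids,
    )


def simulate_from_truth(
    truth: SimulationTruth, n_cases: int, n_controls: int, seed: int
) -> GenotypeDataset:
    """Draw one case-control replicate under a fixed generative truth.

    Individuals are drawn under Hardy-Weinberg genotypes and the logistic
    liability, and kept until both the case and the control quota are full.
    """
    rng = np.random.default_rng(seed)
    m = len(truth.maf)
    need_case, need_ctrl = n_cases, n_controls
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    drawn = 0
    max_draws = _MAX_DRAW_FACTOR * (n_cases + n_controls)
    batch = max(256, n_cases + n_controls)
    while need_case > 0 or need_ctrl > 0:
        if drawn > max_draws:
            raise SimulationTimeoutError(
                f"could not reach {n_cases} cases / {n_controls} controls "
                f"after {drawn} draws; raise baseline_prevalence, shrink the "
                "requested counts, or weaken extreme protective effects"
            )
        g = rng.binomial(2, truth.maf, size=(batch, m)).astype(np.int8)
        eta = truth.alpha + g[:, truth.causal_indices] @ truth.betas
        y = rng.random(batch) < expit(eta)
        drawn += batch
        if need_case > 0:
            take = g[y][:need_case]
            case_rows.append(take)
            need_case -= len(take)
        if need_ctrl > 0:
            take = g[~y][:need_ctrl]
            ctrl_rows.append(take)
            need_ctrl -= len(take)
    genotypes = np.vstack(case_rows + ctrl_rows)
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    n = n_cases + n_controls
    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=phenotype,
        variant_ids=list(truth.variant_ids),
        sample_ids=[f"S{i + 1:0{len(str(n))}d}" for i in range(n)],
        truth=truth,
    )


def simulate_dataset(config: SimulationConfig) -> GenotypeDataset:
    """Simulate a dataset for a config; the truth rides along on ``.truth``."""
    truth = build_truth(config)
    # Decouple the replicate stream from the truth stream so further
    # replicates under the same truth can use fresh seeds.
    rep_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0]
                   % (2 ** 31))
    return simulate_from_truth(truth, config.n_cases, config.n_controls, rep_seed)


# ---------------------------------------------------------------------------
# Depletion sweep (common variants gradually removed)
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Per-repeat held-out AUCs and their aggregation for a depletion sweep."""

    per_repeat: pd.DataFrame  # repeat, common_count, method, auc
    summary: pd.DataFrame  # common_count, method, mean_auc, ci_low, ci_high


def run_depletion_sweep(
    config: SimulationConfig,
    common_counts,
    repeats: int,
    folds: int = 10,
    maf_threshold: float = 0.01,
    ci: float = 0.95,
) -> SweepResult:
    """Compare CROC and FROC while common variants are progressively removed.

    For each repeat a fresh generative truth is drawn; a training replicate
    and an independent testing replicate are simulated from it. For every
    requested common-variant count the same nested subset of common columns
    (plus all rares) is analyzed by both methods, models are fit on the
    training replicate and their AUC measured on the testing replicate.
    """
    from .croc import fit_croc
    from .froc import fit_froc, predict
    from .core import compute_auc

    common_counts = sorted(set(int(c) for c in common_counts))
    if any(c < 0 or c > config.n_common for c in common_counts):
        raise InvalidArgumentError("common_counts outside [0, n_common]")
    if repeats < 1:
        raise InvalidArgumentError("repeats must be >= 1")

    root = np.random.SeedSequence(config.seed)
    records = []
    for r, child in enumerate(root.spawn(repeats)):
        s_truth, s_test, s_sub, s_fit = (
            int(x % (2 ** 31)) for x in child.generate_state(4)
        )
        train = simulate_dataset(replace(config, seed=s_truth))
        test = simulate_from_truth(
            train.truth, config.n_cases, config.n_controls, s_test
        )
        keep_order = np.random.default_rng(s_sub).permutation(config.n_common)
        for count in common_counts:
            cols = np.concatenate([
                np.sort(keep_order[:count]),
                np.arange(config.n_common, config.n_common + config.n_rare),
            ]).astype(int)
            tr = train.take_variants(cols)
            te = test.take_variants(cols)
            fits = {
                "CROC": fit_croc(
                    tr, folds, seed=s_fit, maf_threshold=maf_threshold
                ),
                "FROC": fit_froc(tr, None, folds, seed=s_fit),
            }
            for method, model in fits.items():
                auc = compute_auc(predict(model, te), te.phenotype).auc
                records.append(
                    {"repeat": r, "common_count": count, "method": method,
                     "auc": auc}
                )
    per_repeat = pd.DataFrame.from_records(records)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    summary = (
        per_repeat.groupby(["common_count", "method"])["auc"]
        .agg(
            mean_auc="mean",
            ci_low=lambda s: np.percentile(s, lo_q),
            ci_high=lambda s: np.percentile(s, hi_q),
        )
        .reset_index()
    )
    return SweepResult(per_repeat=per_repeat, summary=summary)
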