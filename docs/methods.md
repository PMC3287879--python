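# Methods

## Risk model

The unit of modeling is the multilocus genotype: for a set of `K` loci,
every distinct tuple of minor-allele counts observed in the training
sample is one risk group. A group with `a` case and `b` control members
receives the likelihood ratio

    LR = [(a + c) / (N_D + cM)] / [(b + c) / (N_D̄ + cM)],

where `M` is the number of observed groups and `c` is a pseudocount
(default 0.5, Haldane-style). With `c = 0` the raw frequency ratio is
used, with groups absent in controls capped at `10^6` and groups absent in
cases floored at `10^-6` so every LR stays positive and finite; the spec
for the raw ratio only fixes the zero-control cap, and the symmetric floor
is the natural completion that preserves rank order. Individuals are
scored by their group's LR; genotype tuples never seen in training score
1.0 (neutral evidence). The AUC of these scores is computed as the
Mann-Whitney statistic with ties counting one half, which equals the
trapezoidal area under the threshold-swept ROC curve.

Ranking groups by the *raw* frequency-ratio LR provably maximizes the
empirical AUC; the smoothed LR can swap near-tied groups when the case and
control sample sizes differ, which is invisible in practice but matters
for exhaustive optimality checks — those therefore rank by the raw LR.

## Forward selection and model-size choice

Selection starts from the null model and at each step adds the candidate
locus that maximizes training AUC (ties broken toward the lowest column
index). "Most significantly improves" is read as the largest AUC increase;
no hypothesis test is involved. The path stops when the best improvement
is ≤ 0 (configurable epsilon) or at a model-size cap (default 20, which
also bounds the genotype-group explosion; a warning fires past 2^12
observed groups). The first locus is always admitted, mirroring the seed
step of the collapsing procedure.

Model size is chosen by stratified 10-fold cross-validation over the path
prefixes. Two protocols are provided:

- `fixed-path` (default): the path is built once on the full training
  sample; folds re-estimate the LR tables at each prefix and score their
  held-out part. This is cheap and keeps the path well-defined, but
  because the loci were chosen using all the data the CV curve is
  optimistically biased and prunes conservatively.
- `nested`: each fold re-runs selection (and, for CROC, rebuilds the
  collapsing plan) on its own training part. Unbiased and noticeably more
  parsimonious, at roughly `folds` times the cost.

Either way the size with the best mean held-out AUC wins, ties going to
the smaller model. Genuinely held-out performance should always be
measured on data the fit never saw; in the simulation experiments below
that is an independent replicate drawn from the same generative truth.

## Multistage collapsing

Variants with training-sample MAF strictly below the threshold (default
0.01) are rare. A pseudo-common variant is the carrier indicator of a
group of rare variants: 1 if the individual carries at least one minor
allele at any member (a burden-count coding, clipped to the 0/1/2 genotype
alphabet, is available but not default). Groups are grown greedily —
seeded with the best single indicator by AUC, extended by whichever
remaining rare variant raises the collapsed indicator's AUC most, stopped
when no increase remains — and the procedure repeats on the leftovers
until the rare set is exhausted, yielding a partition. Group accuracy is
measured by the same LR-ordered AUC as everywhere else (so a
control-enriched, i.e. protective, group still scores above 0.5 and is
grown correctly); this is how bidirectional effects separate into distinct
groups. Groups that never rise above 0.5 are still emitted: downstream
forward selection is what discards useless pseudo-variants. With an empty
rare set the CROC fit reduces exactly — byte-identically — to the FROC
fit.

On null data the greedy growth happily absorbs case-only singleton
carriers, so a group's *training* AUC is inflated by construction; its
held-out AUC on an independent replicate is centered at 0.5, and that is
the property worth asserting.

## Synthetic data

The generator emulates a candidate-gene mini-exome panel: defaults are 209
cases / 488 controls (prevalence 0.3), 133 common variants with MAF ~
U(0.05, 0.45) and 400 rare variants with MAF ~ U(0.0007, 0.01), matching
the 697-individual, 533-SNP, MAF 0.0007–0.45 shape of the benchmark it
imitates. Genotypes are independent Hardy-Weinberg binomial draws; disease
follows a logistic liability on the causal minor-allele counts, with the
intercept centered so the population prevalence stays at baseline; case
and control quotas are filled by rejection sampling (a guard raises a
clear error when a quota is unreachable). Causal subsets may be given as
counts or explicit indices, optionally confined to a MAF band, with
per-variant log-odds effects (negative = protective). Default effects are
log-OR 0.405 for common and 2.0 for rare causal variants — a weak-common /
strong-rare regime typical of sequencing studies.

Not modeled: linkage disequilibrium, population structure, genotyping
error, and environment effects. Consequences: common and rare signals
combine additively (so adding commons always helps a method that can use
them), and independent replicates re-draw carriers (so a selected
singleton generalizes in proportion to its true effect rather than being
frozen noise, as happens in benchmarks whose replicates share genotypes).
Passing tests therefore demonstrate the methods' behavior under clean,
independent signals, not under realistic haplotype structure.

## Study conditions for the headline experiments

The depletion sweep (common variants progressively removed while all rares
stay) uses, per repeat, a fresh generative truth, one training and one
independent testing replicate, and a nested sequence of retained common
subsets shared by both methods. The regime was chosen so each method's
documented failure mode is actually present:

- commons: 4 causal of 50 at MAF 0.25–0.45 with log-OR 1.1, strong enough
  that forward selection recovers them reliably at n = 500;
- rares: 100 causal of 150 near-singletons (MAF 0.0008–0.0018) with
  log-OR 2.6 — individually almost worthless to selection, collectively
  an AUC ≈ 0.6 carrier union.

Under these conditions CROC beats FROC most where only rares remain, and
the gap narrows as informative commons return, because the collapsed
union's marginal value shrinks on top of a strong common signal. The
acceptance script scales the same regime to the full benchmark shape
(267 causal of 400 rares, log-OR 2.2); keeping the causal fraction at
about two-thirds matters — at one-quarter the greedy plan absorbs mostly
noise and the collapsing advantage dissolves.

The recovery experiment (first pseudo-common group should capture causal
rares) follows its prescribed calibration: the causal-union indicator AUC
is ≈ 0.65, which with 5 causal rares and prevalence 0.3 is only reachable
with causal MAFs at the top of the rare band (0.007–0.0099) and a
near-deterministic effect (log-OR 4.5); both values follow from the
closed-form union-AUC bound `0.5 + f(p/π − (1−p)/(1−π))/2` for carrier
frequency `f`, carrier case probability `p` and prevalence `π`.

Problem sizes used by the test suite (200 null simulations at n = 400;
50-repeat sweeps at n = 500; 5-repeat evaluation at n = 697 in the
acceptance script) were chosen as the smallest at which the Monte-Carlo
error is comfortably below the effects being asserted.

## Numerical and interface choices

- Fold assignment uses stratified shuffled K-fold with the run seed; the
  seed is a required input and is recorded in the model document.
- All greedy ties (candidate loci, group seeds, group extensions) break
  toward the lowest variant index, making every fit a pure function of
  (data, config, seed); refits are byte-identical and model documents
  round-trip byte-identically. Model provenance records input checksums
  only — no timestamps — precisely to keep this reproducibility property.
- Missing genotypes are imputed to the major homozygote by default, or
  kept as their own genotype category (`missing_policy="category"`); a
  missing call never counts as a carrier during collapsing.
- VCF input accepts biallelic SNVs only and re-orients to the minor
  allele from the pooled sample (with a logged warning when ALT is the
  major allele) instead of trusting REF/ALT.
- MAF is estimated on the pooled sample (cases + controls).

## Known limitations

- The fixed-path CV default over-selects model size when many candidates
  carry exploitable noise (near-singleton rares); use `cv_mode="nested"`
  when parsimony matters more than runtime.
- Greedy collapsing is not invariant to the noise load: with noise rares
  heavily outnumbering causal ones, early groups absorb enough noise
  carriers to dilute their held-out value.
- LR tables condition on exact genotype tuples; with many selected loci
  most test tuples are unseen and score neutrally, which caps the useful
  model size well below the group-count limit.
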