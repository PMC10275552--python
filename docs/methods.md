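# Methods

## The model

An island of age `t0` (My before present) assembles from a mainland pool of
`M` species.  Each mainland species colonizes at per-species rate
`γ_N = max(0, γ0 (1 − N/K))`, founding a non-endemic island singleton.  Each
island species speciates in situ (cladogenesis) at `λ_N = max(0, λ0c (1 −
N/K))`, being replaced by two endemic daughters; goes extinct at `μ`; and, if
non-endemic, diverges from its mainland ancestor (anagenesis) at `λa` without
a diversity change.  Extinction and anagenesis are diversity-independent.

The diversity count `N` defines the model variant: the whole island's species
count under island-wide (IW) feedback, or each mainland ancestor's own
descendant count under clade-specific (CS) feedback, in which case the same
`K` applies to every clade separately.  `K = ∞` turns feedback off (DI), and
CS and IW then coincide because mainland species evolve independently.  `K`
may be any positive real; rates clamp at zero, so the smallest integer
diversity with zero colonization and cladogenesis rates —
`diversity_cap = ceil(K)` (or `K` itself when integral) — is an absorbing
upper bound.

**The reset rule.**  A repeat colonization by a mainland species whose only
living island descendant is a "virgin" singleton (non-endemic, never
speciated) re-times that lineage's colonization instead of founding a clade.
After the lineage has speciated or anagenized, a repeat colonization founds a
second clade sharing the mainland ancestor; the data model excludes such
doublets (they do not occur in the motivating data), so simulated datasets
containing one are flagged by validation and treated as replicate failures in
the bootstrap pipelines.

## Data

A dataset is the island age, `M`, and one record per surviving colonist
clade: colonization age (stem age — the divergence from the mainland
sister), branching ages of the reconstructed island phylogeny (descending),
and an endemicity status (`endemic_clade`, `non_endemic_singleton`,
`endemic_singleton`).  Complete sampling of extant island species is assumed
throughout; `insert_missing_species` exists precisely to complete a tree with
known-but-unsequenced species before extraction (uniform placement along a tip
branch or over a subtree's branch length, repeated over seeded replicates).

## The likelihood

`Q_n(t)` is the probability that a realization of the process is consistent
with the observed colonization/branching record up to time `t` while carrying
`n` "hidden" species — species alive at `t` with no sampled extant
descendant.  With complete sampling the likelihood is `Q_0` at the present.
Between observed events `Q` obeys a linear master equation with constant
coefficients (rates depend only on state counts), with `k` the number of
observed lineages and all diversity-dependent rates evaluated at the current
total `N`:

- hidden birth: in-situ speciation of a hidden species (`n·λ_N`) or of a
  cladogenesis-capable observed lineage (`2k_c·λ_N` — the factor 2 because
  either daughter may be the doomed one), plus unobserved colonizations that
  found doomed clades (`(M − E − w)·γ_N`);
- hidden death: `n·μ` (observed lineages cannot die — absorbing);
- absorbing outflows: reset-eligible observed lineages' repeat colonizations
  (`E·γ_N`), and any event forbidden by a lineage's status (see below).

At an observed colonization the vector is multiplied by `γ_N` (the founder's
identity is part of the data); at an observed branching by `k_j·λ_N`, where
`k_j` is the clade's reconstructed lineage count just before the event — the
data record branching *times*, not topology, so any current lineage may be the
one that splits.  The vector is renormalized after every interval and event,
accumulating a log scale factor; the likelihood is `log Q_0(0) + log_scale`.

Two refinements make the computation exact for the model semantics:

- **Proto lineages (`reset="exact"`, the default).**  Before a clade's
  observed colonization its founder may already hold a virgin singleton whose
  colonization time will be *reset* (erased) by the observed event.  A small
  extra state axis `p` counts such protos (capped at `p_max = 3`; the
  neglected mass is of order `(γ0·t0)^4`).  Protos count toward `N`, may die
  (`μ`), speciate into doomed pairs (`λ_N`, `n + 2`), or anagenize into a
  doomed endemic (`λa`); the observed colonization either merges a proto
  (probability `p/w` by exchangeability of the `w` founders awaiting
  colonization) or founds the lineage fresh.  `reset="approx"` drops the axis
  and treats each observed colonization as the founder's first; for a
  non-endemic singleton at age `a` with `λ0c = μ = 0` this gives
  `ln γ0 − M γ0 t0` (independent of `a`), whereas the exact bookkeeping gives
  `ln γ0 − γ0 a − (M−1) γ0 t0`, which is what brute-force simulation of the
  process yields.
- **Endemic-singleton flips.**  A present-day endemic singleton must have
  become endemic at some unobserved time (anagenesis, or a speciation whose
  other daughter's subtree died).  One binary state axis per endemic
  singleton records whether the flip has happened; flips occur at `2λ_N`
  (with a hidden sister born) or `λa`, and only fully-flipped states
  contribute at the present.

Status bookkeeping per observed lineage: a non-endemic singleton can undergo
no cladogenesis or anagenesis at all and is reset-eligible over its whole
window (absorbing outflow `γ_N + λ_N + λa`); an endemic clade's stem is
treated as reset-eligible from colonization to its crown (treating stems as
always-virgin is a second-order `O(γ·λ)` approximation — a stem that has
already speciated in an unobserved event would no longer be resettable);
endemic singletons are reset-eligible while unflipped.  Unobserved
colonizations by founders of already-established clades found doomed clades
(allowed); hidden virgin singletons' own resets are rate-neutral and are not
tracked (error of order `n_hidden/M`).

These combinatorial constants — in particular `2k` vs `k` for doomed
daughters of observed lineages, and the event factors `γ_N` and `k_j λ_N` —
are locked by a brute-force Monte-Carlo oracle: `loglik_oracle_mc` bins exact
simulations (each event age within `bin_width/2`, statuses and sizes equal,
founders distinct) and converts the match frequency to a log density,
dividing by the `M(M−1)...(M−C+1)` ordered founder assignments since the data
identify the founders.  The test suite holds the engine to within 3 standard
errors of the oracle on nine toy datasets spanning `μ = 0 / μ > 0`, finite
and infinite `K`, 0/1/2 branchings, both singleton statuses and `λa > 0`; the
pure-birth cases additionally carry closed forms matched to ~1e-9.

### CS and DI likelihoods

For full comparability the CS loglikelihood is a sum of IW loglikelihoods
with a mainland pool of one: one term per observed clade plus `(M − C)` times
the empty-island term (computed once).  DI is CS with `K = ∞`.  All three
agree at `K → ∞`, checked at `K = 10^4..10^6`.

### Numerics

The generator is constant within each inter-event interval, so the default
propagation applies the exact action of the matrix exponential (dense Padé
below 256 states, Krylov-free `expm_multiply` above); `method="ivp"` uses
LSODA with configurable `rtol`/`atol` (defaults 1e-8 / 1e-60 after scaling)
and agrees with the exponential path to ~1e-10, with results stable to <1e-4
under 10× tighter tolerances.  The hidden-species axis is truncated: for
finite caps up to 192 the full physical range is used (exact); otherwise the
truncation starts at the observed species count and doubles until either the
top entry's relative mass falls below `tail_tol = 1e-12` or the
loglikelihood changes by less than `n_conv_tol = 1e-8` between successive
sizes (bounded by `n_max_limit`).  The convergence criterion matters when
cladogenesis exceeds extinction with `K = ∞`: the `Q` mass then spreads over
very large hidden counts whose contribution to the fully-pruned present-time
component is negligible, so a pure tail-mass rule would push the truncation
(and runtime) orders of magnitude past the point where the likelihood has
converged.  Fitting searches with both tolerances relaxed (1e-8 / 1e-4) —
empirically a top-entry mass of 1e-2 already leaves the loglikelihood
accurate to ~1e-8 — and the reported maximum is re-evaluated at the strict
settings.  Vectors are
renormalized whenever the maximum entry leaves a safe range; a vector that
reaches exactly zero marks the data impossible (`-inf`).

No conditioning is applied by default (the likelihood is the plain density of
the data); `conditioning="colonization"` divides by the probability of at
least one surviving colonization.

## Inference

`fit_model` maximizes the variant's loglikelihood by Nelder-Mead on
transformed parameters: log rates, and `log(K − K_floor)` with the floor at
the largest observed clade (CS) or the total island species count (IW).  DI
fixes `K = ∞`; "noA" variants fix `λa = 0`; the five fitted variants have 4
or 5 free parameters.  The default start moment-matches the data (branching
count over summed lineage time for `λ0c`, `C/(M·t0)` for `γ0`, twice the
observed maximum for `K`); additional starts perturb it log-uniformly in
[0.1, 10].  A start with non-finite likelihood is resampled.  Convergence uses
a 1e-6 absolute tolerance on the loglikelihood; an evaluation budget
(default 5000) marks fits incomplete rather than failing them, and the
reported loglikelihood always re-evaluates the returned parameters through
the likelihood modules.

AIC is `2·df − 2·LL` with Akaike weights; BIC uses a configurable effective
sample size (default: the number of observed events, colonizations plus
branchings) because no single convention reproduces all published BIC values.

## Model selection and goodness of fit

`bootstrap_lrt` implements the parametric bootstrap likelihood-ratio test:
simulate `n` datasets under each fitted model's MLEs, refit both models to
every dataset starting from the empirical MLEs — with the starting `K` raised
to at least the simulated dataset's own floor — and compare the empirical
`Δ = LL_CS − LL_IW` with the 5th percentile of the CS-generated and the 95th
percentile of the IW-generated `Δ` distributions (inclusive
linear-interpolation quantiles, recorded in the result).  `Δ` above the IW
95th percentile (and not below the CS 5th) selects CS; the mirrored rule
selects IW; otherwise the comparison is indecisive — a rule monotone in `Δ`.
Replicate failures (empty islands, doublets, optimizer errors) are recorded,
not fatal; refits keep their best-so-far value when they hit the evaluation
budget and are flagged incomplete.

Goodness-of-fit summarizes a dataset as total species, number of colonist
clades, largest clade size, and the colonization-order rank of the largest
clade (rank 1 = oldest colonization; size ties go to the earlier colonizer);
`gof_compare` locates the empirical values within simulated ensembles from a
fitted model, with randomized tie-breaking so percentiles are uniform when
the model is true.

## Synthetic data and what the tests show

The built-in surrogate dataset reproduces the published five-clade structure
(island age 30 My, `M = 1000`, colonization ages 22.09/13.75/11.03/8.85/8.43
My, sizes 28/21/3/5/8) with branching ages synthesized as seeded order
statistics of uniforms below each colonization age.  It exercises the
full-size data path but makes no claim about the real branching times, so
quantities that depend on them (e.g. the empirical loglikelihoods and the
empirical `Δ`) are not reproduced by this package's fixtures — only the
machinery that would compute them from the real data is.

Problem sizes in the test suite and `scripts/acceptance.py` are set for a
single CPU: the Monte-Carlo oracle uses 0.4–1×10^5 simulations per toy case;
the parameter-recovery study fits 12 simulated islands under the reported CS
parameters (the full-scale design uses 1000), asserting the medians of the
four estimates within 25% of truth; the misselection experiment runs 3
replicates per generating model with warm-started, evaluation-capped refits,
and its binomial acceptance bands are computed at that replication — at such
small `n` these bands are wide, so the experiment demonstrates the pipeline
and gives an honest (but low-precision) rate estimate rather than a sharp
test of the full-scale 7.7%/19% reference rates.

## Known limitations

- Recolonization doublets are excluded from the data model (validation flags
  them), and the likelihood does not handle them.
- Colonization-time uncertainty (max-age conventions) and partial sampling
  inside clades are out of scope; complete sampling is assumed.
- Endemic-clade stem virginity is approximated as described above
  (second-order effect on the reset bookkeeping).
- Hidden-species anagenesis is rate-neutral and ignored; `λa` enters only
  through observed non-endemic lineages, proto lineages and singleton flips.
- The per-clade CS carrying capacity is common to all clades; per-clade
  distinct `K` values are not supported.
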