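# Methods

`opsinsel` implements the desk-scale core of a molecular-evolution
workflow for protein-coding genes, shaped by the analyses typically run
on vertebrate visual opsins: codon-model estimation of selective
constraint (dN/dS), likelihood-ratio tests for positively selected site
classes, per-site empirical-Bayes and Bayesian-grid identification of
those sites, and residue-level reports at spectral-tuning sites in
bovine RH1 numbering. This note records the models, the numerical
choices, and the limits of what the bundled simulations can demonstrate.

## The codon substitution model

The unit of evolution is the codon. Substitution between sense codons
*i* and *j* follows a reversible Markov process with

    q_ij = 0                      if i and j differ at 2+ positions
    q_ij ∝ π_j                    single synonymous transversion
    q_ij ∝ κ π_j                  single synonymous transition
    q_ij ∝ ω π_j                  single nonsynonymous transversion
    q_ij ∝ κ ω π_j                single nonsynonymous transition

with κ the transition/transversion rate ratio, ω = dN/dS, and π the
equilibrium codon frequencies over the 61 sense codons of the standard
code (stop codons are excluded from the state space; alternative code
tables can be injected). Codons are ordered lexicographically over
{A,C,G,T} so all matrices are reproducible. Transitions are A↔G and
C↔T. P(t) = exp(Qt) is computed by the π-symmetrized eigendecomposition
(eigenvalues clipped at ≤ 0, probabilities clipped at ≥ 0), with a
generic scaling-and-squaring fallback for non-reversible inputs.

π defaults to F3x4 (position-specific nucleotide frequencies,
renormalized over sense codons, floored at 1e−6); `equal`, F1x4 and F61
are also available. The choice is a known sensitivity of codon-model
fits and is exposed in every interface.

## Random-sites models and rate scaling

Among-site variation in ω is a finite mixture: M0 (one ratio), M1a
(nearly neutral: ω0 < 1 and ω = 1), M2a (adds ω2 ≥ 1), M2a_rel (third
class unconstrained), M3 (three free classes), M7 (Beta(p, q) on (0,1)),
M8a (beta plus a class pinned at ω = 1) and M8 (beta plus ω_s ≥ 1). The
beta is discretized into K = 10 equal-probability classes represented by
their conditional means, computed from regularized incomplete-beta
ratios; K is configurable.

All class matrices share one scale factor chosen so the
*mixture-average* rate is 1. Branch lengths therefore read as expected
substitutions per codon site averaged over classes, and the nesting
identities hold exactly: a model whose extra class has zero weight
evaluates to the same likelihood as its null, to machine precision.
Site columns are compressed to unique patterns with multiplicities;
codons containing gaps/ambiguity codes are marginalized over their
compatible sense codons (a fully ambiguous codon carries no
information), and a codon resolvable only to stops is rejected at
validation.

## Fitting

Likelihoods are maximized by bounded L-BFGS-B on transformed parameters
(proportions via stick-breaking logits; κ, beta shapes and free ω via
log; ω_s via log(ω_s − 1), bounded in [1, 999]). Convergence uses a
relative log-likelihood tolerance of 1e−8. Several starting points are
used (ω-style parameters from {0.05, 0.5, 1.5, 3.0} as applicable) and,
when a nested null has been fitted, its optimum is added as an extra
start with the extra class at weight 1e−8 — this guarantees
lnL(alternative) ≥ lnL(null) − 1e−4 by construction. Every reported lnL
is an exact re-evaluation at the returned parameter point.

Branch lengths: the default (`branch_mode="scale"`) keeps the input
tree's relative branch lengths and frees one overall multiplier;
`"full"` frees every length (initialized from the tree or 0.1 when
absent) and `"fixed"` uses them as given. The scale default reflects
that the tool's tree inputs already carry estimated lengths and that ω
is a rate *ratio*, nearly orthogonal to overall divergence; re-fitting
every length under every 11-class mixture costs roughly 20× more for
changes that move lnL differences by far less than the reporting
precision. The reported `np` column nevertheless counts branch lengths
(2T − 3) plus κ plus the model's own parameters, the convention of the
published tables, so `np` differences between nested models are
preserved regardless of branch handling.

For the beta-family models the optimization runs in two stages: an
inner search over the mixture parameters on a precomputed per-site
log-likelihood surface over (ω, rate-multiplier) — ~40 ω values spaced
densely below 1, six multipliers, bilinear interpolation in (ω, log v) —
followed by an exact-likelihood polish from the best candidate. The
surface is built once per (κ, tree) and shared across M7/M8a/M8. The
interpolation only steers the search; no interpolated value is ever
reported.

## Tests of positive selection

Nested pairs are compared by LRT = 2·ΔlnL against a plain χ² with df
equal to the parameter-count difference (M0–M1a: 1, M1a–M2a: 2,
M1a–M2a_rel: 2, M0–M3: 4, M7–M8: 2, M8a–M8: 1). The plain χ²₁ is used
for the boundary pair M8a–M8 as well — a deliberately conservative
choice consistent with the printed p-values this package's report format
mirrors. Statistics negative within 2e−4 (optimizer noise) are clipped
to zero; larger negative values raise, since they indicate a fitting
failure rather than a tie.

NEB site posteriors are Pr(class | column) ∝ weight × likelihood at the
MLE. BEB integrates the same posterior over a uniform grid on the
mixture parameters (M8: p0 ∈ (0,1), p, q ∈ (0,2), ω_s ∈ (1,11), 10
points per dimension by default; M2a: the (p0, p1) simplex triangle, ω0
∈ (0,1), ω2 ∈ (1,11)), weighting each grid point by its full-data
likelihood. κ and branch lengths stay at their MLEs and the class-matrix
normalization is frozen at the fitted model, so ω is the only moving
part; with a one-point grid the procedure reduces exactly to NEB, which
is the main internal consistency check, alongside simulation-based
detection of planted sites. This is an approximation to the published
BEB procedure validated behaviorally, not a bit-level reimplementation
of any particular program.

## FUBAR-style grid analysis

Each site is placed on a 20×20 grid of (α, β) = (synonymous,
nonsynonymous) rates — values are squares of an even grid on
[0, √max_rate], max_rate 50 — so dS varies freely across sites, unlike
in the random-sites models. The rate matrix at a grid point scales the
synonymous and nonsynonymous components of the ω = 1, mean-rate-1 matrix
by α and β respectively; α = β = r is exactly the neutral process with
branch lengths multiplied by r. Nuisance parameters (κ, π, branch
lengths) come from a prior M0 fit, mirroring the method's two-stage
design. A Dirichlet(0.5) prior over grid weights is sampled by a
collapsed Gibbs sampler (default 5,000 retained draws after 1,000
burn-in; single-seed reproducible) alternating per-site allocations and
conjugate weight draws. Per site the report gives Pr(β > α | data)
averaged over draws; the ω column is (posterior mean β)/(posterior mean
α), a ratio-of-means convention recorded in the output metadata. The
defaults are desk-scale: smaller grids/chains than a production server
would use, all configurable.

## Tuning-site analysis

Opsin residues are numbered by global pairwise alignment (BLOSUM62,
affine gaps: open 10, extend 1) to the packaged 348-residue bovine rod
opsin; each query residue inherits the reference position of its aligned
column, and queries scoring below zero are flagged non-homologous rather
than numbered. The packaged catalog lists 35 spectral-tuning sites
(44–300) with their known variants, plus kinetic/functional sites (47,
59, 83, 288, 292, 299) and chromophore-binding-pocket sites per opsin.
Variation reports join observed residues by descending frequency (ties
alphabetical). Duplicate-copy comparison aligns the translations,
threads codons through the protein alignment, and reports percent
identity over columns where both copies are non-gap (so truncations and
indels do not inflate divergence) plus indel positions in reference
numbering; when an indel falls in a repeat run its placement is only
defined up to that run (the leftmost-equivalent alignment is reported).

## Synthetic data

The simulator is the generative mirror of the likelihood: per site a
class is drawn from the model's mixture, a root codon from π, and each
branch transition from the exact P(t) of that class's matrix under the
same mixture-average normalization — so simulated branch lengths mean
exactly what the fitted ones do. Beta-class sites draw the class
*representative* ω by default (matching the fitted likelihood exactly);
continuous Beta(p, q) draws are available for robustness studies. Random
topologies are grown by sequential random edge bisection from a
three-taxon star; branch lengths are i.i.d. uniform (default 0.05–0.3
expected substitutions/codon, a vertebrate-gene-like scale). All
randomness flows through one PCG64 seed.

What the simulations do not emulate: indels and alignment error,
recombination, selection on synonymous codon usage, non-stationary
composition, and lineage-specific (branch) effects. Passing the bundled
tests therefore demonstrates correctness of the inference machinery
under the model, not robustness to real-data violations of it.

## Validation problem sizes

The bundled test suite validates the pruning engine against brute-force
enumeration over ancestral states (trees ≤ 4 tips, 50 random parameter
draws, agreement to 1e−10); parameter recovery on 20 replicates of 20
taxa × 500 codons simulated with a 10% ω_s = 2 class (median ω̂_s within
[1.6, 2.4], median p̂1 within [0.05, 0.15], M7-vs-M8 power ≥ 16/20);
and type-I error on 50 replicates of 12 taxa × 300 codons under an
opsin-like M7 null (rejection ≤ 10% at nominal 5%). The acceptance
script reruns the same machinery at reduced replicate counts (its JSON
records the `n` used per quantity). An optional integration test refits
the archived opsin alignments when they are supplied locally
(`data/zenodo/`); nothing is downloaded at test time.

## Known limitations

- The BEB grid and priors are this package's own documented choices;
  site posteriors can differ in the second decimal from other BEB
  implementations even when the fitted models agree.
- With `branch_mode="scale"` the branch-length MLEs are inherited from
  the input tree up to one factor; datasets whose true relative branch
  lengths differ grossly from the input tree should be fitted with
  `branch_mode="full"`.
- The FUBAR ω column's ratio-of-means convention is one of several in
  circulation; compare Pr(β > α), not ω magnitudes, across tools.
- The M2a/M2a_rel likelihood surface is multimodal when the data carry
  few positively selected sites; the default two starts plus
  null-seeding find the collapsed optimum reliably, but users probing
  weak signals should pass additional starts.
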