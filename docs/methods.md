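# Methods

## Relative ranks and consensus schemes

Raw docking scores from different functions are not commensurable: they
differ in scale, units, sign convention and sensitivity to protein size.
All consensus machinery therefore operates on within-function relative
ranks. For a function with direction *lower is better*, the lowest score
receives rank 1; for *higher is better*, the highest does. Ties receive
average (fractional) ranks, which preserves the rank sum n(n+1)/2 and is
the convention of standard rank statistics; the tie policy matters only
on degenerate inputs since docking scores are effectively continuous.
Ranks are always computed per target — a docking campaign against one
protein structure is one ranking universe, and pooling across targets
would reintroduce exactly the target-dependent offsets ranking removes.

Two consensus schemes combine the per-function ranks r_ij:

- **Aggregated rank (rank-by-rank).** The Borda count B_i = Σ_j r_ij is
  ranked ascending with average ties. Low aggregated rank = favorable.
- **Exponential consensus rank.** ECR_i = Σ_j (1/σ)·exp(−r_ij/σ),
  defaulting to σ = 10; the scheme is insensitive to σ over a wide range
  because the exponential mainly discounts poor ranks. High ECR =
  favorable. The 1/σ prefactor (the normalization of the underlying
  exponential density) is included by default and can be disabled; it
  rescales values but never reorders ligands.

**Missing scores.** A docking failure removes a whole program's scores
for that ligand. The default policy assigns the missing (ligand,
function) pair the worst possible rank, n_ranked + 1: a ligand that could
not be docked must not be rewarded in consensus. The alternative `omit`
policy drops the pair; a ligand with no ranks at all is then excluded
from aggregation and reported.

## KDE threshold classification

Class-conditional densities of a score are estimated with a Gaussian
kernel. The default bandwidth is Scott's rule h = s·n^(−1/5) (s the
sample standard deviation) — the default of the common plotting stacks
whose KDE panels this mirrors; Silverman's rule and a fixed h are
available. Densities are evaluated on a uniform grid of 512 points padded
by 3h on both sides, which keeps the trapezoid mass of the curve within
[0.98, 1.02].

The decision threshold is a sign change of f_pos − f_neg on a common
grid, refined by linear interpolation between grid points. With
overlapping tails there can be several crossings; the one lying between
the two class medians is taken (that is the boundary a density plot
suggests), falling back to the crossing nearest the midpoint of the
medians, and *all* crossings are retained on the model for audit. Two
near-identical class distributions either raise a "no intersection"
error or return a crossing with the full crossing list attached — the
operation never silently fabricates a confident boundary.

Classification is strict on the positive side; a score exactly at the
threshold is negative, matching the "lower than" phrasing of a
score-cutoff rule. Missing scores classify negative (no favorable
binding evidence) with a warning. MCC uses the convention 0 when any
marginal of the confusion matrix is empty, keeping the metric total.

## Consensus interaction fingerprints

Contacts from two independent placement algorithms are intersected per
ligand on the key (interaction type, residue number, residue type,
chain). Only the intersection enters the bit universe: a contact seen by
one program alone is treated as placement noise. Set semantics collapse
multiple atoms contacting the same residue with the same interaction
type into one key. Bits are named `type@resnum@restype@chain` and ordered
lexicographically by (chain, residue number, residue type, type) for
deterministic serialization.

An empty consensus set is informative — the programs agree on no contact,
so the ligand is unlikely to bind at that site. Empty fingerprints are
kept as all-zero rows and given Tanimoto 0 against everything, including
other empty fingerprints and themselves (diagonal 0); treating two empty
sets as identical (T = 1) would cluster putative nonbinders as if they
shared a binding mode. Affected ligands are flagged.

Hierarchical clustering runs on d = 1 − T with average linkage by
default. The agglomeration is implemented directly (closest pair per
step, ties broken by input ligand order) rather than through a library
call, so identical inputs give byte-identical trees; scipy's linkage is
used as an independent cross-check in the test suite on tie-free inputs.

## Activity correlation

Spearman is computed as Pearson on average-tie ranks; pairing is by
strict key intersection with dropped ligands recorded, and fewer than
three common pairs is an error. No p-values are attached — with ~7
compounds the coefficients are descriptive. The OLS summary provides the
95% confidence band for the conditional mean via the t-distribution with
n − 2 degrees of freedom, evaluated on a uniform abscissa grid for
regression plots.

Sign conventions propagate end-to-end: ECR correlates positively with
pIC50 when the docking signal is real, while the aggregated rank (low =
potent) correlates negatively.

## The synthetic-study generator

The generator emulates the *tabulated outputs* of a two-program
cross-docking campaign, not the docking physics. A single latent affinity
a_it per (ligand, target) drives scores, interactions and activity — the
structure implicitly assumed whenever docking scores are correlated with
assay potency. Defaults mirror the reference study design: 28 ligands
(14 complex-I inhibitors, 11 complex-III inhibitors, 3 uncouplers), 11
scoring functions split 6/5 between two programs with the published
direction conventions, a 21-key interaction core per target, and pIC50
for the binders of the CIII target (the assay-accessible class).

- **Latents.** Binders of a target draw a_it ~ N(2, 1), nonbinders
  ~ N(0, 1). The d′ = 2 separation produces single-function
  classification quality (BAC ≈ 0.8) comparable to what the reference
  campaign observed; it is deliberately not so large that consensus has
  nothing to add.
- **Scores.** raw_j = α_j·a_it + β_j + target-offset + u_ip + ε_j, with
  u_ip ~ N(0, 0.3) shared per (ligand, program) — this induces the
  within-program block correlation visible in real rank heatmaps — and
  per-function noise sd 0.5–3 on scales loosely matching each function's
  magnitude. Higher-is-better functions emit raw, lower-is-better emit
  −raw, so flipping a direction flag negates scores and leaves ranks
  unchanged. Docking fails per (ligand, program) with p = 0.02 (about
  one whole-protocol failure per study, as observed), wiping all of that
  program's scores for the ligand.
- **Interactions.** True binders emit each core key per program with
  p_core = 0.85, so the cross-program consensus covers a core key with
  probability p_core² ≈ 0.72 (mean binder fingerprint ≈ 15 of 21 bits);
  nonbinders leak core keys at 0.05. Spurious contacts arrive as
  Poisson(2) per ligand and program, drawn from program-disjoint pools:
  spurious contacts are placement-algorithm artifacts and must never
  survive the consensus, which makes binder consensus size exactly
  Binomial(core_size, p_core²).
- **Activity.** pIC50 = 5 + 1·a_it + N(0, 0.3) for binders of the
  designated target; intercept and slope put values in the familiar 5–8
  range.

What the generator does **not** emulate: real score magnitudes (offsets
are only loosely realistic), chemistry-driven similarity between ligands
of a class, correlated failure modes (e.g. large ligands failing in both
programs), non-Gaussian score tails, or inter-target ligand promiscuity.
Passing tests therefore demonstrate the correctness and statistical
behavior of the analysis machinery under a faithful noise model — not
that any docking protocol achieves these numbers on real proteins.

## Numerical and design choices

- Scoring directions carry no default; every function must declare one.
- Score CSVs round-trip bit-for-bit (shortest round-tripping decimal
  representation); empty cells and "NA" both read as missing.
- PLIP residue codes are uppercased; chains compared case-sensitively,
  as authored in the PDB file. Water bridges and salt bridges stay
  distinct types — the merge key operates on the interaction type
  verbatim, so collapsing them would change fingerprints.
- Report files round metrics to 3 decimals alongside full precision.
- The pipeline manifest records a SHA-256 config hash and the seed;
  rerunning an identical config yields byte-identical artifacts.

## Test problem sizes

Monte Carlo suites use 50–100 replicates of the default 28-ligand study
(consensus agreement, fingerprint coverage, generative score contract),
a 100-ligand cohort averaged over 5 seeds for threshold-recovery BAC at
score-channel d′ = 3 (population optimum Φ(1.5) = 0.933; the larger
cohort stabilizes the single-study BAC estimate), 2000 samples per class
for Gaussian-crossing accuracy, and exhaustive enumeration of 2×2
confusion tables with margins up to 20 for the metric oracle. The full
suite runs in well under a minute on one CPU.
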