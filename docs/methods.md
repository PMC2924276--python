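# Methods

This note documents the models, conventions and numerical choices
behind `famevol`, in the spirit of the methods documentation of mature
simulation/inference packages: what is assumed, what the defaults mean,
and what passing the test suite does and does not demonstrate.

## Birth–death model for family counts

Family size evolves along each branch of a dated species tree as a
linear birth–death process with per-gene gain rate λ and loss rate μ,
restricted to λ = μ (the single-parameter model standard in CAFE-style
gene family analyses; gene families observed over tens of millions of
years rarely support separate rates from counts alone). With
α = λt/(1+λt), the s-ancestor transition probability is the classical
closed form

    P(s→c) = Σ_{j=0}^{min(s,c)} C(s,j) C(s+c−j−1, s−1) α^{s+c−2j} (1−2α)^j ,

with P(0→0) = 1 (extinction absorbing). The implementation is the
vectorised closed form; the test suite checks it against matrix
exponentiation of the truncated generator to better than 1e-8 for
s,c ≤ 10 and λt ≤ 0.5.

*Likelihood and fit.* The likelihood of one family's tip counts is
computed by pruning over integer states 0..C_max with
C_max = 2·(max observed count) + 5; the root prior is uniform over
1..C_max, i.e. the family is conditioned to exist at the root. The
"present" count at a tip is functional + incomplete annotations
(incomplete genes are real loci whose sequence could not be fully
recovered); pseudogenes are excluded from the present count. λ is
maximised in log-space with a bounded scalar optimiser
(xatol 1e-8, bounds 1e-7..1 /gene/My) — deterministic, no restarts
needed for a 1-D concave-in-practice surface.

*Ancestral counts and events.* Ancestral family sizes are the joint
max-probability (max-product/Viterbi) assignment over the same state
space, ties broken toward the smaller count; an all-zero family
short-circuits to all-zero ancestors. Each unit of count change on a
branch is one event (a +2 branch is two gains). Pseudogene counts
observed at a tip are added to the terminal branch's losses and tallied
separately as pseudogenisation events; because reconstruction runs on
functional+incomplete counts only, this never double-counts a loss.
Per-branch rates divide events by the parent-node count and the branch
length; tree-wide B and D divide the event totals by Σ C_i·t_i, the
gene-time accumulated over all branches, which renders them in
/gene/My. The parent-node count (rather than some within-branch
average) is used as C_i; this is a documented convention.

Note the MAP reconstruction undercounts events relative to the true
history (a gain and a loss on the same branch cancel invisibly), so on
simulations B and D are mild underestimates of λ while the ML λ̂ itself
is unbiased — the recovery tests bound λ̂ within 15% at 500 families.

## Synthetic data

The generators are the study conditions for every estimator test:

* **Families**: exact per-event Gillespie simulation of the linear
  birth–death process (no time discretisation), λ = μ = 0.002/gene/My
  by default on the 12-taxon demo tree (root at 40 My), root count 1,
  500 families for recovery checks. Losses on terminal branches are
  retained as observable pseudogenes with probability 0.5 by default —
  pseudogenes on internal branches are purged, matching the empirical
  observation that drosophilid genomes eliminate dead genes quickly.
* **Introns**: per-branch site loss with probability 1−exp(−rate·t),
  Poisson gains at uniform residues/phases, and slides of at most
  `slide_window` residues (phase preserved; a slide in the log keeps
  the site's identity). Replaying any event log reproduces the tip
  states exactly.
* **Codon alignments**: evolution under the one-ratio GY-style model
  itself (uniform frequencies over the 61 sense codons, so stop codons
  are unreachable), sampling each site from the exact transition matrix
  per branch. Uniform simulator frequencies deliberately isolate ω/κ
  recovery from frequency estimation; the fitter additionally supports
  F3x4.

What the generators do *not* emulate: annotation error in counts,
lineage-specific rate variation, among-site rate variation or indels in
codon alignments, and genomic coordinates for simulated introns beyond
residue/phase. Passing recovery tests therefore demonstrates estimator
correctness under the model, not robustness to real-data misspecification.

## Intron analysis conventions

An intron is keyed by k, the CDS nucleotides preceding it; phase
p = k mod 3; the residue is r = k/3 for phase 0 (the residue before the
junction) and ⌈k/3⌉ otherwise (the interrupted codon), which makes
"same position and phase" a single equality test after projection onto
the alignment. The sliding window defaults to 2 residues ("a few
nucleotides"); it is configurable everywhere it matters.

The character matrix merges observed (column, phase) classes whose
columns fall within the sliding window (single linkage), treating slid
introns as one potential site. Fitch parsimony is searched exhaustively
up to 8 taxa (10 395 topologies); beyond that, deterministic stepwise
addition followed by NNI hill-climbing. Branch "lengths" of the intron
phylogram are the state changes assigned by one deterministic
most-parsimonious reconstruction (ties resolve to the parent state,
root ties to the state of tip 1); other MPRs can distribute the same
total differently, so only the total (the parsimony score) is unique.
Sankoff reconstruction of intron counts uses cost |i−j|; because all
cost profiles are convex, each node's optimal set is an interval and is
reported as such.

## Codon model and optimisation

The substitution model is the Goldman–Yang-style Markov chain on the 61
sense codons: single-nucleotide steps, transition:transversion bias κ,
nonsynonymous factor ω, target-codon frequency π_j, generator scaled to
one expected substitution per codon per unit branch length. The chain
is reversible, so transition matrices come from one symmetric
eigendecomposition per (κ, ω), reused across branch lengths; site
patterns are compressed; per-node partials are rescaled to avoid
underflow. Fits maximise the log-likelihood over
(log κ, log ω per class, log branch lengths) with L-BFGS-B
(bounds 1e-4..99 for rates, 1e-7..30 for lengths), three deterministic
starting points ((κ,ω) = (2,0.4), (1,0.1), (4,1)); the third restart is
skipped when two agree to 1e-4 lnL. A fit is flagged `boundary` when a
rate parameter lands at a search bound or when the tree length
collapses (identical sequences: ω and κ are unidentifiable). With a
rooted input tree only the sum of the two root-adjacent branch lengths
is identifiable under a reversible model; their split is arbitrary and
does not affect lnL, ω or κ.

F3x4 frequencies use a 0.5 pseudocount per nucleotide so every sense
codon keeps positive frequency (keeps the symmetrised generator
well-conditioned). NG86 counting averages site counts over the two
sequences, averages differences over equally weighted minimal
substitution paths (paths through stops excluded; if all paths hit a
stop they are used anyway rather than dropping the codon), and applies
the Jukes–Cantor correction; proportions ≥ 3/4 are flagged saturated
rather than silently clamped.

For two-ratio branch models, the branch that spans the root should fall
in a single ratio class: with a reversible chain only the *sum* of the
two root-adjacent branch lengths is identifiable, and if those halves
carry different ω classes the likelihood acquires a ridge that inflates
the variance of the class estimates and makes the two-ratio-vs-one-ratio
LRT anticonservative.  The simulation studies therefore use a ladder
tree whose root-adjacent branches share a class, matching the standard
ingroup/outgroup labelling where the outgroup ratio is later discarded.

The two-ratio LRT is calibrated on null simulations (one ω simulated,
two fitted, χ²₁): the acceptance suite requires the rejection rate at
α = 0.05 to lie in [0.02, 0.08] over 200 replicates of a 4-taxon,
150-codon alignment — sizes chosen to keep the whole suite at desk
scale while leaving the test statistically meaningful.

Wilcoxon rank-sum comparisons of ω between gene classes enumerate the
exact null distribution when the smaller group has ≤ 8 values and there
are no ties (cross-checked in the tests against an independent exact
implementation), otherwise use the tie-corrected normal approximation.

Duplication dating assumes dS accumulates clock-like through the
duplication: age_k = T_div · dS_after_k/(dS_before + dS_after_k). The
proportional-path form is a documented choice; it reduces to the
midpoint for symmetric dS and to zero for a duplication at the present.

## Conservation index

The ten-property residue classification (hydrophobic, polar, small,
tiny, aliphatic, aromatic, positive, negative, charged, proline —
Taylor-style sets as used in alignment-annotation tools) ships as a
frozen table; a column scores one point per property whose
presence/absence is uniform across its non-gap residues. Gaps are
excluded from the uniformity test rather than zeroing the column
(several gap conventions exist in figure tools; this one is documented
and testable), except that an all-gap column scores 0. Blocks are
non-overlapping windows of 50 columns by default, the final partial
block averaged over its own length.

## Orthology

Best-hit ties disqualify a pair: strictness is deterministic and
conservative, and similarity scores from heuristic search tools carry
no meaningful order among exact ties. Orthogroups are connected
components of the RBH graph; monophyly on a supplied gene tree is
reported, never enforced by splitting, because non-monophyly is itself
a finding (mis-assembly, gene conversion, or tree error). Micro-synteny
evidence, when available, enters only as a manual override of group
membership upstream.

## Pipeline

`run_demo` fans one user seed out to the three generators through fixed
per-stage stream indices (numpy `default_rng([seed, stage])`), so
adding a stage never perturbs earlier stages' draws; reports are plain
JSON/TSV and byte-identical across reruns with the same seed. Demo
problem sizes (200 families, 500 codons by default) keep a full run
under a minute on one core.

## Known limitations

* The λ = μ restriction cannot express clades where gains and losses
  are genuinely asymmetric in rate; the per-branch event tallies still
  expose such asymmetry descriptively.
* Site-class codon models (beta-distributed ω, branch-site tests) are
  out of scope; the LRT scaffold accepts externally computed
  log-likelihood pairs.
* The parsimony NNI search beyond 8 taxa is a hill-climb and can stop
  in a local optimum on adversarial matrices; the exhaustive regime is
  exact.
* Alignment computation is an input, never performed here; all
  column-level conclusions inherit the quality of the supplied MSA.
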