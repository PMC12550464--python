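# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Data model and filtering

The unit of analysis is one protein alignment of one-to-one orthologues per
gene. Before anything else, every column containing a gap (`-`, `.`) or an
ambiguity/non-canonical code (`X B Z J U O * ?`) is removed; selenocysteine
and pyrrolysine are treated as ambiguous because the embedded 20-state
models do not describe them. Alignments retaining fewer than two columns are
discarded. Retained columns are reported 1-based in filtered coordinates,
with a `site_map` back to the original columns. Genes are processed
independently; the species tree is pruned to each gene's taxa, collapsing
unifurcations by summing branch lengths (pairwise leaf-to-leaf path lengths
are preserved exactly).

## Grouping schemes

A grouping scheme is a partition of the 20 canonical residues into labelled
classes, shipped as editable one-class-per-line text files:

* `US` — 20 singleton classes (no grouping). Under US, property convergence
  is definitionally identical to state convergence; the suite asserts this
  exhaustively and the pipeline reduces to a plain state-convergence
  implementation bit for bit.
* `GS1` (6 classes) — polarity/charge: C | AGPST | NDQE | RHK | ILMV | FWY.
* `GS2` (6 classes) — polarity and volume: C | AGV | ILMP | FWY | STNQH |
  DEKR. The membership separates V from I/L and places I, L, P together;
  this is constrained by worked substitution examples the defaults must
  reproduce (V→I with V→L, and T→I with T→P, are class changes into one
  shared class).
* `GS3` (7 classes) — adds a "small neutral" class AGPST mixing small polar
  and nonpolar residues: AGPST | DE | KRH | NQ | C | ILMV | FWY.
* `GS4` (12 classes) — only highly similar side chains share a class:
  G | AILV | P | C | M | ST | NQ | DE | KRH | F | Y | W. The basic class
  must contain R and H together (P→R with P→H is a class-convergent pair
  under this scheme) and the acidic class D, E without K.
* `GS0` (6 classes) — a randomised control partition (GWDC | PM | K | IQLS
  | EATVYF | NHR), used to separate the trivial effect of grouping from
  genuinely physicochemical grouping. `make_random_scheme` generates fresh
  controls by shuffling residues into a template's class sizes.

These memberships satisfy every documented constraint, but fine-grained
class boundaries (for example whether F and Y share a class) are a judgment
call; users reproducing published gene lists should substitute the original
authors' scheme files, which is why schemes are plain data.

## Substitution model and likelihood machinery

The rate matrix is `q_ij = S_ij π_j` from a published symmetric
exchangeability matrix S (LG, JTT or WAG, embedded in the standard
lower-triangle `.dat` layout) and equilibrium frequencies π, normalised to
one expected substitution per unit branch length. By default π is estimated
from the gene alignment (observed residue proportions over all cells,
floored at 1e-6 and renormalised — the "gene model"); the matrices' own
frequencies are selectable. Transition matrices use the symmetric
eigendecomposition available for reversible chains, computed once per
model; P(0) returns the exact identity.

Among-site rate variation is discrete-gamma with k = 4 equal-probability
categories by default and the mean-of-bin convention (regularised
incomplete gamma); median discretisation is selectable. The gamma shape can
be fixed (the calibration experiment uses the generating value 2) or
grid-estimated per gene by maximising the pruning log-likelihood
(default grid 0.25–8).

Site log-likelihoods use Felsenstein pruning with per-node scaling.
Marginal ancestral reconstruction combines, per rate category, the "up"
conditional likelihood below a node with the "down" likelihood of the rest
of the data; categories are weighted by their per-site posterior, and the
reported state is the argmax of the marginal posterior with alphabetical
tie-breaks (ties are recorded on the result object). Both engines are
verified against exhaustive enumeration on four-taxon trees (tolerance
1e-10) and against an independent R phylogenetics implementation to 1e-8,
including the gamma discretisation.

A PAML `rst` parser can substitute codeml's marginal reconstruction for the
native one, reconciling codeml's node numbering by clade matching. It
targets the documented best-state-per-site block; it has been validated
against synthetic fixtures in that layout, not against live codeml output.

## The R statistic

For one gene, one grouping scheme and one pair of phylogenetically
independent focal branches (each addressed by its child node; nested pairs
are rejected):

* **O** counts sites whose reconstructed substitutions on the two branches
  each change class and arrive in the same class. Derived states are the
  observed residues on terminal branches and argmax reconstructions on
  internal ones; ancestral states are always the parent's argmax
  reconstruction.
* **E** sums per-site neutral expectations over rate categories weighted by
  the site's category posterior. Three ancestral conventions exist:
  - `posterior` (default): the parents' full marginal posteriors weight the
    forward transition probabilities;
  - `conditional`: point masses on the parents' argmax states (the
    convention of the original state-convergence R method);
  - `joint`: the product of the two branches' empirical-Bayes
    substitution-type probabilities (joint parent/child endpoint
    posteriors). **This mode is a calibration diagnostic only**: because it
    conditions on the observed derived states, genuine convergent signal
    inflates E together with O, so it cannot detect excess convergence and
    must not back the Poisson test. The spiked positive control in the test
    suite demonstrates exactly this failure mode.
* **R = O/E** and the one-sided Poisson tail `p = P(X ≥ O)`, `X ~
  Poisson(E)`; O = 0 gives p = 1, and E = 0 with O > 0 gives p = 0. No
  multiple-testing correction is applied at this stage, since gene lists
  are expected to pass through downstream enrichment filtering.

Batch scans emit a per-gene table (gene × scheme × branch pair), a site
event table, and the four gene sets of interest: R > 1 (p < 0.05), O > 0,
R(GS) > R(US) and O(GS) > O(US).

## Lineage engines

The **MRCA comparison** engine calls a lineage "changed" at a site when its
focal taxa all carry one class (strict agreement; an any-taxon variant is
selectable) differing from the class of the reconstructed most recent
common ancestor of the focal taxa and their nearest sister species. A site
is convergent when ≥ 2 changed lineages share the derived class; tallies
are keyed by lineage combination with at-least semantics, so each
two-lineage tally contains the three-lineage one.

The **CCS** engine needs no tree: among sites where the outgroup and every
background taxon carry the identical residue (conservation is defined at
residue level even in property mode), a site is convergent when ≥ 2 focal
taxa share one class different from the background residue's class.
Negative controls are plain role swaps in the configuration, and the swap
symmetry is asserted exactly in the tests.

## Neutral simulator and calibration

The simulator evolves gap-free alignments along a uniform random rooted
bifurcating topology (sequential leaf attachment, every topology with
probability 1/(2n−3)!!). Defaults are the benchmark conditions: 1000
alignments × 500 sites × 36 taxa, all branch lengths 0.1, root drawn from
the LG equilibrium frequencies, and continuous Gamma(shape 2, mean 1) site
rates — deliberately continuous while inference discretises at k = 4, so
the calibration also absorbs discretisation error. All randomness flows
through spawned substreams of one seed, giving bit-reproducible runs. The
generator emulates neutral, indel-free, stationary evolution with a single
shared topology; it does not emulate alignment error, indels, heterotachy,
compositional drift or selection, so calibration results speak to
estimator behaviour under the model, not to robustness against real-data
artefacts.

The calibration experiment runs the full pipeline (gene-frequency model,
reconstruction at the generating shape, O and E per scheme) between two
fixed focal branches chosen deterministically from the seed: independent,
non-sibling, not root-adjacent (under reversibility the root's position on
its adjacent edges is unidentifiable, so substitutions cannot be assigned
to one of them), and maximally separated in the topology — the geometry of
distantly related focal lineages that convergence scans target. The suite
checks, at a scaled-down 200 alignments, that pooled ΣO/ΣE lies within
1 ± 3/√ΣE per scheme and that the per-alignment rejection rate at p < 0.05
stays at or below its binomial envelope.

**Known conservativeness.** Counting O on argmax reconstructions loses a
fraction of true double events: reconstruction smooths away precisely the
substitutions that are hardest to resolve. Decomposition on simulations
shows the E engine is exactly calibrated against the true simulated states,
while argmax-based O recovers ~94% of true events under US and ~76% under
the randomised GS0 (whose class changes are disproportionately chemically
conservative substitutions such as D↔E, the easiest for reconstruction to
smooth away). Pooled neutral R therefore sits a few percent below 1 (about
−6% for US, −13% for GS0 at these study conditions), occasionally breaching
the 3σ envelope for GS0; the corresponding acceptance check is left failing
rather than widened, and the one-sided Poisson test of O > E remains valid
— the estimator errs conservative.

The positive control injects property-convergent columns below both focal
branches: at a chosen column, a target class is drawn that differs from the
true parent classes (preferring a class absent from all non-focal taxa, so
the background anchors the parent reconstructions), and each focal clade is
overwritten with one residue from that class. Spiked columns are recovered
as convergence events and drive pooled R significantly above 1 under the
forward E conventions.

## Numerical choices

* frequency floor 1e-6 before renormalisation; no zero equilibrium entries;
* transition probabilities clipped at 0 and row-renormalised after
  eigendecomposition round-off; P(0) exact identity;
* per-node likelihood scaling with log accumulators (no underflow for
  deep trees); impossible configurations yield −inf log-likelihood rather
  than errors;
* argmax ties broken alphabetically and logged;
* problem sizes in the test suite: calibration at 200 alignments × 500
  sites × 36 taxa, oracle checks on 4-taxon trees, parameter-recovery at 50
  replicates × 500 sites, positive control at 5 genes × 4 spiked columns.

## Limitations

* No branch-length or topology optimisation: lengths come from the input
  tree (the upstream pipeline's job, typically PAML's); only the gamma
  shape is estimated natively.
* The rst parser covers marginal best-state blocks in the documented
  layout; other codeml output variants will need adjustment.
* Default scheme memberships are constrained but not authoritative (see
  above); exact reproduction of published gene lists requires the original
  scheme files and data.
* Reconstruction-based counting is mildly conservative under neutrality
  (quantified above); comparisons of R between schemes inherit
  scheme-dependent shrinkage, which is why the randomised control scheme
  and the role-swap negative controls matter in interpretation.
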