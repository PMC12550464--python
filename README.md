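# caap

Detection of **convergent amino-acid property substitutions** in protein
alignments on phylogenies.

Conventional molecular-convergence scans ask whether independent lineages
arrived at the *same amino acid* at a site. But residues with similar
physicochemical properties can be functionally interchangeable: a lysine that
becomes aspartate in one lineage and glutamate in another has undergone the
same basic-to-acidic change twice, even though the derived residues differ.
`caap` groups the 20 residues into physicochemical classes and detects sites
where two or more independent lineages each *changed class* and arrived in
the *same class* — property convergence — alongside the classical state
convergence that it generalises.

## Who this is for

Molecular evolutionary biologists studying adaptive convergence (echolocating
mammals, marine mammals, mangrove plants, or any system with repeated
phenotypic evolution) who want site- and gene-level convergence calls that go
beyond identical amino-acid states, with a calibrated neutral expectation.

## The statistic

For a pair of phylogenetically independent focal branches and a grouping
scheme with class map `c(·)`, a site is **property convergent** when the
per-branch substitutions `x₁→y₁` and `x₂→y₂` satisfy

```
c(y₁) = c(y₂),  c(y₁) ≠ c(x₁),  c(y₂) ≠ c(x₂)
```

Ancestral states come from marginal ancestral sequence reconstruction under
an empirical model (LG/JTT/WAG exchangeabilities, gene-specific equilibrium
frequencies, discrete-gamma rate variation). The gene-level test compares

* **O** — the observed number of property-convergent sites,
* **E** — the neutral expectation, summing over sites and rate categories the
  model probability that both branches change class into one shared class:
  `E_site = Σ_m w_m Σ_c≠classes(x₁,x₂) [Σ_{y∈c} P_{x₁y}(r_m t₁)]·[Σ_{y∈c} P_{x₂y}(r_m t₂)]`,
* **R = O / E**, with a one-sided Poisson tail test of O > E
  (`p = P(X ≥ O), X ~ Poisson(E)`); R significantly above 1 flags putatively
  adaptive convergence.

Three further engines round out the toolkit: an **MRCA-comparison** counter
(a lineage is "changed" when its focal taxa all differ in class from the
reconstructed ancestor it shares with its nearest sister), a
**conserved-site (CCS)** counter (outgroup and background identical in
residue, two or more focal taxa sharing a different class), and a **neutral
simulator** that calibrates R on alignments evolved under the same model.

Six grouping schemes ship as editable text files: `US` (ungrouped — 20
singleton classes, under which property convergence reduces exactly to state
convergence), `GS1`–`GS4` (coarse polarity/volume partitions up to a
fine-grained 12-class partition), and `GS0` (a randomised control partition).

## A worked example

```python
import caap

tree = caap.random_topology(16, seed=11, branch_length=0.1)
pair = caap.choose_calibration_pair(tree, seed=11)
aln = caap.simulate_alignment(tree, caap.build_model("LG"), 400, alpha=2.0,
                              seed=5, gene_id="demo")

model = caap.build_model("LG", "gene", aln)       # gene frequencies
rates = caap.discrete_gamma(2.0, 4)
asr = caap.marginal_asr(aln, tree, model, rates)
for name in ("US", "GS1", "GS4"):
    res = caap.gene_convergence(aln, tree, pair, caap.load_scheme(name),
                                model, rates, asr)
    print(name, res.O, round(res.E, 3), res.p)
```

Running `python examples/rmetric_single_gene.py` (this example with
reporting) prints:

```
gene demo: 16 taxa, 400 sites
focal branches: clades ['t5', 't8'] vs ['t13', 't14']
  US: O=1  E=0.520  R=1.92  p=0.405
    site 313: A->S | A->S (state_and_property)
  GS1: O=0  E=0.295  R=0.00  p=1.000
  GS4: O=1  E=0.370  R=2.70  p=0.309
    site 313: A->S | A->S (state_and_property)
```

One site (313) carries the same A→S substitution on both focal branches: a
state-convergence event that is also property convergence under the
fine-grained scheme, but not under the coarse scheme (A and S share its
small-residue class, so no class change occurred). A neutral gene, as here,
shows O of 0 or 1 against a comparable expectation and an insignificant
Poisson p; a convergently evolving gene would show O well above E with
small p. The `examples/` directory holds one short
script per capability (event classification, the R pipeline, neutral
calibration, MRCA counting, CCS counting, reconstruction-model robustness).

## Command line

```bash
caap schemes                      # list/validate grouping schemes
caap simulate --taxa 36 --sites 500 --genes 100 --seed 1 --out-dir sims/
caap rmetric  --aln-dir genes/ --tree species.nwk --pair nodeA,nodeB \
              --scheme US,GS1 --out results.tsv
caap ccs      --aln-dir genes/ --roles roles.yaml --scheme GS4 --out ccs.tsv
caap calibrate --seed 1 --genes 200 --out calib.tsv
```

Every output table carries a provenance header (tool version, configuration
hash, seed) and a sidecar file with the resolved configuration.

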