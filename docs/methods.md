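# Methods

## Problem and model

`polyprofile` quantifies the relationship between a compound's 2D structure
and its target selectivity in a screening collection. The unit of evidence
is the activity triple (compound, target, outcome ∈ {active, inactive});
selectivity is summarised by the number of *distinct* targets with at least
one active outcome. Classes are **inactive** (0 targets among tested
assays), **black** (1), **gray** (2–4) and **white** (>4). The 1/4
boundaries are the package defaults because they split large pooled
screening libraries into comparably sized classes; both are configurable
(`ClassThresholds`). A compound with no activity evidence at all is
*unclassified* and excluded from every class statistic — absence of testing
is not evidence of inactivity. A compound whose only active records carry
no resolvable target accession is dropped up front
(`filter_untargeted_actives`): it is known to be active but cannot
contribute to target counting.

Chemical identity is an isomeric canonical SMILES of the largest covalent
fragment. Stereo-aware keys were chosen because chirality is itself one of
the descriptors under study; collapsing enantiomers would couple the
deduplication step to the quantity being measured. Largest-fragment
stripping is the usual convention for salt-containing library entries. Two
records with the same compound id but different structures abort loading —
that pattern indicates corrupted input rather than duplication.

## Descriptor panel

All descriptors are 2D and computed on the implicit-hydrogen molecular
graph after RDKit sanitization (explicit hydrogens are suppressed first).

* **Stereocenters.** Tetrahedral centers from RDKit's stereo perception;
  *defined* = parity specified and resolvable to R/S, *undefined* =
  stereogenic but unspecified. Double-bond E/Z stereogenicity is excluded
  from this count. Both numbers are exposed so that analyses counting
  "stereocenters" either way can be reproduced.
* **C=C / C=N double bonds.** Bonds of order exactly 2 joining C–C or C–N,
  excluding aromatic bonds under the toolkit's default aromaticity
  perception. Perception runs after parsing, so kekulized and aromatic
  input dialects give identical counts (pyridine has 0).
* **sp³ chain carbons.** SMARTS `[CX4;H2;!R]`: saturated carbons bearing
  exactly two hydrogens, outside rings. The H2 constraint already excludes
  terminal methyls.
* **Ring profile.** Over the smallest set of smallest rings: a ring is
  *aromatic* when all its bonds are aromatic, *fused* when it shares at
  least one bond with another basis ring (spiro junctions — shared atom
  only — count as single). Counts are per ring, not per ring system, so
  naphthalene contributes two fused aromatic rings. SSSR tie-breaking in
  cage systems follows the toolkit's deterministic choice and is a known
  source of ambiguity there.
* **H-bond donors/acceptors.** Lipinski convention: donors = N–H plus O–H
  hydrogens, acceptors = all N plus O atoms.
* **logP.** Wildman–Crippen atom-contribution model (SlogP): a published
  atom-type hierarchy with summed contributions, hence additive over
  disconnected fragments.
* **logS.** Estimated aqueous solubility, log₁₀ mol/L. The package ships
  the ESOL linear model (Delaney 2004): logS = 0.16 − 0.63·clogP −
  0.0062·MW + 0.066·RB − 0.74·AP, with clogP the Wildman–Crippen value, RB
  rotatable bonds and AP the aromatic-atom proportion. Solubility models
  differ substantially between published parameterizations, so the model is
  pluggable (`LOGS_MODELS`) and the model name travels with every panel;
  absolute logS values should be compared only within one model.
* **MW.** Average-isotopic molecular weight, hydrogens included.

A descriptor failure is recorded as an explicit null, never a silent zero,
and nulls are excluded from both numerator and denominator of any
percentage.

## Stratified comparison

Distributions are reported as binned percentage matrices: bins are
half-open `(lo, hi]`, labeled by upper bound (a bin labeled "350" holds
values in (300, 350]), with underflow and overflow bins at the ends. Default
schemes: 50-Da bins for MW, unit bins for logS and logP, integer bins with a
">4" overflow for counts. Rows are percentages of each class and sum to 100
within rounding.

Class pairs are compared with the two-sided Wilcoxon rank-sum test and the
two-sample Kolmogorov–Smirnov test. The rank-sum p-value is exact (full
null enumeration) for combined sample sizes ≤ 12 without ties, otherwise a
normal approximation with tie and continuity corrections; ties force the
approximate path even at small n and are logged. The KS p-value is exact
for combined sizes ≤ 12, otherwise asymptotic. Both tests are computed by
scipy behind the package interface; the test suite checks the exact path
against an independent exhaustive enumeration over rank assignments. No
multiple-testing correction is applied — the result table carries sample
sizes so the user can apply one — and the pooled one-vs-rest variant is
available alongside the default all-pairs comparison.

## Target families and overlap

Targets map to GPCR / kinase / protease / ion-channel accession catalogs
supplied as plain text files; anything unmatched is *other*. A target
present in several catalogs keeps all memberships for reporting but takes a
single primary label with fixed priority GPCR > kinase > protease >
ion_channel (configurable) so that composition percentages sum to 100.
Family-ligand membership uses active outcomes only. For each family F the
overlap report splits every F-ligand's distinct active targets into
intra-family and off-target hits (histograms binned 0–4 and ">4") and
records, for every family pair (F, G), the fraction of F ligands that hit
at least one G member; the diagonal is 1 by construction.

## Synthetic-data generator

The generator emulates the statistical shape of a pooled screening dataset
while keeping every planted quantity recoverable.

* **Structures** are assembled by chaining 2–8 SMILES fragments drawn from
  a documented pool (CH₂ linkers, a chiral unit, an undefined-stereo unit,
  C=C and C=N units, single aliphatic/aromatic rings, fused-ring units,
  ether and amide groups); ring-closure labels are renumbered per
  occurrence so any fragment combination parses. Fragment assembly (rather
  than sampling descriptor vectors directly) means the descriptor module is
  exercised on real molecules; the realized descriptor panel, not the
  fragment recipe, is the ground truth. Planted duplicates are re-emitted
  with permuted atom order to exercise canonicalization; the truth records
  the total duplicate-key count (planted plus accidental assembly
  collisions), which deduplication must match exactly.
* **Promiscuity** is negative binomial with mean
  `base_rate · exp(Σ β_d · d)`. Defaults: base rate 2 targets, dispersion
  1.2, β = −0.50 (defined stereocenters), −0.15 (sp³ chain carbons), −0.40
  (single aliphatic rings), +0.35 (C=C/C=N), +0.50 (fused aromatic rings) —
  signs encode the selectivity-enhancing vs promiscuity-enhancing roles the
  analysis is designed to detect, and magnitudes were fixed once at values
  that give the four classes non-trivial occupancy at the default base
  rate. The negative binomial (rather than Poisson) allows the
  overdispersion seen in real bioactivity counts.
* **Activities.** An active compound draws a seed family (weighted by
  family size; default catalog 40/35/30/25 named targets plus 70 *other*),
  then hits each other family G with the probability in its seed family's
  cross-reactivity row — by default the GPCR column is elevated (0.35–0.49)
  relative to the others, reproducing the asymmetric GPCR off-target
  pattern of real collections. Each member family receives at least one
  hit and the remaining hits are allocated by row-weighted draws; the
  latent count is raised if needed to fit all drawn memberships, so planted
  cross-rates are exact Bernoulli probabilities per ligand. In planted
  class-mix mode the opposite convention holds: memberships are capped so
  the realized count equals the planted one and the class assignment is
  exact. Tested-but-unhit targets are emitted as inactive records (3 per
  compound by default) so that fully inactive compounds are still "tested".
* **Determinism.** One root seed feeds a splittable generator
  (`numpy` `Generator.spawn`), giving the structure, promiscuity and
  activity stages independent stable streams; dataset files are
  byte-identical across runs of the same config.

What the generator does *not* emulate: chemically realistic, drug-like
libraries (no synthetic-accessibility or property matching to real
screening decks), assay-level noise or replicate structure, potency values,
or target-sequence relationships within families. Passing recovery tests
therefore demonstrates correctness of the pipeline's counting, statistics,
and bookkeeping under the stated generative model — not that the biological
effect sizes in any real dataset will match.

## Worked example stand-in

`polyprofile.worked_example` ships one synthetic molecule,
`CC(CCc1ccccc1)C(=O)NCCCN1CCC(O)CC1`, constructed to carry the structural
signature of a prototypical selective (black) GPCR ligand: one undefined
tetrahedral stereocenter, one aliphatic ring, exactly five `[CX4;H2;!R]`
carbons, an aromatic ring linked to a basic nitrogen by an alkyl chain, and
Wildman–Crippen logP ≈ 2.2. It is a constructed illustration, not a
database retrieval, and its reported values are computed from the structure
at run time.

## Numerical and scale choices

* Exact-test cutoff n₁+n₂ ≤ 12 keeps enumeration instantaneous while the
  normal approximation is already accurate beyond it (agreement within 0.02
  at the boundary is asserted in the tests).
* The acceptance script sizes its runs at 100 molecules for oracle
  agreement, 1,000 replicates for null calibration, 4,000 compounds
  (≈500 seeded ligands) for cross-rate recovery and 5,000 compounds for
  effect-direction recovery — large enough that binomial sampling error is
  well inside the assertion bands, small enough to run in well under a
  minute on one CPU.
* Empty classes, empty families and empty samples yield explicit nulls or
  errors (documented per function), never silently propagated zeros.

## Known limitations

* SSSR-based ring counts are ambiguous for cage polycyclics; the toolkit's
  deterministic choice is used and documented.
* The ESOL logS is a coarse fragment-level model; rank orderings are more
  trustworthy than absolute values, and other parameterizations can be
  registered.
* Classification has no minimum-assay requirement for the inactive class: a
  single negative record suffices to mark a compound tested.
* Catalog-based family assignment inherits any incompleteness of the
  user-supplied accession lists; unlisted targets fall into *other*.
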