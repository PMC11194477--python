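# Methods

## Model

A protein complex is represented at residue resolution: per residue a CA
and a CB coordinate (CA substitutes for CB in glycine, the standard
convention for CB-based contact maps) and a confidence value (plDDT).
plDDT is stored on the [0, 1] scale everywhere; the PDB reader divides by
100 whenever a file carries values above 1, so interface scores are
independent of the input convention.  Chains are identified by *entity* —
the label of a unique sequence — never by file chain id, because an
assembly typically contains many copies of one entity.

Two residues on different chains are in contact when their CB atoms lie
within 8 Å (inclusive).  An interface is scored as

    s = log10(n_contacts) × mean plDDT over the interface residues,

with the mean taken over the union of participating residues from both
chains and s defined as 0 for n_contacts ≤ 1 (log10 of 0 is undefined and
log10(1) = 0).  This product form is deliberately simple: it rewards both
large and confidently predicted interfaces and needs no fitted
parameters.

## Assembly as tree search

The unit of assembly is the *interaction pair*: two chains frozen in the
relative orientation a sub-component prediction gave them.  An assembly
state is a list of placed chains; an action picks a placed chain, a pair
with a matching entity on either side, superposes that side onto the
placed chain (Kabsch on CA atoms; the implementation sign-corrects the
smallest singular vector so reflections can never occur) and adds the
pair's other chain.  A placement is illegal when the new chain's clash
fraction — the share of its CA atoms within 3.0 Å of a placed chain's CA
atoms — exceeds 0.2 against any placed chain.  The tolerance is
deliberately permissive: predicted sub-components carry coordinate error,
and a strict clash rule would veto correct ring closures.

Crucially, a pair may be used many times.  Copy numbers are therefore not
an input: a closed (point-group) complex stops growing because every
further placement clashes with existing chains, and the stoichiometry is
whatever the finished structure contains.  Open helical symmetries have no
such closure, so their termination comes from the chain budget
(`max_chains`, default 30, matching the 10–30-chain regime the method
targets); recovering an exact helical copy number therefore requires the
budget as prior knowledge, which we consider a structural property of
screw symmetry, not an implementation artefact.

The search is plain UCT: UCB1 selection (exploration constant √2, ties
broken by lowest action id, unvisited children first), single-action
expansion, uniform-random rollouts capped at 6 added chains, mean-reward
backup.  After a fixed budget of 100 simulations the best root action by
mean reward is committed and its subtree reused; the loop repeats until
the state is terminal.  Rollout sampling enumerates candidate actions
cheaply and clash-checks them in a seeded random order — the first legal
candidate of a uniform permutation is a uniform draw from the legal set.
All randomness flows through one seeded generator, so runs are
bit-reproducible; run reports echo the full configuration and its digest.

The reward of a state is the mean interface score over contacting chain
pairs multiplied by completeness (placed chains / chain budget).  The
completeness factor stops the search from being satisfied with one good
dimer; the mean (rather than sum) keeps the per-interface scale so that
adding a bad interface lowers the reward.  Sum and min aggregates were
considered; the mean-times-completeness form is the package's choice and
is config-exposed.

The balanced-interface heuristic restricts candidate anchors to placed
chains whose interface-contact tally is at most (minimum tally + 1).  In a
symmetric complex every chain ends with the same interface count, so
under-connected chains are exactly the growth front; the filter prunes
anchors that are already saturated.  It is on by default and switchable
off for asymmetric targets, whose chains have no balanced tallies.

## Processing predicted sub-components

Sub-components arrive in fivefold redundancy (five predictor models) and
overlapping compositions.  Deduplication compares same-composition models
over all entity-consistent chain mappings with a single Kabsch
superposition per mapping, scoring mean 1/(1+(d/d0)²) with the standard
length-dependent d0 (1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å); models at
similarity ≥ 0.9 merge and the copy with the highest mean plDDT survives.
Pairs are then extracted (contact floor: 10 contacts, suppressing grazing
contacts), and near-duplicate relative orientations (partner RMSD ≤ 2 Å
after anchor superposition, including the swapped assignment for
homotypic pairs) are merged keeping the highest-scoring member.  Both
filters compare each item only against already-retained survivors, which
makes them idempotent and order-deterministic (score, then mean plDDT,
then lexicographic id).  Pooling all five models rather than the
top-ranked one matters because the per-model confidence ranking is noisy;
with confidence that tracks accuracy, keep-best filtering across models
selects the least-distorted geometry.

## Synthetic data generator

The generator emulates the upstream predictor so the whole pipeline is
testable offline.  The chain template is a compact 20-residue CA trace
wound on a 4.5 Å sphere with CB pushed 1.2 Å outward — a blob with
realistic contact statistics, not a protein fold.  Units are placed by
exact group operators: cyclic Cn on a ring whose radius makes adjacent
centres sit at the contact distance (14 Å); dihedral Dn as two staggered
rings relatable by a C2 flip; tetrahedral as the 12-point orbit of a
generic direction under the rotation group T (a cuboctahedron); helical
by rise/twist screw operators; plus one fixed asymmetric four-entity
arrangement.  The generator verifies its own contract — every chain has a
contacting neighbour, the contact graph is connected, no pair clashes —
and raises otherwise.

Slicing takes every connected window of k chains of the contact graph
(deterministically subsampled to at most 60 windows), re-centres it,
applies a random orientation, and adds per-residue Gaussian displacement.
`noise_sigma` is the RMS per-atom displacement in Å (per-axis std σ/√3),
so σ = 1 yields superposed RMSDs of about 1 Å against the reference.
Simulated confidence is 0.9 minus a small jitter for core residues;
interface residues are additionally drawn down in proportion to their
realised displacement (coefficient 0.3 per Å), mirroring the fact that
real predictors' confidence estimates correlate with local error — this
correlation is what makes five-model pooling informative.  Decoy pairs
(partner rotated about its centroid by a chosen angle) carry interface
confidence scaled by 0.65, emulating the lower confidence predictors
assign to wrong interfaces.

What the generator does *not* emulate: folds, flexible loops, chains of
unequal length, systematically wrong but confident interfaces, or
predictor failure modes beyond isotropic noise and orientation decoys.
Passing the synthetic bench demonstrates the assembly machinery; it does
not certify accuracy on real predictor output.

## Evaluation

Predicted and reference assemblies are compared with an entity-consistent
one-to-one chain mapping (greedy, seeded by the best single-chain
superposition; exhaustive enumeration available for ≤ 8 chains), a single
global Kabsch superposition over the mapped CA atoms, and the TM-style
score Σ 1/(1+(d_i/d0)²) / L.  The normalisation length L is
max(predicted, reference) total residues, so both missing and surplus
chains lower the score; d0 uses L with the 0.5 Å floor.  This
single-superposition scorer is an internal stand-in adequate for
fixture-scale comparisons — it does not reproduce the iterative alignment
search of the field's external alignment tool, for which an optional
wrapper is provided (and never silently substituted).  A complex counts
as correctly predicted at score ≥ 0.8; stoichiometry correctness is exact
multiset equality of entity counts (a ratio-based definition was
considered and rejected as weaker).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| contact cutoff | 8.0 | Å CB–CB | standard contact-map convention |
| min pair contacts | 10 | contacts | suppresses grazing interfaces |
| dedup similarity threshold | 0.9 | — | near-duplicate models merge, genuine alternatives survive |
| pair RMSD tolerance | 2.0 | Å | below typical inter-orientation distances, above noise |
| clash rule | fraction > 0.2 at 3.0 Å | — | tolerant of predictor noise |
| MCTS iterations / move | 100 | simulations | recovery saturates on the bench at this budget on one CPU |
| exploration constant | √2 | — | standard UCB1 |
| rollout depth | 6 | chains | look-ahead past the next ring position |
| max chains | 30 | chains | the method's target regime |

All are config-exposed (YAML + CLI overrides) and echoed in every run
report.

## Problem sizes used by the test bench

The default matrix is C3, C6, C12, D2, D3, tetrahedral (12 chains) and
helical (10 chains), with 20-residue chains, dimer windows, five
pseudo-models, at noise 0 and 0.5 Å; the acceptance script runs ten seeds
per fixture and the test suite twenty.  These sizes keep a full bench run
in minutes on a single CPU while covering every symmetry class the
generator supports.

## Known limitations

- **Ring-closure drift.** Large cyclic complexes assembled by reusing a
  single noisy step pair replicate that pair's angular error
  systematically; after eleven C12 steps a few degrees of error open a
  gap that admits a thirteenth chain.  At 0.5 Å RMS noise the C12 fixture
  recovers its stoichiometry in roughly half the runs, while every other
  matrix fixture recovers in ≥ 90%.  This is a property of
  pairwise-superposition assembly itself, not of the search; consensus
  averaging of orientation clusters would mitigate it but would change
  the keep-best filtering semantics.
- Helical stoichiometry requires the chain budget as prior knowledge (see
  above).
- The internal complex score is a single-superposition approximation;
  borderline scores near the 0.8 threshold should be confirmed with the
  external alignment tool.
- The evaluation chain mapping is greedy by default; pathological
  symmetric cases can in principle map suboptimally (exhaustive mode
  exists for small complexes).
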