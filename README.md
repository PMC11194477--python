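# mcassembly

Assembly of large protein complexes — and simultaneous inference of their
stoichiometry — from predicted structures of small sub-components, using
Monte Carlo Tree Search.

## The problem

Structure predictors such as AlphaFold-Multimer handle dimers to tetramers
well but cannot model a 10–30-chain complex directly, and every multimer
predictor requires the stoichiometry (the copy number of each unique chain,
e.g. A6B2) as an input.  `mcassembly` removes that requirement: given only
the set of unique chain sequences and predicted structures of their small
sub-complexes, it assembles the full quaternary structure and reads the
stoichiometry off the result.  It is aimed at structural bioinformaticians
who already run multimer predictors and want to scale to large symmetric
(cyclic, dihedral, tetrahedral, helical) or moderately asymmetric
assemblies.

## Method

1. **Enumerate** all sub-component compositions (multisets of entities,
   dimers–tetramers) and emit one FASTA per composition as predictor jobs.
2. **Predict** each composition externally (all five predictor models are
   worth keeping — this package never runs the predictor itself).
3. **Deduplicate** structurally redundant sub-components with a
   chain-mapped, TM-style similarity filter (threshold 0.9; the most
   confident copy survives).
4. **Harvest interaction pairs**: every contacting chain pair inside a
   sub-component, in its predicted relative orientation.  Near-duplicate
   orientations (partner RMSD ≤ 2 Å after anchor superposition) are merged,
   keeping the best-scoring pair.
5. **Assemble** by UCT tree search.  A state is a partial assembly; an
   action rigid-body-superposes one side of a pair onto a placed chain of
   the same entity (Kabsch on CA atoms) and adds the other chain.  Pairs
   may be reused any number of times, so copy numbers emerge from the
   search; growth stops when every placement clashes or the chain budget
   is reached.
6. **Score** interfaces with the pDockQ-style product

   ```
   score = log10(n_contacts) × ⟨interface plDDT⟩
   ```

   where a contact is a CB–CB distance ≤ 8 Å (CA for glycine) and plDDT is
   on the [0, 1] scale.  The search reward is the mean interface score
   over contacting chain pairs times a completeness factor
   (chains placed / chain budget).

A balanced-interface heuristic restricts anchor chains to those whose
interface-contact tally is within one of the current minimum — effective
for symmetric complexes, switchable off (`--asymmetric`) for others.

Because predictor output quality is external to this package, the test
bench is synthetic: `mcassembly simulate` builds ground-truth complexes of
known symmetry from a compact synthetic chain template, slices them into
overlapping sub-components with controllable coordinate noise and
simulated plDDT, and the pipeline is asked to put them back together.

## Worked example

Simulate a noisy C6 homohexamer, rebuild it, and compare with the truth:

```
$ echo '{"symmetry": "cyclic", "n_units": 6, "noise_sigma": 0.5, "seed": 5}' > spec.json
$ mcassembly simulate spec.json --out-dir fixture
wrote A6 fixture (30 sub-components, seed 5) to fixture

$ mcassembly pairs fixture/subcomponents --entity manifest --out-dir pairlib
wrote 1 pairs to pairlib/index.tsv (config f1a884975fc5e3c0, seed 0)

$ mcassembly assemble pairlib --out-dir run --seed 1
assembled A6 (reward 0.2297) -> run/assembly.pdb

$ mcassembly evaluate run/assembly.pdb fixture/reference.pdb \
    --entity-pred "A=A,A=B,A=C,A=D,A=E,A=F" --entity-ref "A=A,A=B,A=C,A=D,A=E,A=F"
{
  "complex_score": 0.9507...,
  "stoichiometry_correct": true,
  ...
}
```

Reading the numbers: the 30 noisy sub-components (6 ring windows × 5
pseudo-models) collapse to a single unique ring-step pair; reusing it, the
search recovers the hexamer (`A6`) without being told the copy number; the
final reward 0.2297 is the mean interface score (≈1.15) × completeness
(6/30 under the default 30-chain budget); and the assembled structure
matches the reference at complex score 0.95 (1.0 = identical; ≥ 0.8 is
the conventional success threshold).

With real predictor output, drop the per-composition PDB files (plDDT in
the B-factor column) into a directory and start from `mcassembly dedup` /
`mcassembly pairs` with an explicit `--entity` map instead of `manifest`.

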