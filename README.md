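# trnacode

Tools for a repeat-based model of tRNA origins and the early evolution of
the genetic code:

- **trna_model** — builds the three 31-nt minihelices from primordial
  repeat sequences (GCG / CGC / UAGCC and the inverted-repeat
  stem-loop-stem), ligates them into the 93-nt precursor, and applies
  internal 9-nt junction deletions to produce segmented type I (75 nt) and
  type II (84 nt) tRNA core models, optionally with 3'-ACCA.
- **trna_compare** — per-segment identity profiles of query tRNAs against
  the model, a positional-identity permutation test for loop homology,
  repeat-motif phase scoring, and pairwise tRNAome distance matrices.
- **code_table** — the genetic code as a 32-cell codon–anticodon table
  (column = anticodon position 2, row = position 3, half = wobble G vs
  C/U), with wobble reading rules and the C>(U~G)>A anticodon preference
  scale.
- **sectoring** — a four-stage simulation of code sectoring from an
  all-Gly table to the standard code, driven by an editable event file,
  plus a displacement audit against the preference scale.
- **aars_network** — homology networks over directed aminoacyl-tRNA
  synthetase score matrices (class I and class II tables ship as packaged
  CSV fixtures): symmetrization, maximum-score spanning trees, best-hit
  digraphs, and a same-column coherence permutation test.
- **synthetic** — seeded generators for mutated tRNAomes and
  planted-tree score matrices, so every analysis stage is testable offline.
- **io / cli** — FASTA and matrix-CSV I/O (ND/NR token dialect), run
  manifests, and the umbrella `trnacode` command.

## Command line

```sh
# build the type I primordial model with a segment annotation sidecar
trnacode build-model --type I --out model.fasta --segments model.tsv

# generate a synthetic tRNAome and score it against the model
trnacode synth trnaome --n 40 --rate 0.1 --seed 7 --out trnaome.fasta
trnacode score-trnas model.fasta trnaome.fasta --out profile.csv
trnacode trnaome-distance trnaome.fasta --out dist.csv

# permutation test for loop homology
trnacode loop-test --a CCGGGUUAAAAACCCGG --b CCGGGUUAAAAACCCGG \
    --n-perm 9999 --seed 1

# the 32-cell codon-anticodon table and the sectoring trajectory
trnacode code-table --format pretty
trnacode simulate-sectoring --out traj/

# aaRS homology network from a score matrix CSV
trnacode aars-network --matrix src/trnacode/data/class2_scores.csv \
    --root GlyRS-IIA --exclude LysRS-IIB --out net/

# planted-tree synthetic score matrix
trnacode synth matrix --nodes 13 --seed 7 --out scores.csv --truth truth.csv
```

Every command writes a JSON run manifest next to its primary output, and
every stochastic command requires an explicit `--seed`.

## Layout

```
src/trnacode/           package modules
src/trnacode/data/      packaged fixtures: class1/class2 score tables,
                        sectoring event file
tests/                  pytest suite (tests/test_acceptance.py holds the
                        acceptance criteria)
scripts/acceptance.py   acceptance report generator
```
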