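# phycysid

Two-stage ensemble classification of plant cystatins (phytocystatins)
from protein sequence.

Phytocystatins are plant inhibitors of cysteine proteinases. They fall
into four subtypes — the intronless type-I clades **I1** and **I2**, the
intron-containing type I (**IwI**), and the carboxy-extended, two-domain
type II (**II**) — distinguished by gene structure, length and domain
architecture. Annotating them correctly in new genomes and transcriptomes
matters for work on senescence, seed germination and biotic/abiotic
stress, but the subtypes (especially I1 vs I2) overlap too much for
single-model or motif-only calls.

`phycysid` classifies protein FASTA input in two ensemble stages over 21
physicochemical descriptors computed from the standardized inhibitory
domain:

1. **GG cutter** — the variable N-terminal extension is trimmed at the
   first diglycine (else the first glycine) within the first 50 residues,
   retaining the conserved domain glycine.
2. **Index-TF8M** — eight classifiers (GB, AdaBoost, Bagging, MLPC, RF,
   QDA, KNN, LR) vote TRUE/FALSE; the index is the TRUE count and

   `is_phycys ⇔ Index-TF8M ≥ 4`.

3. **PhyCysID-12M** — for passing sequences, twelve classifiers vote on
   the subtype; the final class is the modal call and the winning vote
   count (12…4) is reported as its support ("Frequency").

The 21 descriptors cover residue-group fractions (aliphatic, acidic,
aromatic, basic, polar, hydroxyl, cysteine, …), N-glycosylation sequon
count, length, Chou–Fasman helix/sheet/turn propensities, Kyte–Doolittle
hydropathy, Hopp–Woods hydrophilicity, the Guruprasad instability index,
and Henderson–Hasselbalch net charge at pH 7.4 plus isoelectric point
(EMBOSS pKa set). See `docs/methods.md` for definitions and design
rationale.

A full training stack is included — stratified 70/30 split, grid search
with stratified 20-fold cross-validation for all 15 classifier families,
support-weighted evaluation matrices, normalized feature importances —
plus a synthetic-sequence generator that emulates the cystatin domain
grammar (QxVxG, [A/P]W, SNS[L/I], GG cleavage site, subtype-specific
lengths and compositions) so the whole pipeline trains and tests offline.

## Worked example

Generate a labeled synthetic corpus, train both stages, and classify:

```sh
phycysid simulate --n-positive 100 --n-negative 400 --seed 42 \
    --out-fasta corpus.fasta --out-truth truth.tsv
phycysid train corpus.fasta --out-dir model --seed 42
phycysid predict corpus.fasta --bundle model --out predictions.tsv
```

`train` writes `stage1_metrics.tsv` / `stage2_metrics.tsv` (one row per
model plus the voting-index row). On the corpus above the stage-1 table
ends with

```
model       accuracy  precision  specificity  recall    fpr       f1        confusion
...
Index-TF8M  0.979167  0.979466   0.979167     0.979167  0.020833  0.979163  [[119, 4], [1, 116]]
```

i.e. on the 240-sequence held-out 30%, the 8-model vote recovered 119 of
the 120 true phytocystatins (one false negative) and rejected 116 of the
120 decoys. Two rows of `predictions.tsv`:

```
id           cleavage_mode  tf8m_index  is_phycys  ...  Frequency  Final_class
II_syn_0000  GG             8           True       ...  12         II
No_syn_0003  G              0           False      ...
```

`tf8m_index 8` means all eight stage-1 members voted TRUE; `Frequency 12`
means the subtype call was unanimous across the twelve stage-2 members.
Sequences failing stage 1 get no subtype columns. `phycysid evaluate
predictions.tsv truth.tsv` scores both stages against the truth table,
and `--stringency-out` tabulates final classes by their supporting vote
count.

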