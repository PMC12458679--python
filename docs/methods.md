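# Methods

## The classification problem

Phytocystatins are plant inhibitors of cysteine proteinases (papain-family
C1; the carboxy-extended type II also inhibits legumain-family C13). Their
inhibitory domain is compact and well conserved: a flexible amino-terminal
region anchored by a conserved glycine, a central QxVxG loop, an [A/P]-W
pair near the carboxy terminus, and — in type II — a second domain carrying
an SNS[L/I] legumain-inhibitory motif. Four subtypes are distinguished by
gene structure and domain architecture: the intronless type-I clades I1 and
I2, the intron-containing type I (IwI), and the two-domain type II.

`phycysid` decides, from the amino-acid sequence alone, (i) whether a
protein is a phytocystatin at all and (ii) which subtype it belongs to.
Both decisions are ensemble votes over classifiers trained on 21
physicochemical descriptors.

## Pipeline

1. **GG cutter.** The variable N-terminal extension (often a signal
   peptide) is removed by scanning the first 50 residues for a diglycine;
   failing that, for the first lone glycine. The retained segment starts at
   the conserved glycine (the second G of the pair). A `--drop-glycine`
   switch starts the segment one residue later instead; sequences with no
   glycine in the window pass through unchanged, flagged `NONE`, and are
   still classified. The diglycine is searched across the whole window
   before the lone-G fallback applies, so an early lone G never pre-empts a
   later GG.

2. **Featurization.** 21 descriptors per cleaved segment, in a frozen
   column order (see below).

3. **Index-TF8M.** Eight binary classifiers (GB, AdaBoost, Bagging, MLPC,
   RF, QDA, KNN, LR) each vote TRUE/FALSE; the index is the TRUE count and
   a sequence passes with index ≥ 4. The frozen member list corresponds to
   the models whose 20-fold CV accuracy clears 0.9 on the reference corpus;
   `select_members` can instead re-derive the list from CV results at any
   cutoff.

4. **PhyCysID-12M.** For passing sequences only, twelve classifiers
   (the zoo minus DecisionT, BNB, QDA) each call a subtype; the final class
   is the modal call and its vote count is reported as the "frequency"
   (12 … 4).

## The 21 descriptors

Composition descriptors are fractions of the standard residues (positions
holding the ambiguity code X are excluded from numerator and denominator;
B/Z/U/O are mapped to X on input): aliphatic {A,V,I,L,M}, acidic {D,E},
aromatic {F,Y,W} and {F,Y,W,H}, strongly basic {K,R}, basic {K,R,H}, helix
breakers {P,N}, hydroxyl {T,S}, polar {S,T,Y,D,E,H,Q,K,R}, cysteine
fraction (redox potential), and {R,K,G,S,Y} as an interface-enriched proxy
for RNA-binding potential. The redox and RNA-binding definitions are
modeling choices of this package and sit in the swappable scale/group
registry. Counts: the N-glycosylation sequon count (N-X'-[S/T], X' ≠ P,
overlaps counted) and the residue length.

Mean-scale descriptors average a per-residue table over the segment:
Chou–Fasman P(alpha), P(beta) and P(turn) for helix/sheet/turn propensity,
Kyte–Doolittle hydropathy, and Hopp–Woods hydrophilicity. Any table can be
replaced from a YAML registry (`--scales`).

Charge descriptors use a Henderson–Hasselbalch model with the EMBOSS pKa
set (N-terminus 8.6, C-terminus 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1,
C 8.5, Y 10.1): the net charge at pH 7.4, and the isoelectric point found
by bisection on [0, 14]. The charge is strictly decreasing in pH with a
sign change over that interval, so the root is unique; bisection runs to a
pH interval below 1e-6, which keeps the residual charge well under 1e-3
even for weakly buffered sequences (a plain |charge| stopping rule can be
~0.1 pH units off when only the termini ionize). The instability index is
the Guruprasad dipeptide-weight sum, (10/L)·Σ DIWV(x_i, x_{i+1}), computed
over the X-filtered segment.

Using one pKa set for both charge and pI keeps the two descriptors
internally consistent; the set itself, like the scales, is swappable.

## Model zoo and training protocol

Fifteen scikit-learn classifier families: RF, GB, AdaBoost, Bagging, LR,
GNB, BNB, DecisionT, QDA, LDA, MLPC, KNN, RC, Perceptron, SGDC. Each
trains inside a `StandardScaler` pipeline (so every CV fold re-fits its
own scaler; zero-variance columns pass through unscaled with a warning).
The corpus is split 70/30 with class stratification; hyperparameters are
chosen by grid search maximizing mean accuracy over a stratified 20-fold
CV on the training partition, then the best point is refit on the full
training partition. The stage-2 task trains on the positively labeled
rows only. The QDA grid starts at reg_param 0.1 because several
descriptors are nested group fractions (e.g. the two aromatic fractions),
which makes the unregularized per-class covariance singular.

Default grids are deliberately small (1–3 points per family — e.g. RF
depth {None, 10}, LR C {0.1, 1, 10}, KNN k {3, 5, 7}, MLP one hidden layer
of 50 with two weight-decay values): with 20-fold CV over two stages the
full protocol then completes in a few minutes on one CPU, and the grid
contents move the reported metrics only marginally. All grids are
overridable from YAML (`--grids`).

Feature importances: native impurity importances for RF/GB/AdaBoost/
DecisionT (sum to 1); |coefficients| averaged over class rows and min–max
normalized to [0, 1] for LR/RC/Perceptron/LDA/SGDC; for the MLP, which has
no single coefficient vector, the |first-layer weights| summed over hidden
units are normalized the same way (a documented approximation). QDA, GNB,
BNB, KNN and Bagging expose no importances and report none.

## Tie handling

Twelve voters over four classes can tie. Tied classes are ranked by the
summed predicted class probability over probability-capable members; if
still tied, a fixed priority II > IwI > I2 > I1 applies (ordered by
per-class sensitivity of the ensemble). Tied rows are flagged
`tie_broken`. Member verdicts are hard labels throughout — the ensembles
vote, they do not average probabilities.

## Synthetic corpus

The generator makes the pipeline trainable and testable offline. A
positive is assembled as: optional signal-peptide-like prefix (probability
0.5; 15–30 residues from a hydrophobic, glycine-free alphabet, starting
with M) + the planted GG site + the domain grammar (LARFAVDEHN-like helix
block, background, QxVxG, background, [A/P]W; type II appends a linker and
a second domain with SNS[L/I] inserted). Class signal deliberately reaches
the 21 composition-level descriptors, not just motif space:

- post-cleavage length ranges: I1/I2 85–110, IwI 95–125, II 180–220
  (echoing the ~10–16 kDa single-domain vs ~23–26 kDa two-domain span);
- background composition shifts: I1 acidic-enriched (D,E ×1.8), I2
  basic-enriched (K,R ×1.8), II N/S-enriched (×1.6), IwI neutral; the
  helix block is more degenerate in the intronless subtypes (substitution
  rate 0.3 vs 0.1);
- cysteine contrast: a positive carries ≥2 cysteines with probability
  0.108, a decoy with probability 0.615 — the prevalence contrast observed
  between real phytocystatins and their proteome outgroup;
- decoys: 91–249 residues of uniform background (with ~5% glycine
  re-added so the GG cutter engages), rejection-sampled to exclude any
  QxVxG match, headers prefixed `No_`.

What the generator does **not** emulate: phylogenetic covariance between
sequences, alignable homolog families, realistic proteome composition of
the decoys, or insertion/deletion structure. Passing the end-to-end tests
therefore shows that the pipeline machinery recovers a class signal
expressible through the 21 descriptors — it does not certify accuracy on
real proteomes, for which the published training corpus is required.

## Problem sizes and seeds

The end-to-end checks train the 8-member stage on a balanced 1,000-sequence
TRUE/FALSE corpus and the 12-member stage on a 600-sequence subtype corpus
(150 per class), averaged over five seeds; these sizes mirror the reference
corpus scale (1,074 sequences) while keeping a full two-stage grid-searched
run at a few minutes per seed. All randomness — corpus generation, the
70/30 split, CV shuffling, and stochastic learners — flows from a single
integer seed, and fixed seeds reproduce feature tables, splits, metric
reports and predictions byte-for-byte.

## Known limitations

- The frozen member lists are tied to the reference corpus; on a corpus
  with different CV rankings, `--cutoff` re-selection is the safer path.
- The RNA-binding and redox descriptors are proxies (see above); swapping
  their definitions changes trained models and must be followed by
  retraining.
- The cleavage is purely motif-positional; no signal-peptide model is
  consulted, so proteins whose first in-window glycine precedes the true
  domain start are trimmed short.
- Metrics use support-weighted averaging (macro averaging is available via
  `average="macro"`); AUC-ROC is omitted for decision-function-only models
  (RC, Perceptron, SGDC).
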