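# p450nnc

Neural-network-cascade scoring of multi-cytochrome-P450 inhibition from
molecular descriptors.

Most drugs are cleared by a handful of cytochrome P450 enzymes — CYP1A2,
CYP2C9, CYP2C19, CYP2D6 and CYP3A4 — and a compound that inhibits several of
them at once carries a much higher drug–drug-interaction risk than a
single-isoform inhibitor. `p450nnc` is for cheminformaticians and DMPK
scientists who want a graded, structure-based estimate of that risk: it turns
a table of molecular descriptors into a single **P450 inhibition score (PIS)**
in [0, 1] that tracks the number *n* ∈ {0,…,5} of isoforms a compound
inhibits.

## The model

The predictor is a *neural network cascade*: a ladder of small Gaussian
radial-basis-function (RBF) networks, each with 11 hidden units.

1. **Labelling.** Per-isoform assay evidence becomes a call — inhibitor
   (AC50 ≤ 10 µM, or PubChem activity score > 40), non-inhibitor
   (AC50 > 57 µM, or score = 0), indeterminate otherwise. Compounds with five
   definite calls get a count *n* and the graded target *y = n/5*; categories
   are non-inhibitor (*n*=0), non-extensive (*n*=1–2) and multi-P450
   inhibitor (*n*=3–5).
2. **Screening.** After min–max normalization to [0,1], a 1-11-1 RBF network
   is fitted per descriptor against *y*; descriptors whose network output has
   Spearman ρ > 0.4 with *y* are admitted.
3. **Ladder.** The top descriptor's network seeds the cascade. Each further
   rung is a 2-11-1 network fusing the current PIS with one more descriptor;
   the rung giving the maximum — and a strict — increase in ρ is kept, and
   construction stops when no candidate improves ρ.

Each unit is trained on an internal 2:1:1 train/verification/testing split:
k-means centers, nearest-center widths, ridge least-squares readout with the
penalty picked on the verification subset, output min–max rescaled to [0,1].

The package also provides the curation rules (salt/hydrate standardization,
inorganic and mixture rejection, strict MW < 800 Da filter), the validation
statistics (Spearman ρ with exact small-*n* p-values, 2:1:1 and k-fold
splits, AUROC via the Mann–Whitney identity, Youden-optimal thresholds,
paired DeLong AUC comparison, χ² tests), Tanimoto chemical similarity
networks with cluster representatives and a similarity-aware train/validation
split, and a planted-truth synthetic benchmark generator.

## Worked example

```bash
python examples/train_and_score.py
```

trains the cascade on the default planted benchmark (600 compounds,
40 descriptors of which 5 are informative) and prints:

```
ladder: D040 -> D020 -> D021 -> D010 -> D036
rho along the ladder: [0.8929, 0.9304, 0.9408, 0.9471, 0.9506]

recovered 5/5 planted descriptors in the ladder
holdout Spearman rho(PIS, count) = 0.943
holdout AUROC (multi-inhibitor, count>=3) = 0.980
```

The ladder admits exactly the five planted informative descriptors and fuses
them one at a time, with the rank correlation between the PIS and the
inhibited-isoform count rising at every rung. On the 300 held-out compounds
the PIS ranks compounds by their inhibition count with ρ = 0.94, and a
random multi-P450 inhibitor outscores a random non-multi compound 98% of the
time. See `examples/` for curation, validation-statistics and
similarity-network walk-throughs, and the `p450nnc` command
(`simulate` / `train` / `predict` / `validate` / `csn`) for the same workflow
from the shell.

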