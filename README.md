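# affinitygan

Drug–target binding affinity (pKd) regression built around adversarially
pre-trained 1-D convolutional sequence features, BLOSUM protein encoding,
and a validation harness with warm-start cross-validation, logP cold-start
splits, and shuffled-label (straw-model) controls.

The pipeline:

1. **Encoding** — proteins and drug SMILES are treated as character strings.
   Label encoding maps characters to small integers (0 = padding, one extra
   index for unseen characters); BLOSUM encoding maps each residue to its
   row of a bundled 25-letter substitution matrix (20 standard residues plus
   B, Z, X, U, O).
2. **GAN pre-training** — a 1-D convolutional GAN (generator: three stride-2
   transpose convolutions, ReLU/ReLU/tanh; discriminator: five stride-1
   convolutions with filters 4/8/16/32/64, kernel 3, tanh scalar head; no
   batch normalization) is trained on unlabeled corpora with a least-squares
   loss against ±1 targets. The discriminator's fifth convolutional layer
   then serves as a frozen per-position feature extractor.
3. **Prediction** — two convolutional branches (three ReLU convolutions with
   filters 128/256/384, kernel 8 for proteins and 4 for drugs, global
   max-pool) are fused with an *add* layer (elementwise sum; `concat`
   available for the ablation) and fed to a 1024/512/512 fully-connected
   head with dropout 0.25 and a linear output unit. Variants: **A** = GAN
   features for both branches, **B** = BLOSUM protein + GAN drug,
   **C** = GAN features over scaled BLOSUM channels + GAN drug.
4. **Evaluation** — concordance index, MSE, AUPR (after binarizing pKd at 7,
   boundary positive), and r_m²; warm-start k-fold splits, drug-disjoint
   logP cold-start splits, and train/test/both label-shuffle straw controls.
5. **Synthetic data** — desk-scale corpora and labeled datasets with a
   planted motif×pharmacophore interaction signal and a deterministic logP
   surrogate, so the whole pipeline is testable offline.

All networks are implemented in NumPy (`affinitygan._nn`) with explicit
backward passes and Adam, seeded end to end for bit-reproducible runs — no
deep-learning framework is required.

## CLI

```sh
# write a synthetic fixture bundle (FASTA / SMILES / TSV)
affinitygan synth --outdir data --seed 1 --n-pairs 2000

# pre-train a GAN on the drug corpus
affinitygan pretrain-gan --corpus data/drugs.smi --kind smiles \
    --seq-len 40 --epochs 8 --seed 1 --outdir gan_drug

# train variant B on fold 0 of a 5-fold warm-start split
affinitygan train --data data --variant B --drug-gan gan_drug \
    --config desk.json --seed 1 --outdir run_b

# straw control: shuffle training labels before fitting
affinitygan train --data data --variant B --drug-gan gan_drug \
    --config desk.json --straw-mode train --seed 1 --outdir run_b_straw

# cold-start split holding out the top 30% of drugs by logP
affinitygan split --data data --rule cold-logp --top-fraction 0.3 --outdir cold

# metrics from a predictions table (columns y, p)
affinitygan evaluate --predictions preds.tsv --outdir report
```

`--config` accepts a JSON/YAML file overriding `PredictorConfig` fields
(e.g. reduced widths for desk-scale runs). Every run directory receives the
resolved configuration, split provenance, a log file, and the evaluation
report, so runs are exactly reproducible from their artifacts.

## Layout

- `src/affinitygan/encoding.py` — vocabularies, label/BLOSUM encoders
- `src/affinitygan/gan.py` — GAN architectures, adversarial training, frozen feature extraction
- `src/affinitygan/predictor.py` — variants A/B/C, fusion, training, FC/kNN baselines
- `src/affinitygan/metrics.py` — CI, MSE, AUPR, r_m², report aggregation
- `src/affinitygan/splits.py` — k-fold, cold-start logP, straw shuffles
- `src/affinitygan/synthetic.py` — corpora, planted-signal datasets, logP surrogate
- `src/affinitygan/io.py`, `cli.py` — strict file readers/writers and the CLI
- `src/affinitygan/_nn.py` — NumPy layer kernel (conv1d, transpose conv, dense, Adam)
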