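# mraselect

Motor-imagery EEG trial classification from multiresolution wavelet variance
features, with evolutionary multiobjective wrapper feature selection and
sparse-coding baselines.

The pipeline mirrors a classical BCI stack:

1. **Features** (`mraselect.mra`) — each multichannel trial is cut into S
   contiguous segments; every (segment, electrode) signal gets an L-level
   dyadic DWT (orthonormal Daubechies filters, periodized, implemented in
   `mraselect.wavelets`), and each of the 2·L coefficient sets is reduced to
   its population variance, min–max normalized on training data. A trial
   becomes a (2, S, E, L) tensor of 2·S·E·L features.
2. **Classifiers** (`mraselect.classifiers`) — shrinkage LDA and linear SVC
   building blocks and three majority-voting ensembles: the full bank
   (`OPT0`, one LDA per coefficient type × segment × level reading E
   electrode features), a member-selectable bank (`OPT2`), and a per-segment
   bank (`OPT3`, one LDA per segment over that segment's 2·E·L features).
3. **Selection** (`mraselect.moo`) — NSGA-II over real genomes in [0,1]^n
   thresholded into binary masks (flat feature masks for `OPT1`, member masks
   for `OPT2`, per-segment feature masks for `OPT3`), minimizing
   C1 = 1 − training kappa and C2 = mean tenfold cross-validation error.
4. **Sparse baselines** (`mraselect.sparse`) — per-class K-SVD dictionaries
   over per-segment feature vectors, OMP sparse coding against the
   concatenated dictionary, signed-sum histogram pooling per trial, and an
   LDA or one-vs-all linear SVC head (`SR-LDA` / `SR-SVC`).
5. **Evaluation** (`mraselect.evaluation`) — kappa index
   (p0 − pc)/(1 − pc), stratified k-fold machinery, C1/C2 population
   correlation diagnostics, repeated-run experiment tables.
6. **Synthetic data** (`mraselect.synthetic`) — labeled trials of 1/f-like
   colored noise with band-limited oscillation bursts planted at configurable
   (class, electrode, segment-range, band) sites, plus the ground-truth
   feature mask implied by the dyadic level↔band mapping.

## CLI

```bash
mraselect simulate --config cfg.yaml --out data.h5 --seed 42
mraselect extract  --in data.h5 --out feats.h5 --wavelet db4 --levels 6
mraselect train    --method opt0 --features feats.h5 --model model.json
mraselect select   --method opt2 --features feats.h5 --pop 50 --gens 50 \
                   --seed 1 --out archive.json --history history.csv
mraselect evaluate --model model.json --test test_feats.h5
mraselect experiment --config exp.yaml --out report.csv --seed 1
```

`simulate` configs are YAML mappings of `SynthConfig` fields; unknown keys
exit with code 2. Trial containers are HDF5 (`/trials`, `/labels`, sampling
metadata attributes) with a companion `*.labels.csv`; models serialize to
JSON.

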