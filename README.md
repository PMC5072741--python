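# editscan

Prediction of A-to-I RNA editing sites from DNA sequence context with a
string-kernel SVM.

An adenine's fixed-length sequence context (41-mer by default) is compared
to known editing contexts through a weighted combination of the
Levenshtein distance (over the full window, length L1) and the Hamming
distance (over the centered inner window, length L2):

    D = w * DEdit / L1 + (1 - w) * DHamming / L2
    K(a, b) = exp(-gamma * D(a, b)^2)

The kernel feeds precomputed-kernel maximal-margin classifiers: a binary
SVM (editing vs background contexts) and a one-class SVM trained on
positives only, whose `nu` parameter bounds the training rejection
fraction. A two-stage scanner enumerates adenine-centered candidates (or
seed-matches known contexts with up to 3 mismatches), filters them with
the one-class model and calls putative sites with the binary model.

## Layout

| module                | contents                                                         |
|-----------------------|------------------------------------------------------------------|
| `editscan.contexts`   | context extraction, negative sampling, greedy redundancy filter  |
| `editscan.distances`  | edit/Hamming distances, combined distance, kernel matrices       |
| `editscan.model`      | binary / one-class training, prediction, JSON model persistence  |
| `editscan.evaluation` | Sn/Sp/Acc/PPV/MCC/G-mean, oversampled stratified CV, sweeps, ROC |
| `editscan.scan`       | candidate enumeration, mismatch seed search, two-stage caller    |
| `editscan.synthetic`  | synthetic genomes with plantable motif signal (benchmarks)       |
| `editscan.cli`        | `editscan` command-line entry point                              |

## CLI

All randomness is seeded; inputs/outputs are plain text (FASTA, TSV,
BED6, JSON models). A typical end-to-end run on synthetic data:

```sh
editscan simulate --out sim --length 200000 --n-sites 300 --seed 1
editscan extract  --genome sim/genome.fa --sites sim/positives.tsv --flank 20 --out pos.fa
editscan extract  --genome sim/genome.fa --sites sim/negatives.tsv --flank 20 --out neg.fa
editscan train           --pos pos.fa --neg neg.fa --w 0.5 --out binary.json
editscan train-oneclass  --pos pos.fa --nu 0.1 --out oneclass.json
editscan cv    --pos pos.fa --neg neg.fa --w 0.5 --nfolds 5 --out cv.tsv
editscan sweep --mode w --pos pos.fa --neg neg.fa --grid 0,0.2,0.5,0.8,1 --out sweep.tsv
editscan scan  --genome sim/genome.fa --oneclass-model oneclass.json \
               --binary-model binary.json --seeds pos.fa --max-mismatch 1 --out hits.tsv
```

Defaults encode the reference operating point: 41-mer contexts with an
inner 31-mer Hamming window, `gamma 0.1`, `w 0.2`, `nu 0.1`, 5-fold CV.
`editscan --version` prints them. Subcommands also accept a flat
`key = value` config file via `--config`; explicit flags win.

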