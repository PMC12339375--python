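# covani

Containment-ANI estimation and species-level metagenome profiling from
FracMinHash k-mer sketches.

`covani` sketches reference genomes and read sets by keeping the ~1/c of
canonical k-mers whose 64-bit hash falls below M/c. The multiplicities of a
genome's sketch k-mers inside a read sketch are modelled as zero-inflated
Poisson draws: zero inflation comes from sequence divergence, the Poisson
rate λ ("effective coverage") from read sampling. Estimating λ from the
multiplicity histogram lets the containment index be corrected for unseen
k-mers, which removes the systematic downward bias of naive containment ANI
at low coverage. On top of the estimator sits a profiler that reassigns
k-mers shared between reference genomes to the best-matching genome
(winner-take-all), re-estimates, and reports abundances for genomes above a
95% ANI detection threshold.

Highlights:

- genome sketches mask multicopy k-mers and k-mers closer than 30 bp so the
  independence assumptions of the model hold;
- read sketches correct paired-end overlap double-counting and remove PCR
  duplicates with a locality-sensitive fingerprint scheme that tolerates one
  substitution per duplicate;
- λ is estimated by a robust ratio-of-multiplicity estimator with
  percentile-bootstrap confidence intervals;
- effective coverage converts to true coverage via the read-length edge
  factor and an error-survival term E[(1−ε)^k], auto-estimated from the
  sample when no error rate is given;
- a synthetic-data module (`covani.sim`) generates genomes, mutated
  relatives, and read sets with exactly the statistical structure the model
  assumes, so everything is testable offline.

## CLI

```sh
# sketch references (one sketch per FASTA; --multi for one per record)
covani sketch -g genomeA.fasta -g genomeB.fasta -o db/

# sketch reads (single-end -r, or paired -1/-2); gzip is transparent
covani sketch -r reads.fastq.gz -o sample/

# per-genome containment ANI (no reassignment)
covani query sample/reads.ssk db/*.gsk -o query.tsv

# species-level profile with abundances
covani profile sample/reads.ssk db/*.gsk --error-rate 0.005 -o profile.tsv
```

`sketch` accepts `-k` (default 31), `-c` (default 200), `--seed` and
`--spacing`; sketches only compare when k, c and the seed match. `query` and
`profile` accept `--min-kmers`, `--read-len`, `--error-rate`, `--seed` and
`-o`; `profile` additionally `--min-ani` (default 0.95),
`--candidate-floor`, and `--estimate-unknown` to scale abundances by the
detected fraction of reads. A JSON run manifest is written next to each
output file. Sketch files use a small versioned binary format; pass
`--json` to `sketch` (or use a `.json` suffix) for a plain-text dialect.

## Layout

- `src/covani/sketch.py` — hashing, FracMinHash selection, genome/read
  sketching, paired-end and PCR-duplicate handling
- `src/covani/inference.py` — multiplicity histogram, naive/adjusted ANI,
  λ estimation, bootstrap, effective/true coverage, error term
- `src/covani/profiler.py` — query, winner-take-all reassignment, profile,
  abundances, percent reads detected
- `src/covani/sim.py` — synthetic genomes, mutation, read sampling, brute
  containment oracle
- `src/covani/io.py`, `src/covani/cli.py` — file formats and the CLI
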