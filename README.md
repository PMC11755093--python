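# poretrellis

A constrained convolutional DNA/RNA data-storage codec with CTC-matrix soft
decoders, built to study single-read decoding of nanopore basecaller output
at desk scale.

The package contains:

- **`hedges_code`** — hash-driven convolutional encoder. Each base is picked
  by hashing (salt, history bits, base index) into a ranking of the alphabet,
  hard-masking homopolymers (max 3 by default), soft-balancing GC over
  12-base windows, and letting the encoded bit index the ordered survivors
  (so bit 0 / bit 1 always emit different bases). Strands carry a T7
  promoter, synthesis buffer, 50 bp signal buffers, index + CRC-8 header and
  a poly-A tail.
- **`hard_tree_decoder`** — baseline hard decoder: best-first search over a
  tree of bit guesses with substitution/insertion/deletion hypotheses
  against basecalled reads, bounded by a guess budget; CRC-validated
  demultiplexing with reverse-complement retry.
- **`ctc_sim`** — synthetic nanopore CTC matrices (dwell-time variation,
  blank-dominated separators, label miscalls, skips, stutters), shared CTC
  math (`collapse`, `forward_probability`), NPY/HDF5 I/O, and buffer-region
  trimming + orientation detection.
- **`am_decoder`** — the alignment-matrix trellis soft decoder: 2^H states,
  one row of CTC forward variables per state, extended per emitted base by a
  dynamic-programming recurrence and scored by log-sum-exp; O(2^H·L·T) time,
  O(2^H·T) live memory (numba-accelerated inner loops).
- **`beam_decoder`** — beam-trellis soft decoder baseline: 2^H·(L+1) slots
  updated per CTC time step, blank/non-blank score halves, duplicate-message
  merging.
- **`outer_density`** — Reed–Solomon outer-code model: binomial-tail
  codeword failure probability, capacity/MTTF-constrained design choice, and
  density φ (bits/base) projections over strand length.
- **`pipeline_eval`** — end-to-end experiment runner (encode → simulate →
  filter → demultiplex → decode → compare) with reproducible TSV/JSON
  reports.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (forward-oracle
equality against exhaustive path enumeration, recurrence correctness,
zero-noise round trips for all four code rates, cross-decoder consistency,
soft-vs-hard comparison at ~7% base error, positional error cascades,
complexity/memory contracts, outer-code model checks, demultiplexing).
The full suite takes roughly 10 minutes on one CPU.

## CLI

```bash
# encode a payload into FASTA strands (16 bytes per strand)
poretrellis encode --rate 1/6 --hex deadbeef... --salt 7 --out strands.fasta

# simulate basecaller CTC matrices for those strands
poretrellis simulate --strands strands.fasta --seed 1 --out ctc.h5

# trim buffer regions / orient
poretrellis trim --in ctc.h5 --out trimmed.h5

# soft decode (alignment matrix or beam trellis)
poretrellis decode-soft --algo am --ctc trimmed.h5 --rate 1/6 --salt 7 \
    --payload-bytes 16 --out results.tsv

# hard decode basecalled reads
poretrellis decode-hard --reads reads.fasta --rate 1/6 --salt 7 \
    --payload-bytes 16 --guess-limit 1000000 --out results.tsv

# outer-code design + density sweep from a positional error profile
poretrellis density --profile profile.tsv --rate 1/6 \
    --sweep-bytes 20:240:20 --out density.tsv

# full experiment bundle
poretrellis run --config experiment.json --out results/
```

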