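# spliceindex

Detection of differential cassette-exon splicing from exon-junction
microarray probe intensities, built as a reusable, fully tested pipeline that
can be exercised end-to-end on synthetic data with known truth.

## The problem

Exon-junction microarrays interrogate each cassette-exon splicing event with
a small panel of probe sets: one on the cassette exon itself, one on each of
the two inclusion (exon–exon) junctions, and one on the skipping junction
that is formed only when the exon is excluded. Changes in a gene's overall
expression move all of these together; changes in splicing move the
inclusion-reporting and skipping-reporting probe sets in *opposite*
directions. The pipeline separates the two signals with a **splicing index**

```
I_norm = (background-corrected probe-set signal) / (background-corrected gene expression signal)
```

where the gene-expression signal is the median over the gene's exon-type
probe sets. Per probe set, `I_norm` is compared between genotypes with a
pooled two-tailed Student t-test, and events are called in tiers by
probe-set voting:

- **tier 1** — at least two probe sets with P < 0.05 whose implied inclusion
  directions agree (a skipping-junction trend counts with inverted sign;
  opposing significant trends void the event);
- **tier 2 candidate** — exactly one significant probe set, rescued only if
  the event is annotated as conserved and neuron-specifically spliced.

Downstream modules cover the rest of such a study's computational core:
RT-PCR-style inclusion rates `ψ = inc/(inc+skip)` with the inclusive 1.5-fold
differential criterion; polypyrimidine-tract scanning and GC-motif analysis
in the 50-nt intron windows upstream of 3′ splice sites (ZOOPS EM motif
discovery plus Fisher-exact k-mer enrichment, motif offset from the tract 3′
end, and a mutation-effect rule table for the functional (U)GC element);
gene-level differential expression (1.5-fold, Benjamini–Hochberg FDR ≤ 0.15)
with a χ² gene-set overrepresentation test; and exact mapping of a single
genomic deletion from a WT/mutant sequence pair.

## Worked example

```sh
spliceindex run --out-dir results/demo --seed 1
```

simulates the benchmark experiment — 50 genes, one cassette event each, 10
events truly differential (ψ 0.8 → 0.5), 4 + 4 replicates, log2 noise SD
0.15 — runs preprocessing (RMA-style background correction, quantile
normalization, log2 median polish), the `I_norm` caller, noise-free RT-PCR
ψ calls and differential expression, and prints:

```
INFO spliceindex: tier-1 recall 1.000 precision 0.909
```

meaning all 10 planted differential events were recovered at tier 1 and one
of the 11 tier-1 calls was a false positive. `results/demo/event_calls.tsv`
lists per event the tier, inclusion direction, and the voting probe sets;
`psi_calls.tsv` the per-genotype inclusion rates and 1.5-fold calls;
`expression_results.tsv` the per-gene fold change, P, and q. The same
workflow is available programmatically via `spliceindex.run_pipeline`, and
every stage is importable on its own (`spliceindex.preprocess`,
`splicecall`, `psi`, `motifs`, `expression`, `delmap`, `simdata`).

A deletion-mapping call looks like:

```sh
spliceindex delmap --fasta pair.fa --out call.json
# INFO spliceindex: deletion of 2710 bp at [6000, 8710)
```

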