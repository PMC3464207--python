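# Methods

## Signal model and preprocessing

Probe intensities are modelled as `observed = signal + background`, with the
true signal exponential and the optical background normal — the convolution
assumption behind robust multichip average (RMA) background correction. The
corrected value is the posterior mean `E[signal | observed]`, which has the
closed form `a + σ·φ(a/σ)/Φ(a/σ)` with `a = o − μ − σ²α`; it is strictly
positive and monotone in the observation, and for observations far above the
background it reduces to subtracting the background mean. Parameters are
estimated per array by the usual mode/half-width heuristic: μ is the mode of
a kernel density estimate of the column, σ the RMS spread of values below
the mode, and 1/α the mean excess above it. A constant column has no
estimable background and falls back to min-subtraction with a small floor.

The stage order is fixed: background correction → quantile normalization →
log2 → median polish. Quantile normalization maps each column onto the
across-column mean of the sorted columns; ties within a column receive the
mean of the reference values at the rank positions they occupy, so tied
inputs stay tied and the procedure is idempotent. Median polish fits
`overall + probe + sample` by iterated median sweeps (tolerance 1e-6, at
most 10 iterations); the probe-set signal is `overall + sample effect`,
exponentiated back to the linear scale. Because simulated probe affinities
are fixed across samples, they are absorbed by the probe effect, which is
what makes the summarization approximately affinity-free.

Gene expression is the median over the gene's exon-type (non-junction)
probe-set signals. The median rather than the mean keeps a differential
cassette exon from dragging the gene-level estimate, since constitutive
probe sets dominate the panel.

## Splicing index and tiered calling

`I_norm = probe-set signal / gene signal` on the linear scale. Per probe set
a pooled-variance two-sample Student t (df = n₁+n₂−2) compares `I_norm`
between genotypes; zero pooled variance with equal means yields (t=0, P=1),
with unequal means an infinite t and the smallest positive float as P.
α = 0.05 per probe set is a screening threshold, deliberately without
multiplicity correction — the design screens then validates, and the null
false-call rate is controlled empirically (see below). Probe sets flagged
constitutive, multi-gene, or alternative-promoter are excluded from
candidacy (constitutive sets still anchor the gene signal). Votes imply an
inclusion direction (skipping-junction trends inverted); direction
consistency is judged on voting probe sets only — a non-significant probe
set does not veto an otherwise concordant event. This is a deliberate
reading of the opposite-trend requirement: the alternative (requiring all
probe sets, significant or not, to trend consistently) is stricter than what
the screening design implies, and is noted here as an open choice.

Conservation and neuron-specific splicing status are input annotation
flags; deriving them from genome browser tracks or EST libraries is out of
scope.

## Synthetic data

The simulator emulates the study conditions rather than array physics. Per
cassette event there are exactly 4 probe sets (exon, two inclusion
junctions, skipping junction) and per gene 4 constitutive exon probe sets of
4 probes each. Expected probe intensity is
`affinity × expression × f(ψ)` with `f = ψ` for inclusion reporters,
`1 − ψ` for the skipping junction, 1 for constitutive sets; observed
intensity is `mean × 2^N(0, noise_sd_log2) + Exponential(background_mean)`.
Defaults: log2 noise SD 0.15, background mean 20, affinity SD 0.25 (log2),
expression `2^N(9, 1)` — conventional magnitudes for a two-channel-free
oligo array at moderate signal-to-background; the array platform's actual
noise characteristics are not published, so these are stated choices, not
fits. The benchmark configuration is 50 genes each carrying one cassette
event, of which 10 are differential (ψ 0.8 → 0.5) and 40 null (ψ 0.65 both
genotypes), 4 + 4 replicates. Including null events makes tier-1 precision a
meaningful quantity; with only differential events it would be vacuous.

What the simulator does *not* model: probe cross-hybridization, spatial
artifacts, partial-isoform complexity (multiple events per gene,
mutually exclusive exons), or correlated biological replicate structure.
Passing recovery tests therefore demonstrates correctness of the statistical
machinery under the stated noise model, not performance on real arrays.

Sequence windows emulate the last 50 nt of an intron: they end in AG, carry
a pyrimidine tract (length 15–25) directly upstream, and in foreground
windows the GC motif is planted *inside* the tract near its 3′ end (default
offset −6, i.e. the motif's G is the tract's only purine and three
pyrimidines follow). Placement inside the tract mirrors the element's
position in real 3′ splice sites and guarantees the tract scanner's maximal
segment absorbs the single purine, so the planted offset is recoverable
exactly. RT-PCR band tables have `inclusion ∝ ψ`, `skipping ∝ 1 − ψ` with
multiplicative normal noise of a given CV, truncated at zero.

All generators draw from one `numpy` generator stream per seed; identical
configuration and seed give bit-identical outputs.

## Motif analysis

The polypyrimidine tract is the maximal-scoring contiguous segment under
+1 per pyrimidine and −1.5 per purine, minimum length 8, leftmost-longest on
ties, implemented as a Kadane-style scan with a minimum-length constraint
(the scoring weights are configurable; they are a design choice tuned so a
single purine interrupts only weakly, not a published constant). Motif
discovery is ZOOPS EM: each sequence contains zero or one motif occurrence
(prior γ, uniform over positions), 0th-order background estimated from the
input with light smoothing, background-proportional pseudocounts (β = 0.1)
in the M-step so that columns with no site evidence relax to the background
rather than to uniform, convergence at log-likelihood change < 1e-6, best of
20 seeded restarts. Twenty restarts is deliberate head-room: with a short
motif the EM surface has shifted local optima (e.g. a planted UGC recovered
as CUG) that a smaller restart budget occasionally fails to escape.
Enrichment of individual k-mers is a two-sided Fisher exact test on
window-level presence/absence, the model-free complement to EM discovery.
The substitution-effect classifier is a literal rule table for the
functional (U)GC element — G→A and C→U disrupt, substitutions of the
preceding U are neutral, everything else is unknown — and makes no claim
beyond those tested mutations.

## Deletion mapping

A single deletion is located from the longest common prefix and suffix of
the WT and mutant sequences; valid placements form a contiguous interval
when flanking repeats allow sliding, and the leftmost placement is reported
(VCF left-alignment convention) together with the count of equivalent
placements. `N` matches nothing — conservative for breakpoint placement.
Reconstruction is verified exactly; failure raises with the first mismatch
position, signalling more than one variant.

## Expression

Gene-level testing reuses the pooled t on log2 gene signals (the expression
test is otherwise unconstrained, and using one test keeps the pipeline's
inferential machinery uniform). Benjamini–Hochberg step-up q-values are
computed by definition (`q_(i) = min_{j≥i} p_(j)·n/j`, capped at 1); the
1.5-fold and FDR ≤ 0.15 cutoffs are inclusive. Overrepresentation is a
Pearson χ² without continuity correction on the 2×2 membership table; when
any expected cell drops below 1 a warning reports the Fisher exact P
alongside.

## Numerical and testing notes

- Problem sizes: the benchmark simulation uses 50 genes / 50 events / 8
  arrays (~1,600 probes); null control runs 5 seeds of the same size; motif
  recovery uses 30 sequences of 50 nt per run. These sizes give stable
  recovery statistics while keeping the full suite around a minute.
- Every stochastic test fixes its seed; oracle tests compare against
  independent implementations (pure-python median-polish sweeps, quadrature
  of the background conditional expectation, exhaustive segment scoring,
  hypergeometric enumeration, the 35-split exact permutation test,
  brute-force step-up FDR, brute-force deletion placement, statsmodels for
  BH cross-checking).
- The exact-boundary fold comparison (`ratio ≥ 1.5`) uses a relative epsilon
  of 1e-12 so that rates like 0.6/0.4 computed in floating point remain on
  the inclusive side.
- Known limitations: only cassette events with the fixed 4-probe-set design
  are simulated and called; the caller has no effect-size threshold (a vote
  is significance-only, per the screening design); the ZOOPS model has no
  E-value machinery, so discovered motifs should be judged by the companion
  Fisher enrichment; deletion mapping handles exactly one deletion and no
  other variant classes.
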