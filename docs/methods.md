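# Methods

This note documents the models and numerical choices behind `fretscreen`: what
the simulator does and does not emulate, how the read pipeline is specified,
and where design decisions were genuinely open.

## Screen model

### Transduction and purity sorting

Lentiviral integration counts per cell are Poisson with rate `moi_lambda`
(default **0.1**).  By default the population is conditioned on ≥1 integration
(the transduction purity sort), under which the single-integrant fraction is
λe^(−λ)/(1−e^(−λ)) ≈ 0.951 at λ = 0.1.  Multi-integrant cells are tracked
individually because they matter for the read-out: a cell carrying a cognate
minigene plus a passenger contributes *both* inserts to the Shifted gate when
it shifts, which is the dominant source of correlated background at MOI > 0.

Reporter purity sorting is modelled as conditioning each cell on carrying at
least one *productive* minigene (open reading frame without stop codons).  The
default is perfect purity; `purity_sorted=False` reproduces an unsorted
population, and the pipeline's stop-codon filter handles whatever reaches
sequencing either way.  Random degenerate inserts are generated *with* their
in-frame-stop clones (probability 1 − (61/64)^16 ≈ 0.557 for 48-nt inserts)
rather than rejected, since the physical library contains them.

### Spiking

Cognate clones can be spiked at the **cell level** (a binomial draw of cells
replaced by pure single-integrant spike cells, mirroring mixing of separately
prepared cell populations) or at the **DNA level** (the spike is added to the
abundance vector before transduction).  At matched abundance the two are
statistically indistinguishable downstream, and a test asserts both call the
spike identically.

### Co-culture gating

FRET kinetics are deliberately not modelled.  The entire co-culture collapses
to one Bernoulli gate probability per cell:

- cognate-carrying cell → Shifted with `min(1, p_hit·f_reactive·et_ratio + p_fp)`
- any other cell → Shifted with `p_fp`

`p_hit` (default **0.6**) is the hit probability at reactive-effector fraction
1 and E:T = 1:1 over a 4-h co-culture — the safe-sorting window in which the
FRET shift has developed but apoptotic cell loss has not.  Effector dilution
is linear in `f_reactive` and `et_ratio`, capped at 1; no saturation model is
claimed.  `p_fp` (default **1e-4**) lumps bystander granzyme uptake and gate
spillover; it applies to every cell, so with no reactive effectors the whole
population shifts at exactly `p_fp`.  Dead-cell loss, doublets and sorter
purity masks are not modelled; `gate_capacity` emulates finite sort yield by
subsampling each gate without replacement.

### Sequencing

Each gate's templates are its per-clone carrier counts.  Every template
receives an independent log-normal PCR amplification factor (σ = **0.5**) and
`reads_per_gate` (default **5×10⁵**) read pairs are drawn multinomially.  The
amplicon is `flank5 + insert + flank3` with fixed 100-nt constant transgene
flanks, so a 48-nt insert yields a 248-nt amplicon read with 2×250 chemistry —
reads run 2 nt past the amplicon into fixed adapter context, giving the
"outie" pair geometry.  Substitution errors are i.i.d. per base at **0.002**
(drawn as the exactly equivalent binomial-total + uniform-positions process);
indels, index hopping and optical duplicates are out of scope.  Base qualities
are an 8-bit-discretized normal (mean **Q32**, sd 3, clipped to [2, 41]),
independent of the error process — so quality filtering exercises the stated
rule but cannot rescue miscalled bases, a known simplification.  Identical
configuration and seed give byte-identical FASTQ.

## Read pipeline

All stages are deterministic and emit reconciling drop ledgers.

- **Merging.** Candidate overlaps are end-anchored: innie (tail of R1 against
  head of reverse-complemented R2; merged length L1+L2−o) and outie (the
  converse; only the overlap is kept, the 3′ overhangs being adapter).  Among
  candidates with overlap in [`min_overlap`=10, `max_overlap`=304] the minimum
  mismatch-ratio candidate wins; ties prefer the larger overlap, then innie
  (the published mergers do not document their tie order; this one is pinned
  here and mirrored by the test oracle).  Pairs whose best ratio exceeds
  **0.25** fail.  Consensus takes the higher-quality base (R1 on ties);
  consensus quality is max(q) on agreement and max(2, |q1−q2|) on
  disagreement.  The compiled kernel prunes candidates with integer-exact
  bounds and is output-equivalent to the exhaustive scan (tested against an
  independent brute-force oracle).
- **Quality filter.** Keep a contig iff the fraction of bases with quality
  strictly above Q20 is ≥ 0.9.  Phred+33 only.
- **Trimming.** Positional Hamming match of each flank with ≤3 mismatches; no
  indel tolerance, because the simulator emits substitutions only and
  indel-bearing real reads are rare enough to drop.
- **Clustering.** Greedy centroid rule: sequences by descending count (ties
  lexicographic); each joins the earliest-founded cluster within Levenshtein
  distance `max_dist`, else founds one.  `max_dist` defaults to **3**,
  approximating the common clustering tools' default distance for ~48-nt
  inputs (≈ min(8, 2 + L/30)).  Candidate generation uses an exact
  (d+1)-segment pigeonhole index for same-length sequences and exhaustive
  comparison across length classes within d, so the result provably equals
  the naive all-pairs rule; distances come from edlib.
- **Translation filter.** Frame 0 only (inserts are cloned in frame with the
  reporter); non-multiple-of-3 canonicals are length artifacts, stop-bearing
  clusters are residual non-productive inserts.  Both are tallied.
- **Blacklist.** Exact-canonical removal of known PCR / in-silico artifacts;
  absent entries warn.

## Enrichment statistic

Δ relative abundance is the Shifted-gate frequency minus the Unshifted-gate
frequency; it sums to zero and is invariant to per-gate sequencing depth.
Hits are Δ strictly above mean + k·σ with k = **10**.  σ is the *population*
(ddof = 0) standard deviation over **all** minigenes' Δ values, hits included,
matching a single global cutoff line; an `exclude-top-j` background is
available but off by default, and it raises a degenerate-background error
rather than dividing by zero.  One structural consequence worth knowing: with
the hit included in σ, an n-clone screen cannot produce z much above √n, so
small demonstration screens need several hundred clones before the 10σ rule is
meaningful.  Ranking ties break by higher Shifted count, then lexicographic
id, so output ordering is reproducible.

Minigenes seen only in the Unshifted gate get negative Δ and are retained —
they are most of the background.  Minigenes seen in neither gate cannot occur
by construction.

## qPCR quantification

Standard curves are least-squares fits of Ct on log10(copies); efficiency is
10^(−1/slope) − 1.  The fitter accepts arbitrary (copies, Ct) pairs because
the exact placement of points within a 1e5→1e2 series is a lab choice, not a
model constant.  Copy estimates invert the line; replicate CV is sd/mean over
per-replicate copies.  The integration-corrected cell ratio divides each
population's copies by its average integrations per cell before forming the
fraction; the one-tailed t test and Cohen's d helper are the standard
formulas.

## Scales used for verification

The headline statistics recomputed by `scripts/acceptance.py` use a 1:1
binary mixture of 10⁵ + 10⁵ cells (specificity) and 20 replicate screens of a
10⁴-clone library over 3×10⁶ cells with a 1:10,000 cell-level spike at 5×10⁵
reads per gate (detection limit, with reactive-effector fractions 1 and
1/30).  The test suite additionally runs scaled-down screens (≈700 clones,
2–6×10⁴ cells) for end-to-end and CLI checks; those sizes were chosen as the
smallest at which the 10σ rule and the spike ranking behave as at full scale.

## Known limitations

- A single per-cell gate probability stands in for the full kinetics of
  granzyme delivery, reporter cleavage and apoptosis; time-course behaviour
  (signal peaking at 6–8 h, cell death 2–4 h later) is represented only by
  the 4-h default being inside the safe window.
- Sequencing error is substitution-only with error-independent qualities.
- Flank matching assumes fixed amplicon architecture; structural variants or
  chimeric amplicons are dropped, not diagnosed.
- MHC-binding prediction and protein-database annotation of hits are external
  steps; the package only exports hit peptides in FASTA for them.
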