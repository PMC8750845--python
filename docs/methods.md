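# Methods

This note documents the models, conventions and design choices behind
`parafuse`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Informative-site catalog

The two paralog genomic sequences are aligned once with an affine-gap
Smith–Waterman local alignment over their full lengths. A single local
alignment (rather than stitched alignments of conserved sub-regions)
keeps one coherent column frame for everything downstream; for a
genuinely paralogous pair it covers ≥95% of both sequences, and coverage
below 50% of either sequence is rejected as non-homologous.

Default scoring: match +2, mismatch −3, gap open −5, gap extend −2,
with a length-L gap costing `open + (L−1)·extend`. These are
conventional DNA scores; they are configuration-exposed because the
discriminating-site counts on a real pair depend (mildly) on them.

Column classification:

* both bases present and equal → **ambiguous**;
* both present and different → **discriminating** (one unit);
* single-sided gap → **discriminating**, with consecutive gap columns
  of one indel collapsed into a single unit. An indel is one divergence
  event regardless of its length, and per-column counting would inflate
  the catalog by indel length. Under this rule the per-gene unit counts
  (units carrying a base in gene A vs gene B) differ exactly by the
  indel asymmetry between the paralogs. The counting rule is recorded
  in the `sites` output metadata.
* columns overlapping an N in either reference → **masked** outright;
  an N carries no paralog information, so such columns are excluded
  from every statistic.

Known polymorphic positions (a dbSNP subset, supplied as a two-column
TSV or a VCF on the gene's own coordinates) mask ambiguous sites only:
a polymorphism at a discriminating site cannot be honoured without
redefining the paralogs, so it triggers a warning instead. The dbSNP
build is a free-text config field echoed into the output.

Coordinates are 0-based half-open internally and 1-based in every
user-facing report.

An insertion-type unit (bases present only in gene B) has no gene-A
coordinate; for profiling and plotting on the gene-A axis it is anchored
at the last aligned gene-A position to its left.

## Alignment engines

Two engines share one result type:

* **exact** — self-authored affine-gap Smith–Waterman (numba kernel)
  with fully specified determinism: traceback ties prefer
  diagonal > up > left, gap-open over gap-extend, and the traceback
  starts at the first maximal cell in row-major order. Used for the
  paralog-pair alignment and as the reference in validation; the test
  suite checks it against an independently written quadratic DP oracle
  (scores and tracebacks) and against Biopython's `PairwiseAligner`
  (scores).
* **fast** — edlib infix alignment (whole read inside the target), with
  the path re-scored under the Smith–Waterman scheme and trimmed to its
  best-scoring contiguous segment to emulate local end-clipping. The
  score is a lower bound on the exact score; on reads within ~15%
  divergence the two agree closely (asserted in tests). This engine
  handles the thousands of multi-kilobase read alignments at ~2 ms
  each, where the exact kernel takes ~1 s. Orientation is chosen by
  the lower combined infix edit distance against the two paralogs
  (ties prefer forward); the exact engine uses combined scores.

## Per-read genotyping

Each read is aligned to both paralogs in its chosen orientation. A
substitution-type discriminating site is read off **both** alignments
and reconciled: a definite call (matches A / matches B) from either
alignment wins; contradictory definite calls are classified
matches-neither. Rationale: near clustered divergence the
divergent-paralog alignment has cost-equal paths and can place the
wrong read base on a site; requiring consistency turns such
misalignments into excluded errors instead of wrong-direction calls
(observed at ~2–3% of sites with a single-alignment rule). Indel-type
units are read off their host paralog only (the gene that has the
bases); a read carrying the bases matches that gene, a clean gap across
the run matches the other, anything else is neither.

Matches-neither observations are excluded from site coverage — at
nanopore error rates a base matching neither paralog is most plausibly
a sequencing or PCR error, not evidence.

Ambiguous sites are read off the gene-A alignment; gaps there are
treated as not informative rather than as mismatches.

## QC

Reads pass a length window (default 3000–5000 bp inclusive, matching a
~3.9 kb amplicon; scalable in config for shorter test constructs), then
an on-target test: best local-alignment score against either paralog in
either orientation must reach `min_score_frac` (default 0.4) of the
maximum achievable `match × read length`. Random DNA scores far below
0.4 while genuine amplicon reads score ~0.7+ even at 10% combined error.
This internal filter replaces external read correction and whole-genome
mapping; externally corrected reads are accepted through a pass-through
hook and flagged `corrected=true` in reports.

## Profile, background, foreground

Relative to reference A (the default, so a chimera with a gene-A 5′ end
shows a rising step), per site: `n_i` informative observations, `m_i`
of them B-matching (discriminating) or differing from the shared base
(ambiguous), `r_i = m_i/n_i`. Sites with fewer than `min_site_coverage`
(default 5) informative observations are excluded from statistics and
fitting — rates from 1–2 reads are unstable.

* background `b`: 99th percentile of ambiguous rates, linear
  interpolation between order statistics (the common default in
  statistical environments; the convention is echoed in output).
* foreground `f`: arithmetic mean of discriminating rates strictly
  above `b`; absent when no site exceeds `b`, which itself is
  no-fusion evidence.

## Sigmoid fit and fusion decision

The discriminating rates are fitted by least squares with a
four-parameter logistic
`y(x) = c + (d − c)/(1 + exp(s (x − e)))`, `s > 0`, so `d` and `c` are
the left and right asymptote levels and `e` the inflection
(crossover estimate). Initialisation: asymptotes from the outer-third
means, `e` from the midline crossing, slope from the median site
spacing; bounds keep levels in [−0.5, 1.5] and `e` within one span of
the data. Optimiser failure is reported as `converged=false`, never an
exception. At least 4 covered sites are required (4 free parameters).

The fused/no-fusion thresholds are this package's own quantitative
rendering of a judgement that was originally made visually, and all are
config-exposed:

* `min_separation = 0.30`: required `f − b`;
* `min_amplitude = 0.30`: required `|d − c|`, with `e` inside the site
  span;
* `min_plateau_sites = 3`: discriminating sites on the expected side of
  the midline `(b + f)/2`, on each side of `e`.

The defaults call clean steps fused and flat profiles (pure paralog —
rates ≈ 0 or ≈ 1 everywhere — or uniform intermediate noise) no-fusion.
The crossover interval runs from the rightmost reference-side site left
of `e` to the leftmost other-paralog-side site right of it, and is
labelled by the gene-model features it overlaps ("E2-I2" style; a
single-feature interval yields the single label by default).

## Subsampling

`subsample_stability` re-runs profiling → fit → call on random read
subsets (without replacement) and reports concordance (same status and
label) with the full-depth call. Per-read site calls are reused across
subsamples because a read's alignment does not depend on which other
reads were drawn. The recommended minimum depth surfaced as a CLI
warning is 200 reads, the depth at which calls are stable in the
depth-robustness analysis.

## Simulator

`make_toy_gene_pair` draws gene A uniformly at random and derives gene
B with i.i.d. substitutions (default divergence 0.06, mirroring the
~94% identity of the flagship paralog pair) and rare 1–3 bp indels
(default 0.002/base). `make_chimera` joins `A[0..c)` to `B[c'..]` at
the aligned position, snapping into the nearest both-aligned column if
`c` falls in an indel. `simulate_reads` emits full-template reads
(single-amplicon long-range PCR model) with i.i.d. per-base
substitution/insertion/deletion errors, default 5%/2%/3%, half the
reads reverse-complemented, optionally a fraction replaced by random
off-target sequence. Everything is deterministic under a fixed seed,
including FASTQ bytes.

What the simulator does **not** model: homopolymer-dependent or
quality-correlated errors, chimeric PCR artefacts, read-length
variation beyond indel drift, barcode/adapter sequence, or real dbSNP
polymorphism patterns. Passing tests therefore demonstrate the
statistical machinery under calibrated i.i.d. noise, not performance on
every real-data pathology; the error-exclusion rule and the
ambiguous-site background are, however, exactly the mechanisms designed
to absorb such noise.

## Problem sizes used in tests and the acceptance script

Unit tests use 600–2000 bp pairs and tens of reads; the end-to-end
checks use the full study conditions — 4 kb pairs, 200-read samples
over 20 seeds for recovery and specificity, and one 3000-read sample
subsampled at depths 100–3000 with 10 replicates. These sizes give
binomially tight rates while keeping the whole suite in minutes on one
CPU.

## Known limitations

* The fast engine's per-site observations inherit edlib's path
  tie-breaking; the both-alignment reconciliation removes directional
  bias but a small fraction of observations near clustered divergence
  is discarded as conflicts.
* One sample per invocation; multiplexed cohorts are shell loops.
* No SNV/indel variant calling at the loci; the profile sees
  polymorphisms only as elevated ambiguous-site rates (maskable via the
  dbSNP input).
* Fusion calls assume a single crossover (one step); double-crossover
  (conversion-tract) products would show a non-monotone profile and are
  reported as no-fusion with the fit diagnostics exposed.
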