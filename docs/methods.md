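# Methods

## Candidate regions

Candidate regulatory elements are anchored at peaks of chromatin
accessibility (ATAC, scATAC or DNase) unioned with CTCF ChIP-seq peaks.
"Union" is exact-coordinate deduplication, not interval merging:
overlapping peaks of different extents remain distinct candidates. Each
candidate is quantified independently, so merging would silently change
the number of rows in every downstream matrix; peak callers also emit
peaks of naturally variable size, and preserving them keeps the output
traceable to its inputs. Regions sharing at least 1 bp with a blacklist
interval are dropped whole (no trimming). The canonical region order is
(chrom, start, end); a separate permutation, regions ranked by the
difference of summed H3K4me3 and H3K4me1 bigWig coverage (descending,
coordinate ties ascending), orders meta-plot rows only and never affects
classification. An `anchor_mode=accessibility_only` switch restricts
candidates to accessibility peaks for datasets where every element must
intersect open chromatin.

All internal coordinates are BED-convention 0-based half-open; GFF/GTF
1-based inclusive inputs are converted on read. Two non-empty inputs
whose chromosome names share no member *and* use different naming styles
(UCSC `chr1` vs Ensembl `1`) abort with a hard error, because the
alternative is silently zero signal everywhere; inputs confined to
different chromosomes of the same style are legitimate. Coverage lookups
on chromosomes absent from a bigWig return 0 with one warning per
chromosome.

## Signal quantification

For region r and track t, `A[r,t] = 1e6 · auc(r ∩ b_t) / auc(genome)_t`,
with `auc` the summed per-base read coverage over the given bases. The
area definition (rather than a raw read count) keeps numerator and
denominator in the same units and is invariant to read fragmentation; a
read-count variant is available behind `auc_mode=read_count` since
"depth" is sometimes normalised that way. Reads contribute their
CIGAR-consumed reference bases (soft-clips excluded); duplicate,
QC-fail, unmapped, secondary and supplementary reads are excluded by
default. When a region intersects several disjoint fragments of a
track's peak set the fragments are summed; overlapping peaks are unioned
first so no base counts twice. Each aligned read counts independently
(paired-end mates are not collapsed into fragments). No pseudocounts are
added anywhere: `A[r,t] = 0` exactly when the region shares no covered
base with the track's peaks, and the rule clauses test that zero with
exact equality. A track whose peaks overlap no candidate region yields a
structurally zero column without consulting its sequencing depth; a
track with peak overlap but an empty BAM is an error (zero denominator).

Per-region quantification may be chunked across worker processes
(`n_workers`); per-region sums are computed identically regardless of
chunking, so results are independent of worker count and scheduling
(asserted by a byte-identity test of 1- vs 4-worker runs).

## Rank transform and rules

Each row of A is ranked descending (rank 1 = strongest). Strict ranks
need no tie rule, but ties occur — most visibly all-zero rows — so a
fixed track priority breaks them deterministically: H3K4me3 > H3K4me1 >
CTCF > H3K27ac (promoter-mark first; isolated in one constant,
configurable as `tie_break_priority`). An all-zero row is forced to Not
assigned before clause evaluation, since its ranks are pure tie-break
artifacts and the "only this track nonzero" clauses would otherwise fire
vacuously.

Phase 1 assigns Enhancer / Promoter / CTCF / Not assigned, phase 2
refines to Enhancer/CTCF or Promoter/CTCF, with the clause sets given in
the README. A firing phase-2 clause overrides the phase-1 label, and Not
assigned rows remain eligible for the phase-2 zero-pattern clauses; the
alternative reading — phase 2 restricted to rows phase 1 called Enhancer
or Promoter — is available as `hybrid_scope=phase1_labelled`. The two
hybrid clause sets cannot fire together (each requires an opposite zero
status of A1/A2 or an incompatible rank pattern); a defensive tie-break
(larger of A1 vs A2) covers the combination anyway and is exercised by
the exhaustive enumeration test. Under strict all-nonzero ranks the
phase-1 clause sets of different classes are mutually exclusive, verified
by enumerating all 24 permutations.

Enhancer activity: Enhancer and Enhancer/CTCF calls are active when
`A[r, H3K27ac] > activity_threshold`, else inactive. The default
threshold is 0 — presence/absence of acetylation — as no principled
nonzero value exists a priori; it is a config key with units of
normalised signal (per-million of genome-wide coverage).

## Downstream analyses

**TSS distances.** Genes are filtered to protein-coding, miRNA and
lncRNA biotypes (configurable). The TSS is the interval start on the +
strand and the last covered base (end − 1) on the − strand; strandless
records are skipped with a warning. Per region,
`Log.Distance.TSS = log10(d + 1)` where d is the bp gap from the nearer
region edge to the closest TSS, 0 when a TSS lies inside the region —
edge-to-point rather than centre-to-point, because containment must give
exactly 0. Regions on chromosomes without any registered TSS get NaN
("NA" in the output BED).

**Variant intersection.** Variant positions (0-based BED or declared
1-based tables) are assigned to every element containing them under
half-open containment. Counts are reported both per variant-element pair
and per distinct variant, since a variant inside two overlapping
elements of different classes legitimately contributes to both;
multi-hit variants are flagged in the per-variant table and variants
hitting nothing are counted unannotated.

**Meta-plots.** Per track, a regions × bins matrix of mean per-base
coverage over [centre − flank, centre + flank), defaults flank 2000 bp
and bin width 10 bp (the bin width is a rendering granularity choice,
configurable); windows truncated at chromosome edges read 0.

## Synthetic data

The generator plants non-overlapping archetype regions (default width
300 bp, 10 instances per class) on a toy genome (one chromosome, 200 kb
default) and emits the complete input layout: per-track sorted+indexed
BAM, bigWig equal to the BAM pileup at every base, and peak BED, plus
accessibility peaks, GFF3 genes, variant positions and the truth table.
Reads are fixed-length (50 bp) single-end, the simplest model satisfying
the coverage contracts; per region and track the read count is Poisson
with mean `intensity × reads_per_unit` (default 10), and background
reads are added per track at `noise_level` times the planted read count,
uniformly over the genome. Track peaks exist exactly at planted regions
with nonzero intensity for that track, so zero intensities become exact
structural zeros after quantification — emulating how peak gating
produces them on real data.

Default archetype intensity profiles (H3K4me1, H3K4me3, H3K27ac, CTCF):
Promoter (1, 10, 6, 0), Enhancer (10, 1, 6, 0), CTCF (0, 0, 2, 10),
Promoter/CTCF (0, 8, 5, 9), Enhancer/CTCF (8, 0, 5, 9), Not assigned
(0, 0, 0, 0). Every profile is validated against the rule engine at
construction instead of being trusted. A second preset
(`SEPARATED_ARCHETYPES`) spaces each nonzero intensity at least 5× from
the next — e.g. Promoter (0, 10, 2, 0), Promoter/CTCF (0, 10, 2, 50) —
and is used for the noisy-recovery regression bound, where the
well-separated design isolates the effect of background noise from
profile-margin effects.

What passing these tests shows — and does not. The generator exercises
coordinate handling, quantification, normalisation and the rule logic
end to end, with exact oracle comparisons. It does not model fragment
size, GC or mappability bias, diffuse marks, or peak-caller noise, so
recovery rates on it say nothing about classification accuracy on real
chromatin; they certify the machinery, not the biology.

## Numerical and test-scale choices

Signal comparisons against the brute-force per-base pileup oracle use
1e−9 relative tolerance (pure summation arithmetic; anything looser
would hide bugs). Depth invariance is checked under 2× and 5× read
duplication. The regression bound for noisy recovery is ≥ 95% mean over
20 seeds at noise 0.1 (the package's own target). Test problem sizes —
toy genomes of 40–200 kb, 12–60 planted regions, 20 seeds — keep the
full suite in the tens of seconds while leaving every code path
exercised; the acceptance script uses ten noisy seeds of 30 regions
each.

## Known limitations

* The rule set covers active chromatin only: no poised or repressed
  states (H3K27me3, H3K9me3), and no probabilistic uncertainty — a
  region one read away from a rank flip changes label discretely.
* `auc_mode` and the activity threshold materially change calls on
  shallow libraries; defaults are documented above, not universal.
* LD expansion of GWAS variants is out of scope: the variant list is
  consumed as given.
* Resumption covers the quantification stage (the expensive one): the
  signal matrix is reloaded when input checksums and the parameter hash
  in the manifest still match; earlier, cheap stages are recomputed.
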