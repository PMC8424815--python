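# Methods

This note documents the models, parameter choices and numerical conventions
behind `cernet`, and what the synthetic benchmark does and does not show.

## Pipeline model

The pipeline infers lncRNA–miRNA–mRNA ceRNA triplets in five stages, each a
pure function of its inputs (no randomness outside the synthetic generator):

1. **lncRNA filtering and classification.** A candidate passes iff its
   length is strictly greater than `min_lnc_length` (default 200 bp) and its
   longest ATG-initiated, stop-terminated ORF on the given strand is below
   `max_orf_nt` (default 300 nt). The ORF rule is a deliberately simple
   coding-potential surrogate — it is transparent and exactly testable, but
   it is not a trained classifier and will mislabel non-canonical coding
   transcripts (no Kozak context, no codon-usage signal). Positional classes
   relative to the gene annotation: *intergenic* (span overlaps no gene
   span), *antisense* (overlaps ≥ 1 exon of an opposite-strand gene),
   *intronic* (span entirely within one intron of a same-strand gene),
   otherwise *ambiguous*; on multiple hits antisense takes precedence over
   intronic, which makes the assignment deterministic and independent of
   gene order. All coordinates are 1-based closed (GTF convention)
   end-to-end; sequences are canonicalized to the DNA alphabet (U→T) on
   read.

2. **Differential expression.** Expression is assumed already normalized
   (RPKM/FPKM for long RNAs, TPM for miRNAs; `rpkm`/`tpm` are provided for
   count input, with TPM columns summing to 10⁶ by construction). The
   between-condition test is a two-sided Welch t-test on log2(value +
   pseudo), pseudo-count 1.0 by default, with Benjamini–Hochberg adjustment
   across all tested features; a feature is *up* iff log2FC > 1 and adjusted
   p < 0.05, *down* iff log2FC < −1 and adjusted p < 0.05. log2FC =
   log2((mean_treated + pseudo)/(mean_control + pseudo)) on the abundance
   scale. The Welch-on-logs choice is a documented surrogate for
   count-model DE tests: it is well calibrated on log-normal abundances
   (verified on a 2000-feature null) but does not model count overdispersion.
   Degenerate case: when both groups have zero variance the t-statistic is
   undefined; the p-value is set to 1 for equal means and 0 otherwise, which
   keeps constant background features out of the DE set in noise-free data.

3. **MRE scanning.** Ungapped antiparallel alignment of the miRNA (5′→3′)
   against every target window of miRNA length (step 1): miRNA position 1
   pairs the window's 3′-most base. Per position: Watson–Crick pair 0,
   G:U wobble `gu_penalty` (0.5), otherwise `mismatch_penalty` (1.0);
   penalties at miRNA positions `seed_range` (2–13) are multiplied by
   `seed_multiplier` (2.0); windows with total ≤ `max_penalty` (4.0) are
   candidate sites. Overlaps are resolved greedily by ascending penalty,
   ties by smaller start, so the retained set is deterministic and
   order-independent; retained sites may be adjacent but not overlap
   (`min_site_separation` = 1). These defaults follow the classical plant
   target-prediction rule family (near-perfect complementarity, seed
   emphasis, G:U tolerated at half weight); all are configurable. No bulges
   or gaps are modelled — plant duplexes rarely require them and the
   ungapped scheme admits an exact exhaustive oracle. Penalties are
   multiples of 0.5, hence exact in floating point.

4. **Co-expression.** Pearson r with the exact two-sided t-transform
   p-value (t = r·√((n−2)/(1−r²)), df = n−2), computed across all samples
   pooled over conditions. Thresholds are strict: miRNA–target pairs need
   ≥ 1 MRE, r < −0.7 and p < 0.01; lncRNA–mRNA pairs need r > 0.7 and
   p < 0.01. Correlations within 1e-12 of ±1 (numerically collinear data)
   are snapped to exactly ±1 with p = 0. Note the threshold interplay at
   small n: with 6 samples, p < 0.01 already requires |r| ≳ 0.92, so the p
   cutoff, not the r cutoff, is binding there. Constant profiles cannot pass
   a strict threshold and are excluded (all-pairs path) or rejected with an
   error (single-pair path).

5. **Triplet assembly and network.** (L, m, M) is emitted iff m targets L
   and M, L–M is positively co-expressed, the ceRNA score of (L, M) is
   ≥ `score_min` (default 0.5) and — by default — all three members are
   differentially expressed. The ceRNA score is site-weighted: the sum of
   the lncRNA's MRE counts over shared miRNAs divided by its total MRE
   count; a species-weighted variant (shared miRNA species / all miRNA
   species on the lncRNA) is available via `score_mode="species"` since the
   definition admits both readings. The score is in [0,1] and monotone
   non-decreasing in the shared set. Output is deduplicated and sorted
   (L, m, M), so assembly is invariant to input order. The network has one
   node per molecule, deduplicated "targets" and "competes" edges, degrees
   by incidence; hubs are all nodes of maximal degree, with the
   lexicographically smallest designated primary for determinism. Export is
   SIF plus GraphML (node_type on nodes; relation, pcc, cerna_score on
   edges), both Cytoscape-compatible.

An optional key-gene list restricts triplets to curated mRNAs before network
construction, mirroring the common practice of focusing the network on
literature-supported responders; the list is consumed as input, one id per
line.

## Synthetic data: what it emulates

`SimulationParams` defaults define the benchmark conditions: 20 miRNAs
(21 nt), 200 mRNAs (1500 nt), 50 lncRNAs (800 nt), 30 planted triplets,
6 control + 6 treated samples, miRNA induction log2FC = 2, repression
strength β = 1.5, log2-scale noise σ = 0.25. Six samples per condition keep
the r/p thresholds attainable at this noise level (a 3+3 design is
configurable but leaves p < 0.01 nearly unreachable at r ≈ 0.9, which is
worth knowing before applying these thresholds to small designs).

Sequences are uniform random; each planted triplet assignment draws a
distinct lncRNA and mRNA (miRNAs cycle when there are more assignments than
miRNAs) and overwrites 1–3 perfect reverse-complement sites of its miRNA
into both targets, site starts separated by ≥ 2 × miRNA length. Perfect
complementarity makes the exhaustive scanner oracle exact. Expression:
planted miRNAs get baseline + log2FC·1[treated] + N(0, σ) on the log2
scale; each planted target gets baseline − β·(its miRNA's centered realized
log2 profile) + N(0, σ); background features have no condition effect;
values are exponentiated to the positive abundance scale. The shared
repressor induces the negative miRNA–target and positive lncRNA–mRNA
correlations the pipeline filters on; in the σ → 0 limit every sample takes
one of two exact values, so those correlations are exactly ±1. Per-feature
baselines are drawn N(6, 1) on the log2 scale, placing abundances in a
realistic RPKM-like range well above the pseudo-count. The trait vector is
a linear readout (slope 0.8) of the first planted mRNA's abundance plus
Gaussian noise at 20 % of its spread.

**Ground truth is the per-miRNA closure of the drawn assignments**: when two
assignments share a miRNA, every cross combination of that miRNA's lncRNAs
and mRNAs is statistically and mechanistically a true triplet (same
repressor, real planted sites), so it is recorded as planted. The evaluator
counts a planted triplet *eligible* only if its realized correlations pass
the configured thresholds; recall is measured against eligible triplets,
precision against everything reported.

What passing the benchmark does **not** show about real data: uniform-random
sequences lack composition bias, repeats and paralogy (so cross-hybridizing
MREs are rarer than in a genome); expression noise is i.i.d. log-normal with
no library-size, batch or count-overdispersion structure; planted sites are
perfect, whereas real plant MREs carry mismatches; and real ceRNA activity
depends on stoichiometry the model ignores.

## Numerical and design choices

- Toy placements in the synthetic GTF: 3-exon genes at 20 kb spacing with
  2 kb introns; lncRNAs cycle intergenic (3 kb past the host gene) /
  antisense (over exon 1, opposite strand) / intronic (inside intron 1),
  so every positional class is exercised and recorded in the truth file.
- The annotation reader pre-validates lines (line-numbered errors for
  malformed coordinates or missing gene_id) before handing parsing to
  gffutils; GTF and GFF3 are both accepted.
- BH adjustment is the standard step-up procedure (via statsmodels),
  returned in input order.
- The benchmark scale (270 features, 12 samples, ~5 × 10⁶ scored windows)
  was chosen so the complete suite and the acceptance script each run in a
  few seconds on one CPU; precision/recall behaviour is stable across seeds
  at this scale.
- Manifest files echo the full configuration and input checksums but no
  timestamps, keeping reruns byte-comparable.

## Known limitations

- The ORF surrogate and Welch surrogate are documented simplifications (see
  above); swap in dedicated tools upstream if their assumptions bind.
- miRNA–target scanning is O(miRNAs × targets × target length); fine for
  filtered DE feature sets, not for transcriptome-scale all-vs-all scans.
- The ceRNA score ignores site accessibility and expression stoichiometry;
  it is a combinatorial sharing measure, not a binding model.
- Hub analysis reports raw degree only; no betweenness or module detection.
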