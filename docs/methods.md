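# Methods

## Problem and model

`ampliso` analyses long-read sequencing of PCR amplicons that span a single
gene from a forward primer in the first exon to a reverse primer in the last
exon. Because every molecule is (by design) a full-length transcript copy,
the identity of an isoform is carried entirely by its **intron chain** — the
ordered list of donor/acceptor coordinate pairs — and its abundance by the
number of molecules observed. The pipeline therefore works at the level of
exact corrected intron chains rather than probabilistic assembly:

1. **Ingest.** Primary alignments only (secondary/supplementary dropped:
   one placement per molecule). Per-read accuracy is computed from the CIGAR
   and the NM tag as `(M/=/X + I + D − NM) / (M/=/X + I + D)`; skipped
   introns (N) and clipped bases are excluded from both terms, and plain `M`
   bases count toward the match/mismatch term since M is by definition
   matches + mismatches. Reads whose error rate is **greater than or equal
   to** `error_max` (default 0.05) are removed — the boundary read at
   exactly 5% error is out. Each sample is then downsampled to a uniform
   seeded subset (default 10,000 reads) so depth differences between
   barcodes cannot masquerade as expression differences.
2. **Splice-site correction.** Each junction boundary within ±`wobble_nt`
   (default 5 nt) of an annotated donor/acceptor is snapped to it. A
   boundary with no annotated site in range is snapped to the modal observed
   position of its local boundary cluster (ties break to the smaller
   coordinate), so that novel junctions are still denoised without being
   forced onto the annotation. A snap that would create an empty exon or
   intron is abandoned and the read flagged.
3. **Collapse.** One candidate isoform per distinct corrected intron chain;
   unspliced reads are clustered by ≥50% reciprocal overlap because no chain
   key exists for them. A candidate survives with support
   ≥ max(`min_reads_abs` = 3, `min_fraction_by_gene` = 0.001 × gene reads).
   Internal exon boundaries come from the chain; terminal ends are the
   (lower) median of supporting reads' terminal positions. Discovery is
   fully open by default (`novelty_mode="open"`, the novel-discovery-rate
   analog of 1): chains absent from the annotation become novel models. In
   closed mode only annotation-matching chains survive.
4. **Primer filter.** A model is retained only if its genomic span overlaps
   both the forward and reverse primer interval of at least one primer pair
   by ≥1 nt. This is what enforces full-length models and removes
   truncation/off-target artifacts.
5. **Quantification.** Reads are assigned to the unique retained model with
   an identical corrected chain (mono-exon reads by ≥50% reciprocal
   overlap). `TPM_i = counts_i / Σ counts × 10⁶` per sample, with **no
   effective-length normalization**: amplicon reads are whole molecules, so
   molecule counts — not base coverage — are the abundance unit. Strict
   assignment leaves sub-chain (truncated) reads unassigned and reports
   them; a lenient mode splits such reads fractionally equally among
   compatible models for users who cannot enforce full-length chemistry.
6. **Expression filter.** An isoform is kept iff TPM ≥ `tpm_minimum`
   (default 5000, i.e. 0.5% of the gene) in at least
   `required_sample_count(n, samples_minimum)` samples, where a fractional
   `samples_minimum` maps to `max(1, floor(f·n))` (floor, so 25% of 35
   samples is 8) and an integer is capped at the cohort size. TPM and
   proportions are re-normalized over the survivors (toggleable; whether to
   re-normalize after filtering is a genuine design choice — we re-normalize
   so per-sample values always sum to 10⁶). Novel models are then renamed
   Tx1..TxN by decreasing total TPM (ties to the leftmost start).
7. **Classification.** FSM: chain identical to a reference transcript
   (terminal ends ignored). Otherwise, with every donor/acceptor evaluated
   against the union of all the gene's reference transcripts: NNC/ALO if
   any site is unannotated; else NIC with subcategory IR (an exon spans a
   complete reference intron — IR takes precedence when several apply,
   since a retained intron is the isoform's defining feature), COS (a
   junction pairs two known sites never paired in the reference) or COJ
   (known junctions in a novel combination). Mono-exonic isoforms are
   reported outside the three classes. An incomplete-splice-match category
   is deliberately not emitted: the primer filter already guarantees
   full-length models, so an independently supported sub-chain is a
   distinct isoform, not a fragment.
8. **Novel exons** are model exons with zero overlap to any reference exon
   of the gene, reported 1-based inclusive with size = end − start + 1, and
   labelled `<upstream canonical exon number><letter>` using the canonical
   transcript's numbering (canonical = longest spliced reference transcript
   unless specified). Splice motifs are read from the genome, strand-aware;
   GT-AG, GC-AG and AT-AC count as canonical.
9. **ORF / NMD.** Translation starts at the canonical start codon if that
   genomic position is exonic in the model, else at the first usable
   annotated alternative start, else at the longest-ORF ATG; the fallback
   used is recorded. A stop reaching the canonical stop (or falling in the
   last exon) is `coding`. A premature stop is `likely_NMD` when its first
   base lies **more than 50 nt** upstream of the final exon–exon junction in
   transcript coordinates and `NMD_escape_lastexon_proximal` when within
   50 nt inclusive (the boundary is inclusive on the escape side: observed
   escape cases in the literature sit at ~35 nt, and the 50-nt rule is a
   loose empirical boundary; the window is a parameter). Mono-exonic
   transcripts have no junction and are never NMD. `unknown` means no
   usable start codon. Novel-exon consequences reuse the same machinery:
   UTR (outside the translated region), ORF (frame preserved, no stop
   introduced), PTC or PTC(<50nt) by the same distance rule.
10. **Instability index.** Expasy ProtParam's dipeptide statistic
    `II = (10/L) Σ DIWV(aa_i, aa_{i+1})`, using the published DIWV table
    (via Biopython's data module); the conventional unstable threshold of
    40 is reported, never used to filter.
11. **Group statistics.** Per-isoform two-sided Welch t-tests on per-sample
    proportions between exactly two groups, BH step-up adjusted across the
    isoforms of the gene (the amplicon is the natural family), significant
    at q ≤ 0.05. Welch rather than pooled-variance because group sizes and
    variances are rarely balanced; proportions are tested untransformed by
    default with an optional logit flag. Two constant equal groups give
    p = 1 by convention; isoforms with fewer than two observations per
    group are flagged untestable and excluded from the BH family.

## Synthetic data generator

The simulator emulates a spike-in RNA variant (SIRV-style) amplicon
experiment: synthetic multi-isoform genes whose isoforms share an exon pool
and both terminal exons (the primer sites), mixed at known concentrations
and sequenced as full-length, error-bearing long reads.

* `make_locus` builds a random exon pool (exons 80–250 nt, gaps 60–300 nt)
  on a synthetic contig, writes GT..AG motifs at every inter-exon boundary
  (strand-aware) so motif annotation is exercised, and draws distinct
  exon-index chains that all contain the first and last exon. The default
  experiment uses two loci of 8 and 9 exons with 5 isoforms each.
* `default_mix_design` provides an equal mix E0 and two mirrored two-fold
  dilution series E1/E2 (½, ¼, ⅛, 1/16, 1/16 normalized), giving distinct
  ranks for rank-correlation scoring. Real spike-in concentration ratios
  are vendor-proprietary, so the vectors are configurable.
* `simulate_reads` draws each read's isoform from the mix multinomial,
  injects substitutions/insertions/deletions at the configured per-base
  rates (events at interior positions only, so alignments never start or
  end in an indel), emits a reference-consistent CIGAR using `=`/`X`/`I`/
  `D`/`N` with `NM` equal to the injected edits, and truncates a configured
  fraction of reads from the 5' or 3' end by a geometric length
  (mean 300 nt) to mimic RT/PCR artifacts that the primer filter must
  remove. Defaults (2% substitutions, 0.5% + 0.5% indels, 5% truncation)
  emulate high-quality nanopore pass reads.
* `make_sirv_experiment` writes the full fixture — genome FASTA, truth GTF,
  one SAM per sample (3 mixes × 3 replicates per locus), concentration
  table and per-gene parameters files — deterministically from one seed.

What the simulator does **not** model: basecaller-specific error profiles
(homopolymer compression, quality-correlated errors), PCR chimeras,
template switching, and strand-specific coverage bias. Tests passing on
simulated data therefore demonstrate the correctness of the chain-based
discovery/quantification logic and its robustness to uniform noise and to
the annotation provided — not performance on adversarial real-world
artifacts.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GTF I/O converts to 1-based
  inclusive, and printed exon sizes are end − start + 1 on 1-based
  inclusive coordinates.
* Median terminal ends use the lower median, keeping ends on observed
  coordinates.
* Snap ties (equidistant annotated sites, tied modal counts) break toward
  the smaller coordinate; novel-name ties toward the leftmost start.
* Strand comes from the parameters file, not read flags: PCR products are
  strand-ambiguous.
* Samples with zero assigned reads yield all-zero TPM columns rather than
  NaN; Spearman scoring zero-fills the union of truth and called isoforms
  so both misses and spurious calls are punished, and is reported as
  undefined below 3 isoforms or for constant vectors (the equal mix E0).
* Annotation perturbation removes `round(remove_fraction × n)` transcripts
  and builds decoys by recombining existing exons into chains verified
  absent from the truth set.
* All randomness flows from explicit integer seeds (numpy `default_rng`);
  derived seeds stay below 2³¹.

## Problem sizes used in the test suite

The packaged test suite runs the full pipeline on the simulated experiment
at 10,000 reads per sample (2 loci × 5 isoforms × 9 samples), the scale at
which binomial noise on proportions is ~0.005 and the ±0.02 recovery bound
is comfortably testable. Statistical calibration uses 200 null replicates
(9 vs 9 samples, multinomial depth 1000) and 60 seeds for the power check
of a 0.1-vs-0.6 proportion shift.

## Known limitations

* One amplicon locus per run; multi-gene experiments are multiple runs.
* No UMI deduplication and no EM-style multi-mapping resolution; strict
  chain assignment is exact but conservative.
* `unknown` ORF verdicts are defined operationally as "no usable start
  codon"; other definitions of insufficient information are possible.
* The group test is pairwise only; multi-group designs need an external
  ANOVA.
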