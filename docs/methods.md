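# Methods

## Problem and model

Two RNA-binding proteins (RBPs) that occupy the same 3′UTR — here the
miRNA-guided Argonaute AGO2 and the sequence-specific repressors
PUM1/PUM2, treated generically as a focal protein and a partner — can
bind independently, cooperatively (each stabilizes the other), or
antagonistically (one excludes or shields against the other). CLIP-seq
measures per-site occupancy as PCR-collapsed (UMI-deduplicated) read
counts; perturbing one protein and re-CLIPping the other turns these
counts into a site-resolved interaction readout.

The package decomposes the question into four statistics:

1. **Co-occupancy beyond position chance.** Whether two site sets
   overlap more than expected *given which UTRs they occupy* is tested by
   a within-UTR randomization null: each site of one set is repositioned
   independently and uniformly among its `L − w + 1` valid starts on its
   own host, width preserved, and the number of randomized sites with at
   least one overlapping partner is recomputed `n` times (default 100).
   The z-score of the observed count against the null mean/SD is the
   co-occupancy statistic. Shuffling never crosses UTR boundaries, so
   transcript choice is conditioned out and only positional arrangement
   is tested.

2. **Positional density.** Signed center-to-center offsets (3′ positive)
   of query elements around reference sites, binned over ±window, scaled
   by the number of reference sites, with a mean ± 1 SD envelope from the
   same randomization of the query set.

3. **mRNA-normalized differential binding.** Site signal is CPM averaged
   across a condition's replicates; the condition contrast is
   `log2((s_perturbed + c)/(s_control + c))` with pseudocount `c = 1` CPM,
   minus the transcript-level mRNA log2 fold change under the same
   perturbation (supplied as an external table). Subtraction in log space
   treats the mRNA change as a multiplicative availability factor.
   Because only a minority of a UTR's sites are expected to couple to the
   partner, the per-UTR *minimum* and *maximum* normalized LFC are the
   interaction candidates; their distributions are compared between UTR
   co-occupancy classes by two-sided two-sample Kolmogorov–Smirnov tests
   (asymptotic p; no multiple-testing correction — one planned test per
   contrast).

4. **Sequence corroboration.** Pumilio-element scanning (perfect
   UGUAnAUA plus the 3′-relaxed classes) and canonical miRNA
   seed-complement typing (8mer/7mer-m8/7mer-A1) verify that site
   populations carry the expected recognition elements, and Spearman
   correlation of per-family seed tallies compares miRNA repertoires
   between site groups.

Reporter assays provide the orthogonal, single-site readout: WT/mutant
normalized-luciferase ratios across ≥ 3 biological replicates, a strict
`CV > 0.5` technical filter, paired t-tests on log ratios within a cell
condition and Welch t-tests on ratios between conditions (α = 0.05).

## Conventions and numerical choices

- Coordinates are 0-based, half-open, transcript-relative; genomic BED6
  input is mapped through the UTR annotation at ingest (strand consumed,
  sites spanning annotation boundaries rejected). An `one_based` ingest
  flag covers peak callers with inclusive 1-based output rather than
  guessing.
- T/U are interchangeable; sequences are upper-cased RNA internally.
- Overlap requires ≥ 1 shared nucleotide — the most permissive rule, and
  the natural reading of "overlapping peaks"; no minimum-overlap
  fraction.
- Randomized sites may overlap each other; rejection sampling would bias
  the null on short UTRs.
- Site centers use `start + (w − 1) // 2` (round-half-down for even
  widths).
- Motif degenerate classes are mutually exclusive with PERFECT and with
  each other (precedence UGUAnnUA > UGUAnAnA > UGUAnAUn, since the first
  subsumes the other two); `n` matches A/C/G/U but never N, and windows
  containing N are skipped.
- Seed-type precedence is 8mer > 7mer-m8 > 7mer-A1 at a locus; an 8mer
  match suppresses the 7mer-m8 it contains and the 7mer-A1 one base
  downstream. Families are keyed by seed (miRNA nt 2–8). 6mer and
  non-canonical sites are out of scope.
- Replicate aggregation is CPM → condition mean → one LFC (rather than
  averaging per-replicate LFCs), which is more stable at low counts.
- The site read-count filter defaults to the number of samples in the
  CLIP set (≈ one supporting ligation event per sample).
- Degenerate cases carry explicit flags rather than silent values:
  z is undefined (None) when the null SD is zero; repertoire correlation
  is undefined for constant tally vectors; a paired t on all-zero
  differences reports p = 1 with a degeneracy flag, and constant nonzero
  differences report the limiting t = ±inf, p = 0.
- KS comparisons use the asymptotic two-sided p-value; sites on
  transcripts missing from the mRNA table are excluded and counted, never
  dropped silently.
- A single user seed drives all randomization; per-randomization streams
  are drawn sequentially from one `numpy` Generator, so every result is
  reproducible bit-for-bit from the run config.

## The synthetic study

`clipcoreg.simulate` generates the study conditions every test and
driver runs under:

- 600 UTRs, lengths uniform on 500–1500 nt, i.i.d. uniform base
  composition (which makes background motif rates closed-form:
  `4·(L−7)/4^8` perfect elements expected per UTR).
- Deterministic UTR class assignment: 40 % co-bound, 40 % focal-only,
  10 % partner-only, 10 % unbound; two sites per bound protein per bound
  UTR, widths 20–40 nt.
- On each co-bound UTR one focal site is cooperative and one
  antagonistic (δ = 1 log2 unit each); half the partner sites on
  co-bound UTRs are placed overlapping a focal site and are cooperative
  with respect to focal-protein loss. All other sites are independent.
- Counts are negative binomial with mean μ = 100 and dispersion k = 10
  (variance μ + μ²/k ≈ 11 μ, the over-dispersion typical of collapsed
  CLIP ligation events), with a per-site baseline spread of 0.5 log2
  units; three replicates per condition, library size 10⁶ (so counts ≈
  CPM).
- Transcript-level mRNA LFCs are drawn N(class effect, 0.2²) with a
  +0.5 stabilization for partner-bound transcripts upon partner
  knockdown, and are *added to every site's perturbed-condition mean*:
  raw site LFCs are thereby confounded with transcript abundance exactly
  as in real data, and only the normalization step removes it.
- A perfect Pumilio element is planted inside every partner site and a
  seed complement inside every focal site, the family drawn from a fixed
  geometric abundance distribution over eight well-known miRNAs (real
  repertoires are dominated by a few abundant families; a shared skewed
  distribution is what makes repertoire rank-correlations informative).

What the generator does **not** emulate: non-uniform (GC/dinucleotide)
sequence composition, UTR-length or expression biases in site placement,
crosslink-induced mutation signatures, partial knockdown (perturbations
are complete), or correlated replicates. Passing tests therefore
demonstrate the statistics are correct and calibrated under a clean
generative model — not that real CLIP artifacts (crosslinking hotspots,
amplification biases) cannot mimic coupling; the motif/seed
corroboration steps exist precisely because position-level statistics
alone cannot exclude such artifacts.

## Analysis scales

The drivers and the acceptance script use the default 600-UTR study with
100 randomizations per null, which gives ≥ 240 UTRs per compared class
(ample for KS at the planted effect size) and sub-minute runtimes; null
calibration tests use 500 replicate experiments of 100 randomizations
each. All sizes are configurable through `SimConfig` and the
`n`/`window`/`bin` parameters.

## Known limitations

- The mRNA normalization assumes the external mRNA LFC table and the
  CLIP contrast refer to the same perturbation; no uncertainty in the
  mRNA measurement is propagated.
- An alternative normalization (rescaling counts before the LFC) is not
  implemented; log-space subtraction is the single convention, chosen
  because it composes with the pseudocount and keeps the identity
  `normalized = raw` at mRNA LFC 0.
- The randomization null preserves site widths and host assignment but
  not local sequence composition; GC- or length-matched nulls are out of
  scope.
- Venn bookkeeping enumerates all 2^k protein combinations and is meant
  for the typical k ≤ 4 proteins.
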