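# Methods

This note documents the models and procedures implemented in `uorfkit`, the
conventions chosen where more than one was defensible, and what the synthetic
data does and does not establish about behaviour on real data.

## Coordinate and sequence conventions

All annotation operates on the spliced transcript sequence, sense strand,
5'→3', with 0-based half-open coordinates: the 5'UTR occupies `[0, L)` and
the CDS starts at `L`. Genomic strand handling (reverse complementing,
exon splicing) is confined to the GFF3 and VCF readers, so the annotation
core never sees genomic coordinates. This convention makes frame arithmetic
exact: a uAUG at position `s` is in frame with the CDS iff `(L − s) mod 3 = 0`.

Windows containing `N` are skipped during enumeration (codon identity cannot
be asserted), and variants spanning the UTR/CDS junction are rejected rather
than guessed. Pure insertions at the junction are assigned to the UTR (5' of
the canonical ATG), which makes deletions at the UTR's 3' end invertible.

## uORF model

A uORF is an ATG lying entirely within the UTR (`start + 3 ≤ L`) together
with the first downstream in-frame stop codon (TAA/TGA/TAG) also entirely
within the UTR (`stop + 3 ≤ L`); codons straddling the UTR/CDS junction do
not count. An ATG with no such stop is an existing overlapping ORF (oORF):
its reading frame runs into the CDS, in frame (CDS elongation) or out of
frame. Later in-frame stops beyond the first are recorded as alternative
stops; they determine whether removing the first stop merely elongates the
uORF or converts it into an oORF.

Kozak strength is scored from the −3 and +3 positions relative to the A of
the ATG: strong iff −3 ∈ {A, G} and +3 = G; moderate iff exactly one holds;
weak otherwise. "+3" here denotes the base at index `start + 3` — the first
base after the G — drawn from the CDS prefix when the uAUG abuts the CDS.
Because the classical Kozak literature sometimes numbers that column +4, the
offset is exposed as a parameter (`plus_offset`) rather than hard-coded. A
−3 position that falls before the transcript start counts as non-matching.

When several uAUGs converge on the same stop codon, each (start, stop) pair
is reported, all carrying the strongest Kozak among the converging starts.
For stop-removing variants, which are properties of the stop rather than of
any one start, records are collapsed to one set per distinct stop codon and
anchored on the strongest-Kozak start (ties broken 5'-most); all converging
starts share the same frame, so only the reported distance depends on this
choice.

A perturbing variant is **high-impact** when it yields an oORF or CDS
elongation from a strong/moderate-Kozak start (for created uAUGs), or from a
strong/moderate-Kozak *or* translation-evidenced start (for stop-removing and
frameshifting variants affecting existing uORFs).

## Diff-based annotation of supplied variants

Arbitrary SNVs and small indels are annotated by comparing uORF structure
before and after applying the variant under an explicit alignment: positions
left of the edit map identically, positions right of the replaced segment map
with the length shift, and any ATG window touching the edited bases is newly
composed. A merely shifted pre-existing ATG is therefore never reported as
created. An existing uORF emits a record when its stop is no longer an
in-frame stop of the post-edit ORF — either because the stop codon itself was
mutated (`uSTOP_removed`) or because an indel inside the uORF changed the
frame so the stop is bypassed (`uORF_frameshifted`). One variant may emit
several records (e.g. an SNV in a stop codon that simultaneously completes an
ATG in an overlapping window).

Deletions of 1–5 bp are enumerated exhaustively as uAUG creators; insertions
are annotated when supplied but not enumerated, because the space of possible
insertions is unbounded.

## MAPS

For each substitution class — reference trinucleotide, alternate middle base,
and for C>T at CpG sites one of three methylation bins — the mutability table
is the proportion of possible sites observed in a neutral corpus
(intergenic/intronic, autosomal, within the neutral-conservation window
−3.9885 < GERP < 2.6607 and mean coverage in (15, 60)), rescaled so the
possible-site-weighted mean equals the human per-base per-generation rate of
1.2×10⁻⁸. Classes with zero observations receive a 0.5 pseudocount before
scaling so no rate is zero; MAPS is invariant to any overall rescaling of the
raw proportions.

The singleton model is an ordinary least-squares regression of per-class
singleton proportion on mutation rate, fit on synonymous variants (a
near-neutral class distinct from the corpus used to build the table), pooled
across substitution classes and unweighted by default; weighting by class
size is available. Predictions are clipped to [0, 1].

For an evaluated class (autosomal, filter-passing, coverage in (15, 60)):

    MAPS = (observed singletons − Σ predicted singleton probability) / n.

Uncertainty: percentile bootstrap over variants (resample n with replacement;
5th and 95th percentiles of the MAPS distribution form a 90% interval;
default 10,000 draws). Class contrasts: both sets are independently
bootstrap-resampled per permutation and P = Σ[(MAPS(B) − MAPS(A)) < 0] / n_perm;
a zero count is reported as "< 1/n_perm". Resampling both sets (rather than
permuting labels) matches the interval construction and is symmetric in the
two classes. A single seeded generator drives each run, so results are
bit-reproducible for a fixed seed.

## Conservation and enrichment

Conserved bases are those with phyloP-style score ≥ 2; the comparison set for
uORF stop sites is the three bases immediately upstream and downstream of
each stop, clipped at UTR bounds, deduplicated, and excluding bases of any
stop codon (controls must not overlap the test group). The threshold
comparison is ≥ by default with a strict-`>` flag, since both conventions
appear in practice and they differ only at boundary scores. Proportions carry
Clopper–Pearson binomial intervals; group comparisons use the two-sided
Fisher exact test (Haldane-corrected odds ratio when a cell is zero) and the
two-sided Wilcoxon rank-sum test (exact null for small tie-free samples,
normal approximation with tie correction otherwise). Disease-variant
enrichment is a one-sided binomial tail P(X ≥ k | n, π) against the
background proportion π of all possible variants satisfying the predicate
(Kozak moderate/strong, out-of-frame oORF, within 50 bp of the CDS, or
high-impact); one-sided because the direction of enrichment is specified in
advance.

## Gene triage

Genes are assigned the first matching class in the fixed order 0, 1, 2, 3, 4,
5, **8, 7**, 6 (known-LoF-disease genes take precedence over LoF-intolerant
ones): 0 no UTR; 1 no possible perturbing SNV; 2 none high-impact; 3 a
high-confidence existing oORF (strong/moderate Kozak or translation
evidence — creating a second would be low-impact); 4 a high-impact SNV with
population allele count above the threshold (default 15, encoding allele
frequency > 0.1% in a 15,708-genome cohort; configurable for other cohort
sizes); 5 most LoF-tolerant LOEUF sextile; 8 curated haploinsufficient,
dominant-LoF developmental gene, or ≥ 10 pathogenic LoF ClinVar variants;
7 most LoF-intolerant sextile or ≥ 2 such ClinVar variants; 6 otherwise.
Likelihood groups: low = {2, 3, 4, 5}, moderate = {6}, high = {7, 8};
classes 0–1 are unclassified. LOEUF sextiles and curation flags are consumed
as inputs, never recomputed.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes.

*Transcripts.* UTR lengths are log-normal (meanlog 5.0 ≈ 148 nt, sdlog 0.55,
clipped to [12, 1500]), matching the scale of typical human 5'UTRs, with 5%
zero-length UTRs (class-0 fodder) and GC content 0.6 (human 5'UTRs are
GC-rich). Planted uORFs/oORFs (60%/10% of genes by default) are written into
the sequence with a requested Kozak context and verified by re-detection with
the package's own scanner; a configurable fraction (30%) of planted stops
enters the translation-evidence list.

*Population corpus.* The mutation model assigns transition, transversion and
CpG-methylation-bin rates (0.4, 1.5, and 2/6/12 ×10⁻⁸ respectively, with a
seeded log-normal jitter so every class is distinct); CpG contexts are
down-weighted 4× in possible-site counts. A site is observed with probability
proportional to its rate, scaled to a mean observation rate of 2.7% (the
fraction of possible uAUG-creating SNVs observed in a ~15.7k-genome cohort).
Selection is modelled *phenomenologically* as an inflation δ of the singleton
proportion of a class — exactly the quantity MAPS measures — rather than
through a Wright–Fisher model, so parameter recovery is an exact check: the
acceptance surface is MAPS ≈ δ. The baseline singleton probability decreases
with mutability (the confounder MAPS exists to remove); its default form is
linear in the rate, chosen so the linear singleton calibration is exact and
any residual MAPS bias reflects sampling noise alone, with a logit-linear
alternative available (`singleton_model="logit"`). Coverage, GERP, chromosome
and filter columns are drawn so the stated filters remove a controlled ~9% of
observations independently of singleton status.

*Scores and metadata.* phyloP-like scores are Gaussian (sd 1.6, giving ~11%
of background bases ≥ 2, the scale seen at matched UTR control bases) with
functional sites shifted by +0.6 (≈19% conserved, the scale seen at
translation-evidenced uORF stops). Gene metadata assigns LOEUF sextiles by
quantile of a latent score and samples curation flags at realistic base rates
(4% haploinsufficient, 3% dominant-LoF, 15% of genes with any ClinVar LoF
record); annotation-derived fields (possible-variant counts, oORF flags,
maximum high-impact allele count) are computed, never sampled.

Passing tests on this data establish the *internal correctness* of the
machinery — enumeration, calibration, estimator, inference, triage — under
known ground truth. They do not establish that real 5'UTR variant classes are
under selection, nor calibrate real effect sizes: real data add linkage,
demography, genome-scale context composition, annotation error and ascertainment
effects that the generator deliberately omits.

## Problem sizes and numerical choices

The default test and acceptance runs use 200–300 genes, 50,000 observed
variants per MAPS class, 10,000 bootstrap draws for reported intervals
(1,000 in the repeated-coverage study of 200 replicates at n = 2,000), and
2,000 permutations for contrasts; these sizes put Monte-Carlo error well
inside the asserted tolerances (MAPS sampling s.d. ≈ 0.002 at n = 50,000
against a ±0.02 band). Bootstrap index matrices are generated in chunks of
500 draws to bound memory. Ties in Kozak strength between converging starts
break 5'-most; the 5'-most in-frame stop defines each uORF, with alternates
recorded. Degenerate inputs fail loudly: empty variant sets, calibration with
fewer than two distinct rates, unknown substitution classes, and Kozak
scoring past the end of the CDS prefix all raise errors rather than guessing.

## Known limitations

- Only −3/+3 Kozak positions are scored; the full consensus is not modelled.
- Translation-efficiency prediction, leaky scanning and re-initiation are out
  of scope; "high-impact" is a sequence-level prediction, not a quantitative
  effect size.
- Insertions are not enumerated (only annotated when supplied).
- Multi-isoform resolution is not attempted: one canonical transcript per
  gene.
- The bootstrap-permutation p-value is approximate for very small classes;
  at n below a few hundred its null distribution is visibly discrete.
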