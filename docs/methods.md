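# Methods

## Transcript model and coordinates

A transcript is an ordered list of exons in 5′→3′ transcript order plus
the transcript coordinates of the CDS.  Internally all coordinates are
0-based half-open; every I/O surface (c. positions, genomic positions in
reports, GTF/BED12 readers, the JSON summary) is 1-based inclusive,
matching HGVS and GTF conventions.  c.1 is the A of the start codon and
the CDS **includes the stop codon**; GTF input folds `stop_codon` features
into the CDS to preserve this.  Exons are numbered 1..n over all exons,
coding or not, in transcript order.  On the minus strand genomic starts
strictly decrease along the exon list and increasing c. positions map to
decreasing genomic positions; all alleles are expressed on the transcript
(sense) strand, with reverse-complementing confined to genomic I/O.

Splice-site distances are reported exclusively of the variant base (last
exonic base ⇒ donor distance 0).  Because published reports sometimes
count inclusively, the variant-context output carries both conventions
(`dist_to_donor` and `dist_to_donor_inclusive = dist_to_donor + 1`); no
attempt is made to guess which convention another source used.

## Skip consequence

Skipping an exon excises its CDS overlap from the coding sequence.  The
skip is a frameshift exactly when that overlap is not a multiple of 3.
Translation (standard code, stop at the first stop codon) of the original
and mutant CDS is the single source of truth for the protein-level
annotation: HGVS p. notation is derived from the diff of the two proteins,
so junction-spanning codons after an in-frame skip fall out naturally (a
changed fusion residue yields delins; an unchanged one a clean del).
Frameshifts are written `p.{first changed residue}{new residue}fsTer{M}`
with the stop counted from the first changed residue as position 1, `Ter`
spelled out; a mutant with no in-frame stop is reported as an extension
(`fsTer?`, stop fields null), not an error.  Skips of fully non-coding
exons and skips touching any of the three start-codon bases are rejected
(no coding effect / start-loss, outside the supported model); multi-exon
skips are excluded by construction of the event type.

The premature stop is reported three ways: first base in mutant-CDS
coordinates, the same base re-expressed in the original transcript's c.
numbering (bases 3′ of the skipped exon shift by its CDS overlap length),
and the three genomic positions of the codon in reading order — a
descending range on minus-strand genes.

**NMD rule.** NMD is predicted when the stop codon's last base lies at
least `NMD_RULE_NT` nucleotides upstream of the last retained exon–exon
junction.  `NMD_RULE_NT` defaults to 50 nt — the canonical
exon-junction-complex rule — and is a parameter of `annotate_consequence`.
Junction positions are taken on the mutant transcript after the skip.

## ESE scanning

An ESE catalogue is a plain set of k-mers (one per line, `#` comments,
case-folded, duplicates dropped with a logged count).  The statistic is
the number of catalogue members among the k length-k windows containing
the variant base; windows truncated by sequence ends do not exist and are
not counted, and a context shorter than k−1 on either side flags the row
as truncated rather than failing, so short minigene fragments are usable.
The scan window is derived from k (±(k−1) bp) — one rule reproduces both
the ±5 bp window of hexamer catalogues and the ±7 bp window of octamer
catalogues, with no per-set flag.  Scanning is defined on the transcript
(sense) strand because enhancers act on pre-mRNA; whether published counts
were computed on transcript or genomic strand is ambiguous in general, so
the convention is fixed and documented here rather than configurable.

## Case-control statistics

The 2×2 table holds allele counts (cases/controls × alt/ref).  The
two-sided Fisher exact p-value uses the minimum-likelihood rule (sum of
hypergeometric probabilities of tables, with the observed margins, no more
probable than the observed one), computed via scipy's log-gamma-based
hypergeometric machinery, which stays accurate at magnitudes of 10⁻³⁸ and
below; tests compare it against an exact-rational enumeration oracle on
small tables.  The odds-ratio point estimate is always the sample
cross-product ratio.  Two intervals are offered and the output always
names its method:

* **Woolf** (default): exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); with any zero
  cell a Haldane–Anscombe 0.5 is added to every cell *for the interval
  only* (never the point estimate or p) and the output is flagged.
* **exact conditional**: the noncentral-hypergeometric interval.

Published intervals rarely state their method; on the motivating variant's
table the two methods give ≈99–290 and ≈94–297 respectively.  Both
off-diagonal products zero makes the odds ratio 0/0 and is an error.

## Prevalence model

Assumptions: random mating (Hardy–Weinberg), a focal allele with frequency
q pathogenic **only** in trans with one of an aggregate class of other
pathogenic alleles (frequency Q), other/other genotypes affected,
focal homozygotes unaffected.  Then

    P = 2qQ + Q²,   f = 2qQ / P

for disease prevalence P and compound-het patient fraction f.  Inversion
is closed-form: g = 2(1−f)/f, q = √(P/(2g+g²)), Q = gq; the returned
parameter set satisfies both identities to 1e-12 relative tolerance, and
f = 0 or 1 (no compound hets / no other alleles) is a degenerate-model
error.  The expected focal-homozygote frequency q² is reported so the size
of the "homozygotes unaffected" approximation is visible (≈5.5×10⁻⁶ at the
motivating parameter values, i.e. negligible against P = 3.3×10⁻⁵).  No
penetrance, consanguinity, or population-structure parameters are
modelled.

## ACMG engine

The full 2015 combining-rules table is implemented — not only the two
rows exercised by the motivating case — over counts of *applied*
strengths.  A code may be applied below its native strength (downgrade,
preserving the original code for provenance) but never above; duplicates
are rejected.  Pathogenic and benign branches are evaluated independently;
if both fire the result is VUS with both rule lists recorded, as is
evidence matching no rule.  The engine derives no evidence from data:
assigning PS3/PS4 etc. is the caller's judgement.

## Synthetic data

One master seed feeds three independent child streams (transcripts,
cohort tables, populations), so extending one simulator never shifts
another's draws; identical configurations give byte-identical outputs.

* **Transcripts** — exon count, exon-length range, strand, GC content and
  UTR ranges are configurable.  The CDS starts ATG, ends with a stop, and
  contains no internal in-frame stop; stop codons are rejected and
  resampled during codon generation (not edited afterwards), keeping base
  composition near the requested GC within the sense-codon set.  A named
  exon can be forced out of frame (its sampled length, or the adjacent UTR
  for terminal exons, is nudged within the allowed ranges; infeasible
  requests raise a constraint error).  Motif plants overwrite stated
  transcript positions and are re-validated against the start/stop/no-
  internal-stop contract.  The genome is assembled with random introns and
  flanks and mirrored for minus-strand genes.
* **Cohort tables** — binomial draws at stated case/control allele
  frequencies.
* **Populations** — N diploid individuals with two independent allele
  draws over {focal q, other-pathogenic Q, benign}; affected ⇔
  focal/other or other/other, matching the prevalence model's assumptions
  exactly.

What the generator does **not** emulate: realistic splice-site or
enhancer sequence composition, linkage/haplotype structure, penetrance
variation, or population stratification.  Green tests therefore
demonstrate the correctness of the coordinate arithmetic, annotation
logic and estimators under their stated model assumptions — not the
calibration of those assumptions to any real population or gene.

## Problem sizes and numerical choices

The consequence-engine fuzz compares 1,000 simulated transcripts (3–6
exons, 30–90 nt) against an independent translation-diff oracle and
checks the c.↔genomic round trip at every CDS position.  Null calibration
of the exact test uses 10,000 simulated tables at q = 0.01 with 100 case
and 1,000 control alleles (the discrete exact test is conservative, so
the rejection rate at α = 0.05 must stay ≤ 0.05).  Estimator recovery
uses 30 replicate populations of 2×10⁶ individuals at q = Q = 0.004
(≈100 affected per replicate) and requires the replicate mean of q̂ within
3 standard errors of truth.  Model identities in the prevalence module are
enforced at 1e-12 relative tolerance; round-trip tests use 1e-10.

## External validation inputs

Two acceptance-level checks validate against third-party reference
resources that cannot ship with the package.  Drop the following files
under `data/external/` to enable them:

* `chr13_atp7b.fa` — hg19 chr13 sequence (chromosome or a region covering
  the *ATP7B* locus, with matching coordinates);
* `atp7b_nm000053.gtf` — exon/CDS features of NM_000053.3 from RefSeq
  annotation (attribute `transcript_id "NM_000053.3"`);
* `stadler_6mers.txt`, `ke_6mers.txt`, `zhang_8mers.txt` — published ESE
  catalogues, one k-mer per line.

With these present, the suite verifies that skipping *ATP7B* exon 6 gives
the TGA stop at original c.2259 (chr13:52532543-52532541),
p.Glu624ValfsTer105 with NMD predicted, and that c.1934T>G reduces
overlapping catalogue counts 5→2 (hexamer set 1), 5→1 (hexamer set 2) and
0→0 (octamer set).

## Known limitations

Single-exon skip events only; no splice-strength or skipping-fraction
prediction (the decision that an exon is skipped is an input, not an
output); no multi-isoform selection; no selenoproteins, ribosomal
frameshifts or trans-splicing; one variant per report.
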