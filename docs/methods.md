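# Methods

## Scope and model

`neoligand` models the identification of HLA class I ligands — including
mutated (neoepitope) and phosphorylated ones — from two data streams: a
pileup of aligned exome reads over coding sequence, and MS/MS spectra of
eluted peptides. The stages and their assumptions:

**Promiscuous SNV calling.** Each pileup column is treated independently
(no haplotype or strand model). Base observations below Phred 13
(error probability 10^(−13/10) ≈ 0.05) are removed first; depth and
allele frequency are computed on the filtered column. A variant allele is
called when depth > 10 (strict), supporting reads > 5 (strict) and
VAF ≥ 5 % (inclusive). The asymmetry (strict vs inclusive) is deliberate
and pinned by boundary tests: it reflects the natural reading of
"greater than" versus "minimum set to". Multi-allelic columns emit one
call per qualifying allele, most frequent first; `N` bases are ignored.
Only substitutions are modelled — indels, strand bias, mapping quality and
tumour/normal pairing are out of scope (a stringent somatic caller is the
right tool for those; this caller's loss function is asymmetric on purpose,
since a missed SNV silently deletes a candidate neoepitope while a spurious
one merely enlarges the search space that the FDR stage later disciplines).

**Personalized database.** SNVs are mapped through codon arithmetic onto
proteins; synonymous changes are dropped, missense changes produce one
single-variant isoform each (header dialect `>PROTID|var:POSREF>ALT`),
stop-gains produce a truncated isoform and no context window. Multi-variant
isoforms are intentionally not emitted at the database level: co-occurring
variants are handled combinatorially per peptide in the search space, which
bounds the database size while keeping every variant peptide reachable.
Context windows take 11 flanking residues per side (shorter near protein
ends), so a window is 23 residues exactly when the mutation lies at least
11 residues from both termini.

**Search space.** Unspecific digestion enumerates all substrings of length
8–25 in (start, length) order, streamed rather than materialized. For a
base peptide overlapped by k variants, absence/presence patterns are
enumerated by ascending number of present variants, then positional
lexicographic order, truncated at 100 forms; therefore the all-absent form
always survives and the cap discards only high-order combinations, which
are a priori the least plausible. Identical sequences are merged across
provenances; a sequence counts as a variant peptide only if *every* way of
generating it requires at least one variant. Decoys are reversed proteins
(with variant positions re-mapped), expanded identically; decoy sequences
colliding with any target are removed from the decoy set. Isoleucine and
leucine are kept distinct in sequence identity (`il_equivalent=False` by
default): MS cannot distinguish them, but silently merging them would
corrupt database bookkeeping; the switch exists for analyses that prefer
the merged view.

**Spectrum matching.** Neutral mass uses proton mass 1.007276 Da; charges
1–3 only (higher charge states are not fragmented in the emulated
acquisition). Candidate lookup is inclusive at the ±6 ppm precursor
boundary (a guard of 10⁻⁹ relative tolerance absorbs floating-point
rounding so that an offset of exactly 6 ppm is admitted and 7 ppm is not).
Theoretical fragments are b1..b(n−1)/y1..y(n−1) at fragment charges up to
min(precursor charge, 2); a modification's mass rides only on fragments
containing its site. The match score is −10·log₁₀ of the exact binomial
tail P(X ≥ k), X ~ Binomial(n, p), for k of n theoretical fragments matched
within 20 ppm; p is the probability that at least one of the observed peaks
falls in one tolerance window, 1 − (1 − w/span)^m for m observed peaks and
a window of width w evaluated at the centre of the scanned m/z range
(clipped to [10⁻¹², 0.5]). The score is deterministic, closed-form, exactly
testable, and monotone in k; it is a simplified stand-in for a full
probabilistic search engine and is documented as such. At most one
phosphorylation, one oxidation and an optional N-terminal acetylation are
considered per peptide (configurable); chimeric-spectrum ("second peptide")
identification is not implemented. Ties between isobaric candidates (I/L
twins, site isomers with no site-determining ions) are real and yield delta
score 0; the reported top is fixed by a deterministic sort
(score desc, sequence, placements).

**Site localization.** All single-site isomers of a phosphopeptide are
rescored; isomer weights are 10^(score/10) normalized over isomers
(computed shifted by the maximum score for numerical stability), and a
site's probability is the weight mass of isomers placing the
modification there. Probabilities sum to 1 by construction.

**Error model.** PSMs are partitioned into four exhaustive, disjoint
classes (plain / variant / phospho / variant-phospho; oxidation and
acetylation do not define classes). Per class, PEP(score) is the
kernel-density ratio n_d·f_d(s) / (n_t·f_t(s)) of decoy to target score
densities, clipped to [0, 1], capped at 1/(n_d + 1) above the highest decoy
score (no decoy mass there), and monotonized by isotonic regression
(non-increasing in score). Classes with fewer than 50 decoys fall back to
the pooled model; degenerate score distributions fall back to an empirical
tail-count ratio #decoys≥s / #targets≥s before monotonization; a class with
no targets gets PEP 1, with no decoys PEP 1/(n_t + 1). The common FDR
threshold accepts the largest prefix of the pooled PEP-ascending list whose
running mean PEP stays at or below the threshold (q-value from PEP); a
classic decoy-counting FDR curve is emitted as a cross-check, not as the
control. Peptide rollup keeps the lowest-PEP PSM per modified sequence and
recomputes q-values on the rolled-up list; the global report uses q ≤ 0.01
and the mutated-ligand report uses q ≤ 0.05 on the variant classes (the 5 %
relaxation is applied at peptide level; PSM-level q-values remain in the
PSM table). Phosphopeptide reporting requires delta score > 15 and best
localization probability > 0.75, both strict inequalities.

**Analytics.** Coverage counts one unit per ligand row per residue covered
(verified against a brute-force interval-stabbing oracle); patient counts
use distinct patients per residue; a hot spot is a maximal run of residues
covered by ≥ 3 distinct patients (threshold configurable — the notion is
used descriptively in the field without a canonical formula). Antigen
correlation normalizes per patient by the class-matched ligand total,
applies a square-root transform (variance stabilization for count
fractions), Pearson correlation with two-sided p, and Holm correction
across tested antigens (conservative, no independence assumption; the
correction method is recorded in output metadata). Intensity quartiles:
rows sorted by descending intensity with ties broken lexicographically by
sequence; quartile = ⌊4·(rank−1)/n⌋ + 1, so partition sizes differ by at
most one and quartile 1 is the most intense; rows without an intensity
(MS/MS-only identifications) are excluded with a warning. Phospho
summaries are exact counts: shared fraction over unique sequences seen in
≥ 2 patients, S/T/Y fractions over sites, a length × position site matrix,
position-1 residue usage, and per-length position × residue logo matrices.
Peptides mapping to several proteins are counted for each and flagged.

## Synthetic cohorts

The generator emulates: CDS records (ATG + uniform non-stop codons + stop;
a 3n-nucleotide CDS yields an (n−1)-residue protein), planted missense SNVs
at distinct codons with VAFs drawn from `vaf_range`, pileups whose variant
support is Binomial(depth, VAF) with uniform substitution errors elsewhere
and truncated-normal base qualities (so tests can straddle the Q13 cutoff),
a peptidome sampled as exact substrings of the personalized proteome with a
configurable length distribution (default peaking at 9-mers, the typical
eluted HLA-I length) and optional anchor-motif bias via bounded rejection
sampling, phosphosites planted on S/T/Y carriers, and one spectrum per
peptide containing all in-range b/y fragments plus Poisson-count uniform
noise peaks, along with pure-noise spectra whose precursor masses come from
random peptide compositions (so the FDR stage sees realistic true
negatives). Everything derives from a single integer seed through salted
generators, making all outputs byte-identical across runs.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: correlated sequencing errors and alignment
artefacts, retention-time structure, isotope envelopes, co-eluting chimeric
spectra, intensity-dependent fragmentation efficiency, HLA binding-affinity
structure in which peptides are actually presented, and inter-patient
sharing structure beyond uniform patient assignment. FDR control shown on
these fixtures demonstrates the estimator's correctness under the stated
mixture, not its calibration on any particular instrument.

## Default parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| min base quality | 13 | Phred | ≈ 0.05 error probability |
| min depth / support | > 10 / > 5 | reads | permissive pre-filter for the search space |
| min VAF | ≥ 5 | % | inclusive boundary |
| peptide lengths | 8–25 | residues | unspecific HLA search range |
| combination cap | 100 | forms | bounds 2^k blow-up per base peptide |
| precursor / fragment tolerance | 6 / 20 | ppm | inclusive at the boundary |
| modifications | +42.010565, +15.994915, +79.9663304 | Da | N-term acetyl, Met oxidation, phospho (S/T/Y) |
| global / variant peptide FDR | 0.01 / 0.05 | — | common threshold on class-dependent PEP |
| phospho filters | delta > 15, locprob > 0.75 | — | strict inequalities |
| context window flank | 11 | residues | ≤ 23-mer predictor input |
| hot-spot patients | ≥ 3 | patients | configurable, reported |

Generator defaults (12 transcripts × 360 nt, 5 SNVs, VAF 0.2–0.5, depth
80–160, error rate 10⁻³, quality 30 ± 4, 300 peptides, 4 patients, noise
rate 5 peaks/spectrum) describe a small but realistically proportioned
cohort in which the caller operates far from its thresholds and the scorer
far from chance.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each claim is statistically
meaningful: boundary sweeps are exact and run in milliseconds; the FDR
benchmark uses 20 replicates of 5,000 spectra (2,500 planted, 2,500 noise
against ~60k base peptides plus decoys, ≈ 90 s total); the end-to-end
recovery check uses 6 proteins × 6 variants × 400 nine-mers. Cohort-scale
counts from real patient data (tens of thousands of unique peptides per
cohort) are not reproducible from synthetic fixtures and are not claimed.

## Known limitations

- The match score ignores peak intensities and isotope patterns; it ranks
  correctly on clean spectra but is weaker than engine scores on noisy
  real data.
- PEP estimation needs decoys; tiny cohorts fall back to pooled or
  tail-count estimates that are conservative but coarse.
- The caller has no error model beyond the quality cutoff; systematic
  sequencing artefacts would pass it (by design — downstream FDR carries
  the burden of proof).
- I/L twins and other isobaric ties are reported with delta score 0 rather
  than being merged or arbitrated.
- Stop-loss, splice variants and indels are unsupported; stop-gains yield
  truncated isoforms only.
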