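# neoligand

Variant-aware identification of HLA-presented peptides from tumour
immunopeptidomics and exome data.

## The problem

Tumours present mutated self-peptides (neoepitopes) on HLA class I
molecules, and these can be targets for T-cell based immunotherapy. Finding
them directly by mass spectrometry requires searching eluted-ligand MS/MS
spectra against a *personalized* protein database that contains the
patient's own coding variants — and doing so without drowning the rare
mutated peptides in the error statistics of the vastly larger unmutated
search space. `neoligand` implements that workflow as a reusable, tested
pipeline for computational immunologists and proteogenomics developers:

1. **Promiscuous SNV calling.** From pileup columns, after dropping bases
   with Phred quality < 13 (error probability ≈ 0.05), a variant allele *b*
   at a site is called when

   depth > 10 reads, count(*b*) > 5 reads, and
   VAF = 100·count(*b*)/depth ≥ 5 %.

   The caller is deliberately permissive: its job is to make sure no
   candidate neoepitope is lost before the MS evidence is consulted.
2. **Personalized database.** Each amino-acid-changing SNV yields one
   single-variant protein isoform next to the reference proteome, plus a
   ≤23-mer context window (11 residues of flank on each side of the mutated
   position) ready for external MHC binding predictors.
3. **Unspecific search space.** HLA ligands have no protease-defined
   termini, so all substrings of length 8–25 are candidates. A peptide
   overlapped by *k* variants expands into all 2^k absence/presence
   combinations, capped at 100 forms (fewest-variants-first). Decoys come
   from per-protein sequence reversal.
4. **Spectrum matching.** Candidates within ±6 ppm of the observed
   precursor mass are fragmented in silico into b/y ions, matched at
   20 ppm, and scored with a deterministic binomial-tail survival score
   (−10·log₁₀ P(≥k of n fragments match by chance)). Variable
   modifications: N-terminal acetylation (+42.010565 Da), Met oxidation
   (+15.994915 Da), phosphorylation (+79.9663304 Da on S/T/Y).
5. **Class-dependent FDR.** PSMs are partitioned into four classes —
   plain, variant, phospho, variant-phospho — and the posterior error
   probability (PEP) is estimated per class from target/decoy score
   distributions, because the classes have very different prior
   probabilities of being correct. A single common PSM-FDR threshold is
   then applied on the pooled PEP-sorted list; peptide-level reports use
   1 % FDR globally and a less stringent 5 % for mutated ligands.
   Reported phosphopeptides additionally require delta score > 15 and best
   site-localization probability > 0.75.
6. **Ligandome analytics.** Length distributions, per-protein coverage
   profiles with cross-patient hot spots, √-transformed normalized antigen
   counts with Pearson correlation and Holm correction, intensity-rank
   quartile placement, and positional phosphosite summaries.

A synthetic-cohort generator (`neoligand.fixtures`) plants SNVs, peptides,
modifications and spectra with known truth, so the whole chain is testable
end to end without any external data.

## Worked example

Simulate a small cohort (4 transcripts, 3 planted SNVs, 120 peptides of
which 15 % are phosphorylated, 60 pure-noise spectra) and run the chain:

```sh
neoligand simulate --out-dir fix --seed 7 --n-transcripts 4 \
    --n-variants 3 --n-peptides 120 --n-noise-spectra 60 \
    --phospho-fraction 0.15
neoligand run --pileup fix/pileup.tsv --cds fix/cds.fasta \
    --mgf fix/spectra.mgf --ligandome fix/ligandome.tsv --out-dir out
```

The run logs every threshold it applies:

```
[stage:call-variants] thresholds=CallerThresholds(min_quality=13, min_depth_exclusive=10, min_support_exclusive=5, min_vaf_inclusive=5.0)
[stage:build-db] 3 amino-acid variants
[stage:digest] ExpansionConfig(min_len=8, max_len=25, combination_cap=100, il_equivalent=False)
[stage:search] tolerances=SearchTolerances(precursor_ppm=6.0, fragment_ppm=20.0)
[stage:fdr] global=0.01 variant=0.05
[stage:phospho-filter] delta>15 locprob>0.75
```

All 3 planted SNVs are recovered in `out/calls.vcf`, and
`out/variant_peptides.tsv` reports the mutated ligands accepted at the 5 %
variant-class FDR, e.g.:

```
sequence        modified_sequence       peptide_class   is_variant  delta_score  qvalue
TVAWTSCPIPEEYI  TVAWTSCPIPEEYI          variant         True        0.0          0.0
VWPGPSYCFILSQ   VWPGPSYCFILSQ[ph@6]     variant_phospho True        156.97       0.0
```

A delta score of 0 marks a peptide tied with an isobaric isomer (here its
I/L twin, indistinguishable by MS); `qvalue` is the peptide-level FDR at
which the row is first accepted. `out/windows.tsv` holds the
prediction-ready mutation windows, `out/phosphopeptides.tsv` the
confidently localized phosphopeptides, and `out/coverage.tsv` the
per-residue ligand coverage.

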