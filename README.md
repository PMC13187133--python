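# metaport

Curation and metaphylogeographic analysis of COI metabarcoding surveys
of port communities.

Ports concentrate non-indigenous species (NIS) and connect them through
boat traffic. Metabarcoding of standardized passive collectors yields,
after denoising and clustering, two linked tables: MOTUs (molecular
operational taxonomic units, a species proxy) and ESVs (exact sequence
variants, a haplotype proxy) with read counts per sample. `metaport`
takes those tables and answers three questions about a multi-port,
multi-season survey:

1. **Curation** — which ESVs are contaminants, sequencing noise or
   pseudogenes (NUMTs), and which samples are under-sequenced?
2. **Community structure** — how do alpha diversity, Bray–Curtis
   turnover, Sørensen sharing and PERMANOVA/dispersion tests differ
   between the whole community (COMM) and the NIS subset?
3. **Metaphylogeography** — do NIS carry more intra-MOTU haplotype
   (ESV) diversity than curated native species (NAT), and are their
   haplotype pools less differentiated between ports?

## The statistics at the core

**Curation cascade** (strict inequalities, applied in order): an ESV is
deleted when its reads in blanks/PCR negatives exceed 10% of its reads
in true samples; per sample, cells below 0.005% of the sample total and
then cells below 5 reads are zeroed; an ESV whose translation carries a
stop codon under *every* metazoan mitochondrial genetic code (NCBI
tables 2, 4, 5, 9, 13, 14, 21, 24, 33) is deleted; true samples with
fewer than 9,500 reads are discarded.

**Jost's D between two localities**, estimated per MOTU from the number
of samples in which each haplotype is detected (occurrence counts,
columns *j* = localities, rows *i* = haplotypes, totals *N_j*, ñ their
harmonic mean, *n* = 2):

    H_S = mean_j (1 − Σ_i p_ij²)        Ĥ_S = ñ/(ñ−1) · H_S
    H_T = 1 − Σ_i p̄_i²                  Ĥ_T = H_T + Ĥ_S/(ñ·n)
    D   = n/(n−1) · (Ĥ_T − Ĥ_S) / (1 − Ĥ_S)

Negative estimates (sampling noise) are set to 0 per MOTU before
averaging over the MOTUs shared by a locality pair. A low mean D means
the haplotype pools of the two ports are effectively mixed.

Alongside: analytic (hypergeometric) rarefied richness, Shannon
diversity on a seeded rarefied draw, one-way PERMANOVA (Anderson's
pseudo-F, p = (hits+1)/(n_perm+1)), dispersion tests in
principal-coordinate space with negative-eigenvalue correction, and a
per-MOTU multivariate-hypergeometric read rarefaction that removes the
read-abundance confound from ESV richness comparisons.

Because the study's raw data live in a sequence archive, the package
ships a first-class synthetic generator (`metaport.synthetic_data`)
that reproduces the survey design (4 ports × 10 sampling times × 3
replicates plus blanks and negatives; widely shared, read-abundant NIS
vs locality-restricted natives; tunable between-port differentiation θ;
contaminant and pseudogene spike-ins) with a ground-truth ledger, so
every stage is testable without downloads.

## Worked example

```sh
python examples/04_metaphylogeography.py
```

prints (seed 11, study-scale defaults):

```
median ESVs per MOTU: NIS 6.0 vs NAT 2.0 (Mann-Whitney p = 7.68e-08)
rarefaction to 2991 reads eliminated 0.6% of NIS and 1.3% of NAT ESVs
locality_1 locality_2  mean_d_NIS  mean_d_NAT
        BL         LR       0.161       0.335
        ...
mean D: NIS 0.159  NAT 0.318  (paired t-test p = 0.001)
```

NIS MOTUs hold about three times the haplotype richness of natives, the
difference survives rarefying every MOTU to a common read number, and
their between-port differentiation is half that of natives — the
pattern expected if boating keeps NIS populations mixed while natives
disperse naturally. The other examples cover simulation + filtering
(`01`), NIS/NAT classification (`02`) and alpha/beta diversity (`03`).

A thin CLI wraps the same stages for shell use:

```sh
metaport run --seed 1 --outdir out/          # simulate + full pipeline
metaport filter --indir out/simulated --outdir out2/
metaport metaphylo --indir out2/filtered --outdir out2/ --threshold median
```

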