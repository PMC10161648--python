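# markergt

Genotyping known polymorphic sites from short reads against a **pangenome
of phased haplotypes**, using an FM-index augmented with a *marker array*.

Aligning reads to a single linear reference biases genotype calls toward
the reference allele wherever the donor differs from it. `markergt`
instead indexes a whole panel of haplotype sequences at once — the
reference T₀ plus alternative haplotypes T₁..Tₙ taken from a phased VCF —
so reads carrying non-reference alleles match exactly against the
panelists that carry them, preserving the panel's linkage structure
without ever enumerating recombinant allele combinations.

## How it works

**Index.** The haplotypes are concatenated into one text and indexed with
a BWT/FM-index supporting backward search. Every position that falls in a
polymorphic column of the implied multiple alignment is *marked* with a
64-bit word `(chromosome | reference offset | allele index)`; allele 0
means "reference allele, no edit", and indels mark the single base just
left of the event so that suffixes beginning at the mark span the allele.
The marker array `MA[i] = M[SA[i]]` permutes these marks into suffix-rank
order, where identical entries cluster into runs, and is stored
run-length-compressed with the sparse S/E/X/B bitvector encoding. The
production query structure is the *smeared* array `MA^w`, which lists at
rank *i* every marker within `SA[i]..SA[i]+w`, so the scanner only needs
to consult it every *w* backward-search steps.

**Scan.** Each read is matched right-to-left by backward search. A
maximal run of successful steps is an *extension*; markers are collected
every `w = 19` steps (and once when the extension ends) whenever the
suffix-array range is no larger than the number of indexed haplotypes.
Evidence from an extension is discarded if it conflicts at a site, spans
two chromosomes, or the extension matched fewer than 80 bp. One read
strand is chosen at random; the other is tried only if the first found no
qualifying extension.

**Call.** Per-site tallies (k alleles observed, l of them reference) feed
the diploid genotype likelihood with ploidy 2 and a global error rate ε:

    L(g) = (1/2)^k [(2−g)ε + g(1−ε)]^l [(2−g)(1−ε) + gε]^(k−l),   g ∈ {0,1,2}

with `g_max = argmax L(g)` (ties toward reference) and ε = 0.01 by
default. A haploid mode calls the majority allele, reference on ties.

## Worked example

Simulate a 10-haplotype 50 kb panel with a diploid donor and 30× reads at
1% error, index it, genotype, and score against the donor truth:

```sh
markergt simulate --out sim --config sim.json   # {"chrom_len": 50000, "n_haplotypes": 10,
                                                #  "seed": 4, "coverage": 30.0, "error_rate": 0.01}
markergt build --vcf sim/panel.vcf --fasta sim/ref.fa --min-af 0.0 --out idx
markergt genotype --index idx --reads sim/reads.fq --out calls.vcf --seed 2
markergt eval --calls calls.vcf --truth truth.vcf --fasta sim/ref.fa --report report.tsv
```

which prints:

```
panel: 565 variants, 10 haplotypes; donor haplotypes (6, 9); 20004 reads -> sim
indexed 565 variants over 11 documents (43403 BWT runs); skipped: none
tallied evidence at 565 sites -> calls.vcf
stratum  level       TP   FP  FN  TN   precision  recall  F1
SNV      alt_allele  515  0   0   515  1.0000     1.0000  1.0000
Indel    alt_allele  48   0   0   52   1.0000     1.0000  1.0000
All      alt_allele  563  0   0   567  1.0000     1.0000  1.0000
SNV      het_site    209  0   0   306  1.0000     1.0000  1.0000
...
```

Each diploid call is scored as a pair of allele calls (`alt_allele`
level: an ALT call is a true positive when the true genotype contains at
least one ALT) and as heterozygous-site detection (`het_site` level);
strata are SNV, Indel (≤ 50 bp) and SV (> 50 bp). Here the donor's
haplotypes are part of the indexed panel, so every allele is recovered
exactly; the held-out experiments below are the harder test. `calls.vcf`
carries `GT` and log10-scaled `GL` per site, e.g.
`GT:GL  1/1:-4,-0.60206,-0.00873` — a homozygous-ALT call whose
likelihood ratio against heterozygous is 10^3.4.

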