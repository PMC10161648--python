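# Methods

## Model

A pangenome panel is a reference sequence T₀ plus n alternative haplotype
sequences T₁..Tₙ related to it by the multiple alignment implied by a
phased VCF: each panelist either copies the reference at a site or
carries one of up to 15 ALT alleles. The panel text
`T = T₀ $ T₁ $ … Tₙ $` concatenates the documents (chromosomes in
reference order within each document, no intra-document separator; the
scanner's multi-chromosome discard rule handles matches that straddle a
chromosome junction). The separator `$` sorts below every DNA symbol, so
no suffix comparison crosses a document boundary, and reads — which never
contain `$` — cannot match across documents.

Markers attach genotype meaning to text positions. A variant marks
exactly one position per document copy:

* substitution run: the first substituted base;
* insertion/deletion: the base immediately left of the event in the
  alignment. For left-anchored VCF records this is the record's own first
  base; an unanchored indel at a chromosome start has no left flank and
  is skipped (tallied in `skip_counts["flankless"]`).

Marking a single left-flank base per variant, regardless of allele
length, keeps evidence symmetric between long and short alleles. The
marker word packs `(chromosome, reference offset, allele index)` into
12 + 48 + 4 = 64 bits. A 12-bit chromosome field and 48-bit offset cover
any human-scale genome; 4 bits bound the ALT index at 15, and records
with more alternates are skipped.

`MA[i] = M[SA[i]]` reorders marks by suffix rank; `MA^w[i]` lists the
marks of `SA[i]..SA[i]+w`, clipped at the document's separator (a suffix
near a document end cannot overlap the next haplotype). Multimap payloads
are ordered by increasing text offset, so a position's own mark comes
first. Both arrays use the sparse encoding: bitvectors S and E mark run
starts/ends over the array, X stores one payload list per run, B marks
list boundaries within X. Two adjacent entries merge into a run only when
their payload lists are equal element-wise. Rank/select here are plain
prefix-sum and position arrays: the contract is query semantics, not
succinctness, and the serialized form (packed bitvectors + 64-bit words)
is what the size-trend checks measure.

## Scanning and calling

Reads are scanned right-to-left by backward search. The scanner queries
`MA^w` when the matched length is a positive multiple of w **and** the
current SA range has at most N_h rows (N_h counts all documents,
T₀ included) — a larger range means the current suffix occurs more than
once in some haplotype and the evidence would be ambiguous. One further
query fires when an extension ends with a partial window
(`matched_len ≥ w` and not a multiple), so evidence in the final stretch
is not lost. When a step fails, the range resets and matching restarts at
the next character (the failing character is consumed). Extension-level
discard rules: allele conflict at any site, sites on more than one
chromosome, or matched length under `min_seed_len` (80 bp). Per read, a
site contributes at most one observation; the two strands of one read are
not independent evidence, and sites with conflicting alleles across a
read's surviving extensions are dropped. The initial strand is drawn from
`default_rng([strand_seed, read_ordinal])`, making runs reproducible and
order-insensitive to earlier reads; if no extension on the first strand
reaches the seed length, the opposite strand is scanned and its
qualifying evidence used.

The first checkpoint of an extension (matched length exactly w) can see
one position past the matched region, so early evidence can be a false
positive — the fully-sensitive alternative, walking |q|−1 FL steps from
every row of the pattern's range and consulting M at each visited rank,
costs O(|q|·occ) and serves as the oracle the heuristic is tested
against, not as the production path. In practice a wrong allele seen at
the window edge coexists with the true allele from the read's own
haplotype in the same range, triggering the conflict rule.

Diploid likelihoods use ploidy 2 with a single global error rate:
`L(g) = (1/2)^k [(2−g)ε + g(1−ε)]^l [(2−g)(1−ε) + gε]^(k−l)`, where l of
k observations are reference and g ∈ {0,1,2} counts reference copies.
Note the exponent on the first bracket is l; L(1) = 2^(−k) for every l.
Ties (including k = 0, where all three likelihoods are 1) resolve toward
larger g, mirroring the haploid reference-on-tie rule. ε defaults
to 0.01.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w` | 19 | smear window and marker-query period (bases) |
| `min_seed_len` | 80 | minimum matched bases for an extension to count |
| `N_h` | index document count | SA-range ceiling for marker queries |
| `epsilon` | 0.01 | global per-base substitution error rate |
| `min_af` | 0.01 (CLI build) | keep variants with minor-allele frequency strictly above this, measured over the n panelists (T₀ is a synthetic all-REF document and is excluded from the denominator) |

## Synthetic data

The generator emulates the study conditions the method targets at desk
scale: one 50 kb chromosome, 10 haplotypes, SNVs at 10⁻² and indels at
10⁻³ per base (geometric lengths, mean 3, capped at 80 — raising the mean
beyond 50 exercises the SV stratum), carrier counts uniform over
1..n−1, 150 bp single-end reads at 25× with substitution-only errors.
Substitution-only errors match the genotyper's error model; read
qualities are constant because the method never reads them. Variants are
placed without overlap, so every alignment column belongs to at most one
variant. Reads are drawn from a donor's haplotypes rather than from the
panel, so held-out experiments exercise reference bias and heterozygote
recovery. What the simulation does **not** model: real linkage structure
(carrier sets are independent across sites), mutation/error spectrum
bias, coverage or GC bias, PCR duplicates, paired ends, and repetitive
sequence beyond what a uniform random reference contains. Passing the
recovery tests therefore shows the machinery is correct and unbiased
under ideal mapping conditions, not that real-genome accuracy matches
these numbers; repetitive DNA in particular would lower the fraction of
extensions passing the N_h ambiguity filter.

Held-out donors are removed from the panel before indexing; sites left
without any carrier then have uniform alignment columns, are not marked,
and are excluded from evaluation (which is defined over marked sites).

## Numerical and design choices

* Suffix arrays are built by Manber–Myers prefix doubling on numpy
  (exact, O(n log² n)); a naive comparison sort arbitrates in tests.
  Rank is a cumulative-count matrix, select a per-symbol position list.
* Alphabet order `$ < A < C < G < N < T` (ASCII). `N` in the reference is
  indexed verbatim; read symbols outside the text alphabet yield empty
  ranges rather than errors, so `N`-bearing reads degrade gracefully.
* One shared separator class: equal suffixes of different documents are
  ordered by length, which is immaterial to range semantics.
* Overlapping VCF records: the first wins, later overlappers are skipped
  with a tally — the multiple-alignment model assumes consistent columns.
* Coordinates are 0-based half-open internally, 1-based in VCF I/O.
* `MA` (unsmeared) is built for oracle testing only; the production query
  path uses `MA^w` and never needs the suffix array, which is retained
  purely as a locate oracle for tests.
* Serialization is little-endian and bit-exact under save→load→save.
* The evaluator treats truth sites absent from the calls as reference
  calls (no evidence ⇒ reference under the tie rule) and refuses called
  sites absent from truth.

## Problem sizes

Tests and the acceptance script use panels of 2–50 kb and 2–16
haplotypes, 10³–2×10⁴ reads per experiment — sizes chosen so the whole
suite exercises every code path, including full brute-force definition
oracles at every suffix rank, while remaining a desk-scale computation.
The definition-oracle checks run on 20 random panels at ≤ 10 haplotypes ×
2 kb with w ∈ {0, 1, 3, 19}; recovery experiments use the generator's
default conditions above.

## Known limitations

* No symbolic ALTs (`<INS>`, `<DEL>`), breakends or rearrangements.
* One marker per variant per document: evidence from the right flank of a
  variant is not collected (a reverse-text index would be required).
* The full suffix array is kept in memory; there is no O(r)-space
  run-sampled locate structure, so the implementation targets desk-scale
  panels, not whole-genome collections.
* No genotype-quality emission or GQ-based filtering; no imputation; no
  alignment output.
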