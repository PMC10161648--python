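"""Read scanning against the marker index, genotype calling and evaluation.

A read is scanned right-to-left with backward search.  Each maximal run of
successful steps is an *extension*; when a step fails, the range resets and
matching restarts at the next character.  The smeared marker array is
queried only when the matched length is a positive multiple of w and the
current SA range is no larger than the number of haplotypes in the index
(larger ranges mean the match is ambiguous within at least one haplotype),
plus once more when an extension ends.  Evidence from an extension is
discarded wholesale if it conflicts (two alleles at one site), spans more
than one chromosome, or the extension matched fewer than ``min_seed_len``
bases.  A random initial strand is scanned first; the opposite strand is
consulted only if no extension met the seed-length threshold.

Diploid calls use genotype likelihoods with g in {0,1,2} copies of the
reference allele, a global error rate epsilon, and l reference observations
out of k total:

    L(g) = (1/2)^k * [(2-g)e + g(1-e)]^l * [(2-g)(1-e) + g*e]^(k-l)

Haploid calls take the most frequently observed allele, reference on ties.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .fmcore import FMIndexBundle, SARange, backward_step
from .markers import AugmentedMarkerArray
from .panel import HaplotypePanel, decode_marker

Site = tuple[int, int]          # (chrom_id, ref_offset)
Observation = tuple[Site, int]  # site + observed allele id

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class ScanParams:
    """Knobs of the read scanner; defaults follow the method's standard setting."""

    w: int = 19                 # marker-query period, matches the smear window
    min_seed_len: int = 80      # minimum matched bases for an extension to count
    n_h: int | None = None      # haplotype count; defaults to the index's document count
    epsilon: float = 0.01       # global per-base error rate for likelihoods
    strand_seed: int = 1        # base seed for the per-read initial-strand draw

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.min_seed_len < self.w:
            raise ValueError("min_seed_len must be >= w")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")


@dataclass
class Extension:
    """One maximal backward-search match and the marker evidence seen in it."""

    matched_len: int = 0
    evidence: set[Observation] = field(default_factory=set)
    chroms_seen: set[int] = field(default_factory=set)
    matched_seq: str = ""

    def accept(self, min_seed_len: int) -> bool:
        if self.matched_len < min_seed_len:
            return False
        if len(self.chroms_seen) > 1:
            return False
        seen: dict[Site, int] = {}
        for site, allele in self.evidence:
            if seen.setdefault(site, allele) != allele:
                return False
        return True


def _query_markers(maw: AugmentedMarkerArray, rng: SARange, ext: Extension) -> None:
    for row in rng.rows():
        for word in maw.markers_at_rank(row):
            chrom_id, ref_off, allele = decode_marker(word)
            ext.evidence.add(((chrom_id, ref_off), allele))
            ext.chroms_seen.add(chrom_id)


def scan_strand(
    index: FMIndexBundle, maw: AugmentedMarkerArray, seq: str, params: ScanParams, n_h: int
) -> list[Extension]:
    """Backward-scan one strand, returning every extension (accepted or not)."""
    extensions: list[Extension] = []
    rng = index.full_range()
    ext = Extension()

    def finish(current: SARange, at: int) -> None:
        # terminal window check: markers in the last partial window
        if ext.matched_len >= params.w and ext.matched_len % params.w != 0:
            if len(current) <= n_h:
                _query_markers(maw, current, ext)
        ext.matched_seq = seq[at + 1 : at + 1 + ext.matched_len]
        extensions.append(ext)

    pos = len(seq) - 1
    while pos >= 0:
        nxt = backward_step(index, rng, seq[pos])
        if nxt.empty:
            finish(rng, pos)
            rng = index.full_range()
            ext = Extension()
        else:
            rng = nxt
            ext.matched_len += 1
            if ext.matched_len % params.w == 0 and len(rng) <= n_h:
                _query_markers(maw, rng, ext)
        pos -= 1
    finish(rng, pos)
    return extensions


def genotype_read(
    index: FMIndexBundle,
    maw: AugmentedMarkerArray,
    read: str,
    params: ScanParams,
    read_ordinal: int = 0,
) -> list[Observation]:
    """Scan one read; return surviving (site, allele) evidence, one per site.

    The initial strand is drawn from a per-read deterministic RNG; the
    opposite strand is scanned only when no extension on the first strand
    reached ``min_seed_len``.  Sites observed with conflicting alleles
    across surviving extensions are dropped.
    """
    read = read.upper()
    if len(read) < params.min_seed_len:
        return []
    n_h = params.n_h if params.n_h is not None else index.n_docs
    rng = np.random.default_rng([params.strand_seed, read_ordinal])
    first = read if rng.integers(2) == 0 else reverse_complement(read)

    extensions = scan_strand(index, maw, first, params, n_h)
    if not any(e.matched_len >= params.min_seed_len for e in extensions):
        other = reverse_complement(read) if first == read else read
        extensions += scan_strand(index, maw, other, params, n_h)

    site_alleles: dict[Site, set[int]] = {}
    for ext in extensions:
        if not ext.accept(params.min_seed_len):
            continue
        for site, allele in ext.evidence:
            site_alleles.setdefault(site, set()).add(allele)
    return [
        (site, alleles.pop())
        for site, alleles in sorted(site_alleles.items())
        if len(alleles) == 1
    ]


@dataclass
class SiteTally:
    """Per-site evidence: k total observations, l of them reference."""

    site: Site
    k: int = 0
    l: int = 0
    alt_counts: Counter = field(default_factory=Counter)

    def add(self, allele: int) -> None:
        self.k += 1
        if allele == 0:
            self.l += 1
        else:
            self.alt_counts[allele] += 1

    def top_alt(self) -> int:
        """Most observed ALT index (smallest id on ties); 1 if none observed."""
        if not self.alt_counts:
            return 1
        best = max(self.alt_counts.values())
        return min(a for a, c in self.alt_counts.items() if c == best)


def tally_evidence(per_read_evidence: Iterable[Sequence[Observation]]) -> dict[Site, SiteTally]:
    """Aggregate deduplicated per-read observations into per-site tallies."""
    tallies: dict[Site, SiteTally] = {}
    for observations in per_read_evidence:
        for site, allele in observations:
            tallies.setdefault(site, SiteTally(site)).add(allele)
    return tallies


def scan_reads(
    index: FMIndexBundle,
    maw: AugmentedMarkerArray,
    reads: Iterable[str],
    params: ScanParams,
) -> dict[Site, SiteTally]:
    """Scan a read stream and tally evidence as it goes."""

    def stream() -> Iterator[list[Observation]]:
        for ordinal, read in enumerate(reads):
            yield genotype_read(index, maw, read, params, read_ordinal=ordinal)

    return tally_evidence(stream())


def genotype_likelihood(g: int, k: int, l: int, epsilon: float) -> float:
    """Likelihood of observing l reference alleles out of k given genotype g."""
    if g not in (0, 1, 2):
        raise ValueError("g must be 0, 1 or 2")
    if not 0 <= l <= k:
        raise ValueError("need 0 <= l <= k")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    ref_weight = (2 - g) * epsilon + g * (1.0 - epsilon)
    alt_weight = (2 - g) * (1.0 - epsilon) + g * epsilon
    return 0.5**k * ref_weight**l * alt_weight ** (k - l)


@dataclass
class GenotypeCall:
    """Called genotype at one site: g reference-allele copies in {0,1,2}."""

    site: Site
    g: int
    likelihoods: tuple[float, float, float]   # L(0), L(1), L(2)
    alt_allele: int                           # ALT index backing the non-REF copies


def call_diploid(
    tallies: dict[Site, SiteTally], epsilon: float = 0.01
) -> list[GenotypeCall]:
    """Maximum-likelihood diploid genotype per site; ties resolve toward REF.

    Sites with no evidence (k=0) have flat likelihoods and therefore call
    homozygous reference under the tie rule.
    """
    calls = []
    for site in sorted(tallies):
        t = tallies[site]
        lk = tuple(genotype_likelihood(g, t.k, t.l, epsilon) for g in (0, 1, 2))
        g = max(range(3), key=lambda gg: (lk[gg], gg))
        calls.append(GenotypeCall(site, g, lk, t.top_alt()))
    return calls


def call_haploid(tallies: dict[Site, SiteTally]) -> list[tuple[Site, int]]:
    """Most frequently observed allele per site; the reference wins ties."""
    calls = []
    for site in sorted(tallies):
        t = tallies[site]
        best_alt = t.top_alt() if t.alt_counts else 0
        n_alt = t.alt_counts[best_alt] if t.alt_counts else 0
        calls.append((site, 0 if t.l >= n_alt else best_alt))
    return calls


@dataclass
class EvalRow:
    stratum: str
    level: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalReport:
    level: str
    rows: list[EvalRow]

    def row(self, stratum: str) -> EvalRow:
        for r in self.rows:
            if r.stratum == stratum:
                return r
        raise KeyError(stratum)


def _haploid_confusion(called: int, true: int) -> tuple[int, int, int, int]:
    if called == 0 and true == 0:
        return 0, 0, 0, 1
    if called == 0:
        return 0, 0, 1, 0
    if true == 0:
        return 0, 1, 0, 0
    return (1, 0, 0, 0) if called == true else (0, 1, 1, 0)


def _alt_level_confusion(g_called: int, g_true: int) -> tuple[int, int, int, int]:
    # a diploid call is a pair of allele calls: g REF copies, 2-g ALT copies
    tp = fp = fn = tn = 0
    for _ in range(2 - g_called):          # ALT allele calls
        if g_true < 2:
            tp += 1
        else:
            fp += 1
    for _ in range(g_called):              # REF allele calls
        if g_true > 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, fn, tn


def evaluate_calls(
    calls,
    truth: dict[Site, int],
    level: str,
    classes: dict[Site, str] | None = None,
) -> EvalReport:
    """Score calls against truth at one level, stratified by variant class.

    ``level`` is ``haploid`` (calls are (site, allele) pairs, truth the true
    allele id), ``alt_allele`` or ``het_site`` (calls are
    :class:`GenotypeCall`, truth the true count of REF copies).  Truth sites
    missing from ``calls`` are treated as reference calls; a called site
    missing from truth is an error.  ``classes`` maps sites to
    'SNV'/'Indel'/'SV'; strata with no sites are omitted and 'All' always
    reported.
    """
    if level not in ("haploid", "alt_allele", "het_site"):
        raise ValueError(f"unknown evaluation level {level!r}")

    if level == "haploid":
        called_map: dict[Site, int] = dict(calls)
        default = 0
    else:
        called_map = {c.site: c.g for c in calls}
        default = 2
    for site in called_map:
        if site not in truth:
            raise ValueError(f"called site {site} missing from truth")

    strata: dict[str, list[int]] = {}
    for site, true_val in truth.items():
        called = called_map.get(site, default)
        if level == "haploid":
            conf = _haploid_confusion(called, true_val)
        elif level == "alt_allele":
            conf = _alt_level_confusion(called, true_val)
        else:
            is_het_call, is_het = called == 1, true_val == 1
            conf = (
                int(is_het_call and is_het),
                int(is_het_call and not is_het),
                int(is_het and not is_het_call),
                int(not is_het and not is_het_call),
            )
        names = {"All"}
        if classes and site in classes:
            names.add(classes[site])
        for name in names:
            acc = strata.setdefault(name, [0, 0, 0, 0])
            for j in range(4):
                acc[j] += conf[j]

    order = [s for s in ("SNV", "Indel", "SV", "All") if s in strata]
    return EvalReport(level, [EvalRow(s, level, *strata[s]) for s in order])


def write_calls_vcf(
    calls: list[GenotypeCall], panel: HaplotypePanel, out: str, sample: str = "donor"
) -> None:
    """Write diploid calls as VCF 4.2 with GT and log10-scaled GL per site."""
    header = pysam.VariantHeader()
    for name, seq in zip(panel.chrom_names, panel.reference_seqs):
        header.contigs.add(name, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GL", "G", "Float", "Log10-scaled genotype likelihoods")
    header.add_sample(sample)

    by_site = panel.variant_by_site()
    with pysam.VariantFile(out, "w", header=header) as vf:
        for call in sorted(calls, key=lambda c: c.site):
            v = by_site[call.site]
            rec = vf.new_record(
                contig=panel.chrom_names[v.chrom_id],
                start=v.ref_pos,
                alleles=(v.ref_allele, *v.alt_alleles),
            )
            a = call.alt_allele
            gt = {2: (0, 0), 1: (0, a), 0: (a, a)}[call.g]
            rec.samples[sample]["GT"] = gt
            rec.samples[sample].phased = False
            l0, l1, l2 = call.likelihoods
            rec.samples[sample]["GL"] = [
                math.log10(max(x, 1e-300)) for x in (l2, l1, l0)
            ]
            vf.write(rec)
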