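"""Haplotype panel model: reference FASTA + phased VCF -> concatenated pangenome text.

A panel is a reference sequence T_0 plus n alternative haplotype sequences
T_1..T_n, interrelated through the multiple alignment implied by a phased VCF.
This module loads the panel, materializes the concatenated document text
(T_0 T_1 ... T_n, each document terminated by a separator), and extracts the
dense marker map M: for every variant and every document copy, the single
text position that "marks" the polymorphic locus, encoded as a 64-bit word
(chromosome, reference offset, allele index).

Marking rules:

* substitution or run of consecutive substitutions: the first substituted
  base in each document copy is marked;
* insertion/deletion: the base immediately left of the indel in the
  alignment is marked in every document (for left-anchored VCF records this
  is the record's own first base).  The mark covers exactly one position no
  matter how long the allele is, so long and short alleles contribute
  evidence symmetrically.

Reference copies of a locus carry allele id 0 ("no edit"); carriers carry
the 1-based ALT index, which resolves to a concrete edit through the
:class:`EditTable`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF
from pyfaidx import Fasta

#: Document separator. Lexicographically below every DNA symbol (ASCII 0x24),
#: so each document's suffixes never compare past its own terminator.
SEPARATOR = "$"

# 64-bit marker word layout: 12-bit chromosome | 48-bit offset | 4-bit allele.
CHROM_BITS = 12
OFFSET_BITS = 48
ALLELE_BITS = 4
_MAX_CHROM = 1 << CHROM_BITS
_MAX_OFFSET = 1 << OFFSET_BITS
_MAX_ALLELE = 1 << ALLELE_BITS

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


def encode_marker(chrom_id: int, ref_offset: int, allele_id: int) -> int:
    """Pack (chromosome, reference offset, allele index) into a 64-bit word.

    The encoding is order-preserving in (chrom_id, ref_offset) when words are
    compared as unsigned integers; the allele occupies the lowest bits.
    """
    if not 0 <= chrom_id < _MAX_CHROM:
        raise ValueError(f"chrom_id {chrom_id} does not fit in {CHROM_BITS} bits")
    if not 0 <= ref_offset < _MAX_OFFSET:
        raise ValueError(f"ref_offset {ref_offset} does not fit in {OFFSET_BITS} bits")
    if not 0 <= allele_id < _MAX_ALLELE:
        raise ValueError(f"allele_id {allele_id} does not fit in {ALLELE_BITS} bits")
    return (chrom_id << (OFFSET_BITS + ALLELE_BITS)) | (ref_offset << ALLELE_BITS) | allele_id


def decode_marker(word: int) -> tuple[int, int, int]:
    """Inverse of :func:`encode_marker`."""
    allele_id = word & (_MAX_ALLELE - 1)
    ref_offset = (word >> ALLELE_BITS) & (_MAX_OFFSET - 1)
    chrom_id = word >> (OFFSET_BITS + ALLELE_BITS)
    return chrom_id, ref_offset, allele_id


@dataclass
class VariantRecord:
    """One polymorphic site: REF plus up to 15 ALT alleles and per-haplotype calls."""

    chrom_id: int
    ref_pos: int                 # 0-based offset on the reference chromosome
    ref_allele: str
    alt_alleles: list[str]
    genotypes: np.ndarray        # per-haplotype allele index, 0 = REF

    @property
    def ref_end(self) -> int:
        return self.ref_pos + len(self.ref_allele)

    def allele_seq(self, allele_id: int) -> str:
        return self.ref_allele if allele_id == 0 else self.alt_alleles[allele_id - 1]

    def variant_class(self, allele_id: int = 1) -> str:
        """Stratification class of one ALT: 'SNV', 'Indel' (<= 50 bp) or 'SV'."""
        alt = self.alt_alleles[allele_id - 1]
        if len(self.ref_allele) == 1 and len(alt) == 1:
            return "SNV"
        return "Indel" if abs(len(alt) - len(self.ref_allele)) <= 50 else "SV"


@dataclass
class HaplotypePanel:
    """Reference chromosomes plus phased variants for n haplotypes (T_1..T_n)."""

    chrom_names: list[str]
    reference_seqs: list[str]
    variants: list[VariantRecord]
    n_haplotypes: int
    skip_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_docs(self) -> int:
        """Documents in the concatenated text: the panelists plus T_0."""
        return self.n_haplotypes + 1

    def variants_on(self, chrom_id: int) -> list[VariantRecord]:
        return [v for v in self.variants if v.chrom_id == chrom_id]

    def variant_by_site(self) -> dict[tuple[int, int], VariantRecord]:
        return {(v.chrom_id, v.ref_pos): v for v in self.variants}

    def doc_allele(self, variant: VariantRecord, doc: int) -> int:
        """Allele carried by document ``doc`` (0 = T_0, 1..n = panelists)."""
        return 0 if doc == 0 else int(variant.genotypes[doc - 1])


@dataclass
class ConcatenatedText:
    """T_0..T_n concatenated, with per-position provenance back to T_0 columns."""

    sequence: str
    doc_bounds: list[tuple[int, int]]          # [start, end); sequence[end-1] == SEPARATOR
    prov_hap: np.ndarray                       # document index, -0.. ; separators keep their doc
    prov_chrom: np.ndarray                     # chromosome id, -1 at separators
    prov_ref: np.ndarray                       # projected reference offset, -1 at separators
    chrom_segments: dict[tuple[int, int], tuple[int, int]]  # (doc, chrom) -> [gstart, gend)

    def __len__(self) -> int:
        return len(self.sequence)

    def provenance(self, i: int) -> tuple[int, int, int]:
        """(document, chromosome, projected reference offset) at global offset i."""
        return int(self.prov_hap[i]), int(self.prov_chrom[i]), int(self.prov_ref[i])


@dataclass
class EditTable:
    """Decodes edit identifiers. Id 0 is the null operation and is never stored."""

    entries: dict[int, tuple[str, str, int]] = field(default_factory=dict)
    #: (chrom_id, ref_pos, alt_index) -> edit id
    index: dict[tuple[int, int, int], int] = field(default_factory=dict)

    def add(self, key: tuple[int, int, int], kind: str, alt_seq: str, ref_span: int) -> int:
        eid = len(self.entries) + 1
        self.entries[eid] = (kind, alt_seq, ref_span)
        self.index[key] = eid
        return eid


@dataclass
class DenseMarkerMap:
    """Marker map M over global text offsets; at most one marker per position."""

    marks: dict[int, int]        # global offset -> 64-bit marker word
    total_sites: int             # distinct marked (chromosome, reference offset) loci

    def get(self, offset: int) -> int | None:
        return self.marks.get(offset)

    def markers_at(self, offset: int) -> list[int]:
        w = self.marks.get(offset)
        return [] if w is None else [w]

    def __len__(self) -> int:
        return len(self.marks)


def _extract_calls(record, n_expected: int | None, require_phased: bool) -> np.ndarray:
    """Flatten a cyvcf2 record's GT fields into one allele index per haplotype."""
    calls: list[int] = []
    for sample_gt in record.genotypes:
        alleles, phased = sample_gt[:-1], sample_gt[-1]
        if any(a < 0 for a in alleles):
            raise ValueError(f"missing genotype at {record.CHROM}:{record.POS}")
        if len(alleles) > 1 and require_phased and not phased:
            raise ValueError(f"unphased genotype at {record.CHROM}:{record.POS}")
        calls.extend(int(a) for a in alleles)
    gt = np.asarray(calls, dtype=np.int16)
    if n_expected is not None and len(gt) != n_expected:
        raise ValueError(
            f"inconsistent haplotype count at {record.CHROM}:{record.POS}: "
            f"{len(gt)} != {n_expected}"
        )
    return gt


def parse_panel(
    vcf_source: str | os.PathLike,
    fasta_source: str | os.PathLike,
    min_af: float | None = 0.0,
    require_phased: bool = True,
) -> HaplotypePanel:
    """Load a haplotype panel from a phased VCF and its reference FASTA.

    Variants are kept only if their minor-allele frequency among the
    panelists (T_0 excluded) strictly exceeds ``min_af``.  Records failing
    REF-consistency, overlapping an earlier record, or having more than 15
    ALT alleles are skipped and tallied in ``panel.skip_counts``.

    Raises if a VCF chromosome is absent from the FASTA, if diploid GTs are
    unphased (unless ``require_phased=False``), or if records are unsorted.
    """
    fa = Fasta(str(fasta_source), as_raw=True, sequence_always_upper=True)
    chrom_names = list(fa.keys())
    chrom_ids = {name: i for i, name in enumerate(chrom_names)}
    reference_seqs = [str(fa[name][:]) for name in chrom_names]

    vcf = VCF(str(vcf_source))
    header_contigs = [c for c in vcf.seqnames if c in chrom_ids]
    if [chrom_ids[c] for c in header_contigs] != sorted(chrom_ids[c] for c in header_contigs):
        raise ValueError("VCF header contig order differs from FASTA order")

    skip = {"ref_mismatch": 0, "overlap": 0, "too_many_alts": 0, "below_min_af": 0}
    variants: list[VariantRecord] = []
    n_hap: int | None = None
    prev_end: dict[int, int] = {}
    prev_pos: dict[int, int] = {}

    for rec in vcf:
        if rec.CHROM not in chrom_ids:
            raise ValueError(f"VCF chromosome {rec.CHROM!r} missing from FASTA")
        cid = chrom_ids[rec.CHROM]
        pos = rec.POS - 1  # 0-based internally
        if pos < prev_pos.get(cid, -1):
            raise ValueError(f"VCF not sorted at {rec.CHROM}:{rec.POS}")
        prev_pos[cid] = pos

        gt = _extract_calls(rec, n_hap, require_phased)
        if n_hap is None:
            n_hap = len(gt)

        ref = rec.REF.upper()
        alts = [a.upper() for a in rec.ALT]
        if any(not a or any(ch not in "ACGTN" for ch in a) for a in alts):
            raise ValueError(f"symbolic or empty ALT at {rec.CHROM}:{rec.POS}")
        if len(alts) > _MAX_ALLELE - 1:
            skip["too_many_alts"] += 1
            continue
        if reference_seqs[cid][pos : pos + len(ref)] != ref:
            skip["ref_mismatch"] += 1
            continue
        if pos < prev_end.get(cid, 0):
            skip["overlap"] += 1
            continue

        # minor-allele frequency over the panelists; min_af=None disables the filter
        if min_af is not None:
            counts = np.bincount(gt, minlength=len(alts) + 1)
            maf = 1.0 - counts.max() / len(gt)
            if not maf > min_af:
                skip["below_min_af"] += 1
                continue

        prev_end[cid] = pos + len(ref)
        variants.append(VariantRecord(cid, pos, ref, alts, gt))

    if n_hap is None:
        n_hap = 2 * len(vcf.samples)
    vcf.close()
    return HaplotypePanel(chrom_names, reference_seqs, variants, n_hap, skip)


def materialize_text(panel: HaplotypePanel) -> ConcatenatedText:
    """Build the concatenated text T = T_0 $ T_1 $ ... T_n $ with provenance.

    T_0 is the unedited reference; every T_i applies exactly its GT-selected
    alleles.  Each non-separator position records the reference column it
    aligns to; positions inside insertions project to the insertion's
    left-flank column, so projection is monotone within a document.
    """
    parts: list[str] = []
    hap_chunks: list[np.ndarray] = []
    chrom_chunks: list[np.ndarray] = []
    ref_chunks: list[np.ndarray] = []
    doc_bounds: list[tuple[int, int]] = []
    chrom_segments: dict[tuple[int, int], tuple[int, int]] = {}
    g = 0

    for doc in range(panel.n_docs):
        doc_start = g
        for cid in range(len(panel.chrom_names)):
            ref = panel.reference_seqs[cid]
            seg_start = g
            chunk_parts: list[str] = []
            proj_parts: list[np.ndarray] = []
            cursor = 0
            for v in panel.variants_on(cid):
                a = panel.doc_allele(v, doc)
                if a == 0:
                    continue
                alt = v.alt_alleles[a - 1]
                chunk_parts.append(ref[cursor : v.ref_pos])
                proj_parts.append(np.arange(cursor, v.ref_pos, dtype=np.int64))
                chunk_parts.append(alt)
                proj_parts.append(
                    np.minimum(v.ref_pos + np.arange(len(alt), dtype=np.int64), v.ref_end - 1)
                )
                cursor = v.ref_end
            chunk_parts.append(ref[cursor:])
            proj_parts.append(np.arange(cursor, len(ref), dtype=np.int64))

            chunk = "".join(chunk_parts)
            if not chunk:
                raise ValueError(
                    f"document {doc} chromosome {panel.chrom_names[cid]} is empty"
                )
            parts.append(chunk)
            proj = np.concatenate(proj_parts) if proj_parts else np.empty(0, np.int64)
            ref_chunks.append(proj)
            hap_chunks.append(np.full(len(chunk), doc, dtype=np.int32))
            chrom_chunks.append(np.full(len(chunk), cid, dtype=np.int32))
            g += len(chunk)
            chrom_segments[(doc, cid)] = (seg_start, g)
        # document terminator
        parts.append(SEPARATOR)
        hap_chunks.append(np.full(1, doc, dtype=np.int32))
        chrom_chunks.append(np.full(1, -1, dtype=np.int32))
        ref_chunks.append(np.full(1, -1, dtype=np.int64))
        g += 1
        doc_bounds.append((doc_start, g))

    return ConcatenatedText(
        sequence="".join(parts),
        doc_bounds=doc_bounds,
        prov_hap=np.concatenate(hap_chunks),
        prov_chrom=np.concatenate(chrom_chunks),
        prov_ref=np.concatenate(ref_chunks),
        chrom_segments=chrom_segments,
    )


def haplotype_sequence(panel: HaplotypePanel, doc: int) -> str:
    """One document's sequence (chromosomes concatenated, no separator).

    ``doc`` 0 is the unedited reference T_0; ``doc`` i > 0 applies panelist
    i's GT-selected alleles.
    """
    parts: list[str] = []
    for cid in range(len(panel.chrom_names)):
        ref = panel.reference_seqs[cid]
        cursor = 0
        for v in panel.variants_on(cid):
            a = panel.doc_allele(v, doc)
            if a == 0:
                continue
            parts.append(ref[cursor : v.ref_pos])
            parts.append(v.alt_alleles[a - 1])
            cursor = v.ref_end
        parts.append(ref[cursor:])
    return "".join(parts)


def _marked_column(v: VariantRecord) -> int | None:
    """Reference column that carries the mark for variant ``v``.

    Substitution runs are marked at their first base.  Indels are marked at
    the base just left of the indel: for left-anchored records (shared first
    base, the VCF norm) that is the record's own position; otherwise the
    column to the left, which does not exist at a chromosome start.
    """
    if all(len(a) == len(v.ref_allele) for a in v.alt_alleles):
        return v.ref_pos
    if all(a[0] == v.ref_allele[0] for a in v.alt_alleles):
        return v.ref_pos
    return v.ref_pos - 1 if v.ref_pos > 0 else None


def extract_markers(
    panel: HaplotypePanel, text: ConcatenatedText
) -> tuple[DenseMarkerMap, EditTable]:
    """Place one marker per variant per document copy; build the edit table.

    Every mark covers exactly one text position.  Reference copies get
    allele id 0; carriers get their ALT index, decodable through the edit
    table.  Variants with no left-flank base (unanchored indel at a
    chromosome start) are skipped and tallied in ``panel.skip_counts``.
    """
    marks: dict[int, int] = {}
    table = EditTable()
    sites: set[tuple[int, int]] = set()
    panel.skip_counts.setdefault("flankless", 0)

    for v in panel.variants:
        mcol = _marked_column(v)
        if mcol is None:
            panel.skip_counts["flankless"] += 1
            continue
        for j, alt in enumerate(v.alt_alleles, start=1):
            if len(alt) == len(v.ref_allele):
                kind = SUBSTITUTION
            elif len(alt) > len(v.ref_allele):
                kind = INSERTION
            else:
                kind = DELETION
            table.add((v.chrom_id, v.ref_pos, j), kind, alt, len(v.ref_allele))
        sites.add((v.chrom_id, v.ref_pos))

        for doc in range(panel.n_docs):
            seg = text.chrom_segments[(doc, v.chrom_id)]
            proj = text.prov_ref[seg[0] : seg[1]]
            k = int(np.searchsorted(proj, mcol, side="left"))
            if k >= len(proj) or proj[k] != mcol:
                # column elided in this document (adjacent-variant corner case)
                continue
            a = panel.doc_allele(v, doc)
            marks[seg[0] + k] = encode_marker(v.chrom_id, v.ref_pos, a)

    return DenseMarkerMap(marks, len(sites)), table
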