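"""Shared fixtures: toy panels on disk, random simulated panels, small indexes."""

from __future__ import annotations

import numpy as np
import pytest

import markergt as mg

TOY_FASTA = ">chr1\nACGTA\n"
TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=5>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t3\t.\tG\tT\t.\tPASS\t.\tGT\t1|0
"""


def write_panel_files(tmp_path, fasta_text: str, vcf_text: str):
    fa = tmp_path / "ref.fa"
    vcf = tmp_path / "panel.vcf"
    fa.write_text(fasta_text)
    vcf.write_text(vcf_text)
    return str(vcf), str(fa)


@pytest.fixture
def toy_files(tmp_path):
    """5 bp reference with one SNV (chr1:3 G>T) carried by haplotype 1 of 2."""
    return write_panel_files(tmp_path, TOY_FASTA, TOY_VCF)


@pytest.fixture
def toy_panel(toy_files):
    vcf, fa = toy_files
    return mg.parse_panel(vcf, fa, min_af=0.0)


def make_hap_panel(ref: str, variants, n_haplotypes: int) -> mg.HaplotypePanel:
    """Directly construct a single-chromosome panel from (pos, ref, alts, gts)."""
    records = [
        mg.VariantRecord(0, pos, r, list(alts), np.asarray(gts, dtype=np.int16))
        for pos, r, alts, gts in variants
    ]
    return mg.HaplotypePanel(["chr1"], [ref], records, n_haplotypes)


def random_panel(tmp_path, seed: int, **overrides) -> mg.HaplotypePanel:
    """A small simulated panel, written to disk and re-parsed without filtering."""
    cfg = mg.SimConfig(
        chrom_len=overrides.pop("chrom_len", 2000),
        n_haplotypes=overrides.pop("n_haplotypes", 5),
        seed=seed,
        **overrides,
    )
    out = tmp_path / f"sim{seed}"
    fa, vcf, _ = mg.simulate_panel(cfg, out)
    return mg.parse_panel(vcf, fa, min_af=None)


# ---------------------------------------------------------------- oracles


def naive_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_count(text: str, q: str) -> int:
    count = start = 0
    while True:
        hit = text.find(q, start)
        if hit < 0:
            return count
        count += 1
        start = hit + 1


def dense_marker_list(m: mg.DenseMarkerMap, sa, i: int) -> list[int]:
    """Definition-1 entry at rank i, straight from M[SA[i]]."""
    word = m.get(int(sa[i]))
    return [] if word is None else [word]


def smeared_marker_list(m: mg.DenseMarkerMap, sa, i: int, w: int, text: str) -> list[int]:
    """Definition-2 entry at rank i: window scan clipped at the separator."""
    out = []
    for q in range(int(sa[i]), min(int(sa[i]) + w + 1, len(text))):
        if text[q] == mg.panel.SEPARATOR:
            break
        word = m.get(q)
        if word is not None:
            out.append(word)
    return out


def naive_marker_query(text: str, m: mg.DenseMarkerMap, q: str) -> set[tuple[int, int]]:
    """Locate every occurrence of q and report markers its span overlaps."""
    found = set()
    start = 0
    while True:
        hit = text.find(q, start)
        if hit < 0:
            return found
        for off in range(hit, hit + len(q)):
            word = m.get(off)
            if word is not None:
                found.add((off, word))
        start = hit + 1
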