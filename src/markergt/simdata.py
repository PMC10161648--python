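"""Synthetic panels, diploid donors and error-bearing reads with full truth.

The generator emulates the experimental inputs of a pangenome genotyping
study at desk scale: a phased multi-haplotype panel with SNVs and short
indels at configurable rates, a diploid donor drawn from (and optionally
held out of) the panel, and fixed-length single-end reads with uniform
substitution errors and known placements.  Defaults are 150 bp reads at
25-fold coverage with a 1% error rate.  All randomness flows from one seed;
a fixed seed reproduces byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .panel import HaplotypePanel, VariantRecord, haplotype_sequence

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulation.

    Rates are events per reference base.  Indel lengths are geometric with
    the given mean, truncated at ``indel_max_len``; means beyond 50 bp let
    the generator produce the long-indel ("SV") stratum.  Carrier counts per
    variant are uniform over 1..n_haplotypes-1 unless ``af_sampler`` (a
    callable mapping an RNG to a carrier fraction) is supplied.
    """

    n_chroms: int = 1
    chrom_len: int = 50_000
    n_haplotypes: int = 10
    snv_rate: float = 0.01
    indel_rate: float = 0.001
    indel_len_mean: float = 3.0
    indel_max_len: int = 80
    af_sampler: Callable | None = None
    read_len: int = 150
    coverage: float = 25.0
    error_rate: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.snv_rate, self.indel_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic files."""

    variants: list[dict] = field(default_factory=list)   # chrom, pos0, ref, alt, carriers
    donor_genotypes: dict = field(default_factory=dict)  # (chrom_id, pos0) -> REF copies
    placements: list[dict] = field(default_factory=list) # name, hap, start, strand
    n_thinned: int = 0


def _random_reference(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def simulate_panel(
    config: SimConfig, out_dir: str | os.PathLike
) -> tuple[str, str, TruthSet]:
    """Write ref.fa and panel.vcf under ``out_dir``; return their paths + truth.

    Variants are placed without overlap (candidates colliding with an earlier
    record are thinned and counted in ``truth.n_thinned``); the phased VCF
    lists each haplotype as one haploid sample and re-parses with zero skips.
    """
    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, "ref.fa")
    vcf_path = os.path.join(out_dir, "panel.vcf")
    truth = TruthSet()
    n_h = config.n_haplotypes

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    refs = [_random_reference(rng, config.chrom_len) for _ in chrom_names]

    vcf_lines = [
        "##fileformat=VCFv4.2",
        *(
            f"##contig=<ID={name},length={config.chrom_len}>"
            for name in chrom_names
        ),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"H{i + 1}" for i in range(n_h)),
    ]

    for cid, (name, ref) in enumerate(zip(chrom_names, refs)):
        n_snv = rng.binomial(config.chrom_len, config.snv_rate)
        n_indel = rng.binomial(config.chrom_len, config.indel_rate)
        n_total = n_snv + n_indel
        if n_total == 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(1, config.chrom_len - 1), size=min(n_total, config.chrom_len - 2), replace=False)
        )
        is_indel = np.zeros(len(positions), dtype=bool)
        is_indel[rng.permutation(len(positions))[:n_indel]] = True

        prev_end = 0
        for pos, indel in zip(positions, is_indel):
            pos = int(pos)
            if pos <= prev_end:
                truth.n_thinned += 1
                continue
            if indel:
                length = min(int(rng.geometric(1.0 / config.indel_len_mean)), config.indel_max_len)
                if rng.integers(2) == 0:  # insertion
                    ins = rng.choice(BASES, size=length).tobytes().decode("ascii")
                    ref_a, alt_a = ref[pos], ref[pos] + ins
                else:                     # deletion
                    length = min(length, config.chrom_len - 2 - pos)
                    if length < 1:
                        truth.n_thinned += 1
                        continue
                    ref_a, alt_a = ref[pos : pos + length + 1], ref[pos]
            else:
                ref_a = ref[pos]
                alt_a = _other_base(rng, ref_a)
            prev_end = pos + len(ref_a)

            if config.af_sampler is not None:
                frac = float(config.af_sampler(rng))
                n_carriers = min(n_h - 1, max(1, round(frac * n_h)))
            else:
                n_carriers = int(rng.integers(1, n_h)) if n_h > 1 else 1
            carriers = sorted(int(c) for c in rng.choice(n_h, size=n_carriers, replace=False))
            gts = ["1" if h in carriers else "0" for h in range(n_h)]
            vcf_lines.append(
                f"{name}\t{pos + 1}\t.\t{ref_a}\t{alt_a}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
            truth.variants.append(
                {"chrom": name, "chrom_id": cid, "pos0": pos, "ref": ref_a, "alt": alt_a,
                 "carriers": carriers}
            )

    with open(fasta_path, "w") as fh:
        for name, ref in zip(chrom_names, refs):
            fh.write(f">{name}\n")
            for i in range(0, len(ref), 70):
                fh.write(ref[i : i + 70] + "\n")
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(vcf_lines) + "\n")
    return fasta_path, vcf_path, truth


@dataclass
class DiploidDonor:
    """A donor = two panel haplotypes, with per-site truth genotypes."""

    hap_indices: tuple[int, int]         # panelist indices, 0-based
    sequences: tuple[str, str]
    genotypes: dict[tuple[int, int], int]  # site -> REF copies (0, 1 or 2)
    index_panel: HaplotypePanel          # panel to index (donor held out if requested)


def drop_haplotypes(panel: HaplotypePanel, drop: set[int]) -> HaplotypePanel:
    """Panel with the given panelist columns removed.

    Sites left without any carrier have a uniform alignment column and are
    dropped: they can no longer be marked.
    """
    keep = [h for h in range(panel.n_haplotypes) if h not in drop]
    variants = []
    for v in panel.variants:
        gt = v.genotypes[keep]
        if np.any(gt != 0):  # carrier-less columns are uniform, hence unmarked
            variants.append(VariantRecord(v.chrom_id, v.ref_pos, v.ref_allele, v.alt_alleles, gt))
    return HaplotypePanel(
        panel.chrom_names, panel.reference_seqs, variants, len(keep), dict(panel.skip_counts)
    )


def simulate_diploid_donor(
    panel: HaplotypePanel,
    leave_out: bool = True,
    seed: int = 1,
    hap_pair: tuple[int, int] | None = None,
) -> DiploidDonor:
    """Pick two panel haplotypes as the donor; optionally hold them out.

    The truth genotype at each panel site is the donor's number of REF
    copies.  With ``leave_out``, the returned ``index_panel`` excludes the
    donor haplotypes (and any site left without a carrier, whose alignment
    column is then uniform).
    """
    if panel.n_haplotypes < 2:
        raise ValueError("panel must contain at least two haplotypes")
    if hap_pair is None:
        rng = np.random.default_rng(seed)
        pair = tuple(int(h) for h in rng.choice(panel.n_haplotypes, size=2, replace=False))
    else:
        pair = hap_pair
    a, b = pair
    seqs = (haplotype_sequence(panel, a + 1), haplotype_sequence(panel, b + 1))
    genotypes = {
        (v.chrom_id, v.ref_pos): int(v.genotypes[a] == 0) + int(v.genotypes[b] == 0)
        for v in panel.variants
    }
    index_panel = drop_haplotypes(panel, set(pair)) if leave_out else panel
    return DiploidDonor(pair, seqs, genotypes, index_panel)


def simulate_reads(
    donor_seqs: tuple[str, ...] | list[str],
    read_len: int = 150,
    coverage: float = 25.0,
    error_rate: float = 0.01,
    seed: int = 1,
    out_fastq: str | os.PathLike | None = None,
) -> tuple[list[str], TruthSet]:
    """Uniformly placed fixed-length reads from both haplotypes and strands.

    Read count is coverage * total_length / read_len (rounded).  Errors are
    independent per-base substitutions; qualities are constant 'I'.  Returns
    the read sequences and their truth placements, and writes a FASTQ when
    ``out_fastq`` is given.
    """
    from .genotyping import reverse_complement

    rng = np.random.default_rng(seed)
    for s in donor_seqs:
        if len(s) < read_len:
            raise ValueError("read_len exceeds a donor sequence length")
    total_len = sum(len(s) for s in donor_seqs)
    n_reads = int(round(coverage * total_len / read_len))
    truth = TruthSet()
    reads: list[str] = []

    for i in range(n_reads):
        hap = int(rng.integers(len(donor_seqs)))
        src = donor_seqs[hap]
        start = int(rng.integers(0, len(src) - read_len + 1))
        strand = "+" if rng.integers(2) == 0 else "-"
        seq = src[start : start + read_len]
        if strand == "-":
            seq = reverse_complement(seq)
        if error_rate > 0:
            err = np.flatnonzero(rng.random(read_len) < error_rate)
            if len(err):
                chars = list(seq)
                for j in err:
                    chars[j] = _other_base(rng, chars[j])
                seq = "".join(chars)
        reads.append(seq)
        truth.placements.append({"name": f"read{i}", "hap": hap, "start": start, "strand": strand})

    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for p, seq in zip(truth.placements, reads):
                fh.write(f"@{p['name']}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads, truth


def write_truth_json(truth: TruthSet, path: str | os.PathLike) -> None:
    payload = asdict(truth)
    payload["donor_genotypes"] = {
        f"{c}:{p}": g for (c, p), g in truth.donor_genotypes.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
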