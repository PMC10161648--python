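"""The on-disk index: text, suffix array, FM structures and smeared markers.

One directory holds versioned little-endian binary artifacts plus a JSON
manifest.  Bitvectors are packed 8 bits per byte (little bit order), marker
payloads are 64-bit words, and the suffix array is int64.  Loading is
bit-exact: saving a loaded index reproduces identical artifact bytes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .fmcore import FMIndexBundle, build_fm_index, build_suffix_array
from .markers import (
    AugmentedMarkerArray,
    SparseMultimap,
    build_augmented_marker_array,
)
from .panel import (
    ConcatenatedText,
    DenseMarkerMap,
    EditTable,
    HaplotypePanel,
    VariantRecord,
    extract_markers,
    materialize_text,
)

FORMAT_VERSION = 1


def _pack_bits(bits: np.ndarray) -> bytes:
    return np.packbits(bits.astype(np.uint8), bitorder="little").tobytes()


def _unpack_bits(raw: bytes, n: int) -> np.ndarray:
    return np.unpackbits(np.frombuffer(raw, np.uint8), bitorder="little")[:n].astype(bool)


@dataclass
class MarkerIndex:
    """Everything needed to scan reads: FM-index, MA^w, and panel metadata."""

    panel: HaplotypePanel
    fm: FMIndexBundle
    dense: DenseMarkerMap
    maw: AugmentedMarkerArray
    edit_table: EditTable
    w: int
    min_af: float | None = None
    text: ConcatenatedText | None = None

    @property
    def n_h(self) -> int:
        """Haplotype documents in the index, T_0 included."""
        return self.fm.n_docs

    @classmethod
    def build(
        cls, panel: HaplotypePanel, w: int = 19, min_af: float | None = None
    ) -> "MarkerIndex":
        text = materialize_text(panel)
        dense, edits = extract_markers(panel, text)
        sa = build_suffix_array(text.sequence)
        fm = build_fm_index(text.sequence, sa, n_docs=panel.n_docs)
        maw = build_augmented_marker_array(dense, sa, w, text)
        return cls(panel, fm, dense, maw, edits, w, min_af, text)

    def save(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        d = str(out_dir)
        sm = self.maw.sparse

        with open(os.path.join(d, "text.bin"), "wb") as fh:
            fh.write(self.fm.text.encode("ascii"))
        self.fm.sa.astype("<i8").tofile(os.path.join(d, "sa.bin"))
        for name, bits in (("maw_s", sm.s), ("maw_e", sm.e), ("maw_b", sm.b)):
            with open(os.path.join(d, f"{name}.bin"), "wb") as fh:
                fh.write(_pack_bits(bits))
        sm.x.astype("<u8").tofile(os.path.join(d, "maw_x.bin"))

        offs = np.fromiter(sorted(self.dense.marks), dtype="<i8")
        words = np.fromiter((self.dense.marks[int(o)] for o in offs), dtype="<u8")
        offs.tofile(os.path.join(d, "m_offsets.bin"))
        words.tofile(os.path.join(d, "m_words.bin"))

        with open(os.path.join(d, "ref.fa"), "w") as fh:
            for name, seq in zip(self.panel.chrom_names, self.panel.reference_seqs):
                fh.write(f">{name}\n{seq}\n")
        with open(os.path.join(d, "variants.tsv"), "w") as fh:
            for v in self.panel.variants:
                fh.write(
                    f"{v.chrom_id}\t{v.ref_pos}\t{v.ref_allele}\t"
                    f"{','.join(v.alt_alleles)}\t"
                    f"{','.join(str(int(g)) for g in v.genotypes)}\n"
                )
        with open(os.path.join(d, "edits.json"), "w") as fh:
            json.dump(
                {
                    "entries": {str(k): list(v) for k, v in self.edit_table.entries.items()},
                    "index": [[list(k), v] for k, v in self.edit_table.index.items()],
                },
                fh,
            )
        manifest = {
            "format_version": FORMAT_VERSION,
            "alphabet": "".join(self.fm.alphabet),
            "w": self.w,
            "min_af": self.min_af,
            "n_docs": self.fm.n_docs,
            "n_haplotypes": self.panel.n_haplotypes,
            "chrom_names": self.panel.chrom_names,
            "text_len": self.fm.n,
            "x_len": int(len(sm.x)),
            "total_sites": self.dense.total_sites,
        }
        with open(os.path.join(d, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, in_dir: str | os.PathLike) -> "MarkerIndex":
        d = str(in_dir)
        with open(os.path.join(d, "manifest.json")) as fh:
            man = json.load(fh)
        if man["format_version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported index format version {man['format_version']}")
        n, x_len = man["text_len"], man["x_len"]

        with open(os.path.join(d, "text.bin"), "rb") as fh:
            text = fh.read().decode("ascii")
        sa = np.fromfile(os.path.join(d, "sa.bin"), dtype="<i8")
        fm = build_fm_index(text, sa, n_docs=man["n_docs"])

        def bits(name: str, length: int) -> np.ndarray:
            with open(os.path.join(d, f"{name}.bin"), "rb") as fh:
                return _unpack_bits(fh.read(), length)

        sm = SparseMultimap(
            bits("maw_s", n),
            bits("maw_e", n),
            np.fromfile(os.path.join(d, "maw_x.bin"), dtype="<u8"),
            bits("maw_b", x_len),
        )
        maw = AugmentedMarkerArray(man["w"], sm)

        offs = np.fromfile(os.path.join(d, "m_offsets.bin"), dtype="<i8")
        words = np.fromfile(os.path.join(d, "m_words.bin"), dtype="<u8")
        dense = DenseMarkerMap(
            {int(o): int(wd) for o, wd in zip(offs, words)}, man["total_sites"]
        )

        chrom_names, ref_seqs = [], []
        with open(os.path.join(d, "ref.fa")) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    chrom_names.append(line[1:])
                    ref_seqs.append("")
                else:
                    ref_seqs[-1] += line
        variants = []
        with open(os.path.join(d, "variants.tsv")) as fh:
            for line in fh:
                cid, pos, ref, alts, gts = line.rstrip("\n").split("\t")
                variants.append(
                    VariantRecord(
                        int(cid),
                        int(pos),
                        ref,
                        alts.split(","),
                        np.array([int(g) for g in gts.split(",")], dtype=np.int16),
                    )
                )
        panel = HaplotypePanel(chrom_names, ref_seqs, variants, man["n_haplotypes"])
        with open(os.path.join(d, "edits.json")) as fh:
            raw = json.load(fh)
        edits = EditTable(
            entries={int(k): tuple(v) for k, v in raw["entries"].items()},
            index={tuple(k): v for k, v in raw["index"]},
        )
        return cls(panel, fm, dense, maw, edits, man["w"], man["min_af"], text=None)
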