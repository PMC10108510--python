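"""Indexed access to GTB files: block location, O(1) genotype addressing,
region/subject extraction, allele-frequency filtering, VCF/BGZF output.

Within a decompressed block the genotype payload is addressed without any
row materialization: the m-th variant starts at

    P_m = m * ceil(N/l)                          if m <  n_biallelic
          n_biallelic * ceil(N/l) + (m - n_biallelic) * N   otherwise

(N subjects, group width l = 3 phased / 4 unphased), and subject n of a
biallelic variant lives in digit ``n mod l`` of the packed byte at
``P_m + floor(n/l)``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from . import codec
from .clm import ordered_imap
from .compressors import get_compressor
from .gtb import BLOCK_HAS_IDS, GTBManager, GTBNode, GTBTree, read_header

log = logging.getLogger(__name__)


class QueryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# addressing

def variant_pointer(m: int, n_biallelic: int, n_subjects: int, l: int) -> int:
    """Start offset of variant ``m`` inside a block's genotype payload."""
    if m < 0:
        raise IndexError("variant index must be non-negative")
    width = -(-n_subjects // l)
    if m < n_biallelic:
        return m * width
    return n_biallelic * width + (m - n_biallelic) * n_subjects


@dataclass(frozen=True)
class SubjectTriple:
    """(index, groupIndex, codeIndex) address of subject n at group width l."""
    index: int
    group_index: int
    code_index: int

    @classmethod
    def of(cls, n: int, l: int) -> "SubjectTriple":
        return cls(n, n // l, n % l)


def genotype_at(payload: bytes, m: int, n: int, *, n_biallelic: int,
                n_variants: int, n_subjects: int, phased: bool) -> int:
    """BEG code of subject ``n`` at variant ``m`` of a raw genotype payload."""
    if not 0 <= m < n_variants:
        raise IndexError(f"variant index {m} out of range")
    if not 0 <= n < n_subjects:
        raise IndexError(f"subject index {n} out of range")
    l = codec.PHASED_GROUP if phased else codec.UNPHASED_GROUP
    p = variant_pointer(m, n_biallelic, n_subjects, l)
    if m < n_biallelic:
        t = SubjectTriple.of(n, l)
        return codec.unpack_mbeg(payload[p + t.group_index], phased)[t.code_index]
    return payload[p + n]


# ---------------------------------------------------------------------------
# decoded blocks

@dataclass
class DecodedBlock:
    """One block after entity decompression, still in stored (AMDO) order."""
    node: GTBNode
    positions: np.ndarray          # uint32, stored order
    refs: list
    alts: list
    ids: list | None
    payload: bytes                 # raw B1 (MBEG/BEG bytes)
    n_subjects: int
    phased: bool

    @property
    def n_biallelic(self) -> int:
        return self.node.record.n_biallelic

    @property
    def n_variants(self) -> int:
        return self.node.record.n_variants

    def beg_row(self, m: int) -> np.ndarray:
        rec = self.node.record
        bi = m < rec.n_biallelic
        l = codec.PHASED_GROUP if self.phased else codec.UNPHASED_GROUP
        p = variant_pointer(m, rec.n_biallelic, self.n_subjects, l)
        width = codec.variant_payload_len(self.n_subjects, bi, self.phased)
        return codec.decode_variant(self.payload[p:p + width],
                                    self.n_subjects, bi, self.phased)

    def genotype_at(self, m: int, n: int) -> int:
        return genotype_at(self.payload, m, n,
                           n_biallelic=self.n_biallelic,
                           n_variants=self.n_variants,
                           n_subjects=self.n_subjects, phased=self.phased)

    def full_matrix(self) -> np.ndarray:
        return np.vstack([self.beg_row(m) for m in range(self.n_variants)])

    def emit_order(self) -> np.ndarray:
        """Stable position order used when writing variants back out."""
        return np.argsort(self.positions, kind="stable")


def decode_positions(manager: GTBManager, node: GTBNode) -> np.ndarray:
    """Decompress only the position stream of a block."""
    comp = get_compressor(manager.header.compressor_id)
    rec = node.record
    entity = manager.entity_bytes(node)
    raw = comp.decompress(entity[rec.len_b1:rec.len_b1 + rec.len_b2])
    return np.frombuffer(raw, dtype=">u4").astype(np.uint32)


def decode_block(manager: GTBManager, node: GTBNode,
                 entity: bytes | None = None) -> DecodedBlock:
    comp = get_compressor(manager.header.compressor_id)
    rec = node.record
    if entity is None:
        entity = manager.entity_bytes(node)
    o1, o2 = rec.len_b1, rec.len_b1 + rec.len_b2
    o3 = o2 + rec.len_b3
    payload = comp.decompress(entity[:o1])
    positions = np.frombuffer(comp.decompress(entity[o1:o2]),
                              dtype=">u4").astype(np.uint32)
    allele_text = comp.decompress(entity[o2:o3]).decode()
    refs, alts = [], []
    for item in allele_text.split("/") if allele_text else []:
        r, a = item.split("\t")
        refs.append(r)
        alts.append(a)
    ids = None
    if rec.block_magic & BLOCK_HAS_IDS:
        (n4,) = (int.from_bytes(entity[o3:o3 + 4], "big"),)
        ids = comp.decompress(entity[o3 + 4:o3 + 4 + n4]).decode().split("\t")
    if len(positions) != rec.n_variants or len(refs) != rec.n_variants:
        raise QueryError("block streams disagree with abstract record")
    return DecodedBlock(node, positions, refs, alts, ids, payload,
                        len(manager.subjects), manager.phased)


# ---------------------------------------------------------------------------
# block location

def locate_blocks(tree: GTBTree, chrom_idx: int, lo: int, hi: int):
    """Every node whose [min_pos, max_pos] intersects [lo, hi].

    Overlapping nodes (unordered files) are all returned; candidates are
    later verified against their decompressed position stream.
    """
    return [n for n in tree.nodes(chrom_idx)
            if n.record.min_pos <= hi and n.record.max_pos >= lo]


def parse_region(spec: str):
    """'chr', 'chr:beg-end' or 'chr:pos' -> (label, lo, hi), 1-based incl."""
    if ":" not in spec:
        return spec, 0, 2**32 - 1
    chrom, rng = spec.split(":", 1)
    if "-" in rng:
        lo, hi = rng.split("-", 1)
        return chrom, int(lo), int(hi)
    return chrom, int(rng), int(rng)


# ---------------------------------------------------------------------------
# allele frequency

def variant_af(begs: np.ndarray, per_allele: bool = False):
    """Alternative-allele frequency of a BEG row (missing excluded).

    Aggregate mode pools all alternative alleles; per-allele mode returns a
    tuple of per-ALT frequencies.  Returns None when no allele was called.
    """
    idx = np.asarray(begs, dtype=np.intp)
    called = int(codec.BEG_CALLED[idx].sum())
    if called == 0:
        return None
    if not per_allele:
        return float(codec.BEG_ALT_COUNT[idx].sum()) / called
    pairs = codec.begs_to_allele_pairs(begs)
    alleles = pairs[pairs[:, 0] >= 0].ravel()
    top = int(alleles.max(initial=0))
    counts = np.bincount(alleles, minlength=top + 1)
    return tuple(float(c) / called for c in counts[1:])


# ---------------------------------------------------------------------------
# extraction

@dataclass(frozen=True)
class VariantView:
    chrom: str
    pos: int
    ref: str
    alt: str
    id: str
    begs: np.ndarray
    phased: bool
    ploidy: int
    af: float | None

    def gt_strings(self):
        sep = "|" if self.phased else "/"
        out = []
        for a, b in codec.begs_to_allele_pairs(self.begs):
            if a < 0:
                out.append("." if self.ploidy == 1 else f".{sep}.")
            elif self.ploidy == 1:
                out.append(str(a))
            else:
                out.append(f"{a}{sep}{b}")
        return out


def _as_manager(gtb) -> GTBManager:
    return gtb if isinstance(gtb, GTBManager) else read_header(gtb)


def _subject_indices(manager, subjects):
    if subjects is None:
        return None
    unknown = [s for s in subjects if s not in manager.subjects]
    if unknown:
        raise QueryError(f"unknown subjects: {unknown}")
    pos = {name: i for i, name in enumerate(manager.subjects)}
    return [pos[s] for s in subjects]


def iter_records(gtb, regions=None, subjects=None, af_range=None,
                 per_allele_af: bool = False, threads: int = 1):
    """Yield :class:`VariantView` records for a query, one file pass.

    ``regions`` is a list of region strings (None = whole file).  Candidate
    blocks are visited once each, in file order; within a block variants are
    emitted in stable position order.  When ``subjects`` is given, only those
    columns are decoded, via the addressing algorithm.
    """
    manager = _as_manager(gtb)
    contig = manager.contig
    if regions is None:
        wanted = {n.file_index: [(0, 2**32 - 1)] for n in manager.nodes}
    else:
        wanted = {}
        for spec in regions:
            label, lo, hi = parse_region(spec) if isinstance(spec, str) else spec
            cidx = contig.index(label)
            for n in locate_blocks(manager.tree, cidx, lo, hi):
                wanted.setdefault(n.file_index, []).append((lo, hi))
    cols = _subject_indices(manager, subjects)
    order = sorted(wanted)   # single pass in file order

    def load(fi):
        node = manager.nodes[fi]
        return decode_block(manager, node)

    for block in ordered_imap(order, load, threads):
        ranges = wanted[block.node.file_index]
        label = contig.label(block.node.record.chromosome)
        ploidy = contig.ploidy(label)
        for m in block.emit_order():
            pos = int(block.positions[m])
            if not any(lo <= pos <= hi for lo, hi in ranges):
                continue   # candidate verified against real positions
            if cols is None:
                begs = block.beg_row(int(m))
            else:
                begs = np.asarray([block.genotype_at(int(m), c) for c in cols],
                                  dtype=np.uint8)
            af = None
            if af_range is not None or cols is None:
                af = variant_af(block.beg_row(int(m)) if cols is not None
                                else begs)
            if af_range is not None:
                if af is None:
                    log.warning("variant %s:%d has no called alleles; excluded",
                                label, pos)
                    continue
                if not af_range[0] <= af <= af_range[1]:
                    continue
            yield VariantView(
                chrom=label, pos=pos, ref=block.refs[m], alt=block.alts[m],
                id=(block.ids[m] if block.ids else "."), begs=begs,
                phased=manager.phased, ploidy=ploidy, af=af)


def filter_af(gtb, min_af: float, max_af: float, **kw):
    """Variants whose aggregate alternative-allele frequency lies in range."""
    if not 0 <= min_af <= max_af <= 1:
        raise QueryError("require 0 <= min_af <= max_af <= 1")
    return iter_records(gtb, af_range=(min_af, max_af), **kw)


def write_vcf(records, manager: GTBManager, out, subjects=None):
    """Write records as VCF text; '.gz' suffix selects BGZF output."""
    import pysam

    names = list(subjects) if subjects is not None else list(manager.subjects)
    lines = ["##fileformat=VCFv4.2"]
    lines += [ln for ln in manager.header.meta.splitlines()
              if ln.startswith("##contig=")]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names))
    out = os.fspath(out)
    fh = (pysam.BGZFile(out, "wb") if out.endswith(".gz")
          else open(out, "wb"))
    try:
        fh.write(("\n".join(lines) + "\n").encode())
        for rec in records:
            row = (f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                   f"\t.\tPASS\t.\tGT\t" + "\t".join(rec.gt_strings()) + "\n")
            fh.write(row.encode())
    finally:
        fh.close()
    return out


def extract(gtb, out=None, *, regions=None, subjects=None, af_range=None,
            threads: int = 1):
    """Extract by region/subject/AF; write VCF(.gz) if ``out`` is given,
    otherwise return the records as a list."""
    manager = _as_manager(gtb)
    records = iter_records(manager, regions=regions, subjects=subjects,
                           af_range=af_range, threads=threads)
    if out is None:
        return list(records)
    return write_vcf(records, manager, out, subjects=subjects)
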