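"""VCF -> GTB compression pipeline.

The record stream is grouped into blocks (capacity from the sample size; a
block never spans chromosomes or input files), each block is AMDO-ordered
and compressed into three independent streams (genotypes B1, 4-byte
positions B2, allele text B3), and blocks are written in order through the
cyclic-locking executor so multi-threaded builds are byte-deterministic.

Multiple VCFs are concatenated variant-wise: the file with the largest
sample size is the major file and defines the subject order; other files'
columns are matched by name and absent subjects are stored as missing.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from . import codec
from .blocking import (DEFAULT_WINDOWS, amdo_features, amdo_order,
                       block_capacity, estimate_bound, zero_counts)
from .clm import ordered_imap
from .compressors import Compressor, get_compressor
from .gtb import (BLOCK_HAS_IDS, AbstractBlockRecord, ContigSpec, FormatError,
                  GTBHeader, contig_to_meta_lines, default_human_contig,
                  size_class_for, write_gtb)


class BuildError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# chunking

@dataclass(frozen=True)
class Chunk:
    """A record range of one input file: records [start, stop)."""
    path: str
    start: int
    stop: int
    byte_start: int
    byte_stop: int


def _record_offsets(path):
    """Byte offsets/lengths of data records in the (decompressed) VCF text."""
    opener = gzip.open if str(path).endswith(".gz") else open
    offsets, pos = [], 0
    with opener(path, "rb") as fh:
        for line in fh:
            if not line.startswith(b"#"):
                offsets.append((pos, len(line)))
            pos += len(line)
    return offsets


def chunk_input(files, threads: int = 1) -> list[list[Chunk]]:
    """Slice the inputs into ``threads`` chunks of approximately even
    physical size, aligned to whole VCF records."""
    if threads < 1:
        raise ValueError("threads must be >= 1")
    per_file = [(os.fspath(f), _record_offsets(f)) for f in files]
    total = sum(length for _, offs in per_file for _, length in offs)
    if total == 0:
        return [[] for _ in range(threads)]
    target = total / threads
    chunks: list[list[Chunk]] = [[] for _ in range(threads)]
    budget_used = 0
    ci = 0
    for path, offs in per_file:
        start = 0
        start_byte = offs[0][0] if offs else 0
        for i, (off, length) in enumerate(offs):
            budget_used += length
            boundary = (ci < threads - 1
                        and budget_used >= (ci + 1) * target)
            if boundary:
                chunks[ci].append(Chunk(path, start, i + 1, start_byte,
                                        off + length))
                ci = min(ci + 1, threads - 1)
                start, start_byte = i + 1, off + length
        if start < len(offs):
            chunks[ci].append(Chunk(path, start, len(offs), start_byte,
                                    offs[-1][0] + offs[-1][1]))
    return chunks


# ---------------------------------------------------------------------------
# QC hook

@dataclass(frozen=True)
class QCRules:
    """Pluggable genotype/variant quality filters; all off by default.

    ``min_gq``/``min_dp`` set failing genotypes to missing (the variant is
    kept); ``max_missing_rate`` drops a variant whose post-masking missing
    fraction exceeds the cap.  Rules whose FORMAT field is absent are
    silently disabled.
    """
    min_gq: float | None = None
    min_dp: float | None = None
    max_missing_rate: float | None = None


def qc_filter(begs: np.ndarray, fmt: dict, rules: QCRules | None):
    """Apply QC to one variant's BEG row; returns the row or None to drop."""
    if rules is None:
        return begs
    begs = begs.copy()
    for key, thr in (("GQ", rules.min_gq), ("DP", rules.min_dp)):
        if thr is None:
            continue
        arr = fmt.get(key)
        if arr is None:
            continue
        vals = np.asarray(arr, dtype=float).reshape(len(begs), -1)[:, 0]
        begs[np.nan_to_num(vals, nan=-1.0) < thr] = codec.MISSING_CODE
    if rules.max_missing_rate is not None and len(begs):
        if (begs == codec.MISSING_CODE).mean() > rules.max_missing_rate:
            return None
    return begs


# ---------------------------------------------------------------------------
# batches and blocks

@dataclass
class VariantBatch:
    """Variants of one block before AMDO: single chromosome, <= capacity."""
    chrom: int
    positions: list = field(default_factory=list)
    refs: list = field(default_factory=list)
    alts: list = field(default_factory=list)     # comma-joined ALT strings
    ids: list = field(default_factory=list)
    beg_rows: list = field(default_factory=list)
    biallelic: list = field(default_factory=list)

    def __len__(self):
        return len(self.positions)

    def add(self, pos, ref, alt, vid, begs, biallelic):
        self.positions.append(pos)
        self.refs.append(ref)
        self.alts.append(alt)
        self.ids.append(vid)
        self.beg_rows.append(begs)
        self.biallelic.append(biallelic)


class BlockOverflow(FormatError):
    """A compressed stream exceeded its abstract-record field width."""


def build_block(batch: VariantBatch, compressor: Compressor,
                phased: bool, s: int = DEFAULT_WINDOWS,
                store_ids: bool = False, amdo: bool = True):
    """AMDO-order and compress one batch into (record, entity bytes)."""
    if not len(batch):
        raise BuildError("empty batch")
    multi = [not b for b in batch.biallelic]
    if amdo:
        feats = [amdo_features(zero_counts(row), s) for row in batch.beg_rows]
        order = amdo_order(feats, multi)
    else:
        order = np.asarray(
            [i for i, m in enumerate(multi) if not m]
            + [i for i, m in enumerate(multi) if m], dtype=np.intp)
    n_bi = sum(batch.biallelic)
    b1 = b"".join(
        codec.encode_begs_row(batch.beg_rows[i], batch.biallelic[i], phased)
        for i in order)
    b2 = np.asarray([batch.positions[i] for i in order],
                    dtype=">u4").tobytes()
    b3 = "/".join(f"{batch.refs[i]}\t{batch.alts[i]}" for i in order).encode()
    # pre-sized output buffers per the boundary model
    for raw in (b1, b2, b3):
        estimate_bound(len(raw), compressor.bound)
    c1, c2, c3 = (compressor.compress(x) for x in (b1, b2, b3))
    if len(c2) >= 2**24 or len(c1) >= 2**32 or len(c3) >= 2**32:
        raise BlockOverflow("compressed stream exceeds record field width")
    magic = 0
    entity = c1 + c2 + c3
    if store_ids:
        cid = compressor.compress(
            "\t".join(batch.ids[i] or "." for i in order).encode())
        entity += len(cid).to_bytes(4, "big") + cid
        magic |= BLOCK_HAS_IDS
    rec = AbstractBlockRecord(
        chromosome=batch.chrom,
        min_pos=min(batch.positions), max_pos=max(batch.positions),
        n_biallelic=n_bi, n_multiallelic=len(batch) - n_bi,
        len_b1=len(c1), len_b2=len(c2), len_b3=len(c3), block_magic=magic)
    return rec, entity


def _split_batch(batch: VariantBatch):
    mid = len(batch) // 2
    out = []
    for lo, hi in ((0, mid), (mid, len(batch))):
        sub = VariantBatch(batch.chrom)
        for i in range(lo, hi):
            sub.add(batch.positions[i], batch.refs[i], batch.alts[i],
                    batch.ids[i], batch.beg_rows[i], batch.biallelic[i])
        out.append(sub)
    return out


def _build_with_retry(batch, compressor, phased, store_ids, amdo):
    try:
        return [build_block(batch, compressor, phased,
                            store_ids=store_ids, amdo=amdo)]
    except BlockOverflow:
        if len(batch) <= 1:
            raise
        out = []
        for sub in _split_batch(batch):
            out.extend(_build_with_retry(sub, compressor, phased,
                                         store_ids, amdo))
        return out


# ---------------------------------------------------------------------------
# VCF record encoding

def _genotypes_to_begs(gts, n_subjects: int, phased: bool) -> np.ndarray:
    """BEG row from a cyvcf2 genotypes list (missing allele -> code 0)."""
    row = np.empty(n_subjects, dtype=np.uint8)
    for i, gt in enumerate(gts):
        alleles = gt[:-1]
        if len(alleles) == 1:
            a = b = alleles[0]
        else:
            a, b = alleles[0], alleles[1]
        if a < 0 or b < 0:
            row[i] = codec.MISSING_CODE
            continue
        if a >= codec.MAX_ALLELES or b >= codec.MAX_ALLELES:
            raise BuildError(
                f"allele index {max(a, b)} exceeds the {codec.MAX_ALLELES - 1}"
                " limit")
        if not phased and a > b:
            a, b = b, a
        row[i] = codec.BEG_FORWARD[a, b]
    return row


def _iter_file_records(path, contig: ContigSpec, phased: bool,
                       col_map, n_out: int, qc: QCRules | None):
    """Yield (chrom_idx, pos, ref, alt, id, beg_row, biallelic) per record."""
    vcf = VCF(os.fspath(path))
    try:
        for v in vcf:
            try:
                chrom_idx = contig.index(v.CHROM)
            except KeyError:
                raise BuildError(
                    f"chromosome {v.CHROM!r} absent from contig") from None
            begs = _genotypes_to_begs(v.genotypes, len(vcf.samples), phased)
            fmt = {}
            if qc is not None:
                for key in ("GQ", "DP"):
                    try:
                        fmt[key] = v.format(key)
                    except KeyError:
                        pass
            begs = qc_filter(begs, fmt, qc)
            if begs is None:
                continue
            if col_map is not None:
                out = np.zeros(n_out, dtype=np.uint8)  # absent -> missing
                out[col_map] = begs
                begs = out
            alt = ",".join(v.ALT) if v.ALT else "."
            biallelic = len(v.ALT) == 1
            yield (chrom_idx, int(v.POS), v.REF, alt, v.ID or ".",
                   begs, biallelic)
    finally:
        vcf.close()


def _detect_phase(path) -> bool:
    vcf = VCF(os.fspath(path))
    try:
        for v in vcf:
            for gt in v.genotypes:
                alleles = gt[:-1]
                if all(a >= 0 for a in alleles):
                    return bool(gt[-1]) if len(alleles) > 1 else True
    finally:
        vcf.close()
    return True


# ---------------------------------------------------------------------------
# top-level compression

def compress(files, out, *, contig: ContigSpec | None = None,
             phased: bool | None = None, threads: int = 1,
             compressor: str = "zstd", level: int = 3,
             qc: QCRules | None = None, store_ids: bool = False,
             amdo: bool = True, s_windows: int = DEFAULT_WINDOWS) -> str:
    """Compress one or more VCF/VCF.GZ files into a single GTB file."""
    if isinstance(files, (str, os.PathLike)):
        files = [files]
    files = [os.fspath(f) for f in files]
    if not files:
        raise BuildError("no input files")
    if contig is None:
        contig = default_human_contig()

    samples = {}
    for f in files:
        vcf = VCF(f)
        names = list(vcf.samples)
        vcf.close()
        if len(names) != len(set(names)):
            raise BuildError(f"duplicate subject names within {f}")
        samples[f] = names
    major = max(files, key=lambda f: len(samples[f]))
    subjects = samples[major]
    index_of = {name: i for i, name in enumerate(subjects)}
    for f in files:
        unknown = [n for n in samples[f] if n not in index_of]
        if unknown:
            raise BuildError(
                f"subjects of {f} absent from the major file {major}: "
                f"{unknown[:5]}")

    if phased is None:
        phased = _detect_phase(major)
    n_out = len(subjects)
    cap = block_capacity(n_out)
    comp = get_compressor(compressor, level)

    def batches():
        for f in files:
            names = samples[f]
            col_map = (None if names == subjects else
                       np.asarray([index_of[n] for n in names], dtype=np.intp))
            batch = None
            for chrom_idx, pos, ref, alt, vid, begs, bi in _iter_file_records(
                    f, contig, phased, col_map, n_out, qc):
                if batch is not None and (batch.chrom != chrom_idx
                                          or len(batch) >= cap):
                    yield batch
                    batch = None
                if batch is None:
                    batch = VariantBatch(chrom_idx)
                batch.add(pos, ref, alt, vid, begs, bi)
            if batch is not None:
                yield batch    # block never spans input files

    def process(batch):
        return _build_with_retry(batch, comp, phased, store_ids, amdo)

    raw_block_bytes = (cap * codec.variant_payload_len(n_out, True, phased)
                       + 4 * cap)
    header = GTBHeader(
        compressor_id=comp.id, level=comp.level, phased=phased,
        variant_cap=cap, size_class=size_class_for(raw_block_bytes),
        meta="##source=gtbkit\n" + contig_to_meta_lines(contig),
        subjects=tuple(subjects))

    def blocks():
        for group in ordered_imap(batches(), process, threads):
            yield from group

    write_gtb(out, header, blocks())
    return os.fspath(out)
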