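"""The GTB container: header, 25-byte abstract block records, GTBTree index.

File layout (all integers big-endian)::

    magic code            2 bytes   packed build parameters
    block count           3 bytes
    meta                  4-byte length + UTF-8 text (VCF meta incl. contigs)
    subjects              4-byte length + tab-joined UTF-8 subject names
    block entities        concatenated compressed payloads, file order
    abstract records      25 bytes per block, trailing

Magic byte 0: bits 7-5 compression level, bit 4 ordered flag, bit 3 phased
flag, bits 2-0 compressor id.  Magic byte 1: bits 4-3 max-decompressed-block
size class (8/16/32/64 MB), bits 2-0 log2(variant cap) - 7.

The ordered flag asserts that within every chromosome the blocks' coordinate
ranges are non-overlapping; it is computed from the abstract records when the
trailing index is written, never assumed from the input.

Each block entity is ``B1_hat || B2_hat || B3_hat`` (compressed genotypes,
4-byte positions, allele text) optionally followed by a 4-byte length prefix
plus a compressed variant-ID field, flagged in the record's block magic.
These files are this package's own dialect of the layout; no binary
compatibility with other producers is claimed.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

MAGIC_SIZE = 2
BLOCK_COUNT_SIZE = 3
RECORD_SIZE = 25
MAX_BLOCKS = 2**24 - 1
MAX_CONTIGS = 256

#: block_magic bit 0: optional compressed variant-ID field follows B3.
BLOCK_HAS_IDS = 0x01

_SIZE_CLASSES = (8 << 20, 16 << 20, 32 << 20, 64 << 20)


class FormatError(ValueError):
    """Corrupt or out-of-spec GTB data."""


# ---------------------------------------------------------------------------
# contigs

@dataclass(frozen=True)
class ContigSpec:
    """Chromosome labels with ploidy (1 or 2) and length, <= 256 entries.

    Entry order defines the 1-byte chromosome index used on disk.
    """

    entries: tuple = ()

    def __post_init__(self):
        labels = [e[0] for e in self.entries]
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate chromosome labels in contig")
        if len(labels) > MAX_CONTIGS:
            raise FormatError(
                f"{len(labels)} chromosomes exceeds the {MAX_CONTIGS} limit")
        for label, ploidy, length in self.entries:
            if ploidy not in (1, 2):
                raise FormatError(f"unsupported ploidy {ploidy} for {label}")

    def __len__(self):
        return len(self.entries)

    def index(self, label: str) -> int:
        for i, (lab, _, _) in enumerate(self.entries):
            if lab == label:
                return i
        raise KeyError(f"chromosome {label!r} not in contig")

    def label(self, idx: int) -> str:
        return self.entries[idx][0]

    def ploidy(self, label: str) -> int:
        return self.entries[self.index(label)][1]

    def length(self, label: str) -> int:
        return self.entries[self.index(label)][2]

    def labels(self):
        return [e[0] for e in self.entries]

    def to_csv(self) -> str:
        lines = ["#chromosome,ploidy,length"]
        lines += [f"{lab},{p},{ln}" for lab, p, ln in self.entries]
        return "\n".join(lines) + "\n"


def parse_contig(text: str) -> ContigSpec:
    """Parse a contig CSV with header ``#chromosome,ploidy,length``."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].lstrip("#").lower().startswith("chromosome"):
        raise FormatError('contig file must start with "#chromosome,ploidy,length"')
    entries = []
    for ln in lines[1:]:
        parts = ln.split(",")
        if len(parts) != 3:
            raise FormatError(f"malformed contig line: {ln!r}")
        label, ploidy, length = parts[0], int(parts[1]), int(parts[2])
        entries.append((label, ploidy, length))
    if not entries:
        raise FormatError("contig file declares no chromosomes")
    return ContigSpec(tuple(entries))


def default_human_contig() -> ContigSpec:
    """Autosomes 1-22 (diploid), X diploid, Y and MT haploid (GRCh37 lengths)."""
    lengths = [249250621, 243199373, 198022430, 191154276, 180915260,
               171115067, 159138663, 146364022, 141213431, 135534747,
               135006516, 133851895, 115169878, 107349540, 102531392,
               90354753, 81195210, 78077248, 59128983, 63025520,
               48129895, 51304566]
    entries = [(str(i + 1), 2, lengths[i]) for i in range(22)]
    entries += [("X", 2, 155270560), ("Y", 1, 59373566), ("MT", 1, 16569)]
    return ContigSpec(tuple(entries))


# ---------------------------------------------------------------------------
# abstract block records

@dataclass(frozen=True)
class AbstractBlockRecord:
    chromosome: int
    min_pos: int
    max_pos: int
    n_biallelic: int
    n_multiallelic: int
    len_b1: int
    len_b2: int
    len_b3: int
    block_magic: int = 0

    @property
    def n_variants(self) -> int:
        return self.n_biallelic + self.n_multiallelic

    @property
    def entity_core_length(self) -> int:
        return self.len_b1 + self.len_b2 + self.len_b3


def serialize_abstract(rec: AbstractBlockRecord) -> bytes:
    """Exactly 25 bytes: chrom(1) min(4) max(4) nbi(2) nmul(2) lenB1(4)
    lenB2(3) lenB3(4) blockMagic(1)."""
    if not 0 <= rec.chromosome < MAX_CONTIGS:
        raise FormatError("chromosome index out of byte range")
    if not 0 <= rec.min_pos <= rec.max_pos < 2**32:
        raise FormatError("positions out of 4-byte range or min > max")
    if rec.n_biallelic >= 2**16 or rec.n_multiallelic >= 2**16:
        raise FormatError("variant counts exceed 2-byte fields")
    if rec.len_b1 >= 2**32 or rec.len_b3 >= 2**32:
        raise FormatError("B1/B3 length exceeds 4-byte field")
    if rec.len_b2 >= 2**24:
        raise FormatError("B2 length exceeds 3-byte field")
    head = struct.pack(">BIIHHI", rec.chromosome, rec.min_pos, rec.max_pos,
                       rec.n_biallelic, rec.n_multiallelic, rec.len_b1)
    return (head + rec.len_b2.to_bytes(3, "big")
            + struct.pack(">IB", rec.len_b3, rec.block_magic))


def parse_abstract(data: bytes) -> AbstractBlockRecord:
    if len(data) != RECORD_SIZE:
        raise FormatError(f"abstract record must be {RECORD_SIZE} bytes")
    chrom, mn, mx, nbi, nmul, lb1 = struct.unpack(">BIIHHI", data[:17])
    lb2 = int.from_bytes(data[17:20], "big")
    lb3, magic = struct.unpack(">IB", data[20:25])
    if mn > mx:
        raise FormatError("abstract record has min_pos > max_pos")
    return AbstractBlockRecord(chrom, mn, mx, nbi, nmul, lb1, lb2, lb3, magic)


# ---------------------------------------------------------------------------
# header

@dataclass
class GTBHeader:
    compressor_id: int = 0
    level: int = 3
    phased: bool = True
    ordered: bool = False
    variant_cap: int = 16384          # 2^n, n in 7..14
    size_class: int = 0               # index into 8/16/32/64 MB
    meta: str = ""
    subjects: tuple = ()
    block_count: int = 0

    def pack_magic(self) -> bytes:
        n = self.variant_cap.bit_length() - 1
        if self.variant_cap != 1 << n or not 7 <= n <= 14:
            raise FormatError("variant cap must be 2^n with 7 <= n <= 14")
        b0 = ((self.level & 0x7) << 5 | (self.ordered << 4)
              | (self.phased << 3) | (self.compressor_id & 0x7))
        b1 = (self.size_class & 0x3) << 3 | (n - 7)
        return bytes([b0, b1])

    @classmethod
    def unpack_magic(cls, data: bytes) -> "GTBHeader":
        if len(data) != MAGIC_SIZE:
            raise FormatError("magic code must be 2 bytes")
        b0, b1 = data
        return cls(compressor_id=b0 & 0x7, level=(b0 >> 5) & 0x7,
                   phased=bool(b0 & 0x8), ordered=bool(b0 & 0x10),
                   variant_cap=1 << ((b1 & 0x7) + 7),
                   size_class=(b1 >> 3) & 0x3)

    @property
    def max_block_bytes(self) -> int:
        return _SIZE_CLASSES[self.size_class]


def size_class_for(n_bytes: int) -> int:
    for i, cap in enumerate(_SIZE_CLASSES):
        if n_bytes <= cap:
            return i
    return len(_SIZE_CLASSES) - 1


def compute_ordered_flag(records) -> bool:
    """True iff per-chromosome block coordinate ranges are non-overlapping."""
    per_chrom: dict[int, list] = {}
    for r in records:
        per_chrom.setdefault(r.chromosome, []).append((r.min_pos, r.max_pos))
    for ranges in per_chrom.values():
        if ranges != sorted(ranges):
            return False
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ranges, ranges[1:]):
            if b_lo <= a_hi:
                return False
    return True


# ---------------------------------------------------------------------------
# writing

def write_gtb(path, header: GTBHeader, blocks) -> list[AbstractBlockRecord]:
    """Stream blocks to a GTB file.

    Five placeholder bytes (magic + block count) are written first, entities
    are streamed in arrival order, the trailing index is appended, and the
    placeholders are back-patched with the final block count and the
    post-hoc ordered flag.
    """
    records = []
    with open(path, "wb") as fh:
        fh.write(b"\x00" * (MAGIC_SIZE + BLOCK_COUNT_SIZE))
        meta = header.meta.encode()
        fh.write(struct.pack(">I", len(meta)) + meta)
        subj = "\t".join(header.subjects).encode()
        fh.write(struct.pack(">I", len(subj)) + subj)
        for rec, entity in blocks:
            expected = rec.entity_core_length
            if rec.block_magic & BLOCK_HAS_IDS:
                if len(entity) < expected + 4:
                    raise FormatError("entity too short for flagged ID field")
            elif len(entity) != expected:
                raise FormatError("entity length disagrees with record")
            if len(records) >= MAX_BLOCKS:
                raise FormatError(f"more than {MAX_BLOCKS} blocks")
            fh.write(entity)
            records.append(rec)
        for rec in records:
            fh.write(serialize_abstract(rec))
        header.block_count = len(records)
        header.ordered = compute_ordered_flag(records)
        fh.seek(0)
        fh.write(header.pack_magic())
        fh.write(header.block_count.to_bytes(BLOCK_COUNT_SIZE, "big"))
    return records


# ---------------------------------------------------------------------------
# reading

@dataclass
class GTBNode:
    record: AbstractBlockRecord
    file_index: int
    entity_offset: int
    entity_length: int


@dataclass
class GTBTree:
    """Per-chromosome GTBNode lists sorted by (min_pos, max_pos)."""

    by_chrom: dict = field(default_factory=dict)

    @classmethod
    def build(cls, nodes) -> "GTBTree":
        by_chrom: dict[int, list] = {}
        for node in nodes:
            by_chrom.setdefault(node.record.chromosome, []).append(node)
        for group in by_chrom.values():
            group.sort(key=lambda n: (n.record.min_pos, n.record.max_pos))
        return cls(by_chrom)

    def chromosomes(self):
        return sorted(self.by_chrom)

    def nodes(self, chrom_idx: int):
        return self.by_chrom.get(chrom_idx, [])


class GTBManager:
    """In-memory view of everything except the block entities.

    Construction reads the header, subjects, and the trailing abstract
    records, and builds the GTBTree; entity bytes are fetched lazily per
    block.  Managers are cached per (path, mtime, size) so repeated access
    to the same file skips re-parsing.
    """

    def __init__(self, path):
        self.path = os.fspath(path)
        with open(self.path, "rb") as fh:
            fh.seek(0, os.SEEK_END)
            file_size = fh.tell()
            fh.seek(0)
            head = fh.read(MAGIC_SIZE + BLOCK_COUNT_SIZE)
            if len(head) != MAGIC_SIZE + BLOCK_COUNT_SIZE:
                raise FormatError(f"truncated header at offset {len(head)}")
            self.header = GTBHeader.unpack_magic(head[:MAGIC_SIZE])
            self.header.block_count = int.from_bytes(head[MAGIC_SIZE:], "big")
            (meta_len,) = struct.unpack(">I", fh.read(4))
            self.header.meta = fh.read(meta_len).decode()
            (subj_len,) = struct.unpack(">I", fh.read(4))
            raw = fh.read(subj_len).decode()
            self.header.subjects = tuple(raw.split("\t")) if raw else ()
            entity_start = fh.tell()
            index_size = RECORD_SIZE * self.header.block_count
            index_off = file_size - index_size
            if index_off < entity_start:
                raise FormatError(
                    f"block count {self.header.block_count} inconsistent with "
                    f"file size (index would start at {index_off})")
            fh.seek(index_off)
            blob = fh.read(index_size)
            if len(blob) != index_size:
                raise FormatError(f"truncated index at offset {index_off}")
            records = [parse_abstract(blob[i:i + RECORD_SIZE])
                       for i in range(0, index_size, RECORD_SIZE)]
            nodes, offset = [], entity_start
            for i, rec in enumerate(records):
                length = rec.entity_core_length
                if rec.block_magic & BLOCK_HAS_IDS:
                    fh.seek(offset + length)
                    (extra,) = struct.unpack(">I", fh.read(4))
                    length += 4 + extra
                nodes.append(GTBNode(rec, i, offset, length))
                offset += length
            if offset != index_off:
                raise FormatError(
                    f"entities end at {offset} but index starts at {index_off}")
        self.entity_start = entity_start
        self.nodes = nodes                  # file order
        self.tree = GTBTree.build(nodes)
        self.contig = contig_from_meta(self.header.meta)

    # -- lazy entity access

    def entity_bytes(self, node: GTBNode) -> bytes:
        with open(self.path, "rb") as fh:
            fh.seek(node.entity_offset)
            return fh.read(node.entity_length)

    @property
    def subjects(self):
        return self.header.subjects

    @property
    def phased(self) -> bool:
        return self.header.phased


_manager_cache: dict = {}


def read_header(path) -> GTBManager:
    """Load (or fetch from cache) the GTBManager for a file."""
    path = os.fspath(path)
    st = os.stat(path)
    key = (os.path.realpath(path), st.st_mtime_ns, st.st_size)
    mgr = _manager_cache.get(key)
    if mgr is None:
        mgr = GTBManager(path)
        _manager_cache[key] = mgr
    return mgr


# ---------------------------------------------------------------------------
# contig <-> meta embedding

def contig_to_meta_lines(contig: ContigSpec) -> str:
    return "\n".join(
        f"##contig=<ID={lab},length={ln},ploidy={p}>"
        for lab, p, ln in contig.entries)


def contig_from_meta(meta: str) -> ContigSpec:
    entries = []
    for line in meta.splitlines():
        if not line.startswith("##contig=<"):
            continue
        body = line[len("##contig=<"):].rstrip(">")
        fields = dict(part.split("=", 1) for part in body.split(",") if "=" in part)
        if "ID" not in fields:
            continue
        entries.append((fields["ID"], int(fields.get("ploidy", 2)),
                        int(fields.get("length", 0))))
    if not entries:
        return default_human_contig()
    return ContigSpec(tuple(entries))
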