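"""GTB-native management: coordinate sort, concat, split, merge, and the
allele-label consistency checks used when merging genotype batches.

Sorting never decodes more than one old block plus the new block being
assembled: a two-level index table (position, source node, within-block
index) is sorted per chromosome, consecutive variants are re-blocked, and
within each new block the pulls are grouped by source node so every old
block is decompressed at most once per new block.

Merging pops the two lightest files (weight = subject count) from a min-heap
until one remains; variants are matched on (chromosome, position, unordered
allele set) with allele-index remapping when the label order differs.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from . import codec
from .build import VariantBatch, _build_with_retry
from .clm import ordered_imap
from .compressors import get_compressor
from .gtb import GTBHeader, read_header, write_gtb
from .query import decode_block, decode_positions

log = logging.getLogger(__name__)


class ManagerError(RuntimeError):
    pass


def _clone_header(mgr) -> GTBHeader:
    h = mgr.header
    return GTBHeader(compressor_id=h.compressor_id, level=h.level,
                     phased=h.phased, variant_cap=h.variant_cap,
                     size_class=h.size_class, meta=h.meta,
                     subjects=h.subjects)


# ---------------------------------------------------------------------------
# sort

def sort_gtb(in_path, out_path, threads: int = 1) -> dict:
    """Coordinate-sort a GTB; returns instrumentation stats.

    Ties at equal positions keep (source node index, within-block index)
    order, which both makes the sort deterministic and caps old-block
    decompressions at one per new block.
    """
    mgr = read_header(in_path)
    header = _clone_header(mgr)
    cap = header.variant_cap
    comp = get_compressor(header.compressor_id, header.level)
    stats_out = {"block_decompressions": 0, "new_blocks": 0}

    def new_batches():
        for chrom in mgr.tree.chromosomes():
            table = []
            for node in mgr.tree.nodes(chrom):
                for w, pos in enumerate(decode_positions(mgr, node)):
                    table.append((int(pos), node.file_index, w))
            table.sort()
            for lo in range(0, len(table), cap):
                members = table[lo:lo + cap]
                pulls = {}
                for pos, fi, w in members:
                    pulls.setdefault(fi, []).append(w)
                rows = {}
                for fi in sorted(pulls):
                    block = decode_block(mgr, mgr.nodes[fi])
                    stats_out["block_decompressions"] += 1
                    for w in pulls[fi]:
                        rows[(fi, w)] = (
                            block.beg_row(w), block.refs[w], block.alts[w],
                            block.ids[w] if block.ids else ".",
                            w < block.n_biallelic)
                batch = VariantBatch(chrom)
                for pos, fi, w in members:
                    begs, ref, alt, vid, bi = rows[(fi, w)]
                    batch.add(pos, ref, alt, vid, begs, bi)
                stats_out["new_blocks"] += 1
                yield batch

    def process(batch):
        return _build_with_retry(batch, comp, header.phased, False, True)

    def blocks():
        for group in ordered_imap(new_batches(), process, threads):
            yield from group

    write_gtb(out_path, header, blocks())
    return stats_out


# ---------------------------------------------------------------------------
# concat / split

def concat_gtb(parts, out_path) -> str:
    """Concatenate GTBs with identical subjects; entities are byte-copied."""
    mgrs = [read_header(p) for p in parts]
    first = mgrs[0]
    for m in mgrs[1:]:
        if m.subjects != first.subjects:
            raise ManagerError("subject lists differ (names or order)")
        if m.header.compressor_id != first.header.compressor_id:
            raise ManagerError("inputs use different compressors")
        if m.header.phased != first.header.phased:
            raise ManagerError("inputs have different phase states")
        if m.contig.entries != first.contig.entries:
            raise ManagerError("inputs declare different contigs")
    header = _clone_header(first)

    def blocks():
        for m in mgrs:
            for node in m.nodes:
                yield node.record, m.entity_bytes(node)

    write_gtb(out_path, header, blocks())
    return str(out_path)


def split_by_chromosome(in_path, out_dir, stem: str = "split") -> dict:
    """One GTB per chromosome present; entities byte-copied.  Returns
    {chromosome label: path}; empty chromosomes emit no file."""
    import os

    mgr = read_header(in_path)
    os.makedirs(out_dir, exist_ok=True)
    out = {}
    for chrom in mgr.tree.chromosomes():
        label = mgr.contig.label(chrom)
        path = os.path.join(os.fspath(out_dir), f"{stem}.chr{label}.gtb")
        nodes = sorted(mgr.tree.nodes(chrom), key=lambda n: n.file_index)
        header = _clone_header(mgr)
        write_gtb(path, header,
                  ((n.record, mgr.entity_bytes(n)) for n in nodes))
        out[label] = path
    return out


# ---------------------------------------------------------------------------
# allele-label consistency checks

def check_af(af1: float, af2: float, threshold: float = 0.1) -> bool:
    """Consistent iff |AF1 - AF2| < threshold (default 0.1).

    Intended for variants whose minor allele frequency is well below 0.5.
    """
    return abs(af1 - af2) < threshold


class ChiSquareResult(NamedTuple):
    consistent: bool | None     # None = check skipped (zero marginal)
    statistic: float | None
    pvalue: float | None


def check_allele_count(table, alpha: float = 0.05) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) on a 2x2 ref/alt table.

    Consistent iff equal-allele-frequency H0 is not rejected at ``alpha``.
    A zero marginal makes the test undefined; the check is skipped with a
    warning.  Not suitable when the two batches are cases and controls.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        log.warning("zero marginal in allele-count table; check skipped")
        return ChiSquareResult(None, None, None)
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return ChiSquareResult(bool(p > alpha), float(stat), float(p))


def _pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = (x >= 0) & (y >= 0)     # -1 encodes missing
    if m.sum() < 2:
        return np.nan
    xv, yv = x[m], y[m]
    if xv.std() == 0 or yv.std() == 0:
        return np.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def check_ld_pattern(target1, partners1, target2, partners2,
                     r_threshold: float = 0.8) -> str:
    """Decide 'flip' / 'keep' / 'undecided' from nearby-variant LD signs.

    ``targetK`` is the variant's dosage vector in batch K (-1 missing);
    ``partnersK`` the (k, N_k) dosages of the same k nearby variants.  A
    partner is shared when |r| exceeds the threshold in both batches; the
    labels flip when the majority of shared partners change correlation
    sign between the batches.  Useful for variants whose minor allele
    frequency is close to 0.5, where the frequency checks are blind.
    """
    p1 = np.atleast_2d(partners1)
    p2 = np.atleast_2d(partners2)
    if len(p1) != len(p2):
        raise ValueError("batches must provide the same nearby variants")
    flips = keeps = 0
    for row1, row2 in zip(p1, p2):
        r1 = _pearson(target1, row1)
        r2 = _pearson(target2, row2)
        if np.isnan(r1) or np.isnan(r2):
            continue
        if abs(r1) > r_threshold and abs(r2) > r_threshold:
            if np.sign(r1) != np.sign(r2):
                flips += 1
            else:
                keeps += 1
    if flips + keeps == 0:
        return "undecided"
    return "flip" if flips > keeps else "keep"


# ---------------------------------------------------------------------------
# merge

@dataclass
class _Table:
    """Decoded genotype table of one (intermediate) file."""
    subjects: tuple
    # records in file order: (chrom, pos, ref, alts tuple, id, beg row)
    records: list = field(default_factory=list)

    @property
    def weight(self):
        return len(self.subjects)


def _load_table(path) -> _Table:
    mgr = read_header(path)
    t = _Table(tuple(mgr.subjects))
    for node in mgr.nodes:
        block = decode_block(mgr, node)
        for m in block.emit_order():
            alts = tuple(block.alts[m].split(","))
            t.records.append((node.record.chromosome, int(block.positions[m]),
                              block.refs[m], alts,
                              block.ids[m] if block.ids else ".",
                              block.beg_row(int(m))))
    return t


def _remap_row(begs: np.ndarray, mapping: dict, phased: bool) -> np.ndarray:
    code_map = np.arange(codec.MAX_BEG + 1, dtype=np.uint8)
    for c in range(1, codec.MAX_BEG + 1):
        a, b = codec.BEG_BACKWARD[c]
        if a < 0:
            continue
        na, nb = mapping.get(int(a)), mapping.get(int(b))
        if na is None or nb is None:
            continue
        if not phased and na > nb:
            na, nb = nb, na
        code_map[c] = codec.BEG_FORWARD[na, nb]
    return code_map[np.asarray(begs, dtype=np.intp)]


def _merge_pair(a: _Table, b: _Table, mode: str, checks, phased: bool,
                report: list) -> _Table:
    out = _Table(a.subjects + b.subjects)
    n_a, n_b = len(a.subjects), len(b.subjects)
    missing_a = np.zeros(n_a, dtype=np.uint8)
    missing_b = np.zeros(n_b, dtype=np.uint8)
    index_b: dict = {}
    for i, rec in enumerate(b.records):
        chrom, pos, ref, alts, _, _ = rec
        index_b.setdefault((chrom, pos, frozenset((ref,) + alts)), []).append(i)
    used_b = set()
    for chrom, pos, ref, alts, vid, row_a in a.records:
        key = (chrom, pos, frozenset((ref,) + alts))
        cands = [i for i in index_b.get(key, []) if i not in used_b]
        if cands:
            i = cands[0]
            used_b.add(i)
            _, _, ref_b, alts_b, _, row_b = b.records[i]
            labels_a = (ref,) + alts
            labels_b = (ref_b,) + alts_b
            if labels_b != labels_a:
                mapping = {bi: labels_a.index(lab)
                           for bi, lab in enumerate(labels_b)}
                row_b = _remap_row(row_b, mapping, phased)
            if checks:
                _run_checks(chrom, pos, row_a, row_b, checks, report)
            out.records.append((chrom, pos, ref, alts, vid,
                                np.concatenate([row_a, row_b])))
        elif mode == "union":
            out.records.append((chrom, pos, ref, alts, vid,
                                np.concatenate([row_a, missing_b])))
    if mode == "union":
        for i, (chrom, pos, ref, alts, vid, row_b) in enumerate(b.records):
            if i not in used_b:
                out.records.append((chrom, pos, ref, alts, vid,
                                    np.concatenate([missing_a, row_b])))
    return out


def _run_checks(chrom, pos, row_a, row_b, checks, report):
    from .query import variant_af

    if "af" in checks:
        af1, af2 = variant_af(row_a), variant_af(row_b)
        if af1 is not None and af2 is not None and not check_af(af1, af2):
            report.append(("af", chrom, pos, af1, af2))
    if "chi2" in checks:
        idx_a = np.asarray(row_a, dtype=np.intp)
        idx_b = np.asarray(row_b, dtype=np.intp)
        table = [[int(codec.BEG_ZERO_COUNT[idx_a].sum()),
                  int(codec.BEG_ALT_COUNT[idx_a].sum())],
                 [int(codec.BEG_ZERO_COUNT[idx_b].sum()),
                  int(codec.BEG_ALT_COUNT[idx_b].sum())]]
        res = check_allele_count(table)
        if res.consistent is False:
            report.append(("chi2", chrom, pos, res.statistic, res.pvalue))


def merge_gtb(files, out_path, mode: str = "union", checks=(),
              threads: int = 1) -> dict:
    """Merge >= 2 GTBs with pairwise-disjoint subjects via a min-heap.

    Returns {"merge_order": [(w1, w2), ...], "report": [...]} where
    merge_order records the heap-pop weights and report the variants any
    enabled consistency check flagged.
    """
    if mode not in ("union", "intersection"):
        raise ManagerError(f"unknown merge mode {mode!r}")
    mgrs = [read_header(p) for p in files]
    if len(mgrs) < 2:
        raise ManagerError("merging needs at least two files")
    seen: set = set()
    for m in mgrs:
        overlap = seen & set(m.subjects)
        if overlap:
            raise ManagerError(f"overlapping subjects: {sorted(overlap)[:5]}")
        seen |= set(m.subjects)
    phased = mgrs[0].header.phased
    if any(m.header.phased != phased for m in mgrs):
        raise ManagerError("inputs have different phase states")

    heap = []
    for seq, path in enumerate(files):
        t = _load_table(path)
        heapq.heappush(heap, (t.weight, seq, t))
    seq += 1
    report: list = []
    order: list = []
    while len(heap) > 1:
        w1, _, a = heapq.heappop(heap)
        w2, _, b = heapq.heappop(heap)
        order.append((w1, w2))
        merged = _merge_pair(a, b, mode, checks, phased, report)
        heapq.heappush(heap, (merged.weight, seq, merged))
        seq += 1
    final = heap[0][2]

    first = mgrs[0]
    from .blocking import block_capacity
    header = _clone_header(first)
    header.subjects = final.subjects
    header.variant_cap = block_capacity(len(final.subjects))
    comp = get_compressor(header.compressor_id, header.level)
    cap = header.variant_cap

    def batches():
        batch = None
        for chrom, pos, ref, alts, vid, row in final.records:
            if batch is not None and (batch.chrom != chrom
                                      or len(batch) >= cap):
                yield batch
                batch = None
            if batch is None:
                batch = VariantBatch(chrom)
            batch.add(pos, ref, ",".join(alts), vid, row, len(alts) == 1)
        if batch is not None:
            yield batch

    def blocks():
        for group in ordered_imap(
                batches(),
                lambda ba: _build_with_retry(ba, comp, phased, False, True),
                threads):
            yield from group

    write_gtb(out_path, header, blocks())
    return {"merge_order": order, "report": report}
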