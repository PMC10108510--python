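"""Pairwise linkage disequilibrium from bit-plane popcount arithmetic.

Alternative-allele dosages (0/1/2 for diploids) are split into two bit
planes plus a validity mask; all the sums a Pearson correlation needs
(n, sum x, sum y, sum x^2, sum y^2, sum xy) are then exact integer popcounts
of ANDed planes, so ``r`` matches a naive floating-point computation to
rounding error while touching each byte once.  Missing genotypes are handled
by pairwise-complete deletion.  The correlation is genotypic (dosage-level),
also for phased data; multiallelic dosages count all non-reference alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import codec
from .clm import ordered_imap


@dataclass(frozen=True)
class BitPlanes:
    """Dosage bit planes of one variant over the subject universe."""
    b0: np.ndarray       # packed uint8 words, dosage bit 0
    b1: np.ndarray       # packed uint8 words, dosage bit 1
    valid: np.ndarray    # packed uint8 words, non-missing mask
    n_subjects: int

    @classmethod
    def from_dosages(cls, dosages) -> "BitPlanes":
        """Build planes from dosages in {0,1,2}, -1 for missing."""
        d = np.asarray(dosages, dtype=np.int64)
        valid = d >= 0
        dd = np.where(valid, d, 0)
        if dd.max(initial=0) > 2:
            raise ValueError("diploid dosage must be 0, 1 or 2")
        return cls(np.packbits(dd & 1), np.packbits((dd >> 1) & 1),
                   np.packbits(valid), len(d))

    @classmethod
    def from_begs(cls, begs) -> "BitPlanes":
        idx = np.asarray(begs, dtype=np.intp)
        dos = codec.BEG_ALT_COUNT[idx].astype(np.int64)
        dos[idx == codec.MISSING_CODE] = -1
        return cls.from_dosages(dos)


def _pc(x: np.ndarray) -> int:
    return int(np.bitwise_count(x).sum())


class LDResult(NamedTuple):
    r: float
    r2: float
    n_used: int
    defined: bool


def ld_pair(x: BitPlanes, y: BitPlanes) -> LDResult:
    """Genotypic Pearson correlation of two variants from popcount sums."""
    if x.n_subjects != y.n_subjects:
        raise ValueError("variants live on different subject universes")
    m = x.valid & y.valid
    n = _pc(m)
    x0, x1 = x.b0 & m, x.b1 & m
    y0, y1 = y.b0 & m, y.b1 & m
    sx = _pc(x0) + 2 * _pc(x1)
    sy = _pc(y0) + 2 * _pc(y1)
    sxx = _pc(x0) + 4 * _pc(x1)
    syy = _pc(y0) + 4 * _pc(y1)
    sxy = (_pc(x0 & y0) + 2 * (_pc(x0 & y1) + _pc(x1 & y0))
           + 4 * _pc(x1 & y1))
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if n == 0 or vx == 0 or vy == 0:
        return LDResult(math.nan, math.nan, n, False)
    r = (n * sxy - sx * sy) / math.sqrt(vx) / math.sqrt(vy)
    return LDResult(r, r * r, n, True)


def ld_sums(x: BitPlanes, y: BitPlanes):
    """The raw integer sums (n, sx, sy, sxx, syy, sxy) — exact by design."""
    m = x.valid & y.valid
    x0, x1 = x.b0 & m, x.b1 & m
    y0, y1 = y.b0 & m, y.b1 & m
    return (_pc(m), _pc(x0) + 2 * _pc(x1), _pc(y0) + 2 * _pc(y1),
            _pc(x0) + 4 * _pc(x1), _pc(y0) + 4 * _pc(y1),
            _pc(x0 & y0) + 2 * (_pc(x0 & y1) + _pc(x1 & y0))
            + 4 * _pc(x1 & y1))


def ld_window(gtb, region, min_r2: float = 0.0, threads: int = 1):
    """All within-window pairs with defined r and r^2 >= threshold.

    Returns (chrom, pos_i, pos_j, r, r2, n_used) tuples in deterministic
    (i, j) order regardless of thread count.
    """
    from .query import iter_records

    records = list(iter_records(gtb, regions=[region]))
    planes = [BitPlanes.from_begs(rec.begs) for rec in records]

    def row(i):
        out = []
        for j in range(i + 1, len(records)):
            res = ld_pair(planes[i], planes[j])
            if res.defined and res.r2 >= min_r2:
                out.append((records[i].chrom, records[i].pos, records[j].pos,
                            res.r, res.r2, res.n_used))
        return out

    pairs = []
    for chunk in ordered_imap(range(len(records)), row, threads):
        pairs.extend(chunk)
    return pairs
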