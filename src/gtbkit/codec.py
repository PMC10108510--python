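"""Byte encoding of diploid genotypes (BEG) and biallelic packing (MBEG).

A genotype ``a|b`` of a variant with ``n_v`` alleles (``n_v`` in [2, 15],
reference allele 0) is mapped losslessly to one byte by the quadratic
pairing

    a|b -> (a+1)^2 - b   if a >= b
           b^2 + a + 1   if a <  b

with the fully missing genotype mapped to 0.  Unphased genotypes are folded
to ``min|max`` before encoding, so phase lives in a file-level flag, not in
the data.  Haploid calls ``a`` are stored as ``a|a`` and unfolded again on
decode when the contig declares ploidy 1.

For biallelic variants the codes are small (0..4 phased, 0..3 unphased) and
three phased / four unphased consecutive codes are packed into a single
"maximized" byte (MBEG) in base 5 / base 4.  Incomplete trailing groups are
padded by repeating the previous code, which the decoder simply ignores
beyond the subject count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_ALLELES = 15
#: BEG code of a fully missing genotype.
MISSING_CODE = 0
#: Largest BEG code for n_v = 15 (genotype 14|0 -> 15^2).
MAX_BEG = MAX_ALLELES ** 2  # 225

PHASED_GROUP = 3
UNPHASED_GROUP = 4
#: Largest packed phased MBEG value (all three digits 4).
MAX_MBEG_PHASED = 25 * 4 + 5 * 4 + 4  # 124


class CodecError(ValueError):
    """Invalid genotype or corrupt encoded data."""


@dataclass(frozen=True)
class Genotype:
    """One subject's call at one variant.

    ``a``/``b`` are allele indices (ref = 0); haploid calls carry ``a`` only
    and have ``ploidy == 1``.  A genotype with any missing allele is treated
    as fully missing.
    """

    a: int = -1
    b: int = -1
    phased: bool = True
    missing: bool = False
    ploidy: int = 2

    def alleles(self) -> tuple[int, ...]:
        if self.missing:
            return (-1,) * self.ploidy
        return (self.a,) if self.ploidy == 1 else (self.a, self.b)


def _beg_value(a: int, b: int) -> int:
    return (a + 1) ** 2 - b if a >= b else b * b + a + 1


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    forward = np.zeros((MAX_ALLELES, MAX_ALLELES), dtype=np.uint8)
    backward = np.full((MAX_BEG + 1, 2), -1, dtype=np.int16)
    for a in range(MAX_ALLELES):
        for b in range(MAX_ALLELES):
            code = _beg_value(a, b)
            forward[a, b] = code
            backward[code] = (a, b)
    zero = np.zeros(MAX_BEG + 1, dtype=np.uint8)
    for code in range(1, MAX_BEG + 1):
        a, b = backward[code]
        if a >= 0:
            zero[code] = int(a == 0) + int(b == 0)
    return forward, backward, zero


# Precomputed once per process: forward (a,b)->code, backward code->(a,b)
# (-1,-1 for codes no valid genotype produces), and per-code reference-allele
# counts used by the AMDO features.
BEG_FORWARD, BEG_BACKWARD, BEG_ZERO_COUNT = _build_tables()

#: Per-code count of non-reference alleles (missing -> 0), for AF/dosage.
BEG_ALT_COUNT = np.zeros(MAX_BEG + 1, dtype=np.uint8)
#: Per-code number of called alleles (0 for missing, 2 otherwise).
BEG_CALLED = np.zeros(MAX_BEG + 1, dtype=np.uint8)
for _code in range(1, MAX_BEG + 1):
    _a, _b = BEG_BACKWARD[_code]
    if _a >= 0:
        BEG_ALT_COUNT[_code] = int(_a > 0) + int(_b > 0)
        BEG_CALLED[_code] = 2
del _code, _a, _b


def encode_beg(g: Genotype) -> int:
    """Encode one genotype to its BEG byte."""
    if g.missing or g.a < 0 or (g.ploidy == 2 and g.b < 0):
        return MISSING_CODE
    a, b = g.a, (g.a if g.ploidy == 1 else g.b)
    if not (0 <= a < MAX_ALLELES and 0 <= b < MAX_ALLELES):
        raise CodecError(f"allele index out of range [0, {MAX_ALLELES - 1}]: {a}|{b}")
    if not g.phased and a > b:
        a, b = b, a
    return int(BEG_FORWARD[a, b])


def decode_beg(code: int, phased: bool = True, ploidy: int = 2) -> Genotype:
    """Invert :func:`encode_beg`; code 0 decodes to missing."""
    if code == MISSING_CODE:
        return Genotype(phased=phased, missing=True, ploidy=ploidy)
    if not (0 < code <= MAX_BEG) or BEG_BACKWARD[code, 0] < 0:
        raise CodecError(f"not a valid BEG code: {code}")
    a, b = (int(x) for x in BEG_BACKWARD[code])
    if ploidy == 1:
        if a != b:
            raise CodecError(f"heterozygous code {code} on a haploid contig")
        return Genotype(a=a, b=a, phased=phased, ploidy=1)
    return Genotype(a=a, b=b, phased=phased)


def pack_mbeg(begs, phased: bool) -> int:
    """Pack up to 3 (phased) or 4 (unphased) biallelic BEG codes into a byte.

    Short groups are padded by repeating the previous code.
    """
    arity = PHASED_GROUP if phased else UNPHASED_GROUP
    limit = 4 if phased else 3
    begs = list(begs)
    if not 0 < len(begs) <= arity:
        raise CodecError(f"group must hold 1..{arity} codes, got {len(begs)}")
    for v in begs:
        if not 0 <= v <= limit:
            raise CodecError(f"BEG {v} outside biallelic range 0..{limit}")
    while len(begs) < arity:
        begs.append(begs[-1])
    base = 5 if phased else 4
    out = 0
    for v in begs:
        out = out * base + v
    return out


def unpack_mbeg(m: int, phased: bool) -> list[int]:
    """Base-5 / base-4 digit extraction, inverse of :func:`pack_mbeg`."""
    arity = PHASED_GROUP if phased else UNPHASED_GROUP
    bound = MAX_MBEG_PHASED if phased else 255
    if not 0 <= m <= bound:
        raise CodecError(f"MBEG value {m} out of range 0..{bound}")
    base = 5 if phased else 4
    digits = [0] * arity
    for i in range(arity - 1, -1, -1):
        digits[i] = m % base
        m //= base
    return digits


def _mbeg_pack_array(begs: np.ndarray, phased: bool) -> np.ndarray:
    """Vectorized MBEG packing of one variant's BEG row."""
    arity = PHASED_GROUP if phased else UNPHASED_GROUP
    n = len(begs)
    groups = -(-n // arity)
    padded = np.empty(groups * arity, dtype=np.uint8)
    padded[:n] = begs
    padded[n:] = begs[-1] if n else 0  # repeat previous code
    padded = padded.reshape(groups, arity).astype(np.uint16)
    base = 5 if phased else 4
    weights = base ** np.arange(arity - 1, -1, -1, dtype=np.uint16)
    return (padded * weights).sum(axis=1).astype(np.uint8)


def _mbeg_unpack_array(packed: np.ndarray, n_subjects: int, phased: bool) -> np.ndarray:
    arity = PHASED_GROUP if phased else UNPHASED_GROUP
    base = 5 if phased else 4
    vals = packed.astype(np.uint16)
    digits = np.empty((len(packed), arity), dtype=np.uint8)
    for i in range(arity - 1, -1, -1):
        digits[:, i] = vals % base
        vals //= base
    return digits.reshape(-1)[:n_subjects]


def genotypes_to_begs(genotypes, phased: bool) -> np.ndarray:
    """Encode a list of :class:`Genotype` into a BEG row (uint8)."""
    return np.fromiter(
        (encode_beg(g if g.phased == phased else
                    Genotype(g.a, g.b, phased, g.missing, g.ploidy))
         for g in genotypes),
        dtype=np.uint8, count=len(genotypes))


def encode_variant(genotypes, biallelic: bool, phased: bool) -> bytes:
    """Byte payload of one variant across all subjects.

    Biallelic variants use ceil(N/3) (phased) or ceil(N/4) (unphased) MBEG
    bytes; multiallelic variants use one BEG byte per subject.
    """
    for g in genotypes:
        if not g.missing and g.phased != phased:
            raise CodecError("mixed phasing within a variant")
    begs = genotypes_to_begs(genotypes, phased)
    return encode_begs_row(begs, biallelic, phased)


def encode_begs_row(begs: np.ndarray, biallelic: bool, phased: bool) -> bytes:
    if biallelic:
        limit = 4 if phased else 3
        if begs.size and begs.max() > limit:
            raise CodecError("BEG code outside biallelic range")
        return _mbeg_pack_array(begs, phased).tobytes()
    return np.asarray(begs, dtype=np.uint8).tobytes()


def decode_variant(payload: bytes, n_subjects: int, biallelic: bool,
                   phased: bool) -> np.ndarray:
    """Invert :func:`encode_variant` back to a BEG row of length N."""
    raw = np.frombuffer(payload, dtype=np.uint8)
    if biallelic:
        return _mbeg_unpack_array(raw, n_subjects, phased).copy()
    if len(raw) != n_subjects:
        raise CodecError("multiallelic payload length != subject count")
    return raw.copy()


def variant_payload_len(n_subjects: int, biallelic: bool, phased: bool) -> int:
    if not biallelic:
        return n_subjects
    arity = PHASED_GROUP if phased else UNPHASED_GROUP
    return -(-n_subjects // arity)


def begs_to_allele_pairs(begs: np.ndarray) -> np.ndarray:
    """(N, 2) allele-index array, -1 for missing alleles."""
    return BEG_BACKWARD[np.asarray(begs, dtype=np.intp)]
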