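"""Block sizing, AMDO variant ordering, and the compression boundary model.

Blocks are the unit of compression.  The number of variants a block may hold
is a power of two chosen from the sample size so that one decoded block never
exceeds the 2^31 - 2 genotype-code budget (~2 GB).

AMDO (approximate minimum discrepancy ordering) reorders the variants of a
block so rows with similar genotype distributions become adjacent, which
markedly improves the downstream compressor's ratio.  Each variant is
summarized by ``s`` windowed, accumulation-weighted counts of reference
alleles, and variants are sorted by those feature vectors.

The boundary model ``E_s = max(alpha * s, beta)`` upper-bounds a compressor's
output size and is used to pre-allocate buffers; its constants are obtained
by grid search over random trial inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codec import BEG_ZERO_COUNT

MAX_SUBJECTS = 16_777_215  # 2^24 - 1
_GENO_BUDGET = 2**31 - 2
DEFAULT_WINDOWS = 24


class CapacityError(ValueError):
    """No valid block size exists for this sample size."""


def block_capacity(n_subjects: int) -> int:
    """Largest 2^n, 7 <= n <= 14, with 2^n * M <= 2^31 - 2.

    E.g. 16,384 variants for 131,071 subjects, down to 128 variants for the
    format's 16,777,215-subject ceiling.
    """
    if n_subjects < 1:
        raise CapacityError("subject count must be positive")
    if n_subjects > MAX_SUBJECTS:
        raise CapacityError(
            f"{n_subjects} subjects exceeds the {MAX_SUBJECTS} format limit")
    for n in range(14, 6, -1):
        if (1 << n) * n_subjects <= _GENO_BUDGET:
            return 1 << n
    raise CapacityError(f"no block size fits {n_subjects} subjects")


def zero_counts(begs: np.ndarray) -> np.ndarray:
    """Per-subject reference-allele counts of one variant's BEG row.

    Diploid non-missing genotypes contribute 0, 1 or 2; missing genotypes
    contribute 0 (they carry no reference allele).  Haploid calls are stored
    doubled (a|a) and therefore count 2 when reference.
    """
    return BEG_ZERO_COUNT[np.asarray(begs, dtype=np.intp)]


def amdo_features(counts: np.ndarray, s: int = DEFAULT_WINDOWS) -> np.ndarray:
    """Accumulated down-sampling feature vector of a zero-count vector.

    Window ``i`` covers subjects ``i*l .. min(N-1, (i+1)*l - 1)`` with
    ``l = ceil(N/s)`` and accumulates ``sum_j sum_{k<=j} c_k``, i.e. weights
    count ``c_k`` by ``hi - k + 1``.  Trailing empty windows are 0.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = len(counts)
    if n < 1 or s < 1:
        raise ValueError("need at least one subject and one window")
    l = -(-n // s)
    out = np.zeros(s, dtype=np.int64)
    for i in range(s):
        lo = i * l
        if lo > n - 1:
            break
        hi = min(n - 1, (i + 1) * l - 1)
        k = np.arange(lo, hi + 1)
        out[i] = int(((hi - k + 1) * counts[lo:hi + 1]).sum())
    return out


def amdo_order(features, multiallelic_flags) -> np.ndarray:
    """AMDO permutation of variant indices within a block.

    Biallelic variants come first, ordered so a lexicographically larger
    feature vector sorts earlier; multiallelic variants follow with the
    inverted (ascending) comparator.  Ties keep original order.
    """
    feats = [tuple(int(v) for v in f) for f in features]
    flags = list(multiallelic_flags)
    if len(feats) != len(flags):
        raise ValueError("one multiallelic flag per feature vector required")
    bi = [i for i, m in enumerate(flags) if not m]
    multi = [i for i, m in enumerate(flags) if m]
    neg = lambda i: tuple(-v for v in feats[i])
    bi.sort(key=neg)          # descending lexicographic, stable
    multi.sort(key=lambda i: feats[i])  # inverted: ascending, stable
    return np.asarray(bi + multi, dtype=np.intp)


@dataclass(frozen=True)
class BoundaryModel:
    """Affine-with-floor bound max(alpha*s, beta) on compressed size."""

    alpha: float
    beta: int
    name: str = ""

    def __post_init__(self):
        if self.alpha < 1 or self.beta <= 0:
            raise ValueError("require alpha >= 1 and beta > 0")


#: Calibrated constants for the three embedded compressors.
ZSTD_BOUND = BoundaryModel(1.0014, 7168, "zstd")
LZMA_BOUND = BoundaryModel(1.0167, 7680, "lzma")
GZIP_BOUND = BoundaryModel(1.0031, 7680, "gzip")

BOUND_PRESETS = {"zstd": ZSTD_BOUND, "lzma": LZMA_BOUND, "gzip": GZIP_BOUND}


def estimate_bound(s: int, model: BoundaryModel) -> int:
    """Estimated compressed-size upper bound for an input of ``s`` bytes."""
    if s < 0:
        raise ValueError("size must be non-negative")
    return int(max(model.alpha * s, model.beta))


class CalibrationError(RuntimeError):
    pass


def calibrate_boundary(compress_fn, trials,
                       alpha_grid=None, beta_step: int = 512,
                       beta_max: int = 1 << 20) -> BoundaryModel:
    """Fit (alpha, beta) by grid search over random trial inputs.

    Minimizes ``1(E_s < R_s) + alpha + beta / (10 * 1024^2)`` subject to the
    bound dominating every observed compressed size ``R_s``; alpha on a grid
    of 1.0000..1.1000 step 0.0001, beta on 512, 1024, 1536, ...
    """
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(1.0, 1.1 + 1e-9, 0.0001), 4)
    sizes = np.array([len(t) for t in trials], dtype=np.int64)
    comp = np.array([len(compress_fn(bytes(t))) for t in trials],
                    dtype=np.int64)
    best = None
    for beta in range(beta_step, beta_max + 1, beta_step):
        over = comp > beta  # trials the floor alone cannot cover
        if not over.any():
            alpha_req = 1.0
        else:
            with np.errstate(divide="ignore"):
                alpha_req = float(np.max(comp[over] / np.maximum(sizes[over], 1)))
        idx = np.searchsorted(alpha_grid, alpha_req - 1e-12)
        if idx >= len(alpha_grid):
            continue
        alpha = float(alpha_grid[idx])
        objective = alpha + beta / (10 * 1024**2)
        if best is None or objective < best[0]:
            best = (objective, alpha, beta)
    if best is None:
        raise CalibrationError("no feasible (alpha, beta) on the grid")
    return BoundaryModel(best[1], best[2])
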