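"""Shared fixtures and independent text-level oracles for the suite."""

from __future__ import annotations

import gzip

import pytest

import gtbkit


def read_vcf_text(path, fold_unphased=False):
    """Independent text-level VCF reader used as the round-trip oracle.

    Returns (chrom, pos, ref, alt, gt tuple) per record.  With
    ``fold_unphased`` every unphased diploid GT is normalized to min/max
    order, the storage normalization the codec applies.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            gts = []
            for gt in f[9:]:
                if fold_unphased and "/" in gt and "." not in gt:
                    a, b = sorted(int(x) for x in gt.split("/"))
                    gt = f"{a}/{b}"
                gts.append(gt)
            records.append((f[0], int(f[1]), f[3], f[4], tuple(gts)))
    return records


def records_from_gtb(path, **kw):
    """(chrom, pos, ref, alt, gt tuple) view of a GTB via the query engine."""
    return [(r.chrom, r.pos, r.ref, r.alt, tuple(r.gt_strings()))
            for r in gtbkit.extract(path, **kw)]


@pytest.fixture
def dataset(tmp_path):
    """Factory: synthetic VCF + its GTB, configurable per test."""

    def make(seed=0, subjects=40, variants=200, chroms=("1",), phased=True,
             name="d", threads=1, **kw):
        vcf = gtbkit.generate_vcf(
            str(tmp_path / f"{name}.vcf"), subjects=subjects,
            variants=variants, chroms=chroms, phased=phased, seed=seed, **kw)
        gtb = gtbkit.compress(vcf, str(tmp_path / f"{name}.gtb"),
                              phased=phased, threads=threads)
        return vcf, gtb

    return make
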