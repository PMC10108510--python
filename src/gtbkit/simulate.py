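"""Synthetic VCF generation for tests and benchmarks.

Genotypes are drawn by sampling each subject's haplotypes from a small pool
of template haplotypes and adding per-site mutation noise.  Because subjects
share templates, nearby variants are strongly correlated (realistic LD /
haplotype-block structure), which is exactly the redundancy AMDO and the
block compressor exploit.  The generator is a documented stand-in for real
cohort data: it does not model recombination hotspots, allele-frequency
spectra or genotyping-error modes of real call sets.

Coordinate disorder is introduced by displacing a fraction ``disorder`` of
records to random positions in the output, emulating unsorted call sets.
Output is deterministic for a given seed.
"""

from __future__ import annotations

import gzip
import os

import numpy as np

from .gtb import ContigSpec, default_human_contig

_BASES = "ACGT"


def _allele_strings(n_alleles: int, rng) -> tuple[str, list[str]]:
    ref = _BASES[rng.integers(4)]
    pool = [b for b in _BASES if b != ref]
    pool += [a + b for a in _BASES for b in _BASES]
    return ref, pool[:n_alleles - 1]


def generate_vcf(path=None, *, subjects: int = 100, variants: int = 1000,
                 chroms=("1",), allele_count_dist=None, phased: bool = True,
                 missing_rate: float = 0.01, templates: int = 10,
                 mutation_rate: float = 0.01, disorder: float = 0.0,
                 seed: int = 0, contig: ContigSpec | None = None,
                 pos_span: int | None = None):
    """Write (or return as text) a synthetic VCF.

    Parameters mirror the study conditions of the compression experiments:
    ``templates`` haplotype templates per chromosome with ``mutation_rate``
    per-site noise, ``missing_rate`` per-genotype missingness, an
    ``allele_count_dist`` mapping allele counts (2..15) to probabilities
    (default 90% biallelic, 7% tri-, 3% quad-allelic), and ``disorder`` as
    the displaced-record fraction.  Haploid contigs (ploidy 1) emit
    single-allele calls.
    """
    if allele_count_dist is None:
        allele_count_dist = {2: 0.90, 3: 0.07, 4: 0.03}
    if contig is None:
        contig = default_human_contig()
    for c in chroms:
        contig.index(c)  # raises for unknown labels
    rng = np.random.default_rng(seed)
    n_alleles_choices = np.array(sorted(allele_count_dist))
    n_alleles_probs = np.array([allele_count_dist[k] for k in n_alleles_choices],
                               dtype=float)
    n_alleles_probs = n_alleles_probs / n_alleles_probs.sum()

    header = ["##fileformat=VCFv4.2", "##source=gtbkit-simulate"]
    header += [f"##contig=<ID={lab},length={ln},ploidy={p}>"
               for lab, p, ln in contig.entries if lab in set(chroms)]
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    names = [f"S{i:04d}" for i in range(subjects)]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(names))

    per_chrom = [variants // len(chroms)] * len(chroms)
    for i in range(variants % len(chroms)):
        per_chrom[i] += 1

    sep = "|" if phased else "/"
    records = []
    for label, v_c in zip(chroms, per_chrom):
        if v_c == 0:
            continue
        ploidy = contig.ploidy(label)
        span = pos_span or min(max(10 * v_c, 10_000), contig.length(label))
        positions = np.sort(rng.choice(np.arange(1, span + 1), size=v_c,
                                       replace=False))
        n_alleles = rng.choice(n_alleles_choices, size=v_c, p=n_alleles_probs)
        # template haplotypes: biased toward the reference allele
        tmpl = np.zeros((templates, v_c), dtype=np.int8)
        nonref = rng.random((templates, v_c)) > 0.6
        tmpl[nonref] = 1
        multi = n_alleles > 2
        if multi.any():
            extra = rng.integers(1, n_alleles[multi][None, :],
                                 size=(templates, int(multi.sum())))
            tmpl[:, multi] = np.where(nonref[:, multi], extra, 0)
        n_hap = ploidy * subjects
        hap_tmpl = rng.integers(0, templates, size=n_hap)
        haps = tmpl[hap_tmpl]                       # (n_hap, v_c)
        mut = rng.random((n_hap, v_c)) < mutation_rate
        if mut.any():
            repl = rng.integers(0, n_alleles[None, :].repeat(n_hap, axis=0))
            haps = np.where(mut, repl.astype(np.int8), haps)
        miss = rng.random((subjects, v_c)) < missing_rate
        for j in range(v_c):
            ref, alts = _allele_strings(int(n_alleles[j]), rng)
            gts = []
            for si in range(subjects):
                if miss[si, j]:
                    gts.append("." if ploidy == 1 else f".{sep}.")
                elif ploidy == 1:
                    gts.append(str(haps[si, j]))
                else:
                    gts.append(f"{haps[2 * si, j]}{sep}{haps[2 * si + 1, j]}")
            records.append(f"{label}\t{positions[j]}\t.\t{ref}\t"
                           f"{','.join(alts)}\t.\tPASS\t.\tGT\t" + "\t".join(gts))

    if disorder > 0 and len(records) > 1:
        n_move = int(round(disorder * len(records)))
        move = rng.choice(len(records), size=min(n_move, len(records)),
                          replace=False)
        moved = [records[i] for i in move]
        keep = [r for i, r in enumerate(records) if i not in set(move.tolist())]
        for line in moved:
            keep.insert(int(rng.integers(0, len(keep) + 1)), line)
        records = keep

    text = "\n".join(header + records) + "\n"
    if path is None:
        return text
    path = os.fspath(path)
    if path.endswith(".gz"):
        # fixed mtime so identical seeds give byte-identical archives
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(text.encode())
    else:
        with open(path, "w") as fh:
            fh.write(text)
    return path
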