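"""Build pipeline and query engine: chunking, lossless round trips,
addressing, region/subject/AF queries against brute-force oracles."""

import numpy as np
import pytest

import gtbkit
from gtbkit import codec
from gtbkit.build import (QCRules, VariantBatch, build_block, chunk_input,
                          compress, qc_filter)
from gtbkit.compressors import get_compressor
from gtbkit.gtb import GTBManager, read_header
from gtbkit.query import (decode_block, iter_records, locate_blocks,
                          variant_af, variant_pointer)

from conftest import read_vcf_text, records_from_gtb


class TestChunking:
    def test_single_thread_single_chunk(self, tmp_path):
        vcf = gtbkit.generate_vcf(str(tmp_path / "a.vcf"), subjects=5,
                                  variants=50, seed=0)
        chunks = chunk_input([vcf], 1)
        assert len(chunks) == 1
        assert chunks[0][0].start == 0 and chunks[0][-1].stop == 50

    def test_even_byte_split_aligned_to_records(self, tmp_path):
        vcf = gtbkit.generate_vcf(str(tmp_path / "a.vcf"), subjects=20,
                                  variants=200, seed=1)
        chunks = chunk_input([vcf], 4)
        assert len(chunks) == 4
        # chunks partition the records
        spans = [(c[0].start, c[-1].stop) for c in chunks]
        assert spans[0][0] == 0 and spans[-1][1] == 200
        for (_, stop), (start, _) in zip(spans, spans[1:]):
            assert stop == start
        # each boundary within one record of the even byte split
        sizes = [sum(c.byte_stop - c.byte_start for c in chunk)
                 for chunk in chunks]
        total = sum(sizes)
        per_record = total / 200
        running = 0
        for i, s in enumerate(sizes[:-1]):
            running += s
            assert abs(running - (i + 1) * total / 4) <= 1.5 * per_record

    def test_chunks_cover_gz_input(self, tmp_path):
        vcf = gtbkit.generate_vcf(str(tmp_path / "a.vcf.gz"), subjects=5,
                                  variants=30, seed=2)
        chunks = chunk_input([vcf], 2)
        assert sum(c.stop - c.start for ch in chunks for c in ch) == 30


class TestBlockBuild:
    def _batch(self, rows, positions=None, biallelic=None):
        batch = VariantBatch(0)
        for i, row in enumerate(rows):
            batch.add((positions or range(1, len(rows) + 1))[i], "A", "C",
                      ".", np.asarray(row, dtype=np.uint8),
                      True if biallelic is None else biallelic[i])
        return batch

    def test_single_variant_payload_width(self):
        comp = get_compressor("zstd")
        rec, entity = build_block(self._batch([[1, 2, 3, 4]]), comp, True)
        raw = comp.decompress(entity[:rec.len_b1])
        assert len(raw) == 2          # ceil(4/3) MBEG bytes

    def test_identical_rows_compress_smaller_than_random(self):
        rng = np.random.default_rng(0)
        comp = get_compressor("zstd")
        same = [[1] * 60] * 40
        rand = rng.integers(1, 5, size=(40, 60)).tolist()
        rec_s, _ = build_block(self._batch(same), comp, True)
        rec_r, _ = build_block(self._batch(rand), comp, True)
        assert rec_s.len_b1 < rec_r.len_b1

    def test_positions_round_trip_amdo_permuted(self):
        rng = np.random.default_rng(1)
        comp = get_compressor("zstd")
        rows = rng.integers(1, 5, size=(20, 30)).tolist()
        pos = list(range(100, 120))
        rec, entity = build_block(self._batch(rows, positions=pos), comp, True)
        raw = comp.decompress(entity[rec.len_b1:rec.len_b1 + rec.len_b2])
        got = np.frombuffer(raw, dtype=">u4")
        assert sorted(got.tolist()) == pos       # a permutation of the input
        assert rec.min_pos == 100 and rec.max_pos == 119

    def test_chromosome_change_breaks_block(self, tmp_path):
        vcf = gtbkit.generate_vcf(str(tmp_path / "m.vcf"), subjects=5,
                                  variants=3, chroms=("1", "2"), seed=3)
        gtb = compress(vcf, str(tmp_path / "m.gtb"))
        mgr = read_header(gtb)
        assert mgr.header.block_count == 2
        assert len({n.record.chromosome for n in mgr.nodes}) == 2


CONFIGS = [
    dict(phased=True),
    dict(phased=False),
    dict(phased=True, allele_count_dist={2: 0.5, 3: 0.2, 8: 0.2, 15: 0.1}),
    dict(phased=False, missing_rate=0.2),
    dict(phased=True, chroms=("1", "Y", "MT")),      # haploid contigs
    dict(phased=False, chroms=("2", "X"), templates=3),
]


class TestLosslessRoundTrip:
    @pytest.mark.parametrize("cfg", CONFIGS)
    def test_vcf_gtb_vcf(self, tmp_path, cfg):
        cfg = dict(cfg)
        phased = cfg.pop("phased")
        vcf = gtbkit.generate_vcf(str(tmp_path / "rt.vcf"), subjects=30,
                                  variants=120, phased=phased, seed=11, **cfg)
        gtb = compress(vcf, str(tmp_path / "rt.gtb"), phased=phased)
        assert records_from_gtb(gtb) == read_vcf_text(vcf, fold_unphased=True)

    def test_extract_to_vcf_file_round_trips(self, tmp_path, dataset):
        vcf, gtb = dataset(seed=12, subjects=15, variants=60)
        out = str(tmp_path / "out.vcf.gz")
        gtbkit.extract(gtb, out)
        assert read_vcf_text(out) == read_vcf_text(vcf, fold_unphased=True)

    def test_thread_invariance(self, tmp_path):
        vcf = gtbkit.generate_vcf(str(tmp_path / "t.vcf"), subjects=25,
                                  variants=400, chroms=("1", "2"), seed=13)
        g1 = compress(vcf, str(tmp_path / "t1.gtb"), threads=1)
        g8 = compress(vcf, str(tmp_path / "t8.gtb"), threads=8)
        assert records_from_gtb(g1) == records_from_gtb(g8)


class TestMultiFile:
    def test_missing_subjects_filled_and_major_defines_order(self, tmp_path):
        a = gtbkit.generate_vcf(str(tmp_path / "a.vcf"), subjects=10,
                                variants=30, seed=20)
        btxt = gtbkit.generate_vcf(subjects=7, variants=20, seed=21,
                                   chroms=("2",))
        (tmp_path / "b.vcf").write_text(btxt)
        gtb = compress([a, str(tmp_path / "b.vcf")], str(tmp_path / "ab.gtb"))
        mgr = read_header(gtb)
        assert list(mgr.subjects) == [f"S{i:04d}" for i in range(10)]
        recs = records_from_gtb(gtb)
        assert len(recs) == 50
        for chrom, pos, ref, alt, gts in recs:
            if chrom == "2":     # subjects S0007..S0009 absent from file b
                assert set(gts[7:]) == {".|."}

    def test_unknown_subject_errors(self, tmp_path):
        a = gtbkit.generate_vcf(str(tmp_path / "a.vcf"), subjects=6,
                                variants=10, seed=22)
        text = gtbkit.generate_vcf(subjects=5, variants=10, seed=23)
        (tmp_path / "b.vcf").write_text(text.replace("S0004", "OTHER"))
        with pytest.raises(Exception, match="absent from the major"):
            compress([a, str(tmp_path / "b.vcf")], str(tmp_path / "x.gtb"))


class TestQC:
    def test_no_rules_is_identity(self):
        row = np.array([1, 2, 3], dtype=np.uint8)
        assert qc_filter(row, {}, None) is row

    def test_gq_threshold_masks_genotypes(self):
        row = np.array([1, 2, 3], dtype=np.uint8)
        out = qc_filter(row, {"GQ": np.array([50, 5, 50])},
                        QCRules(min_gq=20))
        assert out.tolist() == [1, 0, 3]

    def test_missing_rate_drops_variant(self):
        row = np.zeros(4, dtype=np.uint8)
        assert qc_filter(row, {}, QCRules(max_missing_rate=0.99)) is None

    def test_absent_format_disables_rule(self):
        row = np.array([1, 1], dtype=np.uint8)
        out = qc_filter(row, {}, QCRules(min_gq=20))
        assert out.tolist() == [1, 1]


class TestAddressing:
    @pytest.mark.parametrize("m,expected", [(0, 0), (1, 2), (2, 4), (3, 9)])
    def test_variant_pointer_examples(self, m, expected):
        # 2 biallelic then multiallelic variants, N=5 subjects, phased (l=3)
        assert variant_pointer(m, 2, 5, 3) == expected

    def test_pointer_out_of_range(self):
        with pytest.raises(IndexError):
            variant_pointer(-1, 2, 5, 3)

    def test_random_probes_match_full_decode(self, dataset):
        _, gtb = dataset(seed=30, subjects=37, variants=300,
                         allele_count_dist={2: 0.8, 3: 0.2})
        mgr = read_header(gtb)
        rng = np.random.default_rng(30)
        for node in mgr.nodes:
            block = decode_block(mgr, node)
            full = block.full_matrix()
            for _ in range(400):
                m = int(rng.integers(0, block.n_variants))
                n = int(rng.integers(0, block.n_subjects))
                assert block.genotype_at(m, n) == full[m, n]


def brute_query(vcf, fold, chrom=None, lo=0, hi=2**32 - 1, cols=None):
    out = []
    for c, p, ref, alt, gts in read_vcf_text(vcf, fold_unphased=fold):
        if chrom is not None and c != chrom:
            continue
        if not lo <= p <= hi:
            continue
        if cols is not None:
            gts = tuple(gts[i] for i in cols)
        out.append((c, p, ref, alt, gts))
    return out


class TestQueries:
    def test_region_queries_match_oracle(self, dataset):
        vcf, gtb = dataset(seed=31, subjects=20, variants=250,
                           chroms=("1", "2"))
        rng = np.random.default_rng(31)
        for _ in range(15):
            chrom = str(rng.integers(1, 3))
            lo = int(rng.integers(0, 3000))
            hi = lo + int(rng.integers(0, 3000))
            got = records_from_gtb(gtb, regions=[f"{chrom}:{lo}-{hi}"])
            assert got == brute_query(vcf, True, chrom, lo, hi)

    def test_subject_subset_matches_source_column(self, dataset):
        vcf, gtb = dataset(seed=32, subjects=30, variants=100)
        got = records_from_gtb(gtb, subjects=["S0017"])
        assert got == brute_query(vcf, True, cols=[17])

    def test_unknown_subject_listed(self, dataset):
        _, gtb = dataset(seed=33, subjects=5, variants=20)
        with pytest.raises(Exception, match="NOPE"):
            list(iter_records(gtb, subjects=["NOPE"]))

    def test_extract_all_equals_full_decompression(self, dataset):
        _, gtb = dataset(seed=34, subjects=10, variants=80)
        mgr = read_header(gtb)
        label = mgr.contig.label(mgr.nodes[0].record.chromosome)
        assert records_from_gtb(gtb, regions=[label]) == records_from_gtb(gtb)

    def test_multi_region_single_pass(self, dataset, monkeypatch):
        _, gtb = dataset(seed=35, subjects=10, variants=900,
                         chroms=("1", "2", "3"))
        mgr = read_header(gtb)
        assert mgr.header.block_count >= 3
        reads = []
        orig = GTBManager.entity_bytes
        monkeypatch.setattr(GTBManager, "entity_bytes",
                            lambda self, node: (reads.append(node.file_index),
                                                orig(self, node))[1])
        regions = ["1:1-2000", "1:2500-4000", "2:1-3000", "3"]
        records_from_gtb(mgr, regions=regions)
        assert len(reads) == len(set(reads))     # each block read once

    def test_unordered_file_parity(self, tmp_path):
        kw = dict(subjects=15, variants=300, seed=36, chroms=("1", "2"))
        sorted_vcf = gtbkit.generate_vcf(str(tmp_path / "s.vcf"), **kw)
        messy_vcf = gtbkit.generate_vcf(str(tmp_path / "u.vcf"),
                                        disorder=0.5, **kw)
        gs = compress(sorted_vcf, str(tmp_path / "s.gtb"))
        gu = compress(messy_vcf, str(tmp_path / "u.gtb"))
        assert read_header(gu).header.ordered is False
        q = ["1:2000-6000"]
        assert sorted(records_from_gtb(gu, regions=q)) == \
            sorted(records_from_gtb(gs, regions=q))

    def test_locate_blocks_edges(self, dataset):
        _, gtb = dataset(seed=37, subjects=10, variants=50)
        mgr = read_header(gtb)
        chrom = mgr.nodes[0].record.chromosome
        top = max(n.record.max_pos for n in mgr.tree.nodes(chrom))
        assert locate_blocks(mgr.tree, chrom, top + 1, top + 100) == []
        assert len(locate_blocks(mgr.tree, chrom, 0, top)) \
            == len(mgr.tree.nodes(chrom))


class TestAlleleFrequency:
    def test_hand_counted_af(self):
        row = np.array([codec.encode_beg(codec.Genotype(*p)) for p in
                        [(0, 0), (0, 1), (1, 1)]] + [0], dtype=np.uint8)
        assert variant_af(row) == pytest.approx(3 / 6)

    def test_zero_called_returns_none(self):
        assert variant_af(np.zeros(5, dtype=np.uint8)) is None

    def test_multiallelic_aggregate_and_per_allele(self):
        row = np.array([codec.encode_beg(codec.Genotype(*p)) for p in
                        [(0, 1), (2, 2), (0, 0)]], dtype=np.uint8)
        assert variant_af(row) == pytest.approx(3 / 6)
        assert variant_af(row, per_allele=True) == \
            pytest.approx((1 / 6, 2 / 6))

    def test_filter_matches_oracle(self, dataset):
        vcf, gtb = dataset(seed=38, subjects=25, variants=150,
                           missing_rate=0.1)
        got = {(r.chrom, r.pos) for r in gtbkit.filter_af(gtb, 0.2, 0.6)}
        expect = set()
        for c, p, ref, alt, gts in read_vcf_text(vcf):
            alleles = [int(x) for gt in gts for x in
                       gt.replace("|", "/").split("/") if x != "."]
            if alleles and 0.2 <= np.mean([a > 0 for a in alleles]) <= 0.6:
                expect.add((c, p))
        assert got == expect

    def test_full_af_band_keeps_called_variants(self, dataset):
        vcf, gtb = dataset(seed=39, subjects=10, variants=60)
        n_called = sum(
            any("." not in gt for gt in gts)
            for _, _, _, _, gts in read_vcf_text(vcf))
        assert len(list(gtbkit.filter_af(gtb, 0, 1))) == n_called
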