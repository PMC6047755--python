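import struct
import zlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicbox import (
    ChromosomeTable,
    ConfigError,
    ContainerReader,
    CorruptBlock,
    GenomicLocus,
    InputError,
    MalformedContainer,
    NormNotAvailable,
    UnsupportedFormat,
    build_container,
    query_region,
    read_header,
)
from hicbox.container import MAGIC, VERSION
from hicbox.remote import LocalByteSource

from conftest import oracle_dense_pair, random_records


def _build(tmp_path, recs, table, resolutions, name="c.hicj", **kw):
    path = tmp_path / name
    build_container(recs, table, str(path), resolutions=resolutions, **kw)
    return str(path)


class TestBuildAndDump:
    def test_three_contacts_match_brute_force(self, tmp_path):
        """Binned dump of a tiny 1 kb chromosome equals hand binning."""
        table = ChromosomeTable([("toy", 1000)])
        recs = [("toy", 150, "toy", 850, 1.0), ("toy", 151, "toy", 851, 1.0), ("toy", 20, "toy", 30, 1.0)]
        path = _build(tmp_path, recs, table, [100])
        with ContainerReader(path) as r:
            m = query_region(r, GenomicLocus("toy", 0, 1000), GenomicLocus("toy", 0, 1000), 100)
        expected = oracle_dense_pair(recs, table, "toy", "toy", 100)
        assert m.values.shape == (10, 10)
        np.testing.assert_array_equal(m.values, expected)

    def test_empty_contact_stream_yields_valid_zero_container(self, tmp_path, toy_table):
        path = _build(tmp_path, [], toy_table, [100])
        with ContainerReader(path) as r:
            assert r.chromosomes.names() == ["chrA", "chrB"]
            for name in ("chrA", "chrB"):
                full = GenomicLocus(name, 0, toy_table[name].length)
                m = query_region(r, full, full, 100)
                assert m.values.sum() == 0

    def test_reversed_intra_record_stored_once_upper_triangle(self, tmp_path):
        table = ChromosomeTable([("toy", 1000)])
        path = _build(tmp_path, [("toy", 500, "toy", 100, 1.0)], table, [100])
        with ContainerReader(path) as r:
            a = query_region(r, GenomicLocus("toy", 400, 500), GenomicLocus("toy", 0, 100), 100)
            b = query_region(r, GenomicLocus("toy", 0, 100), GenomicLocus("toy", 400, 500), 100)
            full = query_region(r, GenomicLocus("toy", 0, 1000), GenomicLocus("toy", 0, 1000), 100)
        assert a.values[0, 0] == 1.0 == b.values[0, 0]
        # stored once: upper triangle total equals input total
        assert np.triu(full.values).sum() == 1.0

    def test_unknown_chromosome_names_record(self, tmp_path, toy_table):
        with pytest.raises(InputError, match="record 2"):
            build_container(
                [("chrA", 1, "chrA", 2, 1.0), ("chrZ", 1, "chrA", 2, 1.0)],
                toy_table,
                str(tmp_path / "x.hicj"),
                resolutions=[100],
            )

    def test_position_beyond_chromosome_rejected(self, tmp_path, toy_table):
        with pytest.raises(InputError, match="position"):
            build_container(
                [("chrA", 1001, "chrA", 2, 1.0)], toy_table, str(tmp_path / "x.hicj"),
                resolutions=[100],
            )

    def test_empty_resolution_list_rejected(self, tmp_path, toy_table):
        with pytest.raises(ConfigError):
            build_container([], toy_table, str(tmp_path / "x.hicj"), resolutions=[])


class TestHeader:
    def test_header_roundtrip(self, toy_container):
        reader, _, path = toy_container
        h = reader.header
        assert h.magic == MAGIC and h.version == VERSION
        assert h.chromosomes.names() == ["chrA", "chrB"]
        assert h.resolutions == (500, 250, 100)

    def test_three_byte_file_is_malformed(self, tmp_path):
        p = tmp_path / "tiny"
        p.write_bytes(b"abc")
        with pytest.raises(MalformedContainer):
            read_header(LocalByteSource(str(p)))

    def test_wrong_magic_is_unsupported(self, tmp_path):
        p = tmp_path / "xxxx"
        p.write_bytes(b"XXXX" + b"\0" * 100)
        with pytest.raises(UnsupportedFormat):
            read_header(LocalByteSource(str(p)))


class TestBlocks:
    def test_single_record_roundtrip(self, tmp_path):
        table = ChromosomeTable([("toy", 1000)])
        path = _build(tmp_path, [("toy", 501, "toy", 701, 2.0)], table, [100])
        with ContainerReader(path) as r:
            (entry,) = r.all_block_entries()
            block = r.read_block(entry)
            assert (block.bin_x[0], block.bin_y[0], block.count[0]) == (5, 7, 2.0)

    def test_unindexed_grid_cell_returns_empty_without_io(self, toy_container):
        reader, _, _ = toy_container
        # resolution present but pair grid cell with no block indexed
        entries = reader.block_entries(0, 0, 100)
        missing = max(entries) + 1000
        assert missing not in entries  # caller sees no entry, so no read happens

    def test_flipped_byte_raises_corrupt_block(self, tmp_path):
        table = ChromosomeTable([("toy", 1000)])
        path = _build(tmp_path, [("toy", 501, "toy", 701, 2.0)], table, [100])
        with ContainerReader(path) as r:
            (entry,) = r.all_block_entries()
        blob = bytearray(open(path, "rb").read())
        blob[entry.offset + entry.size // 2] ^= 0xFF
        bad = tmp_path / "bad.hicj"
        bad.write_bytes(bytes(blob))
        with ContainerReader(str(bad)) as r:
            with pytest.raises(CorruptBlock) as exc:
                r.read_block(r.all_block_entries()[0])
        assert exc.value.block_number == entry.block_number

    def test_every_nonzero_bin_reachable_through_exactly_one_block(self, toy_container):
        """Index completeness: nonzero bins partition across indexed blocks."""
        reader, recs, _ = toy_container
        for res in reader.resolutions:
            entries = reader.block_entries(0, 0, res)
            seen = {}
            for entry in entries.values():
                block = reader.read_block(entry)
                for x, y in zip(block.bin_x, block.bin_y):
                    key = (int(x), int(y))
                    assert key not in seen, "bin stored in two blocks"
                    seen[key] = entry.block_number
            table = reader.chromosomes
            expected = oracle_dense_pair(recs, table, "chrA", "chrA", res)
            nz = {(i, j) for i, j in zip(*np.nonzero(np.triu(expected)))}
            assert set(seen) == nz


class TestNormVectors:
    def test_zero_coverage_bin_is_nan_others_positive(self, tmp_path):
        table = ChromosomeTable([("toy", 300)])
        recs = [("toy", 50, "toy", 250, 1.0)]  # bin 1 has no coverage
        path = _build(tmp_path, recs, table, [100])
        with ContainerReader(path) as r:
            v = r.read_norm_vector("BALANCED", 0, 100)
        assert np.isnan(v.values[1])
        assert (v.values[[0, 2]] > 0).all()

    def test_missing_resolution_raises_norm_not_available(self, toy_container):
        reader, _, _ = toy_container
        with pytest.raises(NormNotAvailable):
            reader.read_norm_vector("VC", 0, 12345)

    def test_vector_roundtrips_bit_exactly(self, toy_container):
        """Stored float64 factors survive write/read without any change."""
        reader, recs, _ = toy_container
        from hicbox.normalization import compute_balanced_norm, sparse_symmetric

        expected = oracle_dense_pair(recs, reader.chromosomes, "chrA", "chrA", 100)
        import scipy.sparse as sp

        values, _ = compute_balanced_norm(sp.csr_matrix(expected))
        stored = reader.read_norm_vector("BALANCED", 0, 100).values
        assert stored.tobytes() == values.tobytes()

    def test_none_synthesized_as_ones(self, toy_container):
        reader, _, _ = toy_container
        v = reader.read_norm_vector("NONE", 0, 100)
        assert (v.values == 1.0).all() and len(v) == 10


@st.composite
def contact_lists(draw):
    n = draw(st.integers(0, 60))
    recs = []
    for _ in range(n):
        c1 = draw(st.sampled_from(["chrA", "chrB"]))
        c2 = draw(st.sampled_from(["chrA", "chrB"]))
        p1 = draw(st.integers(1, 1000 if c1 == "chrA" else 800))
        p2 = draw(st.integers(1, 1000 if c2 == "chrA" else 800))
        cnt = draw(st.integers(1, 5))
        recs.append((c1, p1, c2, p2, float(cnt)))
    return recs


class TestRoundTripProperty:
    @settings(max_examples=100)
    @given(recs=contact_lists())
    def test_dump_equals_brute_force_binning(self, tmp_path_factory, recs):
        """Any random contact list round-trips exactly through the container."""
        table = ChromosomeTable([("chrA", 1000), ("chrB", 800)])
        tmp = tmp_path_factory.mktemp("rt")
        path = str(tmp / "c.hicj")
        build_container(recs, table, path, resolutions=[500, 100], norms=[])
        with ContainerReader(path) as r:
            for res in (500, 100):
                for cx, cy in (("chrA", "chrA"), ("chrA", "chrB"), ("chrB", "chrA")):
                    lx = GenomicLocus(cx, 0, table[cx].length)
                    ly = GenomicLocus(cy, 0, table[cy].length)
                    got = query_region(r, lx, ly, res).values
                    expected = oracle_dense_pair(recs, table, cx, cy, res)
                    np.testing.assert_array_equal(got, expected)

    @settings(max_examples=25)
    @given(recs=contact_lists())
    def test_sum_conservation_per_pair(self, tmp_path_factory, recs):
        """Upper-triangle (intra) / full-rectangle (inter) totals match input."""
        table = ChromosomeTable([("chrA", 1000), ("chrB", 800)])
        tmp = tmp_path_factory.mktemp("sum")
        path = str(tmp / "c.hicj")
        build_container(recs, table, path, resolutions=[500, 100], norms=[])
        intra_total = sum(c for a, _, b, _, c in recs if a == b == "chrA")
        inter_total = sum(c for a, _, b, _, c in recs if {a, b} == {"chrA", "chrB"})
        with ContainerReader(path) as r:
            for res in (500, 100):
                full_a = GenomicLocus("chrA", 0, 1000)
                full_b = GenomicLocus("chrB", 0, 800)
                m = query_region(r, full_a, full_a, res).values
                assert np.triu(m).sum() == pytest.approx(intra_total)
                assert query_region(r, full_a, full_b, res).values.sum() == pytest.approx(
                    inter_total
                )
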