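"""Genotype container, GenePop I/O, binning and inclusion filter."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coralpopgen import (
    GenepopParseError,
    GenotypeTable,
    bin_alleles,
    filter_min_n,
    read_genepop,
    write_genepop,
)
from coralpopgen.genodata import validate_site_metadata


def roundtrip(table: GenotypeTable, **kw) -> GenotypeTable:
    buf = io.StringIO()
    write_genepop(table, buf, **kw)
    return read_genepop(io.StringIO(buf.getvalue()), site_names=table.site_ids())


@st.composite
def genotype_tables(draw):
    n_loci = draw(st.integers(1, 4))
    n_sites = draw(st.integers(1, 3))
    alleles = st.integers(40, 333)
    rows, sites = [], []
    n_total = 0
    for s in range(n_sites):
        n = draw(st.integers(1, 5))
        for _ in range(n):
            row = []
            for _ in range(n_loci):
                a, b = draw(alleles), draw(alleles)
                if draw(st.integers(0, 9)) == 0:
                    a = b = 0
                row.append((a, b))
            rows.append(row)
            sites.append(f"site{s}")
            n_total += 1
    calls = np.array(rows).reshape(n_total, n_loci, 2)
    return GenotypeTable(
        [f"i{k}" for k in range(n_total)],
        [f"L{j}" for j in range(n_loci)],
        calls,
        np.array(sites, dtype=object),
    )


class TestGenepopIO:
    def test_two_pop_file_parses(self):
        text = (
            "title line\nLocA\nLocB\nPop\n"
            "a1 , 120130 200200\na2 , 120120 202204\n"
            "Pop\nb1 , 130130 200204\nb2 , 000000 204204\n"
        )
        t = read_genepop(io.StringIO(text))
        assert t.n_individuals == 4
        assert t.loci == ["LocA", "LocB"]
        assert t.site_ids() == ["a2", "b2"]  # last individual names the block
        assert t.calls[3, 0, 0] == 0  # missing
        assert set(t.calls[0, 0]) == {120, 130}

    def test_comma_separated_locus_names(self):
        text = "t\nLocA, LocB\nPop\nx1 , 1213 1415\n"
        t = read_genepop(io.StringIO(text))
        assert t.loci == ["LocA", "LocB"]
        assert set(t.calls[0, 1]) == {14, 15}

    def test_mixed_digit_width_rejected_with_line_number(self):
        text = "t\nLocA\nLocB\nPop\nx1 , 0000 120130\n"
        with pytest.raises(GenepopParseError) as err:
            read_genepop(io.StringIO(text))
        assert err.value.line == 5

    def test_partial_genotype_rejected(self):
        text = "t\nLocA\nPop\nx1 , 120000\n"
        with pytest.raises(GenepopParseError, match="partial"):
            read_genepop(io.StringIO(text))

    def test_duplicate_ids_rejected(self):
        text = "t\nLocA\nPop\nx1 , 1212\nx1 , 1313\n"
        with pytest.raises(GenepopParseError, match="duplicate"):
            read_genepop(io.StringIO(text))

    def test_empty_pop_block_rejected(self):
        text = "t\nLocA\nPop\nPop\nx1 , 1212\n"
        with pytest.raises(GenepopParseError, match="empty Pop"):
            read_genepop(io.StringIO(text))

    def test_write_empty_table_errors(self):
        t = GenotypeTable([], [], np.empty((0, 0, 2)), np.array([], dtype=object))
        with pytest.raises(ValueError, match="no loci"):
            write_genepop(t, io.StringIO())

    def test_single_homozygote_formatting(self):
        t = GenotypeTable(
            ["x"], ["L"], np.array([[[150, 150]]]), np.array(["s"], dtype=object)
        )
        buf = io.StringIO()
        write_genepop(t, buf)
        assert "150150" in buf.getvalue()

    def test_allele_too_large_for_width(self):
        t = GenotypeTable(
            ["x"], ["L"], np.array([[[1500, 1500]]]), np.array(["s"], dtype=object)
        )
        with pytest.raises(ValueError, match="exceeds"):
            write_genepop(t, io.StringIO())

    @given(genotype_tables())
    def test_roundtrip_identity(self, table):
        assert roundtrip(table).equals(table)

    def test_roundtrip_matches_simulation_truth(self, sole_preset):
        table, _, truth = sole_preset
        again = roundtrip(table)
        assert again.equals(table)
        sizes = again.site_sizes()
        assert all(n == truth.config.sample_size for n in sizes.values())


class TestBinning:
    def make(self, raw, unit=2):
        calls = np.array([[[a, a]] for a in raw])
        return GenotypeTable(
            [f"i{k}" for k in range(len(raw))],
            ["L"],
            calls,
            np.array(["s"] * len(raw), dtype=object),
            repeat_units={"L": unit},
        )

    def test_nearest_lattice_point(self):
        t = self.make([150, 150, 151])
        out = bin_alleles(t)
        assert out.calls[2, 0, 0] == 150

    def test_tie_rounds_toward_anchor(self):
        t = self.make([100, 100, 102], unit=4)
        out = bin_alleles(t)
        assert out.calls[2, 0, 0] == 100

    def test_idempotent(self):
        t = self.make([150, 151, 153, 150, 157])
        once = bin_alleles(t)
        twice = bin_alleles(once)
        assert twice.equals(once)

    def test_jittered_lattice_recovered(self):
        rng = np.random.default_rng(0)
        lattice = 150 + 3 * rng.integers(0, 10, size=60)
        jitter = rng.integers(-1, 2, size=60)
        # keep the anchor unambiguous: never jitter the modal allele
        jitter[lattice == np.bincount(lattice).argmax()] = 0
        t = self.make(list(lattice + jitter), unit=3)
        out = bin_alleles(t)
        clean = self.make(list(lattice), unit=3)
        assert np.array_equal(out.calls, clean.calls)


class TestMinNFilter:
    def build(self, sizes):
        rows, sites = [], []
        for s, n in sizes.items():
            for k in range(n):
                rows.append([[100, 102]])
                sites.append(s)
        return GenotypeTable(
            [f"{s}_{k}" for s, n in sizes.items() for k in range(n)],
            ["L"],
            np.array(rows),
            np.array(sites, dtype=object),
        )

    def test_rule_is_strict(self):
        t = self.build({"a": 12, "b": 13})
        out = filter_min_n(t, 12)
        assert out.site_ids() == ["b"]

    def test_min_n_zero_is_identity(self):
        t = self.build({"a": 3, "b": 2})
        assert filter_min_n(t, 0).equals(t)

    def test_all_removed_errors(self):
        t = self.build({"a": 3})
        with pytest.raises(ValueError, match="no site"):
            filter_min_n(t, 5)

    @given(st.dictionaries(st.sampled_from("abcd"), st.integers(1, 8), min_size=1))
    def test_no_surviving_small_site_and_genotypes_unchanged(self, sizes):
        t = self.build(sizes)
        try:
            out = filter_min_n(t, 4)
        except ValueError:
            assert all(n <= 4 for n in sizes.values())
            return
        assert all(n > 4 for n in out.site_sizes().values())
        for i, name in enumerate(out.individuals):
            j = t.individuals.index(name)
            assert np.array_equal(out.calls[i], t.calls[j])


class TestMetadata:
    def test_validation(self):
        meta = pd.DataFrame(
            {
                "site_id": ["a", "b"],
                "seamount": ["X", "X"],
                "region": ["r", "r"],
                "lat": [-44.0, -44.1],
                "lon": [147.0, 147.2],
                "depth_m": [1200, 1300],
                "stratum": ["mid", "mid"],
                "fished": ["true", "false"],
            }
        )
        out = validate_site_metadata(meta)
        assert out["fished"].tolist() == [True, False]

    def test_bad_latitude_rejected(self):
        meta = pd.DataFrame(
            {
                "site_id": ["a"],
                "seamount": ["X"],
                "region": ["r"],
                "lat": [95.0],
                "lon": [0.0],
                "depth_m": [100],
                "stratum": ["mid"],
                "fished": [True],
            }
        )
        with pytest.raises(ValueError, match="latitude"):
            validate_site_metadata(meta)
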