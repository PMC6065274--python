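import numpy as np
import pytest

from conftest import make_matrix, random_matrix
from cusipop.genotype_io import (
    StructureDialect,
    filter_loci,
    first_snp_per_locus,
    read_genepop,
    read_structure,
    read_vcf,
    write_genepop,
    write_structure,
    write_vcf,
    write_popmap,
)
from cusipop.types import MISSING, GenotypeMatrix, ParseError, PopulationMap, ValidationError


def assert_matrices_equal(a: GenotypeMatrix, b: GenotypeMatrix):
    assert a.individual_ids == b.individual_ids
    assert a.locus_ids == b.locus_ids
    # genotypes are unordered pairs: compare sorted along the allele axis
    np.testing.assert_array_equal(np.sort(a.calls, axis=2), np.sort(b.calls, axis=2))


class TestStructure:
    def test_one_row_dialect_all_present(self, tmp_path):
        p = tmp_path / "g.str"
        p.write_text("l1 l2 l3\nA 1 0 1 0 0 1 1\nB 2 1 1 0 1 0 0\n")
        m, pm = read_structure(p)
        assert m.n_individuals == 2 and m.n_loci == 3
        assert not m.missing_mask().any()
        assert pm.assignments == {"A": "1", "B": "2"}
        np.testing.assert_array_equal(m.calls[0, 0], [0, 1])

    def test_missing_pair_and_half_missing_coercion(self, tmp_path, caplog):
        p = tmp_path / "g.str"
        p.write_text("l1 l2\nA 1 -9 -9 0 1\nB 1 0 -9 1 1\n")
        with caplog.at_level("WARNING"):
            m, _ = read_structure(p)
        assert (m.calls[0, 0] == MISSING).all()
        assert (m.calls[1, 0] == MISSING).all()  # (0,-9) coerced
        assert "1 half-missing" in caplog.text

    def test_ragged_rows_name_line(self, tmp_path):
        p = tmp_path / "g.str"
        p.write_text("l1\nA 1 0 1\nB 1 0\n")
        with pytest.raises(ParseError, match="ragged row"):
            read_structure(p)

    def test_unknown_negative_code_rejected(self, tmp_path):
        p = tmp_path / "g.str"
        p.write_text("l1\nA 1 -7 0\n")
        with pytest.raises(ValidationError):
            read_structure(p)

    def test_two_row_dialect_matches_one_row(self, tmp_path):
        d2 = StructureDialect(rows_per_individual=2)
        p1, p2 = tmp_path / "a.str", tmp_path / "b.str"
        p1.write_text("l1 l2\nA 1 0 1 1 1\nB 1 1 1 0 0\n")
        p2.write_text("l1 l2\nA 1 0 1\nA 1 1 1\nB 1 1 0\nB 1 1 0\n")
        m1, _ = read_structure(p1)
        m2, _ = read_structure(p2, d2)
        assert_matrices_equal(m1, m2)

    @pytest.mark.parametrize("dialect", [
        StructureDialect(),
        StructureDialect(rows_per_individual=2),
        StructureDialect(pop_column=False),
        StructureDialect(missing_code=-1),
    ])
    def test_round_trip_random_matrices(self, tmp_path, rng, dialect):
        for k in range(25):
            m, pm = random_matrix(rng, n=rng.integers(2, 8), L=rng.integers(1, 7))
            path = tmp_path / f"r{k}.str"
            write_structure(m, pm, path, dialect)
            m2, pm2 = read_structure(path, dialect)
            assert_matrices_equal(m, m2)
            if dialect.pop_column:
                assert pm2.assignments == pm.assignments

    def test_empty_matrix_write_header_only(self, tmp_path):
        m, pm = random_matrix(np.random.default_rng(0), n=2, L=3)
        empty = m.subset_loci([])
        path = tmp_path / "e.str"
        write_structure(empty, pm, path)
        assert path.read_text().splitlines()[0] == ""


class TestGenepop:
    FILE = (
        "title\nloc1\nloc2\nPOP\n"
        "a1 , 0101 0102\na2 , 0102 0202\n"
        "POP\nb1 , 0101 0000\nb2 , 0202 0102\n"
    )

    def test_two_pop_blocks(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text(self.FILE)
        m, pm = read_genepop(p)
        assert m.n_individuals == 4 and m.n_loci == 2
        assert pm.populations() == ["pop_1", "pop_2"]
        assert (m.calls[2, 1] == MISSING).all()  # "0000" -> missing

    def test_three_digit_twin_identical(self, tmp_path):
        twin = self.FILE.replace("01", "001").replace("02", "002").replace("0000", "000000")
        p2, p3 = tmp_path / "g2.gen", tmp_path / "g3.gen"
        p2.write_text(self.FILE)
        p3.write_text(twin)
        m2, _ = read_genepop(p2)
        m3, _ = read_genepop(p3)
        assert_matrices_equal(m2, m3)

    def test_missing_pop_separator(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text("title\nloc1\na1 , 0101\n")
        with pytest.raises(ParseError, match="POP"):
            read_genepop(p)

    def test_round_trip_random(self, tmp_path, rng):
        # GENEPOP groups individuals into POP blocks, so round-trip identity
        # holds after restoring the original row order
        for k in range(25):
            m, pm = random_matrix(rng, n=5, L=4)
            path = tmp_path / f"r{k}.gen"
            write_genepop(m, pm, path)
            m2, pm2 = read_genepop(path)
            order = [m2.individual_ids.index(i) for i in m.individual_ids]
            assert_matrices_equal(m, m2.subset_individuals(order))
            # the population partition is preserved (labels are renamed)
            part = lambda p: {frozenset(p.members(x)) for x in p.populations()}
            assert part(pm) == part(pm2)

    def test_width_overflow_error(self, tmp_path):
        m, pm = make_matrix([[(0, 150)]])
        with pytest.raises(ValidationError, match="exceed"):
            write_genepop(m, pm, tmp_path / "x.gen", digits=2)


VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t10\tL1\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t20\tL2\tA\tC\t.\t.\t.\tGT\t0|1\t./.\t0/0
1\t30\tL3\tG\tT\t.\t.\t.\tGT\t1/1\t1/1\t0/1
1\t40\tL4\tG\tT\t.\t.\t.\tGT\t./.\t0/0\t0/1
"""


class TestVcf:
    @pytest.fixture
    def vcf_paths(self, tmp_path):
        v = tmp_path / "a.vcf"
        v.write_text(VCF)
        pmap = tmp_path / "pm.tsv"
        pmap.write_text("s1\twest\ns2\twest\ns3\teast\n")
        return v, pmap

    def test_matches_hand_transcription(self, vcf_paths):
        m, pm = read_vcf(*vcf_paths)
        assert m.n_loci == 4 and m.individual_ids == ["s1", "s2", "s3"]
        expected = {  # hand transcription of the fixture text
            ("s1", "L1"): (0, 0), ("s2", "L1"): (0, 1), ("s3", "L1"): (1, 1),
            ("s1", "L2"): (0, 1), ("s2", "L2"): None, ("s3", "L2"): (0, 0),
            ("s1", "L3"): (1, 1), ("s2", "L3"): (1, 1), ("s3", "L3"): (0, 1),
            ("s1", "L4"): None, ("s2", "L4"): (0, 0), ("s3", "L4"): (0, 1),
        }
        for (ind, lid), g in expected.items():
            i = m.individual_ids.index(ind)
            j = m.locus_ids.index(lid)
            got = tuple(sorted(m.calls[i, j]))
            assert got == ((MISSING, MISSING) if g is None else g)
        assert m.locus_positions["L2"] == ("1", 20)

    def test_phased_equals_unphased(self, vcf_paths):
        m, _ = read_vcf(*vcf_paths)
        i, j = 0, m.locus_ids.index("L2")
        assert tuple(sorted(m.calls[i, j])) == (0, 1)

    def test_sample_absent_from_popmap(self, tmp_path, vcf_paths):
        v, _ = vcf_paths
        bad = tmp_path / "bad.tsv"
        bad.write_text("s1\twest\ns2\twest\n")
        with pytest.raises(ValidationError, match="s3"):
            read_vcf(v, bad)

    def test_write_read_round_trip(self, tmp_path, rng):
        m, pm = random_matrix(rng, n=4, L=6, missing_rate=0.2)
        v = tmp_path / "rt.vcf"
        write_vcf(m, v)
        write_popmap(pm, tmp_path / "pm.tsv")
        m2, _ = read_vcf(v, tmp_path / "pm.tsv")
        assert_matrices_equal(m, m2)

    def test_vcf_equals_structure_export(self, tmp_path, rng):
        m, pm = random_matrix(rng, n=5, L=5, missing_rate=0.15)
        write_vcf(m, tmp_path / "x.vcf")
        write_popmap(pm, tmp_path / "pm.tsv")
        write_structure(m, pm, tmp_path / "x.str")
        mv, _ = read_vcf(tmp_path / "x.vcf", tmp_path / "pm.tsv")
        ms, _ = read_structure(tmp_path / "x.str")
        assert_matrices_equal(mv, ms)


class TestFilterLoci:
    def test_single_population_quarter_rule(self):
        # locus genotyped in 4/16 west individuals, 0/17 east: the
        # one-population, 25%-of-individuals rule keeps it
        genos = [[(0, 1)] if i < 4 else [None] for i in range(33)]
        ids = [f"i{i}" for i in range(33)]
        pops = {f"i{i}": ("west" if i < 16 else "east") for i in range(33)}
        m, _ = make_matrix(genos, individual_ids=ids)
        pm = PopulationMap(pops)
        kept = filter_loci(m, pm, min_fraction=0.25, min_populations=1)
        assert kept.n_loci == 1
        assert filter_loci(m, pm, min_fraction=0.25, min_populations=2).n_loci == 0

    def test_full_call_rate_boundary(self, rng):
        m, _ = random_matrix(rng, n=6, L=5, missing_rate=0.0, n_pops=1)
        m.calls[0, :, :] = MISSING  # one missing cell at every locus
        m = GenotypeMatrix(m.individual_ids, m.locus_ids, m.calls)
        pm = PopulationMap({i: "p0" for i in m.individual_ids})
        assert filter_loci(m, pm, min_fraction=1.0).n_loci == 0

    def test_matches_brute_force_count(self, rng):
        for _ in range(10):
            m, pm = random_matrix(rng, n=8, L=6, missing_rate=0.4)
            frac, minpop = 0.5, 1
            kept = filter_loci(m, pm, frac, minpop)
            labels = pm.labels_for(m)
            expect = []
            for j, lid in enumerate(m.locus_ids):  # exhaustive per-locus count
                n_ok = 0
                for pop in pm.populations():
                    rows = [i for i, la in enumerate(labels) if la == pop]
                    got = sum(m.calls[i, j, 0] != MISSING for i in rows)
                    if rows and got / len(rows) >= frac:
                        n_ok += 1
                if n_ok >= minpop:
                    expect.append(lid)
            assert kept.locus_ids == expect

    def test_idempotent(self, rng):
        m, pm = random_matrix(rng, n=8, L=10, missing_rate=0.5)
        once = filter_loci(m, pm, 0.5, 1)
        twice = filter_loci(once, pm, 0.5, 1)
        assert_matrices_equal(once, twice)


class TestFirstSnp:
    def test_keeps_lowest_position(self):
        m, pm = make_matrix([[(0, 1), (0, 0), (1, 1)]],
                            locus_ids=["7_12", "7_3", "9_1"])
        out = first_snp_per_locus(m)
        assert out.locus_ids == ["7_3", "9_1"]

    def test_unique_keys_identity(self):
        m, _ = make_matrix([[(0, 1), (0, 0)]], locus_ids=["1_1", "2_1"])
        assert first_snp_per_locus(m).locus_ids == ["1_1", "2_1"]

    def test_shuffle_invariant(self, rng):
        ids = [f"{k}_{p}" for k in (3, 1, 12) for p in (5, 2, 9)]
        m, _ = make_matrix([[(0, 1)] * 9], locus_ids=ids)
        order = rng.permutation(9)
        shuffled = m.subset_loci(order)
        a = first_snp_per_locus(m)
        b = first_snp_per_locus(shuffled)
        assert a.locus_ids == b.locus_ids
        assert_matrices_equal(a, b)

    def test_missing_position_metadata(self):
        m, _ = make_matrix([[(0, 1)]], locus_ids=["nounderscore"])
        with pytest.raises(ValidationError):
            first_snp_per_locus(m)
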