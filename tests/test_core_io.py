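"""Domain types, file round-trips, coordinate conventions, polarization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import (
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    ScoreTrack,
    Variant,
    polarize,
    read_ancestral_table,
    read_genetic_map,
    read_genotypes,
    read_haplotypes,
    read_population_table,
    read_scores,
    write_ancestral_table,
    write_genetic_map,
    write_genotypes,
    write_population_table,
    write_scores,
    write_vcf,
)
from sweepscan.core import MISSING

from conftest import make_variants


class TestVariant:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Variant("x", "1", 0, ("A", "G"))
        with pytest.raises(ValueError):
            Variant("x", "1", 10, ("A", "A"))
        with pytest.raises(ValueError):
            Variant("x", "1", 10, ("A", "G"), ancestral="T")

    def test_derived_allele(self):
        assert Variant("x", "1", 10, ("A", "G"), "A").derived == "G"
        assert Variant("x", "1", 10, ("A", "G"), "G").derived == "A"
        assert Variant("x", "1", 10, ("A", "G")).derived is None


class TestGenotypeIO:
    def test_vcf_transcription(self, tmp_path, tiny_genotypes):
        """0/0, 0/1, 1/1 transcribe to codes 0, 1, 2."""
        path = tmp_path / "t.vcf"
        write_vcf(tiny_genotypes, path)
        gm = read_genotypes(path)
        assert gm.samples == ["s1", "s2", "s3"]
        np.testing.assert_array_equal(gm.codes[:, 0], [0, 1, 2])

    def test_tsv_round_trip(self, tmp_path, tiny_genotypes):
        tiny_genotypes.codes[0, 1] = MISSING
        path = tmp_path / "t.tsv"
        write_genotypes(tiny_genotypes, path)
        back = read_genotypes(path)
        np.testing.assert_array_equal(back.codes, tiny_genotypes.codes)
        assert [v.id for v in back.variants] == [v.id for v in tiny_genotypes.variants]
        assert [v.pos for v in back.variants] == [v.pos for v in tiny_genotypes.variants]

    def test_empty_body(self, tmp_path):
        gm = GenotypeMatrix(["a", "b"], [], np.zeros((2, 0), dtype=np.int8))
        path = tmp_path / "e.vcf"
        write_vcf(gm, path)
        back = read_genotypes(path)
        assert back.n_variants == 0 and back.n_samples == 2

    def test_duplicate_variant_id_rejected(self):
        v = make_variants(1) * 2
        with pytest.raises(ValueError, match="duplicated"):
            GenotypeMatrix(["a"], v, np.zeros((1, 2), dtype=np.int8))

    def test_malformed_code_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tchrom\tpos\tref\talt\tancestral\ts1\nrs1\t1\t100\tA\tG\tA\t7\n")
        with pytest.raises(ValueError, match="line"):
            read_genotypes(path)

    def test_phased_vcf_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "p.vcf"
        write_vcf(small_panel, path)
        back = read_haplotypes(path)
        np.testing.assert_array_equal(back.haplotypes, small_panel.haplotypes)


class TestGeneticMap:
    def test_identity_and_midpoint(self):
        gmap = GeneticMap(np.array([100.0, 200.0]), np.array([0.0, 1.0]))
        assert gmap.interpolate(100) == 0.0
        assert gmap.interpolate(200) == 1.0
        assert gmap.interpolate(150) == pytest.approx(0.5)

    def test_against_brute_force_interpolation(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 10**6), size=50, replace=False)).astype(float)
        cm = np.cumsum(rng.uniform(0, 0.1, size=50))
        gmap = GeneticMap(pos, cm)
        queries = rng.uniform(pos[0], pos[-1], size=200)

        def brute(q):
            j = np.searchsorted(pos, q) - 1
            j = max(0, min(j, len(pos) - 2))
            frac = (q - pos[j]) / (pos[j + 1] - pos[j])
            return cm[j] + frac * (cm[j + 1] - cm[j])

        expected = np.array([brute(q) for q in queries])
        np.testing.assert_allclose(gmap.interpolate(queries), expected, atol=1e-12)

    def test_extrapolation_uses_terminal_rate(self):
        gmap = GeneticMap(np.array([100.0, 200.0, 300.0]), np.array([0.0, 1.0, 3.0]))
        assert gmap.interpolate(400) == pytest.approx(5.0)  # rate 2 cM / 100 bp
        assert gmap.interpolate(50) == pytest.approx(-0.5)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap(np.array([200.0, 100.0]), np.array([0.0, 1.0]))

    @given(st.lists(st.floats(1, 1e6), min_size=2, max_size=30, unique=True))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_position(self, queries):
        gmap = GeneticMap(np.array([10.0, 500.0, 9000.0]), np.array([0.0, 0.5, 0.9]))
        q = np.sort(np.asarray(queries))
        vals = np.atleast_1d(gmap.interpolate(q))
        assert np.all(np.diff(vals) >= -1e-15)

    def test_map_file_round_trip(self, tmp_path):
        gmap = GeneticMap(np.array([1.0, 1000.0, 5000.0]), np.array([0.0, 0.01, 0.1]))
        path = tmp_path / "map.tsv"
        write_genetic_map(gmap, path)
        back = read_genetic_map(path)
        np.testing.assert_allclose(back.positions, gmap.positions)
        np.testing.assert_allclose(back.cumulative, gmap.cumulative)


class TestTables:
    def test_population_table_round_trip(self, tmp_path, two_pop_structure):
        path = tmp_path / "pops.tsv"
        write_population_table(two_pop_structure, path)
        back = read_population_table(path)
        assert back.sample_to_population == two_pop_structure.sample_to_population
        assert back.population_to_region == two_pop_structure.population_to_region

    def test_sizes(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text(
            "sample\tpopulation\tregion\n"
            "a\tp1\tr1\nb\tp1\tr1\nc\tp2\tr1\nd\tp2\tr1\n"
        )
        s = read_population_table(path)
        assert len(s.sample_to_population) == 4
        assert len(s.population_to_region) == 2
        assert s.regions == ["r1"]

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text("sample\tpopulation\tregion\na\tp1\tr1\na\tp1\tr1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_population_table(path)

    def test_fixed_region_list_rejects_unknown(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text("sample\tpopulation\tregion\na\tp1\tmars\n")
        with pytest.raises(ValueError):
            read_population_table(path, regions=["r1", "r2"])

    def test_missing_sample_listed(self, two_pop_structure):
        with pytest.raises(ValueError, match="zz"):
            two_pop_structure.check_samples(["s0", "zz"])

    def test_ancestral_table_round_trip(self, tmp_path):
        table = {"rs1": "A", "rs2": "G", "rs3": "unknown"}
        path = tmp_path / "anc.tsv"
        write_ancestral_table(table, path)
        assert read_ancestral_table(path) == table


class TestPolarize:
    def test_flip_when_ancestral_is_alt(self):
        variants = [Variant("rs0", "1", 100, ("A", "G"), "unknown")]
        gm = GenotypeMatrix(["a", "b", "c"], variants, np.array([[0], [1], [2]], dtype=np.int8))
        pol, report = polarize(gm, {"rs0": "G"})
        np.testing.assert_array_equal(pol.codes[:, 0], [2, 1, 0])
        assert report.n_flipped == 1

    def test_unknown_ancestral_removed_and_reported(self):
        variants = make_variants(10)
        anc = {v.id: "A" for v in variants}
        for vid in ("rs1", "rs4", "rs7"):
            anc[vid] = "unknown"
        gm = GenotypeMatrix(["a"], variants, np.zeros((1, 10), dtype=np.int8))
        pol, report = polarize(gm, anc)
        assert pol.n_variants == 7
        assert sorted(report.removed_ids) == ["rs1", "rs4", "rs7"]
        assert all(reason == "unknown" for _, reason in report.removed)

    def test_ancestral_not_observed_routed_to_removed(self):
        variants = [Variant("rs0", "1", 100, ("A", "G"))]
        gm = GenotypeMatrix(["a"], variants, np.array([[1]], dtype=np.int8))
        pol, report = polarize(gm, {"rs0": "T"})
        assert pol.n_variants == 0
        assert report.removed == [("rs0", "ancestral-not-observed")]

    def test_daf_complements_on_flip(self, small_panel):
        anc = {v.id: ("G" if i % 2 else "A") for i, v in enumerate(small_panel.variants)}
        pol, _ = polarize(small_panel, anc)
        pre = small_panel.derived_frequency()
        post = pol.derived_frequency()
        for i in range(small_panel.n_variants):
            expected = 1.0 - pre[i] if i % 2 else pre[i]
            assert post[i] == pytest.approx(expected)

    def test_missing_preserved(self):
        variants = [Variant("rs0", "1", 100, ("A", "G"))]
        gm = GenotypeMatrix(["a", "b"], variants, np.array([[MISSING], [2]], dtype=np.int8))
        pol, _ = polarize(gm, {"rs0": "G"})
        assert pol.codes[0, 0] == MISSING
        assert pol.codes[1, 0] == 0


class TestScoreTracks:
    def make_track(self):
        return ScoreTrack(
            "fst", "global-regions", "chr1",
            np.array([101, 250, 980]), np.array([0.1, np.nan, 0.8]),
            ids=["a", "b", "c"], p=np.array([0.5, np.nan, 0.01]),
            maf=np.array([0.3, 0.1, 0.45]),
        )

    def test_bed_convention(self, tmp_path):
        track = self.make_track()
        path = tmp_path / "t.bed"
        write_scores(track, path, format="bed")
        first = path.read_text().splitlines()[0].split("\t")
        assert (first[1], first[2]) == ("100", "101")

    def test_tsv_round_trip(self, tmp_path):
        track = self.make_track()
        path = tmp_path / "t.tsv"
        write_scores(track, path)
        back = read_scores(path)
        np.testing.assert_array_equal(back.pos, track.pos)
        np.testing.assert_allclose(back.score, track.score)
        np.testing.assert_allclose(back.p, track.p)
        assert back.test == "fst" and back.level == "global-regions"

    def test_empty_track_header_only(self, tmp_path):
        track = ScoreTrack("fst", "x", "chr1", np.array([], dtype=int), np.array([]), ids=[])
        path = tmp_path / "e.tsv"
        write_scores(track, path)
        assert len(read_scores(path)) == 0

    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            ScoreTrack("t", "l", "c", np.array([1]), np.array([1.0]), p=np.array([0.0]))
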