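"""Table/metadata I/O invariants and the read-level QC filter."""

import numpy as np
import pytest

from gutdyn.core_io import (
    AbundanceTable,
    AnalysisConfig,
    SampleMetadata,
    make_read,
    parse_month,
    qc_filter_reads,
    read_abundance_table,
    read_metadata,
    validate_metadata,
    write_metadata,
)


class TestAbundanceTable:
    def test_counts_column_normalization(self, tmp_path):
        p = tmp_path / "t.tsv"
        AbundanceTable(
            "genus", ["a", "b"], ["s1", "s2"],
            np.array([[3, 1], [1, 3]]), counts=True,
        ).to_tsv(p)
        rel = read_abundance_table(p, "genus", "relative")
        assert rel.values[:, 0] == pytest.approx([0.75, 0.25])
        assert rel.values[:, 1] == pytest.approx([0.25, 0.75])

    def test_duplicate_sample_label_names_offender(self):
        with pytest.raises(ValueError, match="s1"):
            AbundanceTable("genus", ["a"], ["s1", "s1"],
                           np.array([[0.5, 0.5]]), counts=False)

    def test_negative_entry_rejected_with_labels(self):
        with pytest.raises(ValueError, match="taxA.*s2|s2.*taxA"):
            AbundanceTable("genus", ["taxA"], ["s1", "s2"],
                           np.array([[1.0, -0.5]]), counts=True)

    def test_zero_sum_column_rejected_on_conversion(self):
        t = AbundanceTable("genus", ["a"], ["s1", "s2"],
                           np.array([[5, 0]]), counts=True)
        with pytest.raises(ValueError, match="s2"):
            t.to_relative()

    @pytest.mark.parametrize("fmt", ["tsv", "biom"])
    def test_round_trip_lossless(self, tmp_path, fmt, rng):
        vals = rng.integers(0, 50, size=(6, 4)).astype(float)
        vals[0, 0] = 0  # keep a structural zero
        vals[:, 0] += vals[:, 0].sum() == 0
        t = AbundanceTable("otu", [f"t{i}" for i in range(6)],
                           [f"s{j}" for j in range(4)], vals, counts=True)
        p = tmp_path / f"t.{fmt}"
        (t.to_tsv if fmt == "tsv" else t.to_biom_json)(p)
        back = read_abundance_table(p, "otu", "counts")
        assert back.taxa == t.taxa and back.samples == t.samples
        np.testing.assert_allclose(back.values, t.values)

    def test_relative_conversion_preserves_rank_order(self, rng):
        vals = rng.integers(1, 100, size=(8, 5)).astype(float)
        t = AbundanceTable("genus", [f"t{i}" for i in range(8)],
                           [f"s{j}" for j in range(5)], vals, counts=True)
        rel = t.to_relative()
        for j in range(5):
            assert (np.argsort(vals[:, j]) == np.argsort(rel.values[:, j])).all()


class TestMetadata:
    def test_month_index_arithmetic(self):
        assert parse_month("2016-10") == 2016 * 12 + 10 == 24202

    def test_duplicate_individual_month_rejected(self):
        mds = [
            SampleMetadata("s1", "P1", 24202),
            SampleMetadata("s2", "P1", 24202),
        ]
        with pytest.raises(ValueError, match="P1"):
            validate_metadata(mds)

    def test_missing_covariate_passes_through(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample_id\tindividual_id\tdate\tyogurt\n"
            "s1\tP1\t2016-10\tyes\n"
            "s2\tP1\t2016-11\t\n"
        )
        md = read_metadata(p)
        assert md[0].covariates["yogurt"] == "yes"
        assert md[1].covariates["yogurt"] is None

    def test_unparseable_date_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample_id\tindividual_id\tdate\ns1\tP1\tOct-2016\n")
        with pytest.raises(ValueError, match="date"):
            read_metadata(p)

    def test_write_read_round_trip(self, tmp_path):
        mds = [
            SampleMetadata("s1", "P1", 24202, "T1", {"yogurt": "yes"}),
            SampleMetadata("s2", "P2", 24213, "T2", {"yogurt": "no"}),
        ]
        p = tmp_path / "m.tsv"
        write_metadata(mds, p)
        back = read_metadata(p)
        assert [m.sample_id for m in back] == ["s1", "s2"]
        assert back[0].month_index == 24202
        assert back[1].timepoint_label == "T2"
        assert back[0].covariates["yogurt"] == "yes"


class TestQCFilter:
    def test_trailing_low_quality_trimmed_and_kept(self):
        rec = make_read("r1", "A" * 250, [30] * 240 + [15] * 10)
        kept, rep = qc_filter_reads([rec])
        assert rep.n_kept == 1
        assert len(kept[0]) == 240

    def test_trimmed_below_length_floor_dropped(self):
        rec = make_read("r1", "A" * 210, [30] * 190 + [10] * 20)
        kept, rep = qc_filter_reads([rec])
        assert kept == [] and rep.n_dropped == 1

    def test_high_quality_read_unchanged(self):
        rec = make_read("r1", "A" * 220, [25] * 220)
        kept, _ = qc_filter_reads([rec])
        assert str(kept[0].seq) == "A" * 220

    def test_interior_low_quality_untouched(self):
        # only the maximal *suffix* below Q20 is removed
        quals = [30] * 100 + [5] * 10 + [30] * 100 + [5] * 5
        rec = make_read("r1", "A" * 215, quals)
        kept, _ = qc_filter_reads([rec])
        assert len(kept[0]) == 210

    def test_idempotent(self, rng):
        reads = [
            make_read(f"r{i}", "ACGT" * 60,
                      list(rng.integers(2, 41, size=240)))
            for i in range(30)
        ]
        once, rep1 = qc_filter_reads(reads)
        twice, rep2 = qc_filter_reads(once)
        assert rep2.n_dropped == 0
        assert [str(a.seq) for a in once] == [str(b.seq) for b in twice]


class TestAnalysisConfig:
    def test_defaults_are_published_constants(self):
        cfg = AnalysisConfig()
        assert cfg.bloom_fold_threshold == 5
        assert cfg.perm_reps == 1000
        assert cfg.qc_min_len == 200 and cfg.qc_qual_floor == 20
        assert cfg.group_bounds["Y1"] == (2, 12)
        assert cfg.group_bounds["Y2"] == (13, 24)

    def test_unknown_yaml_key_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("bloom_fold_threshold: 5\nnot_a_key: 1\n")
        with pytest.raises(ValueError, match="not_a_key"):
            AnalysisConfig.from_yaml(p)

    def test_overlapping_group_bounds_rejected(self):
        with pytest.raises(ValueError):
            AnalysisConfig(group_bounds={"M1": (1, 3), "Y1": (2, 12)})
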