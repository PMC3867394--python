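"""Study-table I/O, the bundled dataset, and subgroup classification."""

import io

import pytest

import snpmeta as sm
from snpmeta.errors import SchemaError, ValidationError

HEADER = (
    "study_id,first_author,year,country,ethnicity,cancer_type,control_source,"
    "case_aa,case_ag,case_gg,control_aa,control_ag,control_gg"
)
GU_ROW = "gu2011,Gu,2011,China,Asian,Gastric,HB,94,270,244,138,268,202"


def read(text: str):
    return sm.read_study_table(io.StringIO(text))


class TestReadStudyTable:
    def test_parses_counts_and_metadata(self):
        (rec,) = read(f"{HEADER}\n{GU_ROW}\n")
        assert rec.cases == sm.GenotypeCounts(94, 270, 244)
        assert rec.controls == sm.GenotypeCounts(138, 268, 202)
        assert rec.year == 2011
        assert rec.ethnicity is sm.Ethnicity.ASIAN
        assert rec.control_source is sm.ControlSource.HOSPITAL

    def test_header_only_gives_empty_list(self):
        assert read(f"{HEADER}\n") == []

    def test_missing_column_names_it(self):
        broken = HEADER.replace(",control_gg", "")
        row = GU_ROW.rsplit(",", 1)[0]
        with pytest.raises(SchemaError, match="control_gg"):
            read(f"{broken}\n{row}\n")

    def test_negative_count_names_study(self):
        with pytest.raises(ValidationError, match="gu2011"):
            read(f"{HEADER}\n{GU_ROW.replace(',202', ',-1')}\n")

    def test_non_integer_count_names_study(self):
        with pytest.raises(ValidationError, match="gu2011"):
            read(f"{HEADER}\n{GU_ROW.replace(',202', ',many')}\n")

    def test_duplicate_study_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            read(f"{HEADER}\n{GU_ROW}\n{GU_ROW}\n")

    def test_tab_delimiter_autodetected(self):
        (rec,) = read((f"{HEADER}\n{GU_ROW}\n").replace(",", "\t"))
        assert rec.study_id == "gu2011"

    def test_round_trip_preserves_content(self, fixture_studies):
        buf = io.StringIO()
        sm.write_study_table(fixture_studies, buf)
        again = read(buf.getvalue())
        assert again == fixture_studies


class TestFixture:
    def test_nineteen_studies(self, fixture_studies):
        assert len(fixture_studies) == 19

    def test_case_total(self, fixture_studies):
        assert sum(s.cases.total for s in fixture_studies) == 4162

    def test_control_genotype_total(self, fixture_studies):
        # genotype-count sum; the table's declared per-study totals disagree
        # for one study (Arshad), which is preserved as printed
        assert sum(s.controls.total for s in fixture_studies) == 5173

    def test_specific_rows(self, by_id):
        assert by_id["bektas2012"].cases == sm.GenotypeCounts(67, 56, 6)
        assert by_id["bektas2012"].controls == sm.GenotypeCounts(94, 45, 1)
        assert by_id["qin2009hcc"].controls == by_id["qin2009npc"].controls
        assert by_id["qin2009hcc"].controls == sm.GenotypeCounts(185, 225, 61)


class TestClassify:
    @pytest.mark.parametrize(
        "sid, cancer_group, size_class",
        [
            ("gu2011", sm.CancerGroup.DIGESTIVE, sm.SizeClass.LARGE),
            ("liu2013", sm.CancerGroup.OTHER, sm.SizeClass.LARGE),
            ("kruszyna2011", sm.CancerGroup.OTHER, sm.SizeClass.SMALL),
            ("landi2006", sm.CancerGroup.DIGESTIVE, sm.SizeClass.LARGE),
            ("narter2010", sm.CancerGroup.BLADDER, sm.SizeClass.SMALL),
            ("saenz2008", sm.CancerGroup.PROSTATE, sm.SizeClass.LARGE),
        ],
    )
    def test_fixture_examples(self, by_id, sid, cancer_group, size_class):
        labels = sm.classify(by_id[sid])
        assert labels.cancer_group is cancer_group
        assert labels.size_class is size_class

    def test_exactly_500_participants_is_small(self):
        rec = sm.StudyRecord(
            study_id="edge", first_author="Edge", year=2020, country="X",
            ethnicity=sm.Ethnicity.ASIAN, cancer_type="Gastric",
            control_source=sm.ControlSource.HOSPITAL,
            cases=sm.GenotypeCounts(100, 100, 50),
            controls=sm.GenotypeCounts(100, 100, 50),
        )
        assert rec.n_total == 500
        assert sm.classify(rec).size_class is sm.SizeClass.SMALL

    def test_unknown_cancer_type_maps_to_other(self):
        rec = sm.StudyRecord(
            study_id="odd", first_author="Odd", year=2020, country="X",
            ethnicity=sm.Ethnicity.MIXED, cancer_type="Chordoma",
            control_source=sm.ControlSource.POPULATION,
            cases=sm.GenotypeCounts(5, 5, 5),
            controls=sm.GenotypeCounts(5, 5, 5),
        )
        assert sm.classify(rec).cancer_group is sm.CancerGroup.OTHER

    def test_digestive_membership_is_exactly_the_four_sites(self, fixture_studies):
        digestive = {
            s.study_id
            for s in fixture_studies
            if sm.classify(s).cancer_group is sm.CancerGroup.DIGESTIVE
        }
        expected = {
            s.study_id
            for s in fixture_studies
            if s.cancer_type.lower() in {"oral", "gastric", "colorectal", "hepatocellular"}
        }
        assert digestive == expected
        assert len(digestive) == 6


class TestSubgroupMembers:
    def test_cardinalities_match_published_strata(self, groups):
        assert {k: len(v) for k, v in groups["cancer_group"].items()} == {
            "digestive": 6, "bladder": 5, "prostate": 2, "other": 6,
        }
        assert {k: len(v) for k, v in groups["size_class"].items()} == {
            "large": 7, "small": 12,
        }
        assert {k: len(v) for k, v in groups["ethnicity_group"].items()} == {
            "Asian": 10, "Caucasian": 8, "Mixed": 1,
        }

    def test_partitions_cover_all_studies(self, groups, fixture_studies):
        for factor, levels in groups.items():
            ids = [s.study_id for mem in levels.values() for s in mem]
            assert sorted(ids) == sorted(s.study_id for s in fixture_studies)


class TestGenotypeCounts:
    def test_allele_counts(self):
        g = sm.GenotypeCounts(2, 3, 4)
        assert (g.allele_a, g.allele_g, g.total) == (7, 11, 9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            sm.GenotypeCounts(-1, 0, 0)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValidationError):
            sm.StudyRecord(
                study_id="empty", first_author="E", year=2020, country="X",
                ethnicity=sm.Ethnicity.ASIAN, cancer_type="Lung",
                control_source=sm.ControlSource.HOSPITAL,
                cases=sm.GenotypeCounts(0, 0, 0),
                controls=sm.GenotypeCounts(1, 1, 1),
            )
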