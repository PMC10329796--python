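import numpy as np
import pytest

from florabias import (
    FamilyCount,
    FloraTable,
    SpeciesRecord,
    aggregate_species,
    read_counts_csv,
    read_species_csv,
    validate_table,
    write_counts_csv,
    write_species_csv,
)
from florabias.counts import SchemaError, ValidationError


def rec(name, family="Fam1", origin="native", food=False):
    return SpeciesRecord(
        scientific_name=name, family=family, origin=origin, is_food_use=food
    )


class TestTypes:
    def test_species_record_rejects_empty_name(self):
        with pytest.raises(ValidationError):
            rec("   ")

    def test_species_record_rejects_bad_origin(self):
        with pytest.raises(ValidationError):
            rec("Aa bb", origin="alien")

    def test_family_count_rejects_x_above_n(self):
        with pytest.raises(ValidationError):
            FamilyCount(family="Bad", n_total=2, x_used=3)

    def test_family_count_rejects_zero_n(self):
        with pytest.raises(ValidationError):
            FamilyCount(family="Bad", n_total=0, x_used=0)

    def test_flora_table_rejects_duplicate_families(self):
        with pytest.raises(ValidationError):
            FloraTable.from_counts(
                [FamilyCount("A", 1, 0), FamilyCount("A", 2, 1)]
            )


class TestAggregate:
    def test_basic_counting_excludes_exotics(self):
        records = [
            rec("Aa aa", food=True),
            rec("Bb bb"),
            rec("Cc cc"),
            rec("Dd dd", origin="exotic", food=True),
        ]
        table = aggregate_species(records)
        fam = table.get("Fam1")
        assert (fam.n_total, fam.x_used) == (3, 1)
        assert (table.N_total, table.X_total) == (3, 1)

    def test_duplicate_name_dedupes_keeping_food_flag(self):
        records = [rec("Aa aa", food=False), rec("Aa aa", food=True)]
        table = aggregate_species(records)
        fam = table.get("Fam1")
        assert (fam.n_total, fam.x_used) == (1, 1)

    def test_name_normalization_merges_case_and_whitespace(self):
        records = [rec("Aa  aa "), rec("aa aa")]
        assert aggregate_species(records).N_total == 1

    def test_unknown_origin_excluded(self):
        records = [rec("Aa aa"), rec("Bb bb", origin="unknown")]
        assert aggregate_species(records).N_total == 1

    def test_family_stored_title_case(self):
        table = aggregate_species([rec("Aa aa", family="  fabaceae ")])
        assert table.families[0].family == "Fabaceae"

    def test_no_native_records_raises(self):
        with pytest.raises(ValidationError, match="no native"):
            aggregate_species([rec("Aa aa", origin="exotic")])

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            aggregate_species([])

    def test_random_checklist_matches_set_based_recount(self):
        # independent oracle: recount with plain python sets
        rng = np.random.default_rng(42)
        names = [f"Genus{rng.integers(0, 20)} sp{rng.integers(0, 3)}" for _ in range(50)]
        families = [f"Fam{rng.integers(0, 5)}" for _ in range(50)]
        origins = [
            ["native", "exotic", "naturalized", "unknown"][rng.integers(0, 4)]
            for _ in range(50)
        ]
        foods = [bool(rng.integers(0, 2)) for _ in range(50)]
        records = [
            SpeciesRecord(n, f, o, fd)
            for n, f, o, fd in zip(names, families, origins, foods)
        ]

        native = {}
        for n, f, o, fd in zip(names, families, origins, foods):
            if o != "native":
                continue
            key = n.lower()
            if key in native:
                native[key] = (native[key][0], native[key][1] or fd)
            else:
                native[key] = (f.title(), fd)
        expected_n, expected_x = {}, {}
        for fam, fd in native.values():
            expected_n[fam] = expected_n.get(fam, 0) + 1
            expected_x[fam] = expected_x.get(fam, 0) + int(fd)

        table = aggregate_species(records)
        assert {f.family: f.n_total for f in table} == expected_n
        assert {f.family: f.x_used for f in table} == expected_x
        assert table.N_total == sum(expected_n.values())
        assert table.X_total == sum(expected_x.values())

    def test_aggregation_idempotent(self):
        rng = np.random.default_rng(7)
        records = [
            rec(f"Genus{i} sp", family=f"Fam{rng.integers(0, 4)}",
                food=bool(rng.integers(0, 2)))
            for i in range(40)
        ]
        table = aggregate_species(records)
        # expand each counted species back to one record and re-aggregate
        expanded = []
        for fam in table:
            for i in range(fam.n_total):
                expanded.append(
                    rec(f"{fam.family} resp{i}", family=fam.family,
                        food=i < fam.x_used)
                )
        table2 = aggregate_species(expanded)
        assert {(f.family, f.n_total, f.x_used) for f in table} == {
            (f.family, f.n_total, f.x_used) for f in table2
        }


class TestSpeciesCsv:
    def test_read_well_formed(self, tmp_path):
        p = tmp_path / "species.csv"
        p.write_text(
            "scientific_name,family,origin,is_food_use,source_ref\n"
            "Aa aa,Fam1,native,true,ref1\n"
            "Bb bb,Fam1,exotic,false,ref2\n"
        )
        records = read_species_csv(p)
        assert len(records) == 2
        assert records[0].is_food_use and not records[1].is_food_use

    def test_missing_family_column_is_schema_error(self, tmp_path):
        p = tmp_path / "species.csv"
        p.write_text("scientific_name,origin,is_food_use\nAa aa,native,true\n")
        with pytest.raises(SchemaError, match="family"):
            read_species_csv(p)

    def test_unknown_origin_string_maps_to_unknown(self, tmp_path):
        p = tmp_path / "species.csv"
        p.write_text(
            "scientific_name,family,origin,is_food_use\nAa aa,Fam1,weird,false\n"
        )
        assert read_species_csv(p)[0].origin == "unknown"

    def test_bad_bool_raises_with_row_number(self, tmp_path):
        p = tmp_path / "species.csv"
        p.write_text(
            "scientific_name,family,origin,is_food_use\nAa aa,Fam1,native,maybe\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_species_csv(p)

    def test_round_trip_preserves_all_fields(self, tmp_path):
        rng = np.random.default_rng(3)
        records = [
            SpeciesRecord(
                scientific_name=f"Genus{i} sp{i}",
                family=f"Fam{rng.integers(0, 10)}",
                origin=["native", "exotic", "cultivated", "naturalized", "unknown"][
                    rng.integers(0, 5)
                ],
                is_food_use=bool(rng.integers(0, 2)),
                source_ref=f"ref{i}",
            )
            for i in range(100)
        ]
        p = tmp_path / "species.csv"
        write_species_csv(records, p)
        assert read_species_csv(p) == records


class TestCountsCsv:
    def test_single_row(self, tmp_path):
        p = tmp_path / "counts.csv"
        p.write_text("family,n_total,x_used\nArecaceae,300,27\n")
        table = read_counts_csv(p)
        fam = table.get("Arecaceae")
        assert (fam.n_total, fam.x_used) == (300, 27)

    def test_x_above_n_names_family(self, tmp_path):
        p = tmp_path / "counts.csv"
        p.write_text("family,n_total,x_used\nBad,2,3\n")
        with pytest.raises(ValidationError, match="Bad"):
            read_counts_csv(p)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "counts.csv"
        p.write_text("family,n_total,x_used\nBad,5,-1\n")
        with pytest.raises(ValidationError):
            read_counts_csv(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "counts.csv"
        p.write_text("family,n_total\nA,5\n")
        with pytest.raises(SchemaError, match="x_used"):
            read_counts_csv(p)

    def test_reference_round_trip_totals(self, tmp_path, reference_table):
        p = tmp_path / "counts.csv"
        write_counts_csv(reference_table, p)
        table = read_counts_csv(p)
        assert table.N_total == 32740
        assert table.X_total == 254
        assert table.families == reference_table.families


class TestReferenceFixture:
    def test_orchidaceae(self, reference_table):
        fam = reference_table.get("Orchidaceae")
        assert (fam.n_total, fam.x_used) == (2340, 0)

    def test_typhaceae(self, reference_table):
        fam = reference_table.get("Typhaceae")
        assert (fam.n_total, fam.x_used) == (3, 2)

    def test_totals_match_printed_total_row(self, reference_table):
        assert reference_table.N_total == 32740
        assert reference_table.X_total == 254

    def test_totals_are_sums(self, reference_table):
        assert reference_table.X_total == sum(f.x_used for f in reference_table)
        assert reference_table.N_total == sum(f.n_total for f in reference_table)

    def test_family_count(self, reference_table):
        assert len(reference_table) == 230


class TestValidateTable:
    def test_reference_fixture_is_clean(self, reference_table):
        assert validate_table(reference_table) == []

    def test_duplicate_family_reported(self):
        table = FloraTable(
            families=(FamilyCount("A", 1, 0), FamilyCount("A", 2, 1)),
            N_total=3,
            X_total=1,
        )
        findings = validate_table(table)
        assert [f.kind for f in findings] == ["duplicate family"]

    def test_total_mismatch_reported(self):
        table = FloraTable(
            families=(FamilyCount("A", 5, 1),), N_total=6, X_total=1
        )
        findings = validate_table(table)
        assert [f.kind for f in findings] == ["total mismatch"]
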