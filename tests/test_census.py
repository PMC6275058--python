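import numpy as np
import pytest

from cypcensus import (
    Assignment,
    ValidationError,
    build_census,
    cluster_matrix,
    diversity_percentage,
    dominant_subfamily,
    family_percentages,
    linkage_to_newick,
    presence_matrix,
    validate_census,
)
from cypcensus.census import ABSENT, PRESENT, round_half_up, write_heatmap


def make_assignment(pid, family, sub):
    return Assignment(
        protein_id=pid,
        best_hit=f"{family}{sub}1",
        best_identity=80.0,
        family=family,
        subfamily_label=sub,
        is_novel_family=False,
        is_novel_subfamily=False,
        assigned_name=f"{family}{sub}2",
    )


def census_from(spec):
    """spec: {species: [(family, subfamily), ...]}"""
    return build_census(
        {
            code: [make_assignment(f"{code}_{i}", fam, sub)
                   for i, (fam, sub) in enumerate(entries)]
            for code, entries in spec.items()
        }
    )


class TestBuildCensus:
    def test_two_species_totals(self):
        census = census_from(
            {"SP1": [("CYP102", "A"), ("CYP102", "A")], "SP2": [("CYP107", "J")]}
        )
        assert census.total_p450s == 3
        assert census.total_families == 2
        assert census.total_subfamilies == 2

    def test_zero_p450_species_retained(self):
        census = census_from({"SP1": [("CYP102", "A")], "EMPTY": []})
        codes = {sp.species_code: sp.p450_count for sp in census.species}
        assert codes["EMPTY"] == 0

    def test_empty_census_diversity_is_error(self):
        census = census_from({"SP1": []})
        assert census.total_p450s == 0
        with pytest.raises(ValidationError):
            _ = census.diversity_percent

    def test_conservation_of_counts(self, genus10, library5):
        """Census totals equal the generator's planted totals."""
        from cypcensus import classify_proteome

        by_species = {}
        for code, proteome in genus10.proteomes.items():
            planted = [
                (pid, seq)
                for pid, seq in proteome
                if pid not in genus10.truth.decoy_ids
            ]
            by_species[code] = classify_proteome(planted, genus10.library)
        census = build_census(by_species)
        assert census.total_p450s == len(genus10.truth.planted_assignments)
        total_fam = sum(
            n for sp in census.species for n in sp.family_counts.values()
        )
        total_sub = sum(
            n for sp in census.species for n in sp.subfamily_counts.values()
        )
        assert total_fam == total_sub == census.total_p450s


class TestDiversityPercentage:
    @pytest.mark.parametrize(
        "families,total,expected",
        [(1, 1, 100.0), (5, 100, 5.0), (13, 507, 2.6), (2, 3, 66.7)],
    )
    def test_formula(self, families, total, expected):
        assert diversity_percentage(families, total) == expected

    def test_zero_total_is_error(self):
        with pytest.raises(ValidationError):
            diversity_percentage(1, 0)

    def test_scale_invariance(self):
        for k in (2, 5, 10):
            assert diversity_percentage(3, 40) == diversity_percentage(3 * k, 40 * k)

    def test_rounding_is_half_up(self):
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(31.45, 1) == 31.5
        assert round_half_up(60.5, 0) == 61.0


class TestFamilyProfiles:
    def test_percent_and_ordering(self):
        census = census_from(
            {"SP1": [("CYP107", "J")] * 165 + [("CYP102", "A")] * 342}
        )
        rows = family_percentages(census)
        assert rows[0] == ("CYP102", 342, 67.5)
        assert rows[1] == ("CYP107", 165, 32.5)  # 165/507 = 32.54 -> 32.5

    def test_single_family_is_100(self):
        census = census_from({"SP1": [("CYP1", "A")]})
        assert family_percentages(census) == [("CYP1", 1, 100.0)]

    def test_equal_counts_tie_broken_by_name(self):
        census = census_from({"SP1": [("CYPB", "A"), ("CYPA", "A")]})
        assert [r[0] for r in family_percentages(census)] == ["CYPA", "CYPB"]


class TestDominantSubfamily:
    def test_max_count_wins(self):
        census = census_from(
            {"SP1": [("CYP107", "J")] * 90 + [("CYP107", "H")] * 40
             + [("CYP107", "K")] * 35}
        )
        assert dominant_subfamily(census, "CYP107") == "J"

    def test_single_subfamily(self):
        census = census_from({"SP1": [("CYP102", "A")]})
        assert dominant_subfamily(census, "CYP102") == "A"

    def test_tie_broken_alphabetically(self):
        census = census_from({"SP1": [("CYP107", "K"), ("CYP107", "J")]})
        assert dominant_subfamily(census, "CYP107") == "J"

    def test_absent_family_is_error(self):
        census = census_from({"SP1": [("CYP102", "A")]})
        with pytest.raises(ValidationError):
            dominant_subfamily(census, "CYP999")


class TestPresenceMatrix:
    def test_encoding(self):
        census = census_from({"SP1": [("CYP102", "A")], "SP2": [("CYP107", "J")]})
        m = presence_matrix(census)
        df = m.to_frame()
        assert df.loc["CYP102", "SP1"] == PRESENT
        assert df.loc["CYP102", "SP2"] == ABSENT
        assert set(np.unique(m.values)) <= {PRESENT, ABSENT}

    def test_rethresholding_idempotent(self):
        census = census_from({"SP1": [("CYP102", "A")], "SP2": []})
        m = presence_matrix(census)
        again = np.where(m.values == PRESENT, PRESENT, ABSENT)
        assert (again == m.values).all()

    def test_identical_columns_merge_first(self):
        census = census_from(
            {"S1": [("F1", "A")], "S2": [("F1", "A")], "S3": [("F3", "A")]}
        )
        m = cluster_matrix(presence_matrix(census))
        # S1 and S2 have identical presence vectors: first merge at height 0
        assert m.col_linkage[0, 2] == 0.0
        assert {int(m.col_linkage[0, 0]), int(m.col_linkage[0, 1])} == {0, 1}

    def test_three_point_linkage_matches_hand_upgma(self):
        """Hand-computed UPGMA on three species presence vectors.

        Encoded columns: a=(-3,3,3), b=(-3,-3,3), c=(3,3,-3) giving
        d(a,b)=6, d(a,c)=sqrt(72), d(b,c)=sqrt(108); a,b merge first and
        the (a,b)-c height is the average of the two remaining distances.
        """
        census = census_from(
            {
                "a": [("F1", "A")],
                "b": [("F1", "A"), ("F2", "A")],
                "c": [("F3", "A")],
            }
        )
        m = cluster_matrix(presence_matrix(census))
        link = m.col_linkage
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert link[0, 2] == pytest.approx(6.0)
        expected = (np.sqrt(72) + np.sqrt(108)) / 2
        assert link[1, 2] == pytest.approx(expected)

    def test_label_invariance_of_topology(self):
        """Permuting species input order permutes labels, not the tree."""
        spec = {
            "s1": [("F1", "A")],
            "s2": [("F1", "A"), ("F2", "A")],
            "s3": [("F3", "A")],
            "s4": [("F3", "A"), ("F2", "A")],
        }
        m1 = cluster_matrix(presence_matrix(census_from(spec)))
        permuted = dict(reversed(list(spec.items())))
        m2 = cluster_matrix(presence_matrix(census_from(permuted)))
        order1 = [m1.col_labels[i] for i in m1.col_order]
        order2 = [m2.col_labels[i] for i in m2.col_order]
        def merges(m):
            # heights of merges, topology-invariant summary
            return [round(h, 9) for h in m.col_linkage[:, 2]]
        assert merges(m1) == merges(m2)
        assert set(order1) == set(order2)

    def test_single_column_identity_order(self):
        census = census_from({"only": [("F1", "A")]})
        m = cluster_matrix(presence_matrix(census))
        assert m.col_order == (0,)
        assert linkage_to_newick(m.col_linkage, m.col_labels) == "only;"

    def test_heatmap_export(self, tmp_path):
        census = census_from(
            {"S1": [("F1", "A")], "S2": [("F2", "A")], "S3": [("F1", "A")]}
        )
        write_heatmap(cluster_matrix(presence_matrix(census)), tmp_path)
        matrix = (tmp_path / "heatmap_matrix.tsv").read_text()
        assert "-3" in matrix and "3" in matrix
        newick = (tmp_path / "heatmap_cols.nwk").read_text()
        assert newick.endswith(";\n") and "S1" in newick


class TestValidator:
    def test_consistent_distribution_passes(self):
        report = validate_census(10, 4, {3: 2, 2: 2})
        assert report.ok

    def test_published_distribution_flags_both_mismatches(self):
        """The printed per-species count distribution is internally
        inconsistent with the printed totals (sums to 525 P450s over 116
        species, vs 507 and 114 reported)."""
        distribution = {11: 1, 9: 2, 8: 4, 7: 20, 6: 21, 5: 10,
                        4: 9, 3: 28, 2: 7, 1: 14}
        report = validate_census(507, 114, distribution)
        assert len(report.discrepancies) == 2
        assert "525" in report.discrepancies[0]
        assert "116" in report.discrepancies[1]

    def test_missing_bin_flagged(self):
        report = validate_census(10, 4, {3: 2})  # lost the 2-count bin
        assert not report.ok
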