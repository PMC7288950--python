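import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoscore import (
    LymphocytePanel,
    SubjectRecord,
    build_reference_table,
    bundled_paper_table,
    load_table,
    nonparametric_range,
    save_table,
)
from immunoscore.core import ALL_PARAMETERS
from immunoscore.reference import ReferenceRange, ReferenceTable, TableValidationError

from .conftest import GROUP_ORDER, PUBLISHED_CELLS, parse_cell
from .test_core import make_panel


def percentile_oracle(values, p):
    """Brute-force linear-interpolation percentile: rank position
    p/100*(n-1) between order statistics, interpolated by hand."""
    s = sorted(values)
    h = p / 100 * (len(s) - 1)
    k = math.floor(h)
    if k == len(s) - 1:
        return s[-1]
    return s[k] + (h - k) * (s[k + 1] - s[k])


class TestNonparametricRange:
    def test_constant_sample(self):
        assert nonparametric_range([5, 5, 5, 5, 5] * 10) == (5, 5)

    def test_1_to_40_matches_hand_interpolation(self):
        # h_lo = 0.025*39 = 0.975 -> 1 + 0.975; h_hi = 38.025 -> 39 + 0.025
        lower, upper = nonparametric_range(range(1, 41))
        assert lower == pytest.approx(1.975)
        assert upper == pytest.approx(39.025)

    def test_uniform_draws_recover_true_quantiles(self, rng):
        values = rng.uniform(size=10_000)
        lower, upper = nonparametric_range(values)
        assert lower == pytest.approx(0.025, abs=0.01)
        assert upper == pytest.approx(0.975, abs=0.01)

    def test_matches_oracle_on_all_small_samples(self):
        # exhaustive over every multiset of size 2..12 from a fixed grid
        grid = (0.0, 1.0, 2.5, 7.0, 10.0)
        checked = 0
        for size in range(2, 13):
            for sample in itertools.combinations_with_replacement(grid, size):
                lower, upper = nonparametric_range(sample)
                assert lower == pytest.approx(percentile_oracle(sample, 2.5), abs=1e-12)
                assert upper == pytest.approx(percentile_oracle(sample, 97.5), abs=1e-12)
                checked += 1
        assert checked > 5000

    def test_small_sample_warns_but_returns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            lower, upper = nonparametric_range([1, 2, 3, 4])
        assert lower <= upper

    def test_fewer_than_two_values_error(self):
        with pytest.raises(ValueError):
            nonparametric_range([1.0])

    def test_bad_percentile_order_error(self):
        with pytest.raises(ValueError):
            nonparametric_range(range(100), lo=60, hi=40)

    def test_affine_equivariance_exact(self, rng):
        values = rng.normal(size=75)
        lo1, hi1 = nonparametric_range(values)
        lo2, hi2 = nonparametric_range(values * 3.5 + 11)
        assert lo2 == pytest.approx(3.5 * lo1 + 11)
        assert hi2 == pytest.approx(3.5 * hi1 + 11)

    def test_monotone_transform_exact_at_nearest_rank_positions(self, rng):
        # n=41 puts 2.5/97.5 exactly on order statistics, so any strictly
        # increasing transform maps the endpoints exactly
        values = rng.uniform(1, 2, size=41)
        lo1, hi1 = nonparametric_range(values)
        lo2, hi2 = nonparametric_range(np.exp(values))
        assert lo2 == pytest.approx(np.exp(lo1))
        assert hi2 == pytest.approx(np.exp(hi1))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    @settings(max_examples=150, deadline=None)
    def test_limits_are_ordered_and_within_sample(self, values):
        lower, upper = nonparametric_range(values)
        assert min(values) <= lower <= upper <= max(values)


class TestBundledTable:
    def test_exhaustive_transcription_against_independent_copy(self, paper_table):
        assert len(paper_table) == 80
        assert paper_table.provenance == "paper_tables_1_2"
        for parameter, cells in PUBLISHED_CELLS.items():
            for group, cell in zip(GROUP_ORDER, cells):
                mean, sd, lower, upper = parse_cell(cell)
                entry = paper_table.lookup(parameter, group)
                assert (entry.mean, entry.sd) == (mean, sd), (parameter, group)
                assert (entry.lower, entry.upper) == (lower, upper), (parameter, group)

    @pytest.mark.parametrize(
        ("parameter", "group", "lower", "upper"),
        [
            ("cd4_num_x_func", "adults", 61, 328),
            ("cd28_cd8_num", "elders", 57, 286),
            ("cd4_count", "children", 635, 1979),
        ],
    )
    def test_spot_lookups(self, paper_table, parameter, group, lower, upper):
        entry = paper_table.lookup(parameter, group)
        assert (entry.lower, entry.upper) == (lower, upper)

    def test_group_sizes(self, paper_table):
        sizes = {g: paper_table.lookup("cd4_count", g).n for g in GROUP_ORDER}
        assert sizes == {"children": 47, "adolescents": 72, "adults": 90, "elders": 52}


class TestBuildReferenceTable:
    def test_degenerate_cohort_collapses_ranges(self):
        cohort = [
            (SubjectRecord(f"S{i}", 30 + i, "male"), make_panel()) for i in range(50)
        ]
        table = build_reference_table(cohort)
        entry = table.lookup("cd4_count", "adults")
        assert entry.lower == entry.upper == 648
        assert entry.sd == 0

    def test_study_sized_cohort_covers_all_strata(self):
        from immunoscore import SyntheticCohortSpec, generate_healthy_cohort

        cohort = generate_healthy_cohort(SyntheticCohortSpec(seed=7))
        assert len(cohort) == 261
        table = build_reference_table(cohort)
        assert len(table) == 80  # 20 parameters x 4 groups
        for parameter in ALL_PARAMETERS:
            for group in GROUP_ORDER:
                assert (parameter, group) in table

    def test_non_healthy_subjects_rejected(self):
        cohort = [(SubjectRecord("P1", 30, "male", "hypoimmune"), make_panel())]
        with pytest.raises(ValueError, match="healthy"):
            build_reference_table(cohort)

    def test_sex_stratification_adds_strata(self):
        rng = np.random.default_rng(3)
        cohort = [
            (
                SubjectRecord(f"S{i}", 20 + rng.uniform(0, 40), "male" if i % 2 else "female"),
                make_panel(cd4_count=float(600 + rng.normal(0, 50))),
            )
            for i in range(120)
        ]
        table = build_reference_table(cohort, stratify_by_sex=True)
        assert (("cd4_count", "adults")) in table
        assert (("cd4_count", "adults/male")) in table
        assert (("cd4_count", "adults/female")) in table

    def test_coverage_of_heldout_subjects_is_95pct(self, big_table, heldout_cohort):
        """The estimated limits trap ~95% of fresh same-distribution subjects."""
        from immunoscore.core import assign_age_group, derive_parameters

        inside = {p: 0 for p in ALL_PARAMETERS}
        for record, panel in heldout_cohort:
            group = assign_age_group(record.age).label
            values = panel.as_dict()
            values.update(derive_parameters(panel).as_dict())
            for parameter in ALL_PARAMETERS:
                e = big_table.lookup(parameter, group)
                inside[parameter] += e.lower <= values[parameter] <= e.upper
        n = len(heldout_cohort)
        for parameter, count in inside.items():
            assert count / n == pytest.approx(0.95, abs=0.01), parameter


class TestTableSerialization:
    def test_round_trip_identity(self, paper_table, tmp_path):
        path = tmp_path / "table.json"
        save_table(paper_table, path)
        assert load_table(path) == paper_table

    def test_duplicate_key_rejected(self):
        entry = ReferenceRange("cd4_count", "adults", 100, 200)
        with pytest.raises(TableValidationError, match="duplicate"):
            ReferenceTable([entry, entry])

    def test_inverted_limits_rejected(self):
        with pytest.raises(TableValidationError, match="lower"):
            ReferenceRange("cd4_count", "adults", 300, 200)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(TableValidationError, match="unknown parameter"):
            ReferenceRange("cd3_count", "adults", 100, 200)

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(TableValidationError):
            load_table(path)
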