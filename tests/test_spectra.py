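"""Containers, CSV round-trips, range selection and replicate averaging."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirquant import (
    ReferenceValues, SpectraSet, WavenumberGrid,
    average_replicates, read_reference_values, read_spectra,
    reference_table, select_range, write_reference_values, write_spectra,
)
from nirquant.spectra import GridError, SpectraFormatError


class TestWavenumberGrid:
    def test_acquisition_grid_point_count_by_direct_enumeration(self):
        # 12,500 down in 8 cm^-1 steps: 4,000 is not reachable
        # ((12500-4000)/8 = 1062.5); enumeration stops at 4,004.
        values = np.arange(12500.0, 4000.0 - 1e-9, -8.0)
        assert values.size == 1063 and values[-1] == 4004.0
        grid = WavenumberGrid.from_range(12500.0, 4000.0, 8.0)
        assert grid.n_points == values.size
        np.testing.assert_allclose(grid.values, values)

    def test_rejects_ascending_nonuniform_and_nonpositive(self):
        with pytest.raises(GridError):
            WavenumberGrid(np.array([4000.0, 5000.0, 6000.0]))
        with pytest.raises(GridError):
            WavenumberGrid(np.array([9000.0, 8000.0, 7500.0]))
        with pytest.raises(GridError):
            WavenumberGrid(np.array([8.0, 0.0, -8.0]))


class TestSpectraCSV:
    def test_round_trip_is_bit_identical(self, random_set, tmp_path):
        path = tmp_path / "spectra.csv"
        write_spectra(random_set, path)
        again = read_spectra(path)
        assert again.sample_ids == random_set.sample_ids
        assert np.array_equal(again.absorbance, random_set.absorbance)
        assert again.grid == random_set.grid

    def test_two_writes_are_byte_identical(self, random_set, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_spectra(random_set, p1)
        write_spectra(random_set, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_gzip_round_trip(self, random_set, tmp_path):
        path = tmp_path / "spectra.csv.gz"
        write_spectra(random_set, path)
        with gzip.open(path, "rb") as fh:
            assert fh.read(9) == b"sample_id"
        again = read_spectra(path)
        assert np.array_equal(again.absorbance, random_set.absorbance)

    def test_empty_set_gives_header_only_file(self, coarse_grid, tmp_path):
        empty = SpectraSet((), coarse_grid, np.empty((0, coarse_grid.n_points)))
        path = tmp_path / "empty.csv"
        write_spectra(empty, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert read_spectra(path).n_samples == 0

    def test_ragged_row_error_names_the_sample(self, random_set, tmp_path):
        path = tmp_path / "bad.csv"
        write_spectra(random_set, path)
        lines = path.read_text().splitlines()
        lines[3] = ",".join(lines[3].split(",")[:-2])  # truncate third sample
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SpectraFormatError, match="s2"):
            read_spectra(path)

    def test_non_monotonic_header_is_a_grid_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,5000,6000,4000\nx,1,2,3\n")
        with pytest.raises(GridError):
            read_spectra(path)


class TestReferenceValues:
    def test_total_computed_when_absent(self, tmp_path):
        path = tmp_path / "ref.csv"
        path.write_text("sample_id,oa,ua\ns1,1.9,0.2\n")
        (rec,) = read_reference_values(path)
        assert rec.total == pytest.approx(2.1)

    def test_inconsistent_total_rejected(self, tmp_path):
        path = tmp_path / "ref.csv"
        path.write_text("sample_id,oa,ua,total\ns1,13.4,5.0,15.3\n")
        with pytest.raises(ValueError, match="inconsistent"):
            read_reference_values(path)

    def test_negative_content_rejected(self):
        with pytest.raises(ValueError):
            ReferenceValues("s1", -1.0, 0.5, 0.0)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "ref.csv"
        path.write_text("sample_id,oa,ua\ns1,1,1\ns1,2,2\n")
        with pytest.raises(SpectraFormatError, match="duplicate"):
            read_reference_values(path)

    def test_order_preserved_and_round_trip(self, tmp_path):
        records = [ReferenceValues(f"s{i}", 1.0 + i, 0.5, 1.5 + i)
                   for i in range(10)]
        path = tmp_path / "ref.csv"
        write_reference_values(records, path)
        again = read_reference_values(path)
        assert again == records
        y = reference_table(again, [r.sample_id for r in records], "total")
        np.testing.assert_allclose(y, [r.total for r in records])


class TestSelectRange:
    def test_full_range_is_identity(self, random_set):
        out = select_range(random_set, 4000.0, 9000.0)
        assert np.array_equal(out.absorbance, random_set.absorbance)

    def test_working_window_count_on_acquisition_grid(self):
        # direct-count oracle: values are congruent to 4 mod 8, so 9,000
        # is off-grid and [4,000, 9,000] keeps 8,996..4,004 = 625 columns
        grid = WavenumberGrid.from_range(12500.0, 4000.0, 8.0)
        expected = int(np.sum((grid.values >= 4000) & (grid.values <= 9000)))
        assert expected == 625
        spectra = SpectraSet(("a",), grid, np.zeros((1, grid.n_points)))
        out = select_range(spectra, 4000.0, 9000.0)
        assert out.grid.n_points == expected
        assert out.grid.values[0] == 8996.0 and out.grid.values[-1] == 4004.0

    def test_both_endpoints_kept_when_on_grid(self, random_set):
        out = select_range(random_set, 4000.0, 9000.0)
        assert out.grid.values[0] == 9000.0 and out.grid.values[-1] == 4000.0

    def test_empty_intersection_raises(self, random_set):
        with pytest.raises(ValueError, match="does not intersect"):
            select_range(random_set, 20000.0, 30000.0)

    @given(st.tuples(st.floats(4100, 6000), st.floats(6100, 8900)))
    @settings(max_examples=20, deadline=None)
    def test_selection_is_idempotent(self, bounds):
        lo, hi = bounds
        grid = WavenumberGrid.from_range(9000.0, 4000.0, 40.0)
        spectra = SpectraSet(("a", "b"), grid,
                             np.arange(2 * grid.n_points, dtype=float)
                             .reshape(2, -1))
        once = select_range(spectra, lo, hi)
        twice = select_range(once, lo, hi)
        assert np.array_equal(once.absorbance, twice.absorbance)


class TestAverageReplicates:
    def test_identical_replicates_are_a_fixed_point(self, random_set):
        out = average_replicates([random_set] * 3)
        np.testing.assert_allclose(out.absorbance, random_set.absorbance)

    def test_antisymmetric_pair_averages_to_zero(self, random_set):
        negated = SpectraSet(random_set.sample_ids, random_set.grid,
                             -random_set.absorbance)
        out = average_replicates([random_set, negated])
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-15)

    def test_matches_per_element_brute_force(self, coarse_grid, rng):
        stacks = [SpectraSet(("a", "b", "c", "d", "e"), coarse_grid,
                             rng.normal(size=(5, coarse_grid.n_points)))
                  for _ in range(3)]
        out = average_replicates(stacks)
        brute = np.zeros_like(out.absorbance)
        for i in range(5):
            for j in range(coarse_grid.n_points):
                brute[i, j] = sum(s.absorbance[i, j] for s in stacks) / 3.0
        np.testing.assert_allclose(out.absorbance, brute, atol=1e-14)

    def test_permutation_invariant(self, random_set, rng):
        other = SpectraSet(random_set.sample_ids, random_set.grid,
                           rng.normal(size=random_set.absorbance.shape))
        third = SpectraSet(random_set.sample_ids, random_set.grid,
                           rng.normal(size=random_set.absorbance.shape))
        a = average_replicates([random_set, other, third])
        b = average_replicates([third, random_set, other])
        np.testing.assert_allclose(a.absorbance, b.absorbance, atol=1e-15)

    def test_grid_mismatch_raises(self, random_set, small_grid):
        other = SpectraSet(random_set.sample_ids, small_grid,
                           np.zeros((random_set.n_samples, small_grid.n_points)))
        with pytest.raises(ValueError, match="grids differ"):
            average_replicates([random_set, other])
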