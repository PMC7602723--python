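import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomshift import (
    aitchison_distance,
    baseline_distance_series,
    close,
    clr,
    ilr,
    ilr_basis,
    replace_zeros,
)
from venomshift.compositional import PeakTable, geometric_mean_composition
from venomshift.errors import (
    DegenerateSampleError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)
from conftest import make_snake, random_compositions

positive_parts = st.lists(
    st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=12
)


class TestClose:
    @pytest.mark.parametrize(
        "row, expected",
        [([2, 2], [0.5, 0.5]), ([1, 2, 7], [0.1, 0.2, 0.7])],
    )
    def test_rows_become_proportions(self, row, expected):
        np.testing.assert_allclose(close(np.array(row, float)), expected)

    def test_all_zero_row_names_the_offender(self):
        with pytest.raises(DegenerateSampleError, match=r"\[1\]"):
            close(np.array([[1.0, 1.0], [0.0, 0.0]]))

    @given(positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, parts):
        once = close(np.array(parts))
        np.testing.assert_allclose(close(once), once, atol=1e-12)


class TestReplaceZeros:
    def test_multiplicative_arithmetic(self):
        out = replace_zeros(np.array([0.5, 0.5, 0.0]), delta=0.01)
        np.testing.assert_allclose(out, [0.495, 0.495, 0.01])

    def test_identity_on_zero_free_row(self):
        out = replace_zeros(np.array([0.3, 0.7]), delta=0.01)
        np.testing.assert_allclose(out, [0.3, 0.7])

    def test_delta_too_large(self):
        with pytest.raises(ParameterError):
            replace_zeros(np.array([0.0, 0.4, 0.6]), delta=0.5)

    def test_preserves_ratios_and_closure(self, rng):
        m = random_compositions(rng, 5, 6)
        m[:, 0] = 0.0
        m = m / m.sum(axis=1, keepdims=True)
        out = replace_zeros(m, delta=1e-4)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        # ratios among originally nonzero parts survive
        np.testing.assert_allclose(
            out[:, 2] / out[:, 1], m[:, 2] / m[:, 1], rtol=1e-9
        )


class TestClr:
    def test_uniform_maps_to_zero(self):
        np.testing.assert_allclose(clr(np.full(4, 0.25)), np.zeros(4), atol=1e-12)

    def test_two_part_hand_value(self):
        # g = sqrt(0.16) = 0.4, ln(0.8/0.4) = ln 2
        np.testing.assert_allclose(
            clr(np.array([0.8, 0.2])), [np.log(2), -np.log(2)], atol=1e-9
        )

    @given(positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_components_sum_to_zero(self, parts):
        assert abs(clr(close(np.array(parts))).sum()) < 1e-9

    def test_rejects_zero_part(self):
        with pytest.raises(ValidationError):
            clr(np.array([0.5, 0.5, 0.0]))


class TestIlr:
    def test_equal_parts_map_to_zero(self):
        np.testing.assert_allclose(ilr(np.array([0.5, 0.5])), [0.0], atol=1e-12)

    def test_two_part_hand_value(self):
        # (1/sqrt 2) * ln(0.8/0.2)
        np.testing.assert_allclose(
            ilr(np.array([0.8, 0.2])), [np.log(4) / np.sqrt(2)], atol=1e-9
        )

    def test_isometry_with_aitchison(self, rng):
        for _ in range(20):
            x, y = random_compositions(rng, 2, 7)
            d_ilr = np.linalg.norm(ilr(x) - ilr(y))
            assert d_ilr == pytest.approx(aitchison_distance(x, y), abs=1e-9)

    def test_any_valid_basis_gives_same_distances(self, rng):
        # rotate the default basis: distances must not move
        from scipy.stats import ortho_group

        d = 6
        q = ortho_group.rvs(d - 1, random_state=5)
        basis = q @ ilr_basis(d)
        x, y = random_compositions(rng, 2, d)
        d_default = np.linalg.norm(ilr(x) - ilr(y))
        d_rotated = np.linalg.norm(ilr(x, basis) - ilr(y, basis))
        assert d_rotated == pytest.approx(d_default, abs=1e-9)

    def test_rejects_non_orthonormal_basis(self):
        bad = np.array([[1.0, -1.0]])
        with pytest.raises(ParameterError):
            ilr(np.array([0.5, 0.5]), bad)


class TestAitchisonDistance:
    def test_identity(self, rng):
        x = random_compositions(rng, 1, 5)[0]
        assert aitchison_distance(x, x) == 0.0

    def test_two_part_hand_value(self):
        d = aitchison_distance(np.array([0.8, 0.2]), np.array([0.2, 0.8]))
        assert d == pytest.approx(np.log(16) / np.sqrt(2), abs=1e-9)

    def test_symmetry_and_triangle(self, rng):
        x, y, z = random_compositions(rng, 3, 6)
        assert aitchison_distance(x, y) == pytest.approx(
            aitchison_distance(y, x), abs=1e-12
        )
        assert aitchison_distance(x, z) <= (
            aitchison_distance(x, y) + aitchison_distance(y, z) + 1e-12
        )

    def test_scale_invariance(self, rng):
        x, y = random_compositions(rng, 2, 5)
        assert aitchison_distance(37.0 * x, y) == pytest.approx(
            aitchison_distance(x, y), abs=1e-9
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            aitchison_distance(np.array([0.5, 0.5]), np.array([0.2, 0.3, 0.5]))


class TestBaselineSeries:
    def test_identical_samples_give_zero_distance(self):
        comp = np.array([0.2, 0.3, 0.5])
        table = PeakTable(
            snake_id="X", species="", sample_days=np.arange(5) * 60,
            svl=np.full(5, np.nan), peak_ids=["a", "b", "c"],
            retention_times=[20.0, 40.0, 60.0],
            abundance=np.tile(comp, (5, 1)),
        )
        series = baseline_distance_series(table, scale=False)
        np.testing.assert_allclose(series.distances, 0.0, atol=1e-9)

    def test_single_baseline_reduces_to_first_sample_distance(self, rng):
        m = random_compositions(rng, 6, 8)
        table = PeakTable(
            snake_id="X", species="", sample_days=np.arange(6) * 61,
            svl=np.full(6, np.nan), peak_ids=[f"p{i}" for i in range(8)],
            retention_times=np.linspace(15, 110, 8), abundance=m,
        )
        series = baseline_distance_series(table, n_baseline=1, scale=False)
        expected = [aitchison_distance(row, m[0]) for row in m]
        np.testing.assert_allclose(series.distances, expected, atol=1e-9)

    def test_brute_force_recomputation_on_shifting_snake(self, shifting_snake):
        table = shifting_snake.table
        series = baseline_distance_series(table, n_baseline=3, scale=True)
        base = geometric_mean_composition(table.abundance[:3])
        expected = np.array(
            [aitchison_distance(row, base) for row in table.abundance]
        )
        np.testing.assert_allclose(series.distances, expected, atol=1e-9)
        assert series.scaled_distances.mean() == pytest.approx(1.0, abs=1e-9)
        # planted logistic: later samples sit farther from the baseline
        assert series.distances[-3:].mean() > series.distances[:3].mean()

    def test_requires_enough_samples(self):
        table = PeakTable(
            snake_id="X", species="", sample_days=[0, 50, 100],
            svl=np.full(3, np.nan), peak_ids=["a", "b"],
            retention_times=[20.0, 40.0],
            abundance=np.full((3, 2), 0.5),
        )
        with pytest.raises(InsufficientDataError):
            baseline_distance_series(table, n_baseline=3)


def test_simulated_tables_pass_validation():
    for seed in range(3):
        snake = make_snake(seed=seed, n_logistic=1)
        snake.table.validate(require_closed=True, min_samples=4)
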