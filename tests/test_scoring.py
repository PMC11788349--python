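"""Directional scoring, radar-area SQI and Z-score EMF."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import soilqual as sq
from soilqual.scoring import sqi_upper_bound
from soilqual.trial import Direction


def sqi_transcription(values_by_prop, directions):
    """Independent direct transcription of the scoring formulas, written
    with explicit loops as a cross-check oracle for the vectorized path."""
    names = list(values_by_prop)
    n_plots = len(values_by_prop[names[0]])
    n = len(names)
    li = {}
    for name in names:
        col = values_by_prop[name]
        if directions[name] is Direction.MORE_IS_BETTER:
            li[name] = [v / max(col) for v in col]
        else:
            li[name] = [min(col) / v for v in col]
    out = []
    for i in range(n_plots):
        total = sum(li[name][i] ** 2 for name in names)
        out.append(0.5 * total * math.sin(2 * math.pi / n))
    return out


class TestLinearScores:
    def test_more_is_better_divides_by_max(self):
        assert sq.linear_scores([5, 10], Direction.MORE_IS_BETTER) == pytest.approx([0.5, 1.0])

    def test_less_is_better_hand_oracle(self):
        # v_min = 1.4664; scores are v_min / v
        got = sq.linear_scores([1.4664, 1.88, 1.5416], Direction.LESS_IS_BETTER)
        assert got == pytest.approx([1.0, 0.78, 0.9512195], abs=1e-6)

    @pytest.mark.parametrize("direction", [Direction.MORE_IS_BETTER, Direction.LESS_IS_BETTER])
    def test_constant_column_scores_one_everywhere(self, direction):
        assert sq.linear_scores([3.3, 3.3, 3.3], direction) == pytest.approx([1, 1, 1])

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sq.linear_scores([], Direction.MORE_IS_BETTER)
        with pytest.raises(ValueError):
            sq.linear_scores([0.0, 1.0], Direction.LESS_IS_BETTER)
        with pytest.raises(ValueError):
            sq.linear_scores([1.0], Direction.NOT_SCORED)


class TestSqi:
    @pytest.mark.parametrize("n,expected", [(6, 3 * math.sin(math.pi / 3)), (4, 2.0)])
    def test_all_ones_attains_closed_form_bound(self, n, expected):
        assert sq.sqi(np.ones((1, n)))[0] == pytest.approx(expected)
        assert sqi_upper_bound(n) == pytest.approx(expected)

    def test_hand_calculator_oracle(self):
        # 0.5*sin(60deg)*(0.78^2+0.5236^2+0.6712^2+0.8^2+1+1)
        got = sq.sqi([[0.78, 0.5236, 0.6712, 0.8, 1.0, 1.0]])[0]
        assert got == pytest.approx(1.720, abs=1e-3)

    def test_adjacent_variant_uses_cyclic_products(self):
        # printed: factor*(1+0.25+1); adjacent: factor*(0.5+0.5+1)
        factor = 0.5 * math.sin(2 * math.pi / 3)
        li = [[1.0, 0.5, 1.0]]
        assert sq.sqi(li, variant="printed")[0] == pytest.approx(factor * 2.25)
        assert sq.sqi(li, variant="adjacent")[0] == pytest.approx(factor * 2.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            sq.sqi([[1.0, 1.0]])  # n < 3: no radar area
        with pytest.raises(ValueError):
            sq.sqi([[1.0, 0.5, 1.2]])
        with pytest.raises(ValueError):
            sq.sqi([[1.0, 0.5, 0.9]], variant="nope")

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0.01, 1.0), min_size=4, max_size=8),
            min_size=1, max_size=5,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_bounds_property(self, rows):
        L = np.array(rows)
        vals = sq.sqi(L)
        n = L.shape[1]
        assert np.all(vals > 0)
        assert np.all(vals <= sqi_upper_bound(n) + 1e-12)
        at_bound = np.isclose(vals, sqi_upper_bound(n))
        all_ones = np.all(np.isclose(L, 1.0), axis=1)
        assert np.array_equal(at_bound, all_ones)


class TestEmf:
    def test_two_point_z_scores(self):
        z, e = sq.emf([[1.0], [3.0]])
        assert e == pytest.approx([-math.sqrt(2) / 2, math.sqrt(2) / 2])

    def test_grand_mean_zero_and_column_normalization(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=(12, 4))
        z, e = sq.emf(x)
        assert e.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.mean(axis=0) == pytest.approx(np.zeros(4), abs=1e-10)
        assert z.std(axis=0, ddof=1) == pytest.approx(np.ones(4), abs=1e-10)

    def test_affine_invariance_of_single_column(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=(9, 4))
        _, e1 = sq.emf(x)
        y = x.copy()
        y[:, 2] = 10.0 * y[:, 2] + 5.0
        _, e2 = sq.emf(y)
        assert e2 == pytest.approx(e1)

    def test_zero_variance_column_named_in_error(self):
        frame = pd.DataFrame({"BG": [1.0, 2.0], "CE": [3.0, 3.0]})
        with pytest.raises(ValueError, match="CE"):
            sq.emf(frame)

    def test_needs_two_plots(self):
        with pytest.raises(ValueError):
            sq.emf([[1.0, 2.0]])


class TestScoreDataset:
    def test_zero_noise_calibrated_sqi(self, zero_noise_records):
        # CS holds every favourable extreme -> upper bound; CK value from
        # the hand oracle on the calibrated means
        table = sq.score_dataset(zero_noise_records)
        frame = table.frame
        cs = frame[frame.treatment == "CS"]["SQI"]
        ck = frame[frame.treatment == "CK"]["SQI"]
        assert cs.to_numpy() == pytest.approx(np.full(3, 2.598076), abs=1e-5)
        assert ck.to_numpy() == pytest.approx(np.full(3, 1.72034), abs=1e-4)

    def test_matches_independent_transcription(self, noisy_records):
        frame = sq.records_to_frame(noisy_records)
        props = dict(sq.DEFAULT_SQI_PROPERTIES)
        expected = sqi_transcription(
            {p: frame[p].tolist() for p in props}, props
        )
        table = sq.score_dataset(noisy_records)
        assert table.sqi.to_numpy() == pytest.approx(expected, rel=1e-12)

    def test_single_treatment_zero_noise_sits_at_upper_bound(self):
        specs, effects = sq.default_calibration(cv=0.0)
        records = sq.generate_trial(
            sq.TrialDesign(treatments=("CK", "CK2"), seed=0), specs, effects
        )
        with pytest.raises(ValueError):
            # constant enzyme columns make Z-scores undefined
            sq.score_dataset(records)
        # every property column is constant -> all Li = 1 -> SQI at bound
        frame = sq.records_to_frame(records)
        li = np.column_stack([
            sq.linear_scores(frame[p].to_numpy(), d)
            for p, d in sq.DEFAULT_SQI_PROPERTIES.items()
        ])
        assert sq.sqi(li) == pytest.approx(np.full(6, sqi_upper_bound(6)))

    def test_record_order_invariance(self, noisy_records):
        table = sq.score_dataset(noisy_records)
        shuffled = list(reversed(noisy_records))
        table2 = sq.score_dataset(shuffled)
        merged = table.frame.merge(
            table2.frame, on=["treatment", "replicate"], suffixes=("", "_2")
        )
        assert merged["SQI"].to_numpy() == pytest.approx(merged["SQI_2"].to_numpy())
        assert merged["EMF"].to_numpy() == pytest.approx(merged["EMF_2"].to_numpy())

    def test_missing_variable_named(self, noisy_records):
        with pytest.raises(ValueError, match="XYZ"):
            sq.score_dataset(noisy_records, emf_enzymes=["BG", "XYZ"])

    def test_unit_invariance_end_to_end(self, noisy_records):
        # rescaling one property's units changes no score
        base = sq.score_dataset(noisy_records)
        frame = sq.records_to_frame(noisy_records)
        frame["avK"] = frame["avK"] / 1000.0  # mg/kg -> g/kg
        frame["BG"] = frame["BG"] * 60.0      # per hour -> per minute
        rescored = sq.score_dataset(frame)
        for col in base.frame.columns:
            if col in ("treatment", "replicate"):
                continue
            assert rescored.frame[col].to_numpy() == pytest.approx(
                base.frame[col].to_numpy(), rel=1e-12
            )


def test_monotonicity_of_sqi_in_a_more_is_better_value(noisy_records):
    """Raising the current maximum holder's value cannot lower its SQI nor
    raise anyone else's (their Li for that property shrink)."""
    frame = sq.records_to_frame(noisy_records)
    before = sq.score_dataset(frame).sqi.to_numpy()
    imax = int(frame["avP"].idxmax())
    bumped = frame.copy()
    bumped.loc[imax, "avP"] *= 1.5
    after = sq.score_dataset(bumped).sqi.to_numpy()
    assert after[imax] >= before[imax] - 1e-12
    others = np.arange(len(frame)) != imax
    assert np.all(after[others] <= before[others] + 1e-12)
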