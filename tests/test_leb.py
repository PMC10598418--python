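"""Depth-matched control selection and the paired deterrent-effect bootstrap."""

import numpy as np
import pytest

from trossa.errors import ConfigurationError, MatchingError
from trossa.leb import (
    DIFFERENCE_OF_MEDIANS,
    BootstrapConfig,
    bootstrap_effect,
    effect_table,
    effects_to_frame,
    match_control,
)
from trossa.records import FleetDataset
from trossa.synthetic import FleetConfig, constant_rate, generate_fleet

from conftest import make_record


class _FixedTarget:
    """RNG stand-in returning a chosen target depth; delegates tie-breaking."""

    def __init__(self, target, seed=0):
        self.target = target
        self._rng = np.random.default_rng(seed)

    def normal(self, loc, scale):
        return self.target

    def choice(self, a):
        return self._rng.choice(a)


def _controls(depths, trip="T1"):
    return [make_record(trip, depth=d) for d in depths]


class TestMatchControl:
    def test_closest_to_realised_target_wins(self):
        leb = make_record("T1", depth=30, has_leb=True)
        cands = _controls([20, 25, 40])
        chosen = match_control(leb, cands, 5.0, _FixedTarget(23))
        assert chosen.mean_depth == 25

    def test_single_candidate_always_chosen(self):
        leb = make_record("T1", depth=30, has_leb=True)
        (only,) = _controls([58])
        rng = np.random.default_rng(3)
        assert all(match_control(leb, [only], 5.0, rng) is only for _ in range(20))

    def test_ties_broken_uniformly(self):
        leb = make_record("T1", depth=30, has_leb=True)
        cands = _controls([20, 26])
        stub = _FixedTarget(23)
        picks = [match_control(leb, cands, 5.0, stub).mean_depth for _ in range(10_000)]
        frac = np.mean(np.array(picks) == 20)
        assert abs(frac - 0.5) < 0.02

    def test_empty_candidates_raise(self):
        leb = make_record("T7", depth=30, has_leb=True)
        with pytest.raises(MatchingError, match="T7"):
            match_control(leb, [], 5.0, np.random.default_rng(0))

    def test_cross_trip_candidate_rejected(self):
        leb = make_record("T1", depth=30, has_leb=True)
        with pytest.raises(MatchingError):
            match_control(leb, _controls([25], trip="T2"), 5.0, np.random.default_rng(0))

    def test_small_depth_sd_converges_to_nearest(self):
        """As the target-depth spread shrinks, matching becomes nearest-depth."""
        leb = make_record("T1", depth=30, has_leb=True)
        cands = _controls([10, 28, 45])
        rng = np.random.default_rng(1)
        picks = {match_control(leb, cands, 1e-9, rng).mean_depth for _ in range(50)}
        assert picks == {28}


def _degenerate_dataset():
    """Every trossa identical in counts and effort, two trips with a deterrent."""
    records = []
    for trip in ("T1", "T2"):
        records.append(make_record(trip, depth=25, has_leb=True,
                                   birds={"common_eider": 2}, lumpfish=10))
        for d in (20, 30, 35):
            records.append(make_record(trip, depth=d,
                                       birds={"common_eider": 2}, lumpfish=10))
    return FleetDataset(records=records)


class TestBootstrapEffect:
    def test_identical_trossas_give_zero_difference(self):
        est = bootstrap_effect(_degenerate_dataset(), "all birds",
                               BootstrapConfig(n_iter=500, seed=1))
        assert est.median_diff == 0.0
        assert est.ci_diff == (0.0, 0.0)
        assert not est.significant
        assert est.median_leb == pytest.approx(2.0)  # 2 birds / 1 std trossa-day

    def test_single_pair_oracle(self):
        """With one deterrent and one control the statistic is closed-form."""
        records = [
            make_record("T1", depth=25, has_leb=True, birds={"common_eider": 3}),
            make_record("T1", depth=24, soak=2, birds={"common_eider": 1}),
        ]
        est = bootstrap_effect(FleetDataset(records=records), "all birds",
                               BootstrapConfig(n_iter=200, seed=0))
        assert est.median_leb == pytest.approx(3.0)
        assert est.median_control == pytest.approx(0.5)
        assert est.median_diff == pytest.approx(2.5)
        assert est.ci_diff == (pytest.approx(2.5), pytest.approx(2.5))
        assert est.significant

    def test_deterministic_given_seed(self, study_fleet):
        dataset, _ = study_fleet
        cfg = BootstrapConfig(n_iter=400, seed=99)
        assert bootstrap_effect(dataset, "lumpfish", cfg) == bootstrap_effect(
            dataset, "lumpfish", cfg
        )

    def test_record_order_does_not_matter(self, study_fleet):
        dataset, _ = study_fleet
        shuffled = FleetDataset(
            records=list(reversed(dataset.records)),
            species_groups=dataset.species_groups,
        )
        cfg = BootstrapConfig(n_iter=300, seed=7)
        assert bootstrap_effect(dataset, "all birds", cfg) == bootstrap_effect(
            shuffled, "all birds", cfg
        )

    def test_unknown_group_is_configuration_error(self, study_fleet):
        dataset, _ = study_fleet
        with pytest.raises(ConfigurationError, match="puffins of the abyss"):
            bootstrap_effect(dataset, "puffins of the abyss", BootstrapConfig(n_iter=10))

    def test_leb_trossa_without_control_raises(self):
        records = [make_record("T1", depth=25, has_leb=True)]
        with pytest.raises(MatchingError, match="T1"):
            bootstrap_effect(FleetDataset(records=records), "all birds",
                             BootstrapConfig(n_iter=10, seed=0))

    def test_difference_of_medians_statistic(self):
        """Alternative statistic: diff equals median(device) − median(control)."""
        records = [
            make_record("T1", depth=25, has_leb=True, birds={"common_eider": 3}),
            make_record("T1", depth=24, soak=2, birds={"common_eider": 1}),
        ]
        est = bootstrap_effect(
            FleetDataset(records=records), "all birds",
            BootstrapConfig(n_iter=100, seed=0, statistic=DIFFERENCE_OF_MEDIANS),
        )
        assert est.median_diff == pytest.approx(est.median_leb - est.median_control)


class TestEffectTable:
    def test_empty_group_list(self, study_fleet):
        dataset, _ = study_fleet
        assert effect_table(dataset, [], BootstrapConfig(n_iter=10, seed=0)) == []

    def test_schema_and_determinism(self, study_fleet):
        dataset, _ = study_fleet
        groups = list(dataset.species_groups) + ["lumpfish"]
        cfg = BootstrapConfig(n_iter=300, seed=5)
        frame = effects_to_frame(effect_table(dataset, groups, cfg))
        assert list(frame["group"]) == groups
        assert set(frame.columns) >= {
            "median_leb", "ci_leb_lo", "ci_leb_hi",
            "median_control", "ci_control_lo", "ci_control_hi",
            "median_diff", "ci_diff_lo", "ci_diff_hi", "significant",
        }
        frame2 = effects_to_frame(effect_table(dataset, groups, cfg))
        assert frame.equals(frame2)

    def test_groups_have_independent_seed_streams(self, study_fleet):
        """Adding a group must not perturb another group's estimate."""
        dataset, _ = study_fleet
        cfg = BootstrapConfig(n_iter=300, seed=5)
        alone = effect_table(dataset, ["lumpfish"], cfg)[0]
        together = effect_table(dataset, ["all birds", "lumpfish"], cfg)[1]
        assert alone == together


def test_effect_recovery_direction():
    """A strong simulated deterrent effect yields a negative median difference."""
    cfg = FleetConfig(seed=13, leb_multiplier=0.2, true_bird_rate=constant_rate(1.0))
    dataset, _ = generate_fleet(cfg)
    est = bootstrap_effect(dataset, "all birds", BootstrapConfig(n_iter=1000, seed=2))
    assert est.median_diff < 0
    assert est.significant
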