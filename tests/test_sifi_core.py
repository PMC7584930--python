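import numpy as np
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from sifi.sifi_core import (
    SIFIConfig,
    Variant,
    best_survivor_index,
    compute_sifi,
    sifi_all_variants,
    worst_survivor_index,
)
from sifi.survival_data import (
    CONTROL,
    EXPERIMENTAL,
    DataValidationError,
    SurvivalDataset,
)

from conftest import make_trial, significant_trials

ALPHA = 0.05


# ---------------------------------------------------------------------------
# independent prefix-search oracle: own selection logic, lifelines log-rank,
# fresh from-scratch replay for every candidate k
# ---------------------------------------------------------------------------

def _oracle_p(recs):
    t = np.array([r[0] for r in recs])
    e = np.array([r[1] for r in recs])
    x = np.array([r[2] == EXPERIMENTAL for r in recs])
    return lifelines_logrank(t[x], t[~x], e[x], e[~x]).p_value


def _oracle_select(recs, donor, use_best):
    idx = [i for i, r in enumerate(recs) if r[2] == donor]
    if use_best:
        # longest time; censored preferred at ties; then lowest position
        return max(idx, key=lambda i: (recs[i][0], not recs[i][1], -i), default=None)
    ev = [i for i in idx if recs[i][1]]
    if not ev:
        return None
    return min(ev, key=lambda i: (recs[i][0], i))


def oracle_flip_sifi(ds, variant, alpha=ALPHA):
    """Minimal k such that k from-scratch flips cross the threshold."""
    recs = [(r.time, r.event, r.arm) for r in ds.records]
    p0 = _oracle_p(recs)
    positive = p0 < alpha
    use_best = variant is Variant.FLIP_BEST
    if use_best:
        donor = EXPERIMENTAL if positive else CONTROL
    else:
        donor = CONTROL if positive else EXPERIMENTAL
    recipient = CONTROL if donor == EXPERIMENTAL else EXPERIMENTAL
    for k in range(1, len(recs) + 1):
        fresh = list(recs)
        ok = True
        for _ in range(k):
            if len([r for r in fresh if r[2] == donor]) <= 1:
                ok = False
                break
            i = _oracle_select(fresh, donor, use_best)
            if i is None:
                ok = False
                break
            fresh[i] = (fresh[i][0], fresh[i][1], recipient)
        if not ok:
            return None
        p = _oracle_p(fresh)
        if (p >= alpha) if positive else (p < alpha):
            return k if positive else -k
    return None


# ---------------------------------------------------------------------------
# survivor selection
# ---------------------------------------------------------------------------

class TestSurvivorSelection:
    def test_best_tie_prefers_censored(self):
        ds = SurvivalDataset.from_arrays(
            [3.0, 5.0, 5.0, 1.0], [True, True, False, True],
            [EXPERIMENTAL] * 3 + [CONTROL],
        )
        assert best_survivor_index(ds, EXPERIMENTAL) == 2

    def test_best_single_subject(self):
        ds = SurvivalDataset.from_arrays(
            [3.0, 1.0], [True, True], [EXPERIMENTAL, CONTROL]
        )
        assert best_survivor_index(ds, EXPERIMENTAL) == 0

    def test_worst_is_earliest_event_not_earliest_time(self):
        ds = SurvivalDataset.from_arrays(
            [1.0, 2.0, 9.0], [False, True, True],
            [EXPERIMENTAL, EXPERIMENTAL, CONTROL],
        )
        assert worst_survivor_index(ds, EXPERIMENTAL) == 1

    def test_worst_requires_an_event(self):
        ds = SurvivalDataset.from_arrays(
            [1.0, 2.0], [False, True], [EXPERIMENTAL, CONTROL]
        )
        with pytest.raises(DataValidationError):
            worst_survivor_index(ds, EXPERIMENTAL)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_selection_matches_exhaustive_scan(self, seed):
        ds = make_trial(seed, n=1000, beta=-0.3)
        recs = ds.records
        idx = [i for i, r in enumerate(recs) if r.arm == EXPERIMENTAL]
        best = best_survivor_index(ds, EXPERIMENTAL)
        expected_best = max(
            idx, key=lambda i: (recs[i].time, not recs[i].event, -i)
        )
        assert best == expected_best
        worst = worst_survivor_index(ds, EXPERIMENTAL)
        ev = [i for i in idx if recs[i].event]
        assert worst == min(ev, key=lambda i: (recs[i].time, i))


# ---------------------------------------------------------------------------
# compute_sifi semantics
# ---------------------------------------------------------------------------

class TestComputeSIFI:
    def test_identical_arms_all_variants_negative(self, identical_arms_dataset):
        results = sifi_all_variants(identical_arms_dataset, alpha=ALPHA)
        for res in results.values():
            if not res.exhausted:
                assert res.value < 0
            assert res.p_initial == pytest.approx(1.0)

    def test_negative_trajectory_enters_significance_at_end(
        self, nonsignificant_dataset
    ):
        res = compute_sifi(nonsignificant_dataset, SIFIConfig())
        assert res.value < 0
        assert all(p >= ALPHA for p in res.p_trajectory[:-1])
        assert res.p_trajectory[-1] < ALPHA

    def test_positive_trajectory_contract(self, significant_dataset):
        res = compute_sifi(significant_dataset, SIFIConfig())
        k = res.value
        assert k > 0
        assert len(res.p_trajectory) == k + 1
        assert all(p < ALPHA for p in res.p_trajectory[:k])
        assert res.p_trajectory[k] >= ALPHA

    def test_input_not_modified(self, significant_dataset):
        before = [(r.time, r.event, r.arm) for r in significant_dataset.records]
        compute_sifi(significant_dataset, SIFIConfig())
        after = [(r.time, r.event, r.arm) for r in significant_dataset.records]
        assert before == after

    def test_determinism(self, significant_dataset):
        a = compute_sifi(significant_dataset, SIFIConfig())
        b = compute_sifi(significant_dataset, SIFIConfig())
        assert a.value == b.value and a.p_trajectory == b.p_trajectory

    def test_subject_counts(self, significant_dataset):
        n0 = len(significant_dataset)
        flip = compute_sifi(
            significant_dataset, SIFIConfig(variant=Variant.FLIP_BEST)
        )
        assert len(significant_dataset) == n0  # conserved (copy semantics)
        clone = compute_sifi(
            significant_dataset, SIFIConfig(variant=Variant.CLONE_BEST)
        )
        assert clone.value > 0 or clone.exhausted

    def test_max_iterations_flags_exhaustion(self, significant_dataset):
        res = compute_sifi(
            significant_dataset, SIFIConfig(max_iterations=1)
        )
        if abs(res.value) > 1 or res.p_trajectory[-1] < ALPHA:
            assert res.exhausted

    @pytest.mark.parametrize("variant", [Variant.FLIP_BEST, Variant.FLIP_WORST])
    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_flip_equals_prefix_oracle(self, variant, seed):
        """Iterative first crossing equals the from-scratch minimal k."""
        ds = make_trial(seed, n=60 * 2, beta=-np.log(3) / 1.5)
        res = compute_sifi(ds, SIFIConfig(variant=variant))
        expected = oracle_flip_sifi(ds, variant)
        if expected is None:
            assert res.exhausted
        else:
            assert not res.exhausted
            assert res.value == expected

    def test_all_variants_share_p_initial(self, significant_dataset):
        results = sifi_all_variants(significant_dataset, alpha=ALPHA)
        p0s = {round(r.p_initial, 15) for r in results.values()}
        assert len(p0s) == 1
        assert len(results) == 4

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            SIFIConfig(alpha=1.5)

    def test_literal_flip_worst_direction_moves_experimental_subject(
        self, significant_dataset
    ):
        default = compute_sifi(
            significant_dataset, SIFIConfig(variant=Variant.FLIP_WORST)
        )
        literal = compute_sifi(
            significant_dataset,
            SIFIConfig(variant=Variant.FLIP_WORST, literal_directions=True),
        )
        # the literal (printed) direction strengthens a positive result,
        # so it cannot cross faster than the default direction
        assert literal.exhausted or literal.value >= default.value


class TestVariantMagnitudes:
    def test_clone_best_at_least_flip_best_in_most_trials(self):
        """Cloning retains the donor's record, so more moves are needed.

        Asserted as a >= 90% property over a panel of significant trials.
        """
        panel = significant_trials(60, n=100, beta=-0.7)
        wins = 0
        for ds in panel:
            flip = compute_sifi(ds, SIFIConfig(variant=Variant.FLIP_BEST))
            clone = compute_sifi(ds, SIFIConfig(variant=Variant.CLONE_BEST))
            if clone.exhausted or abs(clone.value) >= abs(flip.value):
                wins += 1
        assert wins / len(panel) >= 0.9
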