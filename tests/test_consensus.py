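import random

import pytest

from lfqpair import ConsistencyError, PairDifference, call_all, consensus_call, fold_display, qualify_pair
from lfqpair.consensus import DIR_DECREASED, DIR_INCREASED, DIR_NONE, MODE_UNIQUE_ALWAYS
from lfqpair.differential import MODE_BOTH, MODE_CTL_ONLY, MODE_IFN_ONLY

DONORS = ["d1", "d2", "d3", "d4", "d5"]


def diff(accession="A", donor="d1", mode=MODE_BOTH, z=0.0, d=None):
    if d is None:
        d = z if mode == MODE_BOTH else (12.0 if mode == MODE_IFN_ONLY else -12.0)
    return PairDifference(
        accession=accession, donor_id=donor, mode=mode, D=d, Z=z,
        ifn_log2=None if mode == MODE_CTL_ONLY else abs(d),
        ctl_log2=None if mode == MODE_IFN_ONLY else abs(d),
    )


def brute_force_direction(donor_evidence, z_threshold=2.0, min_pairs=3):
    """Independent enumeration of the qualify-and-count rule (no veto)."""
    n_up = sum(
        1 for mode, z in donor_evidence
        if mode in (MODE_BOTH, MODE_IFN_ONLY) and z is not None and z >= z_threshold
    )
    n_down = sum(
        1 for mode, z in donor_evidence
        if mode in (MODE_BOTH, MODE_CTL_ONLY) and z is not None and z <= -z_threshold
    )
    if n_up >= min_pairs:
        return DIR_INCREASED, n_up
    if n_down >= min_pairs:
        return DIR_DECREASED, n_down
    return DIR_NONE, max(n_up, n_down)


class TestQualifyPair:
    @pytest.mark.parametrize(
        "z, expected",
        [(2.0, "up"), (2.4, "up"), (-2.0, "down"), (-2.4, "down"),
         (1.99, "none"), (-1.99, "none"), (0.0, "none")],
    )
    def test_threshold_is_inclusive(self, z, expected):
        assert qualify_pair(diff(z=z)) == expected

    def test_exclusive_threshold_option(self):
        assert qualify_pair(diff(z=2.0), inclusive=False) == "none"
        assert qualify_pair(diff(z=2.0001), inclusive=False) == "up"

    def test_mode_unique_is_gated_by_z_by_default(self):
        assert qualify_pair(diff(mode=MODE_IFN_ONLY, z=5.0)) == "up"
        assert qualify_pair(diff(mode=MODE_IFN_ONLY, z=1.0)) == "none"
        assert qualify_pair(diff(mode=MODE_CTL_ONLY, z=-5.0)) == "down"

    def test_mode_unique_always_rule(self):
        assert qualify_pair(diff(mode=MODE_IFN_ONLY, z=1.0),
                            mode_unique_rule=MODE_UNIQUE_ALWAYS) == "up"
        assert qualify_pair(diff(mode=MODE_CTL_ONLY, z=-1.0),
                            mode_unique_rule=MODE_UNIQUE_ALWAYS) == "down"


class TestFoldDisplay:
    def test_fold_rounded_to_one_decimal(self):
        assert fold_display(diff(d=3.053, z=1.0)) == "8.3"

    def test_decreased_tables_show_fold_decrease(self):
        assert fold_display(diff(d=-3.053, z=-1.0), direction=DIR_DECREASED) == "8.3"

    def test_mode_unique_and_absent_tokens(self):
        assert fold_display(diff(mode=MODE_IFN_ONLY)) == "IFN"
        assert fold_display(diff(mode=MODE_CTL_ONLY)) == "CTL"
        assert fold_display(None) == "–"


class TestConsensusCall:
    def test_three_of_five_up(self):
        diffs = [diff(donor=d, z=z) for d, z in zip(DONORS, [2.5, 2.1, 3.0, -0.3, 1.0])]
        call = consensus_call(diffs, DONORS)
        assert call.direction == DIR_INCREASED
        assert call.n_qualifying == 3

    def test_opposite_donor_does_not_veto(self):
        # Three presence-only donors carry the call even though another
        # donor shows the protein only in the untreated sample.
        diffs = [
            diff(donor="d1", mode=MODE_IFN_ONLY, z=8.0),
            diff(donor="d2", mode=MODE_IFN_ONLY, z=7.5),
            diff(donor="d3", mode=MODE_IFN_ONLY, z=9.0),
            diff(donor="d4", z=0.0),
            diff(donor="d5", mode=MODE_CTL_ONLY, z=-8.0),
        ]
        call = consensus_call(diffs, DONORS)
        assert call.direction == DIR_INCREASED
        assert call.per_donor_display == ("IFN", "IFN", "IFN", "1.0", "CTL")

    def test_display_respects_donor_order_and_absence(self):
        diffs = [diff(donor="d2", z=2.5, d=1.0), diff(donor="d4", mode=MODE_IFN_ONLY, z=6.0)]
        call = consensus_call(diffs, DONORS)
        assert call.per_donor_display == ("–", "2.0", "–", "IFN", "–")

    def test_two_differences_for_one_donor_raise(self):
        with pytest.raises(ConsistencyError):
            consensus_call([diff(donor="d1", z=2.5), diff(donor="d1", z=2.5)], DONORS)

    def test_matches_brute_force_on_random_vectors(self):
        rng = random.Random(11)
        modes = [MODE_BOTH, MODE_IFN_ONLY, MODE_CTL_ONLY, None]
        for _ in range(2000):
            evidence, diffs = [], []
            for donor in DONORS:
                mode = rng.choice(modes)
                if mode is None:
                    continue
                if mode == MODE_BOTH:
                    z = rng.gauss(0, 1.5)
                elif mode == MODE_IFN_ONLY:
                    z = abs(rng.gauss(6, 4))
                else:
                    z = -abs(rng.gauss(6, 4))
                evidence.append((mode, z))
                diffs.append(diff(donor=donor, mode=mode, z=z))
            expected_dir, expected_n = brute_force_direction(evidence)
            call = consensus_call(diffs, DONORS)
            assert (call.direction, call.n_qualifying) == (expected_dir, expected_n)

    def test_calls_invariant_under_donor_reordering(self):
        per_donor = {
            d: [diff(accession="A", donor=d, z=z)]
            for d, z in zip(DONORS, [2.5, -2.1, 3.0, 2.2, 1.0])
        }
        forward = call_all(per_donor, DONORS)
        reversed_input = {d: per_donor[d] for d in reversed(DONORS)}
        assert call_all(reversed_input, DONORS) == forward

    def test_raising_threshold_never_creates_calls(self):
        rng = random.Random(5)
        for _ in range(200):
            diffs = [diff(donor=d, z=rng.gauss(0, 2)) for d in DONORS]
            low = consensus_call(diffs, DONORS, z_threshold=2.0)
            high = consensus_call(diffs, DONORS, z_threshold=2.5)
            if low.direction == DIR_NONE:
                assert high.direction == DIR_NONE

    def test_directions_mutually_exclusive_with_majority_rule(self):
        # min_pairs = 3 > 5/2, so both directions can never be reached at
        # once; spot-check an adversarial split.
        diffs = [diff(donor=d, z=z) for d, z in zip(DONORS, [3.0, 2.5, -3.0, -2.5, 0.0])]
        assert consensus_call(diffs, DONORS).direction == DIR_NONE
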