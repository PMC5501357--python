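import numpy as np
import pytest

from lfqpair import (
    ConsistencyError,
    InsufficientDataError,
    PairDifference,
    ProteinQuant,
    central_stats,
    normalize,
    pair_differences,
)
from lfqpair.differential import MODE_BOTH, MODE_CTL_ONLY, MODE_IFN_ONLY


def quant(accession, log2, condition, donor="d1"):
    return ProteinQuant(
        accession=accession, donor_id=donor, condition=condition,
        log2_intensity=log2, n_distinct_peptides=2, n_psms=4,
    )


def both_diff(accession, d, donor="d1"):
    return PairDifference(
        accession=accession, donor_id=donor, mode=MODE_BOTH, D=d,
        ifn_log2=10.0 + d, ctl_log2=10.0,
    )


class TestPairDifferences:
    def test_both_mode_is_subtraction(self):
        (d,) = pair_differences([quant("A", 14.0, "IFN")], [quant("A", 11.0, "CTL")])
        assert (d.mode, d.D) == (MODE_BOTH, 3.0)

    def test_ifn_only_is_positive_signed_intensity(self):
        (d,) = pair_differences([quant("A", 12.5, "IFN")], [])
        assert (d.mode, d.D) == (MODE_IFN_ONLY, 12.5)
        assert d.ctl_log2 is None

    def test_ctl_only_is_negative_signed_intensity(self):
        (d,) = pair_differences([], [quant("A", 10.0, "CTL")])
        assert (d.mode, d.D) == (MODE_CTL_ONLY, -10.0)

    def test_mode_partition_is_exhaustive_and_exclusive(self):
        diffs = pair_differences(
            [quant("A", 14.0, "IFN"), quant("B", 12.0, "IFN")],
            [quant("A", 11.0, "CTL"), quant("C", 9.0, "CTL")],
        )
        assert {d.accession: d.mode for d in diffs} == {
            "A": MODE_BOTH, "B": MODE_IFN_ONLY, "C": MODE_CTL_ONLY,
        }

    def test_donor_mismatch_raises(self):
        with pytest.raises(ConsistencyError):
            pair_differences([quant("A", 14.0, "IFN", donor="d1")],
                             [quant("A", 11.0, "CTL", donor="d2")])

    def test_swapped_condition_labels_raise(self):
        with pytest.raises(ConsistencyError):
            pair_differences([quant("A", 14.0, "CTL")], [quant("A", 11.0, "IFN")])


class TestCentralStats:
    def test_closed_form_example(self):
        stats = central_stats([both_diff("A", -1.0), both_diff("B", 0.0), both_diff("C", 1.0)])
        assert stats.central_mean == pytest.approx(0.0)
        assert stats.central_sd == pytest.approx(1.0)
        assert stats.n_central == 3

    def test_outer_populations_do_not_enter_the_stats(self):
        diffs = [both_diff("A", -1.0), both_diff("B", 0.0), both_diff("C", 1.0),
                 PairDifference("D", "d1", MODE_IFN_ONLY, 12.0, ifn_log2=12.0),
                 PairDifference("E", "d1", MODE_CTL_ONLY, -9.0, ctl_log2=9.0)]
        stats = central_stats(diffs)
        assert stats.central_mean == pytest.approx(0.0)
        assert stats.central_sd == pytest.approx(1.0)
        assert (stats.n_ifn_only, stats.n_ctl_only) == (1, 1)

    def test_constant_differences_have_no_variance(self):
        with pytest.raises(InsufficientDataError):
            central_stats([both_diff(a, 0.5) for a in "ABCD"])

    def test_fewer_than_two_central_points_raise(self):
        with pytest.raises(InsufficientDataError):
            central_stats([both_diff("A", 1.0)])

    def test_robust_estimator_resists_contamination(self):
        rng = np.random.default_rng(0)
        d_values = np.concatenate([rng.normal(0, 0.8, 900), np.full(100, 2.4)])
        diffs = [both_diff(f"P{i}", d) for i, d in enumerate(d_values)]
        classical = central_stats(diffs).central_sd
        robust = central_stats(diffs, robust=True).central_sd
        assert classical > 1.0  # inflated by the contaminated tail
        assert robust == pytest.approx(0.8, abs=0.12)
        assert robust < classical - 0.1

    def test_null_simulation_recovers_generator_noise(self, small_sim):
        # Monte-Carlo check: with no spiked effects the central SD should
        # approximate the generator's pair-difference noise SD.
        from lfqpair import SimConfig, simulate_experiment, quantify_run
        sim = simulate_experiment(SimConfig(n_proteins=500, n_donors=1, frac_de=0.0, seed=21))
        diffs = pair_differences(
            quantify_run(sim.runs[("d1", "IFN")]), quantify_run(sim.runs[("d1", "CTL")])
        )
        stats = central_stats(diffs)
        assert stats.central_mean == pytest.approx(0.0, abs=0.1)
        assert stats.central_sd == pytest.approx(0.8, abs=0.12)


class TestNormalize:
    def test_z_arithmetic(self):
        import dataclasses

        diffs = [both_diff("A", 4.5), both_diff("B", -1.0), both_diff("C", 2.0)]
        stats = dataclasses.replace(central_stats(diffs), central_mean=0.5, central_sd=2.0)
        normalized = normalize(diffs, stats)
        assert normalized[0].Z == pytest.approx(2.0)

    def test_central_population_is_standardized_exactly(self):
        rng = np.random.default_rng(1)
        diffs = [both_diff(f"P{i}", d) for i, d in enumerate(rng.normal(0.3, 1.7, 400))]
        z = np.array([d.Z for d in normalize(diffs, central_stats(diffs))])
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_idempotent_at_the_fixed_point(self):
        rng = np.random.default_rng(2)
        diffs = [both_diff(f"P{i}", d) for i, d in enumerate(rng.normal(0, 1, 200))]
        once = normalize(diffs, central_stats(diffs))
        twice = normalize(once, central_stats(once))
        for a, b in zip(once, twice):
            assert b.Z == pytest.approx(a.Z, abs=1e-12)

    def test_z_is_strictly_increasing_in_d(self):
        rng = np.random.default_rng(3)
        diffs = sorted(
            (both_diff(f"P{i}", d) for i, d in enumerate(rng.normal(0, 1, 100))),
            key=lambda d: d.D,
        )
        z = [d.Z for d in normalize(diffs, central_stats(diffs))]
        assert all(b > a for a, b in zip(z, z[1:]))

    def test_affine_invariance_of_both_mode_z(self):
        ifn = [quant(f"P{i}", 10.0 + i * 0.37, "IFN") for i in range(20)]
        ctl = [quant(f"P{i}", 10.0 + ((i * 7) % 5) * 0.81, "CTL") for i in range(20)]
        shifted_ifn = [quant(q.accession, q.log2_intensity + 3.0, "IFN") for q in ifn]
        shifted_ctl = [quant(q.accession, q.log2_intensity + 3.0, "CTL") for q in ctl]
        base = pair_differences(ifn, ctl)
        shifted = pair_differences(shifted_ifn, shifted_ctl)
        z0 = [d.Z for d in normalize(base, central_stats(base))]
        z1 = [d.Z for d in normalize(shifted, central_stats(shifted))]
        assert z1 == pytest.approx(z0, abs=1e-9)

    def test_stats_from_wrong_donor_raise(self):
        diffs = [both_diff("A", 1.0), both_diff("B", -1.0)]
        stats = central_stats([both_diff("A", 1.0, donor="d2"), both_diff("B", -1.0, donor="d2")])
        with pytest.raises(ConsistencyError):
            normalize(diffs, stats)
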