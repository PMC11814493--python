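import edlib
import numpy as np
import pytest

from telokit.explore import ExploreConfig
from telokit.search import search
from telokit.simulate import (
    ConditionResult,
    ErrorModel,
    alternating_array,
    mix_sensitivity,
    run_condition,
    run_grid,
    simulate_telomere,
    synthetic_assembly,
)

CFG = ExploreConfig(4, 8, 50)


class TestErrorModel:
    def test_fracs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ErrorModel(rate=0.1, sub_frac=0.5, ins_frac=0.5, del_frac=0.5)

    def test_rate_bounds(self):
        with pytest.raises(ValueError, match="rate"):
            ErrorModel(rate=1.5)


class TestSimulateTelomere:
    def test_zero_error_is_exact_tiling(self):
        assert simulate_telomere("TTAGGG", 600, ErrorModel(rate=0.0)) == "TTAGGG" * 100
        # the final copy is truncated to hit the length exactly
        assert simulate_telomere("TTAGGG", 604, ErrorModel(rate=0.0)) == ("TTAGGG" * 101)[:604]

    def test_deterministic_under_seed(self):
        m = ErrorModel(rate=0.05, seed=123)
        assert simulate_telomere("TTAGGG", 1200, m) == simulate_telomere("TTAGGG", 1200, m)

    def test_length_below_unit_rejected(self):
        with pytest.raises(ValueError):
            simulate_telomere("TTAGGG", 3, ErrorModel(rate=0.0))

    def test_edit_distance_tracks_binomial_event_count(self):
        """At rate p, the expected number of events is n*p; the optimal
        alignment can absorb a small fraction of them (e.g. an inserted
        base equal to its neighbour), so the mean edit distance sits just
        below n*p but far above half of it."""
        n, p, reps = 600, 0.10, 100
        clean = "TTAGGG" * 100
        dists = [
            edlib.align(clean, simulate_telomere("TTAGGG", n, ErrorModel(rate=p, seed=s)))[
                "editDistance"
            ]
            for s in range(reps)
        ]
        mean = np.mean(dists)
        sigma = np.sqrt(n * p * (1 - p))  # per-replicate binomial spread
        assert n * p - 3 * sigma <= mean <= n * p + 3 * sigma / np.sqrt(reps)

    def test_substitution_only_preserves_length(self):
        m = ErrorModel(rate=0.2, sub_frac=1.0, ins_frac=0.0, del_frac=0.0, seed=5)
        assert len(simulate_telomere("TTAGGG", 3000, m)) == 3000

    def test_deletion_only_shortens(self):
        m = ErrorModel(rate=0.2, sub_frac=0.0, ins_frac=0.0, del_frac=1.0, seed=5)
        assert len(simulate_telomere("TTAGGG", 3000, m)) < 3000


class TestRunCondition:
    def test_zero_error_recovers_true_repeat(self):
        res = run_condition("TTAGGG", 600, ErrorModel(rate=0.0, seed=1), 10, CFG)
        assert isinstance(res, ConditionResult)
        assert res.top_repeat == "AACCCT"
        assert res.true_repeat_found
        assert res.n_replicates_with_runs == 10

    def test_fully_randomised_sequence_loses_the_repeat(self):
        m = ErrorModel(rate=1.0, sub_frac=1.0, ins_frac=0.0, del_frac=0.0, seed=1)
        res = run_condition("TTAGGG", 600, m, 10, CFG)
        assert not res.true_repeat_found
        assert res.top_repeat != "AACCCT"

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            run_condition("TTAGGG", 600, ErrorModel(rate=0.0), 0, CFG)

    def test_reproducible_given_seed(self):
        m = ErrorModel(rate=0.02, seed=77)
        a = run_condition("TTAGGG", 600, m, 20, CFG)
        b = run_condition("TTAGGG", 600, m, 20, CFG)
        assert a.table.equals(b.table)
        assert (a.top_repeat, a.top_count) == (b.top_repeat, b.top_count)


class TestRunGrid:
    def test_zero_rate_grid_recovers_at_every_length(self):
        g = run_grid(rates=[0.0], n_replicates=5, cfg=CFG, seed=3)
        assert g.n_conditions == 3
        assert g.n_top_match == 3
        assert g.n_true_absent == 0

    def test_grid_shape_and_reproducibility(self):
        kwargs = dict(lengths=[600], rates=[0.0, 0.05], n_replicates=10, cfg=CFG, seed=9)
        a, b = run_grid(**kwargs), run_grid(**kwargs)
        assert a.to_frame().equals(b.to_frame())
        assert list(a.to_frame().columns) == [
            "length", "rate", "n_replicates", "top_repeat", "top_count", "true_repeat_found",
        ]
        assert len(a.results) == 2

    def test_recovery_monotone_in_error_rate(self):
        # replicates contributing a qualifying run can only be lost as the
        # per-base error rate grows
        g = run_grid(lengths=[600], rates=[0.0, 0.01, 0.02, 0.05, 0.10],
                     n_replicates=40, cfg=CFG, seed=11)
        contributing = [r.n_replicates_with_runs for r in g.results]
        assert contributing == sorted(contributing, reverse=True)

    def test_mix_sensitivity_table_shape(self):
        df = mix_sensitivity(
            mixes={"sub_only": (1.0, 0.0, 0.0), "uniform": (1 / 3, 1 / 3, 1 / 3)},
            lengths=[600], rates=[0.0, 0.05], n_replicates=5, cfg=CFG, seed=2,
        )
        assert len(df) == 2
        assert set(df["mix"]) == {"sub_only", "uniform"}


class TestSyntheticFixtures:
    def test_alternating_array(self):
        assert alternating_array("AACCT", "AACCCG", 2) == "AACCTAACCCGAACCTAACCCG"

    def test_assembly_end_peaks(self):
        recs = synthetic_assembly(n_records=4, n_both_ends=3, record_length=6000,
                                  telomere_length=600, seed=1)
        assert len(recs) == 4
        df = search(recs, "TTAGGG", 500)
        for i, (sid, sub) in enumerate(df.groupby("id", sort=False)):
            totals = (sub["forward_repeat_number"] + sub["reverse_repeat_number"]).to_numpy()
            assert totals[0] > 10  # 5' telomere always present
            if i < 3:
                assert totals[-1] > 10
            else:
                assert totals[-1] <= 2

    def test_assembly_deterministic(self):
        assert synthetic_assembly(seed=4) == synthetic_assembly(seed=4)
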