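"""Decontamination tests: per-step rules, iteration laws, oracle equivalence."""

import numpy as np
import pytest

from casecomm import DecontamParams, run_decontam
from casecomm.decontam import (
    read_accounting_percent,
    relative_abundance,
    step1_control_ratio,
    step2_min_abundance,
    step3_sample_retention,
)

from .conftest import make_table
from .reference import reference_decontam

PARAMS = DecontamParams()


class TestRelativeAbundance:
    def test_fractions_sum_to_one_per_sample(self):
        table = make_table({"A": {"u1": 5, "u2": 5}, "B": {"u1": 1}})
        rel = relative_abundance(table)
        assert rel["A"]["u1"] == 0.5 and rel["A"]["u2"] == 0.5
        assert rel["B"]["u1"] == 1.0
        assert np.allclose(rel.sum(axis=0), 1.0)

    def test_empty_sample_raises(self):
        table = make_table({"A": {"u1": 1}, "B": {}})
        with pytest.raises(ValueError):
            relative_abundance(table)


class TestStep1:
    def test_tenfold_rule_boundary(self):
        # u1: control 5%, experimental 60% -> kept (60 >= 10*5... no, 50)
        # u2: control 5%, experimental 40% -> removed (40 < 50)
        table = make_table(
            {"ctl": {"u1": 5, "u2": 5, "u3": 90},
             "exp1": {"u1": 60, "u2": 40},
             "exp2": {"u3": 100}},
            controls={"ctl"},
        )
        kept = step1_control_ratio(table, PARAMS)
        assert "u1" in kept
        assert "u2" not in kept

    def test_sequence_absent_from_controls_kept_if_present(self):
        table = make_table(
            {"ctl": {"u1": 10}, "exp": {"u1": 1, "u2": 9}}, controls={"ctl"}
        )
        kept = step1_control_ratio(table, PARAMS)
        assert "u2" in kept

    def test_requires_experimental_samples(self):
        table = make_table({"ctl": {"u1": 1}}, controls={"ctl"})
        with pytest.raises(ValueError):
            step1_control_ratio(table, PARAMS)


class TestStep2:
    def test_abundance_floor(self):
        table = make_table(
            {"A": {"u1": 2, "rest": 998},       # u1 at 0.2%
             "B": {"u1": 1, "u2": 5, "rest": 9994}},  # u1 0.01%, u2 0.05%
        )
        kept = step2_min_abundance(table, PARAMS)
        assert "u1" in kept      # reaches 0.1% somewhere
        assert "u2" not in kept  # 0.05% everywhere

    def test_empty_table(self):
        table = make_table({"A": {}, "B": {}})
        table.counts = table.counts.iloc[0:0]
        assert step2_min_abundance(table, PARAMS) == set()


class TestStep3:
    @pytest.mark.parametrize("current,kept", [(251, True), (250, True), (249, False)])
    def test_25_percent_boundary(self, current, kept):
        table = make_table({"A": {"u1": current}})
        result = step3_sample_retention(table, {"A": 1000}, PARAMS)
        assert ("A" in result) is kept

    def test_missing_starting_size_raises(self):
        table = make_table({"A": {"u1": 10}})
        with pytest.raises(KeyError):
            step3_sample_retention(table, {}, PARAMS)


class TestRunDecontam:
    def test_clean_table_is_fixed_point(self):
        # abundant everywhere, nothing in controls above threshold
        table = make_table(
            {"ctl": {"c1": 100},
             "e1": {"u1": 60, "u2": 40},
             "e2": {"u1": 30, "u2": 70}},
            controls={"ctl"},
        )
        filtered, report = run_decontam(table)
        # c1 (control-only) is removed, ctl drops out; u1/u2 untouched
        assert sorted(filtered.counts.index) == ["u1", "u2"]
        assert filtered.counts[["e1", "e2"]].equals(table.counts.loc[["u1", "u2"], ["e1", "e2"]])

    def test_no_controls_warns_and_degrades(self):
        table = make_table({"A": {"u1": 600, "u2": 400}})
        with pytest.warns(UserWarning, match="no negative controls"):
            filtered, _ = run_decontam(table)
        assert filtered.counts.equals(table.counts)

    def test_toy_table_removal_sequence(self):
        # hand-built: contam lost to step 1, rare lost to step 2, sample X
        # (dominated by contam) lost to step 3
        table = make_table(
            {
                "ctl": {"contam": 100},
                "X": {"contam": 960, "good": 40},
                "Y": {"good": 500, "rare": 1, "filler": 1499},
                "Z": {"good": 600, "filler": 1400},
            },
            controls={"ctl"},
        )
        filtered, report = run_decontam(table)
        it1 = report.iterations[0]
        assert it1.removed_sequences_step1 == ["contam"]
        assert it1.removed_sequences_step2 == ["rare"]
        assert set(it1.removed_samples) == {"ctl", "X"}
        assert sorted(filtered.sample_ids) == ["Y", "Z"]
        assert sorted(filtered.counts.index) == ["filler", "good"]

    def test_synthetic_controls_all_discarded(self, sim, decontaminated):
        table, _ = sim
        filtered, report = decontaminated
        assert set(filtered.sample_ids) & table.control_ids == set()
        removed = {s for it in report.iterations for s in it.removed_samples}
        assert table.control_ids <= removed

    def test_monotone_and_terminates(self, decontaminated):
        _, report = decontaminated
        reads = [it.reads_before for it in report.iterations]
        assert all(a >= b for a, b in zip(reads, reads[1:]))
        for it in report.iterations:
            assert it.reads_after <= it.reads_before
            assert not (set(it.removed_sequences_step1) & set(it.removed_sequences_step2))

    def test_idempotent(self, decontaminated):
        filtered, _ = decontaminated
        again, report2 = run_decontam(filtered)
        assert again.counts.equals(filtered.counts)
        assert report2.n_iterations == 1

    def test_all_experimental_discarded_reported_not_fatal(self):
        table = make_table(
            {"ctl": {"c": 100}, "e1": {"c": 50}}, controls={"ctl"}
        )
        filtered, report = run_decontam(table)
        assert report.all_experimental_discarded
        assert filtered.experimental_ids == []


class TestOracleEquivalence:
    """Output matches a straight-line reference on small random tables."""

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_reference_on_random_tables(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_seq = int(rng.integers(2, 11))
        n_samp = int(rng.integers(2, 11))
        samples = [f"s{i}" for i in range(n_samp)]
        controls = set(rng.choice(samples, size=max(1, n_samp // 3), replace=False))
        if not set(samples) - controls:
            controls.discard(samples[0])
        counts = {}
        for s in samples:
            col = {}
            for u in range(n_seq):
                if rng.random() < 0.7:
                    col[f"u{u}"] = int(rng.integers(1, 400))
            if not col:
                col["u0"] = 1
            counts[s] = col
        table = make_table(counts, controls=controls)
        filtered, _ = run_decontam(table)
        expected, _ = reference_decontam(
            {s: dict(c) for s, c in counts.items()}, controls
        )
        got = {
            s: {u: int(filtered.counts.loc[u, s])
                for u in filtered.counts.index if filtered.counts.loc[u, s] > 0}
            for s in filtered.sample_ids
        }
        assert got == expected


class TestReadAccounting:
    def test_percent_of_total(self):
        assert read_accounting_percent(682922, 5094718) == 13.40
        with pytest.raises(ValueError):
            read_accounting_percent(1, 0)
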