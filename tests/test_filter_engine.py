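"""Per-step filter predicates, cascade accounting, and the filter laws."""

from __future__ import annotations

import dataclasses
import itertools
import random

import pytest

from conftest import oracle_survivors, random_config, random_table
from exosift.errors import ConfigError
from exosift.filter_engine import (
    CascadeReport,
    FilterConfig,
    filter_exonic,
    filter_fathmm,
    filter_frequency,
    filter_functional_class,
    filter_gerp,
    run_cascade,
)
from exosift.table_io import VariantRecord


def rec(**kwargs) -> VariantRecord:
    base = dict(
        chrom="1", start=100, end=100, ref="A", alt="G",
        func_region="exonic", gene="GENE1", exonic_func="nonsynonymous SNV",
    )
    base.update(kwargs)
    return VariantRecord(**base)


class TestFilterConfig:
    def test_defaults_match_published_rules(self, default_config):
        cfg = default_config
        assert cfg.freq_threshold_1kgp == 0.01
        assert cfg.freq_threshold_esp == 0.01
        assert cfg.gerp_min == 0.0
        assert cfg.fathmm_max == 1.0
        assert "exonic" in cfg.exonic_keep
        assert "synonymous SNV" in cfg.exonic_func_remove

    def test_strict_preset_changes_only_fathmm(self):
        default = FilterConfig.preset("default")
        strict = FilterConfig.preset("strict")
        assert strict.fathmm_max == -1.5
        diff = {
            f.name
            for f in dataclasses.fields(FilterConfig)
            if getattr(default, f.name) != getattr(strict, f.name)
        }
        assert diff == {"fathmm_max"}

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError, match="preset"):
            FilterConfig.preset("lenient")

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            FilterConfig(freq_threshold_1kgp=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = FilterConfig(fathmm_max=-1.5, include_splicing=True)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert FilterConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            FilterConfig.from_dict({"fathm_max": 1.0})


class TestStepPredicates:
    @pytest.mark.parametrize(
        "func_region,kept",
        [
            ("exonic", True),
            ("exonic;splicing", True),
            ("intergenic", False),
            ("intronic", False),
            ("splicing", False),
        ],
    )
    def test_step1_exonic_regions(self, func_region, kept, default_config):
        survivors = filter_exonic([rec(func_region=func_region)], default_config)
        assert bool(survivors) is kept

    def test_step1_include_splicing_extends_keep_set(self):
        cfg = FilterConfig(include_splicing=True)
        assert filter_exonic([rec(func_region="splicing")], cfg)

    @pytest.mark.parametrize(
        "exonic_func,kept",
        [
            ("synonymous SNV", False),
            ("nonframeshift insertion", False),
            ("nonframeshift deletion", False),
            ("nonframeshift substitution", False),
            ("nonsynonymous SNV", True),
            ("frameshift deletion", True),
            ("frameshift insertion", True),
            ("stopgain", True),
            ("stoploss", True),
            ("unknown", True),
            (None, True),
        ],
    )
    def test_step2_functional_classes(self, exonic_func, kept, default_config):
        survivors = filter_functional_class(
            [rec(exonic_func=exonic_func)], default_config
        )
        assert bool(survivors) is kept

    @pytest.mark.parametrize(
        "freq,kept",
        [(0.02, False), (0.01, True), (0.005, True), (None, True), (0.0100001, False)],
    )
    @pytest.mark.parametrize("which", ["kgp", "esp"])
    def test_steps34_one_percent_rarity(self, freq, kept, which, default_config):
        field = "freq_1kgp" if which == "kgp" else "freq_esp6500"
        survivors = filter_frequency(
            [rec(**{field: freq})], default_config, which
        )
        assert bool(survivors) is kept

    def test_steps34_missing_dropped_when_policy_off(self):
        cfg = FilterConfig(keep_missing_freq=False)
        assert not filter_frequency([rec(freq_1kgp=None)], cfg, "kgp")

    def test_steps34_threshold_override(self, default_config):
        survivors = filter_frequency(
            [rec(freq_1kgp=0.04)], default_config, "kgp", threshold=0.05
        )
        assert survivors

    @pytest.mark.parametrize(
        "gerp,kept", [(-1.2, False), (0.0, True), (2.5, True), (None, True)]
    )
    def test_step5_negative_gerp_removed(self, gerp, kept, default_config):
        assert bool(filter_gerp([rec(gerp=gerp)], default_config)) is kept

    @pytest.mark.parametrize(
        "fathmm,fathmm_max,kept",
        [
            (2.5, 1.0, False),
            (1.0, 1.0, True),
            (-3.0, 1.0, True),
            (-3.0, -1.5, True),
            (-1.0, -1.5, False),
            (None, 1.0, True),
        ],
    )
    def test_step6_fathmm_cutoff(self, fathmm, fathmm_max, kept):
        cfg = FilterConfig(fathmm_max=fathmm_max)
        assert bool(filter_fathmm([rec(fathmm=fathmm)], cfg)) is kept


class TestCascade:
    def test_empty_input(self, default_config):
        survivors, report = run_cascade([], default_config)
        assert survivors == []
        assert report.counts == [0] * 7
        assert report.removed == [0] * 7

    def test_single_all_pass_record(self, default_config):
        record = rec(freq_1kgp=0.001, freq_esp6500=None, gerp=3.0, fathmm=-2.0)
        survivors, report = run_cascade([record], default_config)
        assert survivors == [record]
        assert report.counts == [1] * 7

    def test_stratified_counts(self, default_config):
        records = (
            [rec(func_region="intronic") for _ in range(60)]
            + [rec(exonic_func="synonymous SNV") for _ in range(15)]
            + [rec(freq_1kgp=0.3) for _ in range(10)]
            + [rec(freq_esp6500=0.2) for _ in range(5)]
            + [rec(gerp=-2.0) for _ in range(4)]
            + [rec(fathmm=3.0) for _ in range(3)]
            + [rec(gerp=1.0, fathmm=-2.0) for _ in range(3)]
        )
        _, report = run_cascade(records, default_config)
        assert report.counts == [100, 40, 25, 15, 10, 6, 3]
        assert report.removed == [0, 60, 15, 10, 5, 4, 3]

    def test_order_preserved(self, rng):
        records = random_table(rng, 150)
        survivors, _ = run_cascade(records)
        positions = [records.index(s) for s in survivors]
        assert positions == sorted(positions)

    def test_report_rejects_increasing_counts(self):
        with pytest.raises(ValueError, match="non-increasing"):
            CascadeReport(["a", "b"], [1, 2])

    def test_report_serialization(self, tmp_path):
        report = CascadeReport(["input", "s1"], [10, 4])
        report.to_tsv(tmp_path / "r.tsv")
        lines = (tmp_path / "r.tsv").read_text().splitlines()
        assert lines[0] == "step\tsurvivors\tremoved"
        assert lines[2] == "s1\t4\t6"
        payload = report.to_json()
        assert '"counts"' in payload and "[\n    10,\n    4\n  ]" in payload


class TestFilterLaws:
    """The algebraic laws of the cascade on random tables and configs."""

    N_TRIALS = 40

    def test_counts_monotone_and_consistent(self, rng):
        for _ in range(self.N_TRIALS):
            records, cfg = random_table(rng), random_config(rng)
            _, report = run_cascade(records, cfg)
            assert all(a >= b for a, b in zip(report.counts, report.counts[1:]))
            assert all(
                report.removed[i + 1] == report.counts[i] - report.counts[i + 1]
                for i in range(len(report.counts) - 1)
            )

    def test_idempotence(self, rng):
        for _ in range(self.N_TRIALS):
            records, cfg = random_table(rng), random_config(rng)
            survivors, _ = run_cascade(records, cfg)
            again, report = run_cascade(survivors, cfg)
            assert again == survivors
            assert report.counts == [len(survivors)] * 7

    def test_steps_2_to_6_commute_on_final_set(self, rng):
        steps = [
            filter_functional_class,
            lambda rs, c: filter_frequency(rs, c, "kgp"),
            lambda rs, c: filter_frequency(rs, c, "esp"),
            filter_gerp,
            filter_fathmm,
        ]
        for _ in range(8):
            records, cfg = random_table(rng, 80), random_config(rng)
            exonic = filter_exonic(records, cfg)
            reference = None
            for perm in itertools.islice(itertools.permutations(steps), 12):
                out = exonic
                for step in perm:
                    out = step(out, cfg)
                if reference is None:
                    reference = out
                assert out == reference

    def test_missing_toggle_never_increases_survivors(self, rng):
        for _ in range(self.N_TRIALS):
            records, cfg = random_table(rng), random_config(rng)
            on = dataclasses.replace(
                cfg, keep_missing_freq=True, keep_missing_gerp=True,
                keep_missing_fathmm=True,
            )
            off = dataclasses.replace(
                cfg, keep_missing_freq=False, keep_missing_gerp=False,
                keep_missing_fathmm=False,
            )
            assert len(run_cascade(records, off)[0]) <= len(
                run_cascade(records, on)[0]
            )

    def test_threshold_monotonicity(self, rng):
        for _ in range(self.N_TRIALS):
            records, cfg = random_table(rng), random_config(rng)
            looser = dataclasses.replace(
                cfg,
                freq_threshold_1kgp=min(1.0, cfg.freq_threshold_1kgp + 0.05),
                freq_threshold_esp=min(1.0, cfg.freq_threshold_esp + 0.05),
                gerp_min=cfg.gerp_min - 1.0,
                fathmm_max=cfg.fathmm_max + 1.0,
            )
            assert len(run_cascade(records, cfg)[0]) <= len(
                run_cascade(records, looser)[0]
            )

    def test_cascade_equals_brute_force_oracle(self, rng):
        for _ in range(self.N_TRIALS):
            records, cfg = random_table(rng), random_config(rng)
            survivors, _ = run_cascade(records, cfg)
            assert survivors == oracle_survivors(records, cfg)
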