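"""Audit orchestration, sensitivity filters, area tabulation, ROBIS tallies."""

import json
import math

import pandas as pd
import pytest

from metabias import (
    AuditConfig,
    Corpus,
    Judgment,
    MetaAnalysisRecord,
    ResearchArea,
    RobisAssessment,
    parse_robis_csv,
    robis_tabulate,
    run_audit,
    sensitivity_exclude_small,
    sensitivity_min_k,
    tabulate_by_area,
    write_report,
)
from metabias.errors import InvalidInputError
from metabias.study_data import bundled_robis_path
from metabias.synthetic_data import SyntheticConfig, generate_corpus

from conftest import make_study


@pytest.fixture
def small_corpus(five_study_meta):
    tiny = MetaAnalysisRecord(
        meta_id="single_study",
        research_area=ResearchArea.alcohol,
        exposure="wine",
        outcome="CVD mortality",
        studies=[make_study("only")],
    )
    pair = MetaAnalysisRecord(
        meta_id="two_study",
        research_area=ResearchArea.alcohol,
        exposure="beer",
        outcome="ACM",
        studies=[make_study("a", deaths=500), make_study("b", effect=1.4, lo=1.05, hi=1.9, deaths=90)],
    )
    return Corpus(metas=[five_study_meta, tiny, pair])


class TestAuditConfig:
    def test_defaults_follow_the_standard_thresholds(self):
        cfg = AuditConfig()
        assert (cfg.min_k_tests, cfg.egger_alpha, cfg.excess_alpha) == (3, 0.10, 0.10)
        assert (cfg.sensitivity_min_k, cfg.min_deaths) == (10, 200)

    @pytest.mark.parametrize("kwargs", [
        {"egger_alpha": 0.0}, {"excess_alpha": 1.0}, {"min_k_tests": 2},
        {"min_deaths": -1},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            AuditConfig(**kwargs)


class TestRunAudit:
    def test_single_meta_attempts_both_tests(self, five_study_meta):
        res = run_audit(Corpus(metas=[five_study_meta]))
        assert len(res.per_meta) == 1
        row = res.per_meta.iloc[0]
        assert row["egger_eligible"] and row["excess_eligible"]
        assert row["k"] == 5
        assert 0.0 <= row["p_value"] <= 1.0

    def test_under_two_studies_excluded_and_logged(self, small_corpus):
        res = run_audit(small_corpus)
        assert len(res.per_meta) == 2  # the k=1 meta is gone
        assert {"meta_id": "single_study", "reason": "k_lt_2", "event": "meta_excluded"} in [
            {k: e[k] for k in ("meta_id", "reason", "event")} for e in res.log
        ]
        # the k=2 meta is pooled but ineligible for both bias tests
        row = res.per_meta.set_index("meta_id").loc["two_study"]
        assert not row["egger_eligible"] and not row["excess_eligible"]
        assert row["egger_reason"] == "k_lt_min"

    def test_empty_corpus_rejected(self):
        with pytest.raises(InvalidInputError):
            run_audit(Corpus(metas=[]))

    def test_deterministic_reruns_are_byte_identical(self, small_corpus, tmp_path):
        dirs = []
        for name in ("a", "b"):
            res = run_audit(small_corpus)
            paths = write_report(res, tmp_path / name)
            dirs.append(paths)
        for key in dirs[0]:
            assert dirs[0][key].read_bytes() == dirs[1][key].read_bytes()

    def test_run_log_records_config_and_events(self, small_corpus, tmp_path):
        res = run_audit(small_corpus)
        paths = write_report(res, tmp_path, seed=7)
        log = json.loads(paths["run_log"].read_text())
        assert log["seed"] == 7
        assert log["config"]["egger_alpha"] == 0.10
        assert any(e["event"] == "meta_excluded" for e in log["events"])


class TestSensitivityFilters:
    def test_min_k_identity_at_one(self, small_corpus):
        assert [m.meta_id for m in sensitivity_min_k(small_corpus, 1)] == [
            m.meta_id for m in small_corpus
        ]

    def test_min_k_filters_and_preserves_original(self, small_corpus):
        log = []
        filtered = sensitivity_min_k(small_corpus, 5, log=log)
        assert [m.meta_id for m in filtered] == ["pa_walking_acm"]
        assert len(small_corpus) == 3  # untouched
        assert {e["meta_id"] for e in log} == {"single_study", "two_study"}

    def test_min_k_removing_everything_warns(self, small_corpus):
        with pytest.warns(UserWarning, match="removed every"):
            out = sensitivity_min_k(small_corpus, 99)
        assert len(out) == 0

    def test_exclude_small_drops_low_death_studies(self, five_study_meta):
        # death counts 800/250/150/60/1200: two studies fall below 200
        log = []
        out = sensitivity_exclude_small(Corpus(metas=[five_study_meta]), 200, log=log)
        assert out.metas[0].k == 3
        dropped = {e["study_id"] for e in log if e["event"] == "study_excluded"}
        assert dropped == {"s3", "s4"}

    def test_exclude_small_zero_threshold_is_identity(self, five_study_meta):
        out = sensitivity_exclude_small(Corpus(metas=[five_study_meta]), 0)
        assert out.metas[0].studies == five_study_meta.studies

    def test_exclude_small_keeps_missing_deaths_with_warning(self):
        meta = MetaAnalysisRecord(
            meta_id="m", research_area=ResearchArea.diet, exposure="x", outcome="y",
            studies=[make_study("a", deaths=None), make_study("b", deaths=500)],
        )
        with pytest.warns(UserWarning, match="missing death count"):
            out = sensitivity_exclude_small(Corpus(metas=[meta]), 200)
        assert out.metas[0].k == 2

    def test_exclude_small_drops_meta_falling_below_two(self):
        meta = MetaAnalysisRecord(
            meta_id="m", research_area=ResearchArea.diet, exposure="x", outcome="y",
            studies=[make_study("a", deaths=500), make_study("b", deaths=30),
                     make_study("c", deaths=10)],
        )
        log = []
        with pytest.warns(UserWarning, match="removed every"):
            out = sensitivity_exclude_small(Corpus(metas=[meta]), 200, log=log)
        assert len(out) == 0
        assert any(e["reason"] == "k_lt_2_after_exclude_small" for e in log)


class TestTabulateByArea:
    def test_fifty_percent_columns(self):
        per_meta = pd.DataFrame([
            dict(meta_id="a", research_area="diet", k=5, significant=True,
                 egger_eligible=True, egger_flag=True, excess_eligible=True,
                 o_gt_e=True, excess_flag=True),
            dict(meta_id="b", research_area="diet", k=5, significant=False,
                 egger_eligible=True, egger_flag=False, excess_eligible=True,
                 o_gt_e=False, excess_flag=False),
        ])
        table = tabulate_by_area(per_meta).set_index("research_area")
        row = table.loc["diet"]
        assert row["pct_sig"] == row["pct_egger"] == row["pct_excess"] == 50.0

    def test_overall_row_sums_area_rows(self, rng):
        corpus = generate_corpus(SyntheticConfig(seed=9, n_metas=8, p_publish_nonsig=0.3))
        res = run_audit(corpus)
        table = res.area_summary.set_index("research_area")
        areas = [a for a in table.index if a != "overall"]
        for col in ["n_total", "n_sig", "n_egger_eligible", "n_egger_flag",
                    "n_excess_eligible", "n_o_gt_e", "n_excess_flag"]:
            assert table.loc["overall", col] == table.loc[areas, col].sum()

    def test_flag_count_monotonicity_invariant(self):
        corpus = generate_corpus(SyntheticConfig(seed=13, n_metas=20, p_publish_nonsig=0.1))
        table = run_audit(corpus).area_summary
        assert (table["n_excess_flag"] <= table["n_o_gt_e"]).all()
        assert (table["n_o_gt_e"] <= table["n_excess_eligible"]).all()
        assert (table["n_egger_flag"] <= table["n_egger_eligible"]).all()

    def test_percent_cells_recompute_from_counts(self):
        corpus = generate_corpus(SyntheticConfig(seed=21, n_metas=15))
        table = run_audit(corpus).area_summary
        for _, row in table.iterrows():
            assert row["pct_sig"] == math.floor(100 * row["n_sig"] / row["n_total"] + 0.5)
            if row["n_excess_eligible"]:
                assert row["pct_excess"] == math.floor(
                    100 * row["n_excess_flag"] / row["n_excess_eligible"] + 0.5
                )

    def test_unknown_area_label_rejected(self):
        per_meta = pd.DataFrame([
            dict(meta_id="a", research_area="astrology", k=3, significant=True,
                 egger_eligible=True, egger_flag=False, excess_eligible=True,
                 o_gt_e=False, excess_flag=False),
        ])
        with pytest.raises(InvalidInputError, match="astrology"):
            tabulate_by_area(per_meta)


class TestRobisTabulate:
    def test_bundled_domain_counts(self):
        summary = robis_tabulate(parse_robis_csv(bundled_robis_path()))
        assert summary.count("d1", "low") == 32
        assert summary.count("d2", "high") == 40
        assert summary.count("d3", "high") == 28
        assert summary.count("d4", "high") == 30
        # remaining d2 split: 7 low, 2 unclear
        assert summary.count("d2", "low") == 7
        assert summary.count("d2", "unclear") == 2

    def test_counts_sum_to_reviews_per_area_and_domain(self):
        assessments = parse_robis_csv(bundled_robis_path())
        summary = robis_tabulate(assessments)
        t = summary.table
        for area in t["research_area"].unique():
            n_area = len(assessments) if area == "overall" else sum(
                1 for a in assessments if a.research_area.value == area
            )
            for domain in ["d1", "d2", "d3", "d4"]:
                cell = t[(t.research_area == area) & (t.domain == domain)]
                assert cell["count"].sum() == n_area

    def test_all_low_input_is_100_percent_low(self):
        assessments = [
            RobisAssessment(
                review_id=f"r{i}", research_area=ResearchArea.smoking,
                d1=Judgment.low, d2=Judgment.low, d3=Judgment.low, d4=Judgment.low,
                overall=Judgment.low,
            )
            for i in range(5)
        ]
        summary = robis_tabulate(assessments)
        for domain in ["d1", "d2", "d3", "d4", "overall"]:
            assert summary.percent(domain, "low") == 100.0
            assert summary.count(domain, "high") == 0

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            robis_tabulate([])


class TestWriteReport:
    def test_writes_four_documented_files(self, small_corpus, tmp_path):
        res = run_audit(small_corpus)
        summary = robis_tabulate(parse_robis_csv(bundled_robis_path()))
        paths = write_report(res, tmp_path, robis_summary=summary)
        assert sorted(p.name for p in paths.values()) == [
            "area_summary.csv", "per_meta.csv", "robis_summary.csv", "run_log.json",
        ]
        assert all(p.exists() for p in paths.values())

    def test_missing_robis_gives_header_only_csv(self, small_corpus, tmp_path):
        paths = write_report(run_audit(small_corpus), tmp_path)
        df = pd.read_csv(paths["robis_summary"])
        assert len(df) == 0 and "judgment" in df.columns
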