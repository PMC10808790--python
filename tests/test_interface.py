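"""Table ingestion/screening, pipeline orchestration, report writing, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from cuspcat.cli import main as cli_main
from cuspcat.data import StudyTable, read_table
from cuspcat.errors import SchemaError
from cuspcat.pipeline import RunConfig, comparison_text, run_pipeline, write_report
from cuspcat.synthetic import SyntheticSpec, write_csv

from conftest import TRUTH


@pytest.fixture()
def csv_with_missing(tmp_path):
    df = pd.DataFrame(
        {
            "engagement": [1.0, 2.0, None, 4.0, 5.0, 6.0, 7.0, "", 9.0, 10.0],
            "liking": np.arange(10, dtype=float),
            "disorder": np.arange(10, 20, dtype=float),
        }
    )
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    return path


class TestReadTable:
    def test_listwise_deletion_logged(self, csv_with_missing):
        tab = read_table(csv_with_missing)
        assert tab.n_raw == 10
        assert tab.n_analyzed == 8
        assert len(tab.deletion_log) == 2
        assert tab.n_analyzed == tab.n_raw - len(tab.deletion_log)

    def test_missing_role_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"engagement": [1.0], "liking": [2.0]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="disorder"):
            read_table(path)

    def test_complete_table_keeps_everything(self, tmp_path):
        path = tmp_path / "ok.tsv"
        pd.DataFrame(
            {"engagement": [1.0, 2.0], "liking": [3.0, 4.0], "disorder": [5.0, 6.0]}
        ).to_csv(path, sep="\t", index=False)
        tab = read_table(path)  # delimiter sniffed
        assert tab.n_analyzed == tab.n_raw == 2
        assert tab.deletion_log == ()

    def test_non_numeric_and_inf_treated_as_missing(self):
        df = pd.DataFrame(
            {
                "engagement": ["1.5", "oops", "2.5", np.inf],
                "liking": [1, 2, 3, 4],
                "disorder": [1, 2, 3, 4],
            }
        )
        tab = StudyTable.from_dataframe(df)
        assert tab.n_analyzed == 2

    def test_empty_after_screening_is_fatal(self):
        df = pd.DataFrame({"engagement": [None], "liking": [1.0], "disorder": [2.0]})
        with pytest.raises(SchemaError):
            StudyTable.from_dataframe(df)

    def test_constant_role_warns(self):
        df = pd.DataFrame(
            {"engagement": [1.0, 2.0], "liking": [3.0, 3.0], "disorder": [5.0, 6.0]}
        )
        with pytest.warns(UserWarning, match="constant"):
            StudyTable.from_dataframe(df)


@pytest.fixture(scope="module")
def small_report(tmp_path_factory):
    """Full pipeline on a small synthetic table with light Monte-Carlo knobs."""
    path = tmp_path_factory.mktemp("pipe") / "syn.csv"
    write_csv(SyntheticSpec(n=400, coefficients=TRUTH, seed=21), path)
    cfg = RunConfig(
        input=str(path), seed=21, n_starts=3, dip_n_mc=99, silverman_n_boot=50,
        max_modes=3, sizer=True,
    )
    return cfg, run_pipeline(cfg)


class TestPipeline:
    def test_report_sections_present(self, small_report):
        _, rep = small_report
        assert rep["screening"]["n_analyzed"] == 400
        assert "dip" in rep["modality"]
        assert len(rep["comparison"]["table"]) == 3
        assert len(rep["cusp_wald_table"]) == 6
        assert "pseudo_r2" in rep["diagnostics"]

    def test_rerun_is_deterministic(self, small_report):
        cfg, rep = small_report
        rep2 = run_pipeline(cfg)
        a, b = dict(rep), dict(rep2)
        a.pop("timings_s"), b.pop("timings_s")
        assert json.dumps(a, sort_keys=True, default=str) == json.dumps(
            b, sort_keys=True, default=str
        )

    def test_significance_policy_applied(self, small_report):
        _, rep = small_report
        for row in rep["cusp_wald_table"]:
            if np.isfinite(row["p"]):
                assert row["significant"] == (row["p"] < 0.01)

    def test_write_report_round_trip(self, small_report, tmp_path):
        _, rep = small_report
        paths = write_report(rep, tmp_path)
        loaded = json.loads(paths["report"].read_text())
        assert loaded["comparison"]["table"] == json.loads(
            json.dumps(rep["comparison"]["table"])
        )
        text = paths["comparison"].read_text()
        header = text.splitlines()[0]
        for col in ("Loglikelihood", "Parameters", "AIC", "AICc", "BIC"):
            assert col in header
        assert header.index("Loglikelihood") < header.index("AIC") < header.index("BIC")

    def test_empty_results_still_writes_valid_report(self, tmp_path):
        paths = write_report({"manifest": {"config": {}}}, tmp_path)
        assert json.loads(paths["report"].read_text())["manifest"] == {"config": {}}

    def test_comparison_text_empty(self):
        assert comparison_text({}) .startswith("Models tested")


class TestRunConfig:
    def test_from_yaml_file(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 5\nsignificance: 0.01\nn_starts: 2\n")
        cfg = RunConfig.from_file(path)
        assert cfg.seed == 5 and cfg.n_starts == 2

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("sead: 5\n")
        with pytest.raises(SchemaError, match="sead"):
            RunConfig.from_file(path)

    def test_significance_bounds(self):
        with pytest.raises(SchemaError):
            RunConfig(significance=0.6)


class TestCli:
    def test_simulate_then_fit_and_compare(self, tmp_path):
        runner = CliRunner()
        csv = tmp_path / "sim.csv"
        res = runner.invoke(
            cli_main, ["simulate", "--seed", "4", "--n", "300", "--out", str(csv)]
        )
        assert res.exit_code == 0, res.output
        assert pd.read_csv(csv).shape[0] == 300

        res = runner.invoke(cli_main, ["fit", str(csv), "--seed", "1"])
        assert res.exit_code == 0, res.output
        assert "loglik" in res.output and "w1" in res.output

        res = runner.invoke(cli_main, ["compare", str(csv), "--seed", "1"])
        assert res.exit_code == 0, res.output
        assert "cusp" in res.output and "AIC" in res.output
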