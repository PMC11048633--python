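import numpy as np
import pandas as pd
import pytest
import yaml

from wetlandnbn import (
    MetamodelDAG,
    default_dag,
    local_scenarios,
    read_dag_config,
    read_scenarios,
    read_trait_table,
    regional_scenarios,
    validate_trait_table,
)
from wetlandnbn.exceptions import (
    GraphError,
    ScenarioError,
    SchemaError,
    TableValueError,
)
from wetlandnbn.io import SCHEMA_COLUMNS, SINK


class TestTraitTable:
    def test_roundtrip_write_read(self, table16, tmp_path):
        path = tmp_path / "traits.csv"
        table16.write_csv(path)
        back = read_trait_table(path)
        assert back.n_wetlands == 16
        pd.testing.assert_frame_equal(back.data, table16.data)

    def test_missing_column_named_in_error(self, table16):
        broken = table16.data.drop(columns=["water_salinity"])
        with pytest.raises(SchemaError, match="water_salinity"):
            validate_trait_table(broken)

    def test_out_of_range_ordinal_cites_row(self, table16):
        df = table16.data.copy()
        df.loc[4, "tourism_pressure"] = 4
        wid = df.loc[4, "wetland_id"]
        with pytest.raises(TableValueError, match=wid):
            validate_trait_table(df)

    def test_too_few_rows(self, table16):
        with pytest.raises(SchemaError, match="at least 3"):
            validate_trait_table(table16.data.head(2))

    def test_duplicate_ids(self, table16):
        df = table16.data.copy()
        df.loc[1, "wetland_id"] = df.loc[0, "wetland_id"]
        with pytest.raises(SchemaError, match="duplicate"):
            validate_trait_table(df)

    def test_missing_value_rejected(self, table16):
        df = table16.data.copy()
        df.loc[2, "mean_water_level"] = np.nan
        with pytest.raises(TableValueError, match="missing"):
            validate_trait_table(df)

    def test_validation_idempotent(self, table16):
        once = validate_trait_table(table16.data)
        twice = validate_trait_table(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_canonical_column_order(self, table16):
        shuffled = table16.data[list(reversed(SCHEMA_COLUMNS))]
        assert tuple(validate_trait_table(shuffled).columns) == SCHEMA_COLUMNS


class TestMetamodelDAG:
    def test_default_dag_direct_parents_of_sink(self):
        dag = default_dag()
        direct = {p for p, c, _ in dag.arcs if c == SINK}
        assert direct == {
            "anthropization",
            "mean_water_level",
            "tourism_pressure",
            "water_discharges",
            "water_level_fluctuations",
            "water_salinity",
            "isolation",
            "size",
        }
        # the two traits acting only indirectly
        assert "distance_to_coastline" not in direct
        assert "water_diversions" not in direct

    def test_sink_outgoing_arc_rejected(self):
        with pytest.raises(GraphError, match="outgoing"):
            MetamodelDAG(nodes=["x", SINK], arcs=[(SINK, "x", "+")])

    def test_cycle_reported(self):
        with pytest.raises(GraphError, match="cycle"):
            MetamodelDAG(
                nodes=["a", "b", SINK],
                arcs=[("a", "b", "+"), ("b", "a", "+"), ("a", SINK, "+")],
            )

    def test_unknown_arc_endpoint(self):
        with pytest.raises(SchemaError, match="ghost"):
            MetamodelDAG(nodes=["x", SINK], arcs=[("ghost", SINK, "+")])

    def test_two_node_config(self, tmp_path):
        path = tmp_path / "dag.yaml"
        path.write_text(
            yaml.safe_dump({"nodes": ["x", SINK], "arcs": [["x", SINK, "+"]]})
        )
        dag = read_dag_config(path)
        assert len(dag.arcs) == 1 and dag.sink == SINK

    def test_parents_in_arc_order(self):
        dag = default_dag()
        parents = dag.parents("mean_water_level")
        assert parents == ["water_discharges", "water_diversions"]


class TestScenarios:
    def test_regional_fixture(self):
        specs = regional_scenarios()
        assert [s.id for s in specs] == [f"S_{k}" for k in range(21)]
        assert specs[0].evidence == {}
        assert specs[6].evidence == {"water_level_fluctuations": 0.0}
        assert specs[13].evidence == {"water_level_fluctuations": 30.0}
        # the worst possible scenario combines all six deteriorations
        assert len(specs[7].evidence) == 6

    def test_local_fixture_baseline(self):
        specs = local_scenarios()
        assert len(specs) == 31
        base = {
            "water_level_fluctuations": 6.8,
            "water_salinity": 0.0,
            "water_diversions": 2.0,
            "water_discharges": 2.0,
            "tourism_pressure": 1.0,
        }
        assert all(s.baseline == base for s in specs)
        assert specs[0].evidence == {}

    def test_local_fixture_overrides_echo(self):
        by_id = {s.id: s for s in local_scenarios()}
        assert by_id["S_26"].evidence == {"water_level_fluctuations": 0.0}
        assert by_id["S_29"].evidence == {"water_salinity": 3.0, "water_diversions": 3.0}
        assert by_id["S_33"].evidence == {
            "water_level_fluctuations": 0.0,
            "water_salinity": 3.0,
            "water_diversions": 3.0,
            "water_discharges": 0.0,
            "tourism_pressure": 3.0,
        }
        # overrides merge on top of the wetland baseline
        full = by_id["S_26"].full_evidence()
        assert full["water_level_fluctuations"] == 0.0
        assert full["water_diversions"] == 2.0

    def test_empty_scenario_file(self, tmp_path, caplog):
        path = tmp_path / "empty.yaml"
        path.write_text("scenarios: []\n")
        with caplog.at_level("WARNING"):
            assert read_scenarios(path) == []
        assert "no scenarios" in caplog.text

    def test_evidence_on_sink_rejected(self):
        from wetlandnbn import ScenarioSpec

        spec = ScenarioSpec(id="bad", scope="regional", evidence={SINK: 5})
        with pytest.raises(ScenarioError):
            spec.validate_against(default_dag())

    def test_evidence_on_unknown_variable_rejected(self):
        from wetlandnbn import ScenarioSpec

        spec = ScenarioSpec(id="bad", scope="regional", evidence={"bogus": 1})
        with pytest.raises(SchemaError, match="bogus"):
            spec.validate_against(default_dag())
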