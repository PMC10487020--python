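"""Conversion engine: gating, self-conversion, fan-out, chaining, cut-off
tables and bundle round trips."""

import json
from dataclasses import replace

import numpy as np
import pytest

from insulinconv.engine import (CutoffRecord, ModelStore, convert, convert_all,
                                convert_chained, convert_cutoff_table,
                                export_bundle, import_bundle, read_cutoff_csv,
                                round_sig, write_cutoff_csv)
from insulinconv.exceptions import (BundleError, ChainingError,
                                    PairUnavailableError, RangeError,
                                    ValidationError)


class TestConvert:
    @pytest.mark.parametrize("value", [9.5, 10.4, 0.0, 123.45])
    def test_self_conversion_is_identity_with_zero_width_interval(self, value,
                                                                  doubling_store):
        res = convert(value, "G", "G", doubling_store)
        assert res.estimate == value
        assert res.pi_lower == value and res.pi_upper == value

    def test_known_doubling_truth(self, doubling_store):
        """Models trained on y = 2x with low noise: converting 50 lands near
        100 and the 95% interval contains it."""
        res = convert(50.0, "C", "G", doubling_store)
        assert res.pi_lower <= 100.0 <= res.pi_upper
        assert res.estimate == pytest.approx(100.0, abs=2.0)

    def test_missing_pair_is_distinct_from_range_error(self, doubling_store):
        with pytest.raises(PairUnavailableError):
            convert(10.0, "C", "H", doubling_store)
        model = doubling_store.get("C", "G")
        with pytest.raises(RangeError) as exc_info:
            convert(model.input_cap + 1000.0, "C", "G", doubling_store)
        assert f"{model.input_cap:g}" in str(exc_info.value)

    def test_cap_boundary_probes(self, full_store):
        """Querying exactly at the cap succeeds; a hair above it is refused.
        The cap equals the largest training input minus one."""
        store = full_store["store"]
        for model in store.models():
            ok = convert(model.input_cap, model.from_assay, model.to_assay, store)
            assert ok.estimate >= 0.0
            eps = 1e-9 * max(1.0, abs(model.input_cap))
            with pytest.raises(RangeError):
                convert(model.input_cap + eps, model.from_assay, model.to_assay, store)
            if model.input_min > 0:
                with pytest.raises(RangeError):
                    convert(model.input_min * (1 - 1e-9), model.from_assay,
                            model.to_assay, store)

    def test_invalid_values_rejected(self, doubling_store):
        with pytest.raises(ValidationError):
            convert(float("nan"), "C", "G", doubling_store)
        with pytest.raises(ValidationError):
            convert(-5.0, "C", "G", doubling_store)
        with pytest.raises(ValidationError):
            convert(50.0, "C", "G", doubling_store, level=1.5)

    def test_round_trip_bounded_by_interval_half_width(self, doubling_store):
        """Back-conversion C->G->C is not exact, but the deviation stays below
        the C->G interval half-width at every probed point."""
        fwd = doubling_store.get("C", "G")
        rev = doubling_store.get("G", "C")
        grid = np.linspace(fwd.input_min, fwd.input_cap, 40)
        for v in grid:
            est, lo, hi = fwd.predict_with_interval(float(v))
            if not rev.in_range(est):
                continue
            back = rev.predict(est)
            assert abs(back - v) < (hi - lo) / 2.0


class TestConvertAll:
    def test_fan_out_returns_only_direct_models_in_range(self, chain_store):
        results, unavailable = convert_all(50.0, "G", chain_store)
        assert [r.to_assay for r in results] == ["C"]

    def test_all_out_of_range_yields_reasons(self, doubling_store):
        model = doubling_store.get("C", "G")
        too_low = model.input_min / 2.0
        results, unavailable = convert_all(too_low, "C", doubling_store)
        assert results == []
        assert "out of supported range" in unavailable["G"]

    def test_fan_out_intervals_contain_estimates(self, full_store):
        store = full_store["store"]
        for value in (15.0, 30.0, 60.0):
            results, _ = convert_all(value, "G", store)
            assert results, f"no direct conversions from G admitted {value}"
            for r in results:
                assert r.pi_lower <= r.estimate <= r.pi_upper

    def test_fan_out_is_monotone_in_the_input(self, full_store):
        store = full_store["store"]
        res1, _ = convert_all(20.0, "G", store)
        res2, _ = convert_all(40.0, "G", store)
        est1 = {r.to_assay: r.estimate for r in res1}
        est2 = {r.to_assay: r.estimate for r in res2}
        common = set(est1) & set(est2)
        assert common
        for assay in common:
            assert est1[assay] <= est2[assay]


class TestConvertChained:
    def test_two_hop_identity_chain(self, chain_store):
        res = convert_chained(50.0, "H", "C", chain_store)
        assert res.chained is True
        assert res.hops == ("H", "G", "C")
        assert res.estimate == pytest.approx(50.0, abs=3.0)
        assert res.pi_lower <= res.estimate <= res.pi_upper

    def test_refuses_when_direct_model_exists(self, chain_store):
        with pytest.raises(ChainingError, match="direct model"):
            convert_chained(50.0, "H", "G", chain_store)

    def test_no_path_raises(self, chain_store):
        with pytest.raises(ChainingError):
            convert_chained(50.0, "C", "H", chain_store)  # edges are directed

    def test_out_of_range_hop_names_the_hop(self, chain_store):
        with pytest.raises(ChainingError, match="H->G"):
            convert_chained(0.5, "H", "C", chain_store)


class TestCutoffTable:
    def test_reference_rows_pass_through(self, doubling_store):
        records = [CutoffRecord("Lindase et al., 2021", "G", cutoff=9.5),
                   CutoffRecord("de Laat et al., 2022", "G", cutoff=10.4)]
        out = convert_cutoff_table(records, "G", doubling_store)
        assert [r.converted_cutoff for r in out] == [9.5, 10.4]
        assert all(r.convertible for r in out)

    def test_doubling_truth_converts_cutoff(self, doubling_store):
        (rec,) = convert_cutoff_table([CutoffRecord("fixture", "C", cutoff=10.0)],
                                      "G", doubling_store)
        assert rec.convertible
        assert rec.converted_cutoff == pytest.approx(20.0, abs=1.5)

    def test_unconvertible_records_annotated_and_order_preserved(self, doubling_store):
        records = [CutoffRecord("a", "H", cutoff=5.0),
                   CutoffRecord("b", "G", cutoff=9.5)]
        out = convert_cutoff_table(records, "G", doubling_store)
        assert [r.reference for r in out] == ["a", "b"]
        assert out[0].convertible is False and "pair unavailable" in out[0].note
        assert out[1].convertible is True

    def test_packaged_cutoff_table_loads(self):
        from importlib.resources import files
        path = files("insulinconv") / "data" / "cutoffs_basal_insulin.csv"
        records = read_cutoff_csv(str(path))
        assert len(records) == 9
        byref = {(r.reference, r.assay_id): r.cutoff for r in records}
        assert byref[("Lindase et al., 2021", "G")] == 9.5
        assert byref[("de Laat et al., 2022", "G")] == 10.4

    def test_cutoff_csv_round_trip(self, tmp_path, doubling_store):
        records = [CutoffRecord("a", "C", feeding="Fasted", outcome="EHC",
                                metric="Youden's index", cutoff=10.0)]
        out = convert_cutoff_table(records, "G", doubling_store)
        path = tmp_path / "converted.csv"
        write_cutoff_csv(out, path, sig_figs=2)
        text = path.read_text()
        assert "converted_cutoff" in text and "convertible" in text

    def test_round_sig_matches_two_figure_presentation(self):
        assert round_sig(21.755, 2) == 22.0
        assert round_sig(48.6, 2) == 49.0
        assert round_sig(9.5, 2) == 9.5
        assert round_sig(0.0, 2) == 0.0


class TestBundle:
    def test_round_trip_is_lossless(self, full_store, tmp_path):
        store = full_store["store"]
        path = tmp_path / "bundle.json"
        export_bundle(store, path)
        loaded = import_bundle(path)
        assert len(loaded) == len(store)
        rng = np.random.default_rng(1)
        for model in store.models():
            twin = loaded.get(model.from_assay, model.to_assay)
            xq = rng.uniform(model.input_min, model.input_cap, 20)
            e1, l1, h1 = model.predict_with_interval(xq)
            e2, l2, h2 = twin.predict_with_interval(xq)
            assert np.max(np.abs(e1 - e2)) == 0.0
            assert np.max(np.abs(l1 - l2)) == 0.0
            assert np.max(np.abs(h1 - h2)) == 0.0

    def test_missing_field_named_in_error(self, doubling_store, tmp_path):
        bundle = export_bundle(doubling_store)
        del bundle["models"][0]["sigma"]
        with pytest.raises(BundleError, match="sigma"):
            import_bundle(bundle)

    def test_version_mismatch_rejected(self, doubling_store):
        bundle = export_bundle(doubling_store)
        bundle["version"] = 99
        with pytest.raises(BundleError, match="version"):
            import_bundle(bundle)
        bundle = export_bundle(doubling_store)
        bundle["format"] = "something-else"
        with pytest.raises(BundleError, match="format"):
            import_bundle(bundle)

    def test_bundle_is_self_contained_json(self, doubling_store, tmp_path):
        path = tmp_path / "b.json"
        export_bundle(doubling_store, path)
        raw = json.loads(path.read_text())
        assert raw["format"] == "insulinconv-bundle"
        for m in raw["models"]:
            assert {"intercept", "coefficients", "sigma", "dof", "gram_inverse",
                    "input_min", "input_cap", "n_train", "r_squared"} <= set(m)


class TestModelStore:
    def test_store_rejects_self_mapping(self, doubling_store):
        model = replace(doubling_store.get("C", "G"), to_assay="C")
        with pytest.raises(ValidationError):
            ModelStore([model])

    def test_targets_and_assays(self, chain_store):
        assert chain_store.assays() == ["C", "G", "H"]
        assert chain_store.targets_from("H") == ["G"]
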