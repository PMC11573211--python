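"""LOD computation and the SOMAmer/sample filter battery."""

import numpy as np
import pandas as pd
import pytest

from sfsomaqc.filters import (
    FilterError,
    apply_filters,
    compute_lod,
    filter_samples_flagged,
    filter_samples_lod,
    filter_samples_pca,
    filter_samples_total_rfu,
    filter_somamers_confounder,
    filter_somamers_control,
    filter_somamers_r2,
)
from conftest import make_dataset


def blank_dataset(blank_values, n_extra=1):
    """One plate with three blanks holding *blank_values* per SOMAmer."""
    rows = [np.asarray(v, dtype=float) for v in blank_values]
    p = len(rows[0])
    rows += [np.full(p, 1000.0)] * n_extra
    roles = ["blank"] * len(blank_values) + ["study"] * n_extra
    return make_dataset(np.array(rows), roles=roles, scale_state="standardised")


class TestLod:
    def test_worked_example_with_unscaled_mad(self):
        # blanks {100,110,120}: median 110, MAD 10 -> lower = 110 + 49 = 159
        ds = blank_dataset([[100.0], [110.0], [120.0]])
        lod = compute_lod(ds)
        assert lod.lower.loc["P1", "SL001"] == pytest.approx(159.0)
        assert lod.upper == 80000.0

    def test_identical_blanks(self):
        ds = blank_dataset([[50.0], [50.0], [50.0]])
        assert compute_lod(ds).lower.loc["P1", "SL001"] == pytest.approx(50.0)

    def test_location_equivariance(self):
        base = blank_dataset([[100.0, 80.0], [110.0, 90.0], [120.0, 85.0]])
        shifted = base.copy()
        shifted.rfu += 37.0
        lo0 = compute_lod(base).lower
        lo1 = compute_lod(shifted).lower
        np.testing.assert_allclose(lo1.to_numpy(), lo0.to_numpy() + 37.0)

    def test_fewer_than_three_blanks_names_plate(self):
        ds = blank_dataset([[100.0], [110.0]])
        with pytest.raises(FilterError, match="P1"):
            compute_lod(ds)


class TestSampleFilters:
    def _lod_fixture(self, fracs):
        """Study samples whose given fraction of values sits below the floor."""
        p = 100
        blanks = [np.full(p, 50.0)] * 3       # lower LOD = 50 exactly
        rows = list(blanks)
        for f in fracs:
            v = np.full(p, 1000.0)
            v[: int(round(f * p))] = 10.0
            rows.append(v)
        roles = ["blank"] * 3 + ["study"] * len(fracs)
        return make_dataset(np.array(rows), roles=roles, scale_state="standardised")

    def test_boundary_is_strict(self):
        ds = self._lod_fixture([0.30, 0.25, 0.10])
        removed = filter_samples_lod(ds, compute_lod(ds))
        assert removed == {"S004"}          # 30% out; exactly 25% retained

    def test_total_rfu_outlier_removed(self):
        rng = np.random.default_rng(0)
        y = rng.normal(1000, 10, (40, 20))
        y[7] *= 11.0                        # huge total
        ds = make_dataset(y, scale_state="standardised")
        assert filter_samples_total_rfu(ds) == {"S008"}

    def test_identical_totals_none_removed(self):
        ds = make_dataset(np.full((10, 5), 100.0), scale_state="standardised")
        assert filter_samples_total_rfu(ds) == set()

    def test_pca_planted_outlier_removed(self):
        rng = np.random.default_rng(1)
        y = rng.normal(8, 0.5, (200, 30))
        direction = rng.normal(0, 1, 30)
        y[13] += 10 * 0.5 * direction / np.linalg.norm(direction) * np.sqrt(200 / 10)
        ds = make_dataset(y, scale_state="log")
        removed = filter_samples_pca(ds)
        assert "S014" in removed and len(removed) <= 2

    def test_pca_gaussian_null_rarely_removes(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ds = make_dataset(rng.normal(8, 1, (500, 8)), scale_state="log")
            hits += len(filter_samples_pca(ds))
        assert hits <= 1

    def test_vendor_flag_roles(self):
        rng = np.random.default_rng(2)
        y = rng.normal(1000, 10, (6, 4))
        ds = make_dataset(y, roles=["study"] * 4 + ["calibrator", "blank"],
                          vendor_flags=[False, True, True, False, True, True])
        assert filter_samples_flagged(ds) == {"S002", "S003"}

    def test_no_flags_empty(self):
        ds = make_dataset(np.ones((4, 3)), vendor_flags=[False] * 4)
        assert filter_samples_flagged(ds) == set()


class TestSomamerFilters:
    def test_control_and_nonhuman_removed(self):
        types = ["protein", "spuriomer", "protein", "deprecated", "hyb_control_elution"]
        orgs = ["human", "human", "mouse", "human", "human"]
        ds = make_dataset(np.ones((3, 5)), somamer_types=types, organisms=orgs)
        assert filter_somamers_control(ds) == {"SL002", "SL003", "SL004", "SL005"}

    def test_planted_control_set_exact(self, battery):
        _, dataset, truth = battery
        assert filter_somamers_control(dataset) == set(truth.control_somamers)

    def test_confounder_power_and_null(self):
        rng = np.random.default_rng(3)
        n, p = 600, 400
        age = rng.uniform(0, 10, n)
        y = rng.normal(8, 0.2, (n, p))
        y[:, :50] += 0.06 * age[:, None]     # 3x the noise sd over the age range
        ds = make_dataset(y, scale_state="log")
        conf = pd.DataFrame({"age": age})
        removed = filter_somamers_confounder(ds, conf)
        planted = {f"SL{j + 1:03d}" for j in range(50)}
        assert len(removed & planted) >= 48
        assert len(removed - planted) <= 2

    def test_constant_confounder_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(8, 1, (20, 3)),
                          scale_state="log")
        with pytest.raises(FilterError, match="constant"):
            filter_somamers_confounder(ds, pd.DataFrame({"x": np.ones(20)}))

    def test_sparse_confounder_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(8, 1, (20, 3)),
                          scale_state="log")
        x = np.full(20, np.nan)
        x[:5] = [1, 2, 3, 4, 5]
        with pytest.raises(FilterError, match="non-missing"):
            filter_somamers_confounder(ds, pd.DataFrame({"x": x}))

    @pytest.mark.parametrize("oa,injury,expected", [
        (0.6, 0.4, True),       # low in either group removes
        (0.55, 0.55, False),
        (0.5, 0.5, False),      # boundary is strict
        (0.45, 0.9, True),
    ])
    def test_r2_rule_boundaries(self, oa, injury, expected):
        r2o = pd.Series({"X": oa}); r2i = pd.Series({"X": injury})
        removed = filter_somamers_r2(r2o, r2i)
        assert ("X" in removed) is expected

    def test_r2_tables_must_align(self):
        with pytest.raises(FilterError, match="missing"):
            filter_somamers_r2(pd.Series({"A": 0.9}), pd.Series({"B": 0.9}))


class TestApplyFilters:
    def test_battery_recovers_planted_sets(self, battery, battery_run):
        _, _, truth = battery
        report = battery_run.reports["without_ips"]
        planted = {
            "control_somamers": set(truth.control_somamers),
            "confounder_somamers": set(truth.age_somamers) | set(truth.ft_somamers),
            "low_r2_somamers": set(truth.low_r2_somamers),
            "vendor_flagged_samples": set(truth.bad_samples["vendor_flag"]),
            "lod_samples": set(truth.bad_samples["lod"]),
            "total_rfu_samples": set(truth.bad_samples["total_rfu"]),
            "pca_outlier_samples": set(truth.bad_samples["pca"]),
        }
        for name, want in planted.items():
            got = report.removed(name)
            tp = len(got & want)
            sens = tp / len(want)
            pop = (len(battery_run.corrected.seq_ids)
                   if name.endswith("somamers") else
                   len(battery_run.corrected.sample_ids))
            spec_ = 1 - len(got - want) / (pop - len(want))
            assert sens >= 0.95, f"{name}: sensitivity {sens:.2f}"
            assert spec_ >= 0.95, f"{name}: specificity {spec_:.2f}"

    def test_report_bookkeeping_identity(self, battery_run):
        report = battery_run.reports["without_ips"]
        n_samples = len(battery_run.corrected.sample_ids)
        n_somamers = len(battery_run.corrected.seq_ids)
        for entry in report.entries:
            if entry["filter"].endswith("somamers"):
                n_somamers -= entry["n_removed"]
            else:
                n_samples -= entry["n_removed"]
            assert entry["surviving_somamers"] == n_somamers
            assert entry["surviving_samples"] == n_samples

    def test_reapplication_removes_nothing(self, battery_run):
        filtered = battery_run.datasets["without_ips"]
        lin = battery_run.standardised
        lin_sub = lin.subset(seq_ids=list(filtered.seq_ids))
        again, report = apply_filters(filtered, lin_sub)
        removed = {e["filter"]: e["n_removed"] for e in report.entries}
        # sample filters are exactly closed; the R² somamer filter is
        # estimate-based and may drift by a reagent or two once the bad
        # samples are gone from its variance denominators
        assert all(v == 0 for k, v in removed.items() if k.endswith("samples")), removed
        assert removed["control_somamers"] == 0
        assert removed["confounder_somamers"] <= 1
        assert removed["low_r2_somamers"] <= 2

    def test_misaligned_inputs_rejected(self, battery_run):
        filtered = battery_run.datasets["without_ips"]
        with pytest.raises(FilterError, match="SOMAmers"):
            apply_filters(filtered, battery_run.standardised)
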