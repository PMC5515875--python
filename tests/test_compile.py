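"""Status semantics (measured/occluded/absent), replicate accounting, root-6 rule."""

from __future__ import annotations

import numpy as np
import pytest
from conftest import make_table

from rootplates import compile as cmod
from rootplates.errors import ConsistencyError
from rootplates.smartroot_io import CORE_STRUCTURES


def small_condition(day1_overrides=None, day2_overrides=None):
    """Three seedlings on one plate; roots 1-2 + shoot + (day2) root 4.

    ``overrides`` replace the default row list for that day.
    """
    def rows(day, lengths):
        out = []
        for s in (1, 2, 3):
            for struct, L in lengths.items():
                tok = "sht" if struct == "shoot" else f"rt{struct[-1]}"
                out.append((f"seed{s}{tok}", L + s * 0.1, 1))
        return out

    day0 = make_table("WW", 0, rows(0, {"shoot": 9, "root1": 10, "root2": 8}))
    day1_rows = rows(1, {"shoot": 16, "root1": 25, "root2": 21})
    day2_rows = rows(2, {"shoot": 23, "root1": 37, "root2": 31}) + [
        (f"seed{s}rt4", 4.0 + s * 0.1, 1) for s in (1, 2, 3)
    ]
    day1 = make_table("WW", 1, day1_overrides if day1_overrides is not None else day1_rows)
    day2 = make_table("WW", 2, day2_overrides if day2_overrides is not None else day2_rows)
    return cmod.compile_condition(day0, day1, day2)


class TestStatusAssignment:
    def test_missing_core_root_on_day1_is_occluded(self):
        cc = small_condition(
            day1_overrides=[
                ("seed1sht", 16.1, 1), ("seed1rt1", 25.1, 1),  # seed1 root2 skipped
                ("seed2sht", 16.2, 1), ("seed2rt1", 25.2, 1), ("seed2rt2", 21.2, 1),
                ("seed3sht", 16.3, 1), ("seed3rt1", 25.3, 1), ("seed3rt2", 21.3, 1),
            ]
        )
        row = cc.data.query("seedling_index == 1 and structure == 'root2' and day == 1")
        assert row["status"].item() == "occluded"
        assert np.isnan(row["length_mm"].item())

    def test_missing_late_root_is_absent_zero(self):
        cc = small_condition()
        rows = cc.data.query("structure == 'root4' and day in (0, 1)")
        assert (rows["status"] == "absent").all()
        assert (rows["length_mm"] == 0.0).all()

    def test_na_label_is_occluded_not_zero(self):
        cc = small_condition(
            day2_overrides=[
                (f"seed{s}{tok}", L, 1)
                for s in (1, 2, 3)
                for tok, L in (("sht", 23.0), ("rt1", 37.0), ("rt2", 31.0))
            ]
            + [("seed1r4_NA", 2.0, 1), ("seed2rt4", 4.0, 1), ("seed3rt4", 5.0, 1)]
        )
        row = cc.data.query("seedling_index == 1 and structure == 'root4' and day == 2")
        assert row["status"].item() == "occluded"
        assert row["reason"].item() == "na_label"

    def test_wholly_missing_seedling_marks_all_structures_occluded(self):
        cc = small_condition(
            day1_overrides=[
                ("seed2sht", 16.2, 1), ("seed2rt1", 25.2, 1), ("seed2rt2", 21.2, 1),
                ("seed3sht", 16.3, 1), ("seed3rt1", 25.3, 1), ("seed3rt2", 21.3, 1),
            ]
        )
        rows = cc.data.query("seedling_index == 1 and day == 1")
        assert (rows["status"] == "occluded").all()  # incl. root4: photo is missing, not the root
        assert set(rows["reason"]) == {"seedling_missing"}

    def test_emerged_root_cannot_become_absent(self):
        with pytest.raises(ConsistencyError, match="root4"):
            small_condition(
                day1_overrides=[
                    ("seed1sht", 16.1, 1), ("seed1rt1", 25.1, 1), ("seed1rt2", 21.1, 1),
                    ("seed1rt4", 1.5, 1),  # measured on day 1 ...
                    ("seed2sht", 16.2, 1), ("seed2rt1", 25.2, 1), ("seed2rt2", 21.2, 1),
                    ("seed3sht", 16.3, 1), ("seed3rt1", 25.3, 1), ("seed3rt2", 21.3, 1),
                ],
                day2_overrides=[  # ... but no record at all on day 2
                    (f"seed{s}{tok}", L, 1)
                    for s in (1, 2, 3)
                    for tok, L in (("sht", 23.0), ("rt1", 37.0), ("rt2", 31.0))
                ],
            )

    def test_unknown_seedling_index_rejected(self):
        day0 = make_table("WW", 0, [("seed1rt1", 10.0, 1)])
        day1 = make_table("WW", 1, [("seed1rt1", 20.0, 1), ("seed9rt1", 5.0, 1)])
        day2 = make_table("WW", 2, [("seed1rt1", 30.0, 1)])
        with pytest.raises(ConsistencyError, match="9"):
            cmod.compile_condition(day0, day1, day2)


class TestMeansAndAccounting:
    def test_mixed_status_cell_mean(self):
        """{2.0 measured, absent, occluded} → mean (2.0+0)/2 = 1.0 with n=2."""
        cc = small_condition(
            day1_overrides=[
                ("seed1sht", 16.1, 1), ("seed1rt1", 25.1, 1), ("seed1rt2", 21.1, 1),
                ("seed1rt4", 2.0, 1),
                ("seed2sht", 16.2, 1), ("seed2rt1", 25.2, 1), ("seed2rt2", 21.2, 1),
                ("seed3sht", 16.3, 1), ("seed3rt1", 25.3, 1), ("seed3rt2", 21.3, 1),
                ("seed3r4_NA", 0.5, 1),
            ]
        )
        mean, n = cmod.structure_mean(cc, "root4", 1)
        assert (mean, n) == (1.0, 2)

    def test_all_occluded_cell_reports_missing_not_zero(self):
        cc = small_condition(day1_overrides=[])  # nobody photographed on day 1
        mean, n = cmod.structure_mean(cc, "root1", 1)
        assert n == 0 and np.isnan(mean)

    def test_means_match_brute_force_oracle_on_simulation(self, default_experiment):
        """Direct enumeration over raw records reproduces structure_mean exactly."""
        tables = default_experiment["tables"]["WW"]
        cc = default_experiment["ww"]
        day_records = {d: list(tables[d]) for d in (0, 1, 2)}
        seedlings = sorted({r.label.seedling_index for r in day_records[0]})
        for structure in cc.structures:
            for day in (0, 1, 2):
                values = []
                present_seedlings = {r.label.seedling_index for r in day_records[day]}
                recs = {
                    (r.label.seedling_index, r.label.structure): r
                    for r in day_records[day]
                }
                for s in seedlings:
                    rec = recs.get((s, structure))
                    if rec is not None and rec.label.measurable:
                        values.append(rec.length_mm)
                    elif rec is not None:
                        continue  # _NA: excluded
                    elif s not in present_seedlings:
                        continue  # missing photo: occluded
                    elif structure not in CORE_STRUCTURES:
                        values.append(0.0)  # late root not emerged
                mean, n = cmod.structure_mean(cc, structure, day)
                assert n == len(values)
                if n:
                    assert mean == pytest.approx(float(np.mean(values)), abs=0)
                else:
                    assert np.isnan(mean)

    def test_n_accounting_sums_to_seedlings(self, default_experiment):
        cc = default_experiment["ww"]
        counts = cc.data.groupby(["structure", "day"])["status"].count()
        assert (counts == len(cc.seedlings)).all()

    def test_occlusion_locality(self):
        """Occluding one structure of one seedling changes no other cell's n."""
        base = small_condition()
        day1_full = [
            ("seed1sht", 16.1, 1), ("seed1rt1", 25.1, 1), ("seed1rt2", 21.1, 1),
            ("seed2sht", 16.2, 1), ("seed2rt1", 25.2, 1), ("seed2rt2", 21.2, 1),
            ("seed3sht", 16.3, 1), ("seed3rt1", 25.3, 1), ("seed3rt2", 21.3, 1),
        ]
        mutated = small_condition(
            day1_overrides=[r for r in day1_full if r[0] != "seed2rt1"]
        )
        for structure in base.structures:
            for day in (0, 1, 2):
                _, n_base = cmod.structure_mean(base, structure, day)
                _, n_mut = cmod.structure_mean(mutated, structure, day)
                if (structure, day) == ("root1", 1):
                    assert n_mut == n_base - 1
                else:
                    assert n_mut == n_base


class TestRoot6Rule:
    def _with_root6(self, k):
        """k of 8 seedlings show a sixth root on day 2."""
        seedlings = range(1, 9)
        def rows(day, base):
            return [(f"seed{s}rt1", base + s * 0.1, 1) for s in seedlings] + [
                (f"seed{s}sht", base / 2 + s * 0.1, 1) for s in seedlings
            ]
        day2 = rows(2, 30.0) + [(f"seed{s}rt6", 1.0, 1) for s in range(1, k + 1)]
        return cmod.compile_condition(
            make_table("WW", 0, rows(0, 10.0)),
            make_table("WW", 1, rows(1, 20.0)),
            make_table("WW", 2, day2),
        )

    def test_threshold_is_strict(self):
        assert cmod.root6_included(self._with_root6(3)) is False  # 3 of n: excluded
        assert cmod.root6_included(self._with_root6(4)) is True  # 4 of n: included

    def test_threshold_zero_includes_single_sixth_root(self):
        assert cmod.root6_included(self._with_root6(1), threshold=0) is True

    def test_no_sixth_root_anywhere(self):
        assert cmod.root6_included(self._with_root6(0)) is False
        assert cmod.root6_count(self._with_root6(2)) == 2


class TestGrowthIncrements:
    def test_single_seedling_increments(self):
        day0 = make_table("WW", 0, [("seed1rt1", 10.0, 1)])
        day1 = make_table("WW", 1, [("seed1rt1", 25.0, 1)])
        day2 = make_table("WW", 2, [("seed1rt1", 41.0, 1)])
        segs = cmod.growth_increments(cmod.compile_condition(day0, day1, day2)).data
        r1 = segs[segs["structure"] == "root1"].set_index("interval")
        assert r1.loc["day0-1", "mean_change_mm"] == pytest.approx(15.0)
        assert r1.loc["day1-2", "mean_change_mm"] == pytest.approx(16.0)

    def test_occluded_endpoint_excluded_from_that_interval_only(self):
        day0 = make_table("WW", 0, [("seed1rt1", 10.0, 1), ("seed2rt1", 10.0, 1)])
        day1 = make_table("WW", 1, [("seed1rt1", 25.0, 1)])  # seed2 occluded
        day2 = make_table("WW", 2, [("seed1rt1", 41.0, 1), ("seed2rt1", 40.0, 1)])
        segs = cmod.growth_increments(cmod.compile_condition(day0, day1, day2)).data
        r1 = segs[segs["structure"] == "root1"].set_index("interval")
        assert r1.loc["day0-1", "n"] == 1 and r1.loc["day1-2", "n"] == 1
        assert r1.loc["day0-1", "mean_change_mm"] == pytest.approx(15.0)

    def test_static_lengths_give_zero_increments(self):
        day0 = make_table("WW", 0, [("seed1rt1", 10.0, 1), ("seed1sht", 5.0, 1)])
        day1 = make_table("WW", 1, [("seed1rt1", 10.0, 1), ("seed1sht", 5.0, 1)])
        day2 = make_table("WW", 2, [("seed1rt1", 10.0, 1), ("seed1sht", 5.0, 1)])
        segs = cmod.growth_increments(cmod.compile_condition(day0, day1, day2)).data
        core = segs[segs["structure"].isin(["root1", "shoot"])]
        assert (core["mean_change_mm"] == 0.0).all()

    def test_negative_increment_kept_with_warning(self):
        day0 = make_table("WW", 0, [("seed1rt1", 10.0, 1)])
        day1 = make_table("WW", 1, [("seed1rt1", 9.0, 1)])
        day2 = make_table("WW", 2, [("seed1rt1", 12.0, 1)])
        with pytest.warns(UserWarning):
            cc = cmod.compile_condition(day0, day1, day2)
        with pytest.warns(UserWarning):
            segs = cmod.growth_increments(cc).data
        r1 = segs[(segs["structure"] == "root1") & (segs["interval"] == "day0-1")]
        assert r1["mean_change_mm"].item() == pytest.approx(-1.0)


def test_compiled_csv_round_trip(tmp_path, default_experiment):
    cc = default_experiment["ww"]
    path = cc.to_csv(tmp_path / "compiled WW.csv")
    back = cmod.read_compiled(path)
    assert back.condition == cc.condition
    assert back.genotype == cc.genotype
    for structure in cc.structures:
        for day in (0, 1, 2):
            assert cmod.structure_mean(back, structure, day) == pytest.approx(
                cmod.structure_mean(cc, structure, day), nan_ok=True
            )
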