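"""Window assignment, medication encoding, assembly vs a brute-force oracle, splits."""

import numpy as np
import pandas as pd
import pytest

import raforecast as rf
from raforecast.featurize import (DISCARDED, FeatureSchema, WindowConfig, assemble,
                                  assign_window, encode_medications, matrix_arrays,
                                  reduce_window, split)

IDX = pd.Timestamp("2017-01-01")


def _day(d):
    return IDX - pd.Timedelta(days=d)


class TestAssignWindow:
    @pytest.mark.parametrize("d,expected", [
        (10, 4), (119, 4), (120, 3), (130, 3), (240, 2), (479, 1), (480, DISCARDED),
        (0, DISCARDED),
    ])
    def test_default_mapping(self, d, expected):
        assert assign_window(_day(d), IDX, WindowConfig()) == expected

    def test_index_day_included_when_configured(self):
        assert assign_window(IDX, IDX, WindowConfig(include_index_day=True)) == 4

    def test_event_after_index_errors(self):
        with pytest.raises(ValueError, match="after index"):
            assign_window(IDX + pd.Timedelta(days=1), IDX, WindowConfig())

    def test_lookback_cap_override(self):
        cfg = WindowConfig(lookback_cap_days=365)
        assert assign_window(_day(370), IDX, cfg) == DISCARDED
        assert assign_window(_day(360), IDX, cfg) == 1


class TestReduceWindow:
    def test_most_recent_wins(self):
        assert reduce_window([(_day(100), 12.0), (_day(40), 7.0)]) == 7.0

    def test_empty_is_missing(self):
        assert reduce_window([]) is None

    def test_tie_keeps_last_by_order(self):
        assert reduce_window([(_day(40), 1.0), (_day(40), 2.0)]) == 2.0


class TestEncodeMedications:
    def _events(self, rows):
        return pd.DataFrame([{"patient_id": "P", "date": _day(d), "med_code": c,
                              "med_class": "csDMARD"} for d, c in rows])

    def test_first_occurrence_only(self):
        out = encode_medications(self._events([(130, "A"), (10, "A")]), IDX,
                                 WindowConfig(), ("A",))
        assert out[2, 0] == 1 and out[3, 0] == 0 and out.sum() == 1

    def test_first_event_outside_lookback_all_zero(self):
        out = encode_medications(self._events([(500, "A"), (10, "A")]), IDX,
                                 WindowConfig(), ("A",))
        assert out.sum() == 0

    def test_no_events_all_zero(self):
        out = encode_medications(self._events([]), IDX, WindowConfig(), ("A", "B"))
        assert out.shape == (4, 2) and out.sum() == 0

    def test_carry_forward_option(self):
        out = encode_medications(self._events([(130, "A")]), IDX,
                                 WindowConfig(med_carry_forward=True), ("A",))
        assert list(out[:, 0]) == [0, 0, 1, 1]


def brute_force_features(member, tables, cfg, schema):
    """Independent per-event oracle: loop over raw rows, recompute windows by
    date arithmetic, keep latest value / first med occurrence by brute force."""
    n, nw = schema.n_tv, cfg.n_windows
    tv = np.full((nw, n), cfg.missing_sentinel)
    col = {v: j for j, v in enumerate(schema.tv_vars)}

    def window_of(date):
        d = (member.index_date - pd.Timestamp(date)).days
        if d < 0 or d >= cfg.cap or (d == 0 and not cfg.include_index_day):
            return None
        return nw - d // cfg.window_days

    cont = {"CDAI": [], "ESR": [], "CRP": []}
    for _, r in tables.cdai[tables.cdai["patient_id"] == member.patient_id].iterrows():
        cont["CDAI"].append((pd.Timestamp(r["date"]), r["cdai_score"]))
    for _, r in tables.labs[tables.labs["patient_id"] == member.patient_id].iterrows():
        cont[r["lab_name"]].append((pd.Timestamp(r["date"]), r["value"]))
    for var, events in cont.items():
        for w in range(1, nw + 1):
            in_w = [(d, v) for d, v in events if window_of(d) == w]
            if in_w:
                latest = max(d for d, _ in in_w)
                tv[w - 1, col[var]] = [v for d, v in in_w if d == latest][-1]

    first_seen = {}
    for _, r in tables.meds[tables.meds["patient_id"] == member.patient_id].iterrows():
        d = pd.Timestamp(r["date"])
        if d > member.index_date:
            continue
        c = r["med_code"]
        if c not in first_seen or d < first_seen[c]:
            first_seen[c] = d
    for c, d in first_seen.items():
        w = window_of(d)
        if w is not None and c in col:
            tv[w - 1, col[c]] = 1.0

    demo = tables.demographics
    row = demo[demo["patient_id"] == member.patient_id].iloc[0]
    from raforecast.featurize import RACE_CODE, SEX_CODE
    static = np.array([member.index_date.year - int(row["birth_year"]),
                       SEX_CODE[row["sex"]], RACE_CODE[row["race"]],
                       row["rf_positive"], row["ccp_positive"]], dtype=float)
    return np.concatenate([tv.ravel(), static])


def test_schema_total_dim_is_165():
    assert FeatureSchema().total_dim == 165


def test_assemble_matches_brute_force_oracle(small_site):
    tables, schema = small_site["tables"], small_site["schema"]
    cfg = WindowConfig()
    for member in small_site["members"][:100]:
        fast = assemble(member, tables, cfg, schema).flatten()
        slow = brute_force_features(member, tables, cfg, schema)
        np.testing.assert_array_equal(fast, slow)


def test_no_leakage_of_index_cdai(small_site):
    tables = small_site["tables"].copy()
    member = small_site["members"][0]
    before = assemble(member, tables, WindowConfig()).flatten()
    mask = (tables.cdai["patient_id"] == member.patient_id) & \
           (pd.to_datetime(tables.cdai["date"]) == member.index_date)
    assert mask.sum() == 1
    tables.cdai.loc[mask, "cdai_score"] = 71.0
    after = assemble(member, tables, WindowConfig()).flatten()
    np.testing.assert_array_equal(before, after)


def test_missing_labs_become_sentinel(small_site):
    tables = small_site["tables"].copy()
    member = small_site["members"][1]
    tables.labs = tables.labs[tables.labs["patient_id"] != member.patient_id]
    s = assemble(member, tables, WindowConfig())
    schema = FeatureSchema()
    esr_col = schema.tv_vars.index("ESR")
    crp_col = schema.tv_vars.index("CRP")
    assert (s.tv_matrix[:, [esr_col, crp_col]] == 0).all()


def test_event_changes_only_its_window(small_site):
    tables = small_site["tables"].copy()
    member = small_site["members"][2]
    cfg = WindowConfig()
    before = assemble(member, tables, cfg, small_site["schema"])
    new_date = member.index_date - pd.Timedelta(days=130)   # window 3
    tables.labs = pd.concat([tables.labs, pd.DataFrame([{
        "patient_id": member.patient_id, "date": new_date,
        "lab_name": "ESR", "value": 99.0}])], ignore_index=True)
    after = assemble(member, tables, cfg, small_site["schema"])
    diff = np.argwhere(before.tv_matrix != after.tv_matrix)
    assert all(w == 2 for w, _ in diff)          # only window 3 (0-based row 2)
    np.testing.assert_array_equal(before.static_vec, after.static_vec)


class TestSplit:
    class M:
        def __init__(self, i, lab):
            self.patient_id = i
            self.outcome_binary = lab

    def _members(self, n, frac_pos=0.4):
        return [self.M(i, "uncontrolled" if i < frac_pos * n else "controlled")
                for i in range(n)]

    def test_sizes_10(self):
        tr, va, te = split(self._members(10), rf.SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (6, 2, 2)

    def test_sizes_578_reproduce_test_116(self):
        tr, va, te = split(self._members(578), rf.SplitSpec(seed=0))
        assert len(te) == 116 and len(va) == 116 and len(tr) == 346

    def test_deterministic_and_disjoint(self):
        members = self._members(50)
        a = split(members, rf.SplitSpec(seed=4))
        b = split(members, rf.SplitSpec(seed=4))
        ids = lambda part: {m.patient_id for m in part}
        assert [ids(p) for p in a] == [ids(p) for p in b]
        assert not (ids(a[0]) & ids(a[1]) | ids(a[0]) & ids(a[2]) | ids(a[1]) & ids(a[2]))
        assert ids(a[0]) | ids(a[1]) | ids(a[2]) == {m.patient_id for m in members}

    def test_stratification(self):
        tr, va, te = split(self._members(100), rf.SplitSpec(seed=1))
        for part in (tr, va, te):
            frac = np.mean([m.outcome_binary == "uncontrolled" for m in part])
            assert abs(frac - 0.4) <= 0.1

    def test_too_few_members_errors(self):
        with pytest.raises(ValueError):
            split(self._members(2), rf.SplitSpec())
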