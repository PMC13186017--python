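"""Compendium ingestion, Class-I filtering and direction calling."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phoscoreg.compendium import (
    Direction,
    FilterConfig,
    RowError,
    SchemaError,
    SiteKey,
    SiteObservation,
    StudyRef,
    apply_directions,
    call_direction,
    filter_class1,
    normalize_symbol,
    read_observations,
    resolve_conflicts,
    write_observations,
)

HEADER = (
    "pmid\tdataset_id\tcondition_id\tgene_symbol\tresidue\tposition\t"
    "loc_prob\tascore\tfold_change\tp_value\tflanking\tdataset_kind"
)


def _write(tmp_path, lines, name="c.tsv"):
    p = tmp_path / name
    p.write_text("\n".join([HEADER] + lines) + "\n")
    return p


class TestReadObservations:
    def test_row_count_and_missing_cells(self, tmp_path):
        p = _write(
            tmp_path,
            [
                "P1\td1\tc1\tMELK\tS\t356\t0.99\t20\t2.0\t0.01\t\tdifferential",
                "P1\td1\tc1\tMELK\tS\t505\t0.99\t\t\t\t\tprofile",
                "P2\td1\tc2\tMKI67\tT\t2085\t0.8\t15\t0.5\t0.001\t\tdifferential",
            ],
        )
        obs = read_observations(p)
        assert len(obs) == 3
        assert obs[1].fold_change is None and obs[1].p_value is None
        assert obs[1].ascore is None
        assert obs[0].site == SiteKey("MELK", "S", 356)
        assert obs[2].study == StudyRef("P2", "d1", "c2")

    def test_missing_required_column_names_it(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("pmid\tdataset_id\tcondition_id\tgene_symbol\tresidue\tloc_prob\nP1\td\tc\tA\tS\t0.9\n")
        with pytest.raises(SchemaError, match="position"):
            read_observations(p, dataset_kind="profile")

    def test_unparseable_row_reports_line_number(self, tmp_path):
        p = _write(
            tmp_path,
            [
                "P1\td1\tc1\tMELK\tS\t356\t0.99\t20\t2.0\t0.01\t\tdifferential",
                "P1\td1\tc1\tMELK\tS\tnotanint\t0.99\t20\t2.0\t0.01\t\tdifferential",
            ],
        )
        with pytest.raises(RowError, match="line 3"):
            read_observations(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, [])
        assert read_observations(p, dataset_kind="profile") == []

    def test_log2_flag_exponentiates(self, tmp_path):
        p = _write(tmp_path, ["P1\td1\tc1\tMELK\tS\t356\t0.99\t20\t1.0\t0.01\t\tdifferential"])
        obs = read_observations(p, config=FilterConfig(log2_fold=True))
        assert obs[0].fold_change == pytest.approx(2.0)

    def test_round_trip_preserves_observations(self, tmp_path):
        p = _write(
            tmp_path,
            [
                "P1\td1\tc1\tMELK\tS\t356\t0.99\t20\t2.0\t0.01\tABCDEFGSXYZ\tdifferential",
                "P1\td1\tc1\tMELK\tS\t505\t0.8\t\t\t\t\tprofile",
            ],
        )
        obs = read_observations(p)
        out = tmp_path / "rt.tsv"
        write_observations(obs, out)
        again = read_observations(out)
        assert again == obs


@pytest.mark.parametrize(
    "raw,alias,expected",
    [
        ("mki67", {}, "MKI67"),
        ("KIAA0175", {"KIAA0175": "MELK"}, "MELK"),
        ("MELK", {"KIAA0175": "MELK"}, "MELK"),
        ("kiaa0175", {"KIAA0175": "MELK"}, "MELK"),
    ],
)
def test_normalize_symbol(raw, alias, expected):
    assert normalize_symbol(raw, alias) == expected


def test_normalize_symbol_rejects_empty():
    with pytest.raises(ValueError):
        normalize_symbol("", {})


def _obs(loc_prob, ascore):
    return SiteObservation(
        StudyRef("P1", "d1", "c1"), SiteKey("MELK", "S", 356), "differential",
        loc_prob=loc_prob, ascore=ascore, fold_change=2.0, p_value=0.01,
    )


class TestClass1Filter:
    @pytest.mark.parametrize(
        "loc,ascore,kept",
        [
            (0.75, 13.0, True),   # both at threshold pass
            (0.74, 40.0, False),  # localization just below
            (0.99, 12.9, False),  # A-score just below
            (0.80, None, True),   # missing A-score passes by default
        ],
    )
    def test_thresholds(self, loc, ascore, kept):
        out = filter_class1([_obs(loc, ascore)])
        assert (len(out) == 1) is kept

    def test_strict_mode_rejects_missing_ascore(self):
        assert filter_class1([_obs(0.9, None)], FilterConfig(strict_ascore=True)) == []

    def test_empty_input(self):
        assert filter_class1([]) == []

    def test_idempotent_and_order_preserving(self):
        rows = [_obs(0.9, 20.0), _obs(0.5, 20.0), _obs(0.76, None), _obs(0.9, 5.0)]
        once = filter_class1(rows)
        assert filter_class1(once) == once
        assert once == [rows[0], rows[2]]


class TestCallDirection:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.3, 0.01, Direction.UP),
            (0.76, 0.04, Direction.DOWN),
            (2.0, 0.20, Direction.UNCHANGED),  # significance gate
            (1.0, 0.001, Direction.UNCHANGED),  # fold-change dead zone
            (1.29, 0.001, Direction.UNCHANGED),
            (0.77, 0.001, Direction.UNCHANGED),
            (5.0, 0.05, Direction.UNCHANGED),  # p exactly at alpha is not < alpha
        ],
    )
    def test_examples(self, fc, p, expected):
        assert call_direction(fc, p) is expected

    @pytest.mark.parametrize("fc", [None, 0.0, -1.0, math.nan])
    def test_invalid_fold_change(self, fc):
        with pytest.raises(ValueError):
            call_direction(fc, 0.01)

    @given(
        fc=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False),
        p=st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
    )
    def test_partitions_exactly_one_call(self, fc, p):
        d = call_direction(fc, p)
        assert d in (Direction.UP, Direction.DOWN, Direction.UNCHANGED)


class TestResolveConflicts:
    def _mk(self, directions):
        study = StudyRef("P1", "d1", "c1")
        site = SiteKey("MELK", "S", 356)
        fc = {Direction.UP: 2.0, Direction.DOWN: 0.5, Direction.UNCHANGED: 1.0}
        p = {Direction.UP: 0.01, Direction.DOWN: 0.01, Direction.UNCHANGED: 0.5}
        obs = [
            SiteObservation(study, site, "differential", 0.99, 20.0, fc[d], p[d])
            for d in directions
        ]
        return resolve_conflicts(apply_directions(obs))[(study, site)]

    @pytest.mark.parametrize(
        "dirs,expected",
        [
            ([Direction.UP, Direction.UP], Direction.UP),
            ([Direction.UP, Direction.DOWN], Direction.AMBIGUOUS),
            ([Direction.UNCHANGED, Direction.UP], Direction.UP),
            ([Direction.UNCHANGED, Direction.UNCHANGED], Direction.UNCHANGED),
            ([Direction.DOWN], Direction.DOWN),
        ],
    )
    def test_merge_rules(self, dirs, expected):
        assert self._mk(dirs) is expected

    def test_one_entry_per_condition_site(self):
        study = StudyRef("P1", "d1", "c1")
        site = SiteKey("MELK", "S", 356)
        obs = apply_directions(
            [
                SiteObservation(study, site, "differential", 0.99, 20.0, 2.0, 0.01)
                for _ in range(5)
            ]
        )
        assert len(resolve_conflicts(obs)) == 1

    def test_profile_rows_excluded(self):
        study = StudyRef("P1", "d1", "c1")
        site = SiteKey("MELK", "S", 356)
        obs = [SiteObservation(study, site, "profile", 0.99)]
        assert resolve_conflicts(apply_directions(obs)) == {}
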