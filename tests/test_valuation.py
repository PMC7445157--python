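from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pollival as pv
from pollival.valuation import ProductionRecord, crop_psv, display_round


@pytest.mark.parametrize(
    "cpv,dr,expected",
    [
        ("977837000", "0.65", "635594050"),  # açaí
        ("0", "0.95", "0"),
        ("393745250", "0.25", "98436312.5"),  # soybean: exact half dollar
        ("197486500", "0.95", "187612175"),  # cocoa
    ],
)
def test_crop_psv_is_exact_product(cpv, dr, expected):
    assert crop_psv(Decimal(cpv), Decimal(dr)) == Decimal(expected)


def test_crop_psv_rejects_bad_inputs():
    with pytest.raises(ValueError):
        crop_psv(Decimal("-1"), Decimal("0.5"))
    with pytest.raises(ValueError):
        crop_psv(Decimal("1"), Decimal("1.5"))


@pytest.mark.parametrize(
    "value,expected",
    [
        ("98436312.5", 98436313),  # soybean row
        ("14487.5", 14488),  # melon row
        ("26069187.5", 26069188),  # watermelon row
        ("-2.5", -3),  # symmetry of half-away-from-zero
        ("2.4", 2),
        ("2.6", 3),
    ],
)
def test_display_round_half_away_from_zero(value, expected):
    assert display_round(Decimal(value)) == expected


def test_negative_production_record_rejected():
    with pytest.raises(ValueError):
        ProductionRecord("Açaí", "m1", 2016, Decimal("-5"))


class TestStateTable:
    def test_row_count_and_totals(self, valuated):
        rows, totals = valuated
        assert len(rows) == 36
        assert totals.total_cpv == Decimal("2950519500")
        assert totals.total_psv_exact == Decimal("983221475")
        assert totals.total_psv_display == 983221475

    def test_every_printed_psv_reproduced(self, valuated, tables):
        rows, _ = valuated
        printed = {t.crop: t.psv_printed for t in tables[0]}
        for row in rows:
            if printed[row.crop] is None:
                assert row.psv_display is None and row.psv_exact is None
            else:
                assert row.psv_display == int(printed[row.crop]), row.crop

    def test_unknown_crop_in_cpv_but_not_psv(self, valuated):
        rows, totals = valuated
        lemon = next(r for r in rows if r.crop == "Brazilian Lemon")
        assert lemon.dr is None and lemon.psv_exact is None
        # its CPV is inside the grand total
        without = totals.total_cpv - lemon.cpv
        assert without == Decimal("2950519500") - Decimal("17837500")

    def test_rounding_reconciliation_oracle(self, valuated):
        """Brute-force over the 20 dependent rows: the printed-row sum exceeds
        the display-rounded total by exactly 0.5 x (number of half-dollar ties)."""
        rows, totals = valuated
        dependent = [r for r in rows if r.psv_exact is not None]
        n_half = sum(1 for r in dependent if r.psv_exact % 1 == Decimal("0.5"))
        printed_sum = sum(r.psv_display for r in dependent)
        assert n_half == 10
        assert printed_sum - totals.total_psv_display == Decimal("0.5") * n_half


def test_valuate_reports_all_unresolvable_crops(deps):
    recs = [
        ProductionRecord("Cupuaçu", "m1", 2016, Decimal(1)),
        ProductionRecord("Açaí", "m1", 2016, Decimal(1)),
        ProductionRecord("Bacuri", "m2", 2016, Decimal(1)),
    ]
    with pytest.raises(KeyError) as exc:
        pv.valuate(recs, deps)
    assert "Bacuri" in str(exc.value) and "Cupuaçu" in str(exc.value)
    assert "Açaí" not in str(exc.value)


class TestScenario:
    def test_without_acai_matches_study(self, records, deps):
        totals = pv.scenario_without(records, deps, ["Açaí"])
        assert totals.total_psv_exact == Decimal("347627425")
        assert totals.total_cpv == Decimal("1972682500")

    def test_empty_exclusion_is_identity(self, records, deps, valuated):
        _, all_totals = valuated
        totals = pv.scenario_without(records, deps, [])
        assert totals.total_cpv == all_totals.total_cpv
        assert totals.total_psv_exact == all_totals.total_psv_exact

    def test_absent_crop_is_noop(self, records, deps, valuated):
        _, all_totals = valuated
        totals = pv.scenario_without(records, deps, ["Dragonfruit"])
        assert totals.total_cpv == all_totals.total_cpv

    def test_exclusion_complements_subset_totals(self, records, deps, valuated):
        _, all_totals = valuated
        acai = [r for r in records if r.crop == "Açaí"]
        _, acai_totals = pv.valuate(acai, deps)
        without = pv.scenario_without(records, deps, ["açai", "AÇAÍ"])
        assert all_totals.total_cpv - acai_totals.total_cpv == without.total_cpv
        assert (
            all_totals.total_psv_exact - acai_totals.total_psv_exact
            == without.total_psv_exact
        )


class TestCropShare:
    def test_acai_psv_share(self, valuated):
        rows, _ = valuated
        share = pv.crop_share(rows, "Açaí", of="psv")
        assert share.quantize(Decimal("0.0001")) == Decimal("0.6464")

    def test_top4_psv_share_formats_to_96(self, valuated):
        rows, _ = valuated
        share = pv.crop_share(
            rows, ["Açaí", "Cocoa (almond)", "Soybean (grain)", "Watermelon"], of="psv"
        )
        assert share.quantize(Decimal("0.0001")) == Decimal("0.9639")
        assert pv.format_percent(share) == 96

    def test_top5_cpv_share_exceeds_76_percent(self, valuated):
        rows, _ = valuated
        share = pv.crop_share(
            rows,
            ["Açaí", "Manioc", "Soybean (grain)", "Black pepper", "Cocoa (almond)"],
            of="cpv",
        )
        assert share > Decimal("0.76")

    def test_all_crops_share_is_one(self, valuated, tables):
        rows, _ = valuated
        every = [t.crop for t in tables[0]]
        assert pv.crop_share(rows, every, of="cpv") == 1
        assert pv.crop_share(rows, every, of="psv") == 1

    def test_zero_total_errors(self, deps):
        rows, _ = pv.valuate([ProductionRecord("Manioc", "m", 2016, Decimal(10))], deps)
        with pytest.raises(ValueError, match="zero"):
            pv.crop_share(rows, "Manioc", of="psv")


money = st.decimals(min_value=0, max_value=10**9, places=2, allow_nan=False)
crops = st.sampled_from(
    ["Açaí", "Cocoa (almond)", "Manioc", "Watermelon", "Brazilian Lemon", "Papaya"]
)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.tuples(crops, money), max_size=25), st.randoms(use_true_random=False))
def test_totals_are_permutation_invariant_and_additive(deps, pairs, rnd):
    recs = [ProductionRecord(c, "m", 2016, v) for c, v in pairs]
    _, totals = pv.valuate(recs, deps)
    shuffled = list(recs)
    rnd.shuffle(shuffled)
    _, totals2 = pv.valuate(shuffled, deps)
    assert totals.total_cpv == totals2.total_cpv
    assert totals.total_psv_exact == totals2.total_psv_exact
    cut = len(recs) // 2
    _, a = pv.valuate(recs[:cut], deps)
    _, b = pv.valuate(recs[cut:], deps)
    assert a.total_cpv + b.total_cpv == totals.total_cpv
    assert a.total_psv_exact + b.total_psv_exact == totals.total_psv_exact


@settings(max_examples=60, deadline=None)
@given(crops, money)
def test_row_psv_bounded_by_cpv(deps, crop, value):
    rows, _ = pv.valuate([ProductionRecord(crop, "m", 2016, value)], deps)
    row = rows[0]
    if row.psv_exact is not None:
        assert 0 <= row.psv_exact <= row.cpv
        assert row.psv_exact == row.cpv * row.dr
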