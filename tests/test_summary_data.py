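import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivmr import summary_data as sd
from ivmr.estimators import ivw
from ivmr.summary_data import (
    FormatError,
    HarmonizationError,
    InstrumentSet,
    VariantAssociation,
    convert_to_log_scale,
    harmonize,
    log_to_percent,
    percent_to_log,
    read_associations,
    read_instruments,
    rescale_per_sd,
    write_instruments,
)


def variant(rsid="rs1", ea="A", oa="G", beta=0.05, se=0.01, scale=sd.SCALE_LOG_UNITS, **kw):
    return VariantAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se, scale=scale, **kw
    )


class TestScaleConversion:
    @pytest.mark.parametrize(
        "pct, expected",
        [
            (0.0, 0.0),
            (100.0, math.log(2)),  # doubling
            (92.0, 0.6523),  # the study's SD step on the percent scale
        ],
    )
    def test_percent_to_log(self, pct, expected):
        assert percent_to_log(pct) == pytest.approx(expected, abs=5e-5)

    def test_one_sd_in_log_units_is_92_percent(self):
        # A 0.65 log-unit shift in the exposure corresponds to a 92% increase.
        assert log_to_percent(0.65) == pytest.approx(91.6, abs=0.05)
        assert round(log_to_percent(0.65)) == 92

    def test_percent_to_log_domain_error(self):
        with pytest.raises(ValueError):
            percent_to_log(-100.0)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=-99.0, max_value=1e4))
    def test_conversions_are_exact_inverses(self, pct):
        assert percent_to_log(log_to_percent(percent_to_log(pct))) == pytest.approx(
            percent_to_log(pct), abs=1e-12
        )

    def test_convert_percent_records_uses_delta_method_for_se(self):
        rec = variant(beta=50.0, se=5.0, scale=sd.SCALE_PERCENT)
        (out,) = convert_to_log_scale([rec])
        assert out.scale == sd.SCALE_LOG_UNITS
        assert out.beta == pytest.approx(math.log(1.5))
        assert out.se == pytest.approx(5.0 / 150.0)

    def test_convert_odds_ratio_records(self):
        rec = variant(beta=1.25, se=0.04, scale=sd.SCALE_ODDS_RATIO)
        (out,) = convert_to_log_scale([rec])
        assert out.scale == sd.SCALE_LOG_ODDS
        assert out.beta == pytest.approx(math.log(1.25))
        assert out.se == 0.04  # SE already refers to the log-OR


class TestVariantValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"se": 0.0},
            {"se": -1.0},
            {"beta": float("nan")},
            {"ea": "X"},
            {"oa": ""},
            {"eaf": 1.0},
            {"p": 0.0},
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        ea = kw.pop("ea", "A")
        oa = kw.pop("oa", "G")
        with pytest.raises(ValueError):
            variant(ea=ea, oa=oa, **kw)


class TestReadAssociations:
    ROWS = [
        {"rsid": "rs1", "effect_allele": "A", "other_allele": "G", "beta": 0.1, "se": 0.02},
        {"rsid": "rs2", "effect_allele": "C", "other_allele": "T", "beta": -0.05, "se": 0.01},
        {"rsid": "rs3", "effect_allele": "G", "other_allele": "A", "beta": 0.02, "se": 0.03},
    ]

    def test_round_trip_identity(self, write_table):
        path = write_table(self.ROWS)
        result = read_associations(path, scale=sd.SCALE_LOG_UNITS)
        assert len(result.records) == 3
        assert result.n_rejected == 0
        rec = result.records[1]
        assert (rec.rsid, rec.effect_allele, rec.beta, rec.se) == ("rs2", "C", -0.05, 0.01)
        assert all(r.scale == sd.SCALE_LOG_UNITS for r in result.records)

    def test_na_se_row_rejected_with_line_number(self, write_table):
        rows = [dict(r) for r in self.ROWS]
        rows[1]["se"] = "NA"
        path = write_table(rows)
        result = read_associations(path)
        assert len(result.records) == 2
        assert result.n_rejected == 1
        assert result.rejections[0][0] == 3  # header is line 1

    def test_missing_mapped_column_names_it(self, write_table):
        rows = [{k: v for k, v in r.items() if k != "se"} for r in self.ROWS]
        path = write_table(rows)
        with pytest.raises(FormatError, match="se"):
            read_associations(path)

    def test_duplicate_rsids_error(self, write_table):
        path = write_table(self.ROWS + [self.ROWS[0]])
        with pytest.raises(FormatError, match="rs1"):
            read_associations(path)

    def test_column_map_override(self, write_table):
        rows = [
            {"SNP": "rs9", "EA": "a", "OA": "g", "b": 0.1, "stderr": 0.02, "freq": 0.3}
        ]
        path = write_table(rows)
        result = read_associations(
            path,
            column_map={
                "rsid": "SNP",
                "effect_allele": "EA",
                "other_allele": "OA",
                "beta": "b",
                "se": "stderr",
                "eaf": "freq",
            },
        )
        (rec,) = result.records
        assert rec.rsid == "rs9"
        assert rec.effect_allele == "A"  # upper-cased
        assert rec.eaf == 0.3


def _pair(exp_alleles, out_alleles, beta_y=0.02, rsid="rs1"):
    exp = [variant(rsid=rsid, ea=exp_alleles[0], oa=exp_alleles[1], beta=0.05, se=0.01)]
    out = [
        variant(
            rsid=rsid, ea=out_alleles[0], oa=out_alleles[1],
            beta=beta_y, se=0.03, scale=sd.SCALE_LOG_ODDS,
        )
    ]
    return exp, out


class TestHarmonize:
    def test_matching_alleles_kept_as_is(self):
        iset = harmonize(*_pair(("A", "G"), ("A", "G")))
        (inst,) = iset.instruments
        assert inst.beta_y == 0.02
        assert not inst.flipped

    def test_reversed_alleles_flip_outcome_sign(self):
        iset = harmonize(*_pair(("A", "G"), ("G", "A")))
        (inst,) = iset.instruments
        assert inst.beta_y == -0.02
        assert inst.flipped

    def test_strand_complement_resolves(self):
        # outcome reported on the opposite strand: A/G vs T/C
        iset = harmonize(*_pair(("A", "G"), ("T", "C")))
        (inst,) = iset.instruments
        assert inst.beta_y == 0.02 and not inst.flipped
        iset = harmonize(*_pair(("A", "G"), ("C", "T")))
        (inst,) = iset.instruments
        assert inst.beta_y == -0.02 and inst.flipped

    def test_incompatible_alleles_raise_with_rsid(self):
        with pytest.raises(HarmonizationError, match="rs1"):
            harmonize(*_pair(("A", "G"), ("A", "C")))

    @pytest.mark.parametrize("policy, expect_kept", [("keep", True), ("flag", True), ("drop", False)])
    def test_palindromic_policies(self, policy, expect_kept):
        exp, out = _pair(("A", "T"), ("A", "T"))
        exp2, out2 = _pair(("C", "G"), ("C", "G"), rsid="rs2")
        if expect_kept:
            iset = harmonize(exp + exp2, out + out2, palindromic_policy=policy)
            assert iset.L == 2
            assert all(i.palindromic for i in iset.instruments)
        else:
            # both pairs palindromic -> dropping them empties the set
            with pytest.raises(HarmonizationError):
                harmonize(exp + exp2, out + out2, palindromic_policy=policy)

    def test_drop_policy_excludes_only_palindromic(self):
        exp_p, out_p = _pair(("A", "T"), ("A", "T"))
        exp_n, out_n = _pair(("A", "G"), ("A", "G"), rsid="rs2")
        iset = harmonize(exp_p + exp_n, out_p + out_n, palindromic_policy="drop")
        assert iset.rsids == ["rs2"]

    def test_missing_rsid_excluded(self):
        exp, out = _pair(("A", "G"), ("A", "G"))
        exp2, _ = _pair(("A", "G"), ("A", "G"), rsid="rs2")
        iset = harmonize(exp + exp2, out)
        assert iset.rsids == ["rs1"]

    def test_idempotent_on_aligned_pair(self):
        exp, out = _pair(("A", "G"), ("A", "G"))
        first = harmonize(exp, out)
        # re-express the harmonized set as association records and harmonize again
        exp2 = [variant(rsid="rs1", beta=first.instruments[0].beta_x, se=first.instruments[0].se_x)]
        out2 = [
            variant(
                rsid="rs1", beta=first.instruments[0].beta_y,
                se=first.instruments[0].se_y, scale=sd.SCALE_LOG_ODDS,
            )
        ]
        second = harmonize(exp2, out2)
        assert second.instruments[0].beta_y == first.instruments[0].beta_y
        assert not second.instruments[0].flipped

    def test_double_flip_restores_outcome_beta(self):
        # swapping the outcome's allele labels AND negating its beta is a
        # no-op: both encodings harmonize to the same aligned effect
        aligned = harmonize(*_pair(("A", "G"), ("A", "G"), beta_y=0.02))
        recoded = harmonize(*_pair(("A", "G"), ("G", "A"), beta_y=-0.02))
        assert recoded.instruments[0].beta_y == aligned.instruments[0].beta_y
        assert recoded.instruments[0].flipped and not aligned.instruments[0].flipped

    def test_wrong_scale_rejected(self):
        exp, out = _pair(("A", "G"), ("A", "G"))
        bad_exp = [replace(exp[0], scale=sd.SCALE_PERCENT)]
        with pytest.raises(ValueError, match="log-units"):
            harmonize(bad_exp, out)


class TestRescalePerSD:
    def test_linear_scaling(self, make_instruments):
        est = ivw(make_instruments(5, sd_scale=1.0))
        scaled = rescale_per_sd(est, 0.65)
        assert scaled.beta == pytest.approx(0.65 * est.beta)
        assert scaled.se == pytest.approx(0.65 * est.se)
        assert scaled.ci_low == pytest.approx(0.65 * est.ci_low)

    def test_identity_and_z_invariance(self, make_instruments):
        est = ivw(make_instruments(5, sd_scale=1.0))
        assert rescale_per_sd(est, 1.0) == est
        scaled = rescale_per_sd(est, 0.65)
        assert scaled.beta / scaled.se == pytest.approx(est.beta / est.se)
        assert scaled.p == est.p

    def test_nonpositive_scale_rejected(self, make_instruments):
        est = ivw(make_instruments(4))
        with pytest.raises(ValueError):
            rescale_per_sd(est, 0.0)


class TestInstrumentSetIO:
    def test_round_trip(self, tmp_path, make_instruments):
        iset = make_instruments(6, sd_scale=0.65)
        path = tmp_path / "harmonized.tsv"
        write_instruments(iset, path)
        back = read_instruments(path, sd_scale=0.65)
        np.testing.assert_allclose(back.beta_x, iset.beta_x)
        np.testing.assert_allclose(back.se_y, iset.se_y)
        assert back.rsids == iset.rsids

    def test_duplicate_rsids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            InstrumentSet.from_arrays([0.1, 0.2], [0.01, 0.01], [0.0, 0.0], [0.02, 0.02], rsids=["rs1", "rs1"])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            InstrumentSet([], sd_scale=1.0)
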