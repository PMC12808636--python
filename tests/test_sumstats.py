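"""Summary-statistic parsing, validation, and allele harmonization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from pandas.testing import assert_frame_equal

from pwmr.errors import ConfigurationError, HarmonizationError, InputError
from pwmr.simulate import SimScenario, simulate_sumstats
from pwmr.sumstats import (SumStatTable, harmonize, is_palindromic,
                           read_sumstats, write_sumstats)

from conftest import build_table


@pytest.mark.parametrize("ea,nea,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("G", "T", False),
    ("a", "t", True),           # case-insensitive
    ("AT", "A", False),         # indel: palindrome logic not applicable
])
def test_is_palindromic(ea, nea, expected):
    assert is_palindromic(ea, nea) is expected


class TestReadWrite:
    def test_roundtrip_is_bit_identical(self, tmp_path):
        sim = simulate_sumstats(SimScenario(causal_config="h0", n_snps=100, seed=5))
        path = tmp_path / "t.tsv"
        write_sumstats(sim.exposure, path)
        back = read_sumstats(path, trait_id=sim.exposure.trait_id)
        assert_frame_equal(back.df, sim.exposure.df, check_exact=True)

    def test_dialect_maps_headers(self, tmp_path):
        sim = simulate_sumstats(SimScenario(causal_config="h0", n_snps=5, seed=5))
        path = tmp_path / "odd.tsv"
        sim.exposure.df.rename(columns={"rsid": "SNP", "ea": "effect_allele"}) \
            .to_csv(path, sep="\t", index=False)
        with pytest.raises(ConfigurationError):
            read_sumstats(path)
        t = read_sumstats(path, dialect={"SNP": "rsid", "effect_allele": "ea"})
        assert len(t) == 5

    def test_invalid_rows_dropped_and_logged(self, caplog):
        t = build_table([
            {"rsid": "ok1"},
            {"rsid": "bad_se", "se": 0.0},
            {"rsid": "bad_p", "pval": 0.0},
            {"rsid": "bad_eaf", "eaf": 1.2},
            {"rsid": "bad_alleles", "nea": "A"},
            {"rsid": "ok2"},
        ])
        assert t.rsids == ["ok1", "ok2"]

    def test_missing_eaf_allowed(self):
        t = build_table([{"rsid": "x", "eaf": np.nan}])
        assert len(t) == 1

    def test_zero_valid_rows_is_fatal(self):
        with pytest.raises(InputError):
            build_table([{"rsid": "a", "se": 0.0}])

    def test_duplicate_rsids_deduplicated(self):
        t = build_table([{"rsid": "dup", "beta": 0.1}, {"rsid": "dup", "beta": 0.2}])
        assert len(t) == 1 and t.record("dup").beta == 0.1


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = build_table([{"rsid": "v", "ea": "A", "nea": "G",
                            "beta": 0.10, "eaf": 0.30}])
        out = build_table([{"rsid": "v", "ea": "G", "nea": "A",
                            "beta": 0.05, "eaf": 0.70}], trait_type="outcome")
        pair = next(harmonize(exp, out).iter_pairs())
        assert pair.action == "flipped"
        assert pair.beta_y == pytest.approx(-0.05)
        assert pair.eaf_y == pytest.approx(0.30)

    def test_strand_complement_reconciled(self):
        exp = build_table([{"rsid": "v", "ea": "A", "nea": "G", "beta": 0.1}])
        out = build_table([{"rsid": "v", "ea": "T", "nea": "C", "beta": 0.2}],
                          trait_type="outcome")
        pair = next(harmonize(exp, out).iter_pairs())
        assert pair.action == "aligned" and pair.beta_y == pytest.approx(0.2)

    @pytest.mark.parametrize("eaf,kept", [(0.50, False), (0.45, False),
                                          (0.42, True), (0.10, True)])
    def test_palindrome_intermediate_maf_rule_is_strict(self, eaf, kept):
        exp = build_table([{"rsid": "v", "ea": "A", "nea": "T", "eaf": eaf}])
        out = build_table([{"rsid": "v", "ea": "A", "nea": "T", "eaf": eaf}],
                          trait_type="outcome")
        hz = harmonize(exp, out)
        pair = next(hz.iter_pairs(include_excluded=True))
        assert pair.excluded is (not kept)
        if not kept:
            assert pair.exclusion_reason == "palindromic_intermediate_maf"

    def test_palindrome_orientation_from_frequency(self):
        # opposite strands inferred from discordant frequencies
        exp = build_table([{"rsid": "v", "ea": "A", "nea": "T",
                            "eaf": 0.10, "beta": 0.2}])
        out = build_table([{"rsid": "v", "ea": "A", "nea": "T",
                            "eaf": 0.91, "beta": 0.3}], trait_type="outcome")
        pair = next(harmonize(exp, out).iter_pairs())
        assert pair.action == "freq_inferred"
        assert pair.beta_y == pytest.approx(-0.3)
        assert pair.eaf_y == pytest.approx(0.09)

    def test_palindrome_missing_eaf_excluded(self):
        exp = build_table([{"rsid": "v", "ea": "A", "nea": "T", "eaf": np.nan}])
        out = build_table([{"rsid": "v", "ea": "T", "nea": "A", "eaf": 0.1}],
                          trait_type="outcome")
        pair = next(harmonize(exp, out).iter_pairs(include_excluded=True))
        assert pair.excluded and pair.exclusion_reason == "palindromic_missing_eaf"

    def test_irreconcilable_alleles_excluded(self):
        exp = build_table([{"rsid": "v", "ea": "A", "nea": "G"}])
        out = build_table([{"rsid": "v", "ea": "A", "nea": "C"}],
                          trait_type="outcome")
        pair = next(harmonize(exp, out).iter_pairs(include_excluded=True))
        assert pair.excluded and pair.exclusion_reason == "allele_mismatch"

    def test_empty_intersection_names_both_traits(self):
        exp = build_table([{"rsid": "a"}], trait_id="PROT")
        out = build_table([{"rsid": "b"}], trait_id="BMI", trait_type="outcome")
        with pytest.raises(HarmonizationError, match="PROT.*BMI"):
            harmonize(exp, out)

    def test_self_harmonization_is_identity(self):
        rows = [{"rsid": "v1", "ea": "A", "nea": "G"},
                {"rsid": "v2", "ea": "A", "nea": "T", "eaf": 0.2},
                {"rsid": "v3", "ea": "C", "nea": "G", "eaf": 0.35}]
        t = build_table(rows)
        t2 = build_table(rows, trait_type="outcome")
        hz = harmonize(t, t2)
        assert hz.n_valid == 3
        for p in hz.iter_pairs():
            assert p.action == "aligned"
            assert p.beta_x == p.beta_y

    def test_double_allele_flip_invariance(self):
        """Recoding the outcome onto the other allele leaves results unchanged."""
        sim = simulate_sumstats(SimScenario(causal_config="h4", n_snps=40,
                                            palindromic_fraction=0.2, seed=9))
        base = harmonize(sim.exposure, sim.outcome)
        df = sim.outcome.df.copy()
        df[["ea", "nea"]] = df[["nea", "ea"]].to_numpy()
        df["beta"] = -df["beta"]
        df["eaf"] = 1 - df["eaf"]
        flipped_tbl = SumStatTable("BMI", df, "outcome")
        alt = harmonize(sim.exposure, flipped_tbl)
        a, b = base.valid(), alt.valid()
        assert list(a["rsid"]) == list(b["rsid"])
        np.testing.assert_allclose(a["beta_x"], b["beta_x"])
        np.testing.assert_allclose(a["beta_y"], b["beta_y"])

    def test_exclusion_counts_conserved(self):
        sim = simulate_sumstats(SimScenario(causal_config="h0", n_snps=80,
                                            palindromic_fraction=0.3,
                                            maf_range=(0.3, 0.5), seed=3))
        hz = harmonize(sim.exposure, sim.outcome)
        n_inter = len(set(sim.exposure.rsids) & set(sim.outcome.rsids))
        assert hz.n_valid + int(hz.pairs["excluded"].sum()) == n_inter
        audit = hz.exclusions()
        assert len(audit) == int(hz.pairs["excluded"].sum())
        assert set(audit.columns) == {"rsid", "exposure", "outcome", "reason"}

    @given(beta=st.floats(-1, 1, allow_nan=False), eaf=st.floats(0.02, 0.98))
    def test_flip_is_involutive(self, beta, eaf):
        """Flipping outcome coding twice returns the original orientation."""
        exp = build_table([{"rsid": "v", "ea": "A", "nea": "G",
                            "beta": 0.1, "eaf": 0.3}])
        out = build_table([{"rsid": "v", "ea": "G", "nea": "A",
                            "beta": beta, "eaf": eaf}], trait_type="outcome")
        p = next(harmonize(exp, out).iter_pairs())
        assert p.beta_y == pytest.approx(-beta)
        assert p.eaf_y == pytest.approx(1 - eaf)
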