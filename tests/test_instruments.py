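"""Instrument selection, allele harmonization and Steiger filtering."""

import numpy as np
import pandas as pd
import pytest

from mrpv.errors import InstrumentSelectionError
from mrpv.instruments import harmonize, select_instruments, steiger_filter
from mrpv.sumstats import LDMatrix, SummaryStats
from mrpv.simulate import generate_summary_stats, glp1r_like_scenario


def _stats(rows, trait="exposure", trait_type="quantitative"):
    table = pd.DataFrame(
        rows, columns=["snp", "chr", "pos", "a1", "a2", "eaf", "beta", "se", "p", "n"]
    )
    return SummaryStats(table, trait=trait, trait_type=trait_type)


class TestSelectInstruments:
    def test_clumping_keeps_strongest_of_correlated_pair(self):
        stats_ = _stats([
            ("s1", "1", 100, "A", "G", 0.3, 0.5, 0.05, 1e-10, 30000),
            ("s2", "1", 200, "A", "G", 0.3, 0.4, 0.05, 1e-9, 30000),
        ])
        r = np.sqrt(0.5)
        ld = LDMatrix(np.array([[1.0, r], [r, 1.0]]), ["s1", "s2"])
        out = select_instruments(stats_, ld)
        assert out.snps == ["s1"]

    def test_weak_instrument_dropped_at_f_threshold(self):
        stats_ = _stats([
            ("s1", "1", 100, "A", "G", 0.3, 0.15, 0.05, 1e-12, 30000),  # F = 9
            ("s2", "1", 200, "A", "G", 0.3, 0.50, 0.05, 1e-20, 30000),  # F = 100
        ])
        ld = LDMatrix(np.eye(2), ["s1", "s2"])
        out = select_instruments(stats_, ld)
        assert out.snps == ["s2"]

    def test_eaf_filter_uses_minor_allele_frequency(self):
        stats_ = _stats([
            ("s1", "1", 100, "A", "G", 0.995, 0.5, 0.05, 1e-10, 30000),
            ("s2", "1", 200, "A", "G", 0.30, 0.5, 0.05, 1e-10, 30000),
        ])
        ld = LDMatrix(np.eye(2), ["s1", "s2"])
        assert select_instruments(stats_, ld).snps == ["s2"]

    def test_empty_selection_reports_stage_counts(self):
        stats_ = _stats([("s1", "1", 100, "A", "G", 0.3, 0.01, 0.05, 0.5, 30000)])
        ld = LDMatrix(np.eye(1), ["s1"])
        with pytest.raises(InstrumentSelectionError) as err:
            select_instruments(stats_, ld)
        assert err.value.stage_counts["input"] == 1
        assert err.value.stage_counts["p_and_eaf"] == 0

    def test_cis_region_with_22_planted_signals(self):
        """LD-block scenario: greedy clumping recovers exactly the 22 block
        leaders, all with strong instrument F statistics."""
        sset = generate_summary_stats(glp1r_like_scenario(seed=11))
        out = select_instruments(sset.exposure, sset.ld)
        assert len(out) == 22
        f = (out.table["beta"] / out.table["se"]) ** 2
        assert (f >= 10).all()
        # clumped set is pairwise r^2 < 0.01, checked exhaustively
        sub = sset.ld.submatrix(out.snps).r
        off = sub[~np.eye(22, dtype=bool)]
        assert (off**2 < 0.01).all()


class TestHarmonize:
    def _pair(self, out_alleles=("A", "G"), out_beta=-0.2, out_eaf=0.7,
              exp_alleles=("A", "G"), exp_eaf=0.3):
        exp = _stats([("s1", "1", 100, *exp_alleles, exp_eaf, 0.1, 0.02, 1e-8, 30000)])
        out = _stats(
            [("s1", "1", 100, *out_alleles, out_eaf, out_beta, 0.05, 0.01, 400000)],
            trait="outcome", trait_type="binary",
        )
        return exp, out

    def test_swapped_alleles_flip_sign(self):
        exp, out = self._pair(out_alleles=("G", "A"), out_beta=-0.2, out_eaf=0.7)
        h = harmonize(exp, out)
        assert h.n_snps == 1
        assert h.kept["b_out"].iloc[0] == pytest.approx(0.2)
        assert h.kept["eaf_out"].iloc[0] == pytest.approx(0.3)

    def test_strand_flip_matched_without_sign_change(self):
        exp, out = self._pair(out_alleles=("T", "C"), out_beta=-0.2, out_eaf=0.3)
        h = harmonize(exp, out)
        assert h.kept["b_out"].iloc[0] == pytest.approx(-0.2)

    def test_palindromic_at_half_frequency_dropped(self):
        exp, out = self._pair(exp_alleles=("A", "T"), out_alleles=("A", "T"),
                              exp_eaf=0.5, out_eaf=0.5)
        h = harmonize(exp, out)
        assert h.n_snps == 0
        assert h.table["dropped_reason"].iloc[0] == "palindromic_ambiguous"

    def test_palindromic_same_side_kept_opposite_dropped(self):
        exp, out = self._pair(exp_alleles=("C", "G"), out_alleles=("C", "G"),
                              exp_eaf=0.2, out_eaf=0.22)
        assert harmonize(exp, out).n_snps == 1
        exp, out = self._pair(exp_alleles=("C", "G"), out_alleles=("G", "C"),
                              exp_eaf=0.2, out_eaf=0.8)
        assert harmonize(exp, out).n_snps == 0

    def test_allele_mismatch_dropped_with_reason(self):
        exp, out = self._pair(out_alleles=("A", "C"))
        h = harmonize(exp, out)
        assert h.table["dropped_reason"].iloc[0] == "allele_mismatch"

    def test_missing_in_outcome_dropped_with_reason(self):
        exp = _stats([
            ("s1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-8, 30000),
            ("s2", "1", 200, "A", "G", 0.3, 0.1, 0.02, 1e-8, 30000),
        ])
        out = _stats([("s1", "1", 100, "A", "G", 0.3, 0.1, 0.05, 0.01, 400000)],
                     trait="outcome")
        h = harmonize(exp, out)
        assert h.table.set_index("snp")["dropped_reason"]["s2"] == "missing_in_outcome"

    def test_idempotent(self):
        exp, out = self._pair(out_alleles=("G", "A"), out_beta=-0.2, out_eaf=0.7)
        h1 = harmonize(exp, out)
        aligned = SummaryStats(
            h1.kept.rename(columns={
                "b_out": "beta", "se_out": "se", "eaf_out": "eaf", "n_out": "n"
            })[["snp", "chr", "pos", "a1", "a2", "eaf", "beta", "se", "n"]]
            .assign(p=0.01),
            trait="outcome",
        )
        h2 = harmonize(exp, aligned)
        assert h2.kept["b_out"].iloc[0] == pytest.approx(h1.kept["b_out"].iloc[0])

    def test_commutes_with_exposure_relabelling(self):
        """Relabelling the exposure A1<->A2 (sign + frequency flip) flips the
        aligned outcome beta too, leaving the Wald ratio invariant."""
        exp, out = self._pair()
        h1 = harmonize(exp, out)
        exp_flipped = _stats([("s1", "1", 100, "G", "A", 0.7, -0.1, 0.02, 1e-8, 30000)])
        h2 = harmonize(exp_flipped, out)
        r1 = h1.kept["b_out"].iloc[0] / h1.kept["b_exp"].iloc[0]
        r2 = h2.kept["b_out"].iloc[0] / h2.kept["b_exp"].iloc[0]
        assert r1 == pytest.approx(r2)
        assert h1.kept["f_stat"].iloc[0] == pytest.approx(h2.kept["f_stat"].iloc[0])


class TestSteiger:
    def _hset(self, z_exp, n_exp, z_out, n_out):
        from mrpv.instruments import HarmonizedInstrumentSet

        se_exp, se_out = 0.01, 0.002
        return HarmonizedInstrumentSet.from_arrays(
            b_exp=[z_exp * se_exp], se_exp=[se_exp],
            b_out=[z_out * se_out], se_out=[se_out],
            n_exp=n_exp, n_out=n_out,
        )

    def test_strong_exposure_weak_outcome_kept(self):
        h = steiger_filter(self._hset(10, 30_000, 1, 400_000))
        assert h.n_snps == 1

    def test_zero_outcome_association_kept(self):
        h = steiger_filter(self._hset(10, 30_000, 0, 400_000))
        assert h.n_snps == 1

    def test_reverse_direction_removed(self):
        h = steiger_filter(self._hset(7, 30_000, 70, 400_000))
        assert h.n_snps == 0
        assert (h.table["dropped_reason"] == "steiger").all()
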