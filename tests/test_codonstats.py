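import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from codonstab._genetic_code import (AA_TO_CODONS, AMINO_ACIDS, SENSE_CODONS,
                                     STOP_CODONS)
from codonstab.codonstats import (codon_frequencies, compute_aasc, compute_csc,
                                  fisher_r_to_z, frequency_table, spearman)


class TestCodonFrequencies:
    def test_in_frame_toy(self):
        f = codon_frequencies("ATGAAATAA")
        assert f["ATG"] == pytest.approx(1 / 3)
        assert f["AAA"] == pytest.approx(1 / 3)
        assert f["TAA"] == pytest.approx(1 / 3)  # stop counted in denominator

    def test_plus1_shift_removal_rule(self):
        # n=9: remove 1-based positions 1,7,8 -> "TGAAAA" -> TGA, AAA
        f = codon_frequencies("ATGAAATAA", frameshift=1)
        assert f["TGA"] == pytest.approx(0.5)
        assert f["AAA"] == pytest.approx(0.5)
        assert f.sum() == pytest.approx(1.0)

    def test_plus2_shift_removal_rule(self):
        # n=9: remove 1-based positions 1,2,8 -> "GAAATA" -> GAA, ATA
        f = codon_frequencies("ATGAAATAA", frameshift=2)
        assert f["GAA"] == pytest.approx(0.5)
        assert f["ATA"] == pytest.approx(0.5)

    @given(st.integers(2, 40), st.integers(0, 2), st.integers(0, 2 ** 31 - 1))
    def test_frequencies_sum_to_one(self, n_codons, shift, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
        assert codon_frequencies(seq, shift).sum() == pytest.approx(1.0)

    def test_bad_length_errors(self):
        with pytest.raises(ValueError, match="not divisible"):
            codon_frequencies("ATGA")


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_ties_against_brute_force_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])

        def brute_ranks(v):
            return np.array([
                sum(1 for z in v if z < xi) + (sum(1 for z in v if z == xi) + 1) / 2
                for xi in v
            ])

        rx, ry = brute_ranks(x), brute_ranks(y)
        rx, ry = rx - rx.mean(), ry - ry.mean()
        expected = (rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry))
        assert spearman(x, y) == pytest.approx(expected)

    def test_na_pairs_dropped(self):
        r = spearman([1, 2, 3, np.nan], [3, 2, 1, 5])
        assert r == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1, np.nan, 3], [1, 2, 3])


def _freq_table(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    df = pd.DataFrame(0.0, index=list(rows), columns=list(SENSE_CODONS) + list(STOP_CODONS))
    for tid, d in rows.items():
        for codon, v in d.items():
            df.loc[tid, codon] = v
    return df


class TestCSC:
    def test_perfect_monotone_codon(self):
        freqs = _freq_table({
            "t1": {"AAA": 0.1, "CCC": 0.9},
            "t2": {"AAA": 0.2, "CCC": 0.8},
            "t3": {"AAA": 0.3, "CCC": 0.7},
        })
        hl = pd.Series({"t1": 1.0, "t2": 5.0, "t3": 9.0})
        with pytest.warns(UserWarning):  # small n + zero-variance codons
            table = compute_csc(freqs, hl)
        assert table.csc["AAA"] == pytest.approx(1.0)
        assert table.csc["CCC"] == pytest.approx(-1.0)

    def test_stop_codons_absent(self):
        rng = np.random.default_rng(0)
        freqs = pd.DataFrame(rng.dirichlet(np.ones(64), size=30),
                             index=[f"t{i}" for i in range(30)],
                             columns=list(SENSE_CODONS) + list(STOP_CODONS))
        hl = pd.Series(rng.uniform(1, 10, 30), index=freqs.index)
        table = compute_csc(freqs, hl)
        assert set(table.csc.index) == set(SENSE_CODONS)
        assert not set(STOP_CODONS) & set(table.csc.index)

    def test_zero_variance_codon_is_na_with_warning(self):
        rng = np.random.default_rng(1)
        freqs = pd.DataFrame(rng.uniform(0, 1, (25, 64)),
                             index=[f"t{i}" for i in range(25)],
                             columns=list(SENSE_CODONS) + list(STOP_CODONS))
        freqs["AAA"] = 0.25
        hl = pd.Series(rng.uniform(1, 10, 25), index=freqs.index)
        with pytest.warns(UserWarning, match="zero-variance"):
            table = compute_csc(freqs, hl)
        assert np.isnan(table.csc["AAA"])

    def test_matches_scipy_per_codon(self):
        """Vectorised rank correlation agrees with independent per-codon scipy calls."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(2)
        freqs = pd.DataFrame(rng.dirichlet(np.ones(64), size=40),
                             index=[f"t{i}" for i in range(40)],
                             columns=list(SENSE_CODONS) + list(STOP_CODONS))
        hl = pd.Series(rng.uniform(0.5, 20, 40), index=freqs.index)
        table = compute_csc(freqs, hl)
        for codon in list(SENSE_CODONS)[::7]:
            ref = spearmanr(freqs[codon], hl).statistic
            assert table.csc[codon] == pytest.approx(ref, abs=1e-12)


class TestAASC:
    def test_two_codon_mean(self):
        rng = np.random.default_rng(3)
        csc = pd.Series(rng.normal(0, 0.2, 61), index=list(SENSE_CODONS))
        csc["AAA"], csc["AAG"] = 0.1, 0.3
        from codonstab.codonstats import CSCTable
        aasc = compute_aasc(CSCTable(csc=csc, n_transcripts=50))
        assert aasc.aasc["K"] == pytest.approx(0.2)  # lysine: AAA, AAG
        assert aasc.aasc["M"] == pytest.approx(csc["ATG"])   # single-codon Met
        assert aasc.aasc["W"] == pytest.approx(csc["TGG"])   # single-codon Trp

    @given(st.lists(st.one_of(st.floats(-1, 1), st.just(float("nan"))),
                    min_size=61, max_size=61))
    def test_identity_holds_for_every_amino_acid(self, values):
        from codonstab.codonstats import CSCTable
        csc = pd.Series(values, index=list(SENSE_CODONS))
        aasc = compute_aasc(CSCTable(csc=csc, n_transcripts=30))
        for aa in AMINO_ACIDS:
            member = csc.loc[list(AA_TO_CODONS[aa])].dropna()
            if len(member):
                assert aasc.aasc[aa] == pytest.approx(member.mean(), nan_ok=True)
            else:
                assert np.isnan(aasc.aasc[aa])


class TestFisherRtoZ:
    def test_equal_correlations(self):
        z, p = fisher_r_to_z(0.5, 50, 0.5, 60)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_hand_evaluation(self):
        z, p = fisher_r_to_z(0.70, 61, 0.32, 61)
        z_hand = (math.atanh(0.70) - math.atanh(0.32)) / math.sqrt(2.0 / 58.0)
        p_hand = math.erfc(abs(z_hand) / math.sqrt(2.0))
        assert z == pytest.approx(z_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-9)

    def test_antisymmetry(self):
        z1, p1 = fisher_r_to_z(0.7, 40, 0.2, 50)
        z2, p2 = fisher_r_to_z(0.2, 50, 0.7, 40)
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_r_to_z(1.0, 10, 0.5, 10)
        with pytest.raises(ValueError):
            fisher_r_to_z(0.5, 3, 0.5, 10)


def test_frequency_table_skips_bad_lengths():
    cds = {"ok": "ATGAAATAA", "bad": "ATGAAAT"}
    with pytest.warns(UserWarning, match="skipped 1"):
        table = frequency_table(cds)
    assert list(table.index) == ["ok"]
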