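"""Folding stub correctness, window scans, exposure analysis."""

from functools import lru_cache

import numpy as np
import pytest

from elmseq.folding import (
    NussinovProvider,
    exposure_compare,
    exposure_profile,
    fold_energy,
    get_provider,
    window_scan,
)
from elmseq.templates import get_template

from conftest import random_seqs

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def _oracle_max_pairs(rna: str) -> int:
    """Independent recursive maximum-pairing count (min loop 3)."""

    @lru_cache(maxsize=None)
    def best(i, j):
        if j - i < 5:
            return 0
        paired = 0
        if (rna[i], rna[j - 1]) in _PAIRS:
            paired = best(i + 1, j - 1) + 1
        split = max(best(i, k) + best(k, j) for k in range(i + 1, j))
        return max(paired, split)

    return best(0, len(rna))


class TestNussinovStub:
    def test_homopolymer_zero_energy(self):
        energy, structure = NussinovProvider().fold("AAAAAAAAAA")
        assert energy == 0.0 and structure == "." * 10

    def test_hairpin_hand_enumeration(self):
        energy, structure = NussinovProvider().fold("GGGGAAAACCCC")
        assert energy == -4.0
        assert structure == "((((....))))"

    def test_matches_recursive_oracle_on_random_sequences(self, rng):
        provider = NussinovProvider()
        for seq in random_seqs(rng, 40, 30):
            rna = seq.replace("T", "U")
            assert fold_energy(seq, provider) == -1.0 * _oracle_max_pairs(rna)

    def test_structure_pair_count_matches_energy(self, rng):
        provider = NussinovProvider()
        for seq in random_seqs(rng, 10, 40):
            energy, structure = provider.fold(seq)
            assert structure.count("(") == -energy
            assert structure.count("(") == structure.count(")")

    def test_energy_monotone_on_nested_windows(self, rng):
        provider = NussinovProvider()
        seq = random_seqs(rng, 1, 60)[0]
        energies = [fold_energy(seq[:n], provider) for n in range(10, 61, 10)]
        assert all(b <= a for a, b in zip(energies, energies[1:]))

    def test_strand_specific(self):
        from elmseq.templates import revcomp

        seq = "GGGAAACCCAAAGGGAAACCC"
        provider = NussinovProvider()
        # no symmetry is assumed between a strand and its reverse complement
        assert isinstance(fold_energy(revcomp(seq), provider), float)

    def test_unknown_provider_errors(self):
        with pytest.raises(ValueError, match="unknown folding provider"):
            get_provider("nupack9000")


class TestWindowScan:
    @pytest.fixture(scope="class")
    def utr_library(self):
        rng = np.random.default_rng(77)
        template = get_template("utr_strong")
        variants = random_seqs(rng, 150, 25)
        mrnas = [template.mrna(v) for v in variants]
        return rng, template, variants, mrnas

    def test_independent_ratios_give_weak_correlations(self, utr_library):
        rng, _, _, mrnas = utr_library
        ratios = rng.normal(0, 1, len(mrnas))
        scan = window_scan(
            mrnas, ratios, start_range=(-25, -20), end_range=(10, 15),
        )
        valid = scan.table.dropna(subset=["r"])
        assert valid.r.abs().max() < 0.35  # n=150 null fluctuation scale

    def test_planted_window_recovered(self, utr_library):
        rng, _, _, mrnas = utr_library
        provider = NussinovProvider()

        def dg(start, end):
            i0, i1 = 26 + start, 26 + end - 1 + 1
            return provider.fold_many([m[i0:i1] for m in mrnas])

        ratios = -dg(-25, 30) + rng.normal(0, 0.3, len(mrnas))
        scan = window_scan(
            mrnas, ratios, start_range=(-26, -23), end_range=(28, 32),
        )
        assert (scan.best_start, scan.best_end) == (-25, 30)
        assert scan.best_r < -0.8

    def test_out_of_range_windows_na(self, utr_library):
        _, _, _, mrnas = utr_library
        scan = window_scan(
            mrnas[:5], np.arange(5.0), start_range=(-26, -26),
            end_range=(195, 200),
        )
        assert scan.table.r.isna().all()

    def test_shift_invariance_of_correlations(self, utr_library):
        rng, _, _, mrnas = utr_library
        ratios = rng.normal(0, 1, len(mrnas))
        s1 = window_scan(mrnas, ratios, (-25, -24), (10, 12))
        s2 = window_scan(mrnas, ratios + 100.0, (-25, -24), (10, 12))
        assert np.allclose(
            s1.table.r.dropna(), s2.table.r.dropna(), atol=1e-12
        )

    def test_too_few_variants_rejected(self, utr_library):
        _, _, _, mrnas = utr_library
        with pytest.raises(ValueError, match="at least 3"):
            window_scan(mrnas[:1], [1.0], (-25, -25), (10, 10))


class TestExposure:
    def test_all_dots_all_exposed(self):
        assert exposure_profile("ACGU", "....").all()

    def test_hairpin_reading(self):
        exposed = exposure_profile("GGGGAAAACCCC", "((((....))))")
        assert not exposed[:4].any() and not exposed[8:].any()
        assert exposed[4:8].all()

    def test_profile_matches_bracket_oracle(self, rng):
        provider = NussinovProvider()
        for seq in random_seqs(rng, 10, 30):
            _, structure = provider.fold(seq)
            exposed = exposure_profile(seq, structure)
            assert np.array_equal(
                exposed, np.array([c == "." for c in structure])
            )

    def test_unbalanced_structure_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            exposure_profile("ACGU", "((..")
        with pytest.raises(ValueError, match="unbalanced"):
            exposure_profile("ACGU", "..))")

    def test_identical_sets_zero_enrichment(self, rng):
        provider = NussinovProvider()
        seqs = random_seqs(rng, 30, 25)
        folds = [provider.fold(s) for s in seqs]
        dg = np.array([f[0] for f in folds])
        structs = [f[1] for f in folds]
        out = exposure_compare((dg, structs), (dg.copy(), list(structs)))
        assert np.allclose(out.log2_exposure_enrichment, 0.0)

    def test_planted_unpaired_rule_enriched(self, rng):
        """High set forced unpaired at the last 4 positions stands out."""
        provider = NussinovProvider()
        seqs = random_seqs(rng, 120, 25)
        folds = [provider.fold(s) for s in seqs]
        dg = np.array([f[0] for f in folds])
        structs = [f[1] for f in folds]
        exposed_tail = np.array(
            [all(c == "." for c in s[-4:]) for s in structs]
        )
        high = (dg[exposed_tail], [s for s, m in zip(structs, exposed_tail) if m])
        low = (dg[~exposed_tail], [s for s, m in zip(structs, exposed_tail) if not m])
        out = exposure_compare(high, low)
        tail_mean = out.log2_exposure_enrichment.tail(4).mean()
        head_mean = out.log2_exposure_enrichment.head(21).mean()
        assert tail_mean > 0 and tail_mean > head_mean

    def test_infinite_bin_width_equals_unstratified(self, rng):
        provider = NussinovProvider()
        seqs = random_seqs(rng, 40, 25)
        folds = [provider.fold(s) for s in seqs]
        dg = np.array([f[0] for f in folds])
        structs = [f[1] for f in folds]
        high = (dg[:20], structs[:20])
        low = (dg[20:], structs[20:])
        wide = exposure_compare(high, low, bin_width=1e6)
        f_hi = np.stack([[c == "." for c in s] for s in structs[:20]]).sum(0)
        f_lo = np.stack([[c == "." for c in s] for s in structs[20:]]).sum(0)
        expected = np.log2(((f_hi + 0.5) / 21) / ((f_lo + 0.5) / 21))
        assert np.allclose(wide.log2_exposure_enrichment, expected)
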