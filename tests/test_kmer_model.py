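import itertools

import numpy as np
import pytest

from xnapore import (ExtendedSequence, all_kmers, diff_ideal,
                     generate_synthetic_table, ideal_level_series)
from xnapore.kmer_model import KmerCurrentTable, affected_level_range


def brute_force_window_currents(residues, table, enzyme_mode):
    """Oracle: scan windows directly, interleaving means for half steps."""
    k = table.k
    full = [table.current(residues[i:i + k])
            for i in range(len(residues) - k + 1)]
    if enzyme_mode == "phi29":
        return full
    out = []
    for i, c in enumerate(full):
        out.append(c)
        if i < len(full) - 1:
            out.append(0.5 * (c + full[i + 1]))
    return out


class TestTableGeneration:
    @pytest.mark.parametrize("k,expected", [(4, 1296), (1, 6), (2, 36)])
    def test_completeness(self, k, expected):
        table = generate_synthetic_table(seed=0, k=k)
        assert len(table) == expected
        assert set(table.entries) == set(all_kmers(k))

    def test_deterministic_serialization(self, tmp_path):
        a, b, c = tmp_path / "a.tsv", tmp_path / "b.tsv", tmp_path / "c.tsv"
        generate_synthetic_table(seed=5).to_tsv(a)
        generate_synthetic_table(seed=5).to_tsv(b)
        generate_synthetic_table(seed=6).to_tsv(c)
        assert a.read_bytes() == b.read_bytes()
        assert a.read_bytes() != c.read_bytes()

    def test_q_exceeds_its_homolog_by_offset_per_q(self, table4):
        rng = np.random.default_rng(1)
        kmers = [km for km in table4.entries if "Q" in km]
        for km in rng.choice(kmers, size=40, replace=False):
            homolog = km.replace("Q", "C")
            gap = table4.entries[km] - table4.entries[homolog]
            assert gap == pytest.approx(15.0 * km.count("Q"))
            assert gap > 0

    def test_z_offsets_have_mixed_signs(self, table4):
        shifts = [
            table4.entries[km] - table4.entries[km.replace("Z", "C")]
            for km in table4.entries
            if "Z" in km and "Q" not in km
        ]
        assert any(s > 0 for s in shifts) and any(s < 0 for s in shifts)
        mags = np.abs(shifts)
        assert mags.min() >= 5.0 - 1e-9 and mags.max() <= 15.0 + 1e-9

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_synthetic_table(seed=0, k=0)
        with pytest.raises(ValueError):
            generate_synthetic_table(seed=0, q_offset=-1.0)
        with pytest.raises(ValueError):
            generate_synthetic_table(seed=0, base_range=(30.0, 30.0))

    def test_tsv_round_trip(self, table4, tmp_path):
        path = tmp_path / "t.tsv"
        table4.to_tsv(path)
        back = KmerCurrentTable.from_tsv(path)
        assert back.k == table4.k
        assert back.abasic_current == table4.abasic_current
        assert back.entries == pytest.approx(table4.entries)

    def test_incomplete_table_rejected(self, table4):
        entries = dict(table4.entries)
        entries.pop("AAAA")
        with pytest.raises(ValueError):
            KmerCurrentTable(4, entries, current_range=table4.current_range)


class TestIdealSeries:
    def test_single_window(self, table4):
        steps = ideal_level_series(ExtendedSequence("s", "ACGT"), table4)
        assert len(steps) == 1
        assert steps.currents[0] == table4.entries["ACGT"]

    def test_too_short_rejected(self, table4):
        with pytest.raises(ValueError):
            ideal_level_series(ExtendedSequence("s", "ACG"), table4)

    def test_level_counts(self, table4, context_seq):
        phi = ideal_level_series(context_seq, table4, "phi29")
        hel = ideal_level_series(context_seq, table4, "hel308")
        L = len(context_seq)
        assert len(phi) == L - 4 + 1
        assert len(hel) == 2 * (L - 4 + 1) - 1
        assert phi.phases == ("full",) * len(phi)
        assert hel.phases[0::2] == ("full",) * (len(phi))
        assert hel.phases[1::2] == ("half",) * (len(phi) - 1)

    def test_half_levels_interpolate(self, table4, context_seq):
        hel = ideal_level_series(context_seq, table4, "hel308")
        full = hel.currents[0::2]
        half = hel.currents[1::2]
        np.testing.assert_allclose(half, 0.5 * (full[:-1] + full[1:]))

    def test_abasic_override(self, table4):
        steps = ideal_level_series(ExtendedSequence("s", "ACXGTC"), table4)
        # windows 1-3 cover the X at position 3
        assert all(c == table4.abasic_current for c in steps.currents[:3])

    def test_matches_brute_force_scanner(self, table4, context_seq):
        for mode in ("phi29", "hel308"):
            steps = ideal_level_series(context_seq, table4, mode)
            oracle = brute_force_window_currents(context_seq.residues, table4, mode)
            np.testing.assert_allclose(steps.currents, oracle)

    def test_hel308_temporal_order_reversed(self, steps_hel308, steps_phi29):
        np.testing.assert_array_equal(
            steps_hel308.temporal_currents(), steps_hel308.currents[::-1])
        np.testing.assert_array_equal(
            steps_phi29.temporal_currents(), steps_phi29.currents)


class TestSubstitutionFootprint:
    def test_interior_footprints(self, table4, context_seq):
        variant = context_seq.substitute(15, "Q")
        for mode, expected in (("phi29", 4), ("hel308", 9)):
            d = diff_ideal(ideal_level_series(variant, table4, mode),
                           ideal_level_series(context_seq, table4, mode))
            nz = [i for i, delta in d if abs(delta) > 1e-9]
            assert len(nz) == expected
            assert nz == list(range(nz[0], nz[0] + expected))

    def test_q_for_c_offset_value(self, table4, context_seq):
        assert context_seq[15] == "C"
        variant = context_seq.substitute(15, "Q")
        d = diff_ideal(ideal_level_series(variant, table4),
                       ideal_level_series(context_seq, table4))
        nz = [(i, delta) for i, delta in d if abs(delta) > 1e-9]
        assert [i for i, _ in nz] == [12, 13, 14, 15]
        assert all(delta == pytest.approx(15.0) for _, delta in nz)

    def test_antisymmetry_and_self_difference(self, table4, context_seq):
        variant = context_seq.substitute(15, "Z")
        a = ideal_level_series(variant, table4)
        b = ideal_level_series(context_seq, table4)
        ab = diff_ideal(a, b)
        ba = diff_ideal(b, a)
        assert all(x == pytest.approx(-y) for (_, x), (_, y) in zip(ab, ba))
        assert all(x == 0 for _, x in diff_ideal(a, a))

    def test_mode_and_length_mismatch(self, table4, context_seq):
        phi = ideal_level_series(context_seq, table4, "phi29")
        hel = ideal_level_series(context_seq, table4, "hel308")
        with pytest.raises(ValueError):
            diff_ideal(phi, hel)
        short = ideal_level_series(
            ExtendedSequence("s", context_seq.residues[:20]), table4)
        with pytest.raises(ValueError):
            diff_ideal(phi, short)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_footprint_size_exhaustive_small_k(self, k):
        """Every substitution changes min(k, #covering windows) levels,
        verified against a brute-force window scanner."""
        table = generate_synthetic_table(seed=3, k=k)
        rng = np.random.default_rng(k)
        letters = "ACGTZQ"
        for _ in range(25):
            L = int(rng.integers(k, 9))
            residues = "".join(rng.choice(list(letters), size=L))
            seq = ExtendedSequence("s", residues)
            base = brute_force_window_currents(residues, table, "phi29")
            for pos in range(1, L + 1):
                new = rng.choice([c for c in letters if c != seq[pos]])
                var = seq.substitute(pos, new)
                d = diff_ideal(ideal_level_series(var, table),
                               ideal_level_series(seq, table))
                nz = [i for i, delta in d if abs(delta) > 1e-9]
                lo, hi = affected_level_range(pos, k, L, "phi29")
                # every changed level lies in the covering-window range; all
                # covering windows change unless two k-mers collide by value
                assert set(nz) <= set(range(lo, hi + 1))
                var_oracle = brute_force_window_currents(var.residues, table,
                                                         "phi29")
                expected_nz = [i + 1 for i, (x, y) in
                               enumerate(zip(var_oracle, base))
                               if abs(x - y) > 1e-9]
                assert nz == expected_nz


def test_affected_level_range_interior_and_edges():
    assert affected_level_range(15, 4, 30, "phi29") == (12, 15)
    assert affected_level_range(1, 4, 30, "phi29") == (1, 1)
    assert affected_level_range(30, 4, 30, "phi29") == (27, 27)
    lo, hi = affected_level_range(15, 4, 30, "hel308")
    assert hi - lo + 1 == 9
    with pytest.raises(ValueError):
        affected_level_range(0, 4, 30, "phi29")


def test_hel308_level_count_matches_enumeration():
    """2(L-k+1)-1 for L=24, k=4 equals a direct enumeration of interleaved
    full/half windows."""
    table = generate_synthetic_table(seed=0)
    seq = ExtendedSequence("s", ("ACGT" * 6))
    assert len(seq) == 24
    hel = ideal_level_series(seq, table, "hel308")
    n_windows = len(seq) - 4 + 1
    enumerated = list(itertools.chain.from_iterable(
        (("full", i), ("half", i)) for i in range(1, n_windows)))
    enumerated.append(("full", n_windows))
    assert len(hel) == len(enumerated) == 41
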