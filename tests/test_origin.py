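import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boamap import (
    assign_origins,
    b_value,
    build_windows,
    classify_diplotype,
    classify_haplotype,
    encode_haplotypes,
    hamming_fallback,
    indicus_percentage,
    reference_frequencies,
)


class TestBValue:
    @pytest.mark.parametrize(
        "p_bi,p_bt,expected",
        [(0.5, 0.5, 0.5), (0.09, 0.0, 1.0), (0.02, 0.08, 0.2), (0.0, 0.3, 0.0)],
    )
    def test_ratio(self, p_bi, p_bt, expected):
        assert b_value(p_bi, p_bt) == pytest.approx(expected)

    def test_unseen_variant_signals_fallback(self):
        with pytest.raises(ZeroDivisionError, match="fallback"):
            b_value(0.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(0.001, 1.0),
        st.floats(0.001, 1.0),
        st.floats(0.01, 100.0),
    )
    def test_classification_invariant_to_scaling(self, p_bi, p_bt, scale):
        assert classify_haplotype(b_value(p_bi, p_bt)) == classify_haplotype(
            b_value(p_bi * scale, p_bt * scale)
        )


class TestClassify:
    @pytest.mark.parametrize("b,expected", [(0.5, "Bi"), (0.4999, "Bt"), (1.0, "Bi"), (0.0, "Bt")])
    def test_threshold_with_tie_to_indicus(self, b, expected):
        assert classify_haplotype(b) == expected

    @pytest.mark.parametrize(
        "o0,o1,expected",
        [("Bi", "Bi", "Bi"), ("Bi", "Bt", "Bx"), ("Bt", "Bi", "Bx"), ("Bt", "Bt", "Bt")],
    )
    def test_diplotype(self, o0, o1, expected):
        assert classify_diplotype(o0, o1) == expected


class TestHammingFallback:
    def test_as_printed_follows_printed_equations(self):
        # sum(Bi)=0, sum(Bt)=2 -> Prob(Bi)=0/(0+2)=0, allocated to the
        # larger probability, i.e. Bt
        p_bi, p_bt, assigned = hamming_fallback(0b00, {0b00: 2}, {0b11: 1}, "as_printed")
        assert (p_bi, p_bt) == (0.0, 1.0)
        assert assigned == "Bt"

    def test_similarity_mode_prefers_nearer_subspecies(self):
        p_bi, p_bt, assigned = hamming_fallback(0b00, {0b00: 2}, {0b11: 1}, "similarity")
        assert assigned == "Bi"
        assert p_bi == pytest.approx(1.0)

    def test_tie_assigns_indicus(self):
        p_bi, p_bt, assigned = hamming_fallback(0b01, {0b00: 1}, {0b11: 1}, "as_printed")
        assert p_bi == pytest.approx(0.5) and p_bt == pytest.approx(0.5)
        assert assigned == "Bi"

    def test_multiplicity_weights_distances(self):
        # sum over COPIES: Bi = 3 copies at distance 1 -> 3; Bt = 1 copy at 2
        p_bi, _, _ = hamming_fallback(0b00, {0b01: 3}, {0b11: 1}, "as_printed")
        assert p_bi == pytest.approx(3 / 5)

    def test_panel_size_normalisation(self):
        # same mean distance per copy, unequal panel sizes
        p_bi, p_bt, _ = hamming_fallback(
            0b00, {0b01: 8}, {0b01: 2}, "as_printed", normalise=True
        )
        assert p_bi == pytest.approx(0.5) and p_bt == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            hamming_fallback(0, {}, {1: 1})
        with pytest.raises(ValueError):
            hamming_fallback(0, {1: 1}, {1: 1}, mode="bogus")

    def test_similarity_agrees_with_nearest_centroid_for_unanimous_panel(self):
        # Bi panel unanimous at 0b1111; any query closer to it than to the
        # Bt panel mean must be assigned Bi
        rng = np.random.default_rng(4)
        for _ in range(25):
            query = int(rng.integers(0, 16))
            refs_bt = {int(c): 1 for c in rng.integers(0, 16, size=5)}
            _, _, assigned = hamming_fallback(query, {0b1111: 10}, refs_bt, "similarity")
            d_bi = bin(query ^ 0b1111).count("1")
            d_bt = np.mean([bin(query ^ c).count("1") for c in refs_bt])
            expected = "Bi" if d_bi <= d_bt else "Bt"
            assert assigned == expected


class TestAssignOrigins:
    def brute_force(self, target_codes, ft, mode):
        """Exhaustive per-haplotype reimplementation used as the oracle."""
        n, k, _ = target_codes.shape
        out = np.zeros((n, k, 2), dtype=np.uint8)
        for a in range(n):
            for w in range(k):
                for c in (0, 1):
                    code = int(target_codes[a, w, c])
                    p_bi, p_bt = ft.freqs(w, code)
                    if p_bi + p_bt > 0:
                        call = "Bi" if p_bi / (p_bi + p_bt) >= 0.5 else "Bt"
                    else:
                        refs_bi = {c2: n2[0] for c2, n2 in ft.tables[w].items() if n2[0]}
                        refs_bt = {c2: n2[1] for c2, n2 in ft.tables[w].items() if n2[1]}
                        _, _, call = hamming_fallback(code, refs_bi, refs_bt, mode)
                    out[a, w, c] = 1 if call == "Bi" else 0
        return out

    @pytest.mark.parametrize("mode", ["as_printed", "similarity"])
    def test_matches_exhaustive_oracle(self, small_study, mode):
        ws = build_windows(small_study.pools.map, 100)
        ft = reference_frequencies(
            encode_haplotypes(small_study.reference, ws),
            small_study.reference.animal_ids,
            small_study.labels,
            ws,
        )
        codes = encode_haplotypes(small_study.targets.subset_animals(
            small_study.targets.animal_ids[:8]), ws)
        calls = assign_origins(codes, small_study.targets.animal_ids[:8], ft, mode=mode)
        assert np.array_equal(calls.hap_origin, self.brute_force(codes, ft, mode))

    def test_diplotypes_consistent_with_haplotype_calls(self, small_study):
        ws = build_windows(small_study.pools.map, 100)
        ft = reference_frequencies(
            encode_haplotypes(small_study.reference, ws),
            small_study.reference.animal_ids,
            small_study.labels,
            ws,
        )
        tgt = small_study.targets.subset_animals(small_study.targets.animal_ids[:10])
        calls = assign_origins(encode_haplotypes(tgt, ws), tgt.animal_ids, ft)
        dip = calls.diplotypes()
        for a in range(calls.n_animals):
            for k in range(ws.n_windows):
                expected = classify_diplotype(
                    "Bi" if calls.hap_origin[a, k, 0] else "Bt",
                    "Bi" if calls.hap_origin[a, k, 1] else "Bt",
                )
                assert dip[a, k] == expected == calls.diplotype(a, k)

    def test_provenance_marks_fallback(self, small_study):
        ws = build_windows(small_study.pools.map, 100)
        ft = reference_frequencies(
            encode_haplotypes(small_study.reference, ws),
            small_study.reference.animal_ids,
            small_study.labels,
            ws,
        )
        tgt = small_study.targets.subset_animals(small_study.targets.animal_ids[:10])
        calls = assign_origins(encode_haplotypes(tgt, ws), tgt.animal_ids, ft)
        seen = calls.source == "frequency"
        for a, k, c in zip(*np.where(seen)):
            p_bi, p_bt = ft.freqs(k, int(encode_haplotypes(tgt, ws)[a, k, c]))
            assert p_bi + p_bt > 0
        assert 0.0 <= calls.fallback_fraction() <= 1.0


class TestIndicusPercentage:
    def test_extremes(self, small_study):
        ws = build_windows(small_study.pools.map, 100)
        ft = reference_frequencies(
            encode_haplotypes(small_study.reference, ws),
            small_study.reference.animal_ids,
            small_study.labels,
            ws,
        )
        tgt = small_study.targets.subset_animals(small_study.targets.animal_ids[:4])
        calls = assign_origins(encode_haplotypes(tgt, ws), tgt.animal_ids, ft)
        calls.hap_origin[:] = 1
        pct, _ = indicus_percentage(calls)
        assert (pct == 100.0).all()
        calls.hap_origin[:, :, 1] = 0
        pct, _ = indicus_percentage(calls)
        assert (pct == 50.0).all()
        # constant per-window calls make SNP weighting irrelevant
        pct_snp, _ = indicus_percentage(calls, weighting="per_snp")
        assert np.allclose(pct_snp, 50.0)

    def test_per_breed_summary(self, small_study):
        ws = build_windows(small_study.pools.map, 100)
        ft = reference_frequencies(
            encode_haplotypes(small_study.reference, ws),
            small_study.reference.animal_ids,
            small_study.labels,
            ws,
        )
        calls = assign_origins(
            encode_haplotypes(small_study.targets, ws),
            small_study.targets.animal_ids,
            ft,
            mode="similarity",
        )
        _, per_breed = indicus_percentage(calls, breeds=small_study.truth.breed_of)
        assert set(per_breed.index) == {p.name for p in small_study.config.breed_profiles}
        assert set(per_breed.columns) == {"mean", "sd", "min", "max"}

    def test_unknown_weighting_rejected(self, small_study):
        ws = build_windows(small_study.pools.map, 100)
        ft = reference_frequencies(
            encode_haplotypes(small_study.reference, ws),
            small_study.reference.animal_ids,
            small_study.labels,
            ws,
        )
        tgt = small_study.targets.subset_animals(small_study.targets.animal_ids[:2])
        calls = assign_origins(encode_haplotypes(tgt, ws), tgt.animal_ids, ft)
        with pytest.raises(ValueError):
            indicus_percentage(calls, weighting="bogus")
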