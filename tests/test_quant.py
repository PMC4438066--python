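"""Peak matching, molarity, purity and PSI quantification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescreen.quant import (
    AseAssay,
    PeakRecord,
    compute_psi,
    compute_purity,
    match_peaks,
    peak_molarity,
    quantify_assay,
    size_tolerance,
)


class TestPeakMolarity:
    @pytest.mark.parametrize(
        "size,conc,expected",
        [(200, 100, 0.5), (400, 100, 0.25), (200, 0, 0.0), (123.5, 61.75, 0.5)],
    )
    def test_mass_over_length(self, size, conc, expected):
        assert peak_molarity(PeakRecord(size, conc)) == pytest.approx(expected)

    def test_equal_mass_at_double_length_halves_molarity(self):
        """Equal conc at 200 and 400 nt gives a 2:1 molar ratio."""
        m200 = peak_molarity(PeakRecord(200, 50.0))
        m400 = peak_molarity(PeakRecord(400, 50.0))
        assert m200 / m400 == pytest.approx(2.0)

    def test_non_positive_size_rejected(self):
        with pytest.raises(ValueError):
            PeakRecord(0, 10.0)
        with pytest.raises(ValueError):
            PeakRecord(-5, 10.0)


class TestMatchPeaks:
    def test_within_3_percent_matches(self, assay):
        peaks = [PeakRecord(202, 10.0), PeakRecord(300, 10.0)]
        a = match_peaks(peaks, assay)
        assert a.short == 0 and a.long == 1 and a.unmatched == []

    def test_peak_outside_both_windows_unmatched(self, assay):
        # 260 nt vs expected {200, 300}: outside max(2, 3%) of either
        peaks = [PeakRecord(260, 10.0)]
        a = match_peaks(peaks, assay)
        assert a.short is None and a.long is None and a.unmatched == [0]

    def test_equidistant_tie_goes_to_smaller_size(self, assay):
        peaks = [PeakRecord(199, 5.0), PeakRecord(201, 5.0)]
        a = match_peaks(peaks, assay)
        assert a.short == 0
        assert 1 in a.unmatched

    def test_each_expected_size_takes_nearest(self, assay):
        peaks = [PeakRecord(205, 1.0), PeakRecord(201, 1.0), PeakRecord(299, 1.0)]
        a = match_peaks(peaks, assay)
        assert a.short == 1 and a.long == 2 and a.unmatched == [0]

    def test_tolerance_is_max_of_absolute_and_relative(self):
        assert size_tolerance(50) == 2.0  # 3% of 50 = 1.5 < 2 nt
        assert size_tolerance(200) == pytest.approx(6.0)


class TestPurityAndPsi:
    def test_only_expected_peaks_purity_one(self, assay):
        peaks = [PeakRecord(200, 10.0), PeakRecord(300, 15.0)]
        a = match_peaks(peaks, assay)
        assert compute_purity(a, peaks) == pytest.approx(1.0)

    def test_spurious_peak_dilutes_purity(self, assay):
        # matched molarity 2 + 2, spurious molarity 2 -> 4/6
        peaks = [PeakRecord(200, 400.0), PeakRecord(300, 600.0), PeakRecord(500, 1000.0)]
        a = match_peaks(peaks, assay)
        assert compute_purity(a, peaks) == pytest.approx(4 / 6)

    def test_no_matched_peaks_purity_zero(self, assay):
        peaks = [PeakRecord(500, 10.0)]
        a = match_peaks(peaks, assay)
        assert compute_purity(a, peaks) == pytest.approx(0.0)

    def test_zero_total_molarity_undefined(self, assay):
        peaks = [PeakRecord(200, 0.0)]
        a = match_peaks(peaks, assay)
        assert compute_purity(a, peaks) is None

    @pytest.mark.parametrize(
        "long,short,expected",
        [(1.0, 1.0, 50.0), (0.0, 3.7, 0.0), (3.0, 1.0, 75.0), (2.5, 0.0, 100.0)],
    )
    def test_psi_values(self, long, short, expected):
        assert compute_psi(long, short) == pytest.approx(expected)

    def test_psi_undefined_when_both_zero(self):
        assert compute_psi(0.0, 0.0) is None


class TestQuantifyAssay:
    def test_clean_lane_passes(self, assay):
        # equal molarity at both products: conc proportional to size
        peaks = [PeakRecord(200, 200.0), PeakRecord(300, 300.0)]
        r = quantify_assay(peaks, assay, sample_id="brain")
        assert r.purity == pytest.approx(1.0)
        assert r.psi == pytest.approx(50.0)
        assert r.qc_pass

    def test_thirty_percent_contamination_fails_gate(self, assay):
        # spurious peak carrying 30% of lane molarity -> purity 0.70
        peaks = [
            PeakRecord(200, 200.0 * 0.35),
            PeakRecord(300, 300.0 * 0.35),
            PeakRecord(450, 450.0 * 0.30),
        ]
        r = quantify_assay(peaks, assay)
        assert r.purity == pytest.approx(0.70)
        assert not r.qc_pass
        assert r.psi == pytest.approx(50.0)  # psi still defined, just not trusted

    def test_purity_exactly_at_threshold_fails(self, assay):
        # strict ">": exactly 75% must not pass
        peaks = [
            PeakRecord(200, 200.0 * 0.375),
            PeakRecord(300, 300.0 * 0.375),
            PeakRecord(450, 450.0 * 0.25),
        ]
        r = quantify_assay(peaks, assay)
        assert r.purity == pytest.approx(0.75)
        assert not r.qc_pass

    def test_single_band_lane_is_fully_switched_not_undefined(self, assay):
        r = quantify_assay([PeakRecord(300, 30.0)], assay)
        assert r.psi == pytest.approx(100.0)
        assert r.qc_pass
        r = quantify_assay([PeakRecord(200, 20.0)], assay)
        assert r.psi == pytest.approx(0.0)

    def test_empty_lane_undefined(self, assay):
        r = quantify_assay([], assay)
        assert r.psi is None and not r.qc_pass


@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    concs=st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=2, max_size=5),
)
@settings(max_examples=50, deadline=None)
def test_psi_and_purity_invariant_under_concentration_scaling(scale, concs):
    """Multiplying all concentrations by c > 0 changes neither purity nor PSI."""
    assay = AseAssay("A", "G", "mouse", "cassette", 200, 300)
    sizes = [200, 300, 451, 97, 620][: len(concs)]
    base = [PeakRecord(s, c) for s, c in zip(sizes, concs)]
    scaled = [PeakRecord(s, c * scale) for s, c in zip(sizes, concs)]
    r0 = quantify_assay(base, assay)
    r1 = quantify_assay(scaled, assay)
    assert r1.purity == pytest.approx(r0.purity)
    if r0.psi is None:
        assert r1.psi is None
    else:
        assert r1.psi == pytest.approx(r0.psi)


def test_adding_unmatched_peak_strictly_decreases_purity(assay):
    peaks = [PeakRecord(200, 100.0), PeakRecord(300, 100.0)]
    r0 = quantify_assay(peaks, assay)
    for spur_size, spur_conc in [(500, 1.0), (120, 50.0), (260, 0.5)]:
        r1 = quantify_assay(peaks + [PeakRecord(spur_size, spur_conc)], assay)
        assert r1.purity < r0.purity


# --------------------------------------------------------------- brute force

def _oracle_quantify(peaks, assay):
    """Enumerate injective peak->{short,long} assignments and keep the unique
    one consistent with the nearest-match rule, then recompute purity/psi
    from raw sums."""
    idx = range(len(peaks))
    candidates = []
    for s_i, l_i in itertools.product([None, *idx], repeat=2):
        if s_i is not None and l_i is not None and s_i == l_i:
            continue
        candidates.append((s_i, l_i))

    def in_tol(i, expected):
        return abs(peaks[i].size_nt - expected) <= max(2.0, 0.03 * expected)

    def nearest(pool, expected):
        pool = [i for i in pool if in_tol(i, expected)]
        if not pool:
            return None
        return min(pool, key=lambda i: (abs(peaks[i].size_nt - expected), peaks[i].size_nt))

    valid = []
    for s_i, l_i in candidates:
        if s_i != nearest(idx, assay.size_short_nt):
            continue
        rest = [i for i in idx if i != s_i]
        if l_i != nearest(rest, assay.size_long_nt):
            continue
        valid.append((s_i, l_i))
    assert len(valid) == 1
    s_i, l_i = valid[0]
    mol = [p.conc / p.size_nt for p in peaks]
    matched = sum(mol[i] for i in (s_i, l_i) if i is not None)
    total = sum(mol)
    purity = matched / total if total > 0 else None
    ml = mol[l_i] if l_i is not None else 0.0
    ms = mol[s_i] if s_i is not None else 0.0
    psi = 100 * ml / (ml + ms) if ml + ms > 0 else None
    return purity, psi


def test_quantification_matches_bruteforce_on_small_instances(assay):
    """On every random <=5-peak lane, purity and PSI equal an exhaustive
    enumeration of peak assignments respecting the nearest-match rule."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = rng.integers(1, 6)
        sizes = rng.uniform(50, 700, size=n)
        # sometimes drop peaks right onto the expected sizes
        for j in range(n):
            if rng.random() < 0.5:
                target = assay.size_short_nt if rng.random() < 0.5 else assay.size_long_nt
                sizes[j] = target + rng.uniform(-8, 8)
        concs = rng.uniform(0.1, 50.0, size=n)
        peaks = [PeakRecord(float(s), float(c)) for s, c in zip(sizes, concs)]
        r = quantify_assay(peaks, assay)
        purity, psi = _oracle_quantify(peaks, assay)
        assert r.purity == pytest.approx(purity)
        if psi is None:
            assert r.psi is None
        else:
            assert r.psi == pytest.approx(psi)
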