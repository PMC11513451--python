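"""Relative cut frequency: averaging, ratios, per-site summation, classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prolysis import (
    ANXA1_CLASS_EDGES,
    MDH_CLASS_EDGES,
    FilterConfig,
    PeptideMeasurement,
    SubstrateProtein,
    average_intensities,
    classify_sites,
    cut_histogram,
    cumulative_site_counts,
    intensity_ratios,
    relative_cut_frequency,
)
from prolysis.cut_frequency import SiteProfile, supported_bonds

SUB = SubstrateProtein(id="s", sequence="ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKL")


def measurement(start, end, block, control=None, pid=None):
    return PeptideMeasurement(
        peptide_id=pid or f"s{start}_e{end}",
        peptide_sequence=SUB.sequence[start - 1 : end],
        start=start,
        end=end,
        score=100.0,
        intensities=np.asarray(block, float),
        control_intensities=None if control is None else np.asarray(control, float),
    )


class TestAverageIntensities:
    def test_plain_mean_when_significant(self):
        m = measurement(5, 12, [[100.0] * 3] * 4, control=[[0.0] * 3] * 4)
        np.testing.assert_array_equal(
            average_intensities(m), [100.0, 100.0, 100.0]
        )

    def test_zero_fill_mean(self):
        m = measurement(5, 12, [[200, 200], [0, 0], [200, 200], [0, 0]],
                        control=[[0, 0]] * 4)
        np.testing.assert_array_equal(average_intensities(m), [100.0, 100.0])

    def test_not_significant_set_to_zero(self):
        # digest not enriched over control -> averages zeroed
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(5, 0.1, (4, 2)))
        ctrl = np.exp(rng.normal(7, 0.1, (4, 2)))
        m = measurement(5, 12, vals, control=ctrl)
        np.testing.assert_array_equal(average_intensities(m), [0.0, 0.0])

    def test_explicit_significance_override(self):
        m = measurement(5, 12, [[10.0, 10.0]] * 4)
        out = average_intensities(m, significance=[True, False])
        np.testing.assert_array_equal(out, [10.0, 0.0])


class TestIntensityRatios:
    @pytest.mark.parametrize(
        "avgs,expected",
        [
            ([0, 100, 200, 100], [0, 1, 2, 1]),
            ([50, 50, 0], [1, 1, 0]),
            ([0, 0, 0], [0, 0, 0]),
        ],
    )
    def test_reference_is_first_nonzero(self, avgs, expected):
        np.testing.assert_allclose(intensity_ratios(np.array(avgs, float)), expected)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(1e-3, 1e6)),
            min_size=1,
            max_size=12,
        ),
        st.floats(1e-2, 1e2),
    )
    def test_scale_invariance(self, avgs, c):
        """Multiplying a peptide's intensities by a constant leaves its
        ratio series unchanged."""
        a = np.asarray(avgs)
        np.testing.assert_allclose(
            intensity_ratios(a * c), intensity_ratios(a), rtol=1e-9, atol=1e-12
        )


class TestRelativeCutFrequency:
    TP = [0.0, 10.0, 20.0]

    def test_worked_example_two_peptides_one_site(self):
        """Two peptides ending at the same P1 with ratio series [0,1,2]
        and [1,1,0] give the site profile [1,2,2]."""
        m1 = measurement(1, 41, [[0.0] * 3], pid="a")
        m2 = measurement(30, 41, [[0.0] * 3], pid="b")
        profiles = relative_cut_frequency(
            [m1, m2],
            SUB,
            self.TP,
            ratios_by_peptide={"a": np.array([0, 1, 2.0]), "b": np.array([1, 1, 0.0])},
        )
        site41 = next(p for p in profiles if p.p1 == 41)
        np.testing.assert_allclose(site41.frequencies, [1, 2, 2])

    def test_peptide_supports_both_bounding_bonds(self):
        m = measurement(10, 20, [[5.0, 5.0, 5.0]] * 2)
        assert supported_bonds(m, SUB.length) == [9, 20]
        assert supported_bonds(m, SUB.length, c_terminal_only=True) == [20]
        m_nterm = measurement(1, 20, [[5.0] * 3] * 2)
        assert supported_bonds(m_nterm, SUB.length) == [20]
        m_cterm = measurement(30, 50, [[5.0] * 3] * 2)
        assert supported_bonds(m_cterm, SUB.length) == [29]

    def test_all_zero_sites_omitted(self):
        m = measurement(10, 20, [[0.0] * 3] * 4)
        assert relative_cut_frequency([m], SUB, self.TP) == []

    def test_matches_bruteforce_triple_enumeration(self):
        rng = np.random.default_rng(1)
        ms = []
        for i in range(100):
            s = int(rng.integers(1, 40))
            e = int(rng.integers(s, min(s + 12, 50)))
            block = rng.choice([0.0, 1.0], p=[0.3, 0.7], size=(4, 3)) * np.exp(
                rng.normal(8, 1, (4, 3))
            )
            ms.append(measurement(s, e, block, pid=f"p{i}"))
        got = relative_cut_frequency(ms, SUB, self.TP)
        # independent oracle: explicit (peptide, bond, ratio) triples
        expected: dict[int, np.ndarray] = {}
        for m in ms:
            avg = np.nan_to_num(m.intensities).mean(axis=0)
            nz = np.nonzero(avg > 0)[0]
            ratios = np.zeros(3)
            if nz.size:
                ratios[nz[0]:] = avg[nz[0]:] / avg[nz[0]]
            bonds = []
            if m.start > 1:
                bonds.append(m.start - 1)
            if m.end < SUB.length:
                bonds.append(m.end)
            for b in bonds:
                expected.setdefault(b, np.zeros(3))
                expected[b] = expected[b] + ratios
        expected = {b: v for b, v in expected.items() if np.any(v > 0)}
        assert {p.p1 for p in got} == set(expected)
        for p in got:
            np.testing.assert_allclose(p.frequencies, expected[p.p1], rtol=1e-9)

    def test_additivity_over_disjoint_subsets(self):
        rng = np.random.default_rng(2)
        ms = [
            measurement(
                5 + i, 20 + i, np.exp(rng.normal(8, 1, (2, 3))), pid=f"p{i}"
            )
            for i in range(10)
        ]
        whole = {p.p1: p.frequencies for p in relative_cut_frequency(ms, SUB, self.TP)}
        first = {p.p1: p.frequencies for p in relative_cut_frequency(ms[:5], SUB, self.TP)}
        second = {p.p1: p.frequencies for p in relative_cut_frequency(ms[5:], SUB, self.TP)}
        for p1, freqs in whole.items():
            combined = first.get(p1, 0) + second.get(p1, 0)
            np.testing.assert_allclose(freqs, combined, rtol=1e-9)


def profile(p1, freqs, tp=None):
    f = np.asarray(freqs, float)
    t = np.asarray(tp if tp is not None else np.arange(len(f)), float)
    return SiteProfile(p1=p1, time_points=t, frequencies=f)


class TestClassification:
    @pytest.mark.parametrize(
        "max_freq,edges,expected",
        [
            (20.0, ANXA1_CLASS_EDGES, "class 1"),
            (19.9, ANXA1_CLASS_EDGES, "class 2"),
            (11.0, ANXA1_CLASS_EDGES, "class 2"),
            (10.0, ANXA1_CLASS_EDGES, "class 3"),
            (0.5, ANXA1_CLASS_EDGES, "undetected"),
            (30.0, MDH_CLASS_EDGES, "class 1"),
            (25.0, MDH_CLASS_EDGES, "class 2"),
            (15.0, MDH_CLASS_EDGES, "class 3"),
        ],
    )
    def test_presets(self, max_freq, edges, expected):
        df = classify_sites([profile(10, [0, max_freq])], edges)
        assert df.loc[0, "site_class"] == expected

    def test_uses_maximum_over_time(self):
        df = classify_sites([profile(10, [25, 3, 0])])
        assert df.loc[0, "site_class"] == "class 1"

    def test_counts_match_bruteforce_binning(self):
        rng = np.random.default_rng(3)
        profiles = [profile(i + 1, [rng.uniform(0, 40)]) for i in range(500)]
        df = classify_sites(profiles, ANXA1_CLASS_EDGES)
        for i, p in enumerate(profiles):
            mf = p.max_frequency
            label = (
                "class 1" if mf >= 20 else
                "class 2" if mf >= 11 else
                "class 3" if mf >= 1 else "undetected"
            )
            assert df.loc[i, "site_class"] == label


class TestHistograms:
    def test_bins(self):
        profiles = [profile(1, [5.0]), profile(2, [15.0]), profile(3, [25.0])]
        df = cut_histogram(profiles, 0, bin_width=10)
        assert list(df["n_sites"]) == [1, 1, 1]
        assert list(df["bin_low"]) == [0, 10, 20]

    def test_all_zero_single_bin(self):
        df = cut_histogram([profile(1, [0.0]), profile(2, [0.0])], 0)
        assert len(df) == 1 and df.loc[0, "n_sites"] == 2

    def test_cumulative_site_count_nondecreasing(self):
        profiles = [
            profile(1, [0, 1, 2], [0, 10, 20]),
            profile(2, [0, 0, 5], [0, 10, 20]),
            profile(3, [1, 1, 0], [0, 10, 20]),
        ]
        df = cumulative_site_counts(profiles)
        assert list(df["n_sites"]) == [1, 2, 3]
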