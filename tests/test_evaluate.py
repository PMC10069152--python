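import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from nufd.core import FunctionalMap
from nufd.evaluate import deviation, display_map, reproducibility_report, wilcoxon_signed_rank


def _map(values, mask, kind="Vw"):
    return FunctionalMap(values=np.where(mask, values, 0.0), mask=mask, kind=kind)


def brute_force_wilcoxon(d, alternative="two-sided"):
    """Independent oracle: exhaustive sign enumeration with inclusive tails."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    n = len(d)
    ge = le = 0
    for bits in itertools.product((0, 1), repeat=n):
        wn = sum(r for r, b in zip(ranks, bits) if b)
        ge += wn >= w - 1e-12
        le += wn <= w + 1e-12
    ge /= 2**n
    le /= 2**n
    if alternative == "greater":
        return min(ge, 1.0)
    if alternative == "less":
        return min(le, 1.0)
    return min(2 * min(ge, le), 1.0)


class TestDeviation:
    def test_substitution(self):
        mask = np.ones((4, 4), bool)
        d, s = deviation(_map(np.full((4, 4), 2.0), mask), _map(np.full((4, 4), 1.5), mask))
        assert d == pytest.approx(0.25)
        assert s == pytest.approx(0.25)

    def test_identical_maps(self, rng):
        mask = np.ones((6, 6), bool)
        m = _map(rng.uniform(1, 2, (6, 6)), mask)
        assert deviation(m, m) == (0.0, 0.0)

    def test_scale_free(self, rng):
        mask = np.ones((6, 6), bool)
        a = _map(rng.uniform(1, 2, (6, 6)), mask)
        b = _map(rng.uniform(1, 2, (6, 6)), mask)
        d1, _ = deviation(a, b)
        a3 = _map(a.values * 3, mask)
        b3 = _map(b.values * 3, mask)
        d2, _ = deviation(a3, b3)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_zero_reference_rejected(self):
        mask = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="zero"):
            deviation(_map(np.zeros((4, 4)), mask), _map(np.ones((4, 4)), mask))

    def test_mask_mismatch_rejected(self, rng):
        m1 = np.ones((4, 4), bool)
        m2 = m1.copy()
        m2[0, 0] = False
        with pytest.raises(ValueError, match="mask"):
            deviation(_map(np.ones((4, 4)), m1), _map(np.ones((4, 4)), m2))


class TestWilcoxon:
    def test_six_positive_pairs_exact(self):
        p = wilcoxon_signed_rank(np.arange(1.0, 7.0))
        assert p == pytest.approx(2 / 64, abs=1e-15)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.ones(8), np.ones(8))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_signed_rank(np.array([1.0, -2.0, 3.0, 1.5]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 13))
        d = np.round(r.normal(size=n), 2)
        d = np.where(d == 0, 0.5, d)
        for alt in ("two-sided", "greater", "less"):
            assert wilcoxon_signed_rank(d, alternative=alt) == pytest.approx(
                brute_force_wilcoxon(d, alt), abs=1e-12
            )

    def test_large_n_matches_scipy_normal_approximation(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = rng.normal(0.3, 1.0, 40)
        d = d[d != 0]
        p = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, correction=False, method="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_scale_invariance(self, rng):
        d = rng.normal(size=15)
        assert wilcoxon_signed_rank(d) == pytest.approx(wilcoxon_signed_rank(5.0 * d), abs=1e-15)


class TestReport:
    def _scanset(self, means, methods=("uncorrected",), kind="Vw"):
        mask = np.ones((4, 4), bool)
        scans = []
        for i, mu in enumerate(means):
            maps = {(kind, m): _map(np.full((4, 4), mu), mask, kind) for m in methods}
            scans.append(
                {
                    "scan_id": f"s{i}",
                    "slice_label": "aorta",
                    "is_reference": i == 0,
                    "maps": maps,
                }
            )
        return scans

    def test_identical_scans_flag_degenerate(self):
        rep = reproducibility_report(self._scanset([2.0, 2.0]))
        assert (rep.deviations["delta"] == 0).all()
        assert any("degenerate" in n for n in rep.notes)

    def test_hand_computed_medians(self):
        rep = reproducibility_report(self._scanset([2.0, 1.0, 1.5, 2.5, 3.0, 2.2]))
        # deltas vs 2.0: 0.5, 0.25, 0.25, 0.5, 0.1 -> median 0.25
        assert rep.medians.loc[0, "median_delta"] == pytest.approx(0.25)
        assert rep.medians.loc[0, "n"] == 5

    def test_missing_reference_rejected(self):
        scans = self._scanset([2.0, 1.0])
        scans[0]["is_reference"] = False
        with pytest.raises(ValueError, match="reference"):
            reproducibility_report(scans)

    def test_report_files_written(self, tmp_path):
        rep = reproducibility_report(self._scanset([2.0, 1.0, 1.5]))
        rep.write(tmp_path)
        for name in ("report_deviations.csv", "report_medians.csv", "report_statistics.json"):
            assert (tmp_path / name).exists()


class TestDisplayMap:
    def test_visualization_never_mutates_the_map(self, rng, tmp_path):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        values = np.where(mask, rng.uniform(0.0, 2.0, (16, 16)), 0.0)
        fmap = FunctionalMap(values=values.copy(), mask=mask, kind="Vw")
        out = display_map(fmap, tmp_path / "m.png", gaussian_sigma=1.5, log_scale=True)
        assert out.exists()
        assert np.array_equal(fmap.values, values)  # isolation contract

    def test_zero_background_and_no_smoothing(self, tmp_path):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        fmap = FunctionalMap(values=np.where(mask, 1.0, 0.0), mask=mask, kind="Qw")
        out = display_map(fmap, tmp_path / "q.png", gaussian_sigma=0.0, log_scale=True)
        assert out.exists()
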