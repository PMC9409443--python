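"""Per-site statistics: frequency, Wilks CI, transform, pair contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from dmrlink import methylation as meth
from dmrlink.methylation import (
    NoCoverageError,
    SiteMethylation,
    SitePileup,
    clamp_frequency,
    contrast_table,
    pair_contrast,
    read_cytosine_report,
    site_frequency,
    site_methylation,
    transform,
    transform_sd,
    wilks_ci,
    wilks_ci_arrays,
    z_critical,
)


def grid_wilks_ci(k, n, level=0.95, resolution=1_000_001):
    """Brute-force oracle: scan a uniform grid for the LR condition."""
    crit = chi2.ppf(level, 1)
    p = np.linspace(1e-9, 1 - 1e-9, resolution)
    fhat = k / n
    ll = np.where(k > 0, k * np.log(p), 0.0) + np.where(
        n - k > 0, (n - k) * np.log1p(-p), 0.0
    )
    llmax = (k * np.log(fhat) if k > 0 else 0.0) + (
        (n - k) * np.log1p(-fhat) if n - k > 0 else 0.0
    )
    inside = 2 * (llmax - ll) <= crit
    lo = 0.0 if k == 0 else p[inside].min()
    hi = 1.0 if k == n else p[inside].max()
    return lo, hi


class TestSiteFrequency:
    @pytest.mark.parametrize(
        "k,n,expected", [(5, 10, 0.5), (0, 10, 0.0), (7, 7, 1.0)]
    )
    def test_forced_arithmetic(self, k, n, expected):
        assert site_frequency(SitePileup("chr1", 1, "+", k, n)) == expected

    def test_zero_coverage_raises(self):
        with pytest.raises(NoCoverageError):
            site_frequency(SitePileup("chr1", 1, "+", 0, 0))

    def test_pileup_invariants(self):
        with pytest.raises(ValueError):
            SitePileup("chr1", 1, "+", 5, 3)
        with pytest.raises(ValueError):
            SitePileup("chr1", 0, "+", 1, 3)


class TestWilksCI:
    def test_boundary_mles_exact(self):
        assert wilks_ci(0, 20)[0] == 0.0
        assert wilks_ci(20, 20)[1] == 1.0

    def test_symmetric_at_half(self):
        lo, hi = wilks_ci(5, 10)
        assert lo == pytest.approx(1 - hi, abs=1e-7)
        assert lo <= 0.5 <= hi

    @pytest.mark.parametrize("k,n", [(5, 10), (0, 20), (1, 10), (17, 20), (50, 100)])
    def test_matches_grid_oracle(self, k, n):
        lo, hi = wilks_ci(k, n)
        olo, ohi = grid_wilks_ci(k, n)
        assert lo == pytest.approx(olo, abs=2e-6)
        assert hi == pytest.approx(ohi, abs=2e-6)

    def test_contains_mle(self, rng):
        n = rng.integers(1, 200, size=300)
        k = rng.integers(0, n + 1)
        lo, hi = wilks_ci_arrays(k, n)
        f = k / n
        assert np.all((lo <= f + 1e-12) & (f <= hi + 1e-12))
        assert np.all((lo >= 0) & (hi <= 1))

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            wilks_ci(1, 10, level=1.5)

    def test_coverage_moderate_n(self, rng):
        # empirical coverage at n in {30, 100}; the n=10 cells are checked
        # against the exact oracle instead (discreteness puts them outside
        # any tight band around the nominal level)
        for f in (0.1, 0.5, 0.9):
            for n in (30, 100):
                k = rng.binomial(n, f, size=4000)
                lo, hi = wilks_ci_arrays(k, np.full(4000, n))
                cov = np.mean((lo <= f) & (f <= hi))
                assert 0.92 <= cov <= 0.98, (f, n, cov)


class TestTransform:
    def test_zero(self):
        assert transform(0.0) == 0.0

    def test_half_is_ln3(self):
        assert transform(0.5) == pytest.approx(np.log(3.0), abs=1e-12)

    def test_odd_function(self):
        # the formula extends to negative arguments as an odd function
        f = np.array([0.1, 0.37, 0.9])
        assert np.allclose(transform(f), -transform(-f))

    @given(
        st.floats(0, 0.999), st.floats(0, 0.999)
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_monotone(self, f1, f2):
        if f1 == f2:
            return
        lo, hi = sorted((f1, f2))
        assert transform(lo) < transform(hi)

    def test_clamp_keeps_finite(self):
        v = transform(clamp_frequency(1.0, 10))
        assert np.isfinite(v)
        assert transform(clamp_frequency(1.0, 100)) > v  # cap grows with coverage


class TestTransformSD:
    def test_degenerate_interval(self):
        assert transform_sd(0.3, 0.3) == 0.0

    def test_direct_evaluation(self):
        assert transform_sd(0.0, 0.5) == pytest.approx(np.log(3.0) / 6, abs=1e-12)

    def test_monotone_in_width(self, rng):
        lo = rng.uniform(0, 0.4, 100)
        hi = rng.uniform(0.5, 0.95, 100)
        wider = transform_sd(lo - lo * 0.5, hi)
        assert np.all(np.asarray(wider) >= np.asarray(transform_sd(lo, hi)))

    def test_reversed_margins_raise(self):
        with pytest.raises(ValueError):
            transform_sd(0.6, 0.4)


def _sm(v, sd):
    return SiteMethylation(f=0.5, ci_lo=0.0, ci_hi=1.0, v=v, sd_v=sd)


class TestPairContrast:
    def test_identity_case(self):
        c = pair_contrast(_sm(1.0, 0.1), _sm(1.0, 0.1))
        assert c.b1 == 0.0 and c.z == 0.0 and c.direction is None

    def test_worked_example(self):
        c = pair_contrast(_sm(0.0, 0.2), _sm(np.log(3.0), 0.2))
        assert c.b1 == pytest.approx(0.549306, abs=1e-6)
        assert c.sd_b1 == pytest.approx(0.141421, abs=1e-6)
        assert c.z == pytest.approx(3.8842, abs=1e-4)
        assert c.direction == "hyper"

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = _sm(rng.normal(), rng.uniform(0.01, 1)), _sm(
                rng.normal(), rng.uniform(0.01, 1)
            )
            c1, c2 = pair_contrast(a, b), pair_contrast(b, a)
            assert c2.b1 == -c1.b1 and c2.z == pytest.approx(-c1.z)
            assert c2.b0 == c1.b0

    def test_equals_generic_least_squares(self, rng):
        # closed form vs (X'X)^-1 X'Y with X = [[1,-1],[1,+1]]
        X = np.array([[1.0, -1.0], [1.0, 1.0]])
        for _ in range(1000):
            v_ctrl, v_case = rng.normal(size=2) * 3
            b = np.linalg.solve(X.T @ X, X.T @ np.array([v_ctrl, v_case]))
            c = pair_contrast(_sm(v_ctrl, 0.1), _sm(v_case, 0.1))
            assert abs(c.b0 - b[0]) < 1e-10 and abs(c.b1 - b[1]) < 1e-10

    def test_degenerate_infinite(self):
        c = pair_contrast(_sm(0.0, 0.0), _sm(1.0, 0.0))
        assert c.degenerate and np.isinf(c.z) and c.z > 0 and c.direction == "hyper"
        c0 = pair_contrast(_sm(1.0, 0.0), _sm(1.0, 0.0))
        assert c0.z == 0.0 and not c0.degenerate


def _pileup_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "count_methylated", "count_total"]
    )


class TestContrastTable:
    def test_coverage_filter_and_columns(self):
        ctrl = _pileup_frame(
            [("chr1", 10, "+", 2, 10), ("chr1", 20, "+", 1, 3), ("chr1", 30, "-", 9, 10)]
        )
        case = _pileup_frame(
            [("chr1", 10, "+", 9, 10), ("chr1", 20, "+", 3, 30), ("chr1", 30, "-", 1, 10)]
        )
        out = contrast_table(ctrl, case, pair="male", min_coverage=5)
        assert list(out["pos"]) == [10, 30]  # pos 20 fails in ctrl
        assert out.loc[out.pos == 10, "z"].iloc[0] > 0
        assert out.loc[out.pos == 30, "z"].iloc[0] < 0
        assert set(out.columns) >= {
            "chrom", "pos", "strand", "f_ctrl", "f_as", "v_ctrl", "v_as",
            "b1", "sd_b1", "z", "pair",
        }

    def test_scalar_path_agrees(self):
        ctrl = _pileup_frame([("chr1", 10, "+", 2, 12)])
        case = _pileup_frame([("chr1", 10, "+", 9, 11)])
        out = contrast_table(ctrl, case, pair="f")
        a = site_methylation(SitePileup("chr1", 10, "+", 2, 12))
        b = site_methylation(SitePileup("chr1", 10, "+", 9, 11))
        c = pair_contrast(a, b)
        assert out["b1"].iloc[0] == pytest.approx(c.b1, abs=1e-12)
        assert out["z"].iloc[0] == pytest.approx(c.z, rel=1e-10)


class TestZCritical:
    def test_standard_value(self):
        assert z_critical(0.05) == pytest.approx(1.959964, abs=1e-6)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            z_critical(0.0)


class TestCytosineReportImport:
    def test_simple_dialect_roundtrip(self, tmp_path, small_sim):
        track = small_sim.tracks["ctrl_male"]
        p = tmp_path / "t.tsv"
        track.to_csv(p, sep="\t", header=False, index=False)
        back = read_cytosine_report(p)
        pd.testing.assert_frame_equal(
            back, track.sort_values(["chrom", "pos"]).reset_index(drop=True)
        )
        assert back.attrs["convention"] == "printed"

    def test_bismark_dialect_conventions(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("chr1\t100\t+\t6\t4\tCpG\tCGA\nchr1\t200\t-\t0\t10\tCpG\tCGT\n")
        printed = read_cytosine_report(p, dialect="bismark", convention="printed")
        standard = read_cytosine_report(p, dialect="bismark", convention="standard")
        # printed counts the converted reads (column 5), standard column 4
        assert list(printed["count_methylated"]) == [4, 10]
        assert list(standard["count_methylated"]) == [6, 0]
        assert list(printed["count_total"]) == [10, 10]

    def test_bad_counts_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t100\t+\t9\t4\n")
        with pytest.raises(ValueError, match="exceeds coverage"):
            read_cytosine_report(p)
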