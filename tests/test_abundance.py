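"""Abundance model: lumen CDF recovery, DBL smearing, and composition."""

import math

import numpy as np
import pytest

from sipreads.abundance import (
    assign_bd,
    dbl_abundance,
    fragment_window_abundance,
    lumen_abundance,
    lumen_recovery,
    read_abundance,
    shotgun_abundance,
)
from sipreads.exceptions import DomainError
from sipreads.fragments import Fragment
from sipreads.gradient import (
    BDWindow,
    DBLRange,
    dbl_position_range,
    equilibrium_position,
)

INF_WINDOW = BDWindow(-math.inf, math.inf)


def _fragment(gc=0.5, length=10_000, atom_excess=0.0, isotope="13C", params=None):
    frag = Fragment("ref", "scf", 0, length, gc)
    return assign_bd(frag, atom_excess, isotope, params)


class TestLumenRecovery:
    def test_total_probability(self):
        assert lumen_recovery(1.71, 0.001, INF_WINDOW) == pytest.approx(1.0)

    def test_half_mass_above_mean(self):
        assert lumen_recovery(1.71, 0.001, BDWindow(1.71, math.inf)) == pytest.approx(0.5)

    def test_one_sigma_window(self):
        rho, sigma = 1.71, 0.003
        got = lumen_recovery(rho, sigma, BDWindow(rho - sigma, rho + sigma))
        assert got == pytest.approx(0.6826894921, abs=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(DomainError):
            lumen_recovery(1.71, 0.0, INF_WINDOW)


class TestLumenAbundance:
    @pytest.mark.parametrize(
        "alpha,p_dbl,p_lr,expected",
        [(0.3, 0.0, 1.0, 0.3), (0.3, 0.5, 0.0, 0.0), (0.02, 0.001, 0.5, 0.00999)],
    )
    def test_examples(self, alpha, p_dbl, p_lr, expected):
        assert lumen_abundance(alpha, p_dbl, p_lr) == pytest.approx(expected, abs=1e-12)

    def test_invalid_p_dbl(self):
        with pytest.raises(DomainError):
            lumen_abundance(0.1, 1.0, 0.5)


class TestDBLAbundance:
    DBL = DBLRange(x_min=1.0, x_max=2.0, rho_dbl_min=1.70, rho_dbl_max=1.74)

    def test_window_equal_to_dbl_range(self):
        assert dbl_abundance(0.2, 0.01, BDWindow(1.70, 1.74), self.DBL) == pytest.approx(
            0.2 * 0.01
        )

    def test_disjoint_window(self):
        assert dbl_abundance(0.2, 0.01, BDWindow(1.75, 1.78), self.DBL) == 0.0

    def test_half_window(self):
        assert dbl_abundance(0.2, 0.01, BDWindow(1.70, 1.72), self.DBL) == pytest.approx(
            0.2 * 0.01 / 2
        )

    def test_clipping_caps_wide_windows(self):
        wide = BDWindow(1.60, 1.85)
        assert dbl_abundance(0.2, 0.01, wide, self.DBL) == pytest.approx(0.2 * 0.01)
        literal = dbl_abundance(0.2, 0.01, wide, self.DBL, clip=False)
        assert literal > 0.2 * 0.01  # the unclipped proportionality overshoots


class TestFragmentWindowAbundance:
    def test_conservation_with_no_dbl(self, params):
        frag = _fragment(params=params)
        fwa = fragment_window_abundance(frag, 0.3, INF_WINDOW, params, p_dbl=0.0)
        assert fwa.alpha_f == pytest.approx(0.3, abs=1e-12)
        assert fwa.alpha_dbl == 0.0

    def test_alpha_f_is_sum_of_terms(self, params):
        frag = _fragment(params=params)
        fwa = fragment_window_abundance(frag, 0.3, BDWindow(1.70, 1.72), params, p_dbl=0.01)
        assert fwa.alpha_f == fwa.alpha_l + fwa.alpha_dbl

    def test_unlabeled_midgc_fragment_misses_heavy_window(self, params):
        frag = _fragment(gc=0.5, params=params)  # bands at 1.709
        fwa = fragment_window_abundance(frag, 0.3, BDWindow(1.75, 1.78), params, p_dbl=0.0)
        assert fwa.alpha_l == pytest.approx(0.0, abs=1e-12)

    def test_unassigned_fragment_rejected(self, params):
        with pytest.raises(DomainError):
            fragment_window_abundance(
                Fragment("r", "s", 0, 100, 0.5), 0.1, INF_WINDOW, params, 0.0
            )

    def test_conservation_over_fraction_set(self, params, rng):
        """Summing window abundances over a set spanning the lumen band
        and the whole DBL range recovers alpha."""
        from sipreads.community import FractionSet

        for _ in range(20):
            frag = _fragment(
                gc=rng.uniform(0.3, 0.7),
                length=int(rng.integers(1000, 50_000)),
                atom_excess=rng.uniform(0, 1),
                params=params,
            )
            alpha = 0.05
            p_dbl = 0.01
            dbl = dbl_position_range(equilibrium_position(frag.rho, params), params)
            lo = min(frag.rho - 8 * frag.sigma, dbl.rho_dbl_min) - 1e-6
            hi = max(frag.rho + 8 * frag.sigma, dbl.rho_dbl_max) + 1e-6
            fs = FractionSet.from_boundaries(list(np.linspace(lo, hi, 40)))
            total = sum(
                fragment_window_abundance(frag, alpha, w, params, p_dbl).alpha_f
                for w in fs
            )
            assert total == pytest.approx(alpha, abs=1e-4 * alpha)

    def test_labeling_shift_is_monotone_in_heavy_windows(self, params):
        """More labeling never reduces abundance in windows above rho_t."""
        window = BDWindow(1.72, 1.77)
        prev = -1.0
        for excess in np.linspace(0, 1, 11):
            frag = _fragment(gc=0.40, atom_excess=float(excess), params=params)
            alpha_f = fragment_window_abundance(frag, 0.1, window, params, 0.001).alpha_f
            assert alpha_f >= prev - 1e-15
            prev = alpha_f

    def test_high_gc_contamination_of_heavy_window(self, params):
        """Labeled low-G+C DNA gains from the shift, but unlabeled
        high-G+C DNA still appears in the heavy window."""
        window = BDWindow(1.72, 1.77)
        labeled = _fragment(gc=0.30, atom_excess=1.0, params=params)
        unlabeled = _fragment(gc=0.30, atom_excess=0.0, params=params)
        high_gc = _fragment(gc=0.65, atom_excess=0.0, params=params)
        a_labeled = fragment_window_abundance(labeled, 0.1, window, params, 0.001).alpha_f
        a_unlabeled = fragment_window_abundance(unlabeled, 0.1, window, params, 0.001).alpha_f
        a_high_gc = fragment_window_abundance(high_gc, 0.1, window, params, 0.001).alpha_f
        assert a_labeled > a_unlabeled
        assert a_high_gc > 0.0

    def test_monte_carlo_occupancy_small(self, params, rng):
        """Mini simulation oracle: place molecules by the lumen-normal +
        DBL-uniform model and compare window occupancy to alpha_f."""
        frag = _fragment(gc=0.45, length=8000, atom_excess=0.5, params=params)
        p_dbl = 0.1
        n = 100_000
        dbl = dbl_position_range(equilibrium_position(frag.rho, params), params)
        in_dbl = rng.random(n) < p_dbl
        pos = np.where(
            in_dbl,
            rng.uniform(dbl.rho_dbl_min, dbl.rho_dbl_max, n),
            rng.normal(frag.rho, frag.sigma, n),
        )
        for lo, hi in [(1.70, 1.72), (1.715, 1.73), (1.60, 1.90)]:
            window = BDWindow(lo, hi)
            expected = fragment_window_abundance(frag, 1.0, window, params, p_dbl).alpha_f
            observed = np.mean((pos >= lo) & (pos < hi))
            se = math.sqrt(max(expected * (1 - expected), 1e-12) / n)
            assert abs(observed - expected) <= 3 * se + 1e-6


class TestReadAbundance:
    def test_direct_substitution(self):
        assert read_abundance(1.0, 3000, 150) == pytest.approx(10.0)

    def test_zero_abundance(self):
        assert read_abundance(0.0, 3000, 150) == 0.0

    def test_linear_in_fragment_length(self):
        assert read_abundance(0.5, 6000, 150) == pytest.approx(
            2 * read_abundance(0.5, 3000, 150)
        )

    def test_fragment_shorter_than_read_rejected(self):
        with pytest.raises(DomainError):
            read_abundance(0.5, 100, 150)


class TestShotgunAbundance:
    def test_identity(self):
        assert shotgun_abundance(0.02) == 0.02
        assert shotgun_abundance(0.0) == 0.0

    def test_limit_equivalence_with_sip(self, params):
        frag = _fragment(params=params)
        sip = fragment_window_abundance(frag, 0.02, INF_WINDOW, params, p_dbl=0.0)
        assert sip.alpha_f == pytest.approx(shotgun_abundance(0.02), abs=1e-12)
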