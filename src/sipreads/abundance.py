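"""Per-fragment abundance in a sequenced buoyant-density window.

A fragment's recovered abundance has two parts:

* a **lumen** term -- the fragment bands normally around its
  isotope-adjusted BD with the diffusion SD, and the window recovers the
  corresponding normal-CDF mass of the non-DBL population; and
* a **DBL** term -- a user-supplied fraction ``p_DBL`` of the DNA is
  trapped in the diffusive boundary layer along the tube wall, assumed
  uniformly smeared over the BD range the wall contact maps to, and the
  window recovers its proportional share of that range.

Their sum is the fragment's window abundance; multiplying by the number
of read-pair 'slots' on the fragment (fragment length over twice the
read length) gives the fragment's read abundance used to weight read
allocation.  The shotgun (non-SIP) control bypasses the gradient
entirely: fragment abundance equals the parent reference abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import norm

from .exceptions import DomainError, GeometryError, OutOfGradientError
from .fragments import Fragment
from .gradient import (
    BDWindow,
    DBLRange,
    GradientParams,
    dbl_position_range,
    diffusion_sigma,
    equilibrium_position,
    labeled_bd,
    theoretical_bd,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentWindowAbundance",
    "assign_bd",
    "lumen_recovery",
    "lumen_abundance",
    "dbl_abundance",
    "fragment_window_abundance",
    "read_abundance",
    "shotgun_abundance",
]


@dataclass(frozen=True)
class FragmentWindowAbundance:
    """Recovered abundance of one fragment in one BD window."""

    fragment: Fragment
    window: BDWindow
    p_lr: float
    alpha_l: float
    alpha_dbl: float

    @property
    def alpha_f(self) -> float:
        return self.alpha_l + self.alpha_dbl


def assign_bd(
    fragment: Fragment,
    atom_excess: float,
    isotope: str,
    params: GradientParams,
) -> Fragment:
    """Fill in a fragment's buoyant-density statistics in place.

    Sets the theoretical BD from G+C, the isotope-adjusted BD from the
    atom % excess draw, and the diffusion SD from the adjusted BD and
    fragment length.  Returns the same fragment for chaining.
    """
    fragment.atom_excess = atom_excess
    fragment.rho_t = theoretical_bd(fragment.gc)
    fragment.rho = labeled_bd(fragment.rho_t, atom_excess, isotope)
    fragment.sigma = diffusion_sigma(fragment.rho, fragment.length, params)
    return fragment


def lumen_recovery(rho: float, sigma: float, window: BDWindow) -> float:
    """Proportion of the fragment's lumen population inside the window.

    The lumen population is Normal(rho, sigma); the window recovers
    ``Phi((rho_max - rho)/sigma) - Phi((rho_min - rho)/sigma)``.
    """
    if sigma <= 0:
        raise DomainError(f"diffusion sigma must be positive, got {sigma}")
    return float(
        norm.cdf(window.rho_max, loc=rho, scale=sigma)
        - norm.cdf(window.rho_min, loc=rho, scale=sigma)
    )


def lumen_abundance(alpha: float, p_dbl: float, p_lr: float) -> float:
    """Lumen-population abundance in the window: ``alpha*(1-p_DBL)*p_LR``."""
    if not 0 <= p_dbl < 1:
        raise DomainError(f"p_DBL must lie in [0, 1), got {p_dbl}")
    return alpha * (1.0 - p_dbl) * p_lr


def dbl_abundance(
    alpha: float,
    p_dbl: float,
    window: BDWindow,
    dbl: DBLRange,
    clip: bool = True,
) -> float:
    """DBL-population abundance in the window.

    The DBL mass (``alpha * p_DBL``) is uniform over
    ``[rho_DBLmin, rho_DBLmax]``; the window recovers the share
    proportional to the window width over the DBL BD width.  By default
    the window is first intersected with the DBL range so that a window
    wider than (or partly outside) the DBL range can never recover more
    than the total DBL mass; ``clip=False`` applies the literal
    proportionality for parity with implementations that do not clip.
    """
    if not 0 <= p_dbl < 1:
        raise DomainError(f"p_DBL must lie in [0, 1), got {p_dbl}")
    if clip:
        lo = max(window.rho_min, dbl.rho_dbl_min)
        hi = min(window.rho_max, dbl.rho_dbl_max)
        width = max(0.0, hi - lo)
    else:
        width = window.width
    return width / dbl.bd_width * alpha * p_dbl


def fragment_window_abundance(
    fragment: Fragment,
    alpha: float,
    window: BDWindow,
    params: GradientParams,
    p_dbl: float,
    clip_dbl: bool = True,
) -> FragmentWindowAbundance:
    """Compose the full gradient model for one fragment and one window.

    Requires :func:`assign_bd` to have been applied.  A fragment whose
    equilibrium position falls outside the tube contributes zero to the
    window (counted by the caller via the zero result).
    """
    if fragment.rho is None or fragment.sigma is None:
        raise DomainError(
            f"fragment {fragment.reference_id}/{fragment.scaffold_id}:"
            f"{fragment.start}-{fragment.end} has no BD assigned; call assign_bd first"
        )
    p_lr = lumen_recovery(fragment.rho, fragment.sigma, window)
    alpha_l = lumen_abundance(alpha, p_dbl, p_lr)
    if p_dbl == 0.0:
        alpha_d = 0.0
    else:
        try:
            x = equilibrium_position(fragment.rho, params)
            dbl = dbl_position_range(x, params)
        except (OutOfGradientError, GeometryError) as exc:
            logger.debug(
                "fragment %s/%s:%d-%d off-gradient (%s); zero contribution",
                fragment.reference_id,
                fragment.scaffold_id,
                fragment.start,
                fragment.end,
                exc,
            )
            return FragmentWindowAbundance(fragment, window, p_lr=0.0, alpha_l=0.0, alpha_dbl=0.0)
        alpha_d = dbl_abundance(alpha, p_dbl, window, dbl, clip=clip_dbl)
    return FragmentWindowAbundance(
        fragment, window, p_lr=p_lr, alpha_l=alpha_l, alpha_dbl=alpha_d
    )


def read_abundance(alpha_f: float, fragment_length: int, read_length: int) -> float:
    """Read abundance of a fragment: ``alpha_f * l_f / (2 * l_r)``.

    The factor counts the read pairs a fragment of length ``l_f`` can
    yield at read length ``l_r``, scaled by the fragment's window
    abundance.
    """
    if read_length < 1:
        raise DomainError(f"read length must be >= 1, got {read_length}")
    if fragment_length < read_length:
        raise DomainError(
            f"fragment length {fragment_length} shorter than read length {read_length}; "
            "such fragments must be excluded upstream"
        )
    return alpha_f * fragment_length / (2.0 * read_length)


def shotgun_abundance(alpha: float) -> float:
    """Shotgun-control abundance: the reference abundance, unchanged by
    any gradient fractionation."""
    return alpha
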