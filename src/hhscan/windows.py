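"""Per-site entropies and variation-adjusted marker windows.

Around each focal marker, and independently in each population, a window is
grown outward until the summed per-site Shannon entropy on each flank first
reaches a fixed budget (default 10 nats). Windows therefore shrink in more
variable regions and in more diverse populations, normalising background
haplotype length before any haplotype entropy is measured. The focal site
itself is excluded from both flank sums and from the haplotype strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

DEFAULT_THRESHOLD = 10.0  # nats per flank


def site_entropy(allele_frequency: float) -> float:
    """Shannon entropy (nats) of a biallelic site at the given frequency.

    ``-(f ln f + (1-f) ln(1-f))`` with the usual ``0 ln 0 = 0`` convention;
    lies in ``[0, ln 2]``.
    """
    f = float(allele_frequency)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency {f} outside [0, 1]")
    return float(-(xlogy(f, f) + xlogy(1.0 - f, 1.0 - f)))


def site_entropies(frequencies: np.ndarray) -> np.ndarray:
    """Vectorised :func:`site_entropy` (NaN frequencies give NaN)."""
    f = np.asarray(frequencies, dtype=float)
    ok = ~np.isnan(f)
    if np.any((f[ok] < 0) | (f[ok] > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    return -(xlogy(f, f) + xlogy(1.0 - f, 1.0 - f))


@dataclass(frozen=True)
class MarkerWindow:
    """A per-population window around a focal site.

    Indices are positions into the population's ordered site list (not base
    pairs). ``left <= focal <= right``; the flank sums exclude the focal
    site and each is >= ``threshold`` unless the corresponding ``truncated_*``
    flag marks a chromosome end reached first.
    """

    population: str
    focal: int
    left: int
    right: int
    left_sum: float
    right_sum: float
    threshold: float
    truncated_left: bool
    truncated_right: bool

    @property
    def truncated(self) -> bool:
        return self.truncated_left or self.truncated_right

    @property
    def n_flanking(self) -> int:
        return self.right - self.left  # focal excluded


def _flank_extent(entropies_outward: np.ndarray, threshold: float) -> tuple[int, float, bool]:
    """Smallest count c of nearest flank sites with cumulative entropy
    >= threshold; (c, attained sum, truncated)."""
    if threshold <= 0:
        return 0, 0.0, False
    if entropies_outward.size == 0:
        return 0, 0.0, True
    csum = np.cumsum(entropies_outward)
    k = int(np.searchsorted(csum, threshold, side="left"))
    if k >= len(csum):
        return len(csum), float(csum[-1]), True
    return k + 1, float(csum[k]), False


def select_window(
    site_entropies: np.ndarray,
    focal_index: int,
    threshold: float = DEFAULT_THRESHOLD,
    population: str = "",
) -> MarkerWindow:
    """Grow the minimal window whose flank entropy sums reach ``threshold``.

    Each flank is extended outward from the focal site until its cumulative
    entropy first reaches the threshold; if the chromosome end intervenes
    the flank is truncated and flagged. Minimality holds per flank: dropping
    the outermost site would push that flank's sum below the threshold.
    """
    h = np.asarray(site_entropies, dtype=float)
    if h.size == 0:
        raise ValueError("empty entropy profile")
    if not 0 <= focal_index < h.size:
        raise ValueError(f"focal index {focal_index} out of range")
    nl, ls, tl = _flank_extent(h[:focal_index][::-1], threshold)
    nr, rs, tr = _flank_extent(h[focal_index + 1 :], threshold)
    return MarkerWindow(
        population=population,
        focal=focal_index,
        left=focal_index - nl,
        right=focal_index + nr,
        left_sum=ls,
        right_sum=rs,
        threshold=threshold,
        truncated_left=tl,
        truncated_right=tr,
    )


@dataclass(frozen=True)
class HaplotypeCounts:
    """Distinct flanking haplotypes of a window with their chromosome counts,
    split by the allele carried at the focal site."""

    total: np.ndarray  # n*_J, sums to N_p
    minor: np.ndarray  # n'_J among minor-allele carriers, sums to N_mp
    major: np.ndarray  # among major-allele carriers

    def __post_init__(self) -> None:
        assert np.array_equal(self.total, self.minor + self.major)


def window_haplotypes(
    matrix: np.ndarray,
    window: MarkerWindow,
    minor_mask: np.ndarray,
) -> HaplotypeCounts:
    """Tally the distinct haplotype strings over the window's flanking sites.

    ``matrix`` is the population's chromosomes x sites 0/1 matrix in the same
    site indexing as the window; ``minor_mask`` flags chromosomes carrying
    the minor allele at the focal site.
    """
    cols = np.r_[window.left : window.focal, window.focal + 1 : window.right + 1]
    if cols.size == 0:
        raise ValueError("window has no flanking sites; no haplotype defined")
    sub = np.ascontiguousarray(matrix[:, cols])
    _, inverse = np.unique(sub, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    n_hap = int(inverse.max()) + 1
    total = np.bincount(inverse, minlength=n_hap)
    minor = np.bincount(inverse[minor_mask], minlength=n_hap)
    return HaplotypeCounts(total=total, minor=minor, major=total - minor)
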