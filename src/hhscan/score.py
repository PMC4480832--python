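"""The adjusted haplotype conditional-entropy score (H|H).

For a focal marker m and population p, let H*_pm be the plug-in Shannon
entropy of the flanking haplotypes in m's variation-adjusted window, and
H'_pm the same entropy restricted to chromosomes carrying the minor allele
at m. A large drop H* - H' means the minor allele rides one conserved
(long) haplotype — the footprint of a recent selective sweep.

The raw drop depends strongly on the major/minor chromosome counts, so a
per-population empirical calibration removes the linear effect of
ln N_Mp and ln N_mp plus an intercept, chosen so that the adjusted
component averages zero within every population. The final score is the
negated sum of the adjusted components over populations with more than 5
major-allele chromosomes (and at least one minor-allele carrier, without
which the conditional entropy is undefined):

    H|H_m = - sum_p ( H*_pm - H'_pm - a_p - b_Mp ln N_Mp - b_mp ln N_mp )

With this sign convention, strongly swept markers score negative; a
``flip_sign`` output option is provided for users who prefer
"higher = more swept".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .panel import FocalMarkerSet, HaplotypePanel, load_table
from .windows import (
    DEFAULT_THRESHOLD,
    HaplotypeCounts,
    select_window,
    site_entropies,
    window_haplotypes,
)

logger = logging.getLogger(__name__)

MAJOR_COUNT_MIN = 5  # inclusion: N_Mp > 5 (or N_mp > 5 in the alternate mode)


def entropy_from_counts(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy (nats) of a count vector."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty haplotype table")
    f = c / c.sum()
    return float(-np.sum(xlogy(f, f)))


def window_entropy(frequencies: np.ndarray) -> float:
    """Entropy H* of the full window haplotype distribution.

    Accepts frequencies (positive, summing to 1) or raw counts.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise ValueError("empty haplotype table")
    if np.any(f < 0):
        raise ValueError("negative haplotype frequency")
    return entropy_from_counts(f)


def conditional_entropy(frequencies: np.ndarray) -> float:
    """Entropy H' of the haplotype distribution among minor-allele carriers."""
    return window_entropy(frequencies)


@dataclass
class PopComponents:
    """Per-population pieces of one marker's score."""

    h_star: float
    h_prime: float
    n_total: int
    n_major: int
    n_minor: int
    included: bool
    truncated: bool = False


@dataclass
class HHRecord:
    """Score components for one focal marker across populations."""

    marker: str
    site: int
    components: dict[str, PopComponents] = field(default_factory=dict)
    hh: float | None = None


@dataclass
class CalibrationTable:
    """Per-population (alpha, beta_M, beta_m) adjustment coefficients."""

    params: dict[str, tuple[float, float, float]]  # pop -> (alpha, beta_M, beta_m)

    def predict(self, population: str, n_major: int, n_minor: int) -> float:
        a, b_M, b_m = self.params[population]
        return a + b_M * np.log(n_major) + b_m * np.log(n_minor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"Population": p, "alpha": a, "beta_m": b_m, "beta_M": b_M}
                for p, (a, b_M, b_m) in self.params.items()
            ]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CalibrationTable":
        df = load_table(path, "calibration")
        return cls(
            params={
                r.Population: (float(r.alpha), float(r.beta_M), float(r.beta_m))
                for r in df.itertuples()
            }
        )


def fit_calibration(records: Iterable[HHRecord]) -> CalibrationTable:
    """Least-squares fit of (H* - H') on {1, ln N_M, ln N_m} per population.

    Ordinary least squares with an intercept is the unique linear adjustment
    in these two log-counts whose residuals average exactly zero within each
    population, which is the stated defining property of the calibration.
    """
    per_pop: dict[str, list[tuple[float, float, float]]] = {}
    for rec in records:
        for pop, c in rec.components.items():
            if c.included:
                per_pop.setdefault(pop, []).append(
                    (c.h_star - c.h_prime, np.log(c.n_major), np.log(c.n_minor))
                )
    params: dict[str, tuple[float, float, float]] = {}
    for pop, rows in per_pop.items():
        if len(rows) < 3:
            raise ValueError(
                f"population {pop}: only {len(rows)} usable markers; "
                "need >= 3 to fit the calibration"
            )
        arr = np.asarray(rows)
        y = arr[:, 0]
        X = np.column_stack([np.ones(len(arr)), arr[:, 1], arr[:, 2]])
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError(
                f"population {pop}: calibration design is rank-deficient "
                "(constant major or minor chromosome counts)"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        params[pop] = (float(beta[0]), float(beta[1]), float(beta[2]))
    if not params:
        raise ValueError("no population has any included marker")
    return CalibrationTable(params=params)


def _adjusted_component(c: PopComponents, calibration: CalibrationTable, pop: str) -> float:
    return c.h_star - c.h_prime - calibration.predict(pop, c.n_major, c.n_minor)


def hh_score(record: HHRecord, calibration: CalibrationTable) -> float:
    """Aggregate one marker's components into its H|H value."""
    total = 0.0
    for pop, c in record.components.items():
        if not c.included:
            continue
        if pop not in calibration.params:
            raise KeyError(f"population {pop} missing from calibration")
        total += _adjusted_component(c, calibration, pop)
    return -total


# ---------------------------------------------------------------------------
# end-to-end scoring


def _population_components(
    panel: HaplotypePanel,
    pop: str,
    site: int,
    threshold: float,
    inclusion: str,
    minor_scope: str,
    caches: dict,
) -> PopComponents:
    mask = panel.site_mask(pop)
    chrom = panel.chrom[site]
    key = (pop, chrom)
    if key not in caches:
        local_sites = np.where(mask & (panel.chrom == chrom))[0]
        freqs = panel.haplotypes[pop][:, local_sites].mean(axis=0)
        caches[key] = (local_sites, site_entropies(freqs))
    local_sites, entropies = caches[key]

    mat = panel.haplotypes[pop]
    n_total = mat.shape[0]
    excluded = PopComponents(
        h_star=np.nan, h_prime=np.nan, n_total=n_total,
        n_major=0, n_minor=0, included=False,
    )
    if not mask[site]:
        return excluded

    if minor_scope == "global":
        f = panel.global_alt_frequency()[site]
    else:
        f = mat[:, site].mean()
    # minor allele: lower-frequency allele, ties resolved toward ALT
    minor_allele = 1 if f <= 0.5 else 0
    focal_col = mat[:, site]
    minor_mask = focal_col == minor_allele
    n_minor = int(minor_mask.sum())
    n_major = n_total - n_minor
    excluded.n_major, excluded.n_minor = n_major, n_minor

    count = n_major if inclusion == "major" else n_minor
    if n_minor < 1 or count <= MAJOR_COUNT_MIN:
        return excluded

    local = int(np.searchsorted(local_sites, site))
    win = select_window(entropies, local, threshold=threshold, population=pop)
    if win.n_flanking == 0:
        return excluded
    counts = window_haplotypes(mat[:, local_sites], win, minor_mask)
    return PopComponents(
        h_star=entropy_from_counts(counts.total),
        h_prime=entropy_from_counts(counts.minor),
        n_total=n_total,
        n_major=n_major,
        n_minor=n_minor,
        included=True,
        truncated=win.truncated,
    )


def score_markers(
    panel: HaplotypePanel,
    markers: FocalMarkerSet,
    calibration: CalibrationTable | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    inclusion: str = "major",
    minor_scope: str = "population",
    flip_sign: bool = False,
) -> tuple[list[HHRecord], pd.DataFrame]:
    """Score every focal marker; returns records plus a BED-like track table.

    If no calibration is supplied it is fitted on the focal set itself
    (two-pass: components first, then the per-population adjustment).
    Deterministic given its inputs.
    """
    if inclusion not in ("major", "minor"):
        raise ValueError("inclusion must be 'major' or 'minor'")
    if minor_scope not in ("population", "global"):
        raise ValueError("minor_scope must be 'population' or 'global'")
    caches: dict = {}
    records: list[HHRecord] = []
    for marker, site in zip(markers.markers, markers.sites):
        rec = HHRecord(marker=marker, site=int(site))
        for pop in panel.populations:
            rec.components[pop] = _population_components(
                panel, pop, int(site), threshold, inclusion, minor_scope, caches
            )
        records.append(rec)

    if calibration is None:
        calibration = fit_calibration(records)
    sign = -1.0 if flip_sign else 1.0
    rows = []
    for rec in records:
        rec.hh = sign * hh_score(rec, calibration)
        rows.append(
            {
                "chrom": panel.chrom[rec.site],
                "start": int(panel.pos[rec.site]) - 1,
                "end": int(panel.pos[rec.site]),
                "marker": rec.marker,
                "hh": rec.hh,
                "n_pops_included": sum(
                    c.included for c in rec.components.values()
                ),
                "truncated": any(
                    c.truncated for c in rec.components.values() if c.included
                ),
            }
        )
    return records, pd.DataFrame(rows)
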