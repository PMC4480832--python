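"""Haplotype entropies, calibration and the aggregated score."""

import math

import numpy as np
import pandas as pd
import pytest

from hhscan.panel import FocalMarkerSet
from hhscan.score import (
    CalibrationTable,
    HHRecord,
    PopComponents,
    conditional_entropy,
    fit_calibration,
    hh_score,
    score_markers,
    window_entropy,
)
from hhscan.simulate import SimConfig, simulate_panel


def _component(h_star, h_prime, n_major, n_minor, included=True):
    return PopComponents(
        h_star=h_star, h_prime=h_prime, n_total=n_major + n_minor,
        n_major=n_major, n_minor=n_minor, included=included,
    )


@pytest.mark.parametrize(
    "freqs, expected",
    [
        ([1.0], 0.0),
        ([0.5, 0.5], math.log(2)),
        ([0.5, 0.25, 0.25], 0.5 * math.log(2) + 0.5 * math.log(4)),
    ],
)
def test_window_entropy_values(freqs, expected):
    assert window_entropy(np.array(freqs)) == pytest.approx(expected, abs=1e-12)


def test_conditional_entropy_values():
    # one shared carrier haplotype: the sweep signature
    assert conditional_entropy(np.array([1.0])) == 0.0
    assert conditional_entropy(np.array([0.5, 0.5])) == pytest.approx(math.log(2))
    expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
    assert conditional_entropy(np.array([3, 1])) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_empty_table():
    with pytest.raises(ValueError):
        window_entropy(np.array([]))


def test_calibration_recovers_noiseless_coefficients(rng):
    records = []
    for i in range(50):
        n_major = int(rng.integers(10, 200))
        n_minor = int(rng.integers(2, 150))
        y = 5.0 + 0.4 * np.log(n_major) - 0.6 * np.log(n_minor)
        records.append(
            HHRecord(marker=f"m{i}", site=i,
                     components={"POP": _component(y, 0.0, n_major, n_minor)})
        )
    calib = fit_calibration(records)
    a, b_M, b_m = calib.params["POP"]
    assert a == pytest.approx(5.0, abs=1e-10)
    assert b_M == pytest.approx(0.4, abs=1e-10)
    assert b_m == pytest.approx(-0.6, abs=1e-10)


def test_calibration_mean_residual_zero(rng):
    records = []
    for i in range(200):
        n_major = int(rng.integers(6, 200))
        n_minor = int(rng.integers(1, 150))
        y = rng.normal()
        records.append(
            HHRecord(marker=f"m{i}", site=i,
                     components={"P1": _component(max(y, 0) + 1, 0.3, n_major, n_minor)})
        )
    calib = fit_calibration(records)
    resid = [
        c.h_star - c.h_prime - calib.predict("P1", c.n_major, c.n_minor)
        for rec in records
        for c in rec.components.values()
    ]
    assert abs(np.mean(resid)) < 1e-10


def test_calibration_underdetermined_and_rank_errors():
    recs = [
        HHRecord("m1", 0, {"P": _component(1.0, 0.0, 20, 5)}),
        HHRecord("m2", 1, {"P": _component(1.2, 0.0, 30, 7)}),
    ]
    with pytest.raises(ValueError, match="P"):
        fit_calibration(recs)
    # constant minor count -> ln N_m collinear with intercept
    recs = [
        HHRecord(f"m{i}", i, {"Q": _component(1.0 + i, 0.0, 20 + i, 5)})
        for i in range(10)
    ]
    with pytest.raises(ValueError, match="Q"):
        fit_calibration(recs)


def test_hh_score_aggregation():
    calib = CalibrationTable(params={"A": (0.0, 0.0, 0.0), "B": (0.0, 0.0, 0.0)})
    # all populations excluded -> empty sum -> 0
    rec = HHRecord("m", 0, {"A": _component(1, 0, 3, 2, included=False)})
    assert hh_score(rec, calib) == 0.0
    # residual exactly zero -> 0
    rec = HHRecord("m", 0, {"A": _component(0.0, 0.0, 10, 4)})
    assert hh_score(rec, calib) == pytest.approx(0.0)
    # residuals +0.3 and -0.1 -> -(0.3 - 0.1) = -0.2
    rec = HHRecord(
        "m", 0,
        {"A": _component(0.3, 0.0, 10, 4), "B": _component(-0.1, 0.0, 10, 4)},
    )
    assert hh_score(rec, calib) == pytest.approx(-0.2, abs=1e-12)


def test_hh_score_missing_population_is_error():
    calib = CalibrationTable(params={"A": (0.0, 0.0, 0.0)})
    rec = HHRecord("m", 0, {"Z": _component(0.3, 0.0, 10, 4)})
    with pytest.raises(KeyError, match="Z"):
        hh_score(rec, calib)


def test_calibration_table_round_trip(tmp_path):
    calib = CalibrationTable(params={"CEU": (5.8, -0.52, -0.54), "YRI": (4.3, -0.11, -0.65)})
    path = tmp_path / "calib.tsv"
    calib.write(path)
    again = CalibrationTable.read(path)
    assert again.params == calib.params
    # column naming follows the published table layout
    cols = pd.read_csv(path, sep="\t").columns.tolist()
    assert cols == ["Population", "alpha", "beta_m", "beta_M"]


@pytest.fixture(scope="module")
def scored_panel():
    cfg = SimConfig(seed=5, n_regions=12, markers_per_region=6, sweep_fraction=0.3)
    panel, truth = simulate_panel(cfg)
    markers = FocalMarkerSet.from_identifiers(truth["marker"], panel)
    records, track = score_markers(panel, markers)
    return panel, truth, markers, records, track


def test_two_pass_rescoring_is_deterministic(scored_panel):
    panel, truth, markers, records, track = scored_panel
    calib = fit_calibration(records)
    records2, track2 = score_markers(panel, markers, calibration=calib)
    pd.testing.assert_frame_equal(track, track2)


def test_flip_sign_negates_scores(scored_panel):
    panel, truth, markers, records, track = scored_panel
    calib = fit_calibration(records)
    _, flipped = score_markers(panel, markers, calibration=calib, flip_sign=True)
    np.testing.assert_allclose(flipped["hh"], -track["hh"])


def test_component_bounds(scored_panel):
    _, _, _, records, _ = scored_panel
    checked = 0
    for rec in records:
        for c in rec.components.values():
            if not c.included:
                continue
            checked += 1
            assert c.h_star >= -1e-12
            assert -1e-12 <= c.h_prime <= np.log(c.n_minor) + 1e-9 or c.n_minor == 1
            assert c.h_star <= np.log(c.n_total) + 1e-9
            assert c.n_major + c.n_minor == c.n_total
    assert checked > 50


def test_score_is_less_smooth_than_windowed_control():
    """Adjacent-marker autocorrelation of the score stays below that of a
    50-site moving-average statistic on the same panel."""
    cfg = SimConfig(seed=9, n_regions=4, sites_per_region=400,
                    markers_per_region=40, sweep_fraction=0.0)
    panel, truth = simulate_panel(cfg)
    markers = FocalMarkerSet.from_identifiers(truth["marker"], panel)
    _, track = score_markers(panel, markers)

    from hhscan.windows import site_entropies

    def lag1(x):
        x = np.asarray(x, float)
        x = x - x.mean()
        return float(np.sum(x[1:] * x[:-1]) / np.sum(x * x))

    hh_ac, ctrl_ac = [], []
    for contig in [f"region{r}" for r in range(4)]:
        sel = track["chrom"] == contig
        hh_ac.append(lag1(track.loc[sel, "hh"]))
        # 50-site moving average of POP0 site entropy, sampled at the markers
        m = panel.site_mask("POP0") & (panel.chrom == contig)
        ent = site_entropies(panel.haplotypes["POP0"][:, m].mean(axis=0))
        smooth = np.convolve(ent, np.ones(50) / 50, mode="same")
        sites = np.where(panel.chrom == contig)[0]
        marker_sites = np.searchsorted(
            np.where(m)[0], [s for s in sites if panel.ids[s].startswith("rs")]
        )
        ctrl_ac.append(lag1(smooth[np.clip(marker_sites, 0, len(smooth) - 1)]))
    assert np.mean(hh_ac) < np.mean(ctrl_ac)


def test_monomorphic_marker_scores_zero():
    cfg = SimConfig(seed=13, n_regions=3, markers_per_region=3)
    panel, truth = simulate_panel(cfg)
    # force one focal marker monomorphic in every population
    site = int(np.where(panel.ids == truth["marker"].iloc[0])[0][0])
    for pop in panel.populations:
        panel.haplotypes[pop][:, site] = 0
    markers = FocalMarkerSet.from_identifiers(truth["marker"], panel)
    records, track = score_markers(panel, markers)
    rec = next(r for r in records if r.marker == truth["marker"].iloc[0])
    assert all(not c.included for c in rec.components.values())
    assert rec.hh == 0.0
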