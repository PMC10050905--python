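"""Multiplet identification, scoring, refinement and quantification."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hsqcmultiplet as hm
from hsqcmultiplet.library import Coupling, ResonanceEntry
from hsqcmultiplet.matching import (
    MultipletAssignment,
    _rho_of_column,
    adjusted_score,
    align_multiplet,
    analyze_metabolite,
    analyze_resonance,
    classify_trust,
    coefficient_of_determination,
    delta_ppm,
    detect_j_scaling,
    filter_peaks,
    fit_fractions,
    refine_proton_shift,
)
from hsqcmultiplet.multiplet import (
    LineshapeParams,
    enumerate_subsets,
    simulate_components,
)
from hsqcmultiplet.spectral_io import extract_region, nearest_index
from hsqcmultiplet.unmixing import LatentComponent

LINESHAPE = LineshapeParams(4.5)


# ---------------------------------------------------------------------------
# peak filtering
# ---------------------------------------------------------------------------


def bump(n, center, width, height):
    x = np.arange(n)
    return height * np.exp(-0.5 * ((x - center) / width) ** 2)


def test_minor_peak_suppressed_at_half_maximum_rule():
    trace = bump(200, 60, 5, 1.0) + bump(200, 140, 5, 0.4)
    out = filter_peaks(trace, 0.5)
    assert out[140] == 0.0
    assert np.all(out[130:150] == 0.0)
    np.testing.assert_array_equal(out[40:80], trace[40:80])


def test_equal_peaks_and_single_peak_unchanged():
    two = bump(200, 60, 5, 1.0) + bump(200, 140, 5, 1.0)
    np.testing.assert_array_equal(filter_peaks(two, 0.5), two)
    one = bump(200, 100, 5, 1.0)
    np.testing.assert_array_equal(filter_peaks(one, 0.5), one)


def test_all_zero_trace_unchanged():
    z = np.zeros(50)
    np.testing.assert_array_equal(filter_peaks(z, 0.5), z)


def test_retention_fraction_validated():
    with pytest.raises(ValueError):
        filter_peaks(np.ones(10), 1.5)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def test_delta_ppm_axis_weighting():
    gamma = hm.GAMMA_ADJUSTED
    assert delta_ppm(4.0, 70.0, 4.0, 70.0, gamma) == 0.0
    assert delta_ppm(4.07, 70.0, 4.0, 70.0, gamma) == pytest.approx(0.07)
    assert delta_ppm(4.0, 71.5, 4.0, 70.0, gamma) == pytest.approx(1.5 / gamma)
    both = delta_ppm(4.07, 71.5, 4.0, 70.0, gamma)
    assert both == pytest.approx(np.hypot(0.07, 1.5 / gamma))


def test_adjusted_score_penalises_library_distance():
    assert adjusted_score(90.0, 0.0, 1e-4) == pytest.approx(90.0 / 1e-4)
    assert adjusted_score(90.0, 0.01, 1e-4) > adjusted_score(90.0, 0.05, 1e-4)
    assert adjusted_score(0.0, 0.5, 1e-4) == 0.0
    with pytest.raises(ValueError):
        adjusted_score(90.0, 0.01, 0.0)


def test_coefficient_of_determination_identities():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    assert coefficient_of_determination(t, t) == 100.0
    assert coefficient_of_determination(t, np.full(4, t.mean())) == 0.0
    assert coefficient_of_determination(t, np.array([1.0, 2.0, 3.0, 5.0])) \
        == pytest.approx(80.0)


def test_rho_clamped_and_constant_trace_zero(caplog):
    t = np.array([1.0, 2.0, 3.0])
    terrible = np.array([100.0, -50.0, 80.0])
    assert coefficient_of_determination(t, terrible) == 0.0
    with caplog.at_level("WARNING", logger="hsqcmultiplet"):
        assert coefficient_of_determination(np.ones(5), np.arange(5.0)) == 0.0
    assert any("constant" in r.message for r in caplog.records)


@settings(deadline=None, max_examples=40)
@given(
    a=st.floats(min_value=0.1, max_value=50.0),
    b=st.floats(min_value=-100.0, max_value=100.0),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_rho_invariant_under_common_affine_map(a, b, seed):
    rng = np.random.default_rng(seed)
    t = rng.normal(size=30)
    t_hat = t + 0.3 * rng.normal(size=30)
    r1 = coefficient_of_determination(t, t_hat)
    r2 = coefficient_of_determination(a * t + b, a * t_hat + b)
    assert r1 == pytest.approx(r2, abs=1e-8)


@pytest.mark.parametrize("rho,expected", [
    (65.0, "not_trustworthy"),
    (70.0, "not_trustworthy"),
    (75.0, "borderline"),
    (80.0, "trustworthy"),
    (85.0, "trustworthy"),
])
def test_trust_classification_boundaries(rho, expected):
    assert classify_trust(rho, (80.0, 70.0)) == expected


# ---------------------------------------------------------------------------
# fraction regression
# ---------------------------------------------------------------------------


def make_components(entry, center=None, axis=None, freq_c=201.2, j_scaling=1):
    if axis is None:
        axis = np.linspace(entry.delta_c_lib + 2, entry.delta_c_lib - 2, 701)
    if center is None:
        center = entry.delta_c_lib
    return axis, simulate_components(entry, center, axis, LINESHAPE,
                                     freq_c, j_scaling)


def test_exact_mixture_recovered(dd_entry):
    _, comps = make_components(dd_entry)
    weights = np.array([0.5, 0.3, 0.2, 0.0])
    column = sum(w * c.trace for w, c in zip(weights, comps))
    fit = fit_fractions(column, comps)
    np.testing.assert_allclose(fit.fractions, weights, atol=1e-6)
    assert fit.rho == pytest.approx(100.0, abs=1e-6)
    assert fit.trust == "trustworthy"


def test_orthogonal_column_not_found(dd_entry):
    axis, comps = make_components(dd_entry)
    column = -np.ones(axis.size)          # nothing nonnegative can fit
    fit = fit_fractions(column, comps)
    assert fit.trust == "not_found"
    assert fit.rho == 0.0
    assert fit.fractions is None


def test_negative_true_weight_clamped(dd_entry):
    _, comps = make_components(dd_entry)
    column = comps[1].trace - 0.1 * comps[2].trace
    fit = fit_fractions(column, comps)
    assert fit.amplitudes[2] == 0.0
    assert fit.fractions[1] > 0.9


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_fractions_on_simplex(dd_entry, seed):
    """Whatever the data, reported fractions are >= 0 and sum to one."""
    _, comps = make_components(dd_entry)
    rng = np.random.default_rng(seed)
    column = np.abs(rng.normal(size=comps[0].trace.size))
    fit = fit_fractions(column, comps)
    if fit.trust != "not_found":
        assert np.all(fit.fractions >= 0)
        assert fit.fractions.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def region_for(entry, axes=None):
    axes = axes or hm.axes_for_entries([entry])
    grid, _ = hm.generate_spectrum(
        [(entry, np.ones(2 ** len(entry.one_bond_couplings()))
          / 2 ** len(entry.one_bond_couplings()))],
        axes, snr=np.inf, seed=0)
    return extract_region(grid, entry.delta_h_lib, entry.delta_c_lib, 0.15, 3.0)


def test_known_subset_and_offset_recovered(dd_entry, config):
    """A component built from a known subset at a known 13C offset is
    aligned back to that centre and subset."""
    region = region_for(dd_entry)
    axis_c = region.axis_c
    true_center_idx = nearest_index(axis_c, dd_entry.delta_c_lib - 0.4)
    true_center = float(axis_c[true_center_idx])
    comps = simulate_components(dd_entry, true_center, axis_c, LINESHAPE, 201.2)
    subset = (1, 2)                       # the two doublets, no singlet/dd
    trace = comps[1].trace + comps[2].trace
    component = LatentComponent(trace=trace / trace.max(), index=0,
                                assigned_h_ppm=dd_entry.delta_h_lib)
    best = align_multiplet(component, dd_entry, region, config)
    assert best is not None
    assert abs(best.x_c - true_center) <= abs(axis_c[0] - axis_c[1]) + 1e-12
    assert best.best_subset == subset
    assert best.rho > 99.0


def test_library_proximal_candidate_wins_on_equal_rho(doublet_entry, config):
    """Two identical copies of the multiplet, one at the library shift:
    the distance weighting must choose the library-proximal one."""
    region = region_for(doublet_entry)
    axis_c = region.axis_c
    lib_idx = nearest_index(axis_c, doublet_entry.delta_c_lib)
    far_idx = nearest_index(axis_c, doublet_entry.delta_c_lib + 1.2)
    comps_lib = simulate_components(doublet_entry, float(axis_c[lib_idx]),
                                    axis_c, LINESHAPE, 201.2)
    comps_far = simulate_components(doublet_entry, float(axis_c[far_idx]),
                                    axis_c, LINESHAPE, 201.2)
    trace = comps_lib[1].trace + comps_far[1].trace
    component = LatentComponent(trace=trace / trace.max(), index=0,
                                assigned_h_ppm=doublet_entry.delta_h_lib)
    best = align_multiplet(component, doublet_entry, region,
                           config.replace(align_candidates=None))
    assert best is not None
    assert abs(best.x_c - axis_c[lib_idx]) < 0.02


def test_component_without_signal_gives_no_assignment(dd_entry, config):
    region = region_for(dd_entry)
    flat = LatentComponent(trace=-np.ones(region.axis_c.size), index=0,
                           assigned_h_ppm=dd_entry.delta_h_lib)
    assert align_multiplet(flat, dd_entry, region, config) is None


def test_unlocalised_component_rejected(dd_entry, config):
    region = region_for(dd_entry)
    comp = LatentComponent(trace=np.ones(region.axis_c.size), index=0)
    with pytest.raises(ValueError, match="localised"):
        align_multiplet(comp, dd_entry, region, config)


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------


def unimodal_region(entry, j0, seed):
    """Region whose NNLS-rho profile is unimodal with its peak at column j0:
    every column mixes the true multiplet with a disturbance whose weight
    grows linearly with the distance from j0."""
    axes = hm.axes_for_entries([entry])
    axis_h, axis_c = axes.build()
    region = region_for(entry, axes)
    rng = np.random.default_rng(seed)
    _, comps = make_components(entry, center=float(
        region.axis_c[nearest_index(region.axis_c, entry.delta_c_lib)]),
        axis=region.axis_c)
    multiplet = np.mean([c.trace for c in comps], axis=0)
    disturbance = np.abs(rng.normal(size=region.axis_c.size))
    disturbance *= multiplet.max() / disturbance.max()
    n_cols = region.axis_h.size
    intensities = np.empty((region.axis_c.size, n_cols))
    for j in range(n_cols):
        w = 0.05 * abs(j - j0)
        intensities[:, j] = multiplet + w * disturbance
    grid = hm.SpectrumGrid(intensities, region.axis_h, region.axis_c,
                           800.13, 201.2)
    return hm.SpectrumRegion(grid, region.center_h, region.center_c,
                             region.half_width_h, region.half_width_c), comps


def exhaustive_best_column(region, comps):
    design = np.column_stack([c.trace for c in comps])
    rhos = [_rho_of_column(region.intensities[:, j], design)
            for j in range(region.axis_h.size)]
    return int(np.argmax(rhos))


def test_hill_climb_reaches_exhaustive_optimum(dd_entry):
    region, comps = unimodal_region(dd_entry, j0=13, seed=0)
    start = MultipletAssignment(
        entry=dd_entry, x_h=float(region.axis_h[5]), x_c=dd_entry.delta_c_lib,
        delta_ppm=0.0, best_subset=(0,), rho=0.0, rho_adjusted=0.0,
        source_component=0)
    refined = refine_proton_shift(region, start, comps)
    assert refined == pytest.approx(
        float(region.axis_h[exhaustive_best_column(region, comps)]))


def test_hill_climb_fixed_point_at_optimum(dd_entry):
    region, comps = unimodal_region(dd_entry, j0=10, seed=1)
    best = exhaustive_best_column(region, comps)
    start = MultipletAssignment(
        entry=dd_entry, x_h=float(region.axis_h[best]),
        x_c=dd_entry.delta_c_lib, delta_ppm=0.0, best_subset=(0,),
        rho=0.0, rho_adjusted=0.0, source_component=0)
    assert refine_proton_shift(region, start, comps) \
        == pytest.approx(float(region.axis_h[best]))


def test_hill_climb_stops_on_flat_profile(dd_entry):
    region = region_for(dd_entry)          # noiseless: rho identical everywhere
    _, comps = make_components(
        dd_entry, center=float(region.axis_c[nearest_index(
            region.axis_c, dd_entry.delta_c_lib)]), axis=region.axis_c)
    x0 = float(region.axis_h[7])
    start = MultipletAssignment(
        entry=dd_entry, x_h=x0, x_c=dd_entry.delta_c_lib, delta_ppm=0.0,
        best_subset=(0,), rho=0.0, rho_adjusted=0.0, source_component=0)
    assert refine_proton_shift(region, start, comps) == pytest.approx(x0)


# ---------------------------------------------------------------------------
# full per-metabolite analysis
# ---------------------------------------------------------------------------


def test_perturbed_lactate_recovered_noiseless(library, config):
    """Shifts moved by +0.05 ppm 1H / -0.5 ppm 13C are still found within
    0.01 / 0.1 ppm and the fractions within 0.03."""
    entries = library.resonances_of("lactate")
    rng = np.random.default_rng(11)
    shifted, fracs = [], {}
    for e in entries:
        se = dataclasses.replace(e, delta_h_lib=e.delta_h_lib + 0.05,
                                 delta_c_lib=e.delta_c_lib - 0.5)
        fr = hm.random_fractions(2 ** len(e.one_bond_couplings()), rng)
        shifted.append((se, fr))
        fracs[e.key] = fr
    axes = hm.axes_for_entries(entries)
    grid, _ = hm.generate_spectrum(shifted, axes, snr=np.inf, seed=0)
    fits = analyze_metabolite(grid, library, "lactate", config)
    assert len(fits) == 2
    for fit in fits:
        e = fit.entry
        assert fit.assignment is not None
        assert fit.assignment.x_h == pytest.approx(e.delta_h_lib + 0.05, abs=0.01)
        assert fit.assignment.x_c == pytest.approx(e.delta_c_lib - 0.5, abs=0.1)
        np.testing.assert_allclose(fit.fractions, fracs[e.key], atol=0.03)
        assert fit.rho >= 90.0


def test_noiseless_on_grid_recovery_is_essentially_exact(library, config):
    """With shifts on grid points and no noise, every resonance's fractions
    come back within 1e-3 and rho reaches 99.9."""
    rng = np.random.default_rng(31)
    for name in ("lactate", "aspartate"):
        for e in library.resonances_of(name):
            axes = hm.axes_for_entries([e])
            axis_h, axis_c = axes.build()
            snapped = dataclasses.replace(
                e,
                delta_h_lib=float(axis_h[np.argmin(np.abs(axis_h - e.delta_h_lib))]),
                delta_c_lib=float(axis_c[np.argmin(np.abs(axis_c - e.delta_c_lib))]))
            fr = hm.random_fractions(2 ** len(e.one_bond_couplings()), rng)
            grid, _ = hm.generate_spectrum([(snapped, fr)], axes,
                                           snr=np.inf, seed=0)
            fit = analyze_resonance(grid, snapped, config)
            np.testing.assert_allclose(fit.fractions, fr, atol=1e-3)
            assert fit.rho >= 99.9


def test_absent_metabolite_reports_not_found(library, config):
    """A resonance whose signal is missing ends as rho = 0 / not_found."""
    lactate = library.resonances_of("lactate")
    rng = np.random.default_rng(2)
    pairs = [(e, hm.random_fractions(2 ** len(e.one_bond_couplings()), rng))
             for e in lactate]
    axes = hm.axes_for_entries(lactate + library.resonances_of("alanine"))
    grid, _ = hm.generate_spectrum(pairs, axes, snr=100.0, seed=2)
    fits = analyze_metabolite(grid, library, "alanine", config)
    assert len(fits) == 2
    for fit in fits:
        assert fit.trust == "not_found"
        assert fit.rho == 0.0


def test_four_metabolites_give_eleven_results(library, config):
    entries = [e for m in library.metabolites for e in library.resonances_of(m)]
    rng = np.random.default_rng(3)
    pairs = [(e, hm.random_fractions(2 ** len(e.one_bond_couplings()), rng))
             for e in entries]
    axes = hm.axes_for_entries(entries)
    grid, _ = hm.generate_spectrum(pairs, axes, snr=50.0, seed=3)
    results = []
    for m in ("lactate", "alanine", "glutamate", "aspartate"):
        results.extend(analyze_metabolite(grid, library, m, config))
    assert len(results) == 11
    assert sum(f.trust != "not_found" for f in results) >= 9


# ---------------------------------------------------------------------------
# J-scaling detection
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("true_scaling", [1, 2])
def test_j_scaling_detected(library, config, true_scaling):
    entries = library.resonances_of("lactate")
    rng = np.random.default_rng(20 + true_scaling)
    pairs = [(e, hm.random_fractions(2 ** len(e.one_bond_couplings()), rng))
             for e in entries]
    axes = hm.axes_for_entries(entries)
    grid, _ = hm.generate_spectrum(pairs, axes, snr=50.0,
                                   j_scaling=true_scaling,
                                   seed=20 + true_scaling)
    assert detect_j_scaling(grid, library, ["lactate"], config) == true_scaling


def test_j_scaling_fallback_on_unanalysable_spectrum(library, config, caplog):
    entries = library.resonances_of("lactate")
    axes = hm.axes_for_entries(entries)
    axis_h, axis_c = axes.build()
    rng = np.random.default_rng(0)
    grid = hm.SpectrumGrid(rng.normal(size=(axis_c.size, axis_h.size)),
                           axis_h, axis_c, axes.freq_h, axes.freq_c,
                           j_scaling=4)
    with caplog.at_level("WARNING", logger="hsqcmultiplet"):
        assert detect_j_scaling(grid, library, ["lactate"], config) == 4
    assert any("falling back" in r.message for r in caplog.records)
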