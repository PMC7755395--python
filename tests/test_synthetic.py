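import numpy as np
import pytest

from neuroscales.spatial import inverse_distance_weights, moran_I
from neuroscales.spectra import compute_psd_median_welch
from neuroscales.specparam import empirical_acf, fit_spectral_model
from neuroscales.synthetic import (
    PlantedTruth,
    SimSignalConfig,
    add_oscillation,
    generate_aging_cohort,
    generate_electrode_dataset,
    generate_expression_matrix,
    generate_sa_map,
    generate_toy_ontology,
    generate_trial_dataset,
    make_sphere_geometry,
    sa_field,
    simulate_synaptic_current,
)


def test_sim_config_validation():
    with pytest.raises(ValueError):
        SimSignalConfig(fs=-1)
    with pytest.raises(ValueError):
        SimSignalConfig(tau_syn=-0.01)
    with pytest.raises(ValueError):
        SimSignalConfig(event_rate=0)
    with pytest.raises(ValueError, match="Nyquist"):
        SimSignalConfig(oscillations=((600.0, 1.0, 0.0),))
    with pytest.raises(ValueError, match="sample"):
        simulate_synaptic_current(SimSignalConfig(fs=100.0, tau_syn=0.005))


def test_simulation_determinism_and_length():
    cfg = SimSignalConfig(tau_syn=0.02, duration=3.0, seed=7,
                          oscillations=((10.0, 0.5, 1.0),), noise_std=0.1)
    a = simulate_synaptic_current(cfg)
    b = simulate_synaptic_current(cfg)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert len(a) == 3000


def test_delta_kernel_limit_flat_spectrum():
    ts = simulate_synaptic_current(SimSignalConfig(tau_syn=0.0, duration=30.0, seed=1))
    psd = compute_psd_median_welch(ts)
    band = (psd.freqs >= 1) & (psd.freqs <= 400)
    # white shot noise: log-log slope of the PSD indistinguishable from flat
    slope = np.polyfit(np.log10(psd.freqs[band]), np.log10(psd.power[band]), 1)[0]
    assert abs(slope) < 0.1


def test_fitted_knee_matches_theory():
    ts = simulate_synaptic_current(SimSignalConfig(tau_syn=0.02, duration=60.0, seed=2))
    res = fit_spectral_model(compute_psd_median_welch(ts))
    assert res.knee_frequency == pytest.approx(1.0 / (2 * np.pi * 0.02), rel=0.15)


def test_long_simulation_acf_matches_tau():
    ts = simulate_synaptic_current(SimSignalConfig(tau_syn=0.03, duration=300.0, seed=3))
    lags, acf = empirical_acf(ts, 0.3)
    crossing = lags[np.argmax(acf <= 1 / np.e)]
    assert crossing == pytest.approx(0.03, rel=0.20)


def test_add_oscillation_identity_and_peak():
    base = simulate_synaptic_current(SimSignalConfig(tau_syn=0.02, duration=30.0, seed=4))
    assert add_oscillation(base, 10.0, 0.0, 1.0, seed=0) is base
    with_osc = add_oscillation(base, 10.0, 1.0, 0.0, seed=0)
    psd = compute_psd_median_welch(with_osc)
    window = (psd.freqs >= 5) & (psd.freqs <= 15)
    assert psd.freqs[window][np.argmax(psd.power[window])] == pytest.approx(10.0, abs=1.0)
    with pytest.raises(ValueError, match="Nyquist"):
        add_oscillation(base, 600.0, 1.0, 0.0)


def test_drift_widens_fitted_peak():
    base = simulate_synaptic_current(SimSignalConfig(tau_syn=0.02, duration=60.0, seed=5))
    bw = {}
    for drift in (0.0, 1.0):
        osc = add_oscillation(base, 10.0, 1.0, drift, seed=6)
        res = fit_spectral_model(compute_psd_median_welch(osc))
        peaks = [p for p in res.peaks if 6 <= p.center <= 14]
        assert peaks, f"no peak recovered at drift={drift}"
        bw[drift] = max(p.bandwidth for p in peaks)
    assert bw[1.0] > bw[0.0]


def test_geometry_invariants():
    geom = make_sphere_geometry(50, points_per_parcel=3, seed=0)
    assert geom.n_parcels == 50
    assert geom.points.shape == (150, 3)
    d = geom.parcel_distance
    assert np.allclose(d, d.T) and np.all(np.diagonal(d) == 0) and np.all(d >= 0)
    assert np.bincount(geom.point_parcels, minlength=50).min() >= 1
    np.testing.assert_allclose(np.linalg.norm(geom.points, axis=1), 50.0, rtol=1e-9)


def test_sa_map_limits(geometry):
    tiny = generate_sa_map(geometry, 1e-6, seed=1)
    lagged = np.corrcoef(tiny.values[:-1], tiny.values[1:])[0, 1]
    assert abs(lagged) < 0.25
    huge = generate_sa_map(geometry, 1e4, seed=2)
    assert huge.values.var() < 0.05  # near-constant field
    assert np.all(generate_sa_map(geometry, 20.0, seed=3).confidence == 1.0)


def test_sa_map_variogram_increases_and_plateaus(geometry):
    from neuroscales.spatial import variogram

    rng = np.random.default_rng(0)
    fields = sa_field(geometry.parcel_distance, 20.0, rng, size=100)
    gs = np.array([variogram(f, geometry.parcel_distance, n_bins=12)[1] for f in fields])
    g = gs.mean(axis=0)
    assert g[0] < 0.5 * g[-1]  # rises from a small nugget
    assert abs(g[-1] - g[-3]) < 0.15 * np.ptp(g)  # plateau at long range


def test_moran_monotone_in_length_scale(geometry):
    W = inverse_distance_weights(geometry.parcel_distance)
    rng = np.random.default_rng(1)
    means = []
    for ls in (5.0, 15.0, 40.0):
        fields = sa_field(geometry.parcel_distance, ls, rng, size=100)
        means.append(np.mean([moran_I(f, W) for f in fields]))
    assert means[0] < means[1] < means[2]


def test_electrode_dataset_noiseless_single(geometry, smooth_map):
    sets = generate_electrode_dataset(geometry, smooth_map, 1, 1, 0.0, seed=0)
    assert len(sets) == 1 and sets[0].values.size == 1
    from neuroscales.projection import project_subject

    _, conf = project_subject(sets[0], geometry)
    assert np.sum(conf >= 1.0 - 1e-12) == 1  # exactly one point under the electrode
    # value equals the true map at the electrode's parcel
    idx = np.argmax(conf)
    assert sets[0].values[0] == smooth_map.values[geometry.point_parcels[idx]]


def test_electrode_dataset_determinism_and_subject_variability(geometry, smooth_map):
    a = generate_electrode_dataset(geometry, smooth_map, 4, 10, 0.1, seed=5)
    b = generate_electrode_dataset(geometry, smooth_map, 4, 10, 0.1, seed=5)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.positions, y.positions)
        np.testing.assert_array_equal(x.values, y.values)
    assert not np.array_equal(a[0].positions, a[1].positions)


def test_expression_matrix_planted_structure(geometry, smooth_map):
    expr, truth = generate_expression_matrix(geometry, smooth_map, 200, 25, 1.0, 0.0, seed=6)
    assert truth.associated_genes <= set(expr.gene_ids)
    idx = np.isin(expr.gene_ids, list(truth.associated_genes))
    # noiseless planted genes correlate perfectly with the target
    cors = [abs(np.corrcoef(row, smooth_map.values)[0, 1]) for row in expr.X[idx]]
    assert np.allclose(cors, 1.0)
    expr0, _ = generate_expression_matrix(geometry, smooth_map, 200, 0, 0.0, 1.0, seed=7)
    cors0 = [np.corrcoef(row, smooth_map.values)[0, 1] for row in expr0.X]
    assert abs(np.mean(cors0)) < 0.1
    with pytest.raises(ValueError):
        generate_expression_matrix(geometry, smooth_map, 10, 20, 1.0, 0.5, seed=8)


def test_toy_ontology_shapes_and_determinism():
    genes = [f"g{i}" for i in range(30)]
    a = generate_toy_ontology(genes, n_terms=9, term_size_range=(2, 10), seed=3)
    b = generate_toy_ontology(genes, n_terms=9, term_size_range=(2, 10), seed=3)
    assert a.term_genes == b.term_genes
    assert {ns for _, ns in a.term_meta.values()} == {"BP", "CC", "MF"}
    assert all(2 <= len(g) <= 10 for g in a.term_genes.values())
    with pytest.raises(ValueError):
        generate_toy_ontology(genes, term_size_range=(2, 50))


def test_trial_dataset_structure_and_truth():
    records, acc, truth = generate_trial_dataset(
        n_subjects=2, regions=("PC", "PFC"), n_trials=3, seed=1
    )
    assert len(records) == 2 * 2 * 3 * 3
    assert set(acc.index) == {"S00", "S01"}
    assert acc.between(0, 1).all()
    assert truth.delay_expansion == 1.2
    assert set(truth.extra["subject_expansions"]) == {"S00", "S01"}
    with pytest.raises(ValueError, match="regions"):
        generate_trial_dataset(regions=("V1",), seed=0)
    with pytest.raises(ValueError, match="epoch_s"):
        generate_trial_dataset(regions=("MTL",), epoch_s=0.05, seed=0)


def test_trial_dataset_no_effect_case():
    from neuroscales.cohort import wm_trial_features

    records, _, _ = generate_trial_dataset(
        n_subjects=4, regions=("PFC",), n_trials=25, delay_expansion=1.0,
        subject_expansion_log_sd=0.0, seed=2,
    )
    groups = {}
    for r in records:
        groups.setdefault((r.subject_id, r.trial_id), {})[r.period] = r.ts
    deltas = [
        f["delta_log_tau"]
        for f in (wm_trial_features(eps, {"max_peaks": 2}) for eps in groups.values())
        if f is not None
    ]
    deltas = np.asarray(deltas)
    # per-trial log-timescale change centered at zero (within sampling error)
    se = deltas.std(ddof=1) / np.sqrt(deltas.size)
    assert abs(deltas.mean()) < 4.0 * se
    assert abs(np.median(deltas)) < 5.0 * 1.25 * se


def test_trial_dataset_baseline_hierarchy_rank():
    from neuroscales.cohort import wm_cohort_features

    records, _, _ = generate_trial_dataset(
        n_subjects=8, regions=("PC", "PFC", "OFC", "MTL"), n_trials=20,
        baseline_tau_by_region={"PC": 0.010, "PFC": 0.016, "OFC": 0.025,
                                "MTL": 0.040},
        subject_expansion_log_sd=0.0, seed=3,
    )
    feats = wm_cohort_features(records, fit_kwargs={"max_peaks": 2})
    medians = feats.groupby("region")["baseline_tau"].median()
    assert (
        medians["PC"] < medians["PFC"] < medians["OFC"] < medians["MTL"]
    )


def test_aging_cohort_bookkeeping(geometry):
    m, truth = generate_aging_cohort(geometry, n_subjects=40, seed=4)
    assert m.values.shape == (40, geometry.n_parcels)
    assert truth.true_map.shape == (geometry.n_parcels,)
    assert truth.extra["compression_per_year"] == 0.005
    m2, _ = generate_aging_cohort(geometry, n_subjects=40, seed=4)
    np.testing.assert_array_equal(
        np.nan_to_num(m.values), np.nan_to_num(m2.values)
    )


def test_planted_truth_validation():
    with pytest.raises(ValueError):
        PlantedTruth(delay_expansion=0.0)
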