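"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's inputs:
aperiodic field-potential signals built by convolving Poisson population
events with exponential synaptic kernels (whose decay constant tau is the
planted timescale; the theoretical spectrum is Lorentzian with knee
1/(2*pi*tau) and exponent 2), drifting narrowband oscillations, spatially
autocorrelated parcel maps on a spherical surface stand-in, sparse
idiosyncratic electrode coverage, gene expression with a planted subset of
map-associated genes, toy ontology annotations, working-memory trial
epochs with a planted delay-period timescale expansion, and an aging
cohort with a planted timescale compression. Every generator is
deterministic given its seed, and planted truths are returned alongside
the data for recovery tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .cohort import AgingMatrix, EpochRecord, REGIONS
from .projection import ElectrodeSet, ParcelMap, SurfaceGeometry
from .spectra import TimeSeries
from .transcriptomics import ExpressionMatrix, GeneAnnotation

__all__ = [
    "SimSignalConfig",
    "PlantedTruth",
    "simulate_synaptic_current",
    "add_oscillation",
    "make_sphere_geometry",
    "generate_sa_map",
    "generate_electrode_dataset",
    "generate_expression_matrix",
    "generate_trial_dataset",
    "generate_toy_ontology",
    "generate_aging_cohort",
]

logger = logging.getLogger(__name__)

DEFAULT_EVENT_RATE = 2000.0  # aggregate population events/s
KERNEL_TRUNCATION = 10.0  # kernel support in units of tau


@dataclass(frozen=True)
class SimSignalConfig:
    """Parameters of the synaptic-current signal simulation.

    ``tau_syn`` is the synaptic decay constant in seconds — the planted
    neuronal timescale. ``event_rate`` is the aggregate Poisson event rate
    of the driving population spikes. ``oscillations`` lists
    (center_hz, relative_amplitude, drift_std_hz) tuples.
    """

    fs: float = 1000.0
    duration: float = 60.0
    tau_syn: float = 0.02
    event_rate: float = DEFAULT_EVENT_RATE
    oscillations: tuple = ()
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.tau_syn < 0:
            raise ValueError("tau_syn must be non-negative")
        if self.event_rate <= 0:
            raise ValueError("event_rate must be positive")
        for center, _amp, _drift in self.oscillations:
            if center >= self.fs / 2:
                raise ValueError("oscillation center must be below Nyquist")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by a generator, joinable by id downstream."""

    true_map: np.ndarray = None
    associated_genes: frozenset = frozenset()
    effect_size: float = 0.0
    delay_expansion: float = 1.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.delay_expansion > 0:
            raise ValueError("delay_expansion must be positive")


def simulate_synaptic_current(config: SimSignalConfig) -> TimeSeries:
    """Poisson population events convolved with an exponential synaptic kernel.

    For decay constant tau the theoretical PSD is Lorentzian with exponent
    2 and knee frequency 1/(2*pi*tau). tau = 0 degenerates to white shot
    noise (delta kernel). The kernel is causal, truncated at 10*tau, and
    deliberately unnormalized — amplitude scale does not move the knee.
    A kernel-length burn-in is simulated and discarded so the output is
    stationary.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    tau = config.tau_syn
    if tau > 0 and tau * config.fs < 1:
        raise ValueError(
            f"tau_syn = {tau:g} s is below one sample at fs = {config.fs:g} Hz; "
            "increase fs or tau_syn"
        )
    if tau == 0:
        sig = rng.poisson(config.event_rate / config.fs, size=n).astype(float)
    else:
        klen = int(round(KERNEL_TRUNCATION * tau * config.fs))
        events = rng.poisson(config.event_rate / config.fs, size=n + klen).astype(float)
        kernel = np.exp(-np.arange(klen) / (tau * config.fs))
        sig = fftconvolve(events, kernel)[klen : klen + n]
    ts = TimeSeries(sig, config.fs)
    for i, (center, amp, drift) in enumerate(config.oscillations):
        ts = add_oscillation(ts, center, amp, drift, seed=rng.integers(2**31))
    if config.noise_std > 0:
        ts = TimeSeries(ts.samples + rng.normal(0, config.noise_std, n), config.fs)
    return ts


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # fold values into [lo, hi] by reflection
    w = hi - lo
    y = np.mod(x - lo, 2 * w)
    return lo + np.where(y < w, y, 2 * w - y)


def add_oscillation(
    ts: TimeSeries, center: float, amplitude: float, drift_std: float, seed: int = 0
) -> TimeSeries:
    """Add a (possibly frequency-drifting) sinusoid to a signal.

    The instantaneous frequency performs a random walk with standard
    deviation ``drift_std`` Hz per second, reflected within +/- 3 drift
    standard deviations of ``center`` — yielding the broad spectral peak
    characteristic of neural oscillations. ``amplitude`` is relative to the
    RMS of the (demeaned) input. amplitude = 0 returns the input unchanged.
    """
    if center >= ts.fs / 2:
        raise ValueError("oscillation center must be below Nyquist")
    if amplitude == 0:
        return ts
    rng = np.random.default_rng(seed)
    n = ts.samples.size
    if drift_std > 0:
        steps = rng.normal(0.0, drift_std / math.sqrt(ts.fs), size=n)
        f_inst = _reflect(center + np.cumsum(steps), center - 3 * drift_std,
                          center + 3 * drift_std)
        f_inst = np.clip(f_inst, 0.0, ts.fs / 2)
    else:
        f_inst = np.full(n, center)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / ts.fs + rng.uniform(0, 2 * np.pi)
    rms = float(np.std(ts.samples))
    osc = amplitude * rms * math.sqrt(2.0) * np.sin(phase)
    return TimeSeries(ts.samples + osc, ts.fs)


def make_sphere_geometry(
    n_parcels: int = 180,
    points_per_parcel: int = 4,
    radius_mm: float = 50.0,
    jitter_mm: float = 3.0,
    seed: int = 0,
) -> SurfaceGeometry:
    """Parcellated sphere: a cheap stand-in for a cortical hemisphere.

    Parcel centroids are spread quasi-uniformly (Fibonacci lattice) on a
    sphere of the given radius (~100 mm diameter by default); each parcel's
    points jitter tangentially around its centroid and are reprojected onto
    the sphere. Inter-parcel distance is the great-circle distance between
    centroids, the analogue of average geodesic distance.
    """
    rng = np.random.default_rng(seed)
    i = np.arange(n_parcels)
    golden = (1 + math.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n_parcels
    theta = 2 * np.pi * i / golden
    r_xy = np.sqrt(1 - z**2)
    centroids = radius_mm * np.stack(
        [r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1
    )
    pts = np.repeat(centroids, points_per_parcel, axis=0)
    pts = pts + rng.normal(0, jitter_mm, pts.shape)
    pts *= radius_mm / np.linalg.norm(pts, axis=1, keepdims=True)
    point_parcels = np.repeat(np.arange(n_parcels), points_per_parcel)
    unit = centroids / radius_mm
    cosang = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = radius_mm * np.arccos(cosang)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return SurfaceGeometry(
        parcel_ids=np.array([f"P{j:03d}" for j in range(n_parcels)]),
        points=pts,
        point_parcels=point_parcels,
        parcel_distance=dist,
    )


def sa_field(
    distmat: np.ndarray, length_scale: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field(s) with squared-exponential
    covariance exp(-d^2 / (2 * length_scale^2)) over the given distances."""
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    C = np.exp(-np.asarray(distmat, float) ** 2 / (2.0 * length_scale**2))
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(C) / C.shape[0]
        while True:
            try:
                L = np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
                logger.info("SA covariance needed diagonal jitter %.3e", jitter)
                break
            except np.linalg.LinAlgError:
                jitter *= 10
    out = (L @ rng.standard_normal((C.shape[0], size))).T
    return out[0] if size == 1 else out


def generate_sa_map(
    geometry: SurfaceGeometry, length_scale: float, seed: int = 0
) -> ParcelMap:
    """Spatially autocorrelated parcel map with confidence 1 everywhere."""
    rng = np.random.default_rng(seed)
    values = sa_field(geometry.parcel_distance, length_scale, rng)
    return ParcelMap(
        geometry.parcel_ids, values, np.ones(geometry.n_parcels),
        meta={"length_scale": length_scale, "seed": seed},
    )


def generate_electrode_dataset(
    geometry: SurfaceGeometry,
    true_map: ParcelMap,
    n_subjects: int,
    electrodes_per_subject: int,
    value_noise_std: float = 0.0,
    seed: int = 0,
) -> list[ElectrodeSet]:
    """Sparse idiosyncratic electrode coverage sampled from a ground-truth map.

    Each subject's electrodes sit at random geometry points; the electrode
    value is the true map's value at that point's parcel plus Gaussian
    noise.
    """
    if electrodes_per_subject < 1:
        raise ValueError("electrodes_per_subject must be >= 1")
    rng = np.random.default_rng(seed)
    n_points = geometry.points.shape[0]
    out = []
    for s in range(n_subjects):
        idx = rng.choice(n_points, size=min(electrodes_per_subject, n_points),
                         replace=electrodes_per_subject > n_points)
        values = true_map.values[geometry.point_parcels[idx]]
        values = values + rng.normal(0.0, value_noise_std, values.size)
        out.append(ElectrodeSet(f"S{s:03d}", geometry.points[idx], values))
    return out


def generate_expression_matrix(
    geometry: SurfaceGeometry,
    target_map: ParcelMap,
    n_genes: int = 1000,
    n_associated: int = 50,
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    length_scale: float = 20.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Gene-by-parcel expression with a planted map-associated gene subset.

    Associated genes are effect_size * target_map + SA noise of the given
    standard deviation; the remaining genes are pure unit-variance SA
    noise. The associated gene ids are recorded in the returned
    PlantedTruth.
    """
    if n_associated > n_genes:
        raise ValueError("n_associated must be <= n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"G{g:05d}" for g in range(n_genes)])
    fields = sa_field(geometry.parcel_distance, length_scale, rng, size=n_genes)
    X = np.atleast_2d(fields)
    assoc_idx = rng.choice(n_genes, size=n_associated, replace=False)
    X[assoc_idx] = effect_size * target_map.values[None, :] + noise_sd * X[assoc_idx]
    truth = PlantedTruth(
        true_map=target_map.values.copy(),
        associated_genes=frozenset(gene_ids[assoc_idx]),
        effect_size=effect_size,
    )
    return ExpressionMatrix(X, gene_ids), truth


DEFAULT_BASELINE_TAU = {"PC": 0.012, "PFC": 0.018, "OFC": 0.024, "MTL": 0.030}


def generate_trial_dataset(
    n_subjects: int = 14,
    regions: tuple = REGIONS,
    n_trials: int = 40,
    baseline_tau_by_region: dict | None = None,
    delay_expansion: float = 1.2,
    fs: float = 1000.0,
    epoch_s: float = 0.9,
    seed: int = 0,
    subject_expansion_log_sd: float = 0.1,
    event_rate: float = DEFAULT_EVENT_RATE,
    accuracy_slope: float = 8.0,
    accuracy_intercept: float = 0.8,
    accuracy_noise_sd: float = 0.02,
) -> tuple[list[EpochRecord], pd.Series, PlantedTruth]:
    """Working-memory epoch cohort with a planted delay-period expansion.

    Baseline epochs are synaptic-current simulations with region-specific
    timescales; delay epochs use the subject's expanded timescale,
    tau * expansion_s, where expansion_s scatters log-normally around the
    planted ``delay_expansion`` across subjects. Behavioral accuracy is a
    logistic function of the subject's (log) expansion plus noise, so the
    planted accuracy-expansion association is monotone.

    Returns (epoch records, per-subject accuracy, planted truth).
    """
    unknown = set(regions) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown regions: {sorted(unknown)}")
    baseline_tau_by_region = baseline_tau_by_region or {
        r: DEFAULT_BASELINE_TAU[r] for r in regions
    }
    max_tau = max(baseline_tau_by_region.values())
    if epoch_s < 2 * max_tau:
        raise ValueError("epoch_s must be >= 2 * max baseline tau")
    rng = np.random.default_rng(seed)
    records: list[EpochRecord] = []
    accuracy = {}
    expansions = {}
    for s in range(n_subjects):
        sid = f"S{s:02d}"
        expansion = delay_expansion * math.exp(
            rng.normal(0.0, subject_expansion_log_sd)
        )
        expansions[sid] = expansion
        acc = 1.0 / (1.0 + math.exp(-(accuracy_intercept
                                      + accuracy_slope * math.log(expansion / delay_expansion))))
        accuracy[sid] = float(np.clip(acc + rng.normal(0, accuracy_noise_sd), 0.0, 1.0))
        for region in regions:
            tau_b = baseline_tau_by_region[region]
            tau_d = tau_b * expansion
            for trial in range(n_trials):
                for period, tau in (
                    ("baseline", tau_b), ("delay1", tau_d), ("delay2", tau_d)
                ):
                    ts = simulate_synaptic_current(
                        SimSignalConfig(
                            fs=fs, duration=epoch_s, tau_syn=tau,
                            event_rate=event_rate, seed=int(rng.integers(2**31)),
                        )
                    )
                    records.append(
                        EpochRecord(sid, region, f"{sid}-{region}-ch0", period,
                                    trial, ts)
                    )
    truth = PlantedTruth(
        delay_expansion=delay_expansion,
        extra={"subject_expansions": expansions,
               "baseline_tau_by_region": dict(baseline_tau_by_region)},
    )
    return records, pd.Series(accuracy, name="accuracy"), truth


def generate_toy_ontology(
    gene_ids,
    n_terms: int = 30,
    term_size_range: tuple[int, int] = (5, 50),
    seed: int = 0,
    extra_terms: dict | None = None,
) -> GeneAnnotation:
    """Random term-to-gene annotation cycling namespaces over BP/CC/MF.

    ``extra_terms`` may inject terms with chosen gene sets (e.g., exactly a
    planted gene subset) for recovery tests.
    """
    gene_ids = list(gene_ids)
    lo, hi = term_size_range
    if hi > len(gene_ids):
        raise ValueError("term sizes must not exceed the number of genes")
    rng = np.random.default_rng(seed)
    namespaces = ("BP", "CC", "MF")
    term_genes, term_meta = {}, {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        tid = f"TOY:{t:07d}"
        term_genes[tid] = {gene_ids[i] for i in members}
        term_meta[tid] = (f"toy term {t}", namespaces[t % 3])
    for tid, (genes, name, namespace) in (extra_terms or {}).items():
        term_genes[tid] = set(genes)
        term_meta[tid] = (name, namespace)
    return GeneAnnotation(term_genes, term_meta)


def generate_aging_cohort(
    geometry: SurfaceGeometry,
    n_subjects: int = 106,
    age_range: tuple[float, float] = (13.0, 62.0),
    compression_per_year: float = 0.005,
    base_tau_s: float = 0.02,
    map_log_sd: float = 0.3,
    length_scale: float = 20.0,
    coverage_range: tuple[int, int] = (3, 24),
    noise_log_sd: float = 0.1,
    subject_log_sd: float = 0.15,
    seed: int = 0,
) -> tuple[AgingMatrix, PlantedTruth]:
    """Sparse subjects-by-parcels timescale cohort with planted aging compression.

    The per-parcel baseline timescale map is log-normal around
    ``base_tau_s`` with spatial autocorrelation; each subject's timescale
    at a covered parcel is the map value scaled by
    (1 - compression_per_year * (age - age_min)), a subject-level
    log-normal factor (``subject_log_sd``: inter-individual variability
    that does not average out with coverage, keeping the age effect at a
    realistic moderate size), and per-parcel log-normal noise. Coverage is
    idiosyncratic: each subject covers a random subset of parcels whose
    size is uniform over ``coverage_range``, so a realistic fraction of
    subjects falls below the usual 10-parcel analysis threshold.
    """
    rng = np.random.default_rng(seed)
    n_parcels = geometry.n_parcels
    z = sa_field(geometry.parcel_distance, length_scale, rng)
    tau_map = base_tau_s * np.exp(map_log_sd * z)
    ages = rng.uniform(*age_range, size=n_subjects)
    V = np.full((n_subjects, n_parcels), np.nan)
    for s in range(n_subjects):
        k = int(rng.integers(coverage_range[0], coverage_range[1] + 1))
        cover = rng.choice(n_parcels, size=k, replace=False)
        scale = 1.0 - compression_per_year * (ages[s] - age_range[0])
        scale *= math.exp(rng.normal(0.0, subject_log_sd))
        V[s, cover] = tau_map[cover] * scale * np.exp(
            rng.normal(0.0, noise_log_sd, size=k)
        )
    matrix = AgingMatrix(V, ages, subject_ids=np.array([f"S{s:03d}" for s in range(n_subjects)]),
                         parcel_ids=geometry.parcel_ids)
    truth = PlantedTruth(
        true_map=tau_map,
        extra={"compression_per_year": compression_per_year, "ages": ages},
    )
    return matrix, truth
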