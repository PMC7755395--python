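"""Behavioral and lifespan analyses of neuronal timescales.

Two tracks:

* Working memory: per-trial spectral fits of 900 ms baseline and delay
  epochs give a baseline timescale and a delay-vs-baseline log-timescale
  change (plus narrowband theta, high-gamma and spectral-exponent deltas);
  features aggregate channels -> trials -> subject, and region statistics
  test the baseline hierarchy (Mann-Whitney U) and the delay expansion
  (Wilcoxon signed-rank), with a Spearman correlation against behavioral
  accuracy.
* Aging: a subjects-by-parcels timescale matrix with idiosyncratic
  missingness is max-normalized per parcel before per-subject averaging
  (avoiding the coverage/hierarchy confound), then correlated with age,
  overall and parcel-wise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import TimeSeries, band_log_power, compute_psd_epoch
from .specparam import fit_spectral_model

__all__ = [
    "REGIONS",
    "EpochRecord",
    "AgingMatrix",
    "wm_trial_features",
    "wm_cohort_features",
    "wm_region_stats",
    "wm_behavior_correlation",
    "aging_subject_means",
    "aging_age_correlation",
    "aging_parcelwise",
]

logger = logging.getLogger(__name__)

REGIONS = ("PC", "PFC", "OFC", "MTL")
PERIODS = ("baseline", "delay1", "delay2")

THETA_BAND = (3.0, 8.0)
HIGH_GAMMA_BAND = (70.0, 100.0)


@dataclass(frozen=True)
class EpochRecord:
    """One 900 ms (nominal) epoch of one channel in one trial period."""

    subject_id: str
    region: str
    channel_id: str
    period: str
    trial_id: int
    ts: TimeSeries

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}; expected one of {PERIODS}")


def _epoch_features(ts: TimeSeries, fit_kwargs: dict) -> dict | None:
    psd = compute_psd_epoch(ts)
    res = fit_spectral_model(psd, **fit_kwargs)
    if not res.converged or not np.isfinite(res.tau):
        return None
    return {
        "tau": res.tau,
        "exponent": res.aperiodic.exponent,
        "theta": band_log_power(psd, *THETA_BAND),
        "high_gamma": band_log_power(psd, *HIGH_GAMMA_BAND),
    }


def wm_trial_features(
    epochs: dict[str, TimeSeries],
    fit_kwargs: dict | None = None,
    delay_average: str = "geometric",
) -> dict | None:
    """Features for one channel/trial from its baseline, delay1, delay2 epochs.

    The two delay-period timescale estimates are combined into a single
    delay value — geometrically by default: the single-trial tau
    distribution is non-normal (heavy right tail), which is also why the
    timescale change is measured as a difference of natural-log
    timescales, and averaging the two delay estimates on the linear scale
    would push a Jensen bias of order (ln-scale variance)/4 into that
    difference. ``delay_average="arithmetic"`` restores the linear-scale
    mean for sensitivity analysis. Band powers and exponent change as
    delay minus baseline. Returns None (trial dropped) when any epoch's
    fit fails.
    """
    missing = set(PERIODS) - set(epochs)
    if missing:
        raise ValueError(f"missing periods: {sorted(missing)}")
    if delay_average not in ("geometric", "arithmetic"):
        raise ValueError("delay_average must be 'geometric' or 'arithmetic'")
    fit_kwargs = fit_kwargs or {}
    feats = {p: _epoch_features(epochs[p], fit_kwargs) for p in PERIODS}
    if any(f is None for f in feats.values()):
        return None
    base = feats["baseline"]
    if delay_average == "geometric":
        tau_delay = math.sqrt(feats["delay1"]["tau"] * feats["delay2"]["tau"])
    else:
        tau_delay = 0.5 * (feats["delay1"]["tau"] + feats["delay2"]["tau"])

    def delta(key):
        return 0.5 * (feats["delay1"][key] + feats["delay2"][key]) - base[key]

    return {
        "baseline_tau": base["tau"],
        "delay_tau": tau_delay,
        "delta_log_tau": math.log(tau_delay) - math.log(base["tau"]),
        "delta_theta": delta("theta"),
        "delta_high_gamma": delta("high_gamma"),
        "delta_exponent": delta("exponent"),
    }


def wm_cohort_features(
    records: list[EpochRecord],
    fit_kwargs: dict | None = None,
    delay_average: str = "geometric",
) -> pd.DataFrame:
    """Subject-by-region feature table from raw epoch records.

    Aggregation order is fixed: per-trial features are averaged across a
    region's channels first, then across trials, yielding one row per
    (subject, region). Trials with any failed epoch fit are dropped and
    counted in the log.
    """
    rows = []
    dropped = 0
    groups: dict[tuple, dict[str, TimeSeries]] = {}
    for r in records:
        groups.setdefault(
            (r.subject_id, r.region, r.channel_id, r.trial_id), {}
        )[r.period] = r.ts
    for (subject, region, channel, trial), epochs in sorted(groups.items()):
        feats = wm_trial_features(epochs, fit_kwargs, delay_average=delay_average)
        if feats is None:
            dropped += 1
            continue
        rows.append(
            {"subject_id": subject, "region": region, "channel_id": channel,
             "trial_id": trial, **feats}
        )
    if dropped:
        logger.info("working memory: dropped %d trials with failed fits", dropped)
    if not rows:
        raise ValueError("no trials survived spectral fitting")
    df = pd.DataFrame(rows)
    feature_cols = [c for c in df.columns if c not in
                    ("subject_id", "region", "channel_id", "trial_id")]
    # single-trial tau estimates are heavy-tailed (non-normal), so the tau
    # columns aggregate geometrically; log-differences and band deltas are
    # additive and aggregate arithmetically
    tau_cols = ["baseline_tau", "delay_tau"]
    df[tau_cols] = np.log(df[tau_cols])
    per_trial = (
        df.groupby(["subject_id", "region", "trial_id"], sort=True)[feature_cols]
        .mean()
        .reset_index()
    )
    per_subject = (
        per_trial.groupby(["subject_id", "region"], sort=True)[feature_cols]
        .mean()
        .reset_index()
    )
    per_subject[tau_cols] = np.exp(per_subject[tau_cols])
    n_trials = (
        per_trial.groupby(["subject_id", "region"], sort=True)["trial_id"]
        .size()
        .rename("n_trials")
        .reset_index()
    )
    return per_subject.merge(n_trials, on=["subject_id", "region"])


def wm_region_stats(features: pd.DataFrame) -> dict:
    """Baseline-hierarchy and delay-change tests on subject-region features.

    Pairwise two-sided Mann-Whitney U compares subject baseline timescales
    between regions; a per-region two-sided Wilcoxon signed-rank tests the
    subject delay-vs-baseline log-timescale changes against zero. Regions
    with fewer than two subjects are excluded (logged).
    """
    usable = {}
    for region, sub in features.groupby("region"):
        if len(sub) < 2:
            logger.info("region %s has %d subject(s); excluded", region, len(sub))
            continue
        usable[region] = sub
    pairwise = []
    names = [r for r in REGIONS if r in usable]
    for i, ra in enumerate(names):
        for rb in names[i + 1:]:
            u, p = stats.mannwhitneyu(
                usable[ra]["baseline_tau"], usable[rb]["baseline_tau"],
                alternative="two-sided",
            )
            pairwise.append({"region_a": ra, "region_b": rb, "U": float(u), "p": float(p)})
    delay = []
    for region in names:
        w, p = stats.wilcoxon(usable[region]["delta_log_tau"], alternative="two-sided")
        delay.append(
            {"region": region, "W": float(w), "p": float(p),
             "median_expansion": float(np.exp(usable[region]["delta_log_tau"].median()))}
        )
    return {
        "baseline_pairwise": pd.DataFrame(pairwise),
        "delay_change": pd.DataFrame(delay),
    }


def wm_behavior_correlation(
    features: pd.DataFrame,
    accuracy: pd.Series,
    region: str = "PFC",
) -> pd.DataFrame:
    """Spearman correlation of delay timescale expansion with task accuracy.

    Computed for every region; the row for ``region`` (PFC by default) is
    the headline result. ``accuracy`` maps subject_id to mean accuracy.
    """
    rows = []
    for reg, sub in features.groupby("region"):
        joined = sub.set_index("subject_id")["delta_log_tau"].to_frame().join(
            accuracy.rename("accuracy"), how="inner"
        ).dropna()
        if len(joined) < 5:
            continue
        r = stats.spearmanr(joined["delta_log_tau"], joined["accuracy"])
        rows.append(
            {"region": reg, "rho": float(r.statistic), "p": float(r.pvalue),
             "n": len(joined), "headline": reg == region}
        )
    if not rows:
        raise ValueError("no region has >= 5 subjects with both measures")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgingMatrix:
    """Subjects-by-parcels timescale values (NaN = no coverage) with ages."""

    values: np.ndarray
    ages: np.ndarray
    subject_ids: np.ndarray = None
    parcel_ids: np.ndarray = None

    def __post_init__(self):
        values = np.asarray(self.values, float)
        ages = np.asarray(self.ages, float)
        if values.ndim != 2 or values.shape[0] != ages.size:
            raise ValueError("values must be (n_subjects, n_parcels) matching ages")
        if np.any(ages <= 0):
            raise ValueError("ages must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ages", ages)
        if self.subject_ids is None:
            object.__setattr__(self, "subject_ids", np.arange(values.shape[0]))
        if self.parcel_ids is None:
            object.__setattr__(self, "parcel_ids", np.arange(values.shape[1]))


def aging_subject_means(
    matrix: AgingMatrix, min_valid_parcels: int = 10
) -> pd.DataFrame:
    """Per-subject mean of max-normalized parcel timescales.

    Each parcel is first divided by its maximum across subjects (so sparse,
    hierarchy-biased coverage does not masquerade as an age effect), then
    averaged within subjects over their covered parcels. Subjects with
    fewer than ``min_valid_parcels`` covered parcels are excluded and
    flagged. Parcels whose maximum is non-positive are dropped (logged).

    Returns a DataFrame indexed by subject with columns mean_normalized_tau,
    n_valid_parcels, included, age.
    """
    V = matrix.values.copy()
    import warnings

    with warnings.catch_warnings():
        # parcels no subject covers produce an all-NaN column, handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        colmax = np.nanmax(V, axis=0)
    bad = ~(colmax > 0)
    if bad.any():
        logger.warning("dropping %d parcels with non-positive max", int(bad.sum()))
        V[:, bad] = np.nan
        colmax[bad] = np.nan
    norm = V / colmax[None, :]
    n_valid = np.sum(np.isfinite(norm), axis=1)
    included = n_valid >= min_valid_parcels
    if not included.any():
        raise ValueError("no subject passes the minimum-parcel threshold")
    with np.errstate(all="ignore"):
        means = np.nanmean(np.where(np.isfinite(norm), norm, np.nan), axis=1)
    means[n_valid == 0] = np.nan
    return pd.DataFrame(
        {
            "mean_normalized_tau": means,
            "n_valid_parcels": n_valid,
            "included": included,
            "age": matrix.ages,
        },
        index=pd.Index(matrix.subject_ids, name="subject_id"),
    )


def aging_age_correlation(subject_means: pd.DataFrame) -> dict:
    """Spearman correlation between age and per-subject mean timescale."""
    sub = subject_means[subject_means["included"]]
    if len(sub) < 10:
        raise ValueError(f"only {len(sub)} included subjects; >= 10 required")
    r = stats.spearmanr(sub["age"], sub["mean_normalized_tau"])
    return {"rho": float(r.statistic), "p": float(r.pvalue), "n": len(sub)}


def aging_parcelwise(
    matrix: AgingMatrix, min_subjects: int = 5
) -> dict:
    """Per-parcel age-timescale Spearman correlations and their t-test.

    Parcels with fewer than ``min_subjects`` covered subjects are masked.
    The per-parcel correlation distribution is summarized by a two-sided
    one-sample t-test against zero.
    """
    n_parcels = matrix.values.shape[1]
    rhos = np.full(n_parcels, np.nan)
    counts = np.zeros(n_parcels, dtype=int)
    for j in range(n_parcels):
        ok = np.isfinite(matrix.values[:, j])
        counts[j] = ok.sum()
        if counts[j] >= min_subjects:
            rhos[j] = stats.spearmanr(
                matrix.ages[ok], matrix.values[ok, j]
            ).statistic
    valid = np.isfinite(rhos)
    if not valid.any():
        return {"rho": rhos, "n_subjects": counts, "valid_mask": valid,
                "t": np.nan, "p": np.nan, "n_parcels": 0}
    t, p = stats.ttest_1samp(rhos[valid], 0.0)
    return {
        "rho": rhos,
        "n_subjects": counts,
        "valid_mask": valid,
        "t": float(t),
        "p": float(p),
        "n_parcels": int(valid.sum()),
    }
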