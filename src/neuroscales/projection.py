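"""Electrode-to-parcel projection with Gaussian confidence weighting.

Sparse intracranial electrode values (e.g., per-channel timescales) are
extrapolated to surrounding geometry points with a Gaussian distance weight

    w(r) = exp(-r^2 / alpha^2)

acting as a confidence mask: a point directly under an electrode has
confidence 1, and with the default distance-scaling constant a point 4 mm
away has confidence 0.5. Point values are the w-weighted average over all
of a subject's electrodes; points aggregate to parcels by confidence-
weighted mean, and subjects combine into a group map the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeSet",
    "ParcelMap",
    "SurfaceGeometry",
    "gaussian_weight",
    "default_alpha",
    "project_subject",
    "aggregate_to_parcels",
    "combine_subjects",
    "coverage_report",
]


@dataclass(frozen=True)
class SurfaceGeometry:
    """Point/parcel abstraction of a cortical surface.

    ``points`` are 3-D coordinates in mm standing in for voxels/vertices;
    ``point_parcels`` assigns each point the index of its parcel;
    ``parcel_distance`` is a symmetric inter-parcel distance matrix in mm
    (the analogue of average geodesic distance).
    """

    parcel_ids: np.ndarray
    points: np.ndarray
    point_parcels: np.ndarray
    parcel_distance: np.ndarray

    def __post_init__(self):
        parcel_ids = np.asarray(self.parcel_ids)
        points = np.asarray(self.points, float)
        point_parcels = np.asarray(self.point_parcels, int)
        dist = np.asarray(self.parcel_distance, float)
        n = parcel_ids.size
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must be (n_points, 3)")
        if point_parcels.shape != (points.shape[0],):
            raise ValueError("point_parcels must match points")
        if dist.shape != (n, n):
            raise ValueError("parcel_distance must be (n_parcels, n_parcels)")
        if not np.allclose(dist, dist.T):
            raise ValueError("parcel_distance must be symmetric")
        if np.any(np.diagonal(dist) != 0):
            raise ValueError("parcel_distance diagonal must be zero")
        if np.any(dist < 0):
            raise ValueError("parcel_distance must be non-negative")
        counts = np.bincount(point_parcels, minlength=n)
        if np.any(counts == 0):
            raise ValueError("every parcel must contain at least one point")
        for name, val in (
            ("parcel_ids", parcel_ids),
            ("points", points),
            ("point_parcels", point_parcels),
            ("parcel_distance", dist),
        ):
            object.__setattr__(self, name, val)

    @property
    def n_parcels(self) -> int:
        return self.parcel_ids.size


@dataclass(frozen=True)
class ElectrodeSet:
    """One subject's electrodes: positions (mm) and scalar values."""

    subject_id: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, float))
        val = np.atleast_1d(np.asarray(self.values, float))
        if pos.shape != (val.size, 3):
            raise ValueError("positions must be (n_electrodes, 3) matching values")
        if val.size < 1:
            raise ValueError("at least one electrode required")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(val))):
            raise ValueError("non-finite electrode position or value")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class ParcelMap:
    """Per-parcel scalar values with confidence in [0, 1].

    Parcels with confidence below ``confidence_floor`` are invalid
    (``valid_mask`` False) and carry NaN values.
    """

    parcel_ids: np.ndarray
    values: np.ndarray
    confidence: np.ndarray
    confidence_floor: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = np.asarray(self.parcel_ids)
        values = np.asarray(self.values, float)
        conf = np.asarray(self.confidence, float)
        if not (ids.shape == values.shape == conf.shape):
            raise ValueError("parcel_ids, values, confidence must share shape")
        if np.any((conf < 0) | (conf > 1)):
            raise ValueError("confidence must lie in [0, 1]")
        values = values.copy()
        values[conf < self.confidence_floor] = np.nan
        object.__setattr__(self, "parcel_ids", ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "confidence", conf)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.confidence >= self.confidence_floor

    @property
    def n_parcels(self) -> int:
        return self.parcel_ids.size


def default_alpha() -> float:
    """Distance-scaling constant alpha = 4/sqrt(ln 2) mm.

    The unique alpha for which w(4 mm) = 0.5, i.e., a point 4 mm from an
    electrode receives 50% confidence.
    """
    return 4.0 / math.sqrt(math.log(2.0))


def gaussian_weight(r, alpha: float | None = None):
    """Gaussian confidence weight w(r) = exp(-r^2/alpha^2).

    ``r`` is the electrode-to-point Euclidean distance in mm; accepts
    scalars or arrays. With the default alpha, w(0) = 1 and w(4) = 0.5.
    """
    if alpha is None:
        alpha = default_alpha()
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = np.exp(-(r**2) / alpha**2)
    return float(out) if out.ndim == 0 else out


# weights below this total are treated as no evidence rather than divided out
_WEIGHT_FLOOR = 1e-300


def project_subject(
    es: ElectrodeSet,
    geometry: SurfaceGeometry,
    alpha: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extrapolate one subject's electrode values to all geometry points.

    Returns ``(values, confidence)`` per point: the value is the
    w(r)-weighted average over *all* electrodes (no distance cutoff), the
    confidence is the maximum single-electrode weight. Points whose total
    weight underflows get NaN value and confidence 0, never a propagating
    NaN from a 0/0 division.
    """
    diff = geometry.points[:, None, :] - es.positions[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=-1))  # (n_points, n_electrodes)
    w = gaussian_weight(r, alpha)
    wsum = w.sum(axis=1)
    conf = w.max(axis=1)
    values = np.full(geometry.points.shape[0], np.nan)
    ok = wsum > _WEIGHT_FLOOR
    values[ok] = (w[ok] @ es.values) / wsum[ok]
    conf = np.where(ok, conf, 0.0)
    return values, conf


def aggregate_to_parcels(
    point_values: np.ndarray,
    point_confidence: np.ndarray,
    geometry: SurfaceGeometry,
    confidence_floor: float = 0.5,
) -> ParcelMap:
    """Confidence-weighted mean of point values within each parcel.

    Parcel confidence is the maximum over member points; parcels with zero
    total confidence are invalid.
    """
    n = geometry.n_parcels
    values = np.full(n, np.nan)
    conf = np.zeros(n)
    pv = np.asarray(point_values, float)
    pc = np.asarray(point_confidence, float)
    wsum = np.bincount(geometry.point_parcels, weights=pc, minlength=n)
    contrib = np.where(pc > 0, pc * np.nan_to_num(pv), 0.0)
    vsum = np.bincount(geometry.point_parcels, weights=contrib, minlength=n)
    ok = wsum > _WEIGHT_FLOOR
    values[ok] = vsum[ok] / wsum[ok]
    # parcel confidence = max member confidence
    np.maximum.at(conf, geometry.point_parcels, pc)
    return ParcelMap(geometry.parcel_ids, values, conf, confidence_floor=confidence_floor)


def combine_subjects(maps: list[ParcelMap]) -> ParcelMap:
    """Group map: per-parcel confidence-weighted average across subjects.

    Only parcels valid within a subject contribute that subject's value;
    group confidence is the maximum subject confidence; parcels valid in no
    subject are invalid.
    """
    if not maps:
        raise ValueError("no maps to combine")
    ids = maps[0].parcel_ids
    floor = maps[0].confidence_floor
    for m in maps[1:]:
        if not np.array_equal(m.parcel_ids, ids):
            raise ValueError("all maps must share the same parcellation")
    n = ids.size
    num = np.zeros(n)
    den = np.zeros(n)
    conf = np.zeros(n)
    for m in maps:
        use = m.valid_mask & np.isfinite(m.values)
        num[use] += m.confidence[use] * m.values[use]
        den[use] += m.confidence[use]
        conf = np.maximum(conf, m.confidence)
    values = np.full(n, np.nan)
    ok = den > 0
    values[ok] = num[ok] / den[ok]
    # group validity = evidence from at least one subject
    group_conf = np.where(ok, conf, np.minimum(conf, floor * 0.999))
    return ParcelMap(ids, values, group_conf, confidence_floor=floor)


def coverage_report(
    maps: list[ParcelMap], confidence_floor: float = 0.5
) -> tuple[np.ndarray, float]:
    """Per-parcel count of subjects with confidence >= ``confidence_floor``.

    Returns (counts, implied distance bound in mm): confidence >= 0.5 under
    the default alpha corresponds to an electrode within 4 mm.
    """
    if not maps:
        raise ValueError("no maps")
    counts = np.zeros(maps[0].n_parcels, dtype=int)
    for m in maps:
        counts += (m.confidence >= confidence_floor).astype(int)
    # invert w(r) = floor for the implied distance bound
    bound = default_alpha() * math.sqrt(-math.log(confidence_floor))
    return counts, bound
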