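"""Per-segment flight-feature battery.

Each segment yields a fixed, named set of scalar features built from two
kinds of primitive:

* **series features** — per-timestep quantities (speed, accelerations, turn
  angles, orthogonal velocity components, centroid distances ...), each
  reduced to a nine-statistic summary (mean, median, standard deviation,
  1st/3rd quartile, kurtosis, skewness, number of local extrema, number of
  zero crossings);
* **scalar features** — whole-segment shape descriptors (straightness,
  convex-hull volume and surface area, planar curvature summaries, curvature
  scale space summaries, fractal dimension).

Angle-like quantities are undefined across a zero-length displacement
(a stationary frame): such steps are dropped from the affected series rather
than imputed.  A feature whose series collapses entirely is emitted as NaN
and resolved by median imputation fitted on training rows only (see
:func:`fit_imputer`).

Feature names follow ``family_plane_statistic`` (e.g. ``angvel_XY_q3``);
the full schema is enumerated by :func:`feature_schema`.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .css import css_summary
from .segmentation import Segment

logger = logging.getLogger(__name__)

LINEAGE_COLUMNS = ("segment_id", "track_id", "trial_id", "label")

#: Plane tags map to the coordinate columns of the projection.
PLANES = {"XY": (0, 1), "YZ": (1, 2), "XZ": (0, 2)}

SUMMARY_STATS = (
    "mean",
    "median",
    "std",
    "q1",
    "q3",
    "kurtosis",
    "skewness",
    "n_extrema",
    "n_zero_cross",
)

SERIES_FAMILIES = (
    "speed",
    "radial_accel",
    "radial_jerk",
    "vx",
    "vy",
    "vz",
    "ax",
    "ay",
    "az",
    "jx",
    "jy",
    "jz",
    "angle_of_flight",
    "angvel_XY",
    "angvel_YZ",
    "angvel_XZ",
    "angvel_3D",
    "angacc_XY",
    "angacc_YZ",
    "angacc_XZ",
    "angacc_3D",
    "persistence",
    "turning",
    "inclination",
    "centroid_dist",
)

SCALAR_FEATURES = (
    "straightness",
    "hull_volume",
    "hull_area",
    "curv_XY_mean",
    "curv_XY_std",
    "curv_YZ_mean",
    "curv_YZ_std",
    "curv_XZ_mean",
    "curv_XZ_std",
    "css_mean",
    "css_std",
    "fractal_d",
)


def feature_schema() -> list[str]:
    """The fixed, ordered feature-name schema (identical for every segment)."""
    names = [
        f"{family}_{stat}" for family in SERIES_FAMILIES for stat in SUMMARY_STATS
    ]
    names.extend(SCALAR_FEATURES)
    return names


class DegenerateSegmentError(ValueError):
    """Segment too short for the requested stencil."""


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


def kinematics(segment: Segment) -> dict[str, np.ndarray]:
    """Axial velocity/acceleration/jerk plus speed and its derivatives.

    Derivatives use second-order central finite differences on interior
    points with second-order one-sided stencils at the boundaries.  Raw 3D
    velocity enters only through its magnitude (speed): a flying insect
    always moves forward, so the sign of the velocity vector is not
    informative.  ``radial_accel``/``radial_jerk`` are the signed first and
    second time derivatives of speed, capturing all three axes at once.
    """
    if segment.n_samples < 5:
        raise DegenerateSegmentError(
            f"segment {segment.segment_id!r}: need >= 5 samples for jerk"
        )
    t = segment.times
    vel = np.gradient(segment.positions, t, axis=0, edge_order=2)
    acc = np.gradient(vel, t, axis=0, edge_order=2)
    jerk = np.gradient(acc, t, axis=0, edge_order=2)
    speed = np.linalg.norm(vel, axis=1)
    radial_accel = np.gradient(speed, t, edge_order=2)
    radial_jerk = np.gradient(radial_accel, t, edge_order=2)
    return {
        "speed": speed,
        "radial_accel": radial_accel,
        "radial_jerk": radial_jerk,
        "vx": vel[:, 0],
        "vy": vel[:, 1],
        "vz": vel[:, 2],
        "ax": acc[:, 0],
        "ay": acc[:, 1],
        "az": acc[:, 2],
        "jx": jerk[:, 0],
        "jy": jerk[:, 1],
        "jz": jerk[:, 2],
    }


# ---------------------------------------------------------------------------
# turn angles
# ---------------------------------------------------------------------------


def _turn_angles(disp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Angle between consecutive displacement vectors.

    Returns (angles, valid): angles in [0, pi] at junctions 0..M-2 and a
    boolean mask marking junctions where both displacements are non-zero
    (zero-length steps make the angle undefined and are dropped).
    """
    norms = np.linalg.norm(disp, axis=1)
    a, b = disp[:-1], disp[1:]
    na, nb = norms[:-1], norms[1:]
    valid = (na > 0) & (nb > 0)
    denom = np.where(valid, na * nb, 1.0)
    cosang = np.einsum("ij,ij->i", a, b) / denom
    angles = np.arccos(np.clip(cosang, -1.0, 1.0))
    return angles, valid


def angle_of_flight(segment: Segment) -> np.ndarray:
    """3D angle of flight: relative change in direction between positions."""
    if segment.n_samples < 3:
        raise DegenerateSegmentError("need >= 3 samples for angle of flight")
    disp = np.diff(segment.positions, axis=0)
    angles, valid = _turn_angles(disp)
    return angles[valid]


def angular_rates(segment: Segment) -> dict[str, np.ndarray]:
    """Angular velocity/acceleration from the angle of flight.

    Four variants each: the XY, YZ and XZ planar projections plus the full
    3D track.  Angular velocity at a junction is the turn angle divided by
    the local time span (half the time across the two displacements);
    angular acceleration is its first difference over the junction times.
    """
    if segment.n_samples < 3:
        raise DegenerateSegmentError("need >= 3 samples for angular rates")
    t = segment.times
    out: dict[str, np.ndarray] = {}
    dt = (t[2:] - t[:-2]) / 2.0  # time span attributed to each junction
    t_junction = t[1:-1]
    variants: dict[str, np.ndarray] = {"3D": segment.positions}
    for tag, (i, j) in PLANES.items():
        variants[tag] = segment.positions[:, (i, j)]
    for tag, coords in variants.items():
        disp = np.diff(coords, axis=0)
        angles, valid = _turn_angles(disp)
        angvel = angles[valid] / dt[valid]
        tv = t_junction[valid]
        out[f"angvel_{tag}"] = angvel
        if len(angvel) >= 2:
            out[f"angacc_{tag}"] = np.diff(angvel) / np.diff(tv)
        else:
            out[f"angacc_{tag}"] = np.empty(0)
    return out


# ---------------------------------------------------------------------------
# orthogonal velocity components
# ---------------------------------------------------------------------------


def orthogonal_velocities(segment: Segment) -> dict[str, np.ndarray]:
    """Persistence, turning and inclination velocity components.

    Each displacement is expressed in spherical coordinates (rho, theta,
    phi); the angular increments Theta, Phi between consecutive steps and
    the instantaneous speed v = rho/dt are recombined into

        P = v sin(Phi) cos(Theta)   (persistence, tangential tendency)
        T = v sin(Phi) sin(Theta)   (turning, normal tendency)
        I = v cos(Phi)              (inclination, the orthogonal normal)

    which satisfy P^2 + T^2 + I^2 = v^2 exactly.  Steps with zero
    displacement have undefined spherical angles and are dropped.
    """
    if segment.n_samples < 3:
        raise DegenerateSegmentError("need >= 3 samples for orthogonal velocities")
    d = np.diff(segment.positions, axis=0)
    dt = np.diff(segment.times)
    rho = np.linalg.norm(d, axis=1)
    nonzero = rho > 0
    theta = np.arctan2(d[:, 1], d[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.arccos(np.clip(np.divide(d[:, 2], np.where(nonzero, rho, 1.0)), -1, 1))
    v = rho / dt
    # increments pair step i with step i+1; both must be non-degenerate
    valid = nonzero[:-1] & nonzero[1:]
    Theta = (theta[1:] - theta[:-1])[valid]
    Phi = (phi[1:] - phi[:-1])[valid]
    vv = v[:-1][valid]
    return {
        "persistence": vv * np.sin(Phi) * np.cos(Theta),
        "turning": vv * np.sin(Phi) * np.sin(Theta),
        "inclination": vv * np.cos(Phi),
        "v": vv,
    }


# ---------------------------------------------------------------------------
# shape descriptors
# ---------------------------------------------------------------------------


def straightness(segment: Segment) -> float:
    """Path length over start-to-end chord; 1 for a direct path, NaN if the
    segment returns exactly to its start (degenerate chord)."""
    steps = np.diff(segment.positions, axis=0)
    path = float(np.linalg.norm(steps, axis=1).sum())
    chord = float(np.linalg.norm(segment.positions[-1] - segment.positions[0]))
    if chord == 0.0:
        return float("nan")
    return path / chord


def convex_hull_metrics(segment: Segment) -> tuple[float, float]:
    """3D convex-hull volume (m^3) and surface area (m^2).

    Coplanar segments have volume 0 and area equal to both faces of the flat
    hull (twice the planar hull area); collinear segments have zero measure;
    a fully degenerate point cloud yields NaN sentinels.
    """
    pts = segment.positions
    if len(pts) < 4:
        raise DegenerateSegmentError("need >= 4 points for a 3D hull")
    try:
        hull = ConvexHull(pts)
        return float(hull.volume), float(hull.area)
    except QhullError:
        centred = pts - pts.mean(axis=0)
        u, s, vt = np.linalg.svd(centred, full_matrices=False)
        rank = int(np.sum(s > 1e-12 * max(s[0], 1e-300)))
        if rank >= 2:
            flat = centred @ vt[:2].T
            try:
                hull2d = ConvexHull(flat)
                return 0.0, 2.0 * float(hull2d.volume)
            except QhullError:
                return 0.0, 0.0
        if rank == 1:
            return 0.0, 0.0
        return float("nan"), float("nan")


def centroid_distance(segment: Segment) -> np.ndarray:
    """Distance of every sample to the segment centroid.

    Constant for smooth circular motion; variable under sudden direction
    changes.
    """
    centroid = segment.positions.mean(axis=0)
    return np.linalg.norm(segment.positions - centroid, axis=1)


def curvature(segment: Segment) -> dict[str, float]:
    """Planar curvature summaries on the XY, YZ and XZ projections.

    First and second coordinate rates use forward differences over the
    sample times; the signed curvature series k_i = (a' b'' - b' a'') /
    (a'^2 + b'^2)^(3/2) is summarised by its mean and standard deviation.
    Steps with zero planar speed are dropped.
    """
    if segment.n_samples < 3:
        raise DegenerateSegmentError("need >= 3 samples for curvature")
    t = segment.times
    out: dict[str, float] = {}
    for tag, (i, j) in PLANES.items():
        a = segment.positions[:, i]
        b = segment.positions[:, j]
        dt = np.diff(t)
        da = np.diff(a) / dt
        db = np.diff(b) / dt
        dda = np.diff(da) / dt[:-1]
        ddb = np.diff(db) / dt[:-1]
        da, db = da[:-1], db[:-1]
        denom = (da**2 + db**2) ** 1.5
        valid = denom > 0
        k = (da[valid] * ddb[valid] - db[valid] * dda[valid]) / denom[valid]
        if len(k) >= 2:
            out[f"curv_{tag}_mean"] = float(np.mean(k))
            out[f"curv_{tag}_std"] = float(np.std(k, ddof=1))
        elif len(k) == 1:
            out[f"curv_{tag}_mean"] = float(k[0])
            out[f"curv_{tag}_std"] = float("nan")
        else:
            out[f"curv_{tag}_mean"] = float("nan")
            out[f"curv_{tag}_std"] = float("nan")
    return out


def fractal_dimension(segment: Segment) -> float:
    """Path-complexity exponent d = log(n) / log(1/S).

    n is the total 3D path length and 1/S the bounding-box diagonal: a
    straight path has d = 1 exactly, a plane-filling Brownian-like path
    approaches d = 2.  Undefined (NaN) when the diagonal is 0 or exactly 1
    (the scaling-factor logarithm vanishes) or the path has zero length.
    """
    pts = segment.positions
    steps = np.diff(pts, axis=0)
    n = float(np.linalg.norm(steps, axis=1).sum())
    extent = pts.max(axis=0) - pts.min(axis=0)
    diagonal = float(np.linalg.norm(extent))
    if n <= 0 or diagonal <= 0 or diagonal == 1.0:
        return float("nan")
    return float(np.log(n) / np.log(diagonal))


# ---------------------------------------------------------------------------
# nine-statistic summary
# ---------------------------------------------------------------------------


def _sign_changes(values: np.ndarray) -> int:
    """Strict sign changes among the non-zero entries of `values`."""
    s = np.sign(values)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def summarise(values: np.ndarray) -> dict[str, float]:
    """Nine-statistic summary of a per-timestep series.

    Quartiles use the linear-interpolation convention; the standard
    deviation uses the n-1 denominator; kurtosis is Fisher (normal == 0);
    local extrema are strict sign changes of the first difference and zero
    crossings strict sign changes of the raw series (exact zeros skipped).
    Constant series have skewness/kurtosis 0 by convention; an empty series
    yields NaN sentinels.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return {s: float("nan") for s in SUMMARY_STATS}
    mean = float(v.mean())
    d = v - mean
    m2 = float(np.mean(d * d))
    if n == 1 or m2 == 0.0:
        skew, kurt, std = 0.0, 0.0, 0.0
        if n > 1:
            std = float(np.std(v, ddof=1))
    else:
        m3 = float(np.mean(d**3))
        m4 = float(np.mean(d**4))
        skew = m3 / m2**1.5
        kurt = m4 / (m2 * m2) - 3.0  # Fisher convention (normal == 0)
        std = float(np.sqrt(m2 * n / (n - 1)))
    q1, median, q3 = np.percentile(v, (25, 50, 75))
    return {
        "mean": mean,
        "median": float(median),
        "std": std,
        "q1": float(q1),
        "q3": float(q3),
        "kurtosis": kurt,
        "skewness": skew,
        "n_extrema": float(_sign_changes(np.diff(v))) if n > 1 else 0.0,
        "n_zero_cross": float(_sign_changes(v)),
    }


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def extract_features(segment: Segment, css_config: Mapping | None = None) -> dict[str, float]:
    """Compute the full named feature vector for one segment.

    Deterministic; identical schema for every segment (see
    :func:`feature_schema`).  Degenerate sub-features come out as NaN and
    are resolved by imputation at matrix level.
    """
    series: dict[str, np.ndarray] = {}
    series.update(kinematics(segment))
    series["angle_of_flight"] = angle_of_flight(segment)
    series.update(angular_rates(segment))
    ortho = orthogonal_velocities(segment)
    series["persistence"] = ortho["persistence"]
    series["turning"] = ortho["turning"]
    series["inclination"] = ortho["inclination"]
    series["centroid_dist"] = centroid_distance(segment)

    out: dict[str, float] = {}
    for family in SERIES_FAMILIES:
        summary = summarise(series[family])
        for stat in SUMMARY_STATS:
            out[f"{family}_{stat}"] = summary[stat]

    out["straightness"] = straightness(segment)
    volume, area = convex_hull_metrics(segment)
    out["hull_volume"] = volume
    out["hull_area"] = area
    out.update(curvature(segment))
    css_cfg = dict(css_config or {})
    css_mean, css_std = css_summary(segment.positions, **css_cfg)
    out["css_mean"] = css_mean
    out["css_std"] = css_std
    out["fractal_d"] = fractal_dimension(segment)
    return out


def build_feature_matrix(
    segments: Sequence[Segment], css_config: Mapping | None = None
) -> pd.DataFrame:
    """Feature matrix: one row per segment, lineage columns first.

    Segments too short for the stencils are skipped with a log message
    (never a crash); NaN entries remain for the training-fitted imputer.
    """
    rows = []
    skipped = 0
    for seg in segments:
        try:
            feats = extract_features(seg, css_config)
        except DegenerateSegmentError as exc:
            logger.warning("skipping segment %s: %s", seg.segment_id, exc)
            skipped += 1
            continue
        row = {
            "segment_id": seg.segment_id,
            "track_id": seg.track_id,
            "trial_id": seg.trial_id,
            "label": seg.label,
        }
        row.update(feats)
        rows.append(row)
    if skipped:
        logger.info("build_feature_matrix skipped %d degenerate segments", skipped)
    columns = list(LINEAGE_COLUMNS) + feature_schema()
    return pd.DataFrame(rows, columns=columns)


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in LINEAGE_COLUMNS]


def fit_imputer(train_matrix: pd.DataFrame) -> dict[str, float]:
    """Per-feature medians from training rows only (no test leakage)."""
    medians = {}
    for col in feature_columns(train_matrix):
        med = float(train_matrix[col].median())
        medians[col] = med if np.isfinite(med) else 0.0
    return medians


def impute(matrix: pd.DataFrame, medians: Mapping[str, float]) -> pd.DataFrame:
    """Replace NaN sentinels with training medians; returns a copy."""
    out = matrix.copy()
    for col, med in medians.items():
        if col in out.columns:
            out[col] = out[col].fillna(med)
    return out
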