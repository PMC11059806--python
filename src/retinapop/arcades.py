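"""Statistical shape model of the four major temporal arcades.

The macrovascular scaffold of each virtual eye starts from the two arterial
and two venous temporal arcades. A PCA-based statistical shape model is fitted
to a training set of landmark curves (fovea at the origin, left-eye
orientation, optic disc nasal at negative x) and new arcade quartets are drawn
from the model's principal-component distribution.

Training curves are normally manual segmentations of fundus photographs. This
module also ships :func:`generate_arcade_fixture`, a synthetic stand-in that
emulates such segmentations as noisy parabolic arcades opening temporally. The
fixture synthesizes curves in field-of-view degrees and converts them with the
fundus-photograph rule of thumb 10° ≈ 5 mm, the same scale rule applied to
real fundus landmarks.

Landmarks are fixed-count arc-length resamplings of each curve (inflexion
points are ill-posed on synthetic curves); the landmark count is a knob.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VESSEL_LABELS", "MM_PER_DEGREE", "LandmarkCurve", "ShapeModel",
    "generate_arcade_fixture", "reflect_right_eye", "fit_shape_model",
    "sample_arcades", "save_shape_model", "load_shape_model",
]

VESSEL_LABELS = ("sup-artery", "sup-vein", "inf-artery", "inf-vein")
MM_PER_DEGREE = 0.5  # 10 degrees of fundus field of view ~ 5 mm


@dataclass
class LandmarkCurve:
    """Ordered 2-D landmark chain of one arcade vessel (mm, fovea-origin)."""

    label: str
    points: np.ndarray  # (n_landmarks, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.label not in VESSEL_LABELS:
            raise ValueError(f"unknown vessel label {self.label!r}")


@dataclass
class ShapeModel:
    """PCA shape model over flattened 4-curve landmark sets."""

    mean: np.ndarray          # (d,) with d = 4 * n_landmarks * 2
    components: np.ndarray    # (k, d), orthonormal rows
    variances: np.ndarray     # (k,), non-increasing
    n_landmarks: int


def _arclength_resample(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an ordered polyline to ``n`` points uniform in arc length."""
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, points[:, 0]),
                            np.interp(t, s, points[:, 1])])


def generate_arcade_fixture(rng: np.random.Generator, n_eyes: int,
                            n_landmarks: int = 20) -> list[list[LandmarkCurve]]:
    """Synthetic landmark sets emulating segmented temporal arcades.

    Each eye yields four curves (superior/inferior x arterial/venous) modelled
    as noisy parabolic arms rooted at the optic disc (x ~ -4.5 mm, y ~ 0),
    arching temporally around the macula. Arteries are drawn slightly
    straighter than veins. Output is in mm, fovea at the origin, left-eye
    orientation; all curves stay far outside the foveal avascular zone.
    """
    if n_eyes < 2:
        raise ValueError("n_eyes must be >= 2")
    eyes: list[list[LandmarkCurve]] = []
    for _ in range(n_eyes):
        # per-eye anatomy, in degrees of field of view
        disc = np.array([-9.0, 0.0]) + rng.normal(0.0, [0.5, 0.4])
        curves = []
        for label in VESSEL_LABELS:
            sup = label.startswith("sup")
            artery = label.endswith("artery")
            side = 1.0 if sup else -1.0
            # curvature (deg^-1): veins arch more than arteries
            c = rng.normal(0.085 if not artery else 0.070, 0.008)
            c = max(c, 0.04)
            extent = rng.normal(12.0, 1.0)  # superior/inferior reach, deg
            yy = np.linspace(0.35, extent, 64)
            xx = disc[0] + c * yy ** 2
            # smooth low-frequency wiggle along the arm
            phase = rng.uniform(0, 2 * np.pi)
            xx = xx + 0.25 * np.sin(2 * np.pi * yy / extent + phase) * (yy / extent)
            pts_deg = np.column_stack([xx, side * (yy + max(0.0, rng.normal(0.2, 0.1)))])
            pts = _arclength_resample(pts_deg, n_landmarks) * MM_PER_DEGREE
            # keep each arm strictly on its own side of the raphe
            if sup:
                pts[:, 1] = np.maximum(pts[:, 1], 0.02)
            else:
                pts[:, 1] = np.minimum(pts[:, 1], -0.02)
            curves.append(LandmarkCurve(label, pts))
        eyes.append(curves)
    return eyes


def reflect_right_eye(curves: list[LandmarkCurve]) -> list[LandmarkCurve]:
    """Reflect a right-eye landmark set across the y-axis (left-eye frame)."""
    return [LandmarkCurve(c.label, c.points * np.array([-1.0, 1.0]))
            for c in curves]


def _flatten(curves: list[LandmarkCurve], n_landmarks: int) -> np.ndarray:
    by_label = {c.label: c for c in curves}
    rows = []
    for label in VESSEL_LABELS:
        pts = by_label[label].points
        if len(pts) != n_landmarks:
            raise ValueError(
                f"curve {label!r} has {len(pts)} landmarks, expected {n_landmarks}")
        rows.append(pts.ravel())
    return np.concatenate(rows)


def _unflatten(vec: np.ndarray, n_landmarks: int) -> list[LandmarkCurve]:
    parts = vec.reshape(4, n_landmarks, 2)
    return [LandmarkCurve(label, parts[i]) for i, label in enumerate(VESSEL_LABELS)]


def fit_shape_model(landmark_sets: list[list[LandmarkCurve]],
                    n_components: int = 5) -> ShapeModel:
    """Fit the PCA shape model to aligned training sets (fovea at origin,
    right eyes pre-reflected)."""
    if len(landmark_sets) < 2:
        raise ValueError("need at least 2 training sets")
    n_landmarks = len(landmark_sets[0][0].points)
    X = np.stack([_flatten(s, n_landmarks) for s in landmark_sets])
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD-based PCA; ranks beyond n_sets - 1 carry zero variance
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (len(X) - 1)
    k = min(n_components, len(var))
    return ShapeModel(mean=mean, components=Vt[:k], variances=var[:k],
                      n_landmarks=n_landmarks)


def reconstruct(model: ShapeModel, coeffs: np.ndarray) -> list[LandmarkCurve]:
    vec = model.mean + model.components.T @ np.asarray(coeffs, float)
    return _unflatten(vec, model.n_landmarks)


def project(model: ShapeModel, curves: list[LandmarkCurve]) -> np.ndarray:
    """Component coefficients of one landmark set."""
    vec = _flatten(curves, model.n_landmarks)
    return model.components @ (vec - model.mean)


def sample_arcades(model: ShapeModel, rng: np.random.Generator,
                   clamp_sd: float = 3.0) -> list[LandmarkCurve]:
    """Draw one 4-curve arcade set from the shape model.

    Coefficients are zero-mean normal with the model's component variances,
    clamped to ``+-clamp_sd`` standard deviations to avoid implausible
    outliers. ``clamp_sd=0`` returns the mean shape exactly.
    """
    sd = np.sqrt(model.variances)
    coeffs = rng.normal(0.0, 1.0, size=len(sd)) * sd
    coeffs = np.clip(coeffs, -clamp_sd * sd, clamp_sd * sd)
    return reconstruct(model, coeffs)


def save_shape_model(model: ShapeModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"mean": model.mean.tolist(),
                   "components": model.components.tolist(),
                   "variances": model.variances.tolist(),
                   "n_landmarks": model.n_landmarks}, fh)


def load_shape_model(path: str) -> ShapeModel:
    with open(path) as fh:
        d = json.load(fh)
    return ShapeModel(mean=np.array(d["mean"]), components=np.array(d["components"]),
                      variances=np.array(d["variances"]), n_landmarks=d["n_landmarks"])


def curves_to_csv(landmark_sets: list[list[LandmarkCurve]], path: str) -> None:
    """Landmark sets as CSV (eye_id, vessel_label, landmark_index, x_mm, y_mm)."""
    import pandas as pd
    rows = []
    for eye_id, curves in enumerate(landmark_sets):
        for c in curves:
            for i, (x, y) in enumerate(c.points):
                rows.append((eye_id, c.label, i, x, y))
    pd.DataFrame(rows, columns=["eye_id", "vessel_label", "landmark_index",
                                "x_mm", "y_mm"]).to_csv(path, index=False)
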