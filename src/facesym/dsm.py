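"""Dense surface model: a PCA shape space over corresponded surfaces.

The model is fitted on originals *and* their mirrored forms whenever
asymmetry analyses are intended; with a mirror-closed training set the
mean shape is symmetric and the principal modes separate into symmetric
and asymmetric families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correspondence import CorrespondedSurface, surfaces_to_matrix
from .errors import ModelError


@dataclass
class DSMModel:
    mean_shape: np.ndarray       # (3M,) mm
    modes: np.ndarray            # (k, 3M) orthonormal rows, variance-ordered
    variances: np.ndarray        # (k,) non-increasing
    retained: int                # modes covering coverage_target of variance
    coverage_target: float
    n_points: int                # M

    @property
    def cumulative_coverage(self) -> np.ndarray:
        total = self.variances.sum()
        return np.cumsum(self.variances) / total

    def retained_for(self, coverage: float) -> int:
        """Smallest mode count whose cumulative variance fraction ≥ coverage."""
        cum = self.cumulative_coverage
        return int(np.searchsorted(cum, coverage - 1e-12) + 1)


@dataclass
class PCScores:
    subject_id: str
    mirrored: bool
    scores: np.ndarray  # (retained,)


def fit_dsm(surfaces: list[CorrespondedSurface], coverage: float = 0.99) -> DSMModel:
    """PCA (SVD of the centered data matrix, divisor n−1) over corresponded faces.

    Mode signs are fixed so each mode's largest-magnitude coordinate is
    positive, making original/reflected score correlations reproducible.
    """
    if len(surfaces) < 3:
        raise ModelError(f"need at least 3 surfaces, got {len(surfaces)}")
    if not 0.0 < coverage <= 1.0:
        raise ModelError(f"coverage must be in (0, 1], got {coverage}")
    x = surfaces_to_matrix(surfaces)
    m_points = x.shape[1] // 3
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    variances = s**2 / (len(x) - 1)
    if variances.sum() <= 0:
        raise ModelError("zero total shape variance")
    # drop numerically-null modes
    keep = variances > variances[0] * 1e-14
    variances = variances[keep]
    modes = vt[keep]
    # deterministic sign convention
    flip = modes[np.arange(len(modes)), np.argmax(np.abs(modes), axis=1)] < 0
    modes[flip] *= -1.0

    cum = np.cumsum(variances) / variances.sum()
    retained = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    return DSMModel(mean_shape=mean, modes=modes, variances=variances,
                    retained=retained, coverage_target=coverage, n_points=m_points)


def project(model: DSMModel, surface: CorrespondedSurface,
            n_modes: int | None = None) -> PCScores:
    """Retained-mode scores: inner products of (surface − mean) with each mode."""
    k = model.retained if n_modes is None else n_modes
    vec = surface.points.reshape(-1)
    if vec.shape[0] != model.mean_shape.shape[0]:
        raise ModelError(
            f"surface has {vec.shape[0] // 3} points, model expects {model.n_points}")
    scores = model.modes[:k] @ (vec - model.mean_shape)
    return PCScores(subject_id=surface.subject_id, mirrored=surface.mirrored,
                    scores=scores)


def reconstruct(model: DSMModel, scores: PCScores | np.ndarray,
                subject_id: str = "", mirrored: bool = False) -> CorrespondedSurface:
    """mean + Σ scoreᵢ·modeᵢ, reshaped to M points."""
    if isinstance(scores, PCScores):
        vec, subject_id, mirrored = scores.scores, scores.subject_id, scores.mirrored
    else:
        vec = np.asarray(scores, float)
    if len(vec) > len(model.modes):
        raise ModelError(f"{len(vec)} scores but model has {len(model.modes)} modes")
    shape = model.mean_shape + vec @ model.modes[: len(vec)]
    return CorrespondedSurface(subject_id=subject_id, mirrored=mirrored,
                               points=shape.reshape(-1, 3))


def mode_sweep(model: DSMModel, mode_index: int, n_sd: float = 3.0,
               n_steps: int = 7) -> list[CorrespondedSurface]:
    """Surfaces along one mode from −n_sd to +n_sd standard deviations.

    Used to export mode animations that make an asymmetry mode visible.
    """
    sd = float(np.sqrt(model.variances[mode_index]))
    out = []
    for a in np.linspace(-n_sd, n_sd, n_steps):
        scores = np.zeros(mode_index + 1)
        scores[mode_index] = a * sd
        out.append(reconstruct(model, scores, subject_id=f"mode{mode_index}_{a:+.1f}sd"))
    return out


def save_dsm(model: DSMModel, path) -> None:
    np.savez_compressed(
        path, mean_shape=model.mean_shape, modes=model.modes,
        variances=model.variances,
        meta=np.array([model.retained, model.coverage_target, model.n_points]),
    )


def load_dsm(path) -> DSMModel:
    data = np.load(path)
    retained, coverage, n_points = data["meta"]
    return DSMModel(mean_shape=data["mean_shape"], modes=data["modes"],
                    variances=data["variances"], retained=int(retained),
                    coverage_target=float(coverage), n_points=int(n_points))
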