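"""Learned sensory-motor internal models and adaptation.

The planner never touches the plant directly: it plans through *internal
models* — deterministic maps from a motor command to its predicted auditory or
somatosensory consequence, learned by radial-basis-function (RBF) regression on
plant input/output pairs.  Prediction is Gaussian-kernel RBF plus an affine
tail, so a map trained on an affine plant is recovered (numerically) exactly.

Adaptation to a constant auditory perturbation δ is modelled as a complete and
perfect update of the auditory map: the adapted map predicts exactly the
original prediction plus δ.  Because δ is constant this is implemented as a
stored additive offset rather than a refit, which makes the adaptation identity
exact rather than approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

from .plant import N_CONTROLS

MODALITIES = ("auditory", "somatosensory")


class ModalityError(ValueError):
    """A map of the wrong sensory modality was supplied."""


@dataclass(frozen=True)
class PerturbationSpec:
    """A constant shift of the acoustic output, in Hz per formant.

    The reference experiment shifts only F1, down by 100 Hz:
    ``delta = (-100, 0, 0)``.
    """

    delta: tuple[float, float, float] = (-100.0, 0.0, 0.0)
    modality: str = "auditory"

    def __post_init__(self):
        if self.modality != "auditory":
            raise ModalityError("only auditory perturbations are supported")
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("perturbation delta must be finite")


@dataclass(frozen=True)
class SensoryMap:
    """Deterministic learned map from motor command to a 3-D sensory point."""

    modality: str
    centers: np.ndarray            # (k, 6) RBF centers in control space
    weights: np.ndarray            # (k + 7, 3) kernel weights then [1 | m] tail
    bandwidth: float
    bounds: np.ndarray             # (6, 2) training control box
    adaptation_offset: np.ndarray  # (3,) additive sensory offset
    heldout_rmse: np.ndarray       # (3,) per-output held-out RMSE at fit time

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ModalityError(f"unknown modality {self.modality!r}")

    def _features(self, M: np.ndarray) -> np.ndarray:
        cols = [np.ones((len(M), 1)), M]
        if len(self.centers):
            d2 = ((M[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1)
            cols.insert(0, np.exp(-0.5 * d2 / self.bandwidth**2))
        return np.concatenate(cols, axis=1)

    def predict(self, m) -> np.ndarray:
        """Predicted sensory point(s) for command(s) ``m`` (plus offset)."""
        m = np.asarray(m, dtype=float)
        single = m.ndim == 1
        M = np.atleast_2d(m)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        if np.any(M < lo - 1e-9) or np.any(M > hi + 1e-9):
            warnings.warn("predicting outside the training control box (extrapolation)")
        out = self._features(M) @ self.weights + self.adaptation_offset
        return out[0] if single else out

    @classmethod
    def from_affine(cls, A, c, modality: str, bounds) -> "SensoryMap":
        """Exact affine map ``m -> A m + c`` (no kernel part); handy as an
        analytically tractable stand-in for a fitted map."""
        A = np.asarray(A, float)
        c = np.asarray(c, float)
        weights = np.vstack([c[None, :], A.T])
        return cls(
            modality=modality,
            centers=np.empty((0, A.shape[1])),
            weights=weights,
            bandwidth=1.0,
            bounds=np.asarray(bounds, float),
            adaptation_offset=np.zeros(A.shape[0]),
            heldout_rmse=np.zeros(A.shape[0]),
        )

    # ---------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "type": "SensoryMap",
            "modality": self.modality,
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "bandwidth": self.bandwidth,
            "bounds": self.bounds.tolist(),
            "adaptation_offset": self.adaptation_offset.tolist(),
            "heldout_rmse": self.heldout_rmse.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensoryMap":
        if d.get("type") != "SensoryMap":
            raise ValueError(f"not a SensoryMap artifact: {d.get('type')!r}")
        return cls(
            modality=d["modality"],
            centers=np.array(d["centers"], float).reshape(-1, N_CONTROLS)
            if d["centers"]
            else np.empty((0, N_CONTROLS)),
            weights=np.array(d["weights"], float),
            bandwidth=float(d["bandwidth"]),
            bounds=np.array(d["bounds"], float),
            adaptation_offset=np.array(d["adaptation_offset"], float),
            heldout_rmse=np.array(d["heldout_rmse"], float),
        )


def fit_sensory_map(
    M,
    Y,
    modality: str,
    bounds,
    n_centers: int = 800,
    bandwidth: float | None = None,
    ridge: float = 1e-8,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> SensoryMap:
    """Fit an RBF sensory-motor map on (command, sensory output) pairs.

    Centers are a seeded k-means subset of the training commands; the kernel is
    Gaussian with ``bandwidth`` defaulting to the median distance between
    centers; weights come from a ridge-regularised exact linear solve.  A
    ``val_fraction`` held-out split measures the per-output RMSE, which is
    stored on the returned map as its fidelity budget.
    """
    M = np.asarray(M, float)
    Y = np.asarray(Y, float)
    if len(M) < 200:
        raise ValueError("need at least 200 training pairs")
    if len(M) != len(Y):
        raise ValueError("M and Y lengths differ")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(M))
    n_val = max(1, int(round(val_fraction * len(M))))
    val, train = perm[:n_val], perm[n_val:]
    Mt, Yt = M[train], Y[train]

    n_centers = min(n_centers, len(Mt))
    km = KMeans(n_clusters=n_centers, n_init=1, random_state=int(seed) % (2**32))
    km.fit(Mt)
    centers = km.cluster_centers_
    if bandwidth is None:
        d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        bandwidth = 0.5 * float(np.sqrt(np.median(d2[d2 > 0])))

    probe = SensoryMap(
        modality=modality,
        centers=centers,
        weights=np.zeros((len(centers) + N_CONTROLS + 1, Y.shape[1])),
        bandwidth=bandwidth,
        bounds=np.asarray(bounds, float),
        adaptation_offset=np.zeros(Y.shape[1]),
        heldout_rmse=np.zeros(Y.shape[1]),
    )
    Phi = probe._features(Mt)
    # Ridge on the kernel block only: the affine tail stays unpenalised so an
    # affine ground truth is reproduced exactly.
    pen = np.zeros(Phi.shape[1])
    pen[: len(centers)] = ridge
    G = Phi.T @ Phi + np.diag(pen)
    W = np.linalg.solve(G, Phi.T @ Yt)
    if not np.all(np.isfinite(W)):
        raise np.linalg.LinAlgError("singular RBF design despite regularisation")
    fitted = replace(probe, weights=W)
    resid = fitted.predict(M[val]) - Y[val]
    return replace(fitted, heldout_rmse=np.sqrt((resid**2).mean(axis=0)))


def adapt_auditory(smap: SensoryMap, pert: PerturbationSpec) -> SensoryMap:
    """Complete-and-perfect adaptation: shift the auditory map's output by δ.

    The returned map satisfies ``adapted.predict(m) == smap.predict(m) + δ``
    exactly for every command; the somatosensory map is never touched.
    """
    if smap.modality != "auditory":
        raise ModalityError("adaptation applies to the auditory map only")
    return replace(smap, adaptation_offset=smap.adaptation_offset + np.asarray(pert.delta, float))
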