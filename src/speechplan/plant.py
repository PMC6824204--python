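"""Synthetic articulatory plant: motor commands -> tongue contour -> sensory spaces.

The plant is a deterministic, smooth surrogate for a 2-D biomechanical tongue
model.  A 6-D motor command ``m`` (the control variables of an equilibrium-point
muscle model, one per modelled tongue muscle) drives

* a mid-sagittal tongue contour of 17 nodes (34 coordinates), and
* an acoustic output, the first three formant frequencies (F1, F2, F3) in Hz.

The somatosensory space is the score space of the first three principal
components of the flattened contour, fitted on a corpus of contours obtained by
uniform sampling of the control box.  The contour map and the acoustic map use
*different* nonlinearities so that the geometry of the auditory and
somatosensory spaces is mutually distorted, as in real vocal tracts: the
contour map mixes saturating (tanh) features, the acoustic map squashes a
quadratic form through per-formant logistic range maps.

Everything is deterministic given a :class:`Plant` instance, and a plant
serializes to JSON bit-exactly (Python float repr round-trips).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

N_CONTROLS = 6
N_NODES = 17
N_CONTOUR = 2 * N_NODES  # flattened row-major: node index major, x before y

#: Default control bounds: the equilibrium-point control variables are
#: dimensionless and normalised to [-1, 1] per muscle.
DEFAULT_BOUNDS = np.array([[-1.0, 1.0]] * N_CONTROLS)

#: Default plausible formant ranges (Hz), bracketing typical adult French
#: vowel formants: F1 height, F2 front-back, F3.
DEFAULT_FORMANT_RANGES = np.array([[150.0, 900.0], [800.0, 2800.0], [2000.0, 3800.0]])


class OutOfBoundsError(ValueError):
    """A motor command lies outside the plant's control box."""


def _as_controls(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape[-1] != N_CONTROLS:
        raise ValueError(f"motor command must have {N_CONTROLS} components, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("motor command must be finite")
    return m


@dataclass
class Plant:
    """Deterministic forward model from motor commands to sensory spaces.

    Build one with :meth:`Plant.build`; the constructor takes the raw
    parameter arrays (as produced by :meth:`to_dict` / :meth:`from_dict`).
    """

    bounds: np.ndarray                  # (6, 2) control box
    formant_ranges: np.ndarray          # (3, 2) Hz
    base_contour: np.ndarray            # (34,)
    contour_loadings: np.ndarray        # (34, 3) dominant directions
    feat_w: np.ndarray                  # (3, 6) saturating feature weights
    feat_b: np.ndarray                  # (3,)
    residual_mix: np.ndarray            # (34, 6) small full-rank residual
    res_w: np.ndarray                   # (6, 6)
    res_b: np.ndarray                   # (6,)
    res_scale: float
    acoustic_g: np.ndarray              # (3, 3) mixing of the contour features
    acoustic_w: np.ndarray              # (3, 6) residual feature directions
    acoustic_res: float                 # amplitude of the non-shape residual
    acoustic_b: np.ndarray              # (3,)
    acoustic_q: np.ndarray              # (3, 6, 6) symmetric quadratic coefficients
    acoustic_alpha: np.ndarray          # (3,) logistic slopes
    seed: int = 0
    pca_mean: np.ndarray | None = None        # (34,)
    pca_components: np.ndarray | None = None  # (3, 34) orthonormal rows
    pca_explained: np.ndarray | None = None   # (3,) explained-variance fractions

    # ------------------------------------------------------------------ build
    @classmethod
    def build(
        cls,
        seed: int = 0,
        bounds: np.ndarray | None = None,
        formant_ranges: np.ndarray | None = None,
        n_pca: int = 5000,
    ) -> "Plant":
        """Draw the surrogate's fixed mixing weights and fit the contour PCA.

        ``n_pca`` controls the size of the contour corpus used to fit the
        3-component PCA defining the somatosensory space.
        """
        bounds = DEFAULT_BOUNDS.copy() if bounds is None else np.asarray(bounds, float)
        franges = (
            DEFAULT_FORMANT_RANGES.copy()
            if formant_ranges is None
            else np.asarray(formant_ranges, float)
        )
        if bounds.shape != (N_CONTROLS, 2) or not np.all(
            np.isfinite(bounds)
        ) or np.any(bounds[:, 0] > bounds[:, 1]):
            raise ValueError("bounds must be finite (6, 2) with lo <= hi")
        rng = np.random.default_rng(seed)

        # Resting contour: a raised arc, roughly tongue-shaped in arbitrary
        # mid-sagittal units.
        theta = np.linspace(0.15 * np.pi, 0.85 * np.pi, N_NODES)
        base = np.stack([3.0 * np.cos(theta), 2.0 * np.sin(theta)], axis=1).ravel()

        # Dominant deformation directions: three orthonormal 34-D directions
        # with decreasing gains, driven by saturating features of m.  Gains
        # decay so that three PCs dominate the contour corpus.
        raw = rng.normal(size=(N_CONTOUR, 3))
        q, _ = np.linalg.qr(raw)
        # all three shape features clearly observable in the contour, so a
        # tongue shape pins down its acoustics up to the small residual terms
        loadings = q * np.array([1.6, 1.1, 0.8])

        feat_w = rng.normal(size=(3, N_CONTROLS))
        feat_w *= 1.0 / np.linalg.norm(feat_w, axis=1, keepdims=True)
        feat_b = rng.normal(scale=0.2, size=3)

        # Small full-rank residual so the contour Jacobian has column rank 6.
        residual_mix = rng.normal(size=(N_CONTOUR, N_CONTROLS))
        residual_mix /= np.linalg.norm(residual_mix, axis=0, keepdims=True)
        res_w = rng.normal(size=(N_CONTROLS, N_CONTROLS))
        res_w *= 1.0 / np.linalg.norm(res_w, axis=1, keepdims=True)
        res_b = rng.normal(scale=0.2, size=N_CONTROLS)
        res_scale = 0.06

        # Acoustic map: formants are driven by the same saturating contour
        # features as the tongue shape (acoustics is a function of vocal-tract
        # geometry), mixed through an orthogonal rotation, squashed into the
        # formant ranges by per-channel logistics, plus a small motor residual
        # and quadratic cross-terms so the relation to the somatosensory space
        # is distorted-but-not-affine and not exactly deterministic.
        ortho, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        # higher gain on the F1 channel: vowel height uses most of its range
        acoustic_g = np.array([2.9, 2.1, 2.1])[:, None] * ortho
        acoustic_w = rng.normal(size=(3, N_CONTROLS))
        acoustic_w *= 1.2 / np.linalg.norm(acoustic_w, axis=1, keepdims=True)
        acoustic_res = 0.02
        acoustic_b = rng.normal(scale=0.15, size=3)
        acoustic_q = rng.normal(scale=0.01, size=(3, N_CONTROLS, N_CONTROLS))
        acoustic_q = 0.5 * (acoustic_q + np.swapaxes(acoustic_q, 1, 2))
        acoustic_alpha = np.array([1.0, 1.0, 1.0])

        plant = cls(
            bounds=bounds,
            formant_ranges=franges,
            base_contour=base,
            contour_loadings=loadings,
            feat_w=feat_w,
            feat_b=feat_b,
            residual_mix=residual_mix,
            res_w=res_w,
            res_b=res_b,
            res_scale=res_scale,
            acoustic_g=acoustic_g,
            acoustic_w=acoustic_w,
            acoustic_res=acoustic_res,
            acoustic_b=acoustic_b,
            acoustic_q=acoustic_q,
            acoustic_alpha=acoustic_alpha,
            seed=int(seed),
        )
        controls = plant.sample_controls(n_pca, seed=seed + 1)
        plant.fit_pca(plant.contour(controls))
        return plant

    # ------------------------------------------------------------- operations
    def sample_controls(self, n: int, seed: int) -> np.ndarray:
        """Sample ``n`` motor commands i.i.d. uniform over the control box."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("control bounds must be finite")
        rng = np.random.default_rng(seed)
        u = rng.random((n, N_CONTROLS))
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return lo + u * (hi - lo)

    def _check_bounds(self, m: np.ndarray) -> None:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        if np.any(m < lo - 1e-9) or np.any(m > hi + 1e-9):
            raise OutOfBoundsError("motor command outside the control box")

    def contour(self, m) -> np.ndarray:
        """Mid-sagittal tongue contour for command(s) ``m``.

        Returns shape (17, 2) for a single command, (n, 17, 2) for a batch.
        """
        m = _as_controls(m)
        single = m.ndim == 1
        mm = np.atleast_2d(m)
        self._check_bounds(mm)
        g = np.tanh(mm @ self.feat_w.T + self.feat_b)          # (n, 3)
        h = np.tanh(mm @ self.res_w.T + self.res_b)            # (n, 6)
        flat = (
            self.base_contour
            + g @ self.contour_loadings.T
            + self.res_scale * (h @ self.residual_mix.T)
        )
        out = flat.reshape(-1, N_NODES, 2)
        return out[0] if single else out

    def fit_pca(self, contours: np.ndarray) -> np.ndarray:
        """Fit the 3-component contour PCA defining the somatosensory space.

        ``contours`` is (n, 17, 2) or (n, 34); requires n >= 100 distinct
        contours.  Returns the explained-variance fractions.
        """
        X = np.asarray(contours, float).reshape(len(contours), -1)
        if X.shape[0] < 100:
            raise ValueError("need at least 100 contours to fit the PCA")
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < 3:
            raise ValueError("contour corpus is rank-deficient for a 3-component PCA")
        pca = PCA(n_components=3, svd_solver="full")
        pca.fit(X)
        self.pca_mean = pca.mean_
        self.pca_components = pca.components_
        self.pca_explained = pca.explained_variance_ratio_
        return self.pca_explained

    def auditory(self, m) -> np.ndarray:
        """Formant frequencies (F1, F2, F3) in Hz for command(s) ``m``."""
        m = _as_controls(m)
        single = m.ndim == 1
        mm = np.atleast_2d(m)
        self._check_bounds(mm)
        g = np.tanh(mm @ self.feat_w.T + self.feat_b)
        z = g @ self.acoustic_g.T + self.acoustic_b
        z = z + np.einsum("ni,kij,nj->nk", mm, self.acoustic_q, mm)
        z = z + self.acoustic_res * np.tanh(mm @ self.acoustic_w.T)
        s = 1.0 / (1.0 + np.exp(-self.acoustic_alpha * z))
        lo, hi = self.formant_ranges[:, 0], self.formant_ranges[:, 1]
        f = lo + (hi - lo) * s
        return f[0] if single else f

    def somato(self, m) -> np.ndarray:
        """Somatosensory point: 3 PCA scores of the contour for ``m``."""
        if self.pca_components is None:
            raise ValueError("PCA basis not fitted; call fit_pca or Plant.build")
        c = self.contour(m)
        flat = c.reshape(-1, N_CONTOUR) if c.ndim == 3 else c.reshape(1, N_CONTOUR)
        scores = (flat - self.pca_mean) @ self.pca_components.T
        return scores[0] if c.ndim == 2 else scores

    def project_contour(self, contour: np.ndarray) -> np.ndarray:
        """PCA scores of an arbitrary (17, 2) or flattened (34,) contour."""
        if self.pca_components is None:
            raise ValueError("PCA basis not fitted")
        flat = np.asarray(contour, float).reshape(-1)
        return (flat - self.pca_mean) @ self.pca_components.T

    def corpus(self, n: int, seed: int):
        """Sampled controls plus their auditory and somatosensory outputs."""
        M = self.sample_controls(n, seed)
        return M, self.auditory(M), self.somato(M)

    def corpus_frame(self, n: int, seed: int):
        """Corpus as a tidy DataFrame: lambda_1..6, f1..f3, pc1..pc3."""
        import pandas as pd

        M, A, S = self.corpus(n, seed)
        data = {f"lambda_{i+1}": M[:, i] for i in range(N_CONTROLS)}
        data.update({f"f{i+1}": A[:, i] for i in range(3)})
        data.update({f"pc{i+1}": S[:, i] for i in range(3)})
        return pd.DataFrame(data)

    # ---------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = {
            "type": "Plant",
            "seed": self.seed,
            "bounds": self.bounds.tolist(),
            "formant_ranges": self.formant_ranges.tolist(),
            "base_contour": self.base_contour.tolist(),
            "contour_loadings": self.contour_loadings.tolist(),
            "feat_w": self.feat_w.tolist(),
            "feat_b": self.feat_b.tolist(),
            "residual_mix": self.residual_mix.tolist(),
            "res_w": self.res_w.tolist(),
            "res_b": self.res_b.tolist(),
            "res_scale": self.res_scale,
            "acoustic_g": self.acoustic_g.tolist(),
            "acoustic_res": self.acoustic_res,
            "acoustic_w": self.acoustic_w.tolist(),
            "acoustic_b": self.acoustic_b.tolist(),
            "acoustic_q": self.acoustic_q.tolist(),
            "acoustic_alpha": self.acoustic_alpha.tolist(),
        }
        for key in ("pca_mean", "pca_components", "pca_explained"):
            v = getattr(self, key)
            d[key] = None if v is None else v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Plant":
        if d.get("type") != "Plant":
            raise ValueError(f"not a Plant artifact: {d.get('type')!r}")
        arr = lambda k: np.array(d[k], dtype=float)
        opt = lambda k: None if d.get(k) is None else np.array(d[k], dtype=float)
        return cls(
            bounds=arr("bounds"),
            formant_ranges=arr("formant_ranges"),
            base_contour=arr("base_contour"),
            contour_loadings=arr("contour_loadings"),
            feat_w=arr("feat_w"),
            feat_b=arr("feat_b"),
            residual_mix=arr("residual_mix"),
            res_w=arr("res_w"),
            res_b=arr("res_b"),
            res_scale=float(d["res_scale"]),
            acoustic_g=arr("acoustic_g"),
            acoustic_res=float(d["acoustic_res"]),
            acoustic_w=arr("acoustic_w"),
            acoustic_b=arr("acoustic_b"),
            acoustic_q=arr("acoustic_q"),
            acoustic_alpha=arr("acoustic_alpha"),
            seed=int(d["seed"]),
            pca_mean=opt("pca_mean"),
            pca_components=opt("pca_components"),
            pca_explained=opt("pca_explained"),
        )


def apply_perturbation(a, delta) -> np.ndarray:
    """Perceived auditory point under an external formant shift: ``a + delta``."""
    a = np.asarray(a, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(delta))):
        raise ValueError("auditory point and perturbation must be finite")
    return a + delta
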