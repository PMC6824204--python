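"""Phoneme sensory targets: Gaussian regions in auditory and somatosensory space.

Each phoneme (one of six French vowels producible with tongue movement alone)
is characterised by a multivariate Gaussian in each sensory space: a mean
(target centre) and a covariance (the usual range of variation, drawn as a
dispersion ellipsoid of order 2).  Auditory targets are laid out inside the
plant's reachable formant region following the classic vowel-quadrilateral
organisation (height ~ F1, front-back ~ F2).  Somatosensory targets are not
free parameters: they are the images of the auditory regions under the model's
own machinery — motor commands are sampled from the auditory-only planning
posterior, pushed through the somatosensory internal model, and the resulting
cloud is moment-matched to a Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preference import PreferenceParams, effective_covariance

#: The six vowels, ordered front-closed to back-open.
VOWELS = ("i", "e", "ɛ", "a", "œ", "ɔ")  # i e ɛ a œ ɔ

#: Vowel anchor positions in robust-normalised (F1, F2) coordinates
#: (0 = low end of the reachable span, 1 = high end).  F1 grows with vowel
#: openness, F2 with frontness.
_VOWEL_LAYOUT = {
    "i": (0.15, 0.85),
    "e": (0.28, 0.76),
    "ɛ": (0.45, 0.66),
    "a": (0.78, 0.50),
    "œ": (0.50, 0.42),
    "ɔ": (0.60, 0.18),
}


@dataclass
class PhonemeTarget:
    """Gaussian sensory characterisation of one phoneme in both modalities."""

    phoneme: str
    mu_a: np.ndarray       # (3,) Hz
    Gamma_a: np.ndarray    # (3, 3) Hz^2
    mu_s: np.ndarray | None = None      # (3,) contour-PC units
    Gamma_s: np.ndarray | None = None   # (3, 3)

    def mean(self, modality: str) -> np.ndarray:
        return {"auditory": self.mu_a, "somatosensory": self.mu_s}[modality]

    def cov(self, modality: str) -> np.ndarray:
        return {"auditory": self.Gamma_a, "somatosensory": self.Gamma_s}[modality]

    def to_dict(self) -> dict:
        return {
            "phoneme": self.phoneme,
            "mu_a": self.mu_a.tolist(),
            "Gamma_a": self.Gamma_a.tolist(),
            "mu_s": None if self.mu_s is None else self.mu_s.tolist(),
            "Gamma_s": None if self.Gamma_s is None else self.Gamma_s.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhonemeTarget":
        opt = lambda k: None if d.get(k) is None else np.array(d[k], float)
        return cls(
            phoneme=d["phoneme"],
            mu_a=np.array(d["mu_a"], float),
            Gamma_a=np.array(d["Gamma_a"], float),
            mu_s=opt("mu_s"),
            Gamma_s=opt("Gamma_s"),
        )


@dataclass
class PhonemeInventory:
    """Ordered collection of the six vowel targets plus provenance metadata."""

    targets: list[PhonemeTarget]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = [t.phoneme for t in self.targets]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate phoneme labels in inventory")

    def __getitem__(self, phoneme: str) -> PhonemeTarget:
        for t in self.targets:
            if t.phoneme == phoneme:
                return t
        raise KeyError(phoneme)

    def __iter__(self):
        return iter(self.targets)

    def labels(self) -> list[str]:
        return [t.phoneme for t in self.targets]

    def to_dict(self) -> dict:
        return {
            "type": "PhonemeInventory",
            "targets": [t.to_dict() for t in self.targets],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhonemeInventory":
        if d.get("type") != "PhonemeInventory":
            raise ValueError(f"not a PhonemeInventory artifact: {d.get('type')!r}")
        return cls(
            targets=[PhonemeTarget.from_dict(t) for t in d["targets"]],
            provenance=d.get("provenance", {}),
        )

    def means_frame(self):
        """Per-phoneme target means as a tidy DataFrame (for plots/export)."""
        import pandas as pd

        rows = []
        for t in self.targets:
            row = {"phoneme": t.phoneme, "f1": t.mu_a[0], "f2": t.mu_a[1], "f3": t.mu_a[2]}
            if t.mu_s is not None:
                row.update({"pc1": t.mu_s[0], "pc2": t.mu_s[1], "pc3": t.mu_s[2]})
            rows.append(row)
        return pd.DataFrame(rows)


def mahalanobis(x, mu, Gamma) -> float:
    d = np.asarray(x, float) - np.asarray(mu, float)
    return float(np.sqrt(d @ np.linalg.solve(Gamma, d)))


def define_auditory_targets(
    plant,
    seed: int = 0,
    n_layout: int = 4000,
    rel_std: float = 0.03,
    axis_ratio: float = 1.8,
    min_separation: float = 2.2,
    f1_margin: float = 100.0,
    density_radius: float = 0.10,
    density_fraction: float = 0.5,
) -> list[PhonemeTarget]:
    """Lay six well-separated vowel target Gaussians inside the reachable region.

    Means are corpus samples nearest the vowel anchors (so they are reachable
    by construction), restricted to samples whose neighbourhood — and whose
    F1 + ``f1_margin`` image's neighbourhood — is densely covered by the
    corpus, so no target sits on the boundary of the reachable formant region.
    Covariances are mildly anisotropic with per-dimension standard deviation
    ``rel_std`` of the robust formant span, shrunk by a common factor if any
    pairwise Mahalanobis separation falls below ``min_separation``.
    """
    from scipy.spatial import cKDTree

    M = plant.sample_controls(n_layout, seed=seed + 101)
    A = plant.auditory(M)
    lo, hi = np.percentile(A, 5, axis=0), np.percentile(A, 95, axis=0)
    span = hi - lo
    U = (A - lo) / span
    inner = np.all((U > 0.05) & (U < 0.95), axis=1)

    tree = cKDTree(U)
    margin_u = np.array([f1_margin / span[0], 0.0, 0.0])
    dens_here = tree.query_ball_point(U, r=density_radius, return_length=True)
    dens_shift = tree.query_ball_point(U + margin_u, r=density_radius, return_length=True)
    # interiority threshold calibrated to this corpus: a point (and its
    # F1-shifted image) must sit in a neighbourhood at least half as dense as
    # the typical in-bulk neighbourhood
    min_neighbors = density_fraction * np.median(dens_here[inner])
    interior = inner & (dens_here >= min_neighbors) & (dens_shift >= min_neighbors)
    if not np.any(interior):
        raise RuntimeError("no corpus sample satisfies the interiority constraints")

    rng = np.random.default_rng(seed + 202)
    targets = []
    for v in VOWELS:
        uf1, uf2 = _VOWEL_LAYOUT[v]
        want = np.array([uf1, uf2, 0.5])
        cand = np.where(interior)[0]
        # local average of the nearest interior samples: smoother and better
        # centred than snapping to a single corpus point
        k = min(15, len(cand))
        near = cand[np.argsort(((U[cand] - want) ** 2).sum(axis=1))[:k]]
        mu = A[near].mean(axis=0)

        sd = rel_std * span
        D = np.diag((sd * np.array([1.0, axis_ratio, axis_ratio])) ** 2)
        # random but seeded rotation in the (F1, F2) plane for mild orientation
        ang = rng.uniform(-np.pi / 4, np.pi / 4)
        R = np.eye(3)
        R[0, 0] = R[1, 1] = np.cos(ang)
        R[0, 1], R[1, 0] = -np.sin(ang), np.sin(ang)
        Gamma = R @ D @ R.T
        targets.append(PhonemeTarget(phoneme=v, mu_a=mu, Gamma_a=Gamma))

    # enforce pairwise separation by a deterministic common shrink
    for _ in range(20):
        worst = min(
            min(
                mahalanobis(t1.mu_a, t2.mu_a, t1.Gamma_a),
                mahalanobis(t1.mu_a, t2.mu_a, t2.Gamma_a),
            )
            for i, t1 in enumerate(targets)
            for t2 in targets[i + 1 :]
        )
        if worst >= min_separation:
            break
        if worst < 1e-6:
            raise RuntimeError("two vowel targets collapsed onto the same mean")
        factor = (worst / min_separation) ** 2 * 0.95
        for t in targets:
            t.Gamma_a = t.Gamma_a * factor
    else:
        raise RuntimeError("could not separate vowel targets")

    # every mean must be reachable: a corpus sample nearby in normalised units
    for t in targets:
        du = (A - t.mu_a) / span
        if np.sqrt((du**2).sum(axis=1)).min() > density_radius:
            raise RuntimeError(f"target mean for {t.phoneme!r} is outside the reachable region")
    return targets


def target_log_density(target: PhonemeTarget, modality: str, x, prefs: PreferenceParams | None = None) -> float:
    """Log density of the (preference-adjusted) Gaussian target at ``x``."""
    prefs = prefs or PreferenceParams.none()
    cov = effective_covariance(target.cov(modality), prefs, modality)
    return float(stats.multivariate_normal.logpdf(np.asarray(x, float), target.mean(modality), cov))


def derive_somato_target(
    target: PhonemeTarget,
    maps: dict,
    bounds,
    n: int = 5000,
    seed: int = 0,
    chains: int = 10,
    burn: int = 500,
):
    """Somatosensory Gaussian for a phoneme, as the image of its auditory region.

    Samples motor commands from the auditory-only planning posterior for this
    target, pushes them through the somatosensory internal model, and
    moment-matches a Gaussian (sample mean, sample covariance).  Returns
    ``(mu_s, Gamma_s, results)`` where ``results`` carries the chains for
    standard-error diagnostics.
    """
    from .planner import PlanningModel, SamplerConfig

    draws = int(np.ceil(n / chains))
    model = PlanningModel(target, maps, bounds, modalities=("auditory",))
    res = model.fit(SamplerConfig(chains=chains, burn=burn, draws=draws, seed=seed))
    S = maps["somatosensory"].predict(res.lambdas)
    mu_s = S.mean(axis=0)
    Gamma_s = np.cov(S.T)
    try:
        np.linalg.cholesky(Gamma_s)
    except np.linalg.LinAlgError as e:
        raise RuntimeError("degenerate somatosensory push-forward cloud") from e
    return mu_s, Gamma_s, res


def build_inventory(
    plant,
    maps: dict,
    seed: int = 0,
    n_derive: int = 5000,
    layout_kwargs: dict | None = None,
    **derive_kwargs,
) -> PhonemeInventory:
    """Full target construction: auditory layout, then somatosensory derivation."""
    targets = define_auditory_targets(plant, seed=seed, **(layout_kwargs or {}))
    for i, t in enumerate(targets):
        mu_s, Gamma_s, _ = derive_somato_target(
            t, maps, plant.bounds, n=n_derive, seed=seed + 37 * (i + 1), **derive_kwargs
        )
        t.mu_s, t.Gamma_s = mu_s, Gamma_s
    return PhonemeInventory(
        targets=targets,
        provenance={"plant_seed": plant.seed, "layout_seed": seed, "n_derive": n_derive},
    )
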