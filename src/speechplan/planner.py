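"""Bayesian planning core: posterior over motor commands, sampled by MCMC.

Planning a phoneme is an inference problem: given the phoneme's sensory
targets, find motor commands whose *predicted* sensory consequences (through
the deterministic internal models) fall in the target regions.  With uniform
priors over the bounded control box and Dirac internal models, the posterior
over the command ``m`` reduces to a product of Gaussian target densities
evaluated at the internal-model predictions:

* auditory-only      p(m) ∝ N(ρ_a(m); μ_A, Γ̃_A)
* somatosensory-only p(m) ∝ N(ρ_s(m); μ_S, Γ̃_S)
* fusion             p(m) ∝ N(ρ_a(m); μ_A, Γ̃_A) · N(ρ_s(m); μ_S, Γ̃_S)

where Γ̃ is the preference-adjusted covariance (Γ, κΓ, or Γ + η²I; see
:mod:`speechplan.preference`).

The sampler is a random-walk Metropolis–Hastings with symmetric Gaussian
proposals, independent chains with per-chain seeds, rejection of out-of-box
proposals (the uniform prior's support), and proposal-scale adaptation toward
a 23% acceptance rate during burn-in only — the kept draws come from a fixed
kernel.  The default protocol retains 20 chains × 1000 draws = 2·10⁴ samples
after discarding 1000 burn-in steps per chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .preference import PreferenceParams, effective_covariance

PLANNING_MODES = ("auditory", "somatosensory", "fusion")


def modalities_for_mode(mode: str) -> tuple[str, ...]:
    if mode == "fusion":
        return ("auditory", "somatosensory")
    if mode in ("auditory", "somatosensory"):
        return (mode,)
    raise ValueError(f"unknown planning mode {mode!r}")


@dataclass(frozen=True)
class SamplerConfig:
    """Random-walk Metropolis–Hastings protocol parameters."""

    chains: int = 20
    burn: int = 1000
    draws: int = 1000
    proposal_scale: float = 0.05   # initial scale, as a fraction of box width
    target_accept: float = 0.23
    adapt_interval: int = 50
    init_probes: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "chains": self.chains,
            "burn": self.burn,
            "draws": self.draws,
            "proposal_scale": self.proposal_scale,
            "target_accept": self.target_accept,
            "adapt_interval": self.adapt_interval,
            "init_probes": self.init_probes,
            "seed": self.seed,
        }


class LowAcceptanceError(RuntimeError):
    """Every chain accepted fewer than 1% of proposals."""


def random_walk_metropolis(logpdf, bounds, cfg: SamplerConfig):
    """Sample a density on a box with per-chain-seeded random-walk MH.

    ``logpdf`` maps a d-vector to an unnormalised log density (may be -inf).
    Returns ``(samples, acceptance)`` with samples of shape
    (chains, draws, d).  Bit-identical across runs for a fixed config.
    """
    bounds = np.asarray(bounds, float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = len(lo)
    width = hi - lo
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)

    samples = np.empty((cfg.chains, cfg.draws, d))
    acceptance = np.empty(cfg.chains)
    for c in range(cfg.chains):
        rng = np.random.default_rng(children[c])
        probes = lo + rng.random((cfg.init_probes, d)) * width
        lps = np.array([logpdf(p) for p in probes])
        if not np.any(np.isfinite(lps)):
            raise RuntimeError("log density not finite at any initial probe")
        x = probes[np.argmax(lps)]
        lp = lps.max()

        scale = cfg.proposal_scale * width
        accepted = 0
        window = 0
        total = cfg.burn + cfg.draws
        for t in range(total):
            prop = x + rng.normal(size=d) * scale
            if np.all(prop >= lo) & np.all(prop <= hi):
                lp_prop = logpdf(prop)
                if np.log(rng.random()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    accepted += 1
                    window += 1
            if t < cfg.burn:
                if (t + 1) % cfg.adapt_interval == 0:
                    rate = window / cfg.adapt_interval
                    scale = np.clip(
                        scale * np.exp(1.2 * (rate - cfg.target_accept)),
                        1e-4 * width,
                        width,
                    )
                    window = 0
            else:
                samples[c, t - cfg.burn] = x
        acceptance[c] = accepted / total
    if np.all(acceptance < 0.01):
        raise LowAcceptanceError(
            f"all chains below 1% acceptance (max {acceptance.max():.4f}); "
            "proposal scale is misconfigured"
        )
    return samples, acceptance


class PlanningModel:
    """Posterior over motor commands for one phoneme under chosen constraints.

    Parameters
    ----------
    target : PhonemeTarget
        Gaussian sensory characterisation of the phoneme (both modalities).
    maps : dict
        ``{"auditory": SensoryMap, "somatosensory": SensoryMap}`` internal
        models; the auditory one may carry an adaptation offset.
    bounds : (6, 2) array
        Control box (the uniform prior's support).
    modalities : tuple of str
        Active sensory constraints; ("auditory",), ("somatosensory",) or both
        (fusion).  At least one must be active — with none, the posterior is
        the uninformative uniform prior and the query is rejected.
    preference : PreferenceParams, optional
        Sensory-preference adjustment applied to the target covariances.
    """

    def __init__(self, target, maps, bounds, modalities=("auditory", "somatosensory"),
                 preference: PreferenceParams | None = None):
        if len(modalities) == 0:
            raise ValueError("at least one sensory modality must be active")
        for mod in modalities:
            if mod not in ("auditory", "somatosensory"):
                raise ValueError(f"unknown modality {mod!r}")
            if maps[mod].modality != mod:
                raise ValueError(f"map for {mod!r} slot has modality {maps[mod].modality!r}")
        self.target = target
        self.maps = maps
        self.bounds = np.asarray(bounds, float)
        self.modalities = tuple(modalities)
        self.preference = preference or PreferenceParams.none()
        self._terms = []
        for mod in self.modalities:
            mu = np.asarray(target.mean(mod), float)
            cov = effective_covariance(target.cov(mod), self.preference, mod)
            chol = np.linalg.cholesky(cov)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            const = -0.5 * (len(mu) * np.log(2 * np.pi) + logdet)
            self._terms.append((self.maps[mod], mu, chol, const))

    @property
    def mode(self) -> str:
        return "fusion" if len(self.modalities) == 2 else self.modalities[0]

    def loglike(self, m) -> float:
        """Unnormalised log posterior density of a single command ``m``."""
        total = 0.0
        for smap, mu, chol, const in self._terms:
            r = smap.predict(m) - mu
            w = solve_triangular(chol, r, lower=True)
            total += const - 0.5 * float(w @ w)
        return total

    def fit(self, cfg: SamplerConfig | None = None, **kwargs) -> "PlanningResults":
        """Draw posterior samples of the motor command by random-walk MH."""
        if cfg is None:
            cfg = SamplerConfig(**kwargs)
        elif kwargs:
            cfg = replace(cfg, **kwargs)
        samples, acceptance = random_walk_metropolis(self.loglike, self.bounds, cfg)
        return PlanningResults(model=self, config=cfg, samples=samples, acceptance=acceptance)


@dataclass
class PlanningResults:
    """Posterior draws of the motor command, with chain structure kept.

    ``samples`` has shape (chains, draws, 6).  Mapped sensory outcomes are
    computed through the internal models used for planning; ground-truth
    (plant) outcomes are attached by the experiment layer.
    """

    model: PlanningModel
    config: SamplerConfig
    samples: np.ndarray
    acceptance: np.ndarray

    @property
    def lambdas(self) -> np.ndarray:
        """All retained draws, flattened to (chains*draws, 6)."""
        return self.samples.reshape(-1, self.samples.shape[-1])

    def predicted(self, modality: str) -> np.ndarray:
        """Internal-model sensory predictions for every retained draw."""
        return self.model.maps[modality].predict(self.lambdas)

    def chain_means(self, values: np.ndarray | None = None) -> np.ndarray:
        v = self.samples if values is None else values.reshape(
            self.config.chains, self.config.draws, -1
        )
        return v.mean(axis=1)

    def mcse(self, values: np.ndarray | None = None) -> np.ndarray:
        """Monte-Carlo standard error of the mean, from between-chain variance."""
        cm = self.chain_means(values)
        return cm.std(axis=0, ddof=1) / np.sqrt(cm.shape[0])

    def summary(self) -> pd.DataFrame:
        """Posterior summary per control dimension: mean, sd, MC-SE, acceptance."""
        lam = self.lambdas
        df = pd.DataFrame(
            {
                "mean": lam.mean(axis=0),
                "sd": lam.std(axis=0, ddof=1),
                "mcse_mean": self.mcse(),
            },
            index=[f"lambda_{i+1}" for i in range(lam.shape[1])],
        )
        df.attrs["mean_acceptance"] = float(self.acceptance.mean())
        return df

    def dispersion_ellipse(self, modality: str, dims=(0, 1), order: float = 2.0):
        pts = self.predicted(modality)[:, list(dims)]
        return dispersion_ellipse(pts, order=order)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-draw table: chain, draw, lambdas, mapped sensory points."""
        n_ch, n_dr, d = self.samples.shape
        lam = self.lambdas
        data = {
            "chain": np.repeat(np.arange(n_ch), n_dr),
            "draw": np.tile(np.arange(n_dr), n_ch),
        }
        for i in range(d):
            data[f"lambda_{i+1}"] = lam[:, i]
        aud = self.predicted("auditory") if "auditory" in self.model.maps else None
        som = self.predicted("somatosensory") if "somatosensory" in self.model.maps else None
        if aud is not None:
            for i, name in enumerate(("f1", "f2", "f3")):
                data[name] = aud[:, i]
        if som is not None:
            for i, name in enumerate(("pc1", "pc2", "pc3")):
                data[name] = som[:, i]
        return pd.DataFrame(data)


def dispersion_ellipse(points, order: float = 2.0):
    """Dispersion ellipse of order k for a 2-D point cloud.

    Returns ``(center, axes, angle_deg)``: the sample mean, the semi-axis
    lengths k·sqrt(eigenvalues of the sample covariance), and the orientation
    of the principal axis in (-90°, 90°].
    """
    P = np.asarray(points, float)
    if P.ndim != 2 or P.shape[1] != 2 or len(P) < 3:
        raise ValueError("need at least 3 points in 2-D")
    center = P.mean(axis=0)
    cov = np.cov(P.T)
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] <= 0:
        raise ValueError("degenerate (collinear) point cloud")
    # sort descending so axes[0] is the major axis
    vals, vecs = vals[::-1], vecs[:, ::-1]
    axes = order * np.sqrt(vals)
    angle = np.degrees(np.arctan2(vecs[1, 0], vecs[0, 0]))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return center, axes, angle
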