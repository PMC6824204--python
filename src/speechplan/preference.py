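"""Sensory-preference mechanisms: covariance scaling vs soft matching.

Two ways to make one sensory modality weigh more than the other in planning:

* **Target-based** — scale the covariance of a modality's phoneme target by a
  factor κ > 0.  κ > 1 widens the target region (down-weights the modality),
  κ < 1 sharpens it.  The target regions themselves change.
* **Comparison-based** — keep the targets, but soften the match between the
  predicted sensory consequence and the target value: the all-or-nothing
  equality constraint becomes a Gaussian kernel exp(-||x1-x2||² / (2η²)).
  Marginalising the target value under this soft constraint is a Gaussian
  convolution, so the planning density is the target Gaussian with covariance
  Γ + η²I.

Hence the two mechanisms act on the same object — the effective covariance —
multiplicatively (κΓ) or additively (Γ + η²I).  In 1-D they coincide exactly
under κ = 1 + η²/Γ.  In 3-D they differ unless Γ is isotropic: κΓ preserves
eigenvalue ratios and eigenvectors, while Γ + η²I keeps the eigenvectors but
drives the condition number toward 1 (the regions become isotropic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODES = ("none", "target_based", "comparison_based")


@dataclass(frozen=True)
class PreferenceParams:
    """Sensory-preference configuration.

    κ are dimensionless variance scale factors; η are soft-match widths in the
    raw units of the corresponding sensory space (Hz for auditory, contour PC
    units for somatosensory).
    """

    mode: str = "none"
    kappa_a: float = 1.0
    kappa_s: float = 1.0
    eta_a: float = 0.0
    eta_s: float = 0.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown preference mode {self.mode!r}")
        if self.kappa_a <= 0 or self.kappa_s <= 0:
            raise ValueError("kappa factors must be positive")
        if self.eta_a < 0 or self.eta_s < 0:
            raise ValueError("eta widths must be non-negative")
        if self.mode == "none" and (
            (self.kappa_a, self.kappa_s) != (1.0, 1.0) or (self.eta_a, self.eta_s) != (0.0, 0.0)
        ):
            raise ValueError("mode 'none' requires kappa=1 and eta=0")

    @classmethod
    def none(cls) -> "PreferenceParams":
        return cls()

    @classmethod
    def target_based(cls, kappa_a: float = 1.0, kappa_s: float = 1.0) -> "PreferenceParams":
        return cls(mode="target_based", kappa_a=kappa_a, kappa_s=kappa_s)

    @classmethod
    def comparison_based(cls, eta_a: float = 0.0, eta_s: float = 0.0) -> "PreferenceParams":
        return cls(mode="comparison_based", eta_a=eta_a, eta_s=eta_s)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "kappa_a": self.kappa_a,
            "kappa_s": self.kappa_s,
            "eta_a": self.eta_a,
            "eta_s": self.eta_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreferenceParams":
        return cls(**d)


def strict_match(x1, x2) -> int:
    """All-or-nothing matching constraint: 1 iff x1 equals x2 exactly.

    This is the η → 0 limit of :func:`soft_match_prob`; it is kept as the
    limiting reference and never used inside planning densities.
    """
    return int(np.array_equal(np.asarray(x1, float), np.asarray(x2, float)))


def soft_match_prob(x1, x2, eta: float) -> float:
    """Soft matching probability exp(-||x1 - x2||² / (2η²)), in (0, 1].

    Symmetric in its arguments and decreasing in their distance; η → ∞ removes
    the constraint (probability → 1 for any pair).
    """
    if eta <= 0:
        raise ValueError("eta must be positive; use strict_match for eta = 0")
    d2 = float(((np.asarray(x1, float) - np.asarray(x2, float)) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * eta**2)))


def _check_spd(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, float)
    if not np.allclose(G, G.T):
        raise ValueError("covariance must be symmetric")
    try:
        np.linalg.cholesky(G)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance must be positive definite") from e
    return G


def effective_covariance(Gamma, prefs: PreferenceParams, modality: str) -> np.ndarray:
    """Covariance actually used in a planning density for one modality.

    none → Γ; target_based → κΓ; comparison_based → Γ + η²I.
    """
    G = _check_spd(Gamma)
    if modality == "auditory":
        kappa, eta = prefs.kappa_a, prefs.eta_a
    elif modality == "somatosensory":
        kappa, eta = prefs.kappa_s, prefs.eta_s
    else:
        raise ValueError(f"unknown modality {modality!r}")
    if prefs.mode == "target_based":
        return kappa * G
    if prefs.mode == "comparison_based":
        return G + eta**2 * np.eye(G.shape[0])
    return G.copy()


def kappa_equivalent_1d(gamma: float, eta: float) -> float:
    """The κ making multiplicative and additive widening identical in 1-D.

    κγ = γ + η²  ⇒  κ = 1 + η²/γ; with that κ the two 1-D planning densities
    are the same Gaussian.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 1.0 + eta**2 / gamma


def anisotropy(Gamma) -> tuple[float, np.ndarray]:
    """Condition number and leading principal axis of an SPD covariance.

    Used to check the geometric contract of the two mechanisms: κΓ leaves the
    condition number and eigenvectors untouched, Γ + η²I shifts every
    eigenvalue by η² and therefore drives the condition number monotonically
    toward 1 as η grows.
    """
    G = _check_spd(Gamma)
    vals, vecs = np.linalg.eigh(G)
    return float(vals[-1] / vals[0]), vecs[:, -1]
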