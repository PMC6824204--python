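"""Perturbation–adaptation experiments and sensory-preference sweeps.

The reference experiment plans one vowel under three conditions:

* ``unperturbed`` — plan with the learned internal models as they are;
* ``pre_adaptation`` — an external formant shift δ is switched on, but the
  speaker has not yet adapted: plans are the unperturbed ones, only the
  *perceived* acoustic output shifts by δ;
* ``post_adaptation`` — the auditory internal model has been fully updated
  (ρ_a → ρ_a + δ) and planning is redone with the adapted map.

Compensation is summarised by a scalar: the displacement of the *produced*
(ground-truth plant) auditory mean relative to the unperturbed baseline,
projected on the direction opposite to δ, in units of ‖δ‖.  1 means the
production moved to cancel the perturbation exactly; 0 means no change.
Auditory-only planning compensates fully after adaptation, somatosensory-only
planning not at all, and fusion planning lands in between — exactly where is
what the κ/η sensory-preference sweeps trace out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .internal_models import PerturbationSpec, adapt_auditory
from .io import derive_seed
from .planner import PlanningModel, PlanningResults, SamplerConfig, modalities_for_mode
from .plant import apply_perturbation
from .preference import PreferenceParams

# The sampler seed for a run is derived from the master seed, phoneme, mode and
# preference — but never from the condition: a posterior that is unchanged by
# the perturbation (somatosensory-only planning) must yield bit-identical
# draws before and after auditory adaptation.

CONDITIONS = ("unperturbed", "pre_adaptation", "post_adaptation")


@dataclass
class ExperimentConfig:
    """Configuration of the reference perturbation–adaptation experiment."""

    phoneme: str = "ɔ"
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    modes: tuple[str, ...] = ("auditory", "somatosensory", "fusion")
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    preference: PreferenceParams = field(default_factory=PreferenceParams.none)
    seed: int = 0


@dataclass
class CompensationResult:
    """Summary of one (condition, planning mode) run."""

    condition: str
    mode: str
    phoneme: str
    preference: PreferenceParams
    produced_auditory_mean: np.ndarray   # plant output, Hz
    perceived_auditory_mean: np.ndarray  # produced + delta in perturbed conditions
    somato_mean: np.ndarray
    produced_auditory_se: np.ndarray     # between-chain MC standard errors
    somato_se: np.ndarray
    delta: np.ndarray
    results: PlanningResults | None = None

    def to_row(self) -> dict:
        row = {
            "condition": self.condition,
            "mode": self.mode,
            "phoneme": self.phoneme,
            **{f"pref_{k}": v for k, v in self.preference.to_dict().items()},
        }
        for name, arr in [
            ("produced_f", self.produced_auditory_mean),
            ("perceived_f", self.perceived_auditory_mean),
            ("pc", self.somato_mean),
            ("produced_f_se", self.produced_auditory_se),
        ]:
            for i, v in enumerate(arr):
                row[f"{name}{i+1}"] = v
        return row


def run_condition(
    setup,
    cfg: ExperimentConfig,
    condition: str,
    mode: str,
    keep_results: bool = True,
) -> CompensationResult:
    """Plan ``cfg.phoneme`` in one condition with one planning mode.

    ``setup`` bundles the plant, the fitted internal models and the phoneme
    inventory (see :class:`speechplan.io.Setup`).  The sampler seed is derived
    from the master seed, the phoneme and the mode — but not the condition —
    so conditions that share a posterior share draws bit-for-bit.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    delta = np.asarray(cfg.perturbation.delta, float)
    target = setup.inventory[cfg.phoneme]

    maps = dict(setup.maps)
    if condition == "post_adaptation":
        maps["auditory"] = adapt_auditory(maps["auditory"], cfg.perturbation)

    seed = derive_seed(cfg.seed, "plan", cfg.phoneme, mode, cfg.preference.mode,
                       *cfg.preference.to_dict().values())
    model = PlanningModel(
        target,
        maps,
        setup.plant.bounds,
        modalities=modalities_for_mode(mode),
        preference=cfg.preference,
    )
    res = model.fit(replace(cfg.sampler, seed=seed))

    lam = res.lambdas
    produced = setup.plant.auditory(lam)
    somato = setup.plant.somato(lam)
    perturbed = condition in ("pre_adaptation", "post_adaptation")
    perceived = apply_perturbation(produced, delta) if perturbed else produced

    return CompensationResult(
        condition=condition,
        mode=mode,
        phoneme=cfg.phoneme,
        preference=cfg.preference,
        produced_auditory_mean=produced.mean(axis=0),
        perceived_auditory_mean=perceived.mean(axis=0),
        somato_mean=somato.mean(axis=0),
        produced_auditory_se=res.mcse(produced),
        somato_se=res.mcse(somato),
        delta=delta,
        results=res if keep_results else None,
    )


def compensation_ratio(
    post: CompensationResult, baseline: CompensationResult, pert: PerturbationSpec
) -> float:
    """Produced-output displacement along -δ, in units of ‖δ‖.

    1 = full compensation (production moved to cancel the perturbation),
    0 = no compensation.
    """
    delta = np.asarray(pert.delta, float)
    norm = np.linalg.norm(delta)
    if norm == 0:
        raise ValueError("perturbation delta has zero norm")
    shift = post.produced_auditory_mean - baseline.produced_auditory_mean
    return float(shift @ (-delta / norm) / norm)


def run_reference_experiment(setup, cfg: ExperimentConfig, keep_results: bool = False):
    """All conditions × planning modes; returns ``{(condition, mode): result}``."""
    out = {}
    for mode in cfg.modes:
        for condition in CONDITIONS:
            out[(condition, mode)] = run_condition(
                setup, cfg, condition, mode, keep_results=keep_results
            )
    return out


SWEEP_PARAMS = ("kappa_a", "kappa_s", "eta_a", "eta_s")


def preference_for(param: str, value: float) -> PreferenceParams:
    if param.startswith("kappa"):
        return PreferenceParams.target_based(**{param: value})
    if param.startswith("eta"):
        return PreferenceParams.comparison_based(**{param: value})
    raise ValueError(f"unknown preference parameter {param!r}")


def default_grid(param: str, setup=None, phoneme: str = "ɔ", n: int = 6) -> np.ndarray:
    """Geometric default grids spanning several decades.

    κ grids span 10^-2 … 10^2 around the neutral κ = 1 — wide enough that the
    extreme values effectively shut one modality off.  η is in raw sensory
    units and only matters relative to the target covariance it is added to,
    so η grids are anchored on the phoneme target's RMS standard deviation in
    the relevant sensory space.  The auditory grid tops out lower (~3x the
    target sd) than the somatosensory one (~10x): the auditory pathway's
    influence saturates to zero sooner, and grid points beyond saturation
    carry no information.
    """
    if param.startswith("kappa"):
        return 10.0 ** np.linspace(-2.0, 2.0, n)
    scale = 1.0
    if setup is not None:
        target = setup.inventory[phoneme]
        cov = target.cov("auditory" if param == "eta_a" else "somatosensory")
        scale = float(np.sqrt(np.diag(cov).mean()))
    hi = 0.5 if param == "eta_a" else 1.0
    return scale * 10.0 ** np.linspace(-1.0, hi, n)


def sweep_preference(
    setup,
    cfg: ExperimentConfig,
    param: str,
    grid=None,
) -> pd.DataFrame:
    """Post-adaptation fusion compensation across a one-parameter grid.

    One fusion run per grid value, all with shared non-preference seeds for
    variance reduction; the baseline is the unperturbed no-preference fusion
    run.  Returns a tidy long-format table.
    """
    if param not in SWEEP_PARAMS:
        raise ValueError(f"unknown sweep parameter {param!r}")
    grid = default_grid(param, setup, cfg.phoneme) if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("sweep grid is empty")

    base_cfg = replace(cfg, preference=PreferenceParams.none())
    baseline = run_condition(setup, base_cfg, "unperturbed", "fusion", keep_results=False)
    rows = []
    for value in grid:
        pref_cfg = replace(cfg, preference=preference_for(param, float(value)))
        post = run_condition(setup, pref_cfg, "post_adaptation", "fusion", keep_results=False)
        row = post.to_row()
        row.update(
            param=param,
            value=float(value),
            compensation_ratio=compensation_ratio(post, baseline, cfg.perturbation),
        )
        rows.append(row)
    return pd.DataFrame(rows)
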