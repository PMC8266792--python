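"""Synthetic pooled-starvation screen with known ground truth.

Emulates the experimental design of a pooled overexpression
chronological-lifespan screen: a mixed culture of ~6000 cells per
strain is split into eight flasks (two starvation environments x four
replicate cultures), sampled weekly, and each sample is PCR-amplified
and sequenced to a fixed read depth.

The generative model, per (environment, replicate, timepoint):

1. Survival — strain ``i`` decays exponentially with a per-environment
   death rate ``d_ie`` (day^-1); the expected alive-cell count at day
   ``t`` is ``n0 * exp(-d_ie * t)``.
2. Plating bottleneck — a fixed number of cells is drawn multinomially
   from the alive pool, modelling the 0.5-ml aliquot spread on a plate.
   Plating outgrowth is treated as unbiased, so the sample composition
   reflects frequencies among alive cells.
3. Amplification and sequencing — ``read_depth`` reads are drawn
   multinomially with per-strain weight proportional to
   (plated cells) x (amplification efficiency). Efficiency is a
   strain-by-environment constant drawn from a two-component mixture
   (well vs poorly amplifying); a correlation knob controls how
   strongly the well-amplifying component repeats across environments,
   reproducing the observed non-random, repeatable amplification
   dropout.

Counts per sample sum exactly to the read depth, and identical seeds
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .counts import CountTensor

__all__ = ["SimConfig", "SimTruth", "simulate_screen"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic screen.

    Defaults follow the pooled-screen design being emulated: ~6000
    cells of every strain at time zero, two environments (H = water,
    G = water + galactose) x four replicate flasks, weekly sampling
    from day 0 to day 28.

    Attributes
    ----------
    n_strains
        Number of overexpression strains in the pool.
    initial_cells_per_strain
        Cells of each strain in every flask at the start of starvation.
    timepoints
        Sampling days, strictly increasing. Use ``drop_day0`` to
        emulate an analysis that excludes the day-0 sample.
    n_replicates_per_env, environments
        Replicate flasks per environment and environment labels.
    read_depth
        Sequencing reads per sample.
    plating_cells
        Cells drawn at the plating bottleneck (multinomial sample from
        the alive pool).
    death_rate_meanlog, death_rate_sdlog
        Log-normal law of the per-strain baseline death rate
        (day^-1). Defaults give a median of 0.05/day (~25% survival
        at day 28) with substantial strain-to-strain spread.
    env_effect_sd
        SD of an additive per-(strain, environment) perturbation of
        the death rate (day^-1); rates are clipped to stay positive.
    amp_well_fraction
        Fraction of strains in the well-amplifying mixture component.
    amp_well_efficiency, amp_poor_efficiency
        Mean amplification efficiency of the two components (scaled
        Beta draws on [0, 1]).
    amp_cross_env_correlation
        In [0, 1]: probability that a strain keeps its mixture
        component across environments (1 = identical dropout in H and
        G; 0 = independent assignment).
    seed
        Seed for all randomness.
    """

    n_strains: int = 6000
    initial_cells_per_strain: int = 6000
    timepoints: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 28.0)
    n_replicates_per_env: int = 4
    environments: tuple[str, ...] = ("H", "G")
    read_depth: int = 1_000_000
    plating_cells: int = 200_000
    death_rate_meanlog: float = float(np.log(0.05))
    death_rate_sdlog: float = 0.5
    env_effect_sd: float = 0.005
    amp_well_fraction: float = 0.12
    amp_well_efficiency: float = 0.9
    amp_poor_efficiency: float = 0.005
    amp_cross_env_correlation: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be a positive integer")
        if self.initial_cells_per_strain < 1:
            raise ValueError("initial_cells_per_strain must be positive")
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be >=2 strictly increasing days")
        if any(t < 0 or not np.isfinite(t) for t in tps):
            raise ValueError("timepoints must be finite and non-negative")
        if self.n_replicates_per_env < 1:
            raise ValueError("n_replicates_per_env must be positive")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.plating_cells < 1:
            raise ValueError("plating_cells must be positive")
        if not np.isfinite(self.death_rate_meanlog):
            raise ValueError("death_rate_meanlog must be finite")
        if not (np.isfinite(self.death_rate_sdlog) and self.death_rate_sdlog >= 0):
            raise ValueError("death_rate_sdlog must be finite and non-negative")
        if not (np.isfinite(self.env_effect_sd) and self.env_effect_sd >= 0):
            raise ValueError("env_effect_sd must be finite and non-negative")
        for name in ("amp_well_fraction", "amp_well_efficiency",
                     "amp_poor_efficiency", "amp_cross_env_correlation"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def drop_day0(self) -> "SimConfig":
        """Config variant whose sampling starts at the first post-zero day."""
        return replace(self, timepoints=tuple(t for t in self.timepoints if t > 0))


@dataclass
class SimTruth:
    """Ground truth of a simulated screen (the recovery targets).

    All arrays have shape (n_strains, n_environments), matching the
    strain and environment order of the returned count tensor.
    """

    strains: list[str]
    environments: list[str]
    death_rate: np.ndarray
    amp_efficiency: np.ndarray
    is_well_amplified: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.strains), len(self.environments))
        for name in ("death_rate", "amp_efficiency", "is_well_amplified"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.death_rate <= 0):
            raise ValueError("death rates must be positive")

    def to_frame(self):
        import pandas as pd

        rows = []
        for j, env in enumerate(self.environments):
            rows.append(pd.DataFrame({
                "strain": self.strains,
                "environment": env,
                "death_rate": self.death_rate[:, j],
                "amp_efficiency": self.amp_efficiency[:, j],
                "is_well_amplified": self.is_well_amplified[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


def simulate_screen(
    config: SimConfig,
    *,
    death_rate: np.ndarray | None = None,
    amp_efficiency: np.ndarray | None = None,
) -> tuple[CountTensor, SimTruth]:
    """Simulate a pooled-starvation screen.

    Returns the sequencing count tensor and the generating ground
    truth. Deterministic given ``config`` (including its seed).

    ``death_rate`` and ``amp_efficiency`` optionally override the drawn
    truth with explicit (n_strains, n_environments) arrays (or vectors
    broadcast across environments), e.g. to plant strains with known
    rates. Overrides are validated like drawn values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    envs = list(config.environments)
    reps = list(range(1, config.n_replicates_per_env + 1))
    tps = [float(t) for t in config.timepoints]
    strains = [f"ORF{i + 1:04d}" for i in range(n)]

    # Baseline death rates, shared across environments, plus an additive
    # per-(strain, environment) perturbation clipped to stay positive.
    base = rng.lognormal(config.death_rate_meanlog, config.death_rate_sdlog, size=n)
    perturb = rng.normal(0.0, config.env_effect_sd, size=(n, len(envs)))
    if death_rate is None:
        death_rate = np.clip(base[:, None] + perturb, 1e-9, None)
    else:
        death_rate = np.broadcast_to(
            np.asarray(death_rate, dtype=float).reshape(n, -1), (n, len(envs))
        ).copy()
        if not np.all(np.isfinite(death_rate)) or np.any(death_rate <= 0):
            raise ValueError("death_rate override must be finite and positive")

    # Amplification mixture: the component label repeats across
    # environments with probability amp_cross_env_correlation.
    well0 = rng.random(n) < config.amp_well_fraction
    is_well = np.empty((n, len(envs)), dtype=bool)
    is_well[:, 0] = well0
    for j in range(1, len(envs)):
        keep = rng.random(n) < config.amp_cross_env_correlation
        redraw = rng.random(n) < config.amp_well_fraction
        is_well[:, j] = np.where(keep, well0, redraw)
    eff = np.where(
        is_well,
        _beta_about(rng, config.amp_well_efficiency, (n, len(envs))),
        _beta_about(rng, config.amp_poor_efficiency, (n, len(envs))),
    )
    if amp_efficiency is not None:
        eff = np.broadcast_to(
            np.asarray(amp_efficiency, dtype=float).reshape(n, -1), (n, len(envs))
        ).copy()
        if not np.all(np.isfinite(eff)) or np.any((eff < 0) | (eff > 1)):
            raise ValueError("amp_efficiency override must lie in [0, 1]")
        is_well = eff >= 0.5

    shape = (n, len(envs), len(reps), len(tps))
    counts = np.zeros(shape, dtype=np.int64)
    t_arr = np.asarray(tps)
    for j in range(len(envs)):
        # Expected alive cells per strain at each timepoint (shared
        # across replicates; replicate noise enters via the bottleneck).
        alive = config.initial_cells_per_strain * np.exp(
            -death_rate[:, j][:, None] * t_arr[None, :]
        )
        for r in range(len(reps)):
            for k in range(len(tps)):
                alive_frac = alive[:, k] / alive[:, k].sum()
                plated = rng.multinomial(config.plating_cells, alive_frac)
                w = plated * eff[:, j]
                total = w.sum()
                if total == 0:
                    # Degenerate pool (all efficiency zero): reads go nowhere.
                    continue
                counts[:, j, r, k] = rng.multinomial(config.read_depth, w / total)

    tensor = CountTensor(counts, strains, envs, reps, tps)
    truth = SimTruth(strains, envs, death_rate, eff, is_well)
    return tensor, truth


def _beta_about(rng: np.random.Generator, mean: float, size) -> np.ndarray:
    """Beta draws on [0, 1] with the given mean and modest spread."""
    if mean <= 0.0:
        return np.zeros(size)
    if mean >= 1.0:
        return np.ones(size)
    conc = 50.0  # keeps component draws tight around their mean
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)
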