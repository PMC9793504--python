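"""Seeded synthetic-cohort generator with a latent six-archetype structure.

The generator emulates the trajectory structure of a population-based panel
of community-dwelling older adults followed over 11 annual waves: a large
majority with constantly low utilization (LHU) and five minority archetypes
— increasing utilization dominated by home care (IHU), late health
deterioration with deaths/incapacity in the final waves (LHD), high
ambulatory care shifting to permanent nursing-home residence (AC2NH), an
early fatal event in waves 2-6 (EFE), and persistently high ambulatory and
emergency care (HAC).

Each archetype simulates the five channels as independent Markov chains
with phase-specific transition kernels (phases: waves 1-4, 5-8, 9-11), then
overlays incapacity and death hazards (death absorbing, overlays covering
all channels), a permanent-dropout process and transient random
nonresponse.  By default dropout is the enrolment-only-participation event
common to postal panels: attriters answer wave 1 and nothing afterwards, so
they fall below the six-observation inclusion floor whatever happens to
them later, and retained individuals carry only scattered transient
nonresponse.  The dropout probability and the transient nonresponse rate
are calibrated so that about 74.4% of simulated individuals pass the filter
and about 5.9% of retained person-wave cells are nonresponses.

Baseline covariates are drawn per individual from archetype-conditional
categorical distributions whose defaults follow the published
cluster-by-covariate frequency tables.

All numeric defaults live in ``defaults.yaml`` next to this module.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .model import (
    DEAD,
    INCAP,
    N_WAVES,
    NR,
    ChannelSpec,
    Cohort,
    CovariateTable,
    default_channel_specs,
)

ARCHETYPES = ("LHU", "IHU", "LHD", "AC2NH", "EFE", "HAC")

# Wave -> phase (transitions into waves 1-4 / 5-8 / 9-11).
_PHASE = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2])


class ConfigError(ValueError):
    """Generator configuration violates an invariant."""


@dataclass
class ChannelDynamics:
    """Initial distribution and per-phase transition kernels for one channel."""

    initial: np.ndarray  # (K,)
    kernels: np.ndarray  # (3, K, K), row-stochastic

    def validate(self, k: int, where: str) -> None:
        if self.initial.shape != (k,) or not np.isclose(self.initial.sum(), 1):
            raise ConfigError(f"{where}: initial distribution must be length {k}, sum 1")
        if self.kernels.shape != (3, k, k):
            raise ConfigError(f"{where}: need 3 phase kernels of shape {k}x{k}")
        if not np.allclose(self.kernels.sum(axis=2), 1):
            raise ConfigError(f"{where}: kernel rows must sum to 1")
        if (self.initial < 0).any() or (self.kernels < 0).any():
            raise ConfigError(f"{where}: negative probability")


@dataclass
class ArchetypeSpec:
    name: str
    prevalence: float
    channels: dict[str, ChannelDynamics]
    death_hazard: np.ndarray  # (11,) per-wave
    incap_hazard: np.ndarray  # (11,)

    def validate(self, specs: list[ChannelSpec]) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ConfigError(f"{self.name}: prevalence outside [0, 1]")
        for hz in (self.death_hazard, self.incap_hazard):
            if hz.shape != (N_WAVES,) or (hz < 0).any() or (hz > 1).any():
                raise ConfigError(f"{self.name}: hazards must be 11 probabilities")
        for spec in specs:
            dyn = self.channels.get(spec.name)
            if dyn is None:
                raise ConfigError(f"{self.name}: missing channel {spec.name!r}")
            dyn.validate(spec.k, f"{self.name}/{spec.name}")


@dataclass
class GeneratorConfig:
    n_raw: int = 3053
    seed: int = 0
    nonresponse_rate: float = 0.0719
    max_transient_nr: int = 2
    dropout_prob: float = 0.2562
    dropout_waves: tuple[int, int] = (2, 2)
    archetypes: list[ArchetypeSpec] = field(default_factory=list)
    covariate_model: dict = field(default_factory=dict)
    specs: list[ChannelSpec] = field(default_factory=default_channel_specs)

    def validate(self) -> None:
        if self.n_raw < 1:
            raise ConfigError("n_raw must be >= 1")
        for p in (self.nonresponse_rate, self.dropout_prob):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        if not self.archetypes:
            raise ConfigError("no archetypes configured")
        total = sum(a.prevalence for a in self.archetypes)
        if not np.isclose(total, 1.0):
            raise ConfigError(f"archetype prevalences sum to {total}, not 1")
        for arch in self.archetypes:
            arch.validate(self.specs)


def _dynamics_from_dict(d: dict, k: int) -> ChannelDynamics:
    initial = np.asarray(d["initial"], dtype=float)
    kernels = d.get("kernels")
    if kernels is None:
        kernels = np.broadcast_to(np.eye(k), (3, k, k)).copy()
    else:
        kernels = np.asarray(kernels, dtype=float)
        if kernels.ndim == 2:  # one kernel for all phases
            kernels = np.broadcast_to(kernels, (3, k, k)).copy()
        elif kernels.ndim == 3 and kernels.shape[0] == 1:
            kernels = np.broadcast_to(kernels[0], (3, k, k)).copy()
    return ChannelDynamics(initial, kernels)


def _hazard_from_entry(entry) -> np.ndarray:
    if entry is None:
        return np.zeros(N_WAVES)
    hz = np.asarray(entry, dtype=float)
    if hz.ndim == 0:
        hz = np.full(N_WAVES, float(hz))
    return hz


def config_from_dict(raw: dict, specs: list[ChannelSpec] | None = None) -> GeneratorConfig:
    specs = specs or default_channel_specs()
    by_name = {s.name: s for s in specs}
    archetypes = []
    for name, a in raw["archetypes"].items():
        channels = {}
        for ch_name, ch in a["channels"].items():
            if ch_name not in by_name:
                raise ConfigError(f"unknown channel {ch_name!r} in archetype {name}")
            channels[ch_name] = _dynamics_from_dict(ch, by_name[ch_name].k)
        for spec in specs:  # unspecified channels stay at "none"
            if spec.name not in channels:
                init = np.zeros(spec.k)
                init[0] = 1.0
                channels[spec.name] = ChannelDynamics(
                    init, np.broadcast_to(np.eye(spec.k), (3, spec.k, spec.k)).copy()
                )
        archetypes.append(
            ArchetypeSpec(
                name=name,
                prevalence=float(a["prevalence"]),
                channels=channels,
                death_hazard=_hazard_from_entry(a.get("death_hazard")),
                incap_hazard=_hazard_from_entry(a.get("incap_hazard")),
            )
        )
    cfg = GeneratorConfig(
        n_raw=int(raw.get("n_raw", 3053)),
        seed=int(raw.get("seed", 0)),
        nonresponse_rate=float(raw["nonresponse_rate"]),
        max_transient_nr=int(raw.get("max_transient_nr", 2)),
        dropout_prob=float(raw["dropout_prob"]),
        dropout_waves=tuple(raw.get("dropout_waves", (2, 2))),
        archetypes=archetypes,
        covariate_model=raw.get("covariates", {}),
        specs=specs,
    )
    cfg.validate()
    return cfg


def default_config(**overrides) -> GeneratorConfig:
    """Load the packaged default configuration (optionally overriding fields)."""
    text = (
        importlib.resources.files("caretraj").joinpath("defaults.yaml").read_text()
    )
    cfg = config_from_dict(yaml.safe_load(text))
    return replace(cfg, **overrides) if overrides else cfg


def load_config(path, **overrides) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        cfg = config_from_dict(yaml.safe_load(fh))
    return replace(cfg, **overrides) if overrides else cfg


def _markov_sample(rng, n, dyn: ChannelDynamics) -> np.ndarray:
    """Vectorised simulation of one channel for n individuals over all waves."""
    k = dyn.initial.shape[0]
    out = np.empty((n, N_WAVES), dtype=np.int8)
    cum0 = np.cumsum(dyn.initial)
    out[:, 0] = np.searchsorted(cum0, rng.random(n), side="right").clip(0, k - 1)
    cums = np.cumsum(dyn.kernels, axis=2)  # (3, K, K)
    for t in range(1, N_WAVES):
        rows = cums[_PHASE[t]][out[:, t - 1]]
        u = rng.random(n)
        out[:, t] = (u[:, None] > rows).sum(axis=1).clip(0, k - 1)
    return out


def _first_event(rng, hazards: np.ndarray, n: int) -> np.ndarray:
    """First wave (1-based) at which a per-wave hazard fires; 0 = never."""
    fires = rng.random((n, N_WAVES)) < hazards[None, :]
    any_fire = fires.any(axis=1)
    first = np.where(any_fire, fires.argmax(axis=1) + 1, 0)
    return first


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[Cohort, np.ndarray]:
    """Simulate a cohort; returns it with the latent archetype labels.

    Deterministic given the configuration (including its seed; ``seed``
    overrides the configured one).
    """
    cfg = config or default_config()
    cfg.validate()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_raw

    prev = np.array([a.prevalence for a in cfg.archetypes])
    labels = rng.choice(len(cfg.archetypes), size=n, p=prev / prev.sum())

    states = np.empty((n, N_WAVES, len(cfg.specs)), dtype=np.int8)
    death_wave = np.zeros(n, dtype=int)
    incap = np.zeros((n, N_WAVES), dtype=bool)
    for ai, arch in enumerate(cfg.archetypes):
        members = np.flatnonzero(labels == ai)
        if members.size == 0:
            continue
        for j, spec in enumerate(cfg.specs):
            states[members, :, j] = _markov_sample(rng, members.size, arch.channels[spec.name])
        incap[members] = rng.random((members.size, N_WAVES)) < arch.incap_hazard[None, :]
        death_wave[members] = _first_event(rng, arch.death_hazard, members.size)
    incap[:, 0] = False  # enrolment wave: participation confirmed

    # Permanent dropout: an early attrition event; the individual stops
    # responding from the dropout wave on, and nothing (including a later
    # death) is observed afterwards.
    lo, hi = cfg.dropout_waves
    drops = rng.random(n) < cfg.dropout_prob
    drop_wave = np.where(drops, rng.integers(lo, hi + 1, size=n), 0)
    # A death observed before the dropout wave stands (absorbing).
    masked_death = (drop_wave > 0) & ((death_wave == 0) | (death_wave >= drop_wave))
    eff_death = np.where(masked_death, 0, death_wave)
    eff_drop = np.where(masked_death, drop_wave, 0)

    waves = np.arange(1, N_WAVES + 1)
    dead_mask = (eff_death[:, None] > 0) & (waves[None, :] >= eff_death[:, None])
    drop_mask = (eff_drop[:, None] > 0) & (waves[None, :] >= eff_drop[:, None])
    alive = ~dead_mask & ~drop_mask
    incap_mask = incap & alive
    # Transient nonresponse: occasionally missed questionnaires after entry
    # (wave 1 is the enrolment questionnaire, always answered).  A continuing
    # participant misses at most a few waves — chronic non-responders are the
    # dropout process — so the per-person count is a binomial capped at
    # max_transient_nr, placed uniformly over the responsive waves.
    eligible = alive & ~incap_mask
    eligible[:, 0] = False
    transient = np.zeros((n, N_WAVES), dtype=bool)
    n_elig = eligible.sum(axis=1)
    counts = np.minimum(
        rng.binomial(n_elig, cfg.nonresponse_rate), cfg.max_transient_nr
    )
    for i in np.flatnonzero(counts):
        waves_i = np.flatnonzero(eligible[i])
        picks = rng.choice(waves_i, size=min(counts[i], waves_i.size), replace=False)
        transient[i, picks] = True
    nr_mask = drop_mask | transient

    states[dead_mask] = DEAD
    states[incap_mask & ~nr_mask] = INCAP
    states[nr_mask] = NR

    ids = [f"P{i + 1:04d}" for i in range(n)]
    arch_names = np.array([a.name for a in cfg.archetypes])
    cov = generate_covariates(
        arch_names[labels], cfg.covariate_model, rng=rng, ids=ids
    )
    cohort = Cohort(ids, cfg.specs, states, cov)
    return cohort, arch_names[labels]


def generate_covariates(
    labels,
    covariate_model: dict,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    ids=None,
) -> CovariateTable:
    """Draw baseline covariates from archetype-conditional distributions.

    ``covariate_model`` maps covariate name -> {"categories": [...],
    "by_archetype": {archetype: [probabilities]}} for categorical
    covariates, and the special entry ``age`` -> {"base": [lo, hi],
    "mean_by_archetype": {...}}.  Covariates are conditionally independent
    given the archetype.  A category named ``"missing"`` is emitted as an
    empty (NaN) cell.
    """
    labels = np.asarray(labels)
    known = set(ARCHETYPES)
    bad = set(labels) - known
    if bad:
        raise ConfigError(f"unknown archetype labels {sorted(bad)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(labels)
    if ids is None:
        ids = [f"P{i + 1:04d}" for i in range(n)]
    data: dict[str, np.ndarray] = {}
    categorical: dict[str, list[str]] = {}
    numeric: list[str] = []
    for name, spec in covariate_model.items():
        if name == "age":
            lo, hi = spec["base"]
            base = rng.integers(lo, hi + 1, size=n).astype(float)
            shift = np.array(
                [spec["mean_by_archetype"][lab] - (lo + hi) / 2 for lab in labels]
            )
            data[name] = base + shift
            numeric.append(name)
            continue
        cats = list(spec["categories"])
        out = np.empty(n, dtype=object)
        for arch, probs in spec["by_archetype"].items():
            members = np.flatnonzero(labels == arch)
            if members.size == 0:
                continue
            p = np.asarray(probs, dtype=float)
            if (p < 0).any():
                raise ConfigError(f"covariate {name}/{arch}: negative probability")
            p = p / p.sum()
            draws = rng.choice(len(cats), size=members.size, p=p)
            out[members] = [cats[d] for d in draws]
        out[out == "missing"] = None
        data[name] = out
        categorical[name] = [c for c in cats if c != "missing"]
    df = pd.DataFrame(data, index=pd.Index(ids, name="id"))
    return CovariateTable(df, categorical, numeric)


def summarize_cohort(cohort: Cohort) -> dict:
    """Descriptive summary: nonresponse share, never-user shares, state
    distributions per wave, deaths by wave."""
    states = cohort.states
    n, t, c = states.shape
    first = states[:, :, 0]
    nr_share = float((first == NR).mean())
    never_user = {}
    for j, spec in enumerate(cohort.specs):
        ch = states[:, :, j]
        never_user[spec.name] = float(((ch <= 0).all(axis=1)).mean())
    per_wave = {}
    for j, spec in enumerate(cohort.specs):
        ch = states[:, :, j]
        dist = {}
        for code in (DEAD, INCAP, NR, *range(spec.k)):
            dist[spec.decode(code)] = (ch == code).mean(axis=0).tolist()
        per_wave[spec.name] = dist
    newly_dead = (first == DEAD) & np.concatenate(
        [np.ones((n, 1), bool), first[:, :-1] != DEAD], axis=1
    )
    return {
        "n": n,
        "nonresponse_share": nr_share,
        "never_above_none": never_user,
        "state_distribution": per_wave,
        "deaths_by_wave": newly_dead.sum(axis=0).tolist(),
    }


def calibrate_attrition(
    retention_target: float = 2271 / 3053,
    nr_target: float = 0.059,
    n: int = 20000,
    seed: int = 12345,
    tol: float = 5e-4,
    max_iter: int = 12,
) -> tuple[float, float]:
    """One-dimensional searches for the dropout probability and transient
    nonresponse rate hitting the retention and nonresponse-share targets.

    Used once to freeze the packaged defaults; exposed so the calibration is
    reproducible after editing archetype dynamics.
    """
    from .model import filter_min_observations

    cfg = default_config(n_raw=n, seed=seed)

    def measure(dropout, nr_rate):
        c = replace(cfg, dropout_prob=dropout, nonresponse_rate=nr_rate)
        cohort, _ = generate_cohort(c)
        kept, _, _ = filter_min_observations(cohort)
        return kept.n / cohort.n, summarize_cohort(kept)["nonresponse_share"]

    dropout, nr_rate = cfg.dropout_prob, cfg.nonresponse_rate
    for _ in range(max_iter):
        retention, nr_share = measure(dropout, nr_rate)
        if abs(retention - retention_target) < tol and abs(nr_share - nr_target) < tol / 2:
            break
        # Retention responds ~linearly to dropout_prob, NR share to nr_rate.
        dropout = float(np.clip(dropout + (retention - retention_target), 0, 1))
        nr_rate = float(np.clip(nr_rate * nr_target / max(nr_share, 1e-9), 0, 1))
    return dropout, nr_rate
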