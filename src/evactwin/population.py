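"""Zoned synthetic population generation.

A study region is described as a set of zones, each carrying categorical
marginal distributions (age, income, education, ethnicity), a high-risk
flood-zone probability, a prior-hurricane-experience probability, a shelter
distance, and prevalences of evacuation constraints (limited mobility, no
vehicle, financial barriers, pets, caregiving obligations). Agents are sampled
zone-first (zone by weight), then each attribute independently from that
zone's marginals — cross-attribute correlation is expressed only through
between-zone differences.

The packaged default configuration is a synthetic ten-zone region with
heterogeneous flood risk and income/education gradients; it emulates the
*statistical structure* of a coastal-county population and is not an estimate
of any real county.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

CONSTRAINT_NAMES = (
    "mobility_limited",
    "no_vehicle",
    "financial_barrier",
    "pets",
    "caregiving",
)

_SUM_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a population configuration violates its invariants."""


@dataclass(frozen=True)
class Marginal:
    """A categorical distribution: ordered labels with probabilities.

    Label order is meaningful for ordinal attributes (income, education):
    later labels are treated as higher bands by the belief initializer.
    """

    labels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.probs) or not self.labels:
            raise ConfigError("marginal needs matching, nonempty labels and probs")
        if any(p < 0 or p > 1 for p in self.probs):
            raise ConfigError("marginal probabilities must lie in [0, 1]")
        if abs(sum(self.probs) - 1.0) > _SUM_TOL:
            raise ConfigError(
                f"marginal probabilities sum to {sum(self.probs)!r}, expected 1"
            )

    @classmethod
    def from_mapping(cls, m: Mapping[str, float], name: str = "") -> "Marginal":
        try:
            return cls(tuple(m.keys()), tuple(float(v) for v in m.values()))
        except ConfigError as exc:
            raise ConfigError(f"{name or 'marginal'}: {exc}") from None


@dataclass(frozen=True)
class ZoneConfig:
    """One spatial zone's sampling parameters."""

    zone_id: str
    weight: float
    age_marginal: Marginal
    income_marginal: Marginal
    education_marginal: Marginal
    ethnicity_marginal: Marginal
    p_flood_zone: float
    p_prior_hurricane: float
    shelter_distance_km: float | tuple[float, float]  # scalar, or (mean, sd) truncated at 0
    constraint_prevalences: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("weight", "p_flood_zone", "p_prior_hurricane"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"zone {self.zone_id}: {name}={v!r} outside [0, 1]")
        d = self.shelter_distance_km
        if (d if isinstance(d, (int, float)) else d[0]) < 0:
            raise ConfigError(f"zone {self.zone_id}: shelter distance must be >= 0")
        for k, p in self.constraint_prevalences.items():
            if k not in CONSTRAINT_NAMES:
                raise ConfigError(f"zone {self.zone_id}: unknown constraint {k!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"zone {self.zone_id}: prevalence {k}={p!r} outside [0, 1]")


@dataclass(frozen=True)
class PopulationConfig:
    """Full population sampling specification."""

    n_agents: int
    zones: tuple[ZoneConfig, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 0:
            raise ConfigError("n_agents must be >= 0")
        if not self.zones:
            raise ConfigError("at least one zone is required")
        total = sum(z.weight for z in self.zones)
        if abs(total - 1.0) > _SUM_TOL:
            raise ConfigError(f"zone weights sum to {total!r}, expected 1")
        ids = [z.zone_id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ConfigError("zone_id values must be unique")


@dataclass(frozen=True)
class AgentProfile:
    """Demographic, geospatial, and constraint attributes of one resident."""

    agent_id: str
    zone_id: str
    age_band: str
    income_band: str
    education_level: str
    ethnicity: str
    in_flood_zone: bool
    prior_hurricane_experience: bool
    shelter_distance_km: float
    constraints: frozenset[str]


def _parse_zone(d: Mapping[str, object]) -> ZoneConfig:
    def marg(key: str) -> Marginal:
        return Marginal.from_mapping(d[key], name=f"{d.get('zone_id')}.{key}")  # type: ignore[arg-type]

    dist = d.get("shelter_distance_km", 5.0)
    if isinstance(dist, Mapping):
        dist = (float(dist["mean"]), float(dist["sd"]))
    else:
        dist = float(dist)  # type: ignore[arg-type]
    return ZoneConfig(
        zone_id=str(d["zone_id"]),
        weight=float(d["weight"]),  # type: ignore[arg-type]
        age_marginal=marg("age_marginal"),
        income_marginal=marg("income_marginal"),
        education_marginal=marg("education_marginal"),
        ethnicity_marginal=marg("ethnicity_marginal"),
        p_flood_zone=float(d.get("p_flood_zone", 0.0)),  # type: ignore[arg-type]
        p_prior_hurricane=float(d.get("p_prior_hurricane", 0.0)),  # type: ignore[arg-type]
        shelter_distance_km=dist,
        constraint_prevalences=dict(d.get("constraint_prevalences", {})),  # type: ignore[arg-type]
    )


def load_population_config(source: str | Path | Mapping[str, object] | None = None) -> PopulationConfig:
    """Load a population config from YAML/JSON (or the packaged default)."""
    if source is None:
        raw = resources.files("evactwin.data").joinpath("population_default.yaml").read_text()
        doc = yaml.safe_load(raw)
    elif isinstance(source, Mapping):
        doc = source
    else:
        doc = yaml.safe_load(Path(source).read_text())
    try:
        zones = tuple(_parse_zone(z) for z in doc["zones"])
        return PopulationConfig(
            n_agents=int(doc.get("n_agents", 222)),
            zones=zones,
            seed=int(doc.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"missing configuration field: {exc}") from None


def _sample_categorical(
    rng: np.random.Generator, zone_idx: np.ndarray, per_zone: list[Marginal]
) -> np.ndarray:
    """Sample one categorical attribute for every agent, zone-conditionally.

    Returns integer codes into each agent's own zone marginal support.
    """
    n = zone_idx.size
    u = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    for z, marg in enumerate(per_zone):
        mask = zone_idx == z
        if mask.any():
            cdf = np.cumsum(marg.probs)
            out[mask] = np.searchsorted(cdf, u[mask], side="right").clip(0, len(marg.probs) - 1)
    return out


def generate_population_frame(config: PopulationConfig) -> pd.DataFrame:
    """Vectorized sampler; one row per agent.

    Columns: agent_id, zone_id, the four categorical labels plus their ordinal
    codes (``*_code``), in_flood_zone, prior_hurricane_experience,
    shelter_distance_km, and one boolean column per constraint flag.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_agents
    zones = config.zones
    weights = np.array([z.weight for z in zones])
    zone_idx = rng.choice(len(zones), size=n, p=weights / weights.sum())

    cols: dict[str, np.ndarray] = {}
    cols["agent_id"] = np.array([f"a{i:05d}" for i in range(n)])
    zone_ids = np.array([z.zone_id for z in zones])
    cols["zone_id"] = zone_ids[zone_idx] if n else np.array([], dtype=object)

    for attr in ("age", "income", "education", "ethnicity"):
        margs = [getattr(z, f"{attr}_marginal") for z in zones]
        codes = _sample_categorical(rng, zone_idx, margs)
        labels = np.array(
            [margs[zi].labels[c] for zi, c in zip(zone_idx, codes)], dtype=object
        ) if n else np.array([], dtype=object)
        name = {"age": "age_band", "income": "income_band",
                "education": "education_level", "ethnicity": "ethnicity"}[attr]
        cols[name] = labels
        cols[name + "_code"] = codes
        if attr in ("income", "education"):
            # normalised ordinal rank in [0, 1] within each agent's own zone marginal
            n_levels = np.array([len(m.labels) for m in margs])[zone_idx]
            cols[name + "_rank"] = codes / np.maximum(n_levels - 1, 1)

    p_flood = np.array([z.p_flood_zone for z in zones])[zone_idx]
    p_prior = np.array([z.p_prior_hurricane for z in zones])[zone_idx]
    cols["in_flood_zone"] = rng.random(n) < p_flood
    cols["prior_hurricane_experience"] = rng.random(n) < p_prior

    dist_mean = np.empty(len(zones))
    dist_sd = np.empty(len(zones))
    for i, z in enumerate(zones):
        if isinstance(z.shelter_distance_km, tuple):
            dist_mean[i], dist_sd[i] = z.shelter_distance_km
        else:
            dist_mean[i], dist_sd[i] = z.shelter_distance_km, 0.0
    raw = dist_mean[zone_idx] + dist_sd[zone_idx] * rng.standard_normal(n)
    cols["shelter_distance_km"] = np.maximum(raw, 0.0)

    for c in CONSTRAINT_NAMES:
        prev = np.array([float(z.constraint_prevalences.get(c, 0.0)) for z in zones])[zone_idx]
        cols[c] = rng.random(n) < prev

    return pd.DataFrame(cols)


def generate_population(config: PopulationConfig) -> list[AgentProfile]:
    """Sample ``config.n_agents`` agent profiles (seed-deterministic)."""
    frame = generate_population_frame(config)
    return frame_to_profiles(frame)


def frame_to_profiles(frame: pd.DataFrame) -> list[AgentProfile]:
    out = []
    for row in frame.itertuples(index=False):
        active = frozenset(c for c in CONSTRAINT_NAMES if getattr(row, c))
        out.append(
            AgentProfile(
                agent_id=row.agent_id,
                zone_id=row.zone_id,
                age_band=row.age_band,
                income_band=row.income_band,
                education_level=row.education_level,
                ethnicity=row.ethnicity,
                in_flood_zone=bool(row.in_flood_zone),
                prior_hurricane_experience=bool(row.prior_hurricane_experience),
                shelter_distance_km=float(row.shelter_distance_km),
                constraints=active,
            )
        )
    return out


def population_summary(agents: Sequence[AgentProfile] | pd.DataFrame) -> dict[str, pd.Series]:
    """Per-zone counts and per-attribute empirical frequencies.

    Frequencies within each attribute sum to 1 (empty population gives an
    empty summary). Constraint and flag entries report prevalence, not a
    distribution.
    """
    if isinstance(agents, pd.DataFrame):
        frame = agents
    else:
        frame = pd.DataFrame(
            {
                "zone_id": [a.zone_id for a in agents],
                "age_band": [a.age_band for a in agents],
                "income_band": [a.income_band for a in agents],
                "education_level": [a.education_level for a in agents],
                "ethnicity": [a.ethnicity for a in agents],
                "in_flood_zone": [a.in_flood_zone for a in agents],
                "prior_hurricane_experience": [a.prior_hurricane_experience for a in agents],
                **{c: [c in a.constraints for a in agents] for c in CONSTRAINT_NAMES},
            }
        )
    if frame.empty:
        return {}
    summary: dict[str, pd.Series] = {"zone_counts": frame["zone_id"].value_counts().sort_index()}
    for col in ("zone_id", "age_band", "income_band", "education_level", "ethnicity"):
        summary[col] = frame[col].value_counts(normalize=True).sort_index()
    for col in ("in_flood_zone", "prior_hurricane_experience", *CONSTRAINT_NAMES):
        summary[col] = pd.Series({"prevalence": float(frame[col].mean())})
    return summary


def roster_to_csv(agents: Sequence[AgentProfile], path: str | Path) -> None:
    """Write the agent roster as CSV, one row per agent."""
    rows = []
    for a in agents:
        rows.append(
            {
                "agent_id": a.agent_id,
                "zone_id": a.zone_id,
                "age_band": a.age_band,
                "income_band": a.income_band,
                "education_level": a.education_level,
                "ethnicity": a.ethnicity,
                "in_flood_zone": a.in_flood_zone,
                "prior_hurricane_experience": a.prior_hurricane_experience,
                "shelter_distance_km": a.shelter_distance_km,
                **{c: (c in a.constraints) for c in CONSTRAINT_NAMES},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
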