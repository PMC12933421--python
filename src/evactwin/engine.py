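"""Experiment orchestration: 16-condition design, replication, aggregation.

Each condition injects exactly one message into a freshly drawn population
(agent memory is reset between replications and conditions, so conditions are
fully independent — the repeated-measures analogue of a between-subjects
design). Per-replication seeds are derived from (master seed, condition id,
replication index) with a stable SHA-256 hash, making every output byte a
deterministic function of the design and configuration. Across the ten
replications only the population redraw varies (attribute sampling and
belief-initialization noise); the decision step itself is deterministic.

The engine exposes a step/tick loop for future multi-step scenarios, but the
shipped experiment collapses to a single decision tick per run.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .decision import (
    BeliefInitConfig,
    DecisionWeights,
    apply_message_frame,
    decide_frame,
    initialize_beliefs_frame,
)
from .maf import MessageSpec, load_catalog
from .population import PopulationConfig, generate_population_frame, load_population_config


class DesignError(ValueError):
    """Raised for invalid experiment designs (duplicate ids, bad sizes)."""


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: a message shown to n_agents, replicated."""

    condition_id: str
    message: MessageSpec
    n_agents: int = 222
    n_replications: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents <= 0:
            raise DesignError(f"condition {self.condition_id}: n_agents must be > 0")
        if self.n_replications < 1:
            raise DesignError(f"condition {self.condition_id}: n_replications must be >= 1")


@dataclass(frozen=True)
class RunRecord:
    """One agent's outcome in one replication of one condition."""

    condition_id: str
    replication_index: int
    agent_id: str
    evacuated: bool


@dataclass(frozen=True)
class ExperimentResult:
    """All run records plus per-condition aggregated counts.

    ``per_condition_counts`` maps condition id -> (evacuated, not_evacuated),
    where counts are replication means rounded half-up so that they sum to the
    condition's n_agents.
    """

    records: tuple[RunRecord, ...]
    per_condition_counts: Mapping[str, tuple[int, int]]
    condition_order: tuple[str, ...] = field(default_factory=tuple)


def derive_seed(master_seed: int, condition_id: str, replication_index: int) -> int:
    """Stable per-replication seed: SHA-256 of "master:condition:rep", mod 2^31."""
    key = f"{master_seed}:{condition_id}:{replication_index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "big") % (2**31 - 1)


def run_condition(
    spec: ConditionSpec,
    pop_config: PopulationConfig,
    weights: DecisionWeights,
    init_config: BeliefInitConfig | None = None,
) -> list[RunRecord]:
    """Execute one condition: per replication, draw the population, initialize
    beliefs, apply the condition's message once to every agent, decide.

    Agent state is discarded between replications (memory reset).
    """
    init_config = init_config or BeliefInitConfig()
    records: list[RunRecord] = []
    for r in range(spec.n_replications):
        seed_r = derive_seed(spec.seed, spec.condition_id, r)
        pc = replace(pop_config, n_agents=spec.n_agents, seed=seed_r)
        frame = generate_population_frame(pc)
        beliefs = initialize_beliefs_frame(
            frame, init_config, np.random.default_rng(seed_r + 1)
        )
        beliefs = apply_message_frame(beliefs, spec.message.construct_profile)
        evacuated = decide_frame(beliefs, weights)
        records.extend(
            RunRecord(spec.condition_id, r, aid, bool(ev))
            for aid, ev in zip(frame["agent_id"], evacuated)
        )
    return records


def aggregate(
    records: Sequence[RunRecord], condition_order: Sequence[str] | None = None
) -> dict[str, tuple[int, int]]:
    """Per-condition counts: replication-mean evacuated count, rounded half-up.

    Conservation: evacuated + not_evacuated equals the condition's per-
    replication agent count.
    """
    if not records:
        return {}
    df = pd.DataFrame(
        {
            "condition_id": [r.condition_id for r in records],
            "replication_index": [r.replication_index for r in records],
            "evacuated": [r.evacuated for r in records],
        }
    )
    out: dict[str, tuple[int, int]] = {}
    order = condition_order or list(dict.fromkeys(df["condition_id"]))
    for cid, grp in df.groupby("condition_id", sort=False):
        per_rep = grp.groupby("replication_index")["evacuated"].agg(["sum", "count"])
        mean_ev = float(per_rep["sum"].mean())
        n_agents = int(per_rep["count"].iloc[0])
        ev = int(np.floor(mean_ev + 0.5))  # round half-up to integer counts
        out[cid] = (ev, n_agents - ev)
    return {cid: out[cid] for cid in order if cid in out}


def run_experiment(
    conditions: Sequence[ConditionSpec],
    pop_config: PopulationConfig,
    weights: DecisionWeights,
    init_config: BeliefInitConfig | None = None,
) -> ExperimentResult:
    """Run every condition independently and aggregate.

    Results are invariant to condition ordering (memory-reset property);
    total record count is sum(n_agents * n_replications).
    """
    ids = [c.condition_id for c in conditions]
    if len(set(ids)) != len(ids):
        raise DesignError("condition ids must be distinct")
    records: list[RunRecord] = []
    for spec in conditions:
        records.extend(run_condition(spec, pop_config, weights, init_config))
    return ExperimentResult(
        records=tuple(records),
        per_condition_counts=aggregate(records, condition_order=ids),
        condition_order=tuple(ids),
    )


def default_design(
    master_seed: int = 0,
    catalog: Sequence[MessageSpec] | None = None,
    n_replications: int = 10,
) -> list[ConditionSpec]:
    """The shipped 16-condition design: one condition per catalog message,
    222 agents each except the third fear-efficacy-norm condition at 220,
    totalling 3,550 aggregated agent-observations.
    """
    catalog = list(catalog) if catalog is not None else load_catalog()
    specs = []
    for m in catalog:
        n = 220 if m.id == "FEN3" else 222
        specs.append(
            ConditionSpec(
                condition_id=m.id,
                message=m,
                n_agents=n,
                n_replications=n_replications,
                seed=master_seed,
            )
        )
    return specs


def load_design(
    source: str | Path | Mapping[str, object] | None,
    catalog: Sequence[MessageSpec] | None = None,
    master_seed: int | None = None,
) -> list[ConditionSpec]:
    """Load a design from YAML (list of conditions referencing catalog message
    ids), or the default design when ``source`` is None.

    A design document looks like::

        n_replications: 10
        seed: 0
        conditions:
          - message_id: C1
            n_agents: 222
    """
    catalog = list(catalog) if catalog is not None else load_catalog()
    by_id = {m.id: m for m in catalog}
    if source is None:
        return default_design(master_seed or 0, catalog)
    doc = source if isinstance(source, Mapping) else yaml.safe_load(Path(source).read_text())
    default_reps = int(doc.get("n_replications", 10))
    seed = int(master_seed if master_seed is not None else doc.get("seed", 0))
    specs = []
    for entry in doc["conditions"]:
        mid = str(entry["message_id"])
        if mid not in by_id:
            raise DesignError(f"unknown message id {mid!r} in design")
        specs.append(
            ConditionSpec(
                condition_id=str(entry.get("condition_id", mid)),
                message=by_id[mid],
                n_agents=int(entry.get("n_agents", 222)),
                n_replications=int(entry.get("n_replications", default_reps)),
                seed=seed,
            )
        )
    return specs


def records_to_frame(records: Sequence[RunRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition_id": [r.condition_id for r in records],
            "replication_index": [r.replication_index for r in records],
            "agent_id": [r.agent_id for r in records],
            "evacuated": [r.evacuated for r in records],
        }
    )


def counts_to_frame(result: ExperimentResult) -> pd.DataFrame:
    """Aggregated counts in the published table's column layout."""
    rows = []
    for cid, (ev, stay) in result.per_condition_counts.items():
        n = ev + stay
        rows.append(
            {
                "condition": cid,
                "evacuated": ev,
                "not_evacuated": stay,
                "evacuation_pct": round(100.0 * ev / n, 1) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
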