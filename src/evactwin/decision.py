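"""Agent belief initialization, message ingestion, appraisal, and the
evacuation decision rule.

The model follows the Extended Parallel Process Model (EPPM) and the Theory
of Planned Behavior (TPB). Each agent carries five belief components on
[0, 1] — perceived severity, susceptibility, self-efficacy, response
efficacy, and subjective norm — initialized from its demographic and
geospatial profile with seeded Beta-distributed individual noise. A message's
construct profile shifts the corresponding beliefs deterministically.

At decision time the beliefs are collapsed into three constructs::

    T = mean(severity, susceptibility)        perceived threat
    E = mean(self_efficacy, response_efficacy)  perceived efficacy
    N = subjective_norm                         perceived subjective norm

and an EPPM appraisal routes the agent: high threat with low efficacy enters
*fear control* (denial/avoidance — no protective action), otherwise *danger
control*, where the evacuation propensity

    P(evacuate) = sigma(scale * (alpha*T + beta*E + gamma*N - delta*C - c0))

is compared against a decision threshold tau. C is a constraint burden score
summarising mobility, vehicle, financial, pet and caregiving barriers. The
decision step itself is deterministic: population-level variability comes
entirely from heterogeneity in agent traits and the seeded initialization
noise, never from stochastic choice.
"""

from __future__ import annotations

import enum
from itertools import product
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .maf import ConstructProfile, MessageCategory, profile_for
from .population import CONSTRAINT_NAMES, AgentProfile

BELIEF_COMPONENTS = (
    "severity",
    "susceptibility",
    "self_efficacy",
    "response_efficacy",
    "subjective_norm",
)


@dataclass(frozen=True)
class BeliefState:
    """The five theory constructs of one agent, each clipped to [0, 1]."""

    severity: float
    susceptibility: float
    self_efficacy: float
    response_efficacy: float
    subjective_norm: float

    def __post_init__(self) -> None:
        for name in BELIEF_COMPONENTS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"belief {name}={v!r} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in BELIEF_COMPONENTS])


class AppraisalBranch(str, enum.Enum):
    NO_RESPONSE = "no_response"
    FEAR_CONTROL = "fear_control"
    DANGER_CONTROL = "danger_control"


@dataclass(frozen=True)
class AppraisalOutcome:
    branch: AppraisalBranch


#: Default contribution of each active constraint flag to the burden score C.
DEFAULT_CONSTRAINT_WEIGHTS: dict[str, float] = {
    "mobility_limited": 0.30,
    "no_vehicle": 0.25,
    "financial_barrier": 0.25,
    "pets": 0.15,
    "caregiving": 0.15,
}


@dataclass(frozen=True)
class ConstraintScore:
    """Constraint burden: C = min(1, sum of active components' weights)."""

    components: Mapping[str, float]

    @property
    def value(self) -> float:
        return min(1.0, float(sum(self.components.values())))

    @classmethod
    def from_agent(
        cls, agent: AgentProfile, weights: Mapping[str, float] | None = None
    ) -> "ConstraintScore":
        w = dict(DEFAULT_CONSTRAINT_WEIGHTS)
        if weights:
            w.update(weights)
        return cls({c: w[c] for c in agent.constraints if c in w})


@dataclass(frozen=True)
class DecisionWeights:
    """Decision-rule parameters.

    alpha, beta, gamma, delta weight threat, efficacy, norm and constraints;
    tau is the action threshold on the propensity; theta_threat and
    theta_efficacy are the EPPM appraisal thresholds; theta_threat_low
    (default 0, i.e. unused) would route very-low-threat agents to a
    no-response branch; intercept centres the logistic argument and, together
    with tau, sets the control-condition base rate.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    tau: float = 0.5
    theta_threat: float = 0.6
    theta_efficacy: float = 0.4
    theta_threat_low: float = 0.0
    intercept: float = 0.0
    logistic_scale: float = 8.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau", "theta_threat", "theta_efficacy"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.logistic_scale <= 0:
            raise ValueError("logistic_scale must be > 0")


@dataclass(frozen=True)
class BeliefInitConfig:
    """Belief-initialization settings.

    Baselines are the component values for a reference agent (no flags, lowest
    bands, far from shelter) before noise. Shifts encode how profile
    attributes move beliefs: flood-zone residence raises susceptibility,
    prior hurricane experience raises severity, higher income/education bands
    raise self-efficacy (linearly in the normalised band rank), and shelter
    proximity raises response efficacy (linearly down to zero at
    ``distance_ref_km``). Individual noise is symmetric Beta(a, a), centred
    and scaled per component to ``noise_spread[component]`` full width, added
    independently, then everything is clipped to [0, 1].

    The default spreads make threat perception (severity, susceptibility) by
    far the most heterogeneous component — risk perception varies widely
    across residents — while perceived efficacy is tighter and low on
    average, so that most agents sit below the fear-control efficacy
    threshold until a message supplies efficacy cues.
    """

    baselines: Mapping[str, float] = field(
        default_factory=lambda: {
            "severity": 0.36,
            "susceptibility": 0.34,
            "self_efficacy": 0.16,
            "response_efficacy": 0.18,
            "subjective_norm": 0.38,
        }
    )
    flood_zone_susceptibility_shift: float = 0.10
    prior_hurricane_severity_shift: float = 0.10
    income_self_efficacy_shift: float = 0.06
    education_self_efficacy_shift: float = 0.06
    shelter_proximity_shift: float = 0.12
    distance_ref_km: float = 20.0
    noise_beta_a: float = 2.0
    noise_spread: Mapping[str, float] = field(
        default_factory=lambda: {
            "severity": 0.5,
            "susceptibility": 0.5,
            "self_efficacy": 0.3,
            "response_efficacy": 0.3,
            "subjective_norm": 0.9,
        }
    )

    def noise_sd(self, component: str) -> float:
        """Standard deviation of the centred, scaled Beta noise."""
        a = self.noise_beta_a
        return self.noise_spread[component] * float(np.sqrt(1.0 / (4 * (2 * a + 1))))


def initialize_beliefs_frame(
    frame: pd.DataFrame,
    config: BeliefInitConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vectorized belief initialization for a population frame.

    Returns a DataFrame with the five belief columns plus ``constraint_score``.
    Noise is drawn component-by-component in a fixed order, so results are
    deterministic for a given generator state.
    """
    n = len(frame)
    base = {c: np.full(n, config.baselines[c], dtype=float) for c in BELIEF_COMPONENTS}

    base["susceptibility"] += config.flood_zone_susceptibility_shift * frame[
        "in_flood_zone"
    ].to_numpy(dtype=float)
    base["severity"] += config.prior_hurricane_severity_shift * frame[
        "prior_hurricane_experience"
    ].to_numpy(dtype=float)

    base["self_efficacy"] += config.income_self_efficacy_shift * frame[
        "income_band_rank"
    ].to_numpy(dtype=float)
    base["self_efficacy"] += config.education_self_efficacy_shift * frame[
        "education_level_rank"
    ].to_numpy(dtype=float)

    dist = frame["shelter_distance_km"].to_numpy(dtype=float)
    proximity = np.clip(1.0 - dist / config.distance_ref_km, 0.0, 1.0)
    base["response_efficacy"] += config.shelter_proximity_shift * proximity

    a = config.noise_beta_a
    out = {}
    for c in BELIEF_COMPONENTS:
        noise = (rng.beta(a, a, size=n) - 0.5) * config.noise_spread[c]
        out[c] = np.clip(base[c] + noise, 0.0, 1.0)

    cw = DEFAULT_CONSTRAINT_WEIGHTS
    burden = np.zeros(n)
    for name in CONSTRAINT_NAMES:
        burden += cw[name] * frame[name].to_numpy(dtype=float)
    out["constraint_score"] = np.minimum(burden, 1.0)
    return pd.DataFrame(out, index=frame.index)


def initialize_beliefs(
    agent: AgentProfile,
    config: BeliefInitConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    n_income_levels: int = 3,
    n_education_levels: int = 4,
    income_code: int | None = None,
    education_code: int | None = None,
) -> BeliefState:
    """Initialize one agent's beliefs (scalar convenience wrapper).

    Band codes are the ordinal positions of the agent's income/education
    labels; when not supplied they are looked up in the default band orders
    (low/middle/high; no_hs/hs/some_college/bachelor_plus).
    """
    config = config or BeliefInitConfig()
    rng = rng or np.random.default_rng(0)
    inc_orders = {"low": 0, "middle": 1, "high": 2}
    edu_orders = {"no_hs": 0, "hs": 1, "some_college": 2, "bachelor_plus": 3}
    inc = income_code if income_code is not None else inc_orders.get(agent.income_band, 0)
    edu = education_code if education_code is not None else edu_orders.get(agent.education_level, 0)

    frame = pd.DataFrame(
        {
            "zone_id": [agent.zone_id],
            "in_flood_zone": [agent.in_flood_zone],
            "prior_hurricane_experience": [agent.prior_hurricane_experience],
            "income_band_rank": [inc / max(n_income_levels - 1, 1)],
            "education_level_rank": [edu / max(n_education_levels - 1, 1)],
            "shelter_distance_km": [agent.shelter_distance_km],
            **{c: [c in agent.constraints] for c in CONSTRAINT_NAMES},
        }
    )
    beliefs = initialize_beliefs_frame(frame, config, rng).iloc[0]
    return BeliefState(
        severity=float(beliefs["severity"]),
        susceptibility=float(beliefs["susceptibility"]),
        self_efficacy=float(beliefs["self_efficacy"]),
        response_efficacy=float(beliefs["response_efficacy"]),
        subjective_norm=float(beliefs["subjective_norm"]),
    )


def apply_message(beliefs: BeliefState, profile: ConstructProfile) -> BeliefState:
    """Pure belief update: construct deltas added and clipped to [0, 1].

    Threat deltas raise severity and susceptibility; efficacy deltas raise
    self- and response-efficacy; norm deltas raise the subjective norm.
    """
    clip = lambda x: float(np.clip(x, 0.0, 1.0))  # noqa: E731
    return BeliefState(
        severity=clip(beliefs.severity + profile.delta_threat),
        susceptibility=clip(beliefs.susceptibility + profile.delta_threat),
        self_efficacy=clip(beliefs.self_efficacy + profile.delta_efficacy),
        response_efficacy=clip(beliefs.response_efficacy + profile.delta_efficacy),
        subjective_norm=clip(beliefs.subjective_norm + profile.delta_norm),
    )


def apply_message_frame(beliefs: pd.DataFrame, profile: ConstructProfile) -> pd.DataFrame:
    """Vectorized :func:`apply_message` over a belief frame."""
    out = beliefs.copy()
    out["severity"] = np.clip(out["severity"] + profile.delta_threat, 0, 1)
    out["susceptibility"] = np.clip(out["susceptibility"] + profile.delta_threat, 0, 1)
    out["self_efficacy"] = np.clip(out["self_efficacy"] + profile.delta_efficacy, 0, 1)
    out["response_efficacy"] = np.clip(out["response_efficacy"] + profile.delta_efficacy, 0, 1)
    out["subjective_norm"] = np.clip(out["subjective_norm"] + profile.delta_norm, 0, 1)
    return out


_COMPOSERS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "mean": lambda a, b: (a + b) / 2.0,
    "min": np.minimum,
    "product": lambda a, b: a * b,
}


def aggregate_constructs(
    beliefs: BeliefState | pd.DataFrame, composition: str = "mean"
) -> tuple[np.ndarray | float, np.ndarray | float, np.ndarray | float]:
    """Collapse the five beliefs into (T, E, N).

    ``composition`` chooses how the two parent components combine ("mean",
    "min" or "product"); the default is the arithmetic mean.
    """
    comp = _COMPOSERS[composition]
    if isinstance(beliefs, BeliefState):
        T = float(comp(np.asarray(beliefs.severity), np.asarray(beliefs.susceptibility)))
        E = float(comp(np.asarray(beliefs.self_efficacy), np.asarray(beliefs.response_efficacy)))
        return T, E, beliefs.subjective_norm
    T = comp(beliefs["severity"].to_numpy(), beliefs["susceptibility"].to_numpy())
    E = comp(beliefs["self_efficacy"].to_numpy(), beliefs["response_efficacy"].to_numpy())
    return T, E, beliefs["subjective_norm"].to_numpy()


def appraise(T: float, E: float, weights: DecisionWeights) -> AppraisalOutcome:
    """EPPM appraisal: route an agent to a response branch.

    High perceived threat with low perceived efficacy triggers fear control
    (the maladaptive branch — denial, avoidance); otherwise the agent engages
    danger control and deliberates on protective action. Threat below
    ``theta_threat_low`` (off by default) yields no response at all.
    """
    if not (0.0 <= T <= 1.0 and 0.0 <= E <= 1.0):
        raise ValueError("T and E must lie in [0, 1]")
    if T < weights.theta_threat_low:
        return AppraisalOutcome(AppraisalBranch.NO_RESPONSE)
    if T >= weights.theta_threat and E < weights.theta_efficacy:
        return AppraisalOutcome(AppraisalBranch.FEAR_CONTROL)
    return AppraisalOutcome(AppraisalBranch.DANGER_CONTROL)


def evacuation_propensity(
    T: float | np.ndarray,
    E: float | np.ndarray,
    N: float | np.ndarray,
    C: float | np.ndarray,
    weights: DecisionWeights,
) -> float | np.ndarray:
    """P(evacuate) = sigma(scale * (alpha*T + beta*E + gamma*N - delta*C - c0)).

    Strictly increasing in T, E and N; strictly decreasing in C.
    """
    s = (
        weights.alpha * np.asarray(T)
        + weights.beta * np.asarray(E)
        + weights.gamma * np.asarray(N)
        - weights.delta * np.asarray(C)
        - weights.intercept
    )
    p = 1.0 / (1.0 + np.exp(-weights.logistic_scale * s))
    return float(p) if np.isscalar(T) or np.ndim(p) == 0 else p


def decide(
    beliefs: BeliefState,
    constraints: ConstraintScore | float,
    weights: DecisionWeights,
    composition: str = "mean",
) -> str:
    """Threshold-based action selection for one agent: 'evacuate' or 'stay'.

    Fear-control (and no-response) agents stay regardless of propensity;
    danger-control agents evacuate iff propensity >= tau (ties act).
    Deterministic given its inputs.
    """
    T, E, N = aggregate_constructs(beliefs, composition)
    C = constraints.value if isinstance(constraints, ConstraintScore) else float(constraints)
    if appraise(float(T), float(E), weights).branch is not AppraisalBranch.DANGER_CONTROL:
        return "stay"
    p = evacuation_propensity(float(T), float(E), float(N), C, weights)
    return "evacuate" if p >= weights.tau else "stay"


def decide_frame(
    beliefs: pd.DataFrame, weights: DecisionWeights, composition: str = "mean"
) -> np.ndarray:
    """Vectorized decisions for a belief frame with a constraint_score column."""
    T, E, N = aggregate_constructs(beliefs, composition)
    C = beliefs["constraint_score"].to_numpy()
    p = evacuation_propensity(T, E, N, C, weights)
    danger = ~((T >= weights.theta_threat) & (E < weights.theta_efficacy))
    danger &= T >= weights.theta_threat_low
    return danger & (np.asarray(p) >= weights.tau)


# ---------------------------------------------------------------------------
# calibration


def load_default_weights() -> DecisionWeights:
    """The shipped calibrated decision weights."""
    raw = resources.files("evactwin.data").joinpath("weights_default.yaml").read_text()
    return weights_from_mapping(yaml.safe_load(raw))


def weights_from_mapping(doc: Mapping[str, float]) -> DecisionWeights:
    fields = {
        k: float(v)
        for k, v in doc.items()
        if k in DecisionWeights.__dataclass_fields__
    }
    return DecisionWeights(**fields)


def weights_to_mapping(w: DecisionWeights) -> dict[str, float]:
    return {k: float(getattr(w, k)) for k in DecisionWeights.__dataclass_fields__}


def load_weights(source: str | Path | Mapping[str, float] | None = None) -> DecisionWeights:
    if source is None:
        return load_default_weights()
    if isinstance(source, Mapping):
        return weights_from_mapping(source)
    return weights_from_mapping(yaml.safe_load(Path(source).read_text()))


@dataclass(frozen=True)
class CalibrationConfig:
    """Seeded grid-search settings for :func:`calibrate_weights`."""

    alpha_grid: tuple[float, ...] = (0.08, 0.10, 0.12, 0.14, 0.16, 0.20)
    beta_grid: tuple[float, ...] = (0.005, 0.01, 0.02, 0.03)
    gamma_grid: tuple[float, ...] = (0.005, 0.01, 0.02, 0.03)
    delta_grid: tuple[float, ...] = (0.3, 0.4)
    theta_threat_grid: tuple[float, ...] = (0.52, 0.55, 0.58, 0.60)
    theta_efficacy_grid: tuple[float, ...] = (0.40, 0.48, 0.52, 0.56, 0.58, 0.60, 0.62, 0.64)
    n_agents: int = 2500
    n_replications: int = 4
    seed: int = 2024
    tolerance: float = 0.0


def calibrate_weights(
    target_rates: Mapping[str, float],
    search_config: CalibrationConfig | None = None,
    pop_config=None,
    init_config: BeliefInitConfig | None = None,
    deltas: Mapping[str, float] | None = None,
) -> DecisionWeights:
    """Theory-consistent calibration of the decision weights.

    Searches a seeded grid over (alpha, beta, gamma, delta) and the EPPM
    efficacy-appraisal threshold theta_efficacy, subject to alpha >= gamma
    and beta >= gamma (threat and efficacy weigh at least as much as norms).
    For each grid point the intercept is solved directly so that the
    simulated control-condition compliance matches its target (the intercept
    is the matching upper quantile of the control score distribution), then
    the summed absolute deviation between simulated framing-level compliance
    and ``target_rates`` is scored. The first grid
    point achieving deviation <= tolerance wins; otherwise the global
    minimiser (first in grid order on ties). Reproducible for a fixed seed.

    ``target_rates`` maps framing-category names (see
    :class:`~evactwin.maf.MessageCategory`) to target compliance proportions.
    """
    from .population import generate_population_frame, load_population_config

    cfg = search_config or CalibrationConfig()
    if not cfg.alpha_grid or not cfg.beta_grid or not cfg.gamma_grid or not cfg.delta_grid:
        raise ValueError("calibration search grid is empty")
    targets = {MessageCategory(k).value: float(v) for k, v in target_rates.items()}
    if not targets:
        raise ValueError("no calibration targets supplied")
    for k, v in targets.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"target rate {k}={v!r} outside [0, 1]")
    if MessageCategory.CONTROL.value not in targets:
        raise ValueError("a control target rate is required to anchor the intercept")

    pop_config = pop_config or load_population_config()
    init_config = init_config or BeliefInitConfig()

    # Pre-draw replicated populations once; grid scoring reuses them.
    categories = list(targets)
    per_cat: dict[str, dict[str, np.ndarray]] = {}
    rng_master = np.random.default_rng(cfg.seed)
    rep_seeds = rng_master.integers(0, 2**31 - 1, size=cfg.n_replications)
    frames = []
    for s in rep_seeds:
        pc = replace(pop_config, n_agents=cfg.n_agents, seed=int(s))
        frame = generate_population_frame(pc)
        beliefs = initialize_beliefs_frame(frame, init_config, np.random.default_rng(int(s) + 1))
        frames.append(beliefs)
    base = pd.concat(frames, ignore_index=True)
    for cat in categories:
        profile = profile_for(cat, deltas)
        b = apply_message_frame(base, profile)
        T, E, N = aggregate_constructs(b)
        per_cat[cat] = {
            "T": np.asarray(T),
            "E": np.asarray(E),
            "N": np.asarray(N),
            "C": b["constraint_score"].to_numpy(),
        }

    control = per_cat[MessageCategory.CONTROL.value]
    p_control = targets[MessageCategory.CONTROL.value]

    best: tuple[float, DecisionWeights] | None = None
    for a in cfg.alpha_grid:
        for b_ in cfg.beta_grid:
            for g in cfg.gamma_grid:
                if g > a or g > b_:
                    continue
                for d in cfg.delta_grid:
                    for theta_threat, th_e in product(
                        cfg.theta_threat_grid, cfg.theta_efficacy_grid
                    ):
                        s_ctrl = (
                            a * control["T"] + b_ * control["E"]
                            + g * control["N"] - d * control["C"]
                        )
                        gate_ok = ~(
                            (control["T"] >= theta_threat) & (control["E"] < th_e)
                        )
                        # intercept = score quantile putting p_control of
                        # (ungated) control agents at/above threshold
                        c0 = (
                            float(np.quantile(s_ctrl[gate_ok], 1.0 - p_control))
                            if gate_ok.any()
                            else 0.0
                        )
                        w = DecisionWeights(
                            alpha=a, beta=b_, gamma=g, delta=d, intercept=c0,
                            theta_threat=theta_threat, theta_efficacy=th_e,
                        )
                        dev = 0.0
                        for cat in categories:
                            arr = per_cat[cat]
                            danger = ~(
                                (arr["T"] >= theta_threat) & (arr["E"] < th_e)
                            )
                            s = (
                                a * arr["T"] + b_ * arr["E"] + g * arr["N"]
                                - d * arr["C"] - c0
                            )
                            rate = float(np.mean(danger & (s >= 0)))
                            dev += abs(rate - targets[cat])
                        if dev <= cfg.tolerance:
                            return w
                        if best is None or dev < best[0]:
                            best = (dev, w)
    assert best is not None
    return best[1]
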