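"""Q-learning model family for the reward / effort learning task.

Each model tracks a value estimate per shape. After a choice with binary
favourable-outcome ``o``, the chosen shape's value moves toward the scaled
outcome by the learning rate:

    Q(c) <- Q(c) + alpha * (rho * o - Q(c))

Counterfactual variants additionally update the unchosen shape toward the
complementary outcome ``1 - o`` with the same learning rate, reflecting the
anticorrelated contingency structure of the task (when one shape would have
paid off, the other would not). The outcome-sensitivity ``rho`` scales both
targets and the initial values, so for counterfactual variants with binary
outcomes the rho model is an exact reparameterisation of the temperature
model (rho acts as 1/tau on the decision utilities): the two are
observationally equivalent wherever their bounds overlap, and model
comparison can only distinguish them from the *other* family members, not
from each other.

Choices follow a softmax over decision utilities

    U(a) = Q(a) / tau + phi * C(a)

where ``tau`` is a temperature (larger tau, flatter probabilities, more
exploration) and ``C`` is an exponentially decaying trace of past choices,
``C(a) <- gamma * C(a) + 1[a == choice]``, capturing outcome-independent
choice repetition weighted by ``phi``. When the decay ``gamma`` is not a
free parameter it sits at 0, so the trace reduces to the previous-choice
indicator — the standard one-trial-back choice stickiness. Freeing gamma
extends the memory of the trace (gamma = 1 accumulates a full choice
count).

The registered family crosses four parameterisations with factual vs
counterfactual updating (2-4 free parameters per block): {alpha, tau};
{alpha, rho} with tau fixed to 1 (rho and tau are jointly scale-unidentified
with binary outcomes, so they are never both free); {alpha, tau, phi};
{alpha, tau, phi, gamma}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import task
from .task import ADVANTAGEOUS, DISADVANTAGEOUS, SessionData, TaskConfig, TrialRecord

PARAM_NAMES = ("alpha", "rho", "tau", "phi", "gamma")

# Optimisation bounds; wide relative to typical fitted values
# (alpha ~ 0.4-0.45, tau ~ 1.5-2 in this task).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "rho": (0.0, 10.0),
    "tau": (0.01, 20.0),
    "phi": (-5.0, 5.0),
    "gamma": (0.0, 1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free; the rest sit at identity values."""

    name: str
    counterfactual: bool
    use_rho: bool = False
    use_phi: bool = False
    use_gamma: bool = False

    def __post_init__(self) -> None:
        if self.use_gamma and not self.use_phi:
            raise ValueError("gamma (bias decay) requires phi (choice bias)")
        if not 2 <= self.n_free <= 4:
            raise ValueError(f"spec {self.name!r} has {self.n_free} free parameters; need 2-4")

    @property
    def free_names(self) -> tuple[str, ...]:
        names = ["alpha"]
        if self.use_rho:
            names.append("rho")  # tau fixed to 1: rho/tau jointly unidentified
        else:
            names.append("tau")
        if self.use_phi:
            names.append("phi")
        if self.use_gamma:
            names.append("gamma")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_names)


def _registry() -> dict[str, ModelSpec]:
    specs = {}
    for cf, prefix in ((False, "f"), (True, "cf")):
        specs[f"{prefix}_alpha_tau"] = ModelSpec(f"{prefix}_alpha_tau", cf)
        specs[f"{prefix}_alpha_rho"] = ModelSpec(f"{prefix}_alpha_rho", cf, use_rho=True)
        specs[f"{prefix}_alpha_tau_phi"] = ModelSpec(f"{prefix}_alpha_tau_phi", cf, use_phi=True)
        specs[f"{prefix}_alpha_tau_phi_gamma"] = ModelSpec(
            f"{prefix}_alpha_tau_phi_gamma", cf, use_phi=True, use_gamma=True
        )
    return specs


MODEL_REGISTRY: dict[str, ModelSpec] = _registry()

#: The reference model: counterfactual updating with free alpha and tau only.
BEST_MODEL = "cf_alpha_tau"


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class ParameterVector:
    """Values for all five parameters; absent parameters sit at identity."""

    alpha: float
    tau: float = 1.0
    rho: float = 1.0
    phi: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.tau <= 0.0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.rho < 0.0:
            raise ValueError(f"rho must be nonnegative, got {self.rho}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    def free_values(self, spec: ModelSpec) -> np.ndarray:
        return np.array([getattr(self, n) for n in spec.free_names])

    @classmethod
    def from_free(cls, values, spec: ModelSpec) -> "ParameterVector":
        kwargs = dict(zip(spec.free_names, (float(v) for v in values)))
        return cls(**kwargs)


@dataclass(frozen=True)
class QState:
    """Per-shape value estimates and choice-bias trace, index 0 = advantageous."""

    q: tuple[float, float]
    c: tuple[float, float] = (0.0, 0.0)


def init_state(params: ParameterVector) -> QState:
    """Unbiased start: values at the midpoint of the scaled outcome range."""
    q0 = params.rho * 0.5
    return QState(q=(q0, q0))


def choice_probability(state: QState, params: ParameterVector) -> np.ndarray:
    """Softmax choice probabilities over the two shapes (index 0 = advantageous)."""
    if params.tau <= 0.0:
        raise ValueError("tau must be positive")
    u = np.asarray(state.q) / params.tau + params.phi * np.asarray(state.c)
    u = u - u.max()  # numerical stability
    e = np.exp(u)
    return e / e.sum()


def update_state(
    state: QState, choice: int, o: int, params: ParameterVector, spec: ModelSpec
) -> QState:
    """Apply one trial's learning update; ``choice`` indexes the shapes (0 = advantageous)."""
    if o not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {o!r}")
    if choice not in (0, 1):
        raise ValueError(f"choice index must be 0 or 1, got {choice!r}")
    q = list(state.q)
    unchosen = 1 - choice
    q[choice] += params.alpha * (params.rho * o - q[choice])
    if spec.counterfactual:
        q[unchosen] += params.alpha * (params.rho * (1 - o) - q[unchosen])
    c = [params.gamma * ci for ci in state.c]
    c[choice] += 1.0
    return QState(q=(q[0], q[1]), c=(c[0], c[1]))


def _choice_index(choice: str) -> int:
    return 0 if choice == ADVANTAGEOUS else 1


def block_negloglik(
    params: ParameterVector, spec: ModelSpec, trials: list[TrialRecord]
) -> float:
    """Negative log-likelihood of the observed choices in one block."""
    if not trials:
        raise ValueError("cannot score an empty block")
    state = init_state(params)
    nll = 0.0
    for t in trials:
        p = choice_probability(state, params)
        idx = _choice_index(t.choice)
        nll -= np.log(max(p[idx], 1e-300))
        state = update_state(state, idx, t.outcome, params, spec)
    return float(nll)


def session_negloglik(
    params: ParameterVector, spec: ModelSpec, session: SessionData, block: str
) -> float:
    """Negative log-likelihood of one block of a session under the model."""
    return block_negloglik(params, spec, session.block_trials(block))


def negloglik_arrays(
    free_values: np.ndarray, spec: ModelSpec, choices: np.ndarray, outcomes: np.ndarray
) -> float:
    """Likelihood on plain index arrays (0 = advantageous); the fitting hot path.

    Identical recursion to :func:`block_negloglik` but without TrialRecord
    overhead; kept in scalar Python floats, which is faster than numpy at
    this size.
    """
    kw = dict(zip(spec.free_names, free_values))
    alpha = kw.get("alpha", 0.0)
    rho = kw.get("rho", 1.0)
    tau = kw.get("tau", 1.0)
    phi = kw.get("phi", 0.0)
    gamma = kw.get("gamma", 0.0)
    if tau <= 0.0:
        raise ValueError("tau must be positive")
    q0 = q1 = rho * 0.5
    c0 = c1 = 0.0
    cf = spec.counterfactual
    nll = 0.0
    exp, log = math.exp, math.log
    for ch, o in zip(choices.tolist(), outcomes.tolist()):
        u0 = q0 / tau + phi * c0
        u1 = q1 / tau + phi * c1
        m = u0 if u0 > u1 else u1
        e0 = exp(u0 - m)
        e1 = exp(u1 - m)
        p = (e0 if ch == 0 else e1) / (e0 + e1)
        nll -= log(p if p > 1e-300 else 1e-300)
        if ch == 0:
            q0 += alpha * (rho * o - q0)
            if cf:
                q1 += alpha * (rho * (1 - o) - q1)
        else:
            q1 += alpha * (rho * o - q1)
            if cf:
                q0 += alpha * (rho * (1 - o) - q0)
        c0 *= gamma
        c1 *= gamma
        if ch == 0:
            c0 += 1.0
        else:
            c1 += 1.0
    return float(nll)


class QLearningPolicy:
    """Choice policy for :func:`rebl.task.run_session` driven by a Q-learning agent.

    Stateless across calls: the Q state is replayed from the block history,
    so the same policy object can be reused across sessions.
    """

    def __init__(self, params: ParameterVector, spec: ModelSpec, rng: np.random.Generator):
        self.params = params
        self.spec = spec
        self.rng = rng

    def __call__(self, block: str, history) -> str:
        state = init_state(self.params)
        for t in history:
            state = update_state(state, _choice_index(t.choice), t.outcome, self.params, self.spec)
        p = choice_probability(state, self.params)
        return ADVANTAGEOUS if self.rng.random() < p[0] else DISADVANTAGEOUS


def simulate_agent(
    params: ParameterVector,
    spec: ModelSpec,
    config: TaskConfig,
    rng: np.random.Generator,
    participant_id: str = "agent",
) -> SessionData:
    """Closed-loop simulation: softmax choices, task outcomes, learning updates."""
    policy = QLearningPolicy(params, spec, rng)
    return task.run_session(policy, config, rng, participant_id=participant_id)


def session_to_arrays(session: SessionData, block: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract (choice index, outcome) arrays for one block, 0 = advantageous."""
    trials = session.block_trials(block)
    if not trials:
        raise ValueError(f"session has no trials in block {block!r}")
    choices = np.array([_choice_index(t.choice) for t in trials], dtype=np.int64)
    outcomes = np.array([t.outcome for t in trials], dtype=np.int64)
    return choices, outcomes
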