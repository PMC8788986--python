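"""Share/idle recommendations from a forest-management Markov decision process.

The pandemic severity assessment framework (PSAF) scores an outbreak on a
hospitalization ratio, a clinical-severity scale (1-7) and a
transmissibility scale (1-5). Those three numbers parameterize the classic
two-action forest MDP: each stage the hospital either *waits* (keeps its
resources; the "forest" ages, but a disruption resets it to stage 1 with
probability ``p``) or *cuts* (shares resources and resets to stage 1 for an
immediate reward). The hospitalization ratio plays the wildfire probability
``p``; clinical severity is the terminal wait reward ``r1``; transmissibility
is the terminal cut reward ``r2``. Solving the discounted MDP yields a value
and an Idle/Share recommendation per stage; negative values flag an "Ask"
(request resources) state.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "display_round",
    "WAIT",
    "CUT",
    "PSAFCase",
    "MDPModel",
    "PolicySolution",
    "build_forest_mdp",
    "bellman_residual",
    "solve_policy_iteration",
    "solve_value_iteration",
    "psaf_to_mdp",
    "label_actions",
    "decision_table",
    "OutlierRule",
]

def display_round(value: float, decimals: int = 2) -> float:
    """Round-half-even on the exact decimal value, for table display.

    Many solved values land exactly on a half (2.835, 5.985, 9.625);
    their float representations sit a hair below the half, so plain
    ``round`` misrounds them. Solver noise is cleared at 10 decimals
    first, then banker's rounding (the convention of R's ``round``, used
    to produce the reference tables) is applied at ``decimals``.
    """
    cleaned = Decimal(str(round(float(value), 10)))
    q = Decimal(1).scaleb(-decimals)
    return float(cleaned.quantize(q, rounding=ROUND_HALF_EVEN))


WAIT, CUT = 0, 1
ACTION_NAMES = ("Wait", "Cut")
ACTION_LABELS = {"Wait": "Idle", "Cut": "Share"}


@dataclass(frozen=True)
class PSAFCase:
    """One pandemic scenario on the PSAF scales."""

    hospitalization_ratio: float
    clinical_severity: float
    transmissibility: float

    def __post_init__(self) -> None:
        if not 0.0 < self.hospitalization_ratio <= 1.0:
            raise ValueError(
                f"hospitalization_ratio must be in (0, 1], got {self.hospitalization_ratio}"
            )
        if not 1.0 <= self.clinical_severity <= 7.0:
            raise ValueError(
                f"clinical_severity must be in [1, 7], got {self.clinical_severity}"
            )
        if not 1.0 <= self.transmissibility <= 5.0:
            raise ValueError(
                f"transmissibility must be in [1, 5], got {self.transmissibility}"
            )


@dataclass(frozen=True)
class MDPModel:
    """Transition/reward structure of the forest MDP.

    ``transition`` has shape (2, S, S) indexed by (action, from, to);
    ``reward`` has shape (S, 2).
    """

    transition: np.ndarray
    reward: np.ndarray
    fire_prob: float
    wait_terminal_reward: float
    cut_terminal_reward: float

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.ndim != 3 or t.shape[0] != 2 or t.shape[1] != t.shape[2]:
            raise ValueError(f"transition must have shape (2, S, S), got {t.shape}")
        if t.shape[1] < 2:
            raise ValueError("need at least 2 states")
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = t.sum(axis=2)
        if not np.allclose(row_sums, 1.0, atol=1e-12):
            raise ValueError("every transition row must sum to 1")

    @property
    def n_states(self) -> int:
        return self.transition.shape[1]


@dataclass(frozen=True)
class PolicySolution:
    """Optimal discounted values and greedy actions per state."""

    values: np.ndarray
    actions: tuple[str, ...]
    discount: float
    iterations: int


def build_forest_mdp(
    n_states: int = 3,
    r1: float = 2.0,
    r2: float = 2.0,
    p: float = 0.1,
) -> MDPModel:
    """Standard forest formulation with S age states.

    Wait: from state s, a disruption resets to state 1 with probability
    ``p``, otherwise advance to min(s+1, S); reward 0 except ``r1`` in the
    oldest state. Cut: reset to state 1 with certainty; reward 0 in state
    1, 1 in the middle states, ``r2`` in the oldest state.
    """
    if n_states < 2:
        raise ValueError(f"n_states must be >= 2, got {n_states}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be a probability, got {p}")
    if not (np.isfinite(r1) and np.isfinite(r2)):
        raise ValueError("r1 and r2 must be finite")

    S = n_states
    transition = np.zeros((2, S, S))
    for s in range(S):
        transition[WAIT, s, 0] += p
        transition[WAIT, s, min(s + 1, S - 1)] += 1.0 - p
        transition[CUT, s, 0] = 1.0

    reward = np.zeros((S, 2))
    reward[S - 1, WAIT] = r1
    reward[1 : S - 1, CUT] = 1.0
    reward[S - 1, CUT] = r2
    return MDPModel(
        transition=transition,
        reward=reward,
        fire_prob=p,
        wait_terminal_reward=r1,
        cut_terminal_reward=r2,
    )


def _q_values(model: MDPModel, values: np.ndarray, discount: float) -> np.ndarray:
    # Q[s, a] = R[s, a] + gamma * sum_s' P[a, s, s'] V[s']
    return model.reward + discount * np.einsum("ast,t->sa", model.transition, values)


def bellman_residual(model: MDPModel, values: np.ndarray, discount: float) -> float:
    """Sup-norm distance of ``values`` from the Bellman optimality fixed point."""
    q = _q_values(model, values, discount)
    return float(np.max(np.abs(q.max(axis=1) - values)))


def _greedy(q: np.ndarray) -> np.ndarray:
    # argmax with Wait (index 0) preferred on exact ties: conservative default.
    return np.argmax(q, axis=1)


def solve_policy_iteration(
    model: MDPModel, discount: float = 0.5, max_iterations: int = 1000
) -> PolicySolution:
    """Exact policy iteration (Howard): evaluate by linear solve, improve greedily.

    Converges in finitely many steps for finite MDPs; an iteration cap
    guards against pathological policy cycles.
    """
    if not 0.0 < discount < 1.0:
        raise ValueError(f"discount must be in (0, 1), got {discount}")
    S = model.n_states
    policy = np.zeros(S, dtype=int)
    eye = np.eye(S)
    for iteration in range(1, max_iterations + 1):
        p_pi = model.transition[policy, np.arange(S), :]
        r_pi = model.reward[np.arange(S), policy]
        values = np.linalg.solve(eye - discount * p_pi, r_pi)
        new_policy = _greedy(_q_values(model, values, discount))
        if np.array_equal(new_policy, policy):
            return PolicySolution(
                values=values,
                actions=tuple(ACTION_NAMES[a] for a in policy),
                discount=discount,
                iterations=iteration,
            )
        policy = new_policy
    raise RuntimeError(f"policy iteration did not converge in {max_iterations} sweeps")


def solve_value_iteration(
    model: MDPModel,
    discount: float = 0.5,
    tol: float = 1e-12,
    max_iterations: int = 1_000_000,
) -> PolicySolution:
    """Successive approximation to the Bellman fixed point (independent of
    policy iteration; used as a cross-check oracle in the test suite)."""
    if not 0.0 < discount < 1.0:
        raise ValueError(f"discount must be in (0, 1), got {discount}")
    if not tol > 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    values = np.zeros(model.n_states)
    for iteration in range(1, max_iterations + 1):
        q = _q_values(model, values, discount)
        new_values = q.max(axis=1)
        if np.max(np.abs(new_values - values)) < tol:
            values = new_values
            break
        values = new_values
    policy = _greedy(_q_values(model, values, discount))
    return PolicySolution(
        values=values,
        actions=tuple(ACTION_NAMES[a] for a in policy),
        discount=discount,
        iterations=iteration,
    )


def psaf_to_mdp(case: PSAFCase) -> tuple[float, float, float]:
    """Map a PSAF case to forest parameters (p, r1, r2).

    p = hospitalization ratio, r1 = clinical severity, r2 = transmissibility:
    the mapping under which the solved 3-state model reproduces the published
    per-stage value table at discount 0.5.
    """
    return (
        case.hospitalization_ratio,
        case.clinical_severity,
        case.transmissibility,
    )


def label_actions(solution: PolicySolution) -> list[dict]:
    """Translate a solved policy to stage-wise Idle/Share labels.

    Wait maps to "Idle", Cut to "Share". A state with a negative value is
    additionally flagged "Ask" (request resources) regardless of its greedy
    action.
    """
    rows = []
    for stage, (value, action) in enumerate(zip(solution.values, solution.actions), 1):
        rows.append(
            {
                "stage": stage,
                "value": float(value),
                "action": ACTION_LABELS[action],
                "ask": bool(value < 0),
            }
        )
    return rows


@dataclass(frozen=True)
class OutlierRule:
    """Event thresholds: a case at or beyond all three is an Outlier."""

    min_ratio: float = 0.9
    min_severity: float = 7.0
    min_transmissibility: float = 5.0

    def classify(self, case: PSAFCase) -> str:
        extreme = (
            case.hospitalization_ratio >= self.min_ratio
            and case.clinical_severity >= self.min_severity
            and case.transmissibility >= self.min_transmissibility
        )
        return "Outlier" if extreme else "Normal"


def decision_table(
    cases,
    discount: float = 0.5,
    n_states: int = 3,
    outlier_rule: OutlierRule | None = None,
) -> pd.DataFrame:
    """Per-stage value/action table for a list of PSAF cases.

    One row per (case, stage); values rounded to 2 decimals for display.
    The action column reports "Ask" for negative-value states, otherwise
    the Idle/Share label of the greedy action.
    """
    rule = outlier_rule or OutlierRule()
    rows = []
    for use_case, case in enumerate(cases, 1):
        p, r1, r2 = psaf_to_mdp(case)
        model = build_forest_mdp(n_states=n_states, r1=r1, r2=r2, p=p)
        solution = solve_policy_iteration(model, discount=discount)
        event = rule.classify(case)
        for row in label_actions(solution):
            rows.append(
                {
                    "use_case": use_case,
                    "hospitalization_ratio": case.hospitalization_ratio,
                    "clinical_severity": case.clinical_severity,
                    "transmissibility": case.transmissibility,
                    "stage": row["stage"],
                    "value": display_round(row["value"], 2),
                    "action": "Ask" if row["ask"] else row["action"],
                    "event": event,
                }
            )
    columns = [
        "use_case",
        "hospitalization_ratio",
        "clinical_severity",
        "transmissibility",
        "stage",
        "value",
        "action",
        "event",
    ]
    return pd.DataFrame(rows, columns=columns)
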