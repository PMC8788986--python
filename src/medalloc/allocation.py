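"""Bed-allocation readiness scoring and binary-GA allocation decisions.

Two fitness functions score a facility's readiness to absorb extra beds:

    FF2 = alpha * beds / (beta * death_rate) + 1 / (gamma * cost)
    FF1 = rating * FF2

so FF1 = rating x FF2 holds identically. The weights alpha, beta, gamma
let managers emphasize capacity, safety or cost. The allocation decision
is a bit per hospital (1 = receive a bed increment); a binary GA maximizes
the total fleet fitness after the increments, under a bed budget, once per
objective (FF1 and FF2), and the two decision vectors are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ga import GAConfig, ga_maximize

__all__ = [
    "FitnessWeights",
    "AllocationDecision",
    "DecisionComparison",
    "ff1",
    "ff2",
    "derive_effective_constants",
    "optimize_allocation",
    "compare_decision_sets",
]

# Hard penalty slope for chromosomes exceeding the bed budget; large enough
# to dominate any feasible fitness on normalized 0-100 scale inputs.
_BUDGET_PENALTY = 1e9


@dataclass(frozen=True)
class FitnessWeights:
    """Positive weights (alpha, beta, gamma) of the allocation objectives."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.gamma > 0):
            raise ValueError("alpha, beta and gamma must all be > 0")


@dataclass(frozen=True)
class AllocationDecision:
    """Paired per-hospital decisions and fitness under both objectives."""

    hospital_id: str
    ff1: float
    ff2: float
    decision_ff1: int
    decision_ff2: int


@dataclass(frozen=True)
class DecisionComparison:
    agreement_fraction: float
    n_agree: int
    n_total: int
    requests_ff1: int
    requests_ff2: int


def ff2(record, w: FitnessWeights = FitnessWeights()) -> float:
    """Rating-free readiness score: high beds, low death rate, low cost."""
    if not record.death_rate > 0:
        raise ZeroDivisionError(
            f"death_rate must be > 0 for FF2 (got {record.death_rate}); "
            "consider an epsilon guard upstream"
        )
    if not record.cost > 0:
        raise ZeroDivisionError(f"cost must be > 0 for FF2 (got {record.cost})")
    return (w.alpha * record.beds) / (w.beta * record.death_rate) + 1.0 / (
        w.gamma * record.cost
    )


def ff1(record, w: FitnessWeights = FitnessWeights()) -> float:
    """Rating-weighted readiness score: the star rating scales FF2."""
    if record.rating not in (1, 2, 3, 4, 5):
        raise ValueError(f"rating must be in 1..5, got {record.rating!r}")
    return record.rating * ff2(record, w)


def derive_effective_constants(row1, row2) -> tuple[float, float]:
    """Recover the effective constants (a, c) from two published rows.

    With a = alpha/beta and c = 1/gamma, FF2 is linear in (a, c):
    a * (beds / death_rate) + c * (1 / cost) = FF2. Two rows give an exact
    2x2 system; a validation helper for published tables whose weights are
    not stated. Rows are (beds, death_rate, cost, ff2) tuples.
    """
    rows = [row1, row2]
    m = np.array([[b / d, 1.0 / c] for b, d, c, _ in rows])
    y = np.array([f for _, _, _, f in rows])
    det = np.linalg.det(m)
    if abs(det) < 1e-12 * max(1.0, float(np.abs(m).max()) ** 2):
        raise ValueError("singular system: the two rows are proportional")
    a, c = np.linalg.solve(m, y)
    return float(a), float(c)


def _ff2_vector(beds, death_rate, cost, w: FitnessWeights):
    return (w.alpha * beds) / (w.beta * death_rate) + 1.0 / (w.gamma * cost)


def optimize_allocation(
    hospitals,
    w: FitnessWeights = FitnessWeights(),
    config: GAConfig | None = None,
    bed_delta: float = 1.0,
    cost_per_bed=None,
    budget_beds: float | None = None,
) -> list[AllocationDecision]:
    """Decide which hospitals should receive ``bed_delta`` extra beds.

    The chromosome is one bit per hospital. A chromosome's fitness is the
    fleet total of the objective evaluated at the post-increment state:
    granting beds raises the beds column and, through ``cost_per_bed``,
    the cost column. Chromosomes whose total added beds exceed
    ``budget_beds`` incur a hard penalty proportional to the excess.
    The GA runs twice (FF1 then FF2 objective); returned fitness values
    are evaluated at the *current* (pre-increment) conditions.

    ``cost_per_bed`` defaults to each record's cost/beds ratio (marginal
    cost at the current scale); ``budget_beds`` defaults to 10% of the
    current fleet bed total.
    """
    hospitals = list(hospitals)
    if not hospitals:
        raise ValueError("hospital list must be non-empty")
    if not bed_delta > 0:
        raise ValueError("bed_delta must be > 0")

    beds = np.array([h.beds for h in hospitals], dtype=float)
    death = np.array([h.death_rate for h in hospitals], dtype=float)
    cost = np.array([h.cost for h in hospitals], dtype=float)
    rating = np.array([h.rating for h in hospitals], dtype=float)

    if cost_per_bed is None:
        with np.errstate(divide="ignore"):
            cpb = np.where(beds > 0, cost / np.maximum(beds, 1e-300), 0.0)
    else:
        cpb = np.broadcast_to(np.asarray(cost_per_bed, dtype=float), beds.shape).copy()
    if budget_beds is None:
        budget_beds = 0.10 * float(beds.sum())
    if budget_beds < 0:
        raise ValueError("budget_beds must be >= 0")

    base = config or GAConfig(encoding="binary")
    if base.encoding != "binary":
        raise ValueError("allocation requires a binary GA config")

    def make_fitness(use_rating: bool):
        def fitness(bits: np.ndarray) -> float:
            added = float(bits.sum()) * bed_delta
            if added > budget_beds + 1e-12:
                return -_BUDGET_PENALTY * (1.0 + added - budget_beds)
            new_beds = beds + bits * bed_delta
            new_cost = cost + bits * bed_delta * cpb
            per_hospital = _ff2_vector(new_beds, death, new_cost, w)
            if use_rating:
                per_hospital = rating * per_hospital
            return float(per_hospital.sum())

        return fitness

    n = len(hospitals)
    res1 = ga_maximize(make_fitness(use_rating=True), n, base)
    # Independent seed stream for the second objective run.
    base2 = GAConfig(
        **{**base.__dict__, "seed": base.seed + 1}
    )
    res2 = ga_maximize(make_fitness(use_rating=False), n, base2)

    decisions = []
    for i, h in enumerate(hospitals):
        f2 = ff2(h, w)
        decisions.append(
            AllocationDecision(
                hospital_id=h.id,
                ff1=h.rating * f2,
                ff2=f2,
                decision_ff1=int(res1.best_chromosome[i]),
                decision_ff2=int(res2.best_chromosome[i]),
            )
        )
    return decisions


def compare_decision_sets(decisions) -> DecisionComparison:
    """Agreement summary between the FF1 and FF2 decision vectors."""
    decisions = list(decisions)
    n = len(decisions)
    n_agree = sum(1 for d in decisions if d.decision_ff1 == d.decision_ff2)
    return DecisionComparison(
        agreement_fraction=n_agree / n if n else float("nan"),
        n_agree=n_agree,
        n_total=n,
        requests_ff1=sum(d.decision_ff1 for d in decisions),
        requests_ff2=sum(d.decision_ff2 for d in decisions),
    )
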