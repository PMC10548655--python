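"""Golden-section maximization of AG over one assembler parameter.

The search works on the unit interval and maps coordinates into the real
parameter space, either directly or through a log10 transform (used for
divergence-like parameters spanning orders of magnitude, e.g. [0.0001, 0.5]).

The first two evaluations are the classic interior points at
``u = (3 - sqrt(5))/2 ≈ 0.3819660`` and ``u = (sqrt(5) - 1)/2 ≈ 0.6180340``
(equivalently ``(sqrt(5)-1)/(sqrt(5)+1)`` and its complement). Each
subsequent step discards the outer sub-interval on the side of the worse
interior point and evaluates exactly one new interior point, reusing the
surviving one, so the bracket shrinks by the inverse golden ratio per
evaluation: after a budget of ``b`` calls its width is
``((sqrt(5)-1)/2)**(b-2)`` of the initial interval.

AG is integer-valued and plateaus are common, so two deliberate choices
harden the textbook method: on *equal* interior values the right sub-interval
is dropped (biasing toward smaller parameters — for a duplication-removal
aggressiveness knob like Hifiasm's ``-s``, the safer direction), and the
returned optimum is the best over *all* evaluated points rather than the
final bracket midpoint, which is robust to mild non-unimodality. Evaluations
are memoized on the parameter rounded to 10 significant digits, so a
re-proposed point is never re-run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .errors import InvalidArgumentError, OptimizerError

#: Inverse golden ratio, (sqrt(5) - 1) / 2.
INVPHI = (math.sqrt(5.0) - 1.0) / 2.0

#: Default evaluation budget (assemblies per optimization run).
DEFAULT_BUDGET = 10


@dataclass(frozen=True)
class SearchSpace:
    """A one-dimensional parameter interval, searched directly or in log10."""

    lower: float
    upper: float
    transform: str = "identity"

    def __post_init__(self):
        if self.lower >= self.upper:
            raise InvalidArgumentError(
                f"search space needs lower < upper, got [{self.lower}, {self.upper}]"
            )
        if self.transform not in ("identity", "log10"):
            raise InvalidArgumentError(f"unknown transform {self.transform!r}")
        if self.transform == "log10" and self.lower <= 0:
            raise InvalidArgumentError("log10 transform requires lower > 0")


@dataclass(frozen=True)
class Evaluation:
    parameter: float
    ag: float
    artifact: object = None


@dataclass
class SearchTrace:
    """Every evaluated point in call order, plus the selected optimum."""

    evaluations: list[Evaluation]
    best_parameter: float
    best_ag: float
    final_bracket: tuple[float, float]  # unit-interval coordinates


def to_parameter(u: float, space: SearchSpace) -> float:
    """Map a unit-interval coordinate into the parameter space."""
    if not 0.0 <= u <= 1.0:
        raise InvalidArgumentError(f"unit coordinate {u} outside [0, 1]")
    if space.transform == "log10":
        lo, hi = math.log10(space.lower), math.log10(space.upper)
        return 10.0 ** (lo + u * (hi - lo))
    return space.lower + u * (space.upper - space.lower)


def _memo_key(parameter: float) -> str:
    return f"{parameter:.10g}"


def golden_section_maximize(
    objective: Callable[[float], object],
    space: SearchSpace,
    budget: int = DEFAULT_BUDGET,
) -> SearchTrace:
    """Maximize ``objective`` with exactly ``budget`` objective calls.

    ``objective`` receives a parameter value and returns either an AG value
    or an ``(ag, artifact)`` pair; artifacts are carried along in the trace.
    Best-point ties are broken toward the smaller parameter value. An
    objective failure aborts the search with an :class:`OptimizerError`
    carrying the parameter, the evaluation index and the partial trace.
    """
    if budget < 2:
        raise InvalidArgumentError(f"budget must be >= 2, got {budget}")

    evaluations: list[Evaluation] = []
    memo: dict[str, float] = {}

    def evaluate(u: float) -> float:
        parameter = to_parameter(u, space)
        key = _memo_key(parameter)
        if key in memo:
            return memo[key]
        try:
            result = objective(parameter)
        except Exception as exc:
            raise OptimizerError(
                f"objective failed at parameter {parameter!r} "
                f"(evaluation {len(evaluations) + 1}): {exc}",
                partial_evaluations=evaluations,
            ) from exc
        if isinstance(result, tuple):
            ag, artifact = result
        else:
            ag, artifact = result, None
        evaluations.append(Evaluation(parameter=parameter, ag=ag, artifact=artifact))
        memo[key] = ag
        return ag

    a, b = 0.0, 1.0
    x1 = a + (1.0 - INVPHI) * (b - a)
    x2 = a + INVPHI * (b - a)
    f1 = evaluate(x1)
    f2 = evaluate(x2)
    # Guard against the degenerate case where the bracket collapses to within
    # the memoization resolution and no new point can be proposed.
    stall_guard = 10 * budget
    while len(evaluations) < budget and stall_guard > 0:
        stall_guard -= 1
        if f1 >= f2:  # ties drop the right sub-interval
            b, x2, f2 = x2, x1, f1
            x1 = a + (1.0 - INVPHI) * (b - a)
            f1 = evaluate(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + INVPHI * (b - a)
            f2 = evaluate(x2)

    best = min(evaluations, key=lambda e: (-e.ag, e.parameter))
    return SearchTrace(
        evaluations=evaluations,
        best_parameter=best.parameter,
        best_ag=best.ag,
        final_bracket=(a, b),
    )


def optimize_assembly(backend, space: SearchSpace | None = None, budget: int = DEFAULT_BUDGET):
    """Run the full search against an assembler backend, then re-assemble once
    at the best parameter in final mode (all reads, no gene-only restriction).

    ``backend`` provides ``space``, ``objective(parameter) -> (ag, artifact)``
    and ``final_assembly(parameter) -> artifact``. Returns
    ``(trace, final_artifact)``.
    """
    search_space = space if space is not None else backend.space
    trace = golden_section_maximize(backend.objective, search_space, budget=budget)
    final = backend.final_assembly(trace.best_parameter)
    return trace, final


def write_trace_tsv(trace: SearchTrace, dest) -> None:
    """Persist the trace as TSV (evaluation index, parameter, AG)."""
    from .formats_io import _as_output

    with _as_output(dest) as out:
        out.write("evaluation\tparameter\tag\n")
        for i, ev in enumerate(trace.evaluations, start=1):
            out.write(f"{i}\t{ev.parameter:.10g}\t{ev.ag:g}\n")
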