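"""Discrete-state Markov schemes for ion-channel gating.

A channel is described by a set of states connected by voltage- (and
optionally calcium-) dependent transition rates.  From the transition list
the drift generator ``A``, the stoichiometry matrix ``E`` and the
per-transition intensity vector ``d`` are constructed; these are the
coefficients of the reflected stochastic differential equation

    dX_t = A X_t dt + (1/sqrt(N)) E sqrt(D(X_t)) dW + K_t

for the occupancy-fraction vector ``X_t``.  Each column of ``E`` carries one
+1 and one -1 (one channel leaving a state and entering another); ``D`` is
diagonal with entries ``rate_k * x[from_k]``, so that ``A x = E d`` for every
occupancy vector ``x``.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MarkovScheme",
    "ChannelStateVector",
    "Transition",
    "SchemeDefinitionError",
    "build_scheme",
    "evaluate_matrices",
    "steady_state_distribution",
    "hh_gate_scheme",
    "tensor_product_scheme",
    "scheme_to_json",
    "scheme_from_json",
    "RATE_FLOOR",
    "MAX_SCHEME_STATES",
]

#: lower clamp on transition rates (ms^-1); avoids exact-zero intensities
#: breaking the square-root noise terms.
RATE_FLOOR = 1e-10

#: cap on the number of states of an expanded (tensor-product) scheme.
MAX_SCHEME_STATES = 64

_V_CHECK_GRID = np.linspace(-120.0, 80.0, 41)


class SchemeDefinitionError(ValueError):
    """Raised for structurally invalid scheme definitions."""


# --------------------------------------------------------------------------
# rate expressions
# --------------------------------------------------------------------------

_EXPR_NAMES = {
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "tanh": math.tanh,
    "abs": abs,
    "pi": math.pi,
}


def compile_rate(expr: str) -> Callable[[float, float], float]:
    """Compile a symbolic rate expression in ``V`` (mV) and ``Ca_i`` (mM)."""
    code = compile(expr, "<rate>", "eval")
    for name in code.co_names:
        if name not in _EXPR_NAMES and name not in ("V", "Ca_i"):
            raise SchemeDefinitionError(
                f"unknown name {name!r} in rate expression {expr!r}"
            )

    def rate(V: float, Ca_i: float = 1e-4) -> float:
        return eval(code, {"__builtins__": {}}, {**_EXPR_NAMES, "V": V, "Ca_i": Ca_i})

    return rate


@dataclass(frozen=True)
class Transition:
    """One directed transition ``from_state -> to_state``."""

    from_state: str
    to_state: str
    rate: Callable[[float, float], float]
    expr: str | None = None  # symbolic form, kept for lossless JSON round-trips

    def __call__(self, V: float, Ca_i: float = 1e-4) -> float:
        return max(float(self.rate(V, Ca_i)), RATE_FLOOR)


@dataclass(frozen=True)
class MarkovScheme:
    """A validated discrete-state channel gating scheme."""

    name: str
    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    open_states: frozenset[str]
    unitary_conductance: float | None = None  # pS
    reversal_rule: str = ""

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def state_index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def open_indices(self) -> np.ndarray:
        return np.array(sorted(self.state_index(s) for s in self.open_states))

    def transition_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(from, to) state-index arrays, one entry per transition."""
        fr = np.array([self.state_index(t.from_state) for t in self.transitions])
        to = np.array([self.state_index(t.to_state) for t in self.transitions])
        return fr, to

    def rates(self, V: float, Ca_i: float = 1e-4) -> np.ndarray:
        """Per-transition rates (ms^-1) at a given voltage, floor-clamped."""
        return np.array([t(V, Ca_i) for t in self.transitions])

    def open_fraction(self, x: np.ndarray) -> float:
        return float(np.sum(np.asarray(x)[self.open_indices]))


@dataclass
class ChannelStateVector:
    """Occupancy fractions of a scheme's states for one cell."""

    values: np.ndarray
    scheme_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("occupancy fractions must lie in [0, 1]")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("occupancy fractions must sum to 1")


# --------------------------------------------------------------------------
# construction and validation
# --------------------------------------------------------------------------

def _is_connected(n: int, fr: Sequence[int], to: Sequence[int]) -> bool:
    """Strong connectivity by breadth-first search (forward and reverse)."""
    for edges in ((fr, to), (to, fr)):
        adj: list[list[int]] = [[] for _ in range(n)]
        for a, b in zip(*edges):
            adj[a].append(b)
        seen = {0}
        queue = deque([0])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        if len(seen) != n:
            return False
    return True


def build_scheme(definition: dict) -> MarkovScheme:
    """Build and validate a :class:`MarkovScheme` from a structured description.

    ``definition`` holds ``name``, ``states`` (ordered labels), ``transitions``
    (each ``{"from": ..., "to": ..., "rate": expr-or-callable}``),
    ``open_states`` and optionally ``unitary_conductance`` (pS) and
    ``reversal_rule``.
    """
    states = tuple(definition["states"])
    if len(set(states)) != len(states):
        raise SchemeDefinitionError("duplicate state labels")
    if not states:
        raise SchemeDefinitionError("scheme needs at least one state")

    transitions = []
    for tdef in definition["transitions"]:
        a, b = tdef["from"], tdef["to"]
        for s in (a, b):
            if s not in states:
                raise SchemeDefinitionError(f"transition references unknown state {s!r}")
        if a == b:
            raise SchemeDefinitionError("self-transitions are not allowed")
        rate = tdef["rate"]
        if callable(rate):
            transitions.append(Transition(a, b, rate))
        else:
            transitions.append(Transition(a, b, compile_rate(str(rate)), str(rate)))
    transitions = tuple(transitions)

    open_states = frozenset(definition["open_states"])
    if not open_states:
        raise SchemeDefinitionError("scheme must declare at least one open state")
    if not open_states <= set(states):
        raise SchemeDefinitionError("open_states must be a subset of states")

    scheme = MarkovScheme(
        name=str(definition.get("name", "scheme")),
        states=states,
        transitions=transitions,
        open_states=open_states,
        unitary_conductance=definition.get("unitary_conductance"),
        reversal_rule=str(definition.get("reversal_rule", "")),
    )

    fr, to = scheme.transition_indices()
    if len(states) > 1 and not _is_connected(len(states), fr, to):
        raise SchemeDefinitionError(f"scheme {scheme.name!r} is not connected")

    # rates must be finite and non-negative over the physiological voltage range
    for t in transitions:
        for V in _V_CHECK_GRID:
            r = float(t.rate(V, 1e-4))
            if not np.isfinite(r):
                raise SchemeDefinitionError(
                    f"rate {t.from_state}->{t.to_state} not finite at V={V:g} mV"
                )
            if r < 0:
                raise SchemeDefinitionError(
                    f"rate {t.from_state}->{t.to_state} negative at V={V:g} mV"
                )
    return scheme


def evaluate_matrices(
    scheme: MarkovScheme,
    x: ChannelStateVector | np.ndarray,
    V: float,
    Ca_i: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the SDE coefficient matrices at occupancy ``x`` and voltage ``V``.

    Returns ``(A, E, d)`` where ``A`` is the drift generator (columns sum to 0),
    ``E`` the stoichiometry matrix (one +1/-1 pair per column) and ``d`` the
    per-transition intensity vector ``rate_k * x[from_k]``.
    """
    xv = x.values if isinstance(x, ChannelStateVector) else np.asarray(x, float)
    n = scheme.n_states
    if xv.shape != (n,):
        raise ValueError(f"state vector has shape {xv.shape}, expected ({n},)")
    fr, to = scheme.transition_indices()
    rates = scheme.rates(V, Ca_i)

    A = np.zeros((n, n))
    E = np.zeros((n, scheme.n_transitions))
    for k, (a, b) in enumerate(zip(fr, to)):
        A[b, a] += rates[k]
        A[a, a] -= rates[k]
        E[a, k] = -1.0
        E[b, k] = 1.0
    d = rates * xv[fr]
    return A, E, d


def steady_state_distribution(
    scheme: MarkovScheme, V: float, Ca_i: float = 1e-4
) -> ChannelStateVector:
    """Stationary occupancy ``x*`` with ``A x* = 0`` on the unit simplex."""
    n = scheme.n_states
    A, _, _ = evaluate_matrices(
        scheme, np.full(n, 1.0 / n), V, Ca_i
    )
    # replace one redundant row of A with the normalization constraint
    M = np.vstack([A, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    x, _, rank, _ = np.linalg.lstsq(M, b, rcond=None)
    if rank < n:
        raise np.linalg.LinAlgError(
            f"degenerate generator for scheme {scheme.name!r} at V={V:g} mV"
        )
    resid = float(np.linalg.norm(A @ x))
    if resid > 1e-8 or np.any(x < -1e-9):
        raise np.linalg.LinAlgError(
            f"no valid stationary distribution for {scheme.name!r} at V={V:g} mV"
        )
    x = np.clip(x, 0.0, 1.0)
    x /= x.sum()
    return ChannelStateVector(x, scheme.name)


# --------------------------------------------------------------------------
# Hodgkin-Huxley conversion helpers
# --------------------------------------------------------------------------

def hh_gate_scheme(
    name: str,
    alpha: str | Callable[[float, float], float],
    beta: str | Callable[[float, float], float],
    closed: str = "C",
    open_: str = "O",
) -> MarkovScheme:
    """Exact two-state Markov scheme for one Hodgkin-Huxley gate.

    ``alpha`` is the opening rate (C -> O), ``beta`` the closing rate.
    """
    return build_scheme(
        {
            "name": name,
            "states": [closed, open_],
            "transitions": [
                {"from": closed, "to": open_, "rate": alpha},
                {"from": open_, "to": closed, "rate": beta},
            ],
            "open_states": [open_],
        }
    )


def tensor_product_scheme(name: str, a: MarkovScheme, b: MarkovScheme) -> MarkovScheme:
    """Tensor product of two independent gating schemes.

    Each combination of subunit states becomes one scheme state; the channel
    conducts when both factors are in an open state.  This is the exact
    discrete-channel expansion of a product of independent gates, so the
    reflected SDE built on it approximates the true multi-gate channel
    distribution.
    """
    if a.n_states * b.n_states > MAX_SCHEME_STATES:
        raise SchemeDefinitionError(
            f"expanded scheme would have {a.n_states * b.n_states} states "
            f"(cap {MAX_SCHEME_STATES})"
        )

    def lbl(sa: str, sb: str) -> str:
        return f"{sa}.{sb}"

    states = [lbl(sa, sb) for sb in b.states for sa in a.states]
    transitions: list[dict] = []
    for sb in b.states:  # a-transitions within each b-plane
        for t in a.transitions:
            transitions.append(
                {"from": lbl(t.from_state, sb), "to": lbl(t.to_state, sb),
                 "rate": t.rate if t.expr is None else t.expr}
            )
    for sa in a.states:  # b-transitions within each a-plane
        for t in b.transitions:
            transitions.append(
                {"from": lbl(sa, t.from_state), "to": lbl(sa, t.to_state),
                 "rate": t.rate if t.expr is None else t.expr}
            )
    open_states = [lbl(sa, sb) for sa in a.open_states for sb in b.open_states]
    return build_scheme(
        {"name": name, "states": states, "transitions": transitions,
         "open_states": open_states}
    )


# --------------------------------------------------------------------------
# JSON I/O
# --------------------------------------------------------------------------

def scheme_to_json(scheme: MarkovScheme) -> str:
    """Serialize a scheme whose rates were built from symbolic expressions."""
    for t in scheme.transitions:
        if t.expr is None:
            raise ValueError(
                "scheme has callable rates without symbolic expressions; "
                "cannot serialize losslessly"
            )
    doc = {
        "name": scheme.name,
        "states": list(scheme.states),
        "transitions": [
            {"from": t.from_state, "to": t.to_state, "rate": t.expr}
            for t in scheme.transitions
        ],
        "open_states": sorted(scheme.open_states),
        "unitary_conductance": scheme.unitary_conductance,
        "reversal_rule": scheme.reversal_rule,
    }
    return json.dumps(doc, indent=1)


def scheme_from_json(text: str) -> MarkovScheme:
    return build_scheme(json.loads(text))
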