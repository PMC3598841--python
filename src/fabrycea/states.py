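"""Disease states and the allowed-transition graph of the Fabry disease model.

The model follows the natural history of Fabry disease through eleven health
states: an asymptomatic stage, acroparesthesia (neuropathic pain), a
symptomatic stage (left-ventricular hypertrophy, chronic kidney disease
stages 1-4 or white-matter lesions), single / double / triple end-organ
complication states built from end-stage renal disease (ESRD), cardiac
complications and cerebrovascular accident (CVA), and death.  Complications,
once gained, are never lost — with the single exception of a kidney
transplant, which returns an ESRD patient to the symptomatic stage.

For utility and cost lookup the states collapse into five clusters
(asymptomatic; acroparesthesia/symptomatic; single complication; multiple
complications; dead), mirroring how patient-level utilities and resource use
are aggregated when patient numbers per individual state are low.
"""

from __future__ import annotations

import enum
from typing import Dict, FrozenSet, List, Set, Tuple


class State(str, enum.Enum):
    """The eleven Markov states. Death is absorbing."""

    ASYMPTOMATIC = "asymptomatic"
    ACROPARESTHESIA = "acroparesthesia"
    SYMPTOMS = "symptoms"
    ESRD = "esrd"
    CARDIAC = "cardiac"
    CVA = "cva"
    ESRD_CARDIAC = "esrd_cardiac"
    ESRD_CVA = "esrd_cva"
    CARDIAC_CVA = "cardiac_cva"
    ESRD_CARDIAC_CVA = "esrd_cardiac_cva"
    DEATH = "death"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Cluster(str, enum.Enum):
    """Disease-state clusters used for utility and cost lookup."""

    ASYMPTOMATIC = "asymptomatic"
    ACRO_OR_SYMPTOMS = "acro_or_symptoms"
    SINGLE_COMPLICATION = "single_complication"
    MULTIPLE_COMPLICATIONS = "multiple_complications"
    DEAD = "dead"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical state ordering used for occupancy vectors and matrices.
STATES: Tuple[State, ...] = tuple(State)
STATE_INDEX: Dict[State, int] = {s: i for i, s in enumerate(STATES)}
N_STATES: int = len(STATES)

#: Complications carried by each state.
COMPLICATIONS: Dict[State, FrozenSet[str]] = {
    State.ASYMPTOMATIC: frozenset(),
    State.ACROPARESTHESIA: frozenset(),
    State.SYMPTOMS: frozenset(),
    State.ESRD: frozenset({"esrd"}),
    State.CARDIAC: frozenset({"cardiac"}),
    State.CVA: frozenset({"cva"}),
    State.ESRD_CARDIAC: frozenset({"esrd", "cardiac"}),
    State.ESRD_CVA: frozenset({"esrd", "cva"}),
    State.CARDIAC_CVA: frozenset({"cardiac", "cva"}),
    State.ESRD_CARDIAC_CVA: frozenset({"esrd", "cardiac", "cva"}),
    State.DEATH: frozenset(),
}


def complication_count(state: State) -> int:
    """Number of end-organ complications carried in ``state`` (0-3)."""
    return len(COMPLICATIONS[state])


CLUSTER_OF: Dict[State, Cluster] = {
    State.ASYMPTOMATIC: Cluster.ASYMPTOMATIC,
    State.ACROPARESTHESIA: Cluster.ACRO_OR_SYMPTOMS,
    State.SYMPTOMS: Cluster.ACRO_OR_SYMPTOMS,
    State.ESRD: Cluster.SINGLE_COMPLICATION,
    State.CARDIAC: Cluster.SINGLE_COMPLICATION,
    State.CVA: Cluster.SINGLE_COMPLICATION,
    State.ESRD_CARDIAC: Cluster.MULTIPLE_COMPLICATIONS,
    State.ESRD_CVA: Cluster.MULTIPLE_COMPLICATIONS,
    State.CARDIAC_CVA: Cluster.MULTIPLE_COMPLICATIONS,
    State.ESRD_CARDIAC_CVA: Cluster.MULTIPLE_COMPLICATIONS,
    State.DEATH: Cluster.DEAD,
}

#: States counting towards years free of end-organ damage (YFEOD).
YFEOD_STATES: Tuple[State, ...] = (
    State.ASYMPTOMATIC,
    State.ACROPARESTHESIA,
    State.SYMPTOMS,
)

#: Edges over which the first-complication treatment effect (OR 0.82/yr) acts.
FIRST_COMPLICATION_EDGES: Tuple[Tuple[State, State], ...] = (
    (State.SYMPTOMS, State.ESRD),
    (State.SYMPTOMS, State.CARDIAC),
    (State.SYMPTOMS, State.CVA),
)

#: Edges over which the second-complication effect (OR 0.52/yr) acts.
SECOND_COMPLICATION_EDGES: Tuple[Tuple[State, State], ...] = (
    (State.ESRD, State.ESRD_CARDIAC),
    (State.ESRD, State.ESRD_CVA),
    (State.CARDIAC, State.ESRD_CARDIAC),
    (State.CARDIAC, State.CARDIAC_CVA),
    (State.CVA, State.ESRD_CVA),
    (State.CVA, State.CARDIAC_CVA),
)

#: The kidney-transplant return edge (the only edge that loses a complication).
TRANSPLANT_EDGE: Tuple[State, State] = (State.ESRD, State.SYMPTOMS)


def _build_edges() -> Set[Tuple[State, State]]:
    edges: Set[Tuple[State, State]] = set()
    edges.add((State.ASYMPTOMATIC, State.ACROPARESTHESIA))
    edges.add((State.ASYMPTOMATIC, State.SYMPTOMS))
    edges.add((State.ACROPARESTHESIA, State.SYMPTOMS))
    edges.update(FIRST_COMPLICATION_EDGES)
    edges.update(SECOND_COMPLICATION_EDGES)
    for single in (State.ESRD_CARDIAC, State.ESRD_CVA, State.CARDIAC_CVA):
        edges.add((single, State.ESRD_CARDIAC_CVA))
    edges.add(TRANSPLANT_EDGE)
    for s in STATES:
        if s is not State.DEATH:
            edges.add((s, State.DEATH))
    return edges


class TransitionGraph:
    """The set of transitions the Markov model permits.

    Progression edges add exactly one complication (double -> triple included);
    the transplant edge ESRD -> symptoms is the only regression; every living
    state can transition to death; death has no outgoing edges.
    """

    def __init__(self, edges: Set[Tuple[State, State]] | None = None) -> None:
        self.edges: FrozenSet[Tuple[State, State]] = frozenset(
            _build_edges() if edges is None else edges
        )
        self._successors: Dict[State, List[State]] = {s: [] for s in STATES}
        for a, b in sorted(self.edges, key=lambda e: (STATE_INDEX[e[0]], STATE_INDEX[e[1]])):
            self._successors[a].append(b)

    def successors(self, state: State) -> List[State]:
        return list(self._successors[state])

    def progression_edges(self) -> List[Tuple[State, State]]:
        """Non-death, non-transplant edges (the ones parameterised per sex)."""
        return sorted(
            (
                e
                for e in self.edges
                if e[1] is not State.DEATH and e != TRANSPLANT_EDGE
            ),
            key=lambda e: (STATE_INDEX[e[0]], STATE_INDEX[e[1]]),
        )

    def __contains__(self, edge: Tuple[State, State]) -> bool:
        return edge in self.edges


#: Shared default graph.
GRAPH = TransitionGraph()


def edge_key(a: State, b: State) -> str:
    """Serialise an edge as ``from->to`` for parameter files."""
    return f"{a.value}->{b.value}"


def parse_edge(key: str) -> Tuple[State, State]:
    """Inverse of :func:`edge_key`; raises ``ValueError`` on malformed keys."""
    try:
        a, b = key.split("->")
        return State(a.strip()), State(b.strip())
    except ValueError as exc:
        raise ValueError(f"malformed transition key {key!r}") from exc
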