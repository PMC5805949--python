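"""Agent-level innovate-and-propagate (IAP) dynamics.

Each agent is a Chinese-restaurant-style store of convention tokens: the
agent's "restaurant" has one "table" per convention it knows, and the number
of "customers" at a table is the token count ``t_c`` — how many times the
agent has itself produced that convention plus how many times it has heard it
from a neighbour after learning it.  With ``M = sum(t_c)`` tokens stored, the
agent reuses convention ``c`` with probability ``t_c / (M + 1)`` and invents a
brand-new convention with probability ``1 / (M + 1)`` (a concentration-1
rich-get-richer process).

Conventions come in two difficulty classes.  *Easy* conventions (the lexical
analogue) are learned from a single exposure; *Hard* conventions (the
structural analogue) require a configurable number of pooled exposures
(default two, from the same or different neighbours) before they are seated as
a table.  Token loss is modelled either as per-token Bernoulli forgetting
(horizontal transmission) or as agent death and blank-slate replacement
(vertical transmission).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "EASY",
    "HARD",
    "NEW",
    "LEARNED_NOW",
    "ALREADY_KNOWN",
    "STILL_PENDING",
    "Convention",
    "ConventionRegistry",
    "AgentState",
    "LearningThresholds",
    "production_distribution",
    "draw_production",
    "seat_token",
    "receive",
    "forgetting_sweep",
    "kill",
]

EASY = "Easy"
HARD = "Hard"

#: Distinguished outcome of :func:`production_distribution` marking invention.
#: Convention ids are non-negative, so -1 can never collide with a real id.
NEW = -1

LEARNED_NOW = "learned-now"
ALREADY_KNOWN = "already-known"
STILL_PENDING = "still-pending"


@dataclass(frozen=True)
class Convention:
    """A globally unique cultural item with an immutable difficulty class."""

    id: int
    difficulty_class: str

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError(f"convention id must be non-negative, got {self.id}")
        if self.difficulty_class not in (EASY, HARD):
            raise ValueError(
                f"difficulty_class must be {EASY!r} or {HARD!r}, "
                f"got {self.difficulty_class!r}"
            )


@dataclass(frozen=True)
class LearningThresholds:
    """Exposures needed before a convention of each class is learned.

    ``easy_exposures`` defaults to 1 (one hearing suffices) and
    ``hard_exposures`` to 2; the gap between the two is the single knob that
    moves the Easy/Hard cross-over point with population size.
    """

    easy_exposures: int = 1
    hard_exposures: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.easy_exposures <= self.hard_exposures):
            raise ValueError(
                "learning thresholds must satisfy 1 <= easy_exposures <= "
                f"hard_exposures, got easy_exposures={self.easy_exposures}, "
                f"hard_exposures={self.hard_exposures}"
            )

    def required(self, difficulty_class: str) -> int:
        return self.easy_exposures if difficulty_class == EASY else self.hard_exposures


class ConventionRegistry:
    """Issues globally unique convention ids and remembers their class.

    Ids increase monotonically and are never reused within a run.  On
    invention the class is drawn Easy with probability ``class_prob``
    (default 0.5, the even split between lexical-like and structural-like
    innovations).
    """

    __slots__ = ("class_prob", "_classes")

    def __init__(self, class_prob: float = 0.5) -> None:
        if not 0.0 <= class_prob <= 1.0:
            raise ValueError(f"class_prob must be in [0, 1], got {class_prob}")
        self.class_prob = class_prob
        self._classes: list[str] = []

    @property
    def next_id(self) -> int:
        return len(self._classes)

    def __len__(self) -> int:
        return len(self._classes)

    def __contains__(self, cid: int) -> bool:
        return 0 <= cid < len(self._classes)

    def invent(self, rng: np.random.Generator) -> int:
        """Issue a fresh id with a randomly drawn difficulty class."""
        cid = len(self._classes)
        cls = EASY if rng.random() < self.class_prob else HARD
        self._classes.append(cls)
        return cid

    def class_of(self, cid: int) -> str:
        return self._classes[cid]

    def convention(self, cid: int) -> Convention:
        return Convention(cid, self._classes[cid])

    def to_dict(self) -> dict:
        return {"class_prob": self.class_prob, "classes": list(self._classes)}

    @classmethod
    def from_dict(cls, data: dict) -> "ConventionRegistry":
        reg = cls(class_prob=data.get("class_prob", 0.5))
        classes = list(data["classes"])
        for c in classes:
            if c not in (EASY, HARD):
                raise ValueError(f"unknown difficulty class {c!r} in registry data")
        reg._classes = classes
        return reg


@dataclass
class AgentState:
    """One agent's restaurant: token counts, pending exposures, history.

    Tokens are stored twice: ``token_counts`` maps convention id to table
    size ``t_c`` (the view the metrics and learning rules use), and
    ``tokens`` is the flat multiset of the same tokens, one list entry per
    stored token, so drawing a token proportionally to table size is a
    single uniform index and forgetting a token is a swap-and-pop.

    Invariants maintained by the operations in this module:

    * ``M == len(tokens) == sum(token_counts.values())`` and every
      ``t_c >= 1`` (a table whose last token is forgotten is removed);
    * ``pending_exposures`` and ``token_counts`` never share a key;
    * ``token_counts.keys() <= ever_known``.

    ``ever_known`` records every convention learned or generated since the
    agent's (re)birth; it survives forgetting but is wiped by death.
    """

    token_counts: dict[int, int] = field(default_factory=dict)
    M: int = 0
    pending_exposures: dict[int, int] = field(default_factory=dict)
    ever_known: set[int] = field(default_factory=set)
    tokens: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tokens and self.token_counts:
            # canonical flat store for states built from counts alone
            self.tokens = [
                cid for cid, t in self.token_counts.items() for _ in range(t)
            ]
        self.M = len(self.tokens)

    def check_invariants(self) -> None:
        assert self.M == len(self.tokens) == sum(self.token_counts.values())
        counts: dict[int, int] = {}
        for cid in self.tokens:
            counts[cid] = counts.get(cid, 0) + 1
        assert counts == self.token_counts
        assert all(t >= 1 for t in self.token_counts.values())
        assert not (self.token_counts.keys() & self.pending_exposures.keys())
        assert self.token_counts.keys() <= self.ever_known

    def to_dict(self) -> dict:
        return {
            "token_counts": {str(k): v for k, v in self.token_counts.items()},
            "pending_exposures": {str(k): v for k, v in self.pending_exposures.items()},
            "ever_known": sorted(self.ever_known),
            # exact list order matters for bit-identical resumption
            "tokens": list(self.tokens),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AgentState":
        counts = {int(k): int(v) for k, v in data["token_counts"].items()}
        return cls(
            token_counts=counts,
            M=sum(counts.values()),
            pending_exposures={
                int(k): int(v) for k, v in data["pending_exposures"].items()
            },
            ever_known=set(data["ever_known"]),
            tokens=[int(c) for c in data.get("tokens", [])],
        )


def production_distribution(agent: AgentState) -> dict[int, Fraction]:
    """Exact production distribution of an agent.

    Returns a mapping from convention id to probability, with the sentinel
    key :data:`NEW` for invention.  Probabilities are exact rationals over
    the common denominator ``M + 1``, so they sum to 1 exactly:
    ``P(c) = t_c / (M + 1)`` and ``P(NEW) = 1 / (M + 1)``.
    """
    denom = agent.M + 1
    dist = {cid: Fraction(t, denom) for cid, t in agent.token_counts.items()}
    dist[NEW] = Fraction(1, denom)
    return dist


def _draw_from_tokens(
    tokens: list[int],
    registry: ConventionRegistry,
    rng: np.random.Generator,
    class_rng: np.random.Generator | None = None,
) -> int:
    """Draw from a flat token store; invent on the NEW outcome.

    A uniform index into the token list is exactly a draw proportional to
    table sizes; the extra unit of probability mass is the new table.
    """
    M = len(tokens)
    r = rng.random() * (M + 1)
    if r >= M:
        return registry.invent(class_rng if class_rng is not None else rng)
    return tokens[int(r)]


def draw_production(
    agent: AgentState,
    registry: ConventionRegistry,
    rng: np.random.Generator,
    class_rng: np.random.Generator | None = None,
) -> int:
    """Sample one produced convention id (registering a fresh one on NEW).

    Does *not* seat the token: the caller decides whether a forgetting sweep
    runs before the produced token is stored (see
    :func:`iapsim.simulation.step`).
    """
    return _draw_from_tokens(agent.tokens, registry, rng, class_rng)


def seat_token(agent: AgentState, cid: int) -> AgentState:
    """Seat one token of ``cid`` in the agent's restaurant (t_c += 1).

    Seating implies the agent knows the convention, so any pending exposure
    count for it is discarded (never converted into tokens).
    """
    agent.token_counts[cid] = agent.token_counts.get(cid, 0) + 1
    agent.tokens.append(cid)
    agent.M += 1
    agent.ever_known.add(cid)
    agent.pending_exposures.pop(cid, None)
    return agent


def receive(
    listener: AgentState,
    convention: Convention,
    thresholds: LearningThresholds,
    *,
    forget_p: float = 0.0,
    forget_rng: np.random.Generator | None = None,
) -> str:
    """Process one heard token; returns the learning outcome.

    A convention already on a table is simply reinforced (the heard token is
    seated).  An unlearned convention accumulates one pooled exposure; when
    the class threshold is reached the pending entry is cleared and the
    convention is seated with exactly one token (earlier exposures are not
    converted retroactively).  ``forget_p > 0`` applies a forgetting sweep to
    the listener's pre-existing tokens just before a new token is seated —
    sweeps accompany token-adding events only, so a still-pending exposure
    triggers no forgetting.
    """
    cid = convention.id
    if cid in listener.token_counts:
        if forget_p > 0.0:
            forgetting_sweep(listener, forget_p, forget_rng)
        seat_token(listener, cid)
        return ALREADY_KNOWN
    seen = listener.pending_exposures.get(cid, 0) + 1
    if seen >= thresholds.required(convention.difficulty_class):
        listener.pending_exposures.pop(cid, None)
        if forget_p > 0.0:
            forgetting_sweep(listener, forget_p, forget_rng)
        seat_token(listener, cid)
        return LEARNED_NOW
    listener.pending_exposures[cid] = seen
    return STILL_PENDING


def forgetting_sweep(
    agent: AgentState, p: float, rng: np.random.Generator
) -> AgentState:
    """Forget each stored token independently with probability ``p``.

    Implemented exactly as the per-token Bernoulli process: the number of
    forgotten tokens is Binomial(M, p), and removing that many uniformly
    chosen entries from the flat token store allocates the losses across
    tables with the correct (multivariate hypergeometric) law.  Tables
    emptied by the sweep are removed; pending exposures are untouched (only
    the M stored tokens are forgettable) and ``ever_known`` is preserved.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"forgetting probability must be in [0, 1], got {p}")
    if p == 0.0 or agent.M == 0:
        return agent
    if p >= 1.0:
        k = agent.M
    else:
        k = int(rng.binomial(agent.M, p))
    if k == 0:
        return agent
    if k >= agent.M:
        agent.token_counts.clear()
        agent.tokens.clear()
        agent.M = 0
        return agent
    tokens = agent.tokens
    counts = agent.token_counts
    for _ in range(k):
        idx = int(rng.random() * len(tokens))
        cid = tokens[idx]
        last = tokens.pop()
        if idx < len(tokens):
            tokens[idx] = last
        t = counts[cid] - 1
        if t:
            counts[cid] = t
        else:
            del counts[cid]
    agent.M -= k
    return agent


def kill(agent: AgentState) -> AgentState:
    """Replace the agent with a blank slate at the same network location."""
    agent.token_counts.clear()
    agent.tokens.clear()
    agent.pending_exposures.clear()
    agent.ever_known.clear()
    agent.M = 0
    return agent
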