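"""Session planning and experiment-yield accounting for multipatch recordings.

With ``n`` simultaneously recorded neurons, every ordered (pre, post) pair is
probed once, so the number of tested connections is ``c = n*(n-1)``.  After a
full cluster is recorded, some pipettes can be cleaned and moved to fresh
cells while others keep their recordings ("clean-to-extend"); a round that
patches ``n_new`` new cells while maintaining ``n_old`` adds
``c_new = 2*n_new*n_old + n_new*(n_new-1)`` previously untested ordered pairs.

Cells are identified as ``"<cellIndex>.<sessionIndex>"`` (both 1-based), e.g.
``"9.2"`` is the ninth cell overall, first patched in the second session.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, InvalidPlanError

__all__ = [
    "SessionPlan",
    "PlanSummary",
    "YieldSummary",
    "pairs_total",
    "pairs_extension",
    "plan_summary",
    "success_rate",
    "simulate_yield",
]


def _check_count(value, name: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise InvalidArgumentError(f"{name} must be an integer, got {value!r}")
    if value < 0:
        raise InvalidArgumentError(f"{name} must be >= 0, got {value}")
    return int(value)


def pairs_total(n) -> int:
    """Number of ordered (pre, post) pairs among ``n`` co-recorded cells: n*(n-1)."""
    n = _check_count(n, "n")
    return n * (n - 1)


def pairs_extension(n_new, n_old) -> int:
    """Newly testable ordered pairs when ``n_new`` cells join ``n_old`` maintained ones.

    Every new<->old pair contributes both directions (2*n_new*n_old) and the
    new cells contribute all their internal ordered pairs (n_new*(n_new-1));
    old<->old pairs were already probed while the old cells were co-recorded.
    """
    n_new = _check_count(n_new, "n_new")
    n_old = _check_count(n_old, "n_old")
    return 2 * n_new * n_old + n_new * (n_new - 1)


@dataclass(frozen=True)
class SessionPlan:
    """Ordered recording sessions of (newly patched, maintained) cell counts.

    Parameters
    ----------
    sessions
        Sequence of ``(n_new, n_old)`` tuples, one per recording session.
    n_pipettes
        Number of pipettes on the rig; each session may hold at most this
        many cells simultaneously.
    keep
        Optional explicit choice of maintained cell ids per session
        (``keep[k]`` lists the ids maintained *into* session ``k``, 0-based).
        By default the first ``n_old`` cells of the previous session's active
        set are kept, which guarantees the maintained cells were pairwise
        co-recorded (required for the closed-form pair accounting).
    """

    sessions: tuple
    n_pipettes: int = 10
    keep: tuple | None = None

    def __post_init__(self):
        sessions = tuple((int(a), int(b)) for a, b in self.sessions)
        object.__setattr__(self, "sessions", sessions)
        if not sessions:
            raise InvalidPlanError("plan must contain at least one session")
        if self.n_pipettes <= 0:
            raise InvalidPlanError("n_pipettes must be positive")
        prev_size = 0
        for k, (n_new, n_old) in enumerate(sessions):
            if n_new < 0 or n_old < 0:
                raise InvalidPlanError(f"session {k}: negative counts {(n_new, n_old)}")
            if n_new + n_old > self.n_pipettes:
                raise InvalidPlanError(
                    f"session {k}: {n_new}+{n_old} cells exceed {self.n_pipettes} pipettes"
                )
            if k == 0 and n_old != 0:
                raise InvalidPlanError("first session cannot maintain cells (n_old must be 0)")
            # maintained recordings are continuous: the pipette never left the
            # cell, so at most the previous session's cluster can be kept
            if n_old > prev_size:
                raise InvalidPlanError(
                    f"session {k}: cannot maintain {n_old} cells, previous session "
                    f"recorded only {prev_size}"
                )
            prev_size = n_new + n_old

    @classmethod
    def from_json(cls, path) -> "SessionPlan":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            sessions=tuple((s["n_new"], s["n_old"]) for s in obj["sessions"]),
            n_pipettes=int(obj.get("n_pipettes", 10)),
        )

    def to_json(self, path) -> None:
        obj = {
            "n_pipettes": self.n_pipettes,
            "sessions": [{"n_new": a, "n_old": b} for a, b in self.sessions],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


@dataclass
class PlanSummary:
    """Accumulated cells and tested ordered pairs for a session plan."""

    total_cells: int
    total_tested: int
    cell_ids: list
    tested_mask: np.ndarray  # (total_cells, total_cells) bool, [pre, post]
    per_session_tested: list = field(default_factory=list)

    def __iter__(self):
        # allows ``total_cells, total_tested, mask = plan_summary(...)``
        return iter((self.total_cells, self.total_tested, self.tested_mask))


def plan_summary(plan: SessionPlan) -> PlanSummary:
    """Accumulate cells and tested directed pairs over the sessions of ``plan``.

    The first session tests ``pairs_total(n_new)`` pairs; each later session
    adds ``pairs_extension(n_new, n_old)`` pairs.  Old<->old pairs are never
    re-marked.
    """
    if not isinstance(plan, SessionPlan):
        plan = SessionPlan(tuple(plan))
    total_cells = sum(n_new for n_new, _ in plan.sessions)
    mask = np.zeros((total_cells, total_cells), dtype=bool)
    cell_ids: list[str] = []
    per_session = []
    prev_active: list[int] = []  # indices into the global cell list
    next_cell = 0
    for k, (n_new, n_old) in enumerate(plan.sessions):
        if plan.keep is not None:
            id_to_idx = {cid: i for i, cid in enumerate(cell_ids)}
            kept = [id_to_idx[c] for c in plan.keep[k]] if k < len(plan.keep) else []
            if len(kept) != n_old:
                raise InvalidPlanError(
                    f"session {k}: keep list has {len(kept)} cells, plan says n_old={n_old}"
                )
        else:
            kept = prev_active[:n_old]
        new = list(range(next_cell, next_cell + n_new))
        for i in new:
            cell_ids.append(f"{i + 1}.{k + 1}")
        next_cell += n_new
        active = kept + new
        marked = 0
        for i in active:
            for j in active:
                if i != j and (i in new or j in new) and not mask[i, j]:
                    mask[i, j] = True
                    marked += 1
        per_session.append(marked)
        prev_active = active
    total = int(mask.sum())
    expected = pairs_total(plan.sessions[0][0]) + sum(
        pairs_extension(a, b) for a, b in plan.sessions[1:]
    )
    if plan.keep is None and total != expected:
        raise InvalidPlanError(
            f"internal accounting error: mask popcount {total} != closed form {expected}"
        )
    return PlanSummary(
        total_cells=total_cells,
        total_tested=total,
        cell_ids=cell_ids,
        tested_mask=mask,
        per_session_tested=per_session,
    )


def success_rate(mean_cells: float, n_pipettes: int, as_ratio: bool = False):
    """Success rate: recorded cells relative to available pipettes.

    Returns the integer percent (round half up) by default; the raw ratio if
    ``as_ratio`` is set.
    """
    n_pipettes = _check_count(n_pipettes, "n_pipettes")
    if n_pipettes == 0:
        raise InvalidArgumentError("n_pipettes must be positive")
    if not 0 <= mean_cells <= n_pipettes:
        raise InvalidArgumentError(
            f"mean_cells={mean_cells} outside [0, n_pipettes={n_pipettes}]"
        )
    ratio = mean_cells / n_pipettes
    if as_ratio:
        return ratio
    return int(math.floor(100.0 * ratio + 0.5))


@dataclass
class YieldSummary:
    """Monte-Carlo yield of a patching strategy across simulated experiments."""

    cluster_sizes: np.ndarray  # first-session cluster size per experiment
    mean_cluster_size: float
    success_rate_pct: int
    tested_connections: np.ndarray  # total tested pairs per experiment
    mean_tested: float


def simulate_yield(
    n_pipettes: int,
    p_patch: float,
    p_loss_per_patch: float = 0.0,
    cleaning: bool = False,
    max_retries: int = 2,
    extend_rounds: int = 0,
    n_keep: int | None = None,
    n_experiments: int = 1000,
    seed: int = 0,
) -> YieldSummary:
    """Monte-Carlo model of cluster yield with and without pipette cleaning.

    Pipettes attempt patches sequentially; each attempt succeeds with
    probability ``p_patch`` and puts every already-established recording at
    risk (lost with probability ``p_loss_per_patch`` per subsequent attempt).
    With ``cleaning`` enabled a failed pipette is cleaned and retries on a
    fresh neighbouring cell up to ``max_retries`` times (clean-to-complete).
    ``extend_rounds`` additional sessions each maintain ``n_keep`` recordings
    (default ``n_pipettes // 2``) and re-patch the rest, accumulating tested
    pairs via :func:`pairs_extension` (clean-to-extend).
    """
    for name, p in (("p_patch", p_patch), ("p_loss_per_patch", p_loss_per_patch)):
        if not 0.0 <= p <= 1.0:
            raise InvalidArgumentError(f"{name} must be in [0, 1], got {p}")
    n_pipettes = _check_count(n_pipettes, "n_pipettes")
    if n_keep is None:
        n_keep = n_pipettes // 2
    rng = np.random.default_rng(seed)

    sizes = np.zeros(n_experiments, dtype=int)
    tested = np.zeros(n_experiments, dtype=int)

    for e in range(n_experiments):
        established = 0

        def attempt() -> bool:
            nonlocal established
            # every attempt endangers recordings already held
            lost = rng.random(established) < p_loss_per_patch
            established -= int(lost.sum())
            if rng.random() < p_patch:
                established += 1
                return True
            return False

        for _ in range(n_pipettes):
            ok = attempt()
            if not ok and cleaning:
                for _ in range(max_retries):
                    if attempt():
                        break
        size = established
        sizes[e] = size
        c = pairs_total(size)
        assert c % 2 == 0
        total = c
        for _ in range(extend_rounds):
            kept = min(n_keep, established)
            established = kept
            free = n_pipettes - kept
            new_successes = 0
            for _ in range(free):
                ok = attempt()
                if not ok and cleaning:
                    for _ in range(max_retries):
                        if attempt():
                            ok = True
                            break
                if ok:
                    new_successes += 1
            # survivors at screening; losses attributed to maintained cells
            # first (cell identity is not tracked in this coarse model)
            n_new = min(new_successes, established)
            n_old = established - n_new
            total += pairs_extension(n_new, n_old)
        tested[e] = total

    mean_size = float(sizes.mean()) if n_experiments else 0.0
    return YieldSummary(
        cluster_sizes=sizes,
        mean_cluster_size=mean_size,
        success_rate_pct=success_rate(min(mean_size, n_pipettes), n_pipettes),
        tested_connections=tested,
        mean_tested=float(tested.mean()) if n_experiments else 0.0,
    )
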