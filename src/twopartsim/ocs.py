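"""Optimal cross selection: contributions plus mate allocation.

Given selection candidates split into a female and a male pool, each with a
breeding value ``a_i`` and a marker-based coancestry matrix ``C``, a
crossing plan assigns every candidate an integer number of crosses
``n_i`` in {0..4} such that the ``n_c`` crosses pair the two pools.  With
genome-wide contributions ``x = n / (2 n_c)`` the plan has expected gain
``a_bar = x'a`` and group coancestry (the expected inbreeding of the next
generation) ``c_bar = x'Cx``.

The gain/diversity balance is set by a *penalty degree* theta on the
normalised gain-coancestry plane: 0 deg reproduces the maximal-gain
(truncation-equivalent) solution and 90 deg the minimal group coancestry
solution.  Two anchor solutions define the normalisation; an interior
degree theta places a soft ceiling ``1 - sin(theta)`` on the normalised
group coancestry (the quarter-circle mapping between the two anchors) and
maximises normalised gain under it, with a differential-evolution search
over a rank-based encoding (every decoded genotype is feasible by
construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEConfig",
    "OcsProblem",
    "CrossPlan",
    "PlanEvaluation",
    "InfeasiblePlanError",
    "ibs_coancestry",
    "evaluate_plan",
    "optimize",
    "truncation_plan",
]

DEGREE_GRID = tuple([1] + list(range(5, 90, 5)))  # 1, 5, 10, ..., 85


class InfeasiblePlanError(ValueError):
    """A crossing plan or problem violates its structural constraints."""


def ibs_coancestry(M: np.ndarray, n_m: int | None = None) -> np.ndarray:
    """Identity-by-state coancestry C = 1/2 (1 + X X' / n_m), X = M - 1.

    ``M`` is the individuals x markers dosage matrix coded 0/1/2.  The
    diagonal is 1/2 (1 + homozygous fraction): 1 for a fully homozygous
    line, 1/2 for a fully heterozygous one.
    """
    M = np.asarray(M)
    if M.size == 0 or M.ndim != 2:
        raise ValueError("dosage matrix must be non-empty and 2-D")
    if not np.isin(M, (0, 1, 2)).all():
        raise ValueError("dosages must be coded 0, 1 or 2")
    if n_m is None:
        n_m = M.shape[1]
    if n_m < 1:
        raise ValueError("need at least one marker")
    X = M.astype(np.float64) - 1.0
    return 0.5 * (1.0 + (X @ X.T) / n_m)


@dataclass
class DEConfig:
    """Differential-evolution settings (rand/1/bin with clipping)."""

    pop_size: int = 40
    f: float = 0.7
    cr: float = 0.9
    generations: int = 1000
    stall: int = 200
    penalty_multiplier: float = 10.0


@dataclass
class OcsProblem:
    """Candidates, breeding values, coancestry and structural constraints."""

    ids: np.ndarray
    breeding_values: np.ndarray
    coancestry: np.ndarray
    pool: np.ndarray  # "F"/"M" per candidate
    n_crosses: int
    max_per_parent: int = 4
    penalty_degrees: float = 45.0

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        a = np.asarray(self.breeding_values, dtype=np.float64)
        C = np.asarray(self.coancestry, dtype=np.float64)
        pool = np.asarray(self.pool)
        n = self.ids.size
        if a.shape != (n,) or not np.all(np.isfinite(a)):
            raise InfeasiblePlanError("breeding values must be finite, one per candidate")
        if C.shape != (n, n) or not np.allclose(C, C.T, atol=1e-8):
            raise InfeasiblePlanError("coancestry must be a symmetric n x n matrix")
        if C.min() < -1e-8 or C.max() > 1 + 1e-8:
            raise InfeasiblePlanError("coancestry entries must lie in [0, 1]")
        d = np.diag(C)
        if d.min() < 0.5 - 1e-8 or d.max() > 1 + 1e-8:
            raise InfeasiblePlanError("self-coancestry must lie in [0.5, 1]")
        if not set(np.unique(pool)) <= {"F", "M"}:
            raise InfeasiblePlanError("pool labels must be 'F' or 'M'")
        if not (0 <= self.penalty_degrees <= 90):
            raise InfeasiblePlanError("penalty degrees must lie in [0, 90]")
        self.breeding_values = a
        self.coancestry = C
        self.pool = pool
        self._females = np.flatnonzero(pool == "F")
        self._males = np.flatnonzero(pool == "M")
        need = math.ceil(self.n_crosses / self.max_per_parent)
        if self.n_crosses < 1:
            raise InfeasiblePlanError("need at least one cross")
        for name, idx in (("female", self._females), ("male", self._males)):
            if idx.size == 0:
                raise InfeasiblePlanError(f"{name} pool is empty")
            if idx.size < need:
                raise InfeasiblePlanError(
                    f"{name} pool has {idx.size} candidates but "
                    f"{need} parents are needed for {self.n_crosses} crosses"
                )

    @property
    def n_candidates(self) -> int:
        return self.ids.size


@dataclass
class CrossPlan:
    """A mating list plus per-candidate integer contributions."""

    crosses: list[tuple]
    contributions: np.ndarray  # aligned with problem candidates
    n_crosses: int

    @property
    def x(self) -> np.ndarray:
        """Genome contributions x = n / (2 n_c)."""
        return self.contributions / (2.0 * self.n_crosses)

    def validate(self, problem: OcsProblem, allow_duplicates: bool = False) -> None:
        n = np.asarray(self.contributions)
        if n.shape != (problem.n_candidates,):
            raise InfeasiblePlanError("one contribution per candidate required")
        if n.min() < 0 or n.max() > problem.max_per_parent:
            raise InfeasiblePlanError(
                f"contributions must lie in 0..{problem.max_per_parent}"
            )
        if n.sum() != 2 * self.n_crosses:
            raise InfeasiblePlanError("contributions must sum to 2 n_c")
        if len(self.crosses) != self.n_crosses:
            raise InfeasiblePlanError("cross list length must equal n_c")
        lookup = {v: i for i, v in enumerate(problem.ids.tolist())}
        for f, m in self.crosses:
            if problem.pool[lookup[f]] != "F" or problem.pool[lookup[m]] != "M":
                raise InfeasiblePlanError("every cross must pair female x male")
        if not allow_duplicates and len(set(self.crosses)) != len(self.crosses):
            raise InfeasiblePlanError("duplicate crosses are not allowed")


@dataclass(frozen=True)
class PlanEvaluation:
    gain: float
    group_coancestry: float
    norm_gain: float | None = None
    norm_coancestry: float | None = None
    achieved_degrees: float | None = None


def _gain_coancestry(n_vec: np.ndarray, a: np.ndarray, C: np.ndarray, n_c: int):
    x = n_vec / (2.0 * n_c)
    nz = np.flatnonzero(n_vec)
    xs = x[nz]
    gain = float(x @ a)
    coan = float(xs @ C[np.ix_(nz, nz)] @ xs)
    return gain, coan


def evaluate_plan(
    plan: CrossPlan,
    problem: OcsProblem,
    anchors: tuple | None = None,
) -> PlanEvaluation:
    """Exact gain and group coancestry of a plan; normalised coordinates
    and achieved degrees when the anchor solutions are supplied (as
    returned by :func:`optimize` via ``compute_anchors``)."""
    plan.validate(problem, allow_duplicates=True)
    gain, coan = _gain_coancestry(
        np.asarray(plan.contributions, dtype=np.float64),
        problem.breeding_values,
        problem.coancestry,
        plan.n_crosses,
    )
    if anchors is None:
        return PlanEvaluation(gain, coan)
    (g0, c0), (g90, c90) = anchors
    ng = (gain - g90) / (g0 - g90) if g0 != g90 else 1.0
    nc = (coan - c90) / (c0 - c90) if c0 != c90 else 0.0
    deg = math.degrees(math.asin(1.0 - min(max(nc, 0.0), 1.0)))
    return PlanEvaluation(gain, coan, ng, nc, deg)


# ---------------------------------------------------------------------------
# decoding: real-valued DE genotype -> feasible integer contributions


def _decode_pool(scores: np.ndarray, n_c: int, max_per: int) -> np.ndarray:
    """Contributions for one pool from a score vector in [0, 1].

    Candidates are taken in descending score order; the score magnitude
    sets the contribution size (near 0 -> 1 cross, near 1 -> ``max_per``
    crosses), clamped so the pool total always reaches ``n_c``.  Every
    decode is feasible by construction.
    """
    m = scores.size
    order = np.argsort(-scores, kind="stable")
    out = np.zeros(m, dtype=np.int64)
    remaining = n_c
    for j in range(m):
        if remaining <= 0:
            break
        cand = order[j]
        c = int(math.ceil(min(max(scores[cand], 0.0), 1.0) * max_per))
        c = min(max(c, 1), max_per, remaining)
        # cannot leave more slots than the rest of the pool can absorb
        c = max(c, remaining - (m - j - 1) * max_per)
        out[cand] = c
        remaining -= c
    return out


def _pair_slots(
    f_ids: list, m_ids: list, rng: np.random.Generator | None = None
) -> list[tuple]:
    """Pair female and male cross slots avoiding duplicate pairs.

    Slot lists contain one entry per cross for each parent.  Duplicates are
    repaired by swapping male slots; with per-parent caps <= 4 a valid
    assignment always exists for n_c >= 4 and is found greedily.
    """
    n = len(f_ids)
    m = list(m_ids)
    pairs: list[tuple] = []
    used: set = set()
    for j in range(n):
        if (f_ids[j], m[j]) in used:
            for k in range(j + 1, n):
                if (f_ids[j], m[k]) not in used and (
                    k >= n or (f_ids[k], m[j]) not in used if k < n else True
                ):
                    if (f_ids[k], m[j]) in used:
                        continue
                    m[j], m[k] = m[k], m[j]
                    break
        pairs.append((f_ids[j], m[j]))
        used.add((f_ids[j], m[j]))
    return pairs


def _plan_from_contributions(n_vec: np.ndarray, problem: OcsProblem) -> CrossPlan:
    """Materialise a mating list by coancestry-minimising mate allocation.

    Gain and group coancestry depend on the contributions alone, so the
    pairing is free to pursue a secondary goal: each cross greedily pairs
    the female with the most remaining crosses to the least related
    available male, which lowers progeny inbreeding without touching the
    optimised objectives.  Scheduling the largest remainder first keeps
    the no-duplicate-cross constraint satisfiable; a swap repair covers
    the rare forced collision.
    """
    C = problem.coancestry
    a = problem.breeding_values
    rem_f = {int(i): int(n_vec[i]) for i in problem._females if n_vec[i] > 0}
    rem_m = {int(i): int(n_vec[i]) for i in problem._males if n_vec[i] > 0}
    used: set = set()
    crosses_idx: list[tuple[int, int]] = []
    for _ in range(problem.n_crosses):
        f = max(rem_f, key=lambda i: (rem_f[i], a[i], -i))
        opts = [m for m in rem_m if (f, m) not in used]
        if opts:
            m = min(opts, key=lambda j: (C[f, j], -a[j], j))
        else:
            # forced collision: swap the male of an earlier cross
            m = None
            for k, (fk, mk) in enumerate(crosses_idx):
                if (f, mk) in used:
                    continue
                alt = [j for j in rem_m if (fk, j) not in used]
                if alt:
                    j = min(alt, key=lambda q: (C[fk, q], -a[q], q))
                    used.discard((fk, mk))
                    used.add((fk, j))
                    crosses_idx[k] = (fk, j)
                    rem_m[j] -= 1
                    rem_m[mk] = rem_m.get(mk, 0) + 1
                    if rem_m[j] == 0:
                        del rem_m[j]
                    m = mk
                    break
            if m is None:
                # a duplicate is structurally forced (e.g. the maximal-gain
                # plan at n_c <= cap repeats the single best pair)
                m = min(rem_m, key=lambda j: (C[f, j], -a[j], j))
        crosses_idx.append((f, m))
        used.add((f, m))
        rem_f[f] -= 1
        if rem_f[f] == 0:
            del rem_f[f]
        if m in rem_m:
            rem_m[m] -= 1
            if rem_m[m] == 0:
                del rem_m[m]
    crosses = [(problem.ids[f], problem.ids[m]) for f, m in crosses_idx]
    return CrossPlan(crosses, n_vec.copy(), problem.n_crosses)


def _unit_moves(nv: np.ndarray, problem: OcsProblem):
    """All feasible within-pool unit moves (shift one cross i -> j)."""
    cap = problem.max_per_parent
    for idx in (problem._females, problem._males):
        for i in idx:
            if nv[i] == 0:
                continue
            for j in idx:
                if i != j and nv[j] < cap:
                    yield (i, j)


def _polish(nv: np.ndarray, fitness, problem: OcsProblem) -> np.ndarray:
    """Integer refinement of a contribution vector to a depth-2 local
    optimum.

    First-improvement search over single within-pool unit moves, falling
    back to pairs of unit moves when no single move improves.  Per-pool
    totals are invariant so feasibility is preserved, and the result can
    only improve on the input.  The pair neighbourhood is what lifts the
    search off the plateaus of the rank decode on small problems.
    """
    nv = nv.copy()
    best = fitness(nv)

    def apply(mv):
        nv[mv[0]] -= 1
        nv[mv[1]] += 1

    def undo(mv):
        nv[mv[0]] += 1
        nv[mv[1]] -= 1

    for _ in range(200):
        found = None
        for mv in list(_unit_moves(nv, problem)):
            apply(mv)
            f = fitness(nv)
            undo(mv)
            if f > best + 1e-12:
                found, best = (mv,), f
                break
        if found is None:
            for mv1 in list(_unit_moves(nv, problem)):
                apply(mv1)
                for mv2 in _unit_moves(nv, problem):
                    apply(mv2)
                    f = fitness(nv)
                    undo(mv2)
                    if f > best + 1e-12:
                        found, best = (mv1, mv2), f
                        break
                undo(mv1)
                if found:
                    break
        if found is None:
            return nv
        for mv in found:
            apply(mv)
    return nv


# ---------------------------------------------------------------------------
# differential evolution


def _seed_genotypes(problem: OcsProblem, n_seeds: int) -> np.ndarray:
    """Structured starting points for the DE population.

    Scores follow the within-pool breeding-value ranking, scaled to four
    contribution levels: level 1.0 decodes to cap-filled truncation (few
    parents, 4 crosses each) and level 0.25 to an equal spread of single
    crosses over the top parents.  These span the parent-number axis of
    the frontier, which random initial scores essentially never reach on
    problems with hundreds of candidates.
    """
    n = problem.n_candidates
    base = np.zeros(n)
    a = problem.breeding_values
    for idx in (problem._females, problem._males):
        order = np.argsort(np.argsort(-a[idx], kind="stable"))
        base[idx] = 1.0 - order / idx.size
    levels = (1.0, 0.25, 0.5, 0.75)[:n_seeds]
    return np.stack([np.clip(base * lv, 1e-6, 1.0) for lv in levels])


def _de_search(problem: OcsProblem, fitness, cfg: DEConfig, rng: np.random.Generator):
    """rand/1/bin DE over [0,1]^(2n) contribution scores.

    ``fitness`` maps an integer contribution vector to a scalar to
    maximise.  Returns (contributions, fitness).
    """
    n = problem.n_candidates
    D = 2 * n
    NP = cfg.pop_size
    pop = rng.random((NP, D))
    seeds = _seed_genotypes(problem, min(4, NP))
    pop[: seeds.shape[0], :n] = seeds

    def decode(v):
        nv = np.zeros(n, dtype=np.int64)
        s = v[:n]
        nv[problem._females] = _decode_pool(
            s[problem._females], problem.n_crosses, problem.max_per_parent
        )
        nv[problem._males] = _decode_pool(
            s[problem._males], problem.n_crosses, problem.max_per_parent
        )
        return nv

    fit = np.empty(NP)
    decs = []
    for i in range(NP):
        nv = decode(pop[i])
        decs.append(nv)
        fit[i] = fitness(nv)
    best = int(np.argmax(fit))
    best_fit = fit[best]
    stall = 0
    for _ in range(cfg.generations):
        r = np.array(
            [rng.choice(NP - 1, size=3, replace=False) for _ in range(NP)]
        )
        r[r >= np.arange(NP)[:, None]] += 1  # indices distinct from i
        mutant = pop[r[:, 0]] + cfg.f * (pop[r[:, 1]] - pop[r[:, 2]])
        np.clip(mutant, 0.0, 1.0, out=mutant)
        mask = rng.random((NP, D)) < cfg.cr
        mask[np.arange(NP), rng.integers(0, D, NP)] = True
        trial = np.where(mask, mutant, pop)
        for i in range(NP):
            nv = decode(trial[i])
            fv = fitness(nv)
            if fv >= fit[i]:  # accept equal fitness to drift across plateaus
                pop[i] = trial[i]
                fit[i] = fv
                decs[i] = nv
        b = int(np.argmax(fit))
        if fit[b] > best_fit + 1e-12:
            best, best_fit = b, fit[b]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.stall:
                break
    b = int(np.argmax(fit))
    nv = decs[b]
    if n <= 40:  # the O(moves^2) refinement only pays on small problems
        nv = _polish(nv, fitness, problem)
    return nv, fitness(nv)


def _greedy_max_gain(problem: OcsProblem) -> np.ndarray:
    """Exact maximal-gain contributions: the objective is linear in n, so
    filling the per-parent cap down the ranking of breeding values is
    optimal within each pool (ties break by id)."""
    nv = np.zeros(problem.n_candidates, dtype=np.int64)
    a = problem.breeding_values
    for idx in (problem._females, problem._males):
        order = idx[np.lexsort((problem.ids[idx], -a[idx]))]
        remaining = problem.n_crosses
        for i in order:
            c = min(problem.max_per_parent, remaining)
            nv[i] = c
            remaining -= c
            if remaining == 0:
                break
    return nv


def compute_anchors(
    problem: OcsProblem, de_config: DEConfig | None = None, rng_seed: int = 0
):
    """The two endpoint solutions under identical structural constraints:
    S0 maximises gain (computed exactly by greedy cap-filling), S90
    minimises group coancestry (differential evolution, ties broken
    towards higher gain).  Returns ``((plan0, (g0, c0)), (plan90,
    (g90, c90)))``."""
    cfg = de_config or DEConfig()
    s90 = np.random.SeedSequence(rng_seed).spawn(2)[1]
    a = problem.breeding_values
    C = problem.coancestry
    n_c = problem.n_crosses
    scale = max(1.0, float(np.abs(a).max()))
    eps = 1e-9 * scale

    def fit_div(nv):
        g, c = _gain_coancestry(nv.astype(float), a, C, n_c)
        return -c * scale + eps * g

    nv0 = _greedy_max_gain(problem)
    nv90, _ = _de_search(problem, fit_div, cfg, np.random.default_rng(s90))
    p0 = _plan_from_contributions(nv0, problem)
    p90 = _plan_from_contributions(nv90, problem)
    g0, c0 = _gain_coancestry(nv0.astype(float), a, C, n_c)
    g90, c90 = _gain_coancestry(nv90.astype(float), a, C, n_c)
    return (p0, (g0, c0)), (p90, (g90, c90))


def optimize(
    problem: OcsProblem,
    de_config: DEConfig | None = None,
    rng_seed: int = 0,
    degrees: float | None = None,
    anchors=None,
) -> CrossPlan:
    """Optimal cross selection at the problem's penalty degrees.

    The two anchor solutions are found first (pass ``anchors`` from
    :func:`compute_anchors` to reuse them across degrees).  At exactly
    0 deg the maximal-gain anchor is returned and at 90 deg the
    minimal-coancestry anchor (the endpoints ARE those single-objective
    optima).  Interior degrees maximise ``norm_gain - M * max(0,
    norm_coancestry - (1 - sin(theta)))`` with the configured penalty
    multiplier ``M``.  Deterministic for a given seed.
    """
    cfg = de_config or DEConfig()
    theta = problem.penalty_degrees if degrees is None else float(degrees)
    if not 0 <= theta <= 90:
        raise InfeasiblePlanError("penalty degrees must lie in [0, 90]")
    if anchors is None:
        anchors = compute_anchors(problem, cfg, rng_seed)
    (p0, (g0, c0)), (p90, (g90, c90)) = anchors
    if theta == 0.0:
        return p0
    if theta == 90.0:
        return p90
    target = 1.0 - math.sin(math.radians(theta))
    a = problem.breeding_values
    C = problem.coancestry
    n_c = problem.n_crosses
    dg = g0 - g90
    dc = c0 - c90

    def fit(nv):
        g, c = _gain_coancestry(nv.astype(float), a, C, n_c)
        ng = (g - g90) / dg if dg != 0 else 1.0
        nc = (c - c90) / dc if dc != 0 else 0.0
        return ng - cfg.penalty_multiplier * max(0.0, nc - target)

    ss = np.random.SeedSequence(rng_seed)
    smain = ss.spawn(3)[2]
    nv, _ = _de_search(problem, fit, cfg, np.random.default_rng(smain))
    return _plan_from_contributions(nv, problem)


# ---------------------------------------------------------------------------
# truncation selection


def truncation_plan(
    candidate_ids,
    gebv,
    n_parents: int,
    n_crosses: int,
    rng: np.random.Generator,
    max_per_parent: int = 4,
) -> CrossPlan:
    """Truncation selection: top ``n_parents`` by GEBV, alternated into two
    pools by rank, equal contributions (+-1), random pairing between pools
    without duplicate pairs.  Ties in GEBV break by id (stable, so the plan
    is deterministic given the rng)."""
    ids = np.asarray(candidate_ids)
    g = np.asarray(gebv, dtype=np.float64)
    if ids.size != g.size:
        raise InfeasiblePlanError("one GEBV per candidate required")
    lo = 2 * math.ceil(n_crosses / max_per_parent)
    if n_parents % 2 or not (lo <= n_parents <= 2 * n_crosses):
        raise InfeasiblePlanError(
            f"n_parents must be even and within [{lo}, {2 * n_crosses}]"
        )
    if ids.size < n_parents:
        raise InfeasiblePlanError("not enough candidates for the requested parents")
    order = np.lexsort((ids, -g))  # by -GEBV, then id
    top = order[:n_parents]
    females = top[0::2]
    males = top[1::2]
    per_pool = n_parents // 2
    base, rem = divmod(n_crosses, per_pool)
    contrib_counts = np.full(per_pool, base, dtype=np.int64)
    contrib_counts[:rem] += 1
    if contrib_counts.max() > max_per_parent:
        raise InfeasiblePlanError("per-parent cap exceeded; use more parents")
    n_vec = np.zeros(ids.size, dtype=np.int64)
    n_vec[females] = contrib_counts
    n_vec[males] = contrib_counts

    def slots(pool_idx):
        out = []
        for i, c in zip(pool_idx, contrib_counts):
            out.extend([ids[i]] * int(c))
        return out

    f_slots = slots(females)
    m_slots = slots(males)
    for _ in range(50):
        fs = list(rng.permutation(f_slots))
        ms = list(rng.permutation(m_slots))
        pairs = list(zip(fs, ms))
        if len(set(pairs)) == len(pairs) and all(a != b for a, b in pairs):
            return CrossPlan(pairs, n_vec, n_crosses)
    # deterministic fallback: round-robin spreading then swap repair
    pairs = _pair_slots(sorted(f_slots), sorted(m_slots)[::-1])
    return CrossPlan(pairs, n_vec, n_crosses)
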