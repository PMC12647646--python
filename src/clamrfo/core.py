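"""Main CLA-MRFO loop: initialization, foraging, memory, local search,
restarts, and run provenance.

Each iteration advances the per-individual chaotic states, ranks the
population, applies cyclone foraging to elite individuals (top third) and
chain foraging to the rest, somersaults the whole population, and accepts
every move greedily (an individual keeps the better of its old and new
positions).  The iteration's best solution is offered to the memory
banks; the incumbent is refined by local search every ``F_local``
iterations; and a stagnation counter drives partial restarts.  Greedy
acceptance plus restart elitism make the best-so-far trace non-increasing
by construction.

The per-iteration evaluation cost is at most ``2 N`` objective calls
(one candidate per individual per operator), plus the bounded local-search
and restart budgets — the run-time therefore scales as ``O(T_max N D)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from . import foraging as fo
from .initialization import Bounds, InitMix, initial_positions
from .kernels import LevyParams, MapKind, control_value, seed_chaotic_states, step_chaotic_batch
from .local_search import LocalSearchState, refine, refine_binary
from .memory import MemoryBanks, euclidean, hamming_binarized
from .restart import RestartPolicy, StagnationCounter, population_entropy, restart_population
from .schedule import CategorySchedule, schedule_for

__all__ = ["OptimizerConfig", "Toggles", "RunRecord", "Objective", "optimize", "iteration_ratio"]


def iteration_ratio(t: int, t_max: int) -> float:
    """Elapsed fraction of the iteration budget; defined as 1 when ``T_max = 0``."""
    if t_max == 0:
        return 1.0
    if not 0 <= t <= t_max:
        raise ValueError("t must lie in [0, T_max]")
    return t / t_max


@dataclass(frozen=True)
class Toggles:
    """Component switches used by the ablation harness; all on by default."""

    chaos: bool = True
    levy: bool = True
    memory: bool = True
    elite_guidance: bool = True
    adaptive_params: bool = True
    restart: bool = True
    local_search: bool = True


@dataclass
class OptimizerConfig:
    """Tunable parameters of a CLA-MRFO run.

    ``category``/``deceptive`` select the adaptive parameter schedule;
    any of the schedule entries can be overridden explicitly.
    """

    n: int = 200
    t_max: int = 5000
    category: str = "multimodal"
    deceptive: bool = False
    cr0: float = 0.9
    map_kind: MapKind = MapKind.CIRCLE
    levy_beta: float = 1.5
    init_mix: InitMix | None = None
    init_levy_scale: float = 0.1
    chaotic_init: bool = False  # logistic-map trajectories instead of the hybrid mix
    hard: bool = False  # enables Lévy injection in chain foraging
    memory_ref_prob: float = 0.2  # chance a reference point is drawn from memory
    restart_fraction: float = 0.35
    restart_tol: float = 1e-12
    entropy_floor: float | None = None
    success_threshold: float = 1e-2
    convergence_threshold: float = 1e-8
    target_error: float | None = None  # early stop once best error falls below
    f_star: float = 0.0  # known optimum value; error = fitness - f_star
    binary_mode: bool = False  # Hamming memory distances for feature masks
    binary_max_drop: int = 12  # drop probes per binary local-search sweep
    binary_max_add: int = 2  # add probes per binary local-search sweep
    binary_restart_k: int = 8  # expected mask size of binary-mode restarts
    init_positions: np.ndarray | None = None  # explicit starting population
    toggles: Toggles = field(default_factory=Toggles)
    # schedule overrides (None = use the category schedule)
    p_cyclone_base: float | None = None
    s0: float | None = None
    f_local: int | None = None
    t_restart: int | None = None

    def resolved_schedule(self) -> CategorySchedule:
        base = schedule_for(self.category, self.deceptive)
        return CategorySchedule(
            base.category,
            base.deceptive,
            self.p_cyclone_base if self.p_cyclone_base is not None else base.p_cyclone_base,
            self.s0 if self.s0 is not None else base.s0,
            self.f_local if self.f_local is not None else base.f_local,
            self.t_restart if self.t_restart is not None else base.t_restart,
        )


@dataclass
class RunRecord:
    """Provenance and outcome of one optimizer run."""

    best_position: np.ndarray
    best_fitness: float
    error_trace: np.ndarray  # best-so-far error per iteration (index 0 = init)
    convergence_iteration: int | None
    success: bool
    restarts: list[dict]
    evaluations: int
    iterations_run: int
    seed: int | None
    config: dict = field(default_factory=dict)
    entropy_trace: np.ndarray | None = None
    c_log: np.ndarray | None = None  # sampled chaotic control values (diagnostics)

    @property
    def final_error(self) -> float:
        return float(self.error_trace[-1])

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, default=str)


class Objective:
    """Objective wrapper: batching, NaN handling, and an evaluation counter."""

    def __init__(self, f: Callable, batch: bool | None = None):
        self.f = f
        self.evaluations = 0
        if batch is None:
            batch = getattr(f, "supports_batch", False)
        self.batch = batch

    def __call__(self, x: np.ndarray) -> float:
        self.evaluations += 1
        try:
            v = float(self.f(x))
        except (ValueError, FloatingPointError, ArithmeticError):
            return np.inf
        return v if np.isfinite(v) else np.inf

    def many(self, X: np.ndarray) -> np.ndarray:
        if self.batch:
            self.evaluations += X.shape[0]
            v = np.asarray(self.f(X), dtype=float)
            return np.where(np.isfinite(v), v, np.inf)
        return np.array([self(row) for row in X])


def _references(
    n_rows: int,
    x_best: np.ndarray,
    banks: MemoryBanks | None,
    mem_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reference matrix: the incumbent best for most rows, a memory sample
    otherwise (at most 5 distinct samples per call, reused across rows)."""
    refs = np.broadcast_to(x_best, (n_rows, x_best.size)).copy()
    if banks is not None and len(banks) > 0 and mem_prob > 0:
        use_mem = rng.random(n_rows) < mem_prob
        k = int(use_mem.sum())
        if k:
            pool = [banks.sample_reference(rng) for _ in range(min(k, 5))]
            idx = rng.integers(0, len(pool), size=k)
            refs[use_mem] = np.array([pool[i] for i in idx])
    return refs


def optimize(
    f: Callable,
    bounds: Bounds,
    config: OptimizerConfig | None = None,
    seed: int | None = None,
    batch: bool | None = None,
) -> RunRecord:
    """Run CLA-MRFO on objective ``f`` over ``bounds``; minimization.

    ``f`` maps a length-D vector to a finite float (NaN/exceptions are
    treated as +inf). Set ``batch=True`` (or give ``f`` a
    ``supports_batch`` attribute) when ``f`` accepts an ``(n, D)`` matrix.
    Reproducible: identical ``(config, seed)`` give identical records.
    """
    cfg = OptimizerConfig() if config is None else config
    sched = cfg.resolved_schedule()
    tog = cfg.toggles
    ss = np.random.SeedSequence(seed if seed is not None else np.random.SeedSequence().entropy)
    rng_init, rng_op, rng_restart, rng_local = [np.random.default_rng(s) for s in ss.spawn(4)]
    obj = Objective(f, batch=batch)
    levy = LevyParams(beta=cfg.levy_beta)
    n, d = cfg.n, bounds.dim

    # -- initialization ----------------------------------------------------
    if cfg.init_positions is not None:
        positions = bounds.clamp(np.array(cfg.init_positions, dtype=float))
        if positions.shape != (n, d):
            raise ValueError("init_positions must have shape (n, D)")
    elif cfg.chaotic_init:
        positions = _chaotic_init(n, bounds, rng_init)
    else:
        mix = cfg.init_mix
        if not tog.levy and mix is None:
            mix = InitMix(0.65, 0.0)
        positions = initial_positions(
            n, bounds, cfg.category, rng_init, mix=mix, levy=levy,
            levy_scale=cfg.init_levy_scale,
        )
    fitness = obj.many(positions)
    if not np.any(np.isfinite(fitness)):
        raise RuntimeError("objective returned no finite value on the initial population")

    z = seed_chaotic_states(cfg.map_kind, n, rng_init)
    banks: MemoryBanks | None = None
    if tog.memory:
        banks = MemoryBanks(
            distance=hamming_binarized if cfg.binary_mode else euclidean
        )
    counter = StagnationCounter(tol=cfg.restart_tol)
    policy = RestartPolicy(
        t_restart=sched.t_restart, fraction=cfg.restart_fraction,
        tol=cfg.restart_tol, entropy_floor=cfg.entropy_floor,
    )
    ls_state = LocalSearchState()

    i_best = int(np.argmin(fitness))
    best_x = positions[i_best].copy()
    best_f = float(fitness[i_best])
    counter.update(best_f)
    if banks is not None:
        banks.try_insert(best_x, best_f, 0)
    trace = [best_f - cfg.f_star]
    restart_log: list[dict] = []
    entropy_trace: list[float] = []
    c_log: list[float] = []

    t = 0
    for t in range(1, cfg.t_max + 1):
        r_t = iteration_ratio(t, cfg.t_max)
        r_sched = r_t if tog.adaptive_params else 0.0

        # chaotic control values, one per individual
        if tog.chaos:
            z = step_chaotic_batch(cfg.map_kind, z, rng_op)
            c = control_value(z)
        else:
            c = rng_op.uniform(0.1, 0.9, size=n)
        c_log.append(float(c[0]))

        order = np.argsort(fitness, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)

        stagnating = counter.iterations_without_improvement >= max(2, sched.t_restart // 2)

        # -- chain / cyclone ----------------------------------------------
        if tog.elite_guidance:
            elite = ranks < n // 3
            p_cyc = fo.cyclone_probability(sched.p_cyclone_base, ranks, n, r_sched)
            do_cyc = elite & (rng_op.random(n) < p_cyc)
        else:
            do_cyc = np.zeros(n, dtype=bool)
        cand = np.empty_like(positions)
        chain_rows = ~do_cyc
        if np.any(chain_rows):
            cr = fo.crossover_rate(cfg.cr0, r_sched)
            cand[chain_rows] = fo.chain_forage(
                positions[chain_rows], best_x, c[chain_rows], cr, bounds, rng_op,
                levy=levy if (cfg.hard and tog.levy) else None,
            )
        if np.any(do_cyc):
            refs = _references(int(do_cyc.sum()), best_x, banks, cfg.memory_ref_prob, rng_op)
            cand[do_cyc] = fo.cyclone_forage(positions[do_cyc], refs, c[do_cyc], r_sched, bounds)
        f_cand = obj.many(cand)
        better = f_cand < fitness
        positions[better] = cand[better]
        fitness[better] = f_cand[better]

        # -- somersault ----------------------------------------------------
        s = fo.somersault_factor(sched.s0, r_sched, stagnating=stagnating)
        refs = _references(n, best_x, banks, cfg.memory_ref_prob, rng_op)
        cand = fo.somersault_forage(positions, refs, s, bounds, rng_op)
        f_cand = obj.many(cand)
        better = f_cand < fitness
        positions[better] = cand[better]
        fitness[better] = f_cand[better]

        # -- bookkeeping: best, memory -------------------------------------
        i_best = int(np.argmin(fitness))
        if fitness[i_best] < best_f:
            best_f = float(fitness[i_best])
            best_x = positions[i_best].copy()
        if banks is not None:
            banks.try_insert(positions[i_best], float(fitness[i_best]), t)
            j = int(rng_op.integers(0, n))
            banks.try_insert(positions[j], float(fitness[j]), t)

        # -- local refinement ----------------------------------------------
        if tog.local_search and t % sched.f_local == 0:
            if cfg.binary_mode:
                new_x, new_f, improved = refine_binary(
                    best_x, best_f, obj, rng_local,
                    max_drop=cfg.binary_max_drop, max_add=cfg.binary_max_add,
                )
            else:
                new_x, new_f, improved = refine(
                    best_x, best_f, obj, cfg.category, r_sched, bounds, rng_local, ls_state
                )
            if improved:
                best_x, best_f = new_x, new_f
                worst = int(np.argmax(fitness))
                positions[worst] = new_x
                fitness[worst] = new_f
                if banks is not None:
                    banks.try_insert(new_x, new_f, t)

        # -- stagnation & restart ------------------------------------------
        counter.update(best_f)
        if cfg.entropy_floor is not None or not tog.restart:
            entropy_trace.append(population_entropy(positions, bounds))
        if tog.restart:
            low_entropy = (
                cfg.entropy_floor is not None
                and entropy_trace
                and entropy_trace[-1] < cfg.entropy_floor
            )
            if counter.triggered(sched.t_restart) or low_entropy:
                positions, victims, strategy = restart_population(
                    positions, fitness, banks, policy, bounds,
                    cfg.category, r_t, rng_restart, deceptive=cfg.deceptive, levy=levy,
                )
                if cfg.binary_mode and strategy != "memory_based":
                    # Lévy/uniform draws around the box centre binarize to
                    # ~p/2-bit masks, which are meaningless for ultra-sparse
                    # selection; restart with sparse random masks instead.
                    positions[victims] = _sparse_restart(
                        victims.size, d, cfg.binary_restart_k, rng_restart
                    )
                fitness[victims] = obj.many(positions[victims])
                restart_log.append(
                    {"iteration": t, "strategy": strategy, "replaced": int(victims.size)}
                )
                counter.reset()
                # restart must never degrade the incumbent
                i_best = int(np.argmin(fitness))
                if fitness[i_best] < best_f:
                    best_f = float(fitness[i_best])
                    best_x = positions[i_best].copy()

        trace.append(best_f - cfg.f_star)
        if cfg.target_error is not None and trace[-1] <= cfg.target_error:
            break

    errors = np.array(trace)
    conv = np.nonzero(errors <= cfg.convergence_threshold)[0]
    return RunRecord(
        best_position=best_x,
        best_fitness=best_f,
        error_trace=errors,
        convergence_iteration=int(conv[0]) if conv.size else None,
        success=bool(errors[-1] <= cfg.success_threshold),
        restarts=restart_log,
        evaluations=obj.evaluations,
        iterations_run=t,
        seed=seed,
        config=_config_dict(cfg),
        entropy_trace=np.array(entropy_trace) if entropy_trace else None,
        c_log=np.array(c_log) if c_log else None,
    )


def _sparse_restart(n: int, d: int, k: int, rng: np.random.Generator) -> np.ndarray:
    pos = rng.uniform(0.0, 0.5, size=(n, d))
    for i in range(n):
        on = rng.choice(d, size=min(max(1, rng.poisson(k)), d), replace=False)
        pos[i, on] = rng.uniform(0.5, 1.0, size=on.size)
    return pos


def _chaotic_init(n: int, bounds: Bounds, rng: np.random.Generator) -> np.ndarray:
    """Logistic-map trajectories affinely mapped to the bounds (one
    trajectory per individual), used by the sensitivity harness."""
    z = seed_chaotic_states(MapKind.LOGISTIC, n, rng)
    out = np.empty((n, bounds.dim))
    for j in range(bounds.dim):
        z = step_chaotic_batch(MapKind.LOGISTIC, z, rng)
        out[:, j] = bounds.lb[j] + z * bounds.range[j]
    return out


def _config_dict(cfg: OptimizerConfig) -> dict:
    d = asdict(cfg)
    d["map_kind"] = str(cfg.map_kind.value if isinstance(cfg.map_kind, MapKind) else cfg.map_kind)
    if cfg.init_positions is not None:
        d["init_positions"] = f"explicit array {np.asarray(cfg.init_positions).shape}"
    return d
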