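"""Structure evolution (grammar-guided GP) and parameter tuning (PSO).

The base learner's topology is searched by genetic programming over the
two-rule grammar

    Node -> +m(Node, ..., Node)   for m in the function set
    Node -> x_i                   for i in [0, d)

with tournament selection, subtree crossover, and three mutation operators,
all of which preserve grammar validity and the depth/size bounds. Parameters
(weights and biases, flattened) are tuned by global-best particle swarm
optimisation with velocity clamped to +/-Vmax. Each generation, the incumbent
best structure receives one PSO pass; the returned tree gets a final, longer
pass — the two alternating processes of structure search and weight search.

Fitness throughout is the RMSE between the tree output and the (0/1 bit)
targets; lower is better and the incumbent never worsens (elitism and the
gbest guarantee).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fnt_core import (
    Activation,
    FlexibleNeuralTree,
    FNTNode,
    FunctionSet,
    tree_fitness,
)

MAX_DEPTH = 5
MAX_NODES = 200


@dataclass(frozen=True)
class EvolutionConfig:
    """GP budget. Population 50 with crossover 0.4 / mutation 0.01 are the
    published operating point; tournament 3 + elitism 1 are robust defaults
    for populations this small."""

    population_size: int = 50
    crossover_prob: float = 0.4
    mutation_prob: float = 0.01
    max_generations: int = 30
    tournament_size: int = 3
    elitism: int = 1
    patience: int = 10
    max_depth: int = MAX_DEPTH
    max_nodes: int = MAX_NODES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.population_size, self.max_generations,
               self.tournament_size) < 1:
            raise ValueError("sizes must be >= 1")


@dataclass(frozen=True)
class PSOConfig:
    """Swarm budget. c1 = c2 = 2 and vmax = 2 are the published values;
    inertia 0.7 / swarm 30 / 50 iterations bound one tuning pass. Positions
    (weights, biases) are clamped to +/-param_bound."""

    c1: float = 2.0
    c2: float = 2.0
    vmax: float = 2.0
    swarm_size: int = 30
    inertia: float = 0.7
    max_iters: int = 50
    final_iters: int = 200
    param_bound: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vmax <= 0:
            raise ValueError("vmax must be positive")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")


def reduced_budget(seed: int = 0) -> tuple[EvolutionConfig, PSOConfig]:
    """A desk-scale budget (population 20, 10 generations, shorter swarm runs)
    for tests and synthetic-data experiments."""
    evo = EvolutionConfig(population_size=20, max_generations=10, patience=5,
                          max_depth=4, seed=seed)
    pso = PSOConfig(swarm_size=15, max_iters=20, final_iters=60, seed=seed)
    return evo, pso


# -- random tree generation --------------------------------------------------

def random_tree(
    fs: FunctionSet,
    input_dim: int,
    rng: np.random.Generator,
    max_depth: int = MAX_DEPTH,
    activation: Activation = Activation.LOGISTIC,
) -> FlexibleNeuralTree:
    """Grow a grammar-valid tree: root is a neuron; below it each slot becomes
    a neuron with probability 0.5 while depth allows, else a feature leaf.
    Parameters start uniform in [-1, 1]."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    root = _grow(fs, input_dim, rng, depth=1, max_depth=max(2, max_depth),
                 force_function=True)
    return FlexibleNeuralTree(root, input_dim, fs, activation)


def _grow(fs, input_dim, rng, depth, max_depth, force_function=False) -> FNTNode:
    make_function = force_function or (depth < max_depth and rng.random() < 0.5)
    if not make_function:
        return FNTNode("leaf", feature_index=int(rng.integers(input_dim)))
    arity = int(rng.choice(fs.arities))
    children = [
        _grow(fs, input_dim, rng, depth + 1, max_depth) for _ in range(arity)
    ]
    return FNTNode(
        "function",
        weights=rng.uniform(-1.0, 1.0, size=arity),
        bias=float(rng.uniform(-1.0, 1.0)),
        children=children,
    )


def _random_subtree(fs, input_dim, rng, depth_budget) -> FNTNode:
    if depth_budget <= 1 or rng.random() < 0.5:
        return FNTNode("leaf", feature_index=int(rng.integers(input_dim)))
    arity = int(rng.choice(fs.arities))
    return FNTNode(
        "function",
        weights=rng.uniform(-1.0, 1.0, size=arity),
        bias=float(rng.uniform(-1.0, 1.0)),
        children=[_random_subtree(fs, input_dim, rng, depth_budget - 1)
                  for _ in range(arity)],
    )


def _indexed_nodes(root: FNTNode) -> list[tuple[FNTNode | None, int, FNTNode, int]]:
    """(parent, child slot, node, depth) for every node; root has parent None."""
    out: list[tuple[FNTNode | None, int, FNTNode, int]] = []

    def walk(parent, slot, node, depth):
        out.append((parent, slot, node, depth))
        for s, c in enumerate(node.children):
            walk(node, s, c, depth + 1)

    walk(None, -1, root, 1)
    return out


def _tree_ok(t: FlexibleNeuralTree, max_depth: int, max_nodes: int) -> bool:
    return t.depth() <= max_depth and t.n_nodes() <= max_nodes


# -- variation operators ------------------------------------------------------

def crossover(
    a: FlexibleNeuralTree,
    b: FlexibleNeuralTree,
    rng: np.random.Generator,
    max_depth: int = MAX_DEPTH,
    max_nodes: int = MAX_NODES,
    retries: int = 10,
) -> tuple[FlexibleNeuralTree, FlexibleNeuralTree]:
    """Swap two uniformly chosen subtrees. Offspring violating the depth or
    size bound trigger a resampled swap point; after the retry budget the
    parents are returned unchanged (as copies)."""
    if a.function_set != b.function_set or a.input_dim != b.input_dim:
        raise ValueError("parents must share function set and input dimension")
    for _ in range(retries):
        ca, cb = a.copy(), b.copy()
        na = _indexed_nodes(ca.root)
        nb = _indexed_nodes(cb.root)
        pa, sa, node_a, _ = na[rng.integers(len(na))]
        pb, sb, node_b, _ = nb[rng.integers(len(nb))]
        # a root swap on either side must graft a function node
        if (pa is None and node_b.kind != "function") or (
            pb is None and node_a.kind != "function"
        ):
            continue
        if pa is None:
            ca.root = node_b
        else:
            pa.children[sa] = node_b
        if pb is None:
            cb.root = node_a
        else:
            pb.children[sb] = node_a
        ca.fitness = cb.fitness = None
        if _tree_ok(ca, max_depth, max_nodes) and _tree_ok(cb, max_depth, max_nodes):
            return ca, cb
    return a.copy(), b.copy()


def mutate(
    t: FlexibleNeuralTree,
    rng: np.random.Generator,
    max_depth: int = MAX_DEPTH,
    max_nodes: int = MAX_NODES,
) -> FlexibleNeuralTree:
    """One of: replace a subtree with a fresh random one, retarget a leaf's
    feature, or change a neuron's arity (trimming or growing children)."""
    out = t.copy()
    out.fitness = None
    nodes = _indexed_nodes(out.root)
    op = rng.integers(3)

    if op == 0:  # subtree replacement
        parent, slot, node, depth = nodes[rng.integers(len(nodes))]
        budget = max(1, max_depth - depth + 1)
        fresh = (
            _random_subtree(t.function_set, t.input_dim, rng, budget)
            if parent is not None
            else _grow(t.function_set, t.input_dim, rng, 1, max_depth,
                       force_function=True)
        )
        if parent is None:
            out.root = fresh
        else:
            parent.children[slot] = fresh
    elif op == 1:  # leaf feature change
        leaves = [n for _, _, n, _ in nodes if n.kind == "leaf"]
        if leaves:
            leaves[rng.integers(len(leaves))].feature_index = int(
                rng.integers(t.input_dim)
            )
    else:  # arity change on a neuron
        funcs = [(n, d) for _, _, n, d in nodes if n.kind == "function"]
        node, depth = funcs[rng.integers(len(funcs))]
        choices = [a for a in t.function_set.arities if a != node.arity]
        if choices:
            new_arity = int(rng.choice(choices))
            if new_arity < node.arity:
                node.children = node.children[:new_arity]
                node.weights = node.weights[:new_arity]
            else:
                budget = max(1, max_depth - depth)
                while node.arity < new_arity:
                    node.children.append(
                        _random_subtree(t.function_set, t.input_dim, rng, budget)
                    )
                node.weights = np.concatenate(
                    [node.weights,
                     rng.uniform(-1, 1, size=new_arity - len(node.weights))]
                )

    if not _tree_ok(out, max_depth, max_nodes):
        return t.copy()
    return out


# -- particle swarm over flattened parameters --------------------------------

def pso_minimize(
    fun,
    dim: int,
    cfg: PSOConfig | None = None,
    rng: np.random.Generator | None = None,
    max_iters: int | None = None,
    init_position: np.ndarray | None = None,
    callback=None,
) -> tuple[np.ndarray, float]:
    """Global-best PSO on an arbitrary objective.

    v <- inertia*v + c1*r1*(pbest - x) + c2*r2*(gbest - x), |v| <= vmax,
    positions clamped to +/-param_bound. If ``init_position`` is given it
    seeds one particle, so the returned value never exceeds fun(init).
    ``callback(iteration, positions, velocities, gbest_value)`` is invoked
    after each update, for instrumentation.
    """
    cfg = cfg or PSOConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    iters = cfg.max_iters if max_iters is None else max_iters
    if dim < 1:
        raise ValueError("need at least one dimension to optimize")

    pos = rng.uniform(-1.0, 1.0, size=(cfg.swarm_size, dim))
    if init_position is not None:
        pos[0] = np.clip(init_position, -cfg.param_bound, cfg.param_bound)
    vel = rng.uniform(-cfg.vmax, cfg.vmax, size=(cfg.swarm_size, dim))
    fit = np.array([fun(pos[i]) for i in range(cfg.swarm_size)])
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    for it in range(iters):
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        vel = (
            cfg.inertia * vel
            + cfg.c1 * r1 * (pbest - pos)
            + cfg.c2 * r2 * (gbest - pos)
        )
        np.clip(vel, -cfg.vmax, cfg.vmax, out=vel)
        pos = np.clip(pos + vel, -cfg.param_bound, cfg.param_bound)
        for i in range(cfg.swarm_size):
            f = fun(pos[i])
            if f < pbest_fit[i]:
                pbest_fit[i] = f
                pbest[i] = pos[i]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest = pbest[g].copy()
        if callback is not None:
            callback(it, pos, vel, gbest_fit)

    return gbest, gbest_fit


def pso_optimize(
    t: FlexibleNeuralTree,
    X: np.ndarray,
    y: np.ndarray,
    cfg: PSOConfig | None = None,
    rng: np.random.Generator | None = None,
    max_iters: int | None = None,
    callback=None,
) -> FlexibleNeuralTree:
    """Tune the tree's parameters (flattened weights and biases) with
    global-best PSO; the incumbent parameters seed one particle, so the
    returned fitness never exceeds the input tree's fitness."""
    cfg = cfg or PSOConfig()
    p = t.n_params()
    if p < 1:
        raise ValueError("tree has no parameters to optimize")
    work = t.copy()

    def score(theta: np.ndarray) -> float:
        work.set_params(theta)
        return tree_fitness(work, X, y)

    gbest, gbest_fit = pso_minimize(
        score, p, cfg, rng, max_iters,
        init_position=t.get_params(), callback=callback,
    )
    out = t.copy()
    out.set_params(gbest)
    out.fitness = gbest_fit
    return out


# -- the alternating structure/parameter loop --------------------------------

def evolve_structure(
    X: np.ndarray,
    y: np.ndarray,
    fs: FunctionSet,
    cfg: EvolutionConfig | None = None,
    pso_cfg: PSOConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FlexibleNeuralTree:
    """Evolve one tree against 0/1 targets.

    Tournament selection, subtree crossover, mutation and elitism search
    structures; each generation's best individual gets a PSO parameter pass,
    and the final incumbent a longer one. Stops at max_generations or after
    ``patience`` generations without improvement. Returns the lowest-RMSE
    tree seen.
    """
    cfg = cfg or EvolutionConfig()
    pso_cfg = pso_cfg or PSOConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.size == 0 or y.size == 0:
        raise ValueError("cannot evolve on empty data")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    pop = [
        random_tree(fs, X.shape[1], rng, max_depth=cfg.max_depth)
        for _ in range(cfg.population_size)
    ]
    fits = np.array([tree_fitness(t, X, y) for t in pop])
    for t, f in zip(pop, fits):
        t.fitness = float(f)

    best = pop[int(np.argmin(fits))].copy()
    best = pso_optimize(best, X, y, pso_cfg, rng)
    stagnant = 0

    def tournament() -> FlexibleNeuralTree:
        idx = rng.integers(len(pop), size=cfg.tournament_size)
        return pop[idx[np.argmin(fits[idx])]]

    for _ in range(cfg.max_generations):
        nxt: list[FlexibleNeuralTree] = [best.copy() for _ in range(cfg.elitism)]
        while len(nxt) < cfg.population_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_prob:
                c1, c2 = crossover(p1, p2, rng, cfg.max_depth, cfg.max_nodes)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for c in (c1, c2):
                if rng.random() < cfg.mutation_prob:
                    c = mutate(c, rng, cfg.max_depth, cfg.max_nodes)
                if len(nxt) < cfg.population_size:
                    nxt.append(c)
        pop = nxt
        fits = np.array([tree_fitness(t, X, y) for t in pop])
        for t, f in zip(pop, fits):
            t.fitness = float(f)

        gen_best = pop[int(np.argmin(fits))]
        tuned = pso_optimize(gen_best, X, y, pso_cfg, rng)
        if tuned.fitness < best.fitness:
            best = tuned.copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= cfg.patience:
                break

    best = pso_optimize(best, X, y, pso_cfg, rng,
                        max_iters=pso_cfg.final_iters)
    return best


def derive_rng(master_seed: int, *tags: int | str) -> np.random.Generator:
    """Deterministic child generator from a master seed and component tags."""
    ints = [master_seed & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            ints.append(sum(ord(c) * 131**i for i, c in enumerate(t)) % (2**31))
        else:
            ints.append(int(t) % (2**31))
    return np.random.default_rng(np.random.SeedSequence(ints))
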