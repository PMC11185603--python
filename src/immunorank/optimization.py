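"""Learning per-feature weights and curves that maximize MAP.

Two-stage optimizer over the concatenated (weight, curve) parameters of the
scoring function, with the mean average precision of the known targets as the
objective:

1. **Sequential forward selection with Brent line search** — starting from an
   empty feature set, each round tentatively adds every unselected feature at
   the neutral (w=1, c=0) setting, line-searches its weight and then its
   curve with a bounded Brent minimizer while holding the rest fixed, and
   accepts the best candidate only if it improves the objective by at least
   0.1% (relative); the loop stops when no candidate qualifies.
2. **Genetic-algorithm refinement with Nelder-Mead sub-optimization** — a
   real-coded GA (tournament selection, one-point crossover, Gaussian
   mutation) explores the joint parameter vector of the selected features,
   seeded around the SFS solution; each generation the fittest individuals
   are polished with bounded Nelder-Mead, and the incumbent is replaced only
   when the polished objective beats it by the same 0.1% margin — so the
   refinement can never lower the incumbent.

Both stages support a *multi-cancer* mode (one shared parameter set
maximizing mean MAP across several phenotype projects) and a
*phenotype-specific* mode (one parameter set per project).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ._utils import log, normalize_gene
from .transforms import (
    DEFAULT_C_BOUNDS,
    DEFAULT_W_BOUNDS,
    FeatureMatrix,
    FeatureSpec,
    apply_transforms,
    curve_matrix,
    default_specs,
)

#: minimum relative MAP gain for accepting a feature or parameter update
DEFAULT_MIN_GAIN = 0.001
#: absolute acceptance floor used when the current objective is zero
ZERO_OBJECTIVE_FLOOR = 1e-6


@dataclass
class Project:
    """One phenotype's raw feature matrix with its evaluation labels."""

    matrix: FeatureMatrix
    positives: set
    negatives: set
    phenotype: str = ""

    def __post_init__(self) -> None:
        self.positives = {normalize_gene(g) for g in self.positives}
        self.negatives = {normalize_gene(g) for g in self.negatives}
        if self.positives & self.negatives:
            raise ValueError("positive and negative labels overlap")


@dataclass
class _ProjectEval:
    """Pre-transformed evaluation arrays for fast objective calls.

    Rows are the evaluated genes sorted by ascending symbol, so a stable
    argsort on descending score reproduces the scorer's deterministic
    tie-break. In labeled-only mode (any negative present) only the labeled
    genes are kept: unlabeled genes cannot change the AP.
    """

    phenotype: str
    X: np.ndarray          # evaluated genes x candidate features (rescaled+imputed)
    pos: np.ndarray        # boolean mask aligned to rows


def _ap_from_scores(scores: np.ndarray, pos: np.ndarray) -> float:
    order = np.argsort(-scores, kind="stable")
    ranks = np.nonzero(pos[order])[0] + 1
    return float(np.mean(np.arange(1, len(ranks) + 1) / ranks))


@dataclass
class OptimizationProblem:
    """Projects + candidate features + bounds + acceptance rule."""

    projects: list
    features: list | None = None
    w_bounds: tuple[float, float] = DEFAULT_W_BOUNDS
    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS
    min_gain: float = DEFAULT_MIN_GAIN
    seed: int = 0
    specs: dict | None = None
    _evals: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.min_gain <= 0:
            raise ValueError("min_gain must be positive")
        if not self.projects:
            raise ValueError("need at least one project")
        if self.features is None:
            self.features = sorted(self.projects[0].matrix.feature_names)
        self._evals = [self._build_eval(p) for p in self.projects]

    def _build_eval(self, project: Project) -> _ProjectEval:
        matrix = project.matrix
        specs = self.specs or default_specs(matrix.feature_names)
        neutral = {n: s.with_params(curve=0.0) for n, s in specs.items()}
        transformed = matrix if matrix.is_transformed else apply_transforms(matrix, neutral)
        table = transformed.curved[self.features]
        genes = np.array([normalize_gene(g) for g in table.index])
        pos_mask = np.isin(genes, sorted(project.positives))
        if not pos_mask.any():
            raise ValueError(f"project {project.phenotype!r} has no known positive in its matrix")
        neg_mask = np.isin(genes, sorted(project.negatives))
        keep = (pos_mask | neg_mask) if neg_mask.any() else np.ones(len(genes), dtype=bool)
        order = np.argsort(genes[keep], kind="stable")
        X = table.to_numpy(dtype=float)[keep][order]
        return _ProjectEval(phenotype=project.phenotype, X=X, pos=pos_mask[keep][order])

    def feature_indices(self, names) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.features)}
        return np.array([lookup[n] for n in names], dtype=int)

    def objective(self, names, weights, curves) -> float:
        """Mean AP over projects for the given selected-feature parameters."""
        idx = self.feature_indices(names)
        w = np.asarray(weights, dtype=float)
        c = np.asarray(curves, dtype=float)
        total = 0.0
        for ev in self._evals:
            if idx.size == 0:
                scores = np.zeros(ev.X.shape[0])
            else:
                scores = curve_matrix(ev.X[:, idx], c) @ w
            total += _ap_from_scores(scores, ev.pos)
        return total / len(self._evals)

    def per_project_ap(self, names, weights, curves) -> dict:
        idx = self.feature_indices(names)
        w = np.asarray(weights, dtype=float)
        c = np.asarray(curves, dtype=float)
        out = {}
        for ev in self._evals:
            scores = (curve_matrix(ev.X[:, idx], c) @ w) if idx.size else np.zeros(ev.X.shape[0])
            out[ev.phenotype] = _ap_from_scores(scores, ev.pos)
        return out

    def acceptance_threshold(self, current: float) -> float:
        return self.min_gain * current if current > 0 else ZERO_OBJECTIVE_FLOOR


@dataclass
class OptimizationResult:
    """Selected features, their (w, c) parameters, and the acceptance trace."""

    selected: list
    weights: dict
    curves: dict
    objective: float
    trace: list = field(default_factory=list)  # (step description, objective)
    per_project_ap: dict = field(default_factory=dict)
    mode: str = "multi_cancer"
    seed: int = 0
    settings: dict = field(default_factory=dict)

    def parameter_vector(self):
        w = [self.weights[f] for f in self.selected]
        c = [self.curves[f] for f in self.selected]
        return np.array(w, dtype=float), np.array(c, dtype=float)

    def to_feature_specs(self, all_features, base_specs=None) -> dict:
        """FeatureSpecs for scoring: selected features carry (w, c), the rest w=0."""
        base = base_specs or default_specs(all_features)
        out = {}
        for name in all_features:
            spec = base[name]
            if name in self.weights:
                out[name] = spec.with_params(weight=self.weights[name], curve=self.curves[name])
            else:
                out[name] = spec.with_params(weight=0.0, curve=0.0)
        return out

    def to_json(self, path) -> None:
        payload = {
            "selected": self.selected,
            "weights": self.weights,
            "curves": self.curves,
            "objective": self.objective,
            "trace": self.trace,
            "per_project_ap": self.per_project_ap,
            "mode": self.mode,
            "seed": self.seed,
            "settings": self.settings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "OptimizationResult":
        with open(path) as fh:
            payload = json.load(fh)
        payload["trace"] = [tuple(t) for t in payload.get("trace", [])]
        return cls(**payload)


_GRID_POINTS = 21


def _line_search(fun, bounds, neutral: float, xatol: float):
    """One-dimensional minimization of ``-objective`` over a bounded interval.

    The AP-based objective is piecewise constant in any single parameter, so
    a pure local minimizer can sit down on a plateau and miss a better step.
    A coarse grid scan locates the most promising region first; bounded Brent
    minimization then refines within the bracketing sub-interval. The result
    is never worse than the neutral start and never outside the bounds.
    """
    lo, hi = bounds
    grid = np.linspace(lo, hi, _GRID_POINTS)
    fgrid = [fun(g) for g in grid]
    i = int(np.argmin(fgrid))
    x, fx = float(grid[i]), float(fgrid[i])
    span = (hi - lo) / (_GRID_POINTS - 1)
    sub = (max(lo, x - span), min(hi, x + span))
    res = minimize_scalar(fun, bounds=sub, method="bounded",
                          options={"xatol": xatol, "maxiter": 30})
    if float(res.fun) < fx:
        x, fx = float(res.x), float(res.fun)
    f_neutral = fun(neutral)
    if f_neutral <= fx:
        x, fx = neutral, f_neutral
    x = float(np.clip(x, lo, hi))
    return x, -fx


def _coordinate_polish(problem, names, w_sel, c_sel, current, sweeps: int = 2):
    """Post-inclusion local-maximum search: coordinate-wise Brent line
    searches over every selected weight and curve, keeping improvements."""
    for _ in range(sweeps):
        improved = False
        for j in range(len(names)):
            def f_w(wj, j=j):
                trial = list(w_sel)
                trial[j] = wj
                return -problem.objective(names, trial, c_sel)

            w_new, obj = _line_search(f_w, problem.w_bounds,
                                      neutral=w_sel[j], xatol=1e-2)
            if obj > current:
                w_sel[j], current, improved = w_new, obj, True

            def f_c(cj, j=j):
                trial = list(c_sel)
                trial[j] = cj
                return -problem.objective(names, w_sel, trial)

            c_new, obj = _line_search(f_c, problem.c_bounds,
                                      neutral=c_sel[j], xatol=2e-2)
            if obj > current:
                c_sel[j], current, improved = c_new, obj, True
        if not improved:
            break
    return current


def sfs_brent(problem: OptimizationProblem) -> OptimizationResult:
    """Greedy forward selection with per-feature Brent line search.

    Candidates are visited in alphabetical order; each is entered at the
    neutral (w=1, c=0) setting, its weight line-searched first and its curve
    second, one dimension at a time. The best candidate of a round joins the
    selection only if the relative objective gain meets the 0.1% rule; after
    an inclusion, a coordinate-wise Brent search over all selected weights
    and curves moves the parameter vector to a local maximum.
    """
    selected: list[str] = []
    w_sel: list[float] = []
    c_sel: list[float] = []
    current = problem.objective(selected, w_sel, c_sel)
    trace = [("baseline", current)]
    candidates = sorted(problem.features)
    while True:
        threshold = problem.acceptance_threshold(current)
        scored = []  # (objective, name, w, c) after per-candidate line search
        for name in candidates:
            if name in selected:
                continue
            names = selected + [name]

            def f_w(wn):
                return -problem.objective(names, w_sel + [wn], c_sel + [0.0])

            w_new, obj_w = _line_search(f_w, problem.w_bounds, neutral=1.0, xatol=1e-2)

            def f_c(cn):
                return -problem.objective(names, w_sel + [w_new], c_sel + [cn])

            c_new, obj_c = _line_search(f_c, problem.c_bounds, neutral=0.0, xatol=2e-2)
            obj = max(obj_w, obj_c)
            if obj_c < obj_w:
                c_new = 0.0
            scored.append((obj, name, w_new, c_new))
        if not scored:
            break
        # the local-maximum search after a tentative inclusion can lift a
        # candidate off an AP plateau, so every candidate tying the round's
        # best within the gain threshold gets a polish before the 0.1% rule
        # is applied to the best polished configuration
        best_pre = max(obj for obj, *_ in scored)
        best = None  # (objective, name, w_vec, c_vec)
        for obj, name, w_new, c_new in scored:
            if obj < best_pre - max(threshold, 1e-9):
                continue
            w_try = w_sel + [w_new]
            c_try = c_sel + [c_new]
            polished = _coordinate_polish(problem, selected + [name], w_try, c_try,
                                          obj, sweeps=1)
            if best is None or polished > best[0]:
                best = (polished, name, w_try, c_try)
        obj, name, w_try, c_try = best
        if obj - current < threshold:
            break
        selected.append(name)
        w_sel[:] = w_try
        c_sel[:] = c_try
        current = _coordinate_polish(problem, selected, w_sel, c_sel, obj)
        trace.append((f"add {name}", current))
        log.debug("SFS accepted %s -> %.4f", name, current)
    return OptimizationResult(
        selected=selected,
        weights=dict(zip(selected, w_sel)),
        curves=dict(zip(selected, c_sel)),
        objective=current,
        trace=trace,
        per_project_ap=problem.per_project_ap(selected, w_sel, c_sel),
        seed=problem.seed,
        settings={"stage": "sfs_brent", "min_gain": problem.min_gain},
    )


def ga_nm_refine(problem: OptimizationProblem, init: OptimizationResult,
                 population: int = 50, generations: int = 40,
                 elite_fraction: float = 0.1, mutation_sd: float = 0.05,
                 mutation_rate: float = 0.3, polish_top: int = 2,
                 nm_maxfev: int = 80, seed: int | None = None) -> OptimizationResult:
    """Refine an SFS solution with a real-coded GA + Nelder-Mead polish.

    ``mutation_sd`` is the Gaussian mutation standard deviation as a fraction
    of each parameter's range. The incumbent starts at ``init`` and is only
    replaced by a candidate whose objective exceeds it by the 0.1% rule, so
    the returned objective is never below the initial one.
    """
    if not init.selected:
        raise ValueError("GA refinement needs a non-empty initial selection")
    rng = np.random.default_rng(problem.seed if seed is None else seed)
    names = list(init.selected)
    k = len(names)
    w0, c0 = init.parameter_vector()
    lo = np.array([problem.w_bounds[0]] * k + [problem.c_bounds[0]] * k)
    hi = np.array([problem.w_bounds[1]] * k + [problem.c_bounds[1]] * k)
    x0 = np.concatenate([w0, c0])
    if np.any(x0 < lo) or np.any(x0 > hi):
        log.warning("initial parameters outside bounds; clipping")
        x0 = np.clip(x0, lo, hi)
    span = hi - lo

    def obj_vec(x: np.ndarray) -> float:
        return problem.objective(names, x[:k], x[k:])

    incumbent_x = x0.copy()
    incumbent_f = obj_vec(x0)
    trace = list(init.trace) + [("ga_init", incumbent_f)]

    pop = np.clip(
        x0[np.newaxis, :] + rng.normal(0.0, mutation_sd, (population, 2 * k)) * span,
        lo, hi,
    )
    pop[0] = x0
    fitness = np.array([obj_vec(ind) for ind in pop])
    n_elite = max(1, int(round(elite_fraction * population)))

    def consider(x: np.ndarray, f: float, label: str) -> None:
        nonlocal incumbent_x, incumbent_f
        if f - incumbent_f >= problem.acceptance_threshold(incumbent_f):
            incumbent_x, incumbent_f = x.copy(), f
            trace.append((label, f))

    for gen in range(generations):
        order = np.argsort(-fitness, kind="stable")
        pop, fitness = pop[order], fitness[order]
        # Nelder-Mead polish of the fittest individuals
        for i in range(min(polish_top, population)):
            res = minimize(
                lambda x: -obj_vec(x), pop[i], method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={"maxfev": nm_maxfev, "xatol": 1e-3, "fatol": 1e-6},
            )
            xp = np.clip(res.x, lo, hi)
            fp = obj_vec(xp)
            if fp > fitness[i]:
                pop[i], fitness[i] = xp, fp
            consider(pop[i], fitness[i], f"nm_gen{gen}")
        # next generation: elites + tournament/crossover/mutation offspring
        children = [pop[i].copy() for i in range(n_elite)]
        while len(children) < population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, population, size=3)
                parents.append(pop[contenders[np.argmax(fitness[contenders])]])
            cut = int(rng.integers(1, 2 * k)) if k > 0 else 0
            child = np.concatenate([parents[0][:cut], parents[1][cut:]])
            mutate = rng.random(2 * k) < mutation_rate
            child[mutate] += rng.normal(0.0, mutation_sd, mutate.sum()) * span[mutate]
            children.append(np.clip(child, lo, hi))
        pop = np.array(children)
        fitness = np.array([obj_vec(ind) for ind in pop])
        for i in range(population):
            consider(pop[i], fitness[i], f"ga_gen{gen}")

    # terminal local-maximum search from the incumbent: coordinate-wise Brent
    # line searches, keeping any strict improvement (same closing step as the
    # selection stage applies after an inclusion)
    w_fin = list(incumbent_x[:k])
    c_fin = list(incumbent_x[k:])
    polished = _coordinate_polish(problem, names, w_fin, c_fin, incumbent_f)
    if polished > incumbent_f:
        incumbent_x = np.array(w_fin + c_fin)
        incumbent_f = polished
        trace.append(("final_polish", polished))

    weights = dict(zip(names, incumbent_x[:k].tolist()))
    curves = dict(zip(names, incumbent_x[k:].tolist()))
    return OptimizationResult(
        selected=names,
        weights=weights,
        curves=curves,
        objective=incumbent_f,
        trace=trace,
        per_project_ap=problem.per_project_ap(names, incumbent_x[:k], incumbent_x[k:]),
        mode=init.mode,
        seed=problem.seed if seed is None else seed,
        settings={
            **init.settings,
            "stage": "sfs_brent+ga_nm",
            "population": population,
            "generations": generations,
            "elite_fraction": elite_fraction,
            "mutation_sd": mutation_sd,
            "polish_top": polish_top,
            "nm_maxfev": nm_maxfev,
        },
    )


def optimize(projects, mode: str = "multi_cancer", features=None,
             min_gain: float = DEFAULT_MIN_GAIN, seed: int = 0,
             w_bounds=DEFAULT_W_BOUNDS, c_bounds=DEFAULT_C_BOUNDS,
             specs=None, ga_settings: dict | None = None, run_ga: bool = True):
    """Run the full SFS+Brent then GA+NM stack.

    multi_cancer: one shared parameter set maximizing mean MAP over all
    projects (requires >= 2 projects). phenotype_specific: one parameter set
    per project maximizing its own AP; returns a dict keyed by phenotype.
    Projects without any known positive are excluded with a warning.
    """
    ga_settings = ga_settings or {}
    usable = []
    for p in projects:
        if p.positives:
            usable.append(p)
        else:
            log.warning("excluding phenotype %r: no known positives", p.phenotype)
    if not usable:
        raise ValueError("no project has known positives; nothing to optimize")

    def run_one(project_list, label_seed):
        problem = OptimizationProblem(
            projects=project_list, features=features, w_bounds=w_bounds,
            c_bounds=c_bounds, min_gain=min_gain, seed=label_seed, specs=specs,
        )
        result = sfs_brent(problem)
        if run_ga and result.selected:
            result = ga_nm_refine(problem, result, **ga_settings)
        return result

    if mode == "multi_cancer":
        if len(usable) < 2:
            raise ValueError("multi_cancer mode requires at least two projects")
        result = run_one(usable, seed)
        result.mode = "multi_cancer"
        return result
    if mode == "phenotype_specific":
        out = {}
        for i, p in enumerate(sorted(usable, key=lambda q: q.phenotype)):
            res = run_one([p], seed + i)
            res.mode = "phenotype_specific"
            out[p.phenotype] = res
        return out
    raise ValueError(f"unknown optimization mode {mode!r}")
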