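"""Tree-augmented naive Bayes (TAN) classifier for coded cohorts.

The classifier follows Friedman's construction: the class (5-year outcome,
Dead=0 / Alive=1) is a parent of every attribute, and the attributes are
additionally connected by a tree chosen to maximize the total
class-conditional mutual information I(Xi; Xj | C). Structure learning is

1. compute I(Xi; Xj | C) for every attribute pair (in bits),
2. build the undirected maximum-weight spanning tree over the attributes
   (Kruskal, ties broken by attribute order for determinism),
3. orient the tree away from a chosen root (breadth-first),

after which the class prior and one conditional probability table per
attribute are estimated from counts with additive (Laplace) smoothing.
Inference is exact: with a tree per class, the joint factorizes and the
posterior is a normalized product of CPT entries.

The encoded joint distribution does not depend on the root choice (root
invariance of tree factorizations), so the root only fixes a drawing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .codebook import VariableCodebook
from .cohort import Cohort, PatientRecord

__all__ = [
    "TanStructure",
    "TanModel",
    "conditional_mutual_information",
    "maximum_weight_spanning_tree",
    "orient_tree",
    "fit_tan",
    "posterior_alive",
    "posterior_alive_many",
    "predict_status",
    "class_conditional_marginals",
    "sample_tan",
]

DEAD, ALIVE = 0, 1


# --------------------------------------------------------------------------
# structure learning primitives
# --------------------------------------------------------------------------

def _class_and_levels(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    det = cohort.determinate()
    if len(det) == 0:
        raise ValueError("cohort has no records with a determinate 5-year label")
    return det.label_array(), det.levels


def conditional_mutual_information(cohort: Cohort, a: str, b: str) -> float:
    """Empirical class-conditional mutual information I(a; b | C) in bits.

    Computed from relative frequencies over the determinate records;
    0*log(0) terms contribute 0. Non-negative up to float rounding.
    """
    if a == b:
        raise ValueError("attributes must differ")
    cb = cohort.codebook
    ia, ib = cb.index_of(a), cb.index_of(b)
    ka, kb = cb[ia].n_levels, cb[ib].n_levels
    classes, levels = _class_and_levels(cohort)
    n = classes.size
    flat = (classes * ka + levels[:, ia]) * kb + levels[:, ib]
    counts = np.bincount(flat, minlength=2 * ka * kb).reshape(2, ka, kb)
    p_cab = counts / n
    p_ca = p_cab.sum(axis=2, keepdims=True)
    p_cb = p_cab.sum(axis=1, keepdims=True)
    p_c = p_cab.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p_cab * p_c / (p_ca * p_cb)
        terms = np.where(p_cab > 0, p_cab * np.log2(np.where(p_cab > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def maximum_weight_spanning_tree(
    attributes: list[str], weights: np.ndarray
) -> list[tuple[str, str]]:
    """Maximum-weight spanning tree over ``attributes`` (Kruskal).

    ``weights`` is the symmetric pairwise weight matrix in attribute order.
    Ties are broken by lexicographic (index, index) edge order, so the result
    is deterministic. Returns |attributes|-1 undirected edges as name pairs.
    """
    m = len(attributes)
    if m == 0:
        raise ValueError("need at least one attribute")
    weights = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(weights[np.triu_indices(m, 1)])):
        raise ValueError("pairwise weights must be finite")
    edges = sorted(
        ((i, j) for i in range(m) for j in range(i + 1, m)),
        key=lambda e: (-weights[e[0], e[1]], e[0], e[1]),
    )
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[tuple[str, str]] = []
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            chosen.append((attributes[i], attributes[j]))
            if len(chosen) == m - 1:
                break
    return chosen


def orient_tree(
    edges: list[tuple[str, str]], root: str
) -> list[tuple[str, str]]:
    """Breadth-first orientation of an undirected tree away from ``root``."""
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    if edges and root not in adj:
        raise ValueError(f"root {root!r} is not a vertex of the tree")
    nodes = set(adj) if edges else {root}
    directed: list[tuple[str, str]] = []
    seen = {root}
    frontier = [root]
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for v in adj.get(u, []):
                if v not in seen:
                    seen.add(v)
                    directed.append((u, v))
                    nxt.append(v)
        frontier = nxt
    if seen != nodes:
        raise ValueError("edges do not form a single tree containing the root")
    if len(directed) != len(edges):
        raise ValueError("edges contain a cycle")
    return directed


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TanStructure:
    attributes: tuple[str, ...]
    root: str
    edges: tuple[tuple[str, str], ...]  # directed (parent -> child)

    def __post_init__(self) -> None:
        attrs = set(self.attributes)
        if self.root not in attrs:
            raise ValueError("root must be one of the attributes")
        parents: dict[str, str] = {}
        for u, v in self.edges:
            if u not in attrs or v not in attrs:
                raise ValueError(f"edge ({u}, {v}) uses unknown attribute")
            if v in parents:
                raise ValueError(f"attribute {v!r} has two parents")
            parents[v] = u
        if self.root in parents:
            raise ValueError("root must not have an attribute parent")
        if set(parents) != attrs - {self.root}:
            raise ValueError("every non-root attribute needs exactly one parent")
        # reachability from root guarantees acyclicity for this in-degree profile
        order = self.topological_order()
        if set(order) != attrs:
            raise ValueError("edges are not a tree rooted at the root")

    @property
    def parent_of(self) -> dict[str, str]:
        return {v: u for u, v in self.edges}

    def topological_order(self) -> list[str]:
        children: dict[str, list[str]] = {a: [] for a in self.attributes}
        for u, v in self.edges:
            children[u].append(v)
        order, frontier = [], [self.root]
        while frontier:
            node = frontier.pop(0)
            order.append(node)
            frontier.extend(children[node])
        return order


@dataclass(frozen=True)
class TanModel:
    """TAN structure plus smoothed CPTs.

    ``class_prior`` is indexed (Dead=0, Alive=1). The root attribute's CPT
    has shape (2, k); every other attribute's CPT has shape
    (2, parent_levels, k). Rows sum to 1; with alpha > 0 all entries are
    strictly positive.
    """

    codebook: VariableCodebook
    structure: TanStructure
    class_prior: np.ndarray
    cpts: dict[str, np.ndarray]
    alpha: float

    def __post_init__(self) -> None:
        prior = np.asarray(self.class_prior, dtype=float)
        object.__setattr__(self, "class_prior", prior)
        if prior.shape != (2,) or abs(prior.sum() - 1.0) > 1e-12:
            raise ValueError("class prior must be a 2-vector summing to 1")
        parent_of = self.structure.parent_of
        for name in self.structure.attributes:
            k = self.codebook[name].n_levels
            cpt = np.asarray(self.cpts[name], dtype=float)
            expect = (
                (2, k)
                if name == self.structure.root
                else (2, self.codebook[parent_of[name]].n_levels, k)
            )
            if cpt.shape != expect:
                raise ValueError(f"CPT shape for {name!r}: {cpt.shape} != {expect}")
            if np.abs(cpt.sum(axis=-1) - 1.0).max() > 1e-12:
                raise ValueError(f"CPT rows for {name!r} must sum to 1")
            if self.alpha > 0 and (cpt <= 0).any():
                raise ValueError(f"CPT for {name!r} has non-positive entries")

    def to_yaml(self, path) -> None:
        doc = {
            "attributes": list(self.structure.attributes),
            "root": self.structure.root,
            "edges": [list(e) for e in self.structure.edges],
            "alpha": self.alpha,
            "class_prior": self.class_prior.tolist(),
            "cpts": {k: np.asarray(v).tolist() for k, v in self.cpts.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def fit_tan(
    train: Cohort,
    attributes: list[str] | None = None,
    alpha: float = 1.0,
    *,
    root: str | None = None,
) -> TanModel:
    """Learn TAN structure and CPTs from the determinate training records.

    ``root`` defaults to the first attribute given; the encoded distribution
    is root-invariant, so the choice is cosmetic. ``alpha`` is the additive
    smoothing pseudo-count (Laplace for alpha=1).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    cb = train.codebook
    attrs = list(attributes) if attributes is not None else list(cb.names)
    if not attrs:
        raise ValueError("need at least one attribute")
    det = train.determinate()
    classes, levels = _class_and_levels(det)
    if len(np.unique(classes)) < 2:
        raise ValueError("training data must contain both classes")
    if root is None:
        root = attrs[0]

    if len(attrs) > 1:
        m = len(attrs)
        w = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                w[i, j] = w[j, i] = conditional_mutual_information(
                    det, attrs[i], attrs[j]
                )
        undirected = maximum_weight_spanning_tree(attrs, w)
        directed = tuple(orient_tree(undirected, root))
    else:
        directed = ()
    structure = TanStructure(tuple(attrs), root, directed)

    n = classes.size
    n_by_class = np.bincount(classes, minlength=2)
    class_prior = (n_by_class + alpha) / (n + 2 * alpha)

    col = {name: cb.index_of(name) for name in attrs}
    parent_of = structure.parent_of
    cpts: dict[str, np.ndarray] = {}
    for name in attrs:
        k = cb[name].n_levels
        x = levels[:, col[name]]
        if name == root or name not in parent_of:
            counts = np.zeros((2, k))
            np.add.at(counts, (classes, x), 1.0)
        else:
            kp = cb[parent_of[name]].n_levels
            xp = levels[:, col[parent_of[name]]]
            counts = np.zeros((2, kp, k))
            np.add.at(counts, (classes, xp, x), 1.0)
        denom = counts.sum(axis=-1, keepdims=True) + alpha * k
        cpts[name] = (counts + alpha) / denom
    return TanModel(cb, structure, class_prior, cpts, alpha)


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _log_joint(model: TanModel, levels: np.ndarray) -> np.ndarray:
    """log P(c, x) for each record and class; shape (n, 2)."""
    cb = model.codebook
    parent_of = model.structure.parent_of
    n = levels.shape[0]
    with np.errstate(divide="ignore"):
        out = np.tile(np.log(model.class_prior), (n, 1))
        for name in model.structure.attributes:
            x = levels[:, cb.index_of(name)]
            cpt = model.cpts[name]
            if name == model.structure.root:
                vals = cpt[:, x].T  # (n, 2)
            else:
                xp = levels[:, cb.index_of(parent_of[name])]
                vals = cpt[:, xp, x].T
            out += np.log(vals)
    return out


def posterior_alive_many(model: TanModel, levels: np.ndarray) -> np.ndarray:
    """Vectorized P(Alive | x) for an (n, #codebook) level matrix."""
    levels = np.atleast_2d(np.asarray(levels, dtype=np.int64))
    for name in model.structure.attributes:
        j = model.codebook.index_of(name)
        if (levels[:, j] < 0).any() or (
            levels[:, j] >= model.codebook[name].n_levels
        ).any():
            raise ValueError(f"level index out of range for {name!r}")
    lj = _log_joint(model, levels)
    mx = lj.max(axis=1, keepdims=True)
    num = np.exp(lj - mx)
    return num[:, ALIVE] / num.sum(axis=1)


def posterior_alive(model: TanModel, record: PatientRecord) -> float:
    """Exact posterior probability of 5-year survival for one record."""
    return float(posterior_alive_many(model, np.asarray(record.levels)[None, :])[0])


def predict_status(
    model: TanModel, record: PatientRecord, threshold: float = 0.5
) -> str:
    """"Alive" iff the survival posterior meets the threshold (ties Alive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    return "Alive" if posterior_alive(model, record) >= threshold else "Dead"


def class_conditional_marginals(model: TanModel) -> dict[str, np.ndarray]:
    """P(attribute | class) for every attribute, by a topological pass.

    Exploits the tree factorization: the root's class-conditional marginal
    is its CPT, and each child's is its CPT averaged over the parent's
    marginal. Shapes are (2, n_levels).
    """
    parent_of = model.structure.parent_of
    out: dict[str, np.ndarray] = {}
    for name in model.structure.topological_order():
        cpt = model.cpts[name]
        if name == model.structure.root:
            out[name] = cpt.copy()
        else:
            pm = out[parent_of[name]]  # (2, kp)
            out[name] = np.einsum("cp,cpk->ck", pm, cpt)
    return out


def sample_tan(
    model: TanModel, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (levels, classes) from the model's joint distribution.

    Attributes outside the model keep level 0. Used for structure-recovery
    and calibration experiments.
    """
    rng = np.random.default_rng(seed)
    cb = model.codebook
    classes = (rng.random(n) < model.class_prior[ALIVE]).astype(np.int64)
    levels = np.zeros((n, len(cb)), dtype=np.int64)
    parent_of = model.structure.parent_of
    for name in model.structure.topological_order():
        j = cb.index_of(name)
        cpt = model.cpts[name]
        if name == model.structure.root:
            rows = cpt[classes]
        else:
            xp = levels[:, cb.index_of(parent_of[name])]
            rows = cpt[classes, xp]
        u = rng.random(n)
        levels[:, j] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1).clip(
            0, cb[name].n_levels - 1
        )
    return levels, classes
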