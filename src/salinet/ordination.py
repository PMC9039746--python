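"""Constrained ordination and environmental-response models.

Implements collinearity screening by variance inflation factors,
canonical correspondence analysis (CCA) with per-variable permutation
tests, variation partitioning across predictor sets, and the
multivariate regression tree (MRT) used to cut a community gradient into
discrete environmental classes.

CCA here is the classical chi-square formulation: with ``P = Y / sum(Y)``,
row and column weights ``r`` and ``c``, the standardised residual matrix
is ``Q = (P - r c') / sqrt(r c')`` and total inertia is ``||Q||_F^2``.
Constrained inertia is the squared norm of the weighted projection of
``Q`` onto the column space of the (row-weighted, centred) constraints.
The implementation is cross-checked against vegan's ``cca`` in the test
suite.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OtuTable, SalinetError

# ---------------------------------------------------------------------------
# VIF selection
# ---------------------------------------------------------------------------


def _vif_one(x: np.ndarray, others: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(x)), others])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    ss_tot = np.sum((x - x.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vifs(variables: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1 / (1 - R^2_j) for every variable."""
    x = variables.to_numpy(dtype=float)
    if np.any(x.std(axis=0) == 0):
        const = variables.columns[x.std(axis=0) == 0].tolist()
        raise SalinetError(f"constant variables have undefined VIF: {const}")
    out = {}
    for j, name in enumerate(variables.columns):
        others = np.delete(x, j, axis=1)
        out[name] = _vif_one(x[:, j], others) if others.shape[1] else 1.0
    return pd.Series(out, name="vif")


@dataclass
class VifSelection:
    kept: list[str]
    dropped: list[str]
    final_vifs: pd.Series


def vif_select(variables: pd.DataFrame, threshold: float = 10.0) -> VifSelection:
    """Iteratively drop the highest-VIF variable until all VIF < threshold."""
    if variables.shape[1] < 2:
        raise SalinetError("VIF selection needs at least 2 variables")
    if variables.isna().any().any():
        raise SalinetError("missing values in variables")
    current = variables.copy()
    dropped: list[str] = []
    while True:
        v = vifs(current)
        if (v < threshold).all() or current.shape[1] == 1:
            return VifSelection(kept=list(current.columns), dropped=dropped, final_vifs=v)
        worst = v.idxmax()
        dropped.append(worst)
        current = current.drop(columns=[worst])


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------


def _chi_square_residuals(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    total = counts.sum()
    if total == 0:
        raise SalinetError("empty community matrix")
    p = counts / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise SalinetError("zero-sum row or column in community matrix; filter upstream")
    expected = np.outer(r, c)
    q = (p - expected) / np.sqrt(expected)
    return q, r


def _weighted_design(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    # centre columns with row weights r, then scale rows by sqrt(r)
    means = (r[:, None] * x).sum(axis=0)
    xc = x - means
    return np.sqrt(r)[:, None] * xc


def _projected_inertia(q: np.ndarray, xw: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(xw, q, rcond=None)
    fitted = xw @ beta
    return float(np.sum(fitted**2))


def cca_inertia(
    counts: np.ndarray, constraints: np.ndarray, conditioning: np.ndarray | None = None
) -> tuple[float, float]:
    """(constrained, total) inertia of a CCA of ``counts`` on ``constraints``.

    With ``conditioning`` the constrained term is partial: both the
    residual matrix and the constraints are first residualised on the
    conditioning variables in the row-weighted space.
    """
    q, r = _chi_square_residuals(counts)
    total = float(np.sum(q**2))
    xw = _weighted_design(constraints, r)
    if conditioning is not None and conditioning.shape[1] > 0:
        zw = _weighted_design(conditioning, r)
        bq, *_ = np.linalg.lstsq(zw, q, rcond=None)
        q = q - zw @ bq
        bx, *_ = np.linalg.lstsq(zw, xw, rcond=None)
        xw = xw - zw @ bx
    return _projected_inertia(q, xw), total


@dataclass
class CcaTermResult:
    """Per-variable marginal CCA summary plus the full model."""

    terms: pd.DataFrame  # index variable: vif, explained_fraction, pseudo_f, p_value
    total_inertia: float
    constrained_inertia: float  # full model, all variables jointly
    n_permutations: int

    @property
    def constrained_fraction(self) -> float:
        return self.constrained_inertia / self.total_inertia


def cca(
    table: OtuTable,
    constraints: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = 0,
) -> CcaTermResult:
    """CCA of the community table on selected environmental variables.

    Per-variable "explained variance" is the marginal fraction: the
    constrained inertia of a single-constraint CCA divided by total
    inertia.  Each variable's pseudo-F is
    ``CI_j / ((TI - CI_j) / (n - 2))``, tested by permuting sample rows
    of the constraint.
    """
    y = table.counts.to_numpy(dtype=float)
    if list(constraints.index) != table.sample_ids:
        constraints = constraints.loc[table.sample_ids]
    x = constraints.to_numpy(dtype=float)
    n = y.shape[0]
    ci_full, ti = cca_inertia(y, x)
    all_vifs = vifs(constraints) if constraints.shape[1] > 1 else pd.Series(
        {constraints.columns[0]: 1.0}
    )
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(constraints.columns):
        xj = x[:, [j]]
        if np.std(xj) == 0:
            raise SalinetError(f"constant constraint {name!r}: zero inertia")
        ci_j, _ = cca_inertia(y, xj)
        f_obs = ci_j / ((ti - ci_j) / (n - 2))
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ci_p, _ = cca_inertia(y, xj[perm])
            f_p = ci_p / ((ti - ci_p) / (n - 2))
            if f_p >= f_obs:
                count += 1
        rows.append(
            {
                "variable": name,
                "vif": float(all_vifs[name]),
                "explained_fraction": ci_j / ti,
                "pseudo_f": f_obs,
                "p_value": (1 + count) / (1 + n_perm),
            }
        )
    terms = pd.DataFrame(rows).set_index("variable")
    return CcaTermResult(
        terms=terms, total_inertia=ti, constrained_inertia=ci_full, n_permutations=n_perm
    )


# ---------------------------------------------------------------------------
# Variation partitioning
# ---------------------------------------------------------------------------


def vpa(
    table: OtuTable, partition_sets: dict[str, list[str]], metadata: pd.DataFrame
) -> dict[str, float]:
    """Variation partitioning of the community among predictor sets.

    Returns the unique fraction per set, every shared fraction (keys are
    ``"+"``-joined set names) and ``"unexplained"``; fractions sum to 1.
    Negative shared fractions are reported as computed (they are a known
    feature of partial ordination arithmetic, not an error).
    """
    names = list(partition_sets)
    if len(names) < 2:
        raise SalinetError("VPA needs at least 2 predictor sets")
    flat = [v for vs in partition_sets.values() for v in vs]
    if len(flat) != len(set(flat)):
        raise SalinetError("partition sets must be disjoint")
    y = table.counts.to_numpy(dtype=float)
    meta = metadata.loc[table.sample_ids]

    def design(subset: tuple[str, ...]) -> np.ndarray:
        cols = [v for s in subset for v in partition_sets[s]]
        return meta[cols].to_numpy(dtype=float)

    # explained fraction for every nonempty union of sets
    unions = {}
    ti = None
    for k in range(1, len(names) + 1):
        for subset in itertools.combinations(names, k):
            ci, ti = cca_inertia(y, design(subset))
            unions[frozenset(subset)] = ci / ti

    # atoms: one per nonempty subset T of sets (variance shared by exactly T)
    atoms = [frozenset(c) for k in range(1, len(names) + 1)
             for c in itertools.combinations(names, k)]
    union_keys = list(unions)
    a_mat = np.array([[1.0 if atom & u else 0.0 for atom in atoms] for u in union_keys])
    b_vec = np.array([unions[u] for u in union_keys])
    sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    out: dict[str, float] = {}
    for atom, val in zip(atoms, sol):
        key = "+".join(sorted(atom))
        out[key] = float(val)
    out["unexplained"] = float(1.0 - unions[frozenset(names)])
    return out


# ---------------------------------------------------------------------------
# Multivariate regression tree
# ---------------------------------------------------------------------------


@dataclass
class MrtNode:
    sample_idx: np.ndarray
    prediction: np.ndarray
    split_var: str | None = None
    split_threshold: float | None = None
    left: "MrtNode | None" = None
    right: "MrtNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None


@dataclass
class MrtTree:
    root: MrtNode
    n_leaves: int
    splits: list[tuple[str, float]]
    leaf_assignments: pd.Series
    cv_table: pd.DataFrame  # size, mean_cv_error, se
    chosen_size: int
    relative_error: float


def _node_ss(ysum: np.ndarray, ysq: float, n: int) -> float:
    if n == 0:
        return 0.0
    return ysq - float(ysum @ ysum) / n


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (var, threshold, gain, left_mask) over all midpoint splits."""
    n, _ = y.shape
    ysq_rows = np.sum(y**2, axis=1)
    total_ss = _node_ss(y.sum(axis=0), ysq_rows.sum(), n)
    best = None
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        xs = x[order, j]
        ys = y[order]
        csum = np.cumsum(ys, axis=0)
        csq = np.cumsum(ysq_rows[order])
        tot_sum, tot_sq = csum[-1], csq[-1]
        for i in range(min_leaf - 1, n - min_leaf):
            if xs[i] == xs[i + 1]:
                continue
            nl = i + 1
            ss_left = _node_ss(csum[i], csq[i], nl)
            ss_right = _node_ss(tot_sum - csum[i], tot_sq - csq[i], n - nl)
            gain = total_ss - ss_left - ss_right
            if best is None or gain > best[2] + 1e-12:
                thr = 0.5 * (xs[i] + xs[i + 1])
                best = (j, thr, gain, x[:, j] <= thr)
    return best


def _grow_with_nodes(x, y, var_names, max_leaves, min_leaf):
    """Grow a tree best-first on sum-of-squares gain.

    Returns the root and the ordered list of (split node, gain).  Because
    growth is best-first, truncating after ``s - 1`` splits yields the
    nested tree with ``s`` leaves, which is what the cross-validation
    over tree sizes relies on.
    """
    root = MrtNode(sample_idx=np.arange(len(y)), prediction=y.mean(axis=0))
    heap: list = []
    counter = itertools.count()

    def push(node: MrtNode):
        idx = node.sample_idx
        if len(idx) < 2 * min_leaf:
            return
        found = _best_split(x[idx], y[idx], min_leaf)
        if found is None or found[2] <= 1e-12:
            return
        j, thr, gain, left_mask = found
        heapq.heappush(heap, (-gain, next(counter), node, j, thr, left_mask))

    push(root)
    order: list[tuple[MrtNode, float]] = []
    while heap and len(order) < max_leaves - 1:
        neg_gain, _, node, j, thr, left_mask = heapq.heappop(heap)
        idx = node.sample_idx
        node.split_var = var_names[j]
        node.split_threshold = thr
        node.left = MrtNode(sample_idx=idx[left_mask], prediction=y[idx[left_mask]].mean(axis=0))
        node.right = MrtNode(
            sample_idx=idx[~left_mask], prediction=y[idx[~left_mask]].mean(axis=0)
        )
        order.append((node, -neg_gain))
        push(node.left)
        push(node.right)
    return root, order


def _truncate_predict(root: MrtNode, applied_order: list, size: int, x_new: np.ndarray,
                      var_index: dict[str, int]) -> np.ndarray:
    """Predict with the tree truncated to ``size`` leaves."""
    allowed = set()
    for node, _thr in applied_order[: size - 1]:
        allowed.add(id(node))
    preds = np.empty((len(x_new), len(root.prediction)))
    for i, row in enumerate(x_new):
        node = root
        while not node.is_leaf and id(node) in allowed:
            j = var_index[node.split_var]
            node = node.left if row[j] <= node.split_threshold else node.right
        preds[i] = node.prediction
    return preds


def mrt(
    table: OtuTable,
    variables: pd.DataFrame,
    n_cv: int = 1000,
    seed: int | None = 0,
    max_leaves: int = 8,
    min_leaf: int = 2,
    n_folds: int = 10,
    size_rule: str = "min",
) -> MrtTree:
    """Multivariate regression tree of the community on environment.

    The response is the row-normalised community matrix; splits are
    midpoints of sorted unique predictor values chosen greedily to
    minimise total within-node sum of squares (best-first growth, so the
    size-``s`` tree is nested in the size-``s+1`` tree).  Tree size is
    selected by ``n_cv`` repetitions of ``n_folds``-fold cross-validation:
    ``size_rule="min"`` takes the size minimising mean CV relative error,
    ``"1se"`` the smallest size within one standard error of it.
    """
    if table.n_samples < 8:
        raise SalinetError("MRT needs at least 8 samples")
    if size_rule not in ("min", "1se"):
        raise SalinetError(f"unknown size rule {size_rule!r}")
    y = table.relative_abundance().to_numpy(dtype=float)
    variables = variables.loc[table.sample_ids]
    x = variables.to_numpy(dtype=float)
    var_names = list(variables.columns)
    var_index = {v: j for j, v in enumerate(var_names)}
    n = len(y)
    tss = _node_ss(y.sum(axis=0), float(np.sum(y**2)), n)

    root, node_order = _grow_with_nodes(x, y, var_names, max_leaves, min_leaf)

    max_size = len(node_order) + 1
    sizes = list(range(1, max_size + 1))
    rng = np.random.default_rng(seed)
    rep_errors = np.zeros((n_cv, len(sizes)))
    folds = min(n_folds, n)
    for rep in range(n_cv):
        perm = rng.permutation(n)
        fold_ids = np.array_split(perm, folds)
        err = np.zeros(len(sizes))
        for test_idx in fold_ids:
            train_idx = np.setdiff1d(perm, test_idx)
            r_t, order_t = _grow_with_nodes(
                x[train_idx], y[train_idx], var_names, max_leaves, min_leaf
            )
            for si, s in enumerate(sizes):
                pred = _truncate_predict(r_t, order_t, s, x[test_idx], var_index)
                err[si] += float(np.sum((y[test_idx] - pred) ** 2))
        rep_errors[rep] = err / tss
    mean_err = rep_errors.mean(axis=0)
    se_err = rep_errors.std(axis=0, ddof=1) / np.sqrt(n_cv) if n_cv > 1 else np.zeros_like(mean_err)
    best_i = int(np.argmin(mean_err))
    if size_rule == "1se":
        limit = mean_err[best_i] + se_err[best_i]
        best_i = int(np.flatnonzero(mean_err <= limit)[0])
    chosen = sizes[best_i]

    pred_full = _truncate_predict(root, node_order, chosen, x, var_index)
    rel_err = float(np.sum((y - pred_full) ** 2) / tss)
    leaf_of = _leaf_labels(root, node_order, chosen, x, var_index)
    cv_table = pd.DataFrame({"size": sizes, "mean_cv_error": mean_err, "se": se_err})
    splits = [(node.split_var, node.split_threshold) for node, _ in node_order[: chosen - 1]]
    return MrtTree(
        root=root,
        n_leaves=chosen,
        splits=splits,
        leaf_assignments=pd.Series(leaf_of, index=table.sample_ids, name="leaf"),
        cv_table=cv_table,
        chosen_size=chosen,
        relative_error=rel_err,
    )


def _leaf_labels(root, node_order, size, x, var_index):
    allowed = {id(node) for node, _ in node_order[: size - 1]}
    labels = []
    for row in x:
        node = root
        path = "L"
        while not node.is_leaf and id(node) in allowed:
            if row[var_index[node.split_var]] <= node.split_threshold:
                node = node.left
                path += "l"
            else:
                node = node.right
                path += "r"
        labels.append(path)
    return labels
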