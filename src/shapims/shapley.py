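"""Exact observational Shapley attributions for tree ensembles.

A feature's Shapley value for one pixel is its contribution to the
classifier's raw log-odds output, averaged over all feature orderings,
where "introducing" a feature means conditioning the model's expected
output on it. For trees, the conditional expectation is estimated
tree-path-dependently (the *observational* formulation): at a split on a
conditioned feature the observation's own branch is followed, at a split
on an unconditioned feature the two children are averaged with weights
proportional to their covers (training rows routed through them).

Three routes to the same quantity are provided:

- :func:`tree_shapley_orderings` — literal average over all D! orderings
  of the tree's used features (oracle, D <= 8);
- :func:`tree_shapley_subsets` — the equivalent subset-weighted sum over
  all 2^D coalitions (oracle, D <= 15);
- :func:`tree_shapley_path` — the polynomial-time TreeSHAP recursion that
  tracks, along each root-to-leaf path, the weighted number of feature
  subsets of each cardinality (the production route).

Attributions are computed on the raw log-odds margin, never the
probability, so they are additive across trees: the ensemble attribution
is the shrinkage-weighted sum of per-tree attributions, and together with
the base value (the unconditioned expected margin) they reconstruct each
pixel's raw output exactly (local accuracy).

Features that appear in no split of a tree receive exactly zero from that
tree; their marginal contribution is identically zero, so each tree's game
collapses to its D used features.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .boosting import RegressionTree, TreeEnsemble
from .ims_data import IMSDataset

__all__ = [
    "Coalition",
    "ShapleyMatrix",
    "GlobalScores",
    "FeatureRanking",
    "tree_expectation",
    "tree_shapley_subsets",
    "tree_shapley_orderings",
    "tree_shapley_path",
    "ensemble_shapley",
    "check_local_accuracy",
    "global_shap_scores",
    "rank_features",
]

MAX_SUBSET_FEATURES = 15
MAX_ORDERING_FEATURES = 8

Coalition = frozenset  # coalition of feature indices


def tree_expectation(tree: RegressionTree, x: np.ndarray,
                     S: frozenset | set) -> float:
    """Tree-path-dependent estimate of E[tree(x) | features in S].

    Splits on conditioned features follow x's branch (``<=`` goes left);
    splits on unconditioned features return the cover-weighted average of
    both children.
    """
    x = np.asarray(x, dtype=float)

    def rec(node: int) -> float:
        if tree.is_leaf(node):
            return float(tree.value[node])
        j = tree.feature[node]
        left, right = tree.children_left[node], tree.children_right[node]
        if j in S:
            branch = left if x[j] <= tree.threshold[node] else right
            return rec(branch)
        wl, wr = tree.cover[left], tree.cover[right]
        tot = wl + wr
        if tot <= 0:
            raise ValueError(f"zero cover at internal node {node}")
        return (wl * rec(left) + wr * rec(right)) / tot

    return rec(0)


def _expectations_by_mask(tree: RegressionTree, x: np.ndarray,
                          used: np.ndarray) -> np.ndarray:
    """E[tree(x)|S] for every S subset of `used`, indexed by bitmask."""
    D = len(used)
    pos = {int(j): i for i, j in enumerate(used)}
    out = np.empty(1 << D)
    for mask in range(1 << D):
        S = {int(j) for j in used if (mask >> pos[int(j)]) & 1}
        out[mask] = tree_expectation(tree, x, S)
    return out


def tree_shapley_subsets(tree: RegressionTree, x: np.ndarray) -> dict[int, float]:
    """Exact Shapley values via subset enumeration (oracle).

    For each used feature j:
    ``phi_j = sum_{S subset of U\\{j}} |S|! (D-|S|-1)! / D! * (E(S+j) - E(S))``.
    Features unused by the tree are omitted (their value is exactly 0).
    """
    used = tree.used_features()
    D = len(used)
    if D == 0:
        return {}
    if D > MAX_SUBSET_FEATURES:
        raise ValueError(
            f"tree uses {D} features; subset oracle capped at "
            f"{MAX_SUBSET_FEATURES}"
        )
    E = _expectations_by_mask(tree, x, used)
    fact = [math.factorial(k) for k in range(D + 1)]
    phi = {int(j): 0.0 for j in used}
    for i, j in enumerate(used):
        jbit = 1 << i
        for mask in range(1 << D):
            if mask & jbit:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[D - s - 1] / fact[D]
            phi[int(j)] += w * (E[mask | jbit] - E[mask])
    return phi


def tree_shapley_orderings(tree: RegressionTree, x: np.ndarray) -> dict[int, float]:
    """Exact Shapley values by averaging over all D! orderings (oracle)."""
    used = tree.used_features()
    D = len(used)
    if D == 0:
        return {}
    if D > MAX_ORDERING_FEATURES:
        raise ValueError(
            f"tree uses {D} features; ordering oracle capped at "
            f"{MAX_ORDERING_FEATURES}"
        )
    pos = {int(j): i for i, j in enumerate(used)}
    E = _expectations_by_mask(tree, x, used)
    phi = {int(j): 0.0 for j in used}
    n_orderings = math.factorial(D)
    for perm in itertools.permutations(used):
        mask = 0
        for j in perm:
            new_mask = mask | (1 << pos[int(j)])
            phi[int(j)] += (E[new_mask] - E[mask]) / n_orderings
            mask = new_mask
    return phi


# ---------------------------------------------------------------------------
# Polynomial-time path-dependent recursion (TreeSHAP)
#
# Along each root-to-leaf path the recursion maintains, per path element,
# the proportion of feature subsets of each cardinality that flow down the
# path, split into "one" weights (feature conditioned: follow x) and
# "zero" weights (feature unconditioned: cover fraction). EXTEND pushes a
# new path element; UNWIND removes one, undoing its effect on the subset
# weights.
# ---------------------------------------------------------------------------

def _extend(d, z, o, w, pz, po, pi):
    l = len(w)
    d.append(pi)
    z.append(pz)
    o.append(po)
    w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1) / (l + 1)
        w[i] = pz * w[i] * (l - i) / (l + 1)


def _unwind(d, z, o, w, i):
    l = len(w)
    n = w[l - 1]
    zi, oi = z[i], o[i]
    W = w[: l - 1]
    for j in range(l - 2, -1, -1):
        if oi != 0.0:
            t = W[j]
            W[j] = n * l / ((j + 1) * oi)
            n = t - W[j] * zi * (l - 1 - j) / l
        else:
            W[j] = W[j] * l / (zi * (l - 1 - j))
    return d[:i] + d[i + 1:], z[:i] + z[i + 1:], o[:i] + o[i + 1:], W


def _unwound_sum(z, o, w, i):
    l = len(w)
    n = w[l - 1]
    zi, oi = z[i], o[i]
    total = 0.0
    for j in range(l - 2, -1, -1):
        if oi != 0.0:
            t = n * l / ((j + 1) * oi)
            total += t
            n = w[j] - t * zi * (l - 1 - j) / l
        else:
            total += w[j] * l / (zi * (l - 1 - j))
    return total


def tree_shapley_path(tree: RegressionTree, x: np.ndarray) -> dict[int, float]:
    """Exact Shapley values in polynomial time (path-dependent TreeSHAP)."""
    x = np.asarray(x, dtype=float)
    phi: dict[int, float] = {int(j): 0.0 for j in tree.used_features()}

    def recurse(node, d, z, o, w, pz, po, pi):
        d, z, o, w = list(d), list(z), list(o), list(w)
        _extend(d, z, o, w, pz, po, pi)
        if tree.is_leaf(node):
            leaf_value = tree.value[node]
            for i in range(1, len(w)):
                s = _unwound_sum(z, o, w, i)
                phi[d[i]] += s * (o[i] - z[i]) * leaf_value
            return
        j = int(tree.feature[node])
        left, right = tree.children_left[node], tree.children_right[node]
        if x[j] <= tree.threshold[node]:
            hot, cold = left, right
        else:
            hot, cold = right, left
        cov = tree.cover[node]
        if cov <= 0:
            raise ValueError(f"zero cover at internal node {node}")
        iz, io = 1.0, 1.0
        try:
            k = d.index(j, 1)
        except ValueError:
            k = -1
        if k >= 0:
            iz, io = z[k], o[k]
            d, z, o, w = _unwind(d, z, o, w, k)
        recurse(hot, d, z, o, w, iz * tree.cover[hot] / cov, io, j)
        recurse(cold, d, z, o, w, iz * tree.cover[cold] / cov, 0.0, j)

    recurse(0, [], [], [], [], 1.0, 1.0, -1)
    return phi


# ---------------------------------------------------------------------------
# Ensemble-level attribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapleyMatrix:
    """Per-pixel, per-feature attributions in log-odds units.

    ``base_value`` is the unconditioned expected margin; for every covered
    pixel, ``base_value + values[i].sum()`` equals the ensemble's raw
    output at that pixel (local accuracy).
    """

    base_value: float
    values: np.ndarray  # (m', n)
    pixel_indices: np.ndarray  # (m',) rows of the source dataset

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        idx = np.asarray(self.pixel_indices, dtype=int)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "pixel_indices", idx)
        if v.ndim != 2 or len(idx) != v.shape[0]:
            raise ValueError("values and pixel_indices are misaligned")
        if not np.isfinite(v).all() or not np.isfinite(self.base_value):
            raise ValueError("non-finite attribution")

    def to_csv(self, path: str | Path) -> Path:
        """Delimited matrix with a one-line header carrying the base value."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# base_value={self.base_value:.17g}\n")
            pd.DataFrame(self.values, index=self.pixel_indices).to_csv(
                fh, header=False, float_format="%.17g"
            )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ShapleyMatrix":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# base_value="):
                raise ValueError("missing base_value header line")
            base = float(header.split("=", 1)[1])
            df = pd.read_csv(fh, header=None, index_col=0)
        return cls(base, df.to_numpy(dtype=float), df.index.to_numpy())


def _tree_mean(tree: RegressionTree) -> float:
    """Cover-weighted mean leaf value — E[tree] with nothing conditioned."""
    leaves = tree.children_left == -1
    return float(np.average(tree.value[leaves], weights=tree.cover[leaves]))


def ensemble_shapley(ens: TreeEnsemble, ds: IMSDataset,
                     pixels: np.ndarray | None = None) -> ShapleyMatrix:
    """Shapley attribution of every pixel's raw margin across all features.

    By linearity of the Shapley operator over the additive ensemble, the
    attribution is the shrinkage-weighted sum of per-tree attributions.
    Covers all pixels by default; explanation needs no labels, so unlabeled
    pixels are first-class.
    """
    if ens.n_features != ds.n_features:
        raise ValueError(
            f"ensemble expects {ens.n_features} features, dataset has "
            f"{ds.n_features}"
        )
    if pixels is None:
        pixels = np.arange(ds.n_pixels)
    else:
        pixels = np.asarray(pixels, dtype=int)
    X = ds.intensities[pixels]
    values = np.zeros((len(pixels), ds.n_features))
    base = ens.base_prediction
    nu = ens.learning_rate
    for tree in ens.trees:
        base += nu * _tree_mean(tree)
        for row, x in enumerate(X):
            for j, v in tree_shapley_path(tree, x).items():
                values[row, j] += nu * v
    return ShapleyMatrix(base, values, pixels)


def check_local_accuracy(sm: ShapleyMatrix, ens: TreeEnsemble,
                         ds: IMSDataset, tol: float = 1e-6) -> dict:
    """Verify that base value + attributions reconstruct the raw margin."""
    raw = ens.predict_raw(ds.intensities[sm.pixel_indices])
    recon = sm.base_value + sm.values.sum(axis=1)
    dev = np.abs(recon - raw)
    offending = sm.pixel_indices[dev > tol]
    return {
        "max_deviation": float(dev.max()) if len(dev) else 0.0,
        "tolerance": tol,
        "n_pixels": len(dev),
        "offending_pixels": offending.tolist(),
        "passed": len(offending) == 0,
    }


@dataclass(frozen=True)
class GlobalScores:
    """Mean absolute Shapley value per feature over the covered pixels."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.ndim != 1 or (s < 0).any():
            raise ValueError("scores must be a non-negative vector")


def global_shap_scores(sm: ShapleyMatrix) -> GlobalScores:
    """``Phi_j = mean_i |phi_ij|`` over the matrix's covered pixels."""
    if sm.values.shape[0] == 0:
        raise ValueError("empty Shapley matrix")
    return GlobalScores(np.abs(sm.values).mean(axis=0))


@dataclass(frozen=True)
class FeatureRanking:
    """Features in descending global SHAP score; ties by ascending m/z."""

    table: pd.DataFrame  # columns: rank, feature_index, mz, global_shap_score

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False, float_format="%.12g")
        return path


def rank_features(gs: GlobalScores, mz_values: np.ndarray) -> FeatureRanking:
    mz = np.asarray(mz_values, dtype=float)
    if mz.shape != gs.scores.shape:
        raise ValueError("scores and m/z lists differ in length")
    df = pd.DataFrame({
        "feature_index": np.arange(len(mz)),
        "mz": mz,
        "global_shap_score": gs.scores,
    })
    df = df.sort_values(
        ["global_shap_score", "mz"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return FeatureRanking(df)
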