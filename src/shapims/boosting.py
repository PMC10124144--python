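"""Gradient-boosted regression trees on logistic loss for pixel classification.

The classifier is an additive logistic model: its raw output is the
log-odds

    f(x) = tau0 + nu * sum_k tau_k(x)

where ``tau0`` is the training-set base-rate log-odds, ``nu`` is the
shrinkage (learning rate), and each ``tau_k`` is a regression tree fitted
by second-order (Newton) boosting on the logistic negative log-likelihood:
with current probability ``p_i`` and 0/1 target ``t_i``, the gradient is
``g_i = p_i - t_i`` and the hessian ``h_i = p_i (1 - p_i)``; trees are
grown by exact greedy split search maximising the usual gain with an L2
leaf penalty ``lambda``, and leaf values are ``-sum g / (sum h + lambda)``.
Rows are subsampled per boosting round and columns per node, so training is
stochastic but fully reproducible from the seed.

Every node additionally records its *cover* — the number of full-training-
set rows routed through it after the tree is grown — which later supplies
the weights for observational (tree-path-dependent) Shapley expectations.

Routing convention, fixed across training, prediction and attribution:
``x[feature] <= threshold`` goes to the left child; equality goes left.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ims_data import AnnotationMask, IMSDataset, Label, SpatialImage, values_image

__all__ = [
    "LabeledSubset",
    "TrainingConfig",
    "RegressionTree",
    "TreeEnsemble",
    "ClassificationMetrics",
    "make_labels",
    "downsample_negatives",
    "split_holdout",
    "train_ensemble",
    "import_ensemble",
    "from_xgboost",
    "predict_raw",
    "predict_probability",
    "predict_class",
    "evaluate",
    "prediction_image",
]

_LEAF = -1


@dataclass(frozen=True)
class LabeledSubset:
    """Pixel indices into a dataset with labels in {-1, +1}."""

    pixel_indices: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.pixel_indices, dtype=int)
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "pixel_indices", idx)
        object.__setattr__(self, "labels", lab)
        if idx.shape != lab.shape or idx.ndim != 1:
            raise ValueError("indices and labels must be equal-length 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("pixel indices must be unique")
        if not np.isin(lab, [-1, 1]).all():
            raise ValueError("labels must be -1 or +1")

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == -1).sum())

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class TrainingConfig:
    """Boosting hyper-parameters.

    ``learning_rate`` (the shrinkage nu) defaults to 0.3; the remaining
    defaults are conventional choices for gradient boosting on tabular
    data and are all config-exposed.
    """

    n_trees: int = 100
    max_depth: int = 4
    learning_rate: float = 0.3
    l2_leaf_penalty: float = 1.0
    row_subsample: float = 0.8
    col_subsample: float = 0.8
    min_child_cover: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0.0 < self.learning_rate < 1.0:
            raise ValueError("learning_rate must be in (0, 1)")
        if self.l2_leaf_penalty < 0:
            raise ValueError("l2_leaf_penalty must be >= 0")
        if not 0.0 < self.row_subsample <= 1.0:
            raise ValueError("row_subsample must be in (0, 1]")
        if not 0.0 < self.col_subsample <= 1.0:
            raise ValueError("col_subsample must be in (0, 1]")
        if self.min_child_cover < 1:
            raise ValueError("min_child_cover must be >= 1")


class RegressionTree:
    """A binary regression tree stored as parallel node arrays.

    Node 0 is the root. ``children_left[i] == -1`` marks a leaf; internal
    nodes carry ``feature`` and ``threshold`` (x <= threshold goes left),
    leaves carry ``value``. ``cover`` is positive at every node and
    conserved: cover(parent) = cover(left) + cover(right).
    """

    def __init__(self, children_left, children_right, feature, threshold,
                 value, cover):
        self.children_left = np.asarray(children_left, dtype=int)
        self.children_right = np.asarray(children_right, dtype=int)
        self.feature = np.asarray(feature, dtype=int)
        self.threshold = np.asarray(threshold, dtype=float)
        self.value = np.asarray(value, dtype=float)
        self.cover = np.asarray(cover, dtype=float)
        n = len(self.children_left)
        arrays = (self.children_right, self.feature, self.threshold,
                  self.value, self.cover)
        if any(len(a) != n for a in arrays):
            raise ValueError("node arrays must have equal length")
        if not np.isfinite(self.threshold[self.children_left != _LEAF]).all():
            raise ValueError("non-finite threshold")
        if not np.isfinite(self.value[self.children_left == _LEAF]).all():
            raise ValueError("non-finite leaf value")
        if (self.cover <= 0).any():
            raise ValueError("every node must have positive cover")

    @property
    def n_nodes(self) -> int:
        return len(self.children_left)

    def is_leaf(self, node: int) -> bool:
        return self.children_left[node] == _LEAF

    def used_features(self) -> np.ndarray:
        """Distinct feature indices appearing in internal splits."""
        internal = self.children_left != _LEAF
        return np.unique(self.feature[internal])

    def decision_path_leaf(self, x: np.ndarray) -> int:
        node = 0
        while not self.is_leaf(node):
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Leaf values for every row of ``X``, vectorised."""
        X = np.atleast_2d(X)
        out = np.empty(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if self.is_leaf(node):
                out[idx] = self.value[node]
                continue
            go_left = X[idx, self.feature[node]] <= self.threshold[node]
            stack.append((self.children_left[node], idx[go_left]))
            stack.append((self.children_right[node], idx[~go_left]))
        return out

    def recompute_covers(self, X: np.ndarray) -> None:
        """Set each node's cover to the number of rows of ``X`` it routes."""
        counts = np.zeros(self.n_nodes)
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            counts[node] = len(idx)
            if self.is_leaf(node):
                continue
            go_left = X[idx, self.feature[node]] <= self.threshold[node]
            stack.append((self.children_left[node], idx[go_left]))
            stack.append((self.children_right[node], idx[~go_left]))
        if (counts <= 0).any():
            raise ValueError("a node received zero cover on the cover set")
        self.cover = counts

    def check_cover_conservation(self, atol: float = 1e-9) -> bool:
        internal = np.flatnonzero(self.children_left != _LEAF)
        lhs = self.cover[internal]
        rhs = (self.cover[self.children_left[internal]]
               + self.cover[self.children_right[internal]])
        return bool(np.allclose(lhs, rhs, atol=atol))


@dataclass
class TreeEnsemble:
    """Additive log-odds ensemble: ``tau0 + nu * sum_k tau_k(x)``."""

    base_prediction: float
    learning_rate: float
    trees: list[RegressionTree]
    n_features: int

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        if not np.isfinite(X).all():
            raise ValueError("non-finite input")
        out = np.full(X.shape[0], self.base_prediction)
        for tree in self.trees:
            out += self.learning_rate * tree.predict(X)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "base_prediction": self.base_prediction,
            "learning_rate": self.learning_rate,
            "n_features": self.n_features,
            "trees": [
                {
                    "nodes": [
                        {
                            "id": i,
                            "is_leaf": bool(t.is_leaf(i)),
                            "feature": int(t.feature[i]),
                            "threshold": float(t.threshold[i]),
                            "left": int(t.children_left[i]),
                            "right": int(t.children_right[i]),
                            "value": float(t.value[i]),
                            "cover": float(t.cover[i]),
                        }
                        for i in range(t.n_nodes)
                    ]
                }
                for t in self.trees
            ],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def make_labels(mask: AnnotationMask) -> LabeledSubset:
    """POS -> +1, NEG -> -1, EXCLUDED dropped."""
    if mask.n_pos == 0 or mask.n_neg == 0:
        raise ValueError(
            f"mask {mask.class_name!r} needs at least one POS and one NEG "
            f"pixel (has {mask.n_pos} POS, {mask.n_neg} NEG)"
        )
    keep = mask.labels != int(Label.EXCLUDED)
    idx = np.flatnonzero(keep)
    lab = np.where(mask.labels[keep] == int(Label.POS), 1, -1)
    return LabeledSubset(idx, lab)


def downsample_negatives(ls: LabeledSubset, pos_fraction: float,
                         seed: int) -> LabeledSubset:
    """Subsample negatives so positives make up ``pos_fraction`` of rows.

    All positives are kept. If there are too few negatives to reach the
    requested fraction, all are kept and a warning is issued.
    """
    if not 0.0 < pos_fraction < 1.0:
        raise ValueError("pos_fraction must be in (0, 1)")
    pos = ls.pixel_indices[ls.labels == 1]
    neg = ls.pixel_indices[ls.labels == -1]
    n_neg_wanted = round(len(pos) * (1.0 - pos_fraction) / pos_fraction)
    if n_neg_wanted >= len(neg):
        if n_neg_wanted > len(neg):
            warnings.warn(
                f"only {len(neg)} negatives available, "
                f"{n_neg_wanted} needed for pos_fraction={pos_fraction}; "
                "keeping all negatives",
                stacklevel=2,
            )
        kept_neg = neg
    else:
        rng = np.random.default_rng(seed)
        kept_neg = np.sort(rng.choice(neg, size=n_neg_wanted, replace=False))
    idx = np.concatenate([pos, kept_neg])
    lab = np.concatenate([np.ones(len(pos), int), -np.ones(len(kept_neg), int)])
    order = np.argsort(idx)
    return LabeledSubset(idx[order], lab[order])


def split_holdout(ls: LabeledSubset, test_fraction: float,
                  seed: int) -> tuple[LabeledSubset, LabeledSubset]:
    """Stratified train/test partition of a labelled subset."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (1, -1):
        members = np.flatnonzero(ls.labels == cls)
        if len(members) < 2:
            raise ValueError(f"class {cls:+d} has fewer than 2 members")
        n_test = max(1, round(len(members) * test_fraction))
        if n_test >= len(members):
            n_test = len(members) - 1
        perm = rng.permutation(members)
        test_parts.append(perm[:n_test])
        train_parts.append(perm[n_test:])
    def subset(parts):
        sel = np.sort(np.concatenate(parts))
        return LabeledSubset(ls.pixel_indices[sel], ls.labels[sel])
    return subset(train_parts), subset(test_parts)


def _grow_tree(X, g, h, rows, rng, cfg):
    """Exact greedy tree growth on the given (subsampled) rows."""
    n_features = X.shape[1]
    n_cols = max(1, round(cfg.col_subsample * n_features))
    lam = cfg.l2_leaf_penalty

    children_left, children_right = [], []
    feature, threshold, value, cover = [], [], [], []

    def new_node():
        children_left.append(_LEAF)
        children_right.append(_LEAF)
        feature.append(-1)
        threshold.append(np.nan)
        value.append(0.0)
        cover.append(0.0)
        return len(children_left) - 1

    def best_split(idx):
        if cfg.col_subsample < 1.0:
            cols = rng.choice(n_features, size=n_cols, replace=False)
        else:
            cols = np.arange(n_features)
        G, H = g[idx].sum(), h[idx].sum()
        parent_score = G * G / (H + lam)
        best = (0.0, -1, np.nan)  # gain, feature, threshold
        for j in cols:
            v = X[idx, j]
            order = np.argsort(v, kind="stable")
            vs = v[order]
            gs = np.cumsum(g[idx][order])
            hs = np.cumsum(h[idx][order])
            # candidate split after position i (1-based count i+1 on the left)
            cand = np.flatnonzero(vs[:-1] < vs[1:])
            if len(cand) == 0:
                continue
            n_left = cand + 1
            n_right = len(idx) - n_left
            ok = (n_left >= cfg.min_child_cover) & (n_right >= cfg.min_child_cover)
            cand = cand[ok]
            if len(cand) == 0:
                continue
            GL, HL = gs[cand], hs[cand]
            GR, HR = G - GL, H - HL
            gain = GL * GL / (HL + lam) + GR * GR / (HR + lam) - parent_score
            k = int(np.argmax(gain))
            if gain[k] > best[0] + 1e-12:
                # threshold = left-side max value, so `<=` reproduces the
                # sorted partition exactly
                best = (float(gain[k]), int(j), float(vs[cand[k]]))
        return best

    def build(idx, depth):
        node = new_node()
        cover[node] = float(len(idx))
        if depth < cfg.max_depth and len(idx) >= 2 * cfg.min_child_cover:
            gain, j, thr = best_split(idx)
            if j >= 0:
                go_left = X[idx, j] <= thr
                feature[node] = j
                threshold[node] = thr
                left = build(idx[go_left], depth + 1)
                right = build(idx[~go_left], depth + 1)
                children_left[node] = left
                children_right[node] = right
                return node
        value[node] = -g[idx].sum() / (h[idx].sum() + lam)
        return node

    build(rows, 0)
    return RegressionTree(children_left, children_right, feature,
                          threshold, value, cover)


def train_ensemble(ds: IMSDataset, ls: LabeledSubset,
                   cfg: TrainingConfig) -> TreeEnsemble:
    """Fit a boosted log-odds ensemble to the labelled pixels of ``ds``.

    After each tree is grown on its row subsample, node covers are
    recomputed on the FULL training set, so observational Shapley
    expectations later reference the training distribution.
    """
    if len(ls) == 0:
        raise ValueError("empty training set")
    if ls.n_pos == 0 or ls.n_neg == 0:
        raise ValueError("training set must contain both classes")
    X = ds.intensities[ls.pixel_indices]
    if not np.isfinite(X).all():
        raise ValueError("non-finite intensities")
    t = (ls.labels + 1) / 2.0
    tau0 = math.log(ls.n_pos / ls.n_neg)
    rng = np.random.default_rng(cfg.seed)

    raw = np.full(len(ls), tau0)
    trees: list[RegressionTree] = []
    n = len(ls)
    n_rows = max(2, round(cfg.row_subsample * n))
    for _ in range(cfg.n_trees):
        p = 1.0 / (1.0 + np.exp(-raw))
        g = p - t
        h = p * (1.0 - p)
        if cfg.row_subsample < 1.0:
            rows = rng.choice(n, size=n_rows, replace=False)
        else:
            rows = np.arange(n)
        tree = _grow_tree(X, g, h, rows, rng, cfg)
        tree.recompute_covers(X)
        raw += cfg.learning_rate * tree.predict(X)
        trees.append(tree)
    return TreeEnsemble(tau0, cfg.learning_rate, trees, ds.n_features)


# ---------------------------------------------------------------------------
# Import of serialized / external ensembles
# ---------------------------------------------------------------------------

def import_ensemble(dump: str | Path) -> TreeEnsemble:
    """Read a JSON ensemble dump (the schema written by ``to_json``).

    Every node must carry a cover; covers supply the weights of the
    observational Shapley expectations, so a dump without them is rejected.
    """
    if isinstance(dump, Path):
        text = dump.read_text()
    elif dump.lstrip().startswith("{"):
        text = dump
    else:
        text = Path(dump).read_text()
    obj = json.loads(text)
    try:
        trees = []
        for tr in obj["trees"]:
            nodes = sorted(tr["nodes"], key=lambda nd: nd["id"])
            for nd in nodes:
                if "cover" not in nd or nd["cover"] is None:
                    raise KeyError("cover")
            trees.append(RegressionTree(
                [nd["left"] if not nd["is_leaf"] else _LEAF for nd in nodes],
                [nd["right"] if not nd["is_leaf"] else _LEAF for nd in nodes],
                [nd.get("feature", -1) for nd in nodes],
                [nd.get("threshold", np.nan) if not nd["is_leaf"] else np.nan
                 for nd in nodes],
                [nd.get("value", 0.0) for nd in nodes],
                [nd["cover"] for nd in nodes],
            ))
        ens = TreeEnsemble(
            float(obj["base_prediction"]),
            float(obj["learning_rate"]),
            trees,
            int(obj["n_features"]),
        )
    except KeyError as exc:
        if exc.args and exc.args[0] == "cover":
            raise ValueError(
                "cover required for observational Shapley"
            ) from None
        raise ValueError(f"ensemble dump missing field {exc}") from None
    return ens


def from_xgboost(booster, n_features: int | None = None) -> TreeEnsemble:
    """Convert a trained xgboost binary-logistic booster.

    xgboost routes ``x < threshold`` to the yes-branch; our convention is
    ``x <= threshold`` left. Each imported threshold is replaced by
    ``nextafter(t, -inf)`` so that ``x <= t'`` is equivalent to ``x < t``
    for every float, and imported margins match the external booster
    exactly. Leaf values already include xgboost's shrinkage, so the
    imported ensemble uses learning_rate 1.
    """
    import xgboost  # test/cross-check dependency only

    config = json.loads(booster.save_config())
    base_score = float(
        config["learner"]["learner_model_param"]["base_score"])
    tau0 = math.log(base_score / (1.0 - base_score))
    if n_features is None:
        n_features = booster.num_features()

    trees = []
    for dump in booster.get_dump(dump_format="json", with_stats=True):
        raw_nodes: dict[int, dict] = {}

        def walk(nd):
            raw_nodes[nd["nodeid"]] = nd
            for ch in nd.get("children", []):
                walk(ch)

        walk(json.loads(dump))
        ids = sorted(raw_nodes)
        remap = {nid: i for i, nid in enumerate(ids)}
        cl, cr, feat, thr, val, cov = [], [], [], [], [], []
        for nid in ids:
            nd = raw_nodes[nid]
            if "cover" not in nd:
                raise ValueError("cover required for observational Shapley")
            cov.append(float(nd["cover"]))
            if "leaf" in nd:
                cl.append(_LEAF)
                cr.append(_LEAF)
                feat.append(-1)
                thr.append(np.nan)
                val.append(float(nd["leaf"]))
            else:
                f = nd["split"]
                feat.append(int(f[1:]) if isinstance(f, str) and f.startswith("f")
                            else int(f))
                thr.append(np.nextafter(float(nd["split_condition"]), -np.inf))
                cl.append(remap[nd["yes"]])
                cr.append(remap[nd["no"]])
                val.append(0.0)
        trees.append(RegressionTree(cl, cr, feat, thr, val, cov))
    return TreeEnsemble(tau0, 1.0, trees, int(n_features))


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def predict_raw(ens: TreeEnsemble, x: np.ndarray) -> float | np.ndarray:
    """Log-odds output; scalar for one row, vector for a matrix."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = ens.predict_raw(x)
    return float(out[0]) if single else out


def predict_probability(ens: TreeEnsemble, x: np.ndarray) -> float | np.ndarray:
    raw = predict_raw(ens, x)
    return 1.0 / (1.0 + np.exp(-raw))


def predict_class(ens: TreeEnsemble, x: np.ndarray,
                  eta: float = 0.5) -> int | np.ndarray:
    """+1 iff predicted probability >= eta (ties go positive)."""
    if not 0.0 < eta < 1.0:
        raise ValueError("eta must be in (0, 1)")
    p = predict_probability(ens, x)
    if np.isscalar(p):
        return 1 if p >= eta else -1
    return np.where(p >= eta, 1, -1)


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion counts and imbalance-aware rates.

    A rate whose denominator is zero is ``None`` (undefined); balanced
    accuracy is undefined if either component is.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    sensitivity = recall

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def balanced_accuracy(self) -> float | None:
        r, s = self.recall, self.specificity
        if r is None or s is None:
            return None
        return (r + s) / 2.0

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
        }


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> ClassificationMetrics:
    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predictions.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    for arr in (predictions, truth):
        if not np.isin(arr, [-1, 1]).all():
            raise ValueError("labels must be -1 or +1")
    return ClassificationMetrics(
        tp=int(((predictions == 1) & (truth == 1)).sum()),
        fp=int(((predictions == 1) & (truth == -1)).sum()),
        tn=int(((predictions == -1) & (truth == -1)).sum()),
        fn=int(((predictions == -1) & (truth == 1)).sum()),
    )


def prediction_image(ens: TreeEnsemble, ds: IMSDataset,
                     eta: float = 0.5) -> SpatialImage:
    """Class prediction (+1/-1) for every pixel, placed on the grid."""
    cls = predict_class(ens, ds.intensities, eta)
    return values_image(ds, cls.astype(float),
                        legend=f"class prediction (eta={eta})")
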