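"""Shared random-tree generator for oracle sweeps."""

import numpy as np

from shapims.boosting import RegressionTree


def random_tree(rng, n_features=10, max_depth=5, split_prob=0.75):
    """Random regression tree with random integer covers.

    Drawing split features from a pool of ``n_features`` bounds the number
    of distinct used features; repeated features along a path are allowed
    and exercised.
    """
    cl, cr, feat, thr, val, cov = [], [], [], [], [], []

    def build(depth, cover):
        node = len(cl)
        cl.append(-1)
        cr.append(-1)
        feat.append(-1)
        thr.append(np.nan)
        val.append(0.0)
        cov.append(cover)
        if depth < max_depth and cover >= 2 and rng.random() < split_prob:
            feat[node] = int(rng.integers(n_features))
            thr[node] = float(rng.normal())
            wl = float(rng.integers(1, int(cover)))
            left = build(depth + 1, wl)
            right = build(depth + 1, cover - wl)
            cl[node], cr[node] = left, right
        else:
            val[node] = float(rng.normal())
        return node

    build(0, float(rng.integers(20, 200)))
    return RegressionTree(cl, cr, feat, thr, val, cov)
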