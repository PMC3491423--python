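"""Decision trees on binary methylation calls with leave-one-out selection.

Classification trees (greedy Gini splits, CART-style) are fit on binary
methylation features to predict patient outcome classes.  Marker
selection follows the leave-one-out protocol: one tree per left-out
patient, counting how often each marker appears in any split; markers
present in at least half of the trees form the restricted signature,
which is then re-evaluated by leave-one-out prediction and a log-rank
test between the predicted classes.

Determinism contract: split ties are broken by feature id (column
order after sorting), and missing calls are routed down the branch
holding the majority of the node's non-missing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CartParams:
    min_split: int = 10     # minimum samples to attempt a split
    min_leaf: int = 5       # minimum samples per child
    cp: float = 0.01        # minimum improvement, as a fraction of root impurity
    max_depth: int = 5


@dataclass
class CartNode:
    prediction: object
    proportions: dict
    n: int
    feature: str | None = None
    missing_to: int | None = None  # 0 or 1: branch receiving missing calls
    children: list["CartNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def features_used(self) -> set[str]:
        if self.is_leaf:
            return set()
        out = {self.feature}
        for ch in self.children:
            out |= ch.features_used()
        return out


def _gini(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - (p**2).sum())


def _majority(y: np.ndarray):
    vals, counts = np.unique(y, return_counts=True)
    return vals[np.argmax(counts)]  # ties: first in sorted order


def _route(col: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Boolean masks for branch 0 / branch 1 with missing values routed
    to the majority branch; returns (mask0, mask1, missing_branch)."""
    is0 = col == 0
    is1 = col == 1
    missing_to = 1 if is1.sum() >= is0.sum() else 0
    miss = ~(is0 | is1)
    if missing_to == 1:
        is1 = is1 | miss
    else:
        is0 = is0 | miss
    return is0, is1, missing_to


def _build(
    x: np.ndarray,
    y: np.ndarray,
    features: list[str],
    params: CartParams,
    root_impurity: float,
    depth: int,
) -> CartNode:
    vals, counts = np.unique(y, return_counts=True)
    node = CartNode(
        prediction=_majority(y),
        proportions={v: c / len(y) for v, c in zip(vals, counts)},
        n=len(y),
    )
    if (
        len(vals) == 1
        or len(y) < params.min_split
        or depth >= params.max_depth
    ):
        return node

    impurity = _gini(y)
    best = None  # (improvement, feature index)
    for j in range(x.shape[1]):
        m0, m1, _ = _route(x[:, j])
        n0, n1 = m0.sum(), m1.sum()
        if n0 < params.min_leaf or n1 < params.min_leaf:
            continue
        child_imp = (n0 * _gini(y[m0]) + n1 * _gini(y[m1])) / len(y)
        improvement = impurity - child_imp
        if best is None or improvement > best[0] + 1e-12:
            best = (improvement, j)
    if best is None or best[0] < params.cp * root_impurity:
        return node

    j = best[1]
    m0, m1, missing_to = _route(x[:, j])
    node.feature = features[j]
    node.missing_to = missing_to
    node.children = [
        _build(x[m0], y[m0], features, params, root_impurity, depth + 1),
        _build(x[m1], y[m1], features, params, root_impurity, depth + 1),
    ]
    return node


def cart_fit(
    X: pd.DataFrame, y: pd.Series, params: CartParams = CartParams()
) -> CartNode:
    """Fit a CART-style tree on binary features (NaN = missing call).

    Greedy Gini-impurity splits; a split must improve impurity by at
    least ``cp`` times the root impurity and leave ``min_leaf`` samples
    in each child.  Column order (feature id) breaks ties, so refitting
    on the same data yields an identical tree.
    """
    X = X.reindex(sorted(X.columns), axis=1)
    x = X.to_numpy(dtype=float)
    yv = np.asarray(y.reindex(X.index) if isinstance(y, pd.Series) else y)
    root_imp = _gini(yv)
    if root_imp == 0.0:
        root_imp = 1.0  # single-class y: any cp stops splitting anyway
    return _build(x, yv, list(X.columns), params, root_imp, depth=0)


def cart_predict(tree: CartNode, X: pd.DataFrame) -> pd.Series:
    preds = []
    for _, row in X.iterrows():
        node = tree
        while not node.is_leaf:
            v = row.get(node.feature)
            if pd.isna(v) or v not in (0, 1):
                branch = node.missing_to
            else:
                branch = int(v)
            node = node.children[branch]
        preds.append(node.prediction)
    return pd.Series(preds, index=X.index)


def loo_marker_frequency(
    X: pd.DataFrame, y: pd.Series, params: CartParams = CartParams()
) -> pd.Series:
    """Fraction of leave-one-out trees using each feature in any split."""
    if len(X) < 3:
        raise ValueError("need at least 3 samples")
    counts = pd.Series(0.0, index=sorted(X.columns))
    for sample in X.index:
        rest = X.index != sample
        tree = cart_fit(X.loc[rest], y.loc[rest], params)
        for f in tree.features_used():
            counts[f] += 1
    return counts / len(X)


def select_markers(freq: pd.Series, min_fraction: float = 0.5) -> list[str]:
    """Markers included in at least ``min_fraction`` of the trees."""
    return list(freq.index[freq >= min_fraction])


def loo_predict_restricted(
    X_selected: pd.DataFrame, y: pd.Series, params: CartParams = CartParams()
) -> pd.Series:
    """Per-sample class predicted by the tree trained without it.

    Restricting ``X_selected`` to the selected signature reproduces the
    evaluation feeding the Kaplan-Meier / log-rank comparison of
    predicted classes.
    """
    if X_selected.shape[1] == 0:
        raise ValueError("empty marker selection")
    preds = {}
    for sample in X_selected.index:
        rest = X_selected.index != sample
        tree = cart_fit(X_selected.loc[rest], y.loc[rest], params)
        preds[sample] = cart_predict(tree, X_selected.loc[[sample]]).iloc[0]
    return pd.Series(preds)
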