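"""Code co-occurrence network models.

For each unit of analysis (a case), co-occurrences of code pairs are
accumulated within conversations (information patches), either over the
whole conversation or in a moving window of utterances.  Each unit's
accumulated pair-count vector is normalized to unit length, so edge weights
express relative co-occurrence frequency independent of narrative length
and fall in [0, 1].  A dimensional reduction (SVD, or a means rotation that
places the two group means on the first axis) projects the normalized
vectors to 2-D scores, and node positions are co-registered with the scores
by a least-squares fit, so that each unit's score sits near the
edge-weighted centroid of its own network.

Implemented as a scikit-learn style estimator (:class:`ENAModel`) plus thin
functional wrappers; mean and difference networks, per-dimension confidence
intervals and per-patch trajectory models are derived from the fitted
projection space.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .alignment import UnifiedDataset

__all__ = [
    "ModelSpec",
    "ENAModel",
    "accumulate",
    "normalize",
    "mean_network",
    "difference_network",
    "score_ci",
    "network_to_graph",
    "export_model_json",
]


@dataclass
class ModelSpec:
    """Accumulation parameters: what groups utterances and which codes count.

    window is "whole_conversation" (the default: a conversation is one
    information patch) or "moving_window" with ``window_size`` utterances.
    """

    codes: list[str]
    unit: str = "caseID"
    conversation: str = "patch_id"
    window: str = "whole_conversation"
    window_size: int = 4

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("codes must be non-empty")
        if self.window not in ("whole_conversation", "moving_window"):
            raise ValueError(f"unknown window {self.window!r}")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.codes, 2))


def _pair_counts_conversation(block: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Pair-count vector for one conversation (rows = utterances, cols = codes).

    A pair counts at most once per accumulation window (binarized
    co-occurrence); whole-conversation treats the conversation as one window.
    """
    C = block.shape[1]
    idx = list(itertools.combinations(range(C), 2))
    out = np.zeros(len(idx))
    if spec.window == "whole_conversation":
        present = block.any(axis=0)
        for k, (i, j) in enumerate(idx):
            out[k] = 1.0 if present[i] and present[j] else 0.0
        return out
    k_size = spec.window_size
    for t in range(block.shape[0]):
        current = block[t] > 0
        window = block[max(0, t - k_size + 1): t + 1].any(axis=0)
        for k, (i, j) in enumerate(idx):
            if (current[i] and window[j]) or (current[j] and window[i]):
                out[k] += 1.0
    return out


def accumulate(ds: UnifiedDataset, spec: ModelSpec) -> pd.DataFrame:
    """Raw co-occurrence vectors: one row per unit, one column per code pair."""
    missing = [c for c in spec.codes if c not in ds.df.columns]
    if missing:
        raise KeyError(f"unknown code column(s): {', '.join(missing)}")
    cols = [f"{a}&{b}" for a, b in spec.pairs]
    rows: dict[str, np.ndarray] = {}
    df = ds.df
    for unit, unit_df in df.groupby(spec.unit, sort=True):
        vec = np.zeros(len(cols))
        for _, conv_df in unit_df.groupby(spec.conversation, sort=False):
            block = conv_df[spec.codes].to_numpy()
            vec += _pair_counts_conversation(block, spec)
        rows[unit] = vec
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()


def normalize(raw_vectors: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each unit's vector to unit Euclidean length.

    Zero vectors (units with no co-occurrences) stay zero and are flagged in
    the returned boolean Series.
    """
    X = raw_vectors.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    scaled = np.divide(X, np.where(zero, 1.0, norms)[:, None])
    return (
        pd.DataFrame(scaled, index=raw_vectors.index, columns=raw_vectors.columns),
        pd.Series(zero, index=raw_vectors.index, name="zero_vector"),
    )


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Resolve SVD sign indeterminacy: the largest-magnitude loading on each
    dimension is made positive."""
    V = V.copy()
    for d in range(V.shape[1]):
        lead = np.argmax(np.abs(V[:, d]))
        if V[lead, d] < 0:
            V[:, d] = -V[:, d]
    return V


class ENAModel(BaseEstimator):
    """Co-occurrence network model with a shared 2-D projection space.

    Parameters
    ----------
    codes : list of str
        Binary code columns of the unified dataset to model.
    unit, conversation : str
        Grouping columns (defaults: case and patch).
    window, window_size : accumulation rule, see :class:`ModelSpec`.
    projection : "svd" or "means_rotation"
        Means rotation needs ``group`` and exactly two group labels; it puts
        the two group means on the first axis (so both means have a second
        coordinate of zero) and takes the leading residual SVD direction as
        the second axis.
    group : str
        Column holding group labels (used by means rotation, mean networks
        and confidence intervals).
    """

    def __init__(
        self,
        codes: list[str] | None = None,
        unit: str = "caseID",
        conversation: str = "patch_id",
        window: str = "whole_conversation",
        window_size: int = 4,
        projection: str = "svd",
        group: str = "groupID",
    ):
        self.codes = codes
        self.unit = unit
        self.conversation = conversation
        self.window = window
        self.window_size = window_size
        self.projection = projection
        self.group = group

    # -- fitting -----------------------------------------------------------

    def _spec(self, ds: UnifiedDataset) -> ModelSpec:
        codes = self.codes
        if codes is None:
            codes = ds.stream_code_columns("think_aloud")
        return ModelSpec(
            codes=list(codes),
            unit=self.unit,
            conversation=self.conversation,
            window=self.window,
            window_size=self.window_size,
        )

    def fit(self, ds: UnifiedDataset, y=None) -> "ENAModel":
        spec = self._spec(ds)
        if self.projection not in ("svd", "means_rotation"):
            raise ValueError(f"unknown projection {self.projection!r}")
        raw = accumulate(ds, spec)
        if len(raw) < 2:
            raise ValueError("need at least 2 units to fit a projection")
        norm, zero = normalize(raw)
        groups = (
            ds.df.groupby(spec.unit, sort=True)[self.group].first()
            if self.group in ds.df.columns
            else pd.Series("", index=raw.index)
        )
        X = norm.to_numpy()[~zero.to_numpy()]
        if X.shape[0] < 2:
            raise ValueError("need at least 2 nonzero units to fit a projection")
        mean = X.mean(axis=0)
        Xc = X - mean
        if self.projection == "svd":
            _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
            V = _fix_signs(Vt[:2].T)
        else:
            V = self._means_rotation(Xc, groups[~zero].to_numpy())
        self.spec_ = spec
        self.raw_vectors_ = raw
        self.norm_vectors_ = norm
        self.zero_units_ = zero
        self.groups_ = groups
        self.mean_ = mean
        self.projection_matrix_ = V
        self.scores_ = self._project(norm, zero)
        self.node_positions_ = self._coregister_nodes()
        return self

    def _means_rotation(self, Xc: np.ndarray, groups: np.ndarray) -> np.ndarray:
        labels = pd.unique(groups)
        if len(labels) != 2:
            raise ValueError(f"means rotation needs exactly 2 groups, got {list(labels)}")
        m1 = Xc[groups == labels[0]].mean(axis=0)
        m2 = Xc[groups == labels[1]].mean(axis=0)
        d = m1 - m2
        nd = np.linalg.norm(d)
        if nd == 0:
            raise ValueError("group means coincide; means rotation undefined")
        ax1 = d / nd
        resid = Xc - np.outer(Xc @ ax1, ax1)
        _, _, Vt = np.linalg.svd(resid, full_matrices=False)
        ax2 = Vt[0]
        V = np.column_stack([ax1, ax2])
        return _fix_signs(V)

    def _project(self, norm: pd.DataFrame, zero: pd.Series) -> pd.DataFrame:
        Xc = norm.to_numpy() - self.mean_
        S = Xc @ self.projection_matrix_
        S[zero.to_numpy()] = 0.0  # codeless units sit at the origin
        return pd.DataFrame(S, index=norm.index, columns=["x", "y"])

    def _coregister_nodes(self) -> pd.DataFrame:
        """Least-squares node placement: minimize the squared distance between
        each unit's score and the edge-weighted centroid of its network."""
        codes = self.spec_.codes
        pairs = self.spec_.pairs
        W = self.norm_vectors_.to_numpy()
        keep = ~self.zero_units_.to_numpy()
        W = W[keep]
        S = self.scores_.to_numpy()[keep]
        L = np.zeros((W.shape[0], len(codes)))
        code_idx = {c: i for i, c in enumerate(codes)}
        for k, (a, b) in enumerate(pairs):
            L[:, code_idx[a]] += W[:, k]
            L[:, code_idx[b]] += W[:, k]
        row_sums = L.sum(axis=1, keepdims=True)
        row_sums[row_sums == 0] = 1.0
        L = L / row_sums
        N, *_ = np.linalg.lstsq(L, S, rcond=None)
        return pd.DataFrame(N, index=codes, columns=["x", "y"])

    # -- transform & derived models ---------------------------------------

    def transform(self, ds: UnifiedDataset) -> pd.DataFrame:
        """Project new units into the fitted space (ENA scores)."""
        self._check_fitted()
        raw = accumulate(ds, self.spec_)
        norm, zero = normalize(raw)
        return self._project(norm, zero)

    def fit_transform(self, ds: UnifiedDataset, y=None) -> pd.DataFrame:
        return self.fit(ds).scores_

    def _check_fitted(self) -> None:
        if not hasattr(self, "projection_matrix_"):
            raise RuntimeError("model is not fitted")

    def _group_members(self, group: str) -> pd.Index:
        members = self.groups_[self.groups_ == group].index
        if len(members) == 0:
            raise ValueError(f"empty group {group!r}")
        return members

    def mean_network(self, group: str) -> pd.Series:
        """Mean edge weights (normalized co-occurrence) over a group's units."""
        self._check_fitted()
        return self.norm_vectors_.loc[self._group_members(group)].mean(axis=0)

    def difference_network(self, g1: str, g2: str) -> pd.Series:
        """Edge-wise subtraction of two groups' mean networks (g1 − g2)."""
        return self.mean_network(g1) - self.mean_network(g2)

    def mean_score(self, group: str) -> pd.Series:
        self._check_fitted()
        return self.scores_.loc[self._group_members(group)].mean(axis=0)

    def score_ci(self, group: str, level: float = 0.95) -> pd.DataFrame:
        """t-distribution confidence interval of the group mean per dimension."""
        self._check_fitted()
        S = self.scores_.loc[self._group_members(group)]
        n = len(S)
        if n < 2:
            raise ValueError(f"confidence interval needs n >= 2, got n={n}")
        mean = S.mean(axis=0)
        sem = S.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
        return pd.DataFrame(
            {"mean": mean, "lower": mean - tcrit * sem, "upper": mean + tcrit * sem}
        )

    def trajectory(self, ds: UnifiedDataset) -> dict[str, pd.DataFrame]:
        """Per-unit trajectory: each conversation (patch) accumulated alone,
        normalized and projected into the fitted space, ordered by patch
        ordinal.  Codeless patches project to the origin."""
        self._check_fitted()
        spec = self.spec_
        out: dict[str, pd.DataFrame] = {}
        for unit, unit_df in ds.df.groupby(spec.unit, sort=True):
            recs = []
            convs = list(dict.fromkeys(unit_df[spec.conversation]))
            for ordinal, conv in enumerate(convs, start=1):
                block = unit_df[unit_df[spec.conversation] == conv][spec.codes].to_numpy()
                vec = _pair_counts_conversation(block, spec)
                nrm = np.linalg.norm(vec)
                if nrm == 0:
                    xy = np.zeros(2)
                else:
                    xy = (vec / nrm - self.mean_) @ self.projection_matrix_
                recs.append(
                    {"conversation": conv, "ordinal": ordinal, "x": xy[0], "y": xy[1]}
                )
            out[unit] = pd.DataFrame(recs)
        return out


# -- functional wrappers and exports --------------------------------------


def mean_network(model: ENAModel, group: str) -> pd.Series:
    return model.mean_network(group)


def difference_network(model: ENAModel, g1: str, g2: str) -> pd.Series:
    return model.difference_network(g1, g2)


def score_ci(model: ENAModel, group: str, level: float = 0.95) -> pd.DataFrame:
    return model.score_ci(group, level)


def network_to_graph(edge_weights: pd.Series, node_positions: pd.DataFrame | None = None) -> nx.Graph:
    """Undirected weighted graph from an edge-weight vector ("A&B" index)."""
    G = nx.Graph()
    for pair, w in edge_weights.items():
        a, b = pair.split("&")
        G.add_node(a)
        G.add_node(b)
        if w != 0:
            G.add_edge(a, b, weight=float(w))
    if node_positions is not None:
        for code, row in node_positions.iterrows():
            if code in G:
                G.nodes[code]["x"] = float(row["x"])
                G.nodes[code]["y"] = float(row["y"])
    return G


def export_model_json(model: ENAModel, path) -> None:
    model._check_fitted()
    payload = {
        "codes": model.spec_.codes,
        "pairs": ["&".join(p) for p in model.spec_.pairs],
        "raw_vectors": model.raw_vectors_.to_dict(orient="index"),
        "norm_vectors": model.norm_vectors_.to_dict(orient="index"),
        "scores": model.scores_.to_dict(orient="index"),
        "node_positions": model.node_positions_.to_dict(orient="index"),
        "projection": model.projection,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
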