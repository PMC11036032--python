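"""State-transition models over patch content types.

A participant's session is an ordered sequence of states — here the content
type of each visited patch (engine, SERP, page, file), though any
categorical coding scheme can be supplied, which supports sensitivity
analyses over alternative schemes.  Adjacent pairs are tallied into an
asymmetric S×S count matrix whose diagonal holds self-loops; dividing each
row by its total outgoing count gives row-stochastic transition
probabilities in [0, 1].  States with no outgoing transitions (a session's
terminal patch type) keep an all-zero row and are flagged absorbing.

Per-unit matrices are kept alongside the pooled matrix; subsample
probabilities are computed from pooled counts by default, with per-unit
averaging available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .rock_io import PATCH_TYPES

__all__ = [
    "StateSequence",
    "StateTransitionModel",
    "count_transitions",
    "transition_probabilities",
    "sequences_from_patches",
    "export_network",
]


@dataclass
class StateSequence:
    """One unit's ordered walk through states, with optional dwell times."""

    unit: str
    states: list[str]
    durations: list[float] | None = None

    def __post_init__(self) -> None:
        if self.durations is not None:
            if len(self.durations) != len(self.states):
                raise ValueError(
                    f"{self.unit}: {len(self.durations)} durations for "
                    f"{len(self.states)} states"
                )
            if any(d < 0 for d in self.durations):
                raise ValueError(f"{self.unit}: negative duration")


def count_transitions(
    seqs: list[StateSequence], scheme: tuple[str, ...] | list[str] = PATCH_TYPES
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Tally adjacent-pair transitions across sequences.

    Returns ``(counts, occupancy, self_ref)``: the S×S count matrix (rows =
    sending state), total participant-state occurrences per state, and the
    diagonal self-transition counts.  Transitions are only counted within a
    sequence, never across units.
    """
    scheme = list(scheme)
    idx = {s: i for i, s in enumerate(scheme)}
    counts = np.zeros((len(scheme), len(scheme)), dtype=int)
    occupancy = np.zeros(len(scheme), dtype=int)
    for seq in seqs:
        for s in seq.states:
            if s not in idx:
                raise ValueError(f"state {s!r} not in scheme {scheme}")
            occupancy[idx[s]] += 1
        for a, b in zip(seq.states, seq.states[1:]):
            counts[idx[a], idx[b]] += 1
    counts_df = pd.DataFrame(counts, index=scheme, columns=scheme)
    return (
        counts_df,
        pd.Series(occupancy, index=scheme, name="occupancy"),
        pd.Series(np.diag(counts), index=scheme, name="self_ref"),
    )


def transition_probabilities(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-normalize counts into probabilities.

    Each cell is the count for that sender→receiver pair divided by the
    sender's total outgoing count.  Rows with no outgoing transitions stay
    all-zero and are flagged absorbing in the returned boolean Series.
    """
    totals = counts.sum(axis=1)
    absorbing = totals == 0
    safe = totals.replace(0, 1)
    probs = counts.div(safe, axis=0).astype(float)
    return probs, absorbing.rename("absorbing")


class StateTransitionModel(BaseEstimator):
    """Estimator over state sequences.

    Parameters
    ----------
    scheme : list of str
        The closed state vocabulary (default: the four patch content types).
    pooling : "pooled" or "mean"
        Subsample probabilities from summed counts (default) or as the mean
        of per-unit probability matrices.
    """

    def __init__(self, scheme: tuple[str, ...] | list[str] = PATCH_TYPES, pooling: str = "pooled"):
        self.scheme = scheme
        self.pooling = pooling

    def fit(self, sequences: list[StateSequence], y=None) -> "StateTransitionModel":
        if not sequences:
            raise ValueError("need at least one sequence")
        if self.pooling not in ("pooled", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        self.sequences_ = list(sequences)
        self.states_ = list(self.scheme)
        self.counts_, self.occupancy_, self.self_ref_ = count_transitions(
            sequences, self.states_
        )
        self.unit_counts_ = {
            seq.unit: count_transitions([seq], self.states_)[0] for seq in sequences
        }
        if self.pooling == "pooled":
            self.probs_, self.absorbing_ = transition_probabilities(self.counts_)
        else:
            per_unit = [
                transition_probabilities(c)[0] for c in self.unit_counts_.values()
            ]
            self.probs_ = sum(per_unit) / len(per_unit)
            self.absorbing_ = (self.counts_.sum(axis=1) == 0).rename("absorbing")
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "counts_"):
            raise RuntimeError("model is not fitted")

    def node_statistics(self) -> pd.DataFrame:
        """Per-state occupancy, self-reference proportion and dwell time.

        Self-reference proportion is self-loop count over occupancy (zero
        for unvisited states); dwell time sums any per-state durations.
        """
        self._check_fitted()
        occ = self.occupancy_.astype(float)
        prop = (self.self_ref_ / occ.replace(0, np.nan)).fillna(0.0)
        stats_df = pd.DataFrame(
            {
                "occupancy": self.occupancy_,
                "self_ref": self.self_ref_,
                "self_ref_proportion": prop,
            }
        )
        if any(seq.durations is not None for seq in self.sequences_):
            dwell = pd.Series(0.0, index=self.states_)
            for seq in self.sequences_:
                if seq.durations is None:
                    raise ValueError(f"{seq.unit}: durations missing for dwell-time stats")
                for s, d in zip(seq.states, seq.durations):
                    dwell[s] += d
            stats_df["dwell_time"] = dwell
        return stats_df

    def to_graph(self) -> nx.DiGraph:
        """Directed graph with probability/count edge attributes.

        State pairs with no transitions in either direction get no edge at
        all; absorbing states contribute no outgoing edges.
        """
        self._check_fitted()
        G = nx.DiGraph()
        ns = self.node_statistics()
        for s in self.states_:
            G.add_node(
                s,
                occupancy=int(ns.loc[s, "occupancy"]),
                self_ref=int(ns.loc[s, "self_ref"]),
                self_ref_proportion=float(ns.loc[s, "self_ref_proportion"]),
            )
        for a in self.states_:
            for b in self.states_:
                c = int(self.counts_.loc[a, b])
                if c > 0:
                    G.add_edge(a, b, count=c, probability=float(self.probs_.loc[a, b]))
        return G


def sequences_from_patches(patch_attrs, unit_key=None) -> list[StateSequence]:
    """Build per-case state sequences from patch attribute records, ordered
    by each patch's ordinal, with dwell times from the start/end stamps."""
    from .rock_io import _seconds

    by_case: dict[str, list] = {}
    for p in patch_attrs:
        by_case.setdefault(p.case_id, []).append(p)
    seqs = []
    for case, patches in sorted(by_case.items()):
        patches.sort(key=lambda p: p.ordinal)
        seqs.append(
            StateSequence(
                unit=case,
                states=[p.patchType for p in patches],
                durations=[float(_seconds(p.end) - _seconds(p.start)) for p in patches],
            )
        )
    return seqs


def export_network(model: StateTransitionModel, path, fmt: str = "graphml") -> None:
    """Write the transition network as GraphML, JSON (node-link) or DOT."""
    G = model.to_graph()
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "json":
        payload = nx.node_link_data(G, edges="edges")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
    elif fmt == "dot":
        lines = ["digraph quest {"]
        for n, attrs in G.nodes(data=True):
            lines.append(f'  "{n}" [occupancy={attrs["occupancy"]}];')
        for a, b, attrs in G.edges(data=True):
            lines.append(f'  "{a}" -> "{b}" [label="{attrs["probability"]:.3f}"];')
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
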