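"""Information-scent scoring, patch-feature frequencies and coder reliability.

Information scent — how strongly a patch signals that it will advance the
active information goal — is scored from three aligned streams.  For every
patch and code, a derived variable takes:

* ``+1`` when the stimulus stream shows the code and the participant engaged
  with it (code present in the think-aloud OR the HCI stream),
* ``-1`` when the stimulus is present but engaged with in neither stream,
* ``0``  when the stimulus is absent (noted or not).

A participant's information scent is the sum of derived-variable values over
visited patches and codes; dividing by the maximum attainable value (one per
patch-code cell by default) normalizes it into [-1, 1].

The module also computes normalized patch-feature code frequencies
(binarized per patch, divided by patches visited, summed per subsample) and
Cohen's kappa for inter- and intra-rater reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import STREAM_PREFIX, UnifiedDataset

__all__ = [
    "StreamPresence",
    "ScentMatrix",
    "FrequencyProfile",
    "derive_variable",
    "stream_presence",
    "scent_matrix",
    "scent_trajectory",
    "code_frequencies",
    "cohens_kappa",
    "intra_rater_kappa",
]


@dataclass
class StreamPresence:
    """Per-patch, per-code binary presence in each stream (aligned frames)."""

    stim: pd.DataFrame
    ta: pd.DataFrame
    hci: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("ta", "hci"):
            other = getattr(self, name)
            if not (
                other.index.equals(self.stim.index)
                and other.columns.equals(self.stim.columns)
            ):
                raise ValueError(f"{name} frame not aligned with stim frame")
        for name in ("stim", "ta", "hci"):
            vals = getattr(self, name).to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} presence indicators must be 0/1")

    def absent(self, stream: str) -> pd.DataFrame:
        """Complementary absence indicators for a stream."""
        return 1 - getattr(self, stream)


def derive_variable(stim_present: int, ta_present: int, hci_present: int) -> int:
    """Score one patch-code cell from its three presence indicators."""
    for v in (stim_present, ta_present, hci_present):
        if v not in (0, 1):
            raise ValueError(f"presence indicators must be 0/1, got {v!r}")
    if not stim_present:
        return 0
    return 1 if (ta_present or hci_present) else -1


def stream_presence(ds: UnifiedDataset, codes: list[str]) -> StreamPresence:
    """Collapse a unified dataset to per-patch presence per stream.

    ``codes`` are bare labels; the matching ``STIM_``/``TA_``/``HCI_``
    columns are looked up (missing columns count as all-absent).
    """
    df = ds.df[ds.df["patch_id"] != ""]
    patches = list(dict.fromkeys(df["patch_id"]))
    frames = {}
    for stream, prefix in STREAM_PREFIX.items():
        mat = pd.DataFrame(0, index=patches, columns=codes, dtype="int64")
        for code in codes:
            col = f"{prefix}_{code}"
            if col in df.columns:
                present = df.groupby("patch_id", sort=False)[col].max()
                mat[code] = present.reindex(patches).fillna(0).astype("int64")
        frames[stream] = mat
    return StreamPresence(stim=frames["stimulus"], ta=frames["think_aloud"], hci=frames["hci"])


@dataclass
class ScentMatrix:
    """Derived-variable values (patches × codes, in {-1, 0, +1}) with totals."""

    values: pd.DataFrame
    max_scent: int

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("scent matrix needs at least one patch")
        if not np.isin(self.values.to_numpy(), (-1, 0, 1)).all():
            raise ValueError("derived-variable values must be in {-1, 0, +1}")

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "ScentMatrix":
        """Wrap an already-derived matrix; maximum = one point per cell."""
        return cls(values=values, max_scent=int(values.size))

    @property
    def column_sums(self) -> pd.Series:
        return self.values.sum(axis=0)

    @property
    def grand_sum(self) -> int:
        return int(self.values.to_numpy().sum())

    @property
    def normalized(self) -> float:
        """Information scent in [-1, 1]: grand sum over maximum."""
        return self.grand_sum / self.max_scent


def scent_matrix(presence: StreamPresence, max_mode: str = "all_cells") -> ScentMatrix:
    """Element-wise derived variable over aligned presence frames.

    ``max_mode`` sets the normalizing maximum: ``"all_cells"`` (default,
    patches × codes — each cell can contribute at most +1) or
    ``"stim_present"`` (only cells whose stimulus occurred, letting richer
    patches weigh more).
    """
    stim = presence.stim.to_numpy()
    engaged = (presence.ta.to_numpy() | presence.hci.to_numpy()).astype(int)
    vals = stim * (2 * engaged - 1)  # present: +1 engaged / -1 not; absent: 0
    values = pd.DataFrame(vals, index=presence.stim.index, columns=presence.stim.columns)
    if max_mode == "all_cells":
        max_scent = int(values.size)
    elif max_mode == "stim_present":
        max_scent = int(stim.sum())
    else:
        raise ValueError(f"unknown max_mode {max_mode!r}")
    return ScentMatrix(values=values, max_scent=max_scent)


def scent_trajectory(matrix: ScentMatrix) -> pd.DataFrame:
    """Per-patch scent increments and their cumulative sum (for line graphs);
    the per-cell grid stays available on the matrix itself for heat maps."""
    inc = matrix.values.sum(axis=1)
    return pd.DataFrame(
        {"increment": inc, "cumulative": inc.cumsum()}, index=matrix.values.index
    )


@dataclass
class FrequencyProfile:
    """Normalized code frequencies: per case in [0, 1], summed per subsample."""

    per_case: pd.DataFrame  # cases × codes
    per_group: pd.DataFrame  # groups × codes (sum over member cases)


def code_frequencies(
    ds: UnifiedDataset, codes: list[str] | None = None, group_col: str = "groupID"
) -> FrequencyProfile:
    """Binarize code occurrence per patch, normalize by patches visited.

    Per case and code: (number of patches where the code occurs) divided by
    (number of patches visited).  Subsample values are sums over member
    cases.  A case with no visited patches is an error.
    """
    codes = codes if codes is not None else ds.code_columns
    df = ds.df[ds.df["patch_id"] != ""]
    case_rows = {}
    groups = {}
    for case, case_df in ds.df.groupby("caseID", sort=True):
        visited = case_df.loc[case_df["patch_id"] != "", "patch_id"].nunique()
        if visited == 0:
            raise ValueError(f"case {case!r} visited zero patches")
        sub = df[df["caseID"] == case]
        per_patch = sub.groupby("patch_id", sort=False)[codes].max()
        case_rows[case] = per_patch.sum(axis=0) / visited
        groups[case] = case_df[group_col].iloc[0] if group_col in case_df else ""
    per_case = pd.DataFrame.from_dict(case_rows, orient="index")[codes].astype(float)
    per_group = per_case.groupby(pd.Series(groups)).sum()
    return FrequencyProfile(per_case=per_case, per_group=per_group)


def cohens_kappa(r1, r2) -> float:
    """Cohen's kappa for two raters' labelings of the same items.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the raters' marginal label distributions.
    When chance agreement is 1 (both raters constant on one label), the
    statistic is undefined; perfect agreement returns a flagged 1.0.
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"ratings must be equal-length 1-D, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("no items rated")
    p_o = float(np.mean(a == b))
    labels = np.union1d(a, b)
    p1 = np.array([np.mean(a == lab) for lab in labels])
    p2 = np.array([np.mean(b == lab) for lab in labels])
    p_e = float(p1 @ p2)
    if p_e >= 1.0:
        if p_o == 1.0:
            warnings.warn("chance agreement is 1; kappa undefined, returning 1.0")
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 without perfect agreement")
    return (p_o - p_e) / (1 - p_e)


def intra_rater_kappa(
    first_pass, second_pass, checkpoints: tuple[float, ...] = (0.5, 1.0)
) -> dict[float, float]:
    """Consistency of one rater re-coding the corpus: kappa over the first
    fraction of items at each checkpoint (defaults: half and full corpus)."""
    a = np.asarray(first_pass)
    b = np.asarray(second_pass)
    out = {}
    for frac in checkpoints:
        if not 0 < frac <= 1:
            raise ValueError(f"checkpoint {frac} outside (0, 1]")
        n = max(1, int(round(frac * a.size)))
        out[frac] = cohens_kappa(a[:n], b[:n])
    return out
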