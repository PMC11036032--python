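"""Anchor-based alignment of data streams and the unified tabular dataset.

Anchors are text strings embedded in every stream at patch transitions.
Alignment slices each stream into inter-anchor intervals and attributes
codes from the secondary streams (HCI, screen content) to the matching
interval of the primary stream (the think-aloud).  The unified dataset has
one row per primary-stream utterance and one binary column per code per
stream, plus case and patch attributes in categorical form.

Secondary-stream codes are attributed at interval granularity: the binary
indicator is set on the first primary row of the interval, which keeps
columns 0/1 and makes total code mass (counted as distinct
(interval, code) pairs per secondary stream) exactly conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .rock_io import CaseAttributes, CodedSource, PatchAttributes

__all__ = [
    "AlignedCase",
    "UnifiedDataset",
    "AlignmentError",
    "align_streams",
    "build_unified_dataset",
    "concat_datasets",
    "export_csv",
    "read_csv",
    "to_long",
]

#: column prefix per stream; code column "TA_Code_A" = code Code_A in think-aloud
STREAM_PREFIX = {"think_aloud": "TA", "hci": "HCI", "stimulus": "STIM"}

CASE_ATTR_COLS = [
    "caseID", "groupID", "sex", "gender", "ethnicity", "race",
    "country", "education", "pol_aff",
]
PATCH_ATTR_COLS = ["patch_id", "patchType", "patchTag", "domain", "patch_start", "patch_end"]
TEXT_COLS = ["uid", "text_think_aloud", "text_hci", "text_stimulus"]


class AlignmentError(ValueError):
    pass


@dataclass
class AlignedCase:
    """Streams of one case sliced into matched inter-anchor intervals."""

    case_id: str
    primary: CodedSource
    secondaries: list[CodedSource]
    #: anchor id -> {stream: utterance position of the anchor in that stream}
    anchor_map: dict[str, dict[str, int]]
    #: anchor ids in primary order
    anchor_order: list[str] = field(default_factory=list)

    def n_intervals(self) -> int:
        return len(self.anchor_order) + 1

    def interval_slices(self, source: CodedSource) -> list[slice]:
        """Utterance slices of ``source`` for each inter-anchor interval."""
        n = len(source.utterances)
        bounds = [0]
        prev = 0
        missing_fill: list[int] = []
        for aid in self.anchor_order:
            pos = self.anchor_map[aid].get(source.stream)
            if pos is None:
                missing_fill.append(len(bounds))
                bounds.append(-1)  # filled from the next known boundary
            else:
                bounds.append(pos)
                prev = pos
        bounds.append(n)
        # back-fill boundaries for anchors this stream lacks
        for i in range(len(bounds) - 2, 0, -1):
            if bounds[i] == -1:
                bounds[i] = bounds[i + 1]
        return [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _anchor_ids(source: CodedSource) -> list[str]:
    ids = [aid for aid, _ in source.anchors]
    if len(set(ids)) != len(ids):
        dup = next(a for a in ids if ids.count(a) > 1)
        raise AlignmentError(f"{source.stream}: duplicate anchor {dup!r}")
    return ids


def align_streams(primary: CodedSource, secondaries: list[CodedSource]) -> AlignedCase:
    """Match inter-anchor intervals of the secondary streams onto the primary.

    Every anchor appearing in a secondary must exist in the primary, in the
    same relative order; violations raise :class:`AlignmentError`.
    """
    if primary.stream != "think_aloud":
        warnings.warn(f"primary stream is {primary.stream!r}, not think_aloud")
    p_ids = _anchor_ids(primary)
    anchor_map: dict[str, dict[str, int]] = {
        aid: {primary.stream: pos} for aid, pos in primary.anchors
    }
    rank = {aid: i for i, aid in enumerate(p_ids)}
    for sec in secondaries:
        s_ids = _anchor_ids(sec)
        for aid in s_ids:
            if aid not in rank:
                raise AlignmentError(
                    f"anchor {aid!r} in {sec.stream} stream missing from primary"
                )
        for a, b in zip(s_ids, s_ids[1:]):
            if rank[a] > rank[b]:
                raise AlignmentError(
                    f"{sec.stream}: anchors ({a!r}, {b!r}) inverted relative to primary"
                )
        for aid, pos in sec.anchors:
            anchor_map[aid][sec.stream] = pos
    aligned = AlignedCase(
        case_id=primary.case_id,
        primary=primary,
        secondaries=list(secondaries),
        anchor_map=anchor_map,
        anchor_order=p_ids,
    )
    _check_patch_anchor_agreement(aligned)
    return aligned


def _check_patch_anchor_agreement(aligned: AlignedCase) -> None:
    """Anchors are placed at patch transitions; warn if the primary stream's
    patch ids change anywhere other than an interval boundary."""
    slices = aligned.interval_slices(aligned.primary)
    utts = aligned.primary.utterances
    for sl in slices:
        pids = {u.patch_id for u in utts[sl]}
        if len(pids) > 1:
            warnings.warn(
                f"{aligned.case_id}: patch ids {sorted(map(str, pids))} change "
                "inside one anchor interval"
            )


def build_unified_dataset(
    aligned: AlignedCase,
    case_attrs: CaseAttributes | None = None,
    patch_attrs: list[PatchAttributes] | None = None,
    strict: bool = True,
    collapse_streams: bool = False,
) -> "UnifiedDataset":
    """Build the unified table: one row per primary utterance; columns are
    case attributes, patch attributes, raw text per stream, and one binary
    column per code per stream (or per code, with ``collapse_streams``)."""
    patch_attrs = patch_attrs or []
    patch_by_pid = {p.pid: p for p in patch_attrs}
    referenced = set(aligned.primary.patch_ids())
    for sec in aligned.secondaries:
        referenced |= set(sec.patch_ids())
    missing = sorted(referenced - set(patch_by_pid))
    if missing and strict:
        raise AlignmentError(f"missing patch attributes for: {', '.join(missing)}")

    utts = aligned.primary.utterances
    n = len(utts)
    p_slices = aligned.interval_slices(aligned.primary)
    interval_first_row = [sl.start for sl in p_slices]
    row_interval = []
    for i, sl in enumerate(p_slices):
        row_interval.extend([i] * (sl.stop - sl.start))

    rows: list[dict] = []
    for u in utts:
        row = {c: "" for c in CASE_ATTR_COLS + PATCH_ATTR_COLS + TEXT_COLS}
        if case_attrs is not None:
            row["caseID"] = case_attrs.caseID
            row["groupID"] = case_attrs.groupID
            for c in CASE_ATTR_COLS[2:]:
                row[c] = getattr(case_attrs, c)
        else:
            row["caseID"] = aligned.case_id
        row["uid"] = u.uid
        row["patch_id"] = u.patch_id or ""
        pa = patch_by_pid.get(u.patch_id or "")
        if pa is not None:
            row["patchType"] = pa.patchType
            row["patchTag"] = pa.patchTag
            row["domain"] = pa.domain
            row["patch_start"] = pa.start
            row["patch_end"] = pa.end
        row["text_think_aloud"] = u.text
        rows.append(row)
    df = pd.DataFrame(rows, columns=CASE_ATTR_COLS + PATCH_ATTR_COLS + TEXT_COLS)

    code_cols: dict[str, list[int]] = {}

    def col_name(stream: str, code: str) -> str:
        return code if collapse_streams else f"{STREAM_PREFIX[stream]}_{code}"

    # primary codes at utterance granularity
    for i, u in enumerate(utts):
        for code in u.codes:
            col = col_name("think_aloud", code)
            code_cols.setdefault(col, [0] * n)[i] = 1
    # secondary codes at interval granularity, set on the interval's first row
    for sec in aligned.secondaries:
        s_slices = aligned.interval_slices(sec)
        text_col = f"text_{sec.stream}"
        for k, sl in enumerate(s_slices):
            seg = sec.utterances[sl]
            if not seg:
                continue
            if k >= len(interval_first_row) or interval_first_row[k] >= n:
                warnings.warn(
                    f"{aligned.case_id}/{sec.stream}: interval {k} has no primary "
                    "rows; its codes are dropped"
                )
                continue
            r = interval_first_row[k]
            texts = [u.text for u in seg if u.text]
            if texts:
                df.loc[r, text_col] = " ".join(texts)
            for u in seg:
                for code in u.codes:
                    col = col_name(sec.stream, code)
                    code_cols.setdefault(col, [0] * n)[r] = 1
    for col in sorted(code_cols):
        df[col] = pd.Series(code_cols[col], dtype="int64")
    df["_interval"] = pd.Series(row_interval, dtype="int64") if n else pd.Series(dtype="int64")
    return UnifiedDataset(df=df)


@dataclass
class UnifiedDataset:
    """Tabular merge of all streams and attributes for one or more cases."""

    df: pd.DataFrame

    @property
    def code_columns(self) -> list[str]:
        fixed = set(CASE_ATTR_COLS + PATCH_ATTR_COLS + TEXT_COLS + ["_interval"])
        return [c for c in self.df.columns if c not in fixed]

    def stream_code_columns(self, stream: str) -> list[str]:
        prefix = STREAM_PREFIX[stream] + "_"
        return [c for c in self.code_columns if c.startswith(prefix)]

    def code_mass(self) -> int:
        """Total number of set binary code cells."""
        cols = self.code_columns
        return int(self.df[cols].to_numpy().sum()) if cols else 0

    def cases(self) -> list[str]:
        return list(dict.fromkeys(self.df["caseID"]))


def concat_datasets(datasets: list[UnifiedDataset]) -> UnifiedDataset:
    """Stack several cases' tables; absent code columns fill with 0."""
    if not datasets:
        return UnifiedDataset(df=pd.DataFrame(columns=CASE_ATTR_COLS + PATCH_ATTR_COLS + TEXT_COLS))
    frames = [d.df for d in datasets]
    all_codes = sorted({c for d in datasets for c in d.code_columns})
    out = pd.concat(frames, ignore_index=True)
    for c in all_codes:
        if c in out.columns:
            out[c] = out[c].fillna(0).astype("int64")
    fixed = CASE_ATTR_COLS + PATCH_ATTR_COLS + TEXT_COLS
    cols = fixed + all_codes + (["_interval"] if "_interval" in out.columns else [])
    out = out[cols]
    for c in fixed:
        out[c] = out[c].fillna("")
    if "_interval" in out.columns:
        out["_interval"] = out["_interval"].fillna(0).astype("int64")
    return UnifiedDataset(df=out)


def export_csv(ds: UnifiedDataset, path) -> None:
    """RFC-4180 CSV export; :func:`read_csv` reproduces the table exactly."""
    ds.df.to_csv(path, index=False, encoding="utf-8")


def read_csv(path) -> UnifiedDataset:
    df = pd.read_csv(path, keep_default_na=False, encoding="utf-8")
    fixed = set(CASE_ATTR_COLS + PATCH_ATTR_COLS + TEXT_COLS)
    for c in df.columns:
        if c in fixed:
            df[c] = df[c].astype(str)
        else:
            df[c] = pd.to_numeric(df[c]).astype("int64")
    return UnifiedDataset(df=df)


def to_long(ds: UnifiedDataset) -> pd.DataFrame:
    """Tidy export: one row per (utterance, code-column) with value 1."""
    cols = ds.code_columns
    if not cols:
        return pd.DataFrame(columns=["caseID", "uid", "patch_id", "code"])
    melted = ds.df.melt(
        id_vars=["caseID", "uid", "patch_id"],
        value_vars=cols,
        var_name="code",
        value_name="present",
    )
    return melted[melted["present"] == 1].drop(columns="present").reset_index(drop=True)
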