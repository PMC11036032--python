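"""Reading, writing and merging plain-text coded sources.

Coded sources are UTF-8 plain-text files with one utterance (sentence) per
line.  Inline double-bracket tokens carry the machine-readable layer:

* ``[[Code_A]]`` — a qualitative code attached to the utterance;
* ``[[patch_001_2]]`` — a patch (class-instance) identifier; once seen it
  applies to every following utterance until the next patch identifier;
* ``[[anchor:a1]]`` — a cross-stream alignment anchor;
* ``[[uid=tt_3]]`` — an explicit utterance identifier (auto-generated
  deterministically from case, stream and line index when absent).

Lines consisting only of tokens update parser state (active patch, pending
anchor) but produce no utterance.  YAML attribute blocks fenced by ``---``
describe cases and patches and may be embedded in a source or kept in
standalone files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "Utterance",
    "CodedSource",
    "CaseAttributes",
    "PatchAttributes",
    "ParseError",
    "MergeError",
    "parse_source",
    "write_source",
    "parse_attributes",
    "merge_coded_sources",
]

STREAMS = ("think_aloud", "hci", "stimulus")
PATCH_TYPES = ("engine", "SERP", "page", "file")
#: accepted group labels; "E"/"N" are canonicalised to expert/novice
GROUP_VOCAB = {"E": "expert", "N": "novice", "expert": "expert", "novice": "novice"}

TOKEN_RE = re.compile(r"\[\[([^\[\]]+)\]\]")
DEFAULT_PATCH_RE = re.compile(r"patch_[0-9]+_[0-9]+\Z")
ANCHOR_RE = re.compile(r"anchor:(\S+)\Z")
UID_RE = re.compile(r"uid=(\S+)\Z")
LABEL_RE = re.compile(r"[A-Za-z0-9_]+\Z")
CASE_ID_RE = re.compile(r"case_[0-9]+\Z")
PATCH_PID_RE = re.compile(r"patch_[0-9]+_[0-9]+\Z")
TIME_RE = re.compile(r"([0-9]+):([0-9]{2})\Z")


class ParseError(ValueError):
    """Malformed source text; carries a 1-based line number when known."""


class MergeError(ValueError):
    """Incompatible coder versions of the same source."""


@dataclass
class Utterance:
    uid: str
    line_index: int
    text: str
    codes: set[str] = field(default_factory=set)
    patch_id: str | None = None
    anchor_id: str | None = None


@dataclass
class CodedSource:
    """One data stream of one case: an ordered list of utterances.

    ``anchors`` records every anchor as ``(anchor_id, position)`` where
    position is the number of utterances emitted before the anchor; the
    alignment layer slices utterance intervals between consecutive anchors.
    """

    case_id: str
    stream: str
    utterances: list[Utterance] = field(default_factory=list)
    anchors: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise ValueError(f"unknown stream {self.stream!r}; expected one of {STREAMS}")

    def codes(self) -> set[str]:
        out: set[str] = set()
        for u in self.utterances:
            out |= u.codes
        return out

    def patch_ids(self) -> list[str]:
        """Distinct patch ids in order of first appearance."""
        seen: list[str] = []
        for u in self.utterances:
            if u.patch_id is not None and u.patch_id not in seen:
                seen.append(u.patch_id)
        return seen


@dataclass
class CaseAttributes:
    caseID: str
    groupID: str
    sex: str = ""
    gender: str = ""
    ethnicity: str = ""
    race: str = ""
    country: str = ""
    education: str = ""
    pol_aff: str = ""

    def __post_init__(self) -> None:
        if not CASE_ID_RE.match(self.caseID):
            raise ValueError(f"caseID {self.caseID!r} does not match case_<digits>")
        if self.groupID not in GROUP_VOCAB:
            raise ValueError(
                f"groupID {self.groupID!r} not in closed vocabulary {sorted(GROUP_VOCAB)}"
            )
        self.groupID = GROUP_VOCAB[self.groupID]


@dataclass
class PatchAttributes:
    pid: str
    patchType: str
    patchTag: str = ""
    domain: str = ""
    start: str = "00:00"
    end: str = "00:00"

    def __post_init__(self) -> None:
        if not PATCH_PID_RE.match(self.pid):
            raise ValueError(f"pid {self.pid!r} does not match patch_<case>_<ordinal>")
        canonical = {"serp": "SERP", "engine": "engine", "page": "page", "file": "file"}
        if self.patchType.lower() not in canonical:
            raise ValueError(f"patchType {self.patchType!r} not one of {PATCH_TYPES}")
        self.patchType = canonical[self.patchType.lower()]
        if _seconds(self.start) > _seconds(self.end):
            raise ValueError(f"patch {self.pid}: start {self.start} after end {self.end}")

    @property
    def case_id(self) -> str:
        return "case_" + self.pid.split("_")[1]

    @property
    def ordinal(self) -> int:
        return int(self.pid.split("_")[2])


def _seconds(stamp: str) -> int:
    m = TIME_RE.match(stamp)
    if not m:
        raise ValueError(f"bad mm:ss timestamp {stamp!r}")
    return int(m.group(1)) * 60 + int(m.group(2))


def _classify_token(tok: str, patch_re: re.Pattern) -> tuple[str, str]:
    """Classify a bracket-token body as patch / anchor / uid / code."""
    tok = tok.strip()
    if patch_re.match(tok):
        return "patch", tok
    m = ANCHOR_RE.match(tok)
    if m:
        return "anchor", m.group(1)
    m = UID_RE.match(tok)
    if m:
        return "uid", m.group(1)
    if LABEL_RE.match(tok):
        return "code", tok
    raise ParseError(f"malformed bracket token [[{tok}]]")


def parse_source(
    text: str,
    stream: str,
    case_id: str = "case_000",
    patch_pattern: str | re.Pattern | None = None,
) -> CodedSource:
    """Parse a plain-text coded source into a :class:`CodedSource`.

    Empty lines and YAML attribute blocks are skipped; token-only lines
    update parser state without producing an utterance.  Raises
    :class:`ParseError` with the offending 1-based line number for malformed
    tokens or duplicate explicit uids.
    """
    patch_re = re.compile(patch_pattern) if patch_pattern is not None else DEFAULT_PATCH_RE
    src = CodedSource(case_id=case_id, stream=stream)
    active_patch: str | None = None
    pending_anchor: str | None = None
    seen_uids: set[str] = set()
    in_yaml = False

    for line_index, raw in enumerate(text.splitlines()):
        line = raw.rstrip("\r")
        stripped = line.strip()
        if stripped == "---":
            in_yaml = not in_yaml
            continue
        if in_yaml or not stripped:
            continue

        codes: set[str] = set()
        uid: str | None = None
        anchor_here: str | None = None
        try:
            for tok in TOKEN_RE.findall(line):
                kind, value = _classify_token(tok, patch_re)
                if kind == "patch":
                    active_patch = value
                elif kind == "anchor":
                    anchor_here = value
                elif kind == "uid":
                    uid = value
                else:
                    codes.add(value)
        except ParseError as exc:
            raise ParseError(f"line {line_index + 1}: {exc}") from None
        if "[[" in TOKEN_RE.sub("", line) or "]]" in TOKEN_RE.sub("", line):
            raise ParseError(f"line {line_index + 1}: unbalanced bracket token")

        clean = TOKEN_RE.sub("", line).strip()
        clean = re.sub(r"\s{2,}", " ", clean)
        if anchor_here is not None:
            src.anchors.append((anchor_here, len(src.utterances)))
            pending_anchor = anchor_here if clean or codes else None

        if not clean and not codes and uid is None:
            continue  # token-only line: state updated, no utterance

        if uid is None:
            uid = f"{case_id}-{stream}-{line_index}"
        if uid in seen_uids:
            raise ParseError(f"line {line_index + 1}: duplicate uid {uid!r}")
        seen_uids.add(uid)
        src.utterances.append(
            Utterance(
                uid=uid,
                line_index=line_index,
                text=clean,
                codes=codes,
                patch_id=active_patch,
                anchor_id=pending_anchor,
            )
        )
        pending_anchor = None
    return src


def write_source(source: CodedSource, include_uids: bool = False) -> str:
    """Render a source back to canonical text (single space before tokens).

    Emits a patch-identifier token on the first utterance of each patch and
    an anchor token at each recorded anchor position.
    """
    anchor_at: dict[int, list[str]] = {}
    for aid, pos in source.anchors:
        anchor_at.setdefault(pos, []).append(aid)
    lines: list[str] = []
    current_patch: str | None = None
    for i, u in enumerate(source.utterances):
        for aid in anchor_at.get(i, ()):
            if u.anchor_id == aid:
                continue  # emitted inline below
            lines.append(f"[[anchor:{aid}]]")
        parts = [u.text] if u.text else []
        for code in sorted(u.codes):
            parts.append(f"[[{code}]]")
        if u.patch_id is not None and u.patch_id != current_patch:
            parts.append(f"[[{u.patch_id}]]")
            current_patch = u.patch_id
        if u.anchor_id is not None:
            parts.append(f"[[anchor:{u.anchor_id}]]")
        if include_uids:
            parts.append(f"[[uid={u.uid}]]")
        lines.append(" ".join(parts))
    tail = len(source.utterances)
    for aid in anchor_at.get(tail, ()):
        lines.append(f"[[anchor:{aid}]]")
    return "\n".join(lines) + ("\n" if lines else "")


def parse_attributes(yaml_text: str) -> list[CaseAttributes | PatchAttributes]:
    """Parse one or more ``---``-fenced YAML attribute documents.

    Each document holds a top-level ``ROCK_attributes`` list; entries with a
    ``caseID`` key become :class:`CaseAttributes`, entries with a ``pid`` key
    become :class:`PatchAttributes`.
    """
    out: list[CaseAttributes | PatchAttributes] = []
    for doc in yaml.safe_load_all(yaml_text):
        if doc is None:
            continue
        if not isinstance(doc, dict) or "ROCK_attributes" not in doc:
            raise ParseError("attribute document lacks top-level ROCK_attributes key")
        entries = doc["ROCK_attributes"] or []
        for i, entry in enumerate(entries):
            if not isinstance(entry, dict):
                raise ParseError(f"entry {i}: not a mapping")
            entry = {k: ("" if v is None else str(v)) for k, v in entry.items()}
            if "caseID" in entry:
                out.append(CaseAttributes(**entry))
            elif "pid" in entry:
                out.append(PatchAttributes(**entry))
            else:
                raise ParseError(f"entry {i}: missing identifier key (caseID or pid)")
    return out


def merge_coded_sources(versions: list[CodedSource]) -> CodedSource:
    """Merge several coders' versions of one source by utterance identifier.

    Code sets are unioned per uid; text comes from the first version; patch
    and anchor assignments must agree across versions.
    """
    if not versions:
        raise MergeError("no versions to merge")
    first = versions[0]
    for v in versions[1:]:
        if (v.case_id, v.stream) != (first.case_id, first.stream):
            raise MergeError(
                f"cannot merge {v.case_id}/{v.stream} into {first.case_id}/{first.stream}"
            )
        uids_a = [u.uid for u in first.utterances]
        uids_b = [u.uid for u in v.utterances]
        if uids_a != uids_b:
            divergent = next((a for a, b in zip(uids_a, uids_b) if a != b), None)
            if divergent is None:  # one sequence is a prefix of the other
                longer = uids_a if len(uids_a) > len(uids_b) else uids_b
                divergent = longer[min(len(uids_a), len(uids_b))]
            raise MergeError(f"uid sequences diverge at {divergent!r}")
    merged_utts = []
    for i, u in enumerate(first.utterances):
        codes = set(u.codes)
        for v in versions[1:]:
            other = v.utterances[i]
            if other.patch_id != u.patch_id:
                raise MergeError(
                    f"conflicting patch_id at uid {u.uid!r}: "
                    f"{u.patch_id!r} vs {other.patch_id!r}"
                )
            if other.anchor_id != u.anchor_id:
                raise MergeError(f"conflicting anchor at uid {u.uid!r}")
            codes |= other.codes
        merged_utts.append(replace(u, codes=codes))
    return CodedSource(
        case_id=first.case_id,
        stream=first.stream,
        utterances=merged_utts,
        anchors=list(first.anchors),
    )
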