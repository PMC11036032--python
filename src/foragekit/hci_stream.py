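"""Human–computer-interaction transcripts.

Each observed interaction is one line in the ``Action | Content | Location``
template, optionally prefixed with an ordinal identifier (``HCI1:``).  The
action vocabulary is closed (type, click, scroll, hover, highlight); the
location vocabulary is pluggable because SERP-element taxonomies vary.
Patch-identifier and anchor tokens are the same as in coded sources, so an
HCI transcript can be converted to a :class:`~foragekit.rock_io.CodedSource`
and participate in code-level analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .rock_io import (
    ANCHOR_RE,
    DEFAULT_PATCH_RE,
    LABEL_RE,
    TOKEN_RE,
    CodedSource,
    ParseError,
    Utterance,
)

__all__ = [
    "HCIEvent",
    "ACTIONS",
    "DEFAULT_LOCATIONS",
    "VocabularyError",
    "parse_hci_line",
    "parse_hci_source",
    "hci_to_source",
    "format_hci_line",
]

ACTIONS = ("type", "click", "scroll", "hover", "highlight")

# minimal default SERP/website location set; callers may extend it
DEFAULT_LOCATIONS = (
    "search_bar",
    "SERP_organic_result",
    "SERP_ad",
    "SERP_knowledge_panel",
    "page",
    "hyperlink",
    "menu",
)

_PREFIX_RE = re.compile(r"\s*HCI(\d+)\s*:\s*", re.IGNORECASE)
_PIPE_SPLIT_RE = re.compile(r"(?<!\\)\|")


class VocabularyError(ParseError):
    """Token outside a closed vocabulary."""


@dataclass
class HCIEvent:
    event_id: str  # "HCI1", "HCI2", ...
    action: str
    content: str
    location: str
    patch_id: str | None = None
    anchor_id: str | None = None
    codes: set[str] = field(default_factory=set)  # qualitative codes on the event

    @property
    def ordinal(self) -> int:
        return int(self.event_id[3:])


def parse_hci_line(line: str, ordinal: int = 1) -> HCIEvent:
    """Parse one ``Action | Content | Location`` line.

    ``ordinal`` supplies the event number when the line carries no ``HCI<n>:``
    prefix.  Pipes inside a field must be escaped as ``\\|``.
    """
    m = _PREFIX_RE.match(line)
    if m:
        ordinal = int(m.group(1))
        line = line[m.end():]
    fields = _PIPE_SPLIT_RE.split(line)
    if len(fields) != 3:
        raise ParseError(
            f"expected 'Action | Content | Location' (2 pipes), got {len(fields) - 1} "
            f"in {line.strip()!r}"
        )
    action, content, location = (f.replace("\\|", "|").strip() for f in fields)
    action = action.lower()
    if action not in ACTIONS:
        raise VocabularyError(f"action {action!r} not in {ACTIONS}")
    return HCIEvent(event_id=f"HCI{ordinal}", action=action, content=content, location=location)


def format_hci_line(event: HCIEvent) -> str:
    esc = lambda s: s.replace("|", "\\|")
    line = f"{event.event_id}: {event.action} | {esc(event.content)} | {esc(event.location)}"
    for code in sorted(event.codes):
        line += f" [[{code}]]"
    return line


def parse_hci_source(
    text: str,
    case_id: str = "case_000",
    patch_pattern: str | re.Pattern | None = None,
) -> list[HCIEvent]:
    """Parse a full HCI transcript, tracking patch and anchor tokens.

    Token-only lines (``[[patch_001_2]]``, ``[[anchor:a2]]``) update the
    active patch / pending anchor exactly as in coded-source parsing.
    """
    patch_re = re.compile(patch_pattern) if patch_pattern is not None else DEFAULT_PATCH_RE
    events: list[HCIEvent] = []
    active_patch: str | None = None
    pending_anchor: str | None = None
    ordinal = 1
    for line_index, raw in enumerate(text.splitlines()):
        line = raw.strip()
        if not line:
            continue
        tokens = TOKEN_RE.findall(line)
        rest = TOKEN_RE.sub("", line).strip()
        codes: set[str] = set()
        for tok in tokens:
            tok = tok.strip()
            if patch_re.match(tok):
                active_patch = tok
            elif ANCHOR_RE.match(tok):
                pending_anchor = ANCHOR_RE.match(tok).group(1)
            elif LABEL_RE.match(tok):
                codes.add(tok)  # qualitative code applied to this event
            else:
                raise ParseError(f"line {line_index + 1}: unexpected token [[{tok}]]")
        if not rest:
            continue
        try:
            ev = parse_hci_line(rest, ordinal=ordinal)
        except ParseError as exc:
            raise type(exc)(f"line {line_index + 1}: {exc}") from None
        ev.patch_id = active_patch
        ev.anchor_id = pending_anchor
        ev.codes = codes
        pending_anchor = None
        events.append(ev)
        ordinal = ev.ordinal + 1
    return events


def hci_to_source(events: list[HCIEvent], case_id: str = "case_000") -> CodedSource:
    """Represent HCI events as a coded source so the stream joins code-level
    analyses: each event becomes one utterance coded ``act_<action>`` and
    ``loc_<location>``."""
    src = CodedSource(case_id=case_id, stream="hci")
    for i, ev in enumerate(events):
        if ev.anchor_id is not None:
            src.anchors.append((ev.anchor_id, len(src.utterances)))
        codes = {f"act_{ev.action}"} | set(ev.codes)
        if ev.location:
            codes.add("loc_" + re.sub(r"[^A-Za-z0-9_]", "_", ev.location))
        src.utterances.append(
            Utterance(
                uid=f"{case_id}-hci-{ev.event_id}",
                line_index=i,
                text=ev.content,
                codes=codes,
                patch_id=ev.patch_id,
                anchor_id=ev.anchor_id,
            )
        )
    return src
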