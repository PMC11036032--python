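"""Synthetic three-stream foraging sessions with known ground truth.

The generator emulates the study design the package targets: two subsamples
(expert and novice, ten cases each) performing a 10-minute online search
task over a sequence of information patches.  Patch content types follow a
first-order Markov chain seeded at a search engine; each patch's stimulus
stream emits codes with a type-dependent probability; engagement with a
present stimulus (its code surfacing in the think-aloud or HCI stream) is
Bernoulli with a group-specific probability — the expert/novice engagement
gap is the configured ground-truth effect that downstream scent comparisons
should recover.

Think-aloud text is template-generated filler: only the token structure
(codes, patch identifiers, anchors) matters to downstream computation.
Output parses cleanly through :mod:`~foragekit.rock_io` /
:mod:`~foragekit.hci_stream` and aligns through :mod:`~foragekit.alignment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hci_stream import ACTIONS, DEFAULT_LOCATIONS
from .rock_io import PATCH_TYPES, CaseAttributes, PatchAttributes

__all__ = ["SimConfig", "SessionBundle", "generate_session", "generate_corpus",
           "ground_truth", "sample_chain", "write_fixture_dir"]

DEFAULT_CODES = (
    "Rel_Topic",
    "Rel_Recency",
    "Trust_AuthAff",
    "Trust_Domain",
    "Und_Mechanism",
    "Und_Evidence",
)

#: row-stochastic patch-type transitions (order: engine, SERP, page, file).
#: Sessions start at a search engine; engines lead to SERPs, SERPs mostly to
#: pages, pages bounce back to SERPs or on to further pages/files.
DEFAULT_TRANSITIONS = np.array(
    [
        [0.05, 0.85, 0.08, 0.02],
        [0.10, 0.10, 0.70, 0.10],
        [0.10, 0.40, 0.40, 0.10],
        [0.15, 0.45, 0.35, 0.05],
    ]
)
DEFAULT_INITIAL = np.array([1.0, 0.0, 0.0, 0.0])

_FILLER = (
    "Okay let me look at this.",
    "This seems interesting.",
    "I am not sure about this one.",
    "Let me read a bit more here.",
    "That is what I expected to see.",
    "Hmm, moving on now.",
)

_DOMAINS = {
    "engine": ("google.com", "bing.com", "duckduckgo.com"),
    "SERP": ("google.com", "bing.com"),
    "page": ("cdc.gov", "who.int", "wikipedia.org", "cnbc.com", "nytimes.com"),
    "file": ("ncbi.nlm.nih.gov", "who.int", "arxiv.org"),
}


@dataclass
class SimConfig:
    """Ground-truth parameters of the session generator.

    Defaults mirror the emulated study: 10 cases per subsample, patch counts
    a 10-minute task plausibly yields, and an engagement-probability gap
    between experts (0.75) and novices (0.45).
    """

    n_cases_per_group: int = 10
    codes: tuple[str, ...] = DEFAULT_CODES
    states: tuple[str, ...] = PATCH_TYPES
    initial: np.ndarray = field(default_factory=lambda: DEFAULT_INITIAL.copy())
    transitions: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    patch_count_range: tuple[int, int] = (4, 12)
    #: per-patch-type probability that any given code is present as stimulus
    stim_emission: dict[str, float] = field(
        default_factory=lambda: {"engine": 0.15, "SERP": 0.5, "page": 0.7, "file": 0.6}
    )
    #: probability a present stimulus is engaged with, by group
    engagement_prob: dict[str, float] = field(
        default_factory=lambda: {"expert": 0.75, "novice": 0.45}
    )
    #: given engagement, chance the code surfaces in the think-aloud / HCI
    p_engage_ta: float = 0.7
    p_engage_hci: float = 0.5
    utterances_per_patch: tuple[int, int] = (2, 6)
    dwell_range_s: tuple[int, int] = (5, 90)
    seed: int = 0

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.transitions.shape != (len(self.states), len(self.states)):
            raise ValueError("transition matrix shape does not match states")
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        probs = [*self.stim_emission.values(), *self.engagement_prob.values(),
                 self.p_engage_ta, self.p_engage_hci]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SessionBundle:
    """Everything generated for one case: raw stream texts plus attributes."""

    case_id: str
    group: str
    think_aloud_text: str
    hci_text: str
    stimulus_text: str
    case_attributes: CaseAttributes
    patch_attributes: list[PatchAttributes]
    #: ground truth per patch: {code: (stim, ta, hci)} presence triples
    truth: list[dict[str, tuple[int, int, int]]]


def ground_truth(cfg: SimConfig) -> dict:
    """The exact generator parameters, for recovery tests."""
    return {
        "states": tuple(cfg.states),
        "initial": cfg.initial.copy(),
        "transitions": cfg.transitions.copy(),
        "stim_emission": dict(cfg.stim_emission),
        "engagement_prob": dict(cfg.engagement_prob),
    }


def sample_chain(cfg: SimConfig, n: int, rng: np.random.Generator) -> list[str]:
    """Draw a length-``n`` state sequence from the configured Markov chain."""
    states = list(cfg.states)
    seq = [rng.choice(len(states), p=cfg.initial)]
    for _ in range(n - 1):
        seq.append(rng.choice(len(states), p=cfg.transitions[seq[-1]]))
    return [states[i] for i in seq]


def _mmss(seconds: int) -> str:
    return f"{seconds // 60:02d}:{seconds % 60:02d}"


def generate_session(
    cfg: SimConfig, case_id: str, group: str, rng: np.random.Generator | None = None
) -> SessionBundle:
    """Generate one case's aligned three-stream session.

    Anchors and patch identifiers are placed at every patch transition in
    all three streams, so alignment intervals and patches coincide.
    """
    if group not in cfg.engagement_prob:
        raise ValueError(f"group {group!r} has no engagement probability")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    case_num = case_id.split("_")[1]
    n_patches = int(rng.integers(cfg.patch_count_range[0], cfg.patch_count_range[1] + 1))
    types = sample_chain(cfg, n_patches, rng)
    p_engage = cfg.engagement_prob[group]

    ta_lines: list[str] = []
    hci_lines: list[str] = []
    stim_lines: list[str] = []
    patch_attrs: list[PatchAttributes] = []
    truth: list[dict[str, tuple[int, int, int]]] = []
    clock = 0
    hci_ordinal = 1

    for k, ptype in enumerate(types, start=1):
        pid = f"patch_{case_num}_{k}"
        anchor = f"a{case_num}_{k}"
        marker = f"[[anchor:{anchor}]] [[{pid}]]"
        for lines in (ta_lines, hci_lines, stim_lines):
            lines.append(marker)

        dwell = int(rng.integers(cfg.dwell_range_s[0], cfg.dwell_range_s[1] + 1))
        domain = str(rng.choice(_DOMAINS[ptype]))
        patch_attrs.append(
            PatchAttributes(
                pid=pid,
                patchType=ptype,
                patchTag=f"{domain.split('.')[0]} {ptype}",
                domain=domain,
                start=_mmss(clock),
                end=_mmss(clock + dwell),
            )
        )
        clock += dwell + 1

        p_stim = cfg.stim_emission[ptype]
        cell: dict[str, tuple[int, int, int]] = {}
        ta_codes: list[str] = []
        hci_codes: list[str] = []
        for code in cfg.codes:
            stim = int(rng.random() < p_stim)
            ta = hci = 0
            if stim:
                stim_lines.append(f"Element {code} visible on {ptype}. [[{code}]]")
                if rng.random() < p_engage:
                    ta = int(rng.random() < cfg.p_engage_ta)
                    hci = int(rng.random() < cfg.p_engage_hci)
                    if not (ta or hci):
                        ta = 1  # engagement must surface in at least one stream
                    if ta:
                        ta_codes.append(code)
                    if hci:
                        hci_codes.append(code)
            cell[code] = (stim, ta, hci)
        truth.append(cell)

        n_utts = int(rng.integers(cfg.utterances_per_patch[0], cfg.utterances_per_patch[1] + 1))
        n_utts = max(n_utts, 1)
        slots = rng.integers(0, n_utts, size=len(ta_codes))
        for u in range(n_utts):
            line = str(rng.choice(_FILLER))
            for code, slot in zip(ta_codes, slots):
                if slot == u:
                    line += f" [[{code}]]"
            ta_lines.append(line)

        n_events = max(1, len(hci_codes) + int(rng.integers(1, 4)))
        ev_slots = rng.integers(0, n_events, size=len(hci_codes))
        slot_codes: dict[int, list[str]] = {}
        for code, slot in zip(hci_codes, ev_slots):
            slot_codes.setdefault(int(slot), []).append(code)
        for e in range(n_events):
            action = str(rng.choice(ACTIONS))
            location = str(rng.choice(DEFAULT_LOCATIONS))
            line = f"HCI{hci_ordinal}: {action} | {ptype} element {e + 1} | {location}"
            for code in slot_codes.get(e, ()):
                line += f" [[{code}]]"
            hci_lines.append(line)
            hci_ordinal += 1

    attrs = CaseAttributes(
        caseID=case_id,
        groupID="E" if group == "expert" else "N",
        sex=str(rng.choice(("male", "female"))),
        gender=str(rng.choice(("man", "woman", "transgender"))),
        ethnicity=str(rng.choice(("no_hisp", "hisp"))),
        race=str(rng.choice(("white", "black", "asian", "AIAN"))),
        country="USA",
        education=str(rng.choice(("HS", "SC", "BA<"))),
        pol_aff=str(rng.choice(("dem", "rep", "ind", "other", "NA"))),
    )
    return SessionBundle(
        case_id=case_id,
        group=group,
        think_aloud_text="\n".join(ta_lines) + "\n",
        hci_text="\n".join(hci_lines) + "\n",
        stimulus_text="\n".join(stim_lines) + "\n",
        case_attributes=attrs,
        patch_attributes=patch_attrs,
        truth=truth,
    )


def generate_corpus(cfg: SimConfig) -> list[SessionBundle]:
    """Generate the full two-subsample corpus, deterministically from the
    config seed (experts first, then novices, sequential case numbers)."""
    rng = np.random.default_rng(cfg.seed)
    bundles = []
    n = 1
    for group in ("expert", "novice"):
        for _ in range(cfg.n_cases_per_group):
            bundles.append(generate_session(cfg, f"case_{n:03d}", group, rng))
            n += 1
    return bundles


def write_fixture_dir(bundles: list[SessionBundle], path) -> None:
    """Write a complete fixture directory consumable by the CLI: per-case
    stream files plus case and patch attribute YAML."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    case_yaml = ["---", "ROCK_attributes:"]
    patch_yaml = ["---", "ROCK_attributes:"]
    for b in bundles:
        (root / f"{b.case_id}_think_aloud.rock").write_text(b.think_aloud_text, encoding="utf-8")
        (root / f"{b.case_id}_hci.rock").write_text(b.hci_text, encoding="utf-8")
        (root / f"{b.case_id}_stimulus.rock").write_text(b.stimulus_text, encoding="utf-8")
        a = b.case_attributes
        case_yaml.append(f'  - caseID: "{a.caseID}"')
        for f_ in ("groupID", "sex", "gender", "ethnicity", "race", "country",
                   "education", "pol_aff"):
            case_yaml.append(f'    {f_}: "{getattr(a, f_)}"')
        for p in b.patch_attributes:
            patch_yaml.append(f'  - patchTag: "{p.patchTag}"')
            patch_yaml.append(f'    domain: "{p.domain}"')
            patch_yaml.append(f'    pid: "{p.pid}"')
            patch_yaml.append(f'    patchType: "{p.patchType}"')
            patch_yaml.append(f'    start: "{p.start}"')
            patch_yaml.append(f'    end: "{p.end}"')
    case_yaml.append("---")
    patch_yaml.append("---")
    (root / "case_attributes.yaml").write_text("\n".join(case_yaml) + "\n", encoding="utf-8")
    (root / "patch_attributes.yaml").write_text("\n".join(patch_yaml) + "\n", encoding="utf-8")
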