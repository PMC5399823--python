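"""Combinatorial model of HpaII/MspI restriction-site methylation events.

The 5'-CCGG-3' site recognised by the isoschizomers HpaII and MspI carries
four cytosines: an external and an internal one on each strand.  The two
enzymes tolerate methylation differently — HpaII cuts sites that are
unmethylated or carry a single methylated *external* cytosine, while MspI
cuts sites whose external cytosines are unmethylated, regardless of internal
methylation.  Comparing the EcoRI/HpaII and EcoRI/MspI band patterns of a
control sample with those of a stressed sample therefore yields a four-bit
presence/absence code per fragment, and each code admits a finite set of
explanations: pairs of (control state, stressed state) of the underlying
restriction site.

Each explanation decomposes, cytosine by cytosine, into four elementary
events:

* ``DM``   — demethylation (methylated in control, not in stressed)
* ``DNM``  — de novo methylation (unmethylated in control, methylated in
  stressed)
* ``MSP``  — preservation of a methylated cytosine
* ``NMSP`` — preservation of a non-methylated cytosine

Changes at the external cytosine are scored as CHG-context events, changes
at the internal cytosine as CG-context events.  Under the working assumption
that all explanations of a code are equally probable, the per-code event
weights are the raw sums of event counts over all of its explanations; these
weights are what turns observed code counts into relative quantitative
methylation characteristics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SiteState",
    "DigestProfile",
    "EventVector",
    "CodeExplanation",
    "WeightTable",
    "ALL_CODES",
    "EVENT_COLUMNS",
    "parse_code",
    "digest_profile",
    "consistent_states",
    "count_transition_events",
    "enumerate_explanations",
    "code_weights",
    "build_weight_table",
]


class SiteState(enum.Enum):
    """Admissible methylation configuration of a CCGG/GGCC duplex site.

    The value is the flag tuple ``(ext_top, ext_bottom, int_top,
    int_bottom)`` with 1 marking a methylated cytosine.  Only six
    configurations are admissible; partial patterns mixing external and
    internal methylation have never been described for this site and are
    excluded from the model.  Hemimethylated states do not distinguish
    which strand carries the mark: ``HE`` stands for the class
    {(1,0,0,0), (0,1,0,0)} and ``HI`` for {(0,0,1,0), (0,0,0,1)}.
    """

    U = (0, 0, 0, 0)  #: unmethylated
    HE = (1, 0, 0, 0)  #: hemimethylated external cytosine
    FE = (1, 1, 0, 0)  #: both external cytosines methylated
    HI = (0, 0, 1, 0)  #: hemimethylated internal cytosine
    FI = (0, 0, 1, 1)  #: both internal cytosines methylated
    FM = (1, 1, 1, 1)  #: fully methylated

    @property
    def ext_top(self) -> int:
        return self.value[0]

    @property
    def ext_bottom(self) -> int:
        return self.value[1]

    @property
    def int_top(self) -> int:
        return self.value[2]

    @property
    def int_bottom(self) -> int:
        return self.value[3]

    @property
    def n_methylated(self) -> int:
        return sum(self.value)


#: Deterministic state ordering used for explanation lists and serialisation.
STATE_ORDER: tuple[SiteState, ...] = (
    SiteState.U,
    SiteState.HE,
    SiteState.FE,
    SiteState.HI,
    SiteState.FI,
    SiteState.FM,
)

#: Bit patterns admissible up to the strand-symmetry convention above.
ADMISSIBLE_PATTERNS: frozenset[tuple[int, int, int, int]] = frozenset(
    {(0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0), (1, 1, 0, 0),
     (0, 0, 1, 0), (0, 0, 0, 1), (0, 0, 1, 1), (1, 1, 1, 1)}
)


def canonical_state(flags: Iterable[int]) -> SiteState:
    """Map an admissible flag tuple to its :class:`SiteState`, folding the
    strand-symmetric hemimethylated mirrors onto their canonical member.

    Raises ``ValueError`` for configurations outside the admissible set.
    """
    t = tuple(int(f) for f in flags)
    if len(t) != 4 or any(f not in (0, 1) for f in t):
        raise ValueError(f"flags must be four 0/1 values, got {t!r}")
    if t == (0, 1, 0, 0):
        return SiteState.HE
    if t == (0, 0, 0, 1):
        return SiteState.HI
    try:
        return SiteState(t)
    except ValueError:
        raise ValueError(
            f"inadmissible site configuration {t!r}: mixed external/internal "
            "partial methylation patterns are outside the six-state model"
        ) from None


DigestProfile = tuple[int, int]
"""Fragment presence ``(hpa_present, msp_present)`` implied by one state."""


def digest_profile(state: SiteState) -> DigestProfile:
    """Presence of the fragment in the EcoRI/HpaII and EcoRI/MspI digests.

    HpaII cuts sites with no internal methylation and at most one methylated
    external cytosine; MspI cuts sites with no external methylation
    (internal methylation is tolerated).
    """
    if not isinstance(state, SiteState):
        raise ValueError(
            f"inadmissible site state {state!r}; expected one of "
            f"{[s.name for s in STATE_ORDER]}"
        )
    n_ext = state.ext_top + state.ext_bottom
    n_int = state.int_top + state.int_bottom
    hpa = 1 if (n_int == 0 and n_ext <= 1) else 0
    msp = 1 if n_ext == 0 else 0
    return (hpa, msp)


ALL_PROFILES: tuple[DigestProfile, ...] = ((1, 1), (1, 0), (0, 1), (0, 0))


def consistent_states(profile: DigestProfile) -> tuple[SiteState, ...]:
    """States whose digestion pattern equals ``profile`` (the preimage of
    :func:`digest_profile`), in canonical state order."""
    profile = (int(profile[0]), int(profile[1]))
    if profile not in ALL_PROFILES:
        raise ValueError(f"invalid digest profile {profile!r}")
    return tuple(s for s in STATE_ORDER if digest_profile(s) == profile)


@dataclass(frozen=True)
class EventVector:
    """Counts of the four elementary events and their context splits.

    ``dm``/``dnm`` split exactly into CG (internal cytosine) and CHG
    (external cytosine) components; ``m`` and ``nm`` are the derived totals
    of methylated and non-methylated cytosines in the stressed sample.
    """

    dm: int = 0
    dnm: int = 0
    msp: int = 0
    nmsp: int = 0
    dm_cg: int = 0
    dm_chg: int = 0
    dnm_cg: int = 0
    dnm_chg: int = 0

    def __post_init__(self) -> None:
        for name in ("dm", "dnm", "msp", "nmsp", "dm_cg", "dm_chg",
                     "dnm_cg", "dnm_chg"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.dm != self.dm_cg + self.dm_chg:
            raise ValueError("dm must equal dm_cg + dm_chg")
        if self.dnm != self.dnm_cg + self.dnm_chg:
            raise ValueError("dnm must equal dnm_cg + dnm_chg")

    @property
    def m(self) -> int:
        """Methylated cytosines in the stressed sample (DNM + MSP)."""
        return self.dnm + self.msp

    @property
    def nm(self) -> int:
        """Non-methylated cytosines in the stressed sample (DM + NMSP)."""
        return self.dm + self.nmsp

    @property
    def total(self) -> int:
        return self.dm + self.dnm + self.msp + self.nmsp

    def __add__(self, other: "EventVector") -> "EventVector":
        if not isinstance(other, EventVector):
            return NotImplemented
        return EventVector(
            dm=self.dm + other.dm,
            dnm=self.dnm + other.dnm,
            msp=self.msp + other.msp,
            nmsp=self.nmsp + other.nmsp,
            dm_cg=self.dm_cg + other.dm_cg,
            dm_chg=self.dm_chg + other.dm_chg,
            dnm_cg=self.dnm_cg + other.dnm_cg,
            dnm_chg=self.dnm_chg + other.dnm_chg,
        )

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "DM": self.dm,
                "DNM": self.dnm,
                "MSP": self.msp,
                "NMSP": self.nmsp,
                "M": self.m,
                "NM": self.nm,
                "DNM-CHG": self.dnm_chg,
                "DNM-CG": self.dnm_cg,
                "DM-CHG": self.dm_chg,
                "DM-CG": self.dm_cg,
            }
        )


#: Report column order for event tables.
EVENT_COLUMNS: tuple[str, ...] = (
    "DM", "DNM", "MSP", "NMSP", "M", "NM",
    "DNM-CHG", "DNM-CG", "DM-CHG", "DM-CG",
)

#: The sixteen four-bit codes, ordered as binary numbers.  Bit order is
#: (control-HpaII, control-MspI, stressed-HpaII, stressed-MspI).
ALL_CODES: tuple[str, ...] = tuple(
    "".join(map(str, bits)) for bits in product((0, 1), repeat=4)
)


def parse_code(code: str) -> str:
    """Validate a four-bit presence/absence code, returning its canonical
    string form (e.g. ``"1110"``)."""
    s = str(code).strip()
    if len(s) != 4 or any(c not in "01" for c in s):
        raise ValueError(
            f"malformed four-bit code {code!r}: expected four characters "
            "from {0,1} ordered (control-HpaII, control-MspI, "
            "stressed-HpaII, stressed-MspI)"
        )
    return s


def count_transition_events(control: SiteState, stressed: SiteState) -> EventVector:
    """Per-cytosine events of the transition ``control -> stressed``.

    Each of the four positions contributes exactly one event; changes at the
    external positions are CHG-context, at the internal positions CG-context.
    """
    for s in (control, stressed):
        if not isinstance(s, SiteState):
            raise ValueError(f"inadmissible site state {s!r}")
    counts = dict(dm=0, dnm=0, msp=0, nmsp=0,
                  dm_cg=0, dm_chg=0, dnm_cg=0, dnm_chg=0)
    for pos, (before, after) in enumerate(zip(control.value, stressed.value)):
        ctx = "chg" if pos < 2 else "cg"  # external positions first
        if before and after:
            counts["msp"] += 1
        elif before and not after:
            counts["dm"] += 1
            counts[f"dm_{ctx}"] += 1
        elif after:
            counts["dnm"] += 1
            counts[f"dnm_{ctx}"] += 1
        else:
            counts["nmsp"] += 1
    return EventVector(**counts)


@dataclass(frozen=True)
class CodeExplanation:
    """One (control state, stressed state) pair consistent with a code."""

    code: str
    control_state: SiteState
    stressed_state: SiteState
    events: EventVector


def enumerate_explanations(code: str) -> list[CodeExplanation]:
    """All explanations of ``code``: the cross-product of the states
    consistent with its control profile and its stressed profile, in
    canonical state order."""
    code = parse_code(code)
    control_profile = (int(code[0]), int(code[1]))
    stressed_profile = (int(code[2]), int(code[3]))
    out = []
    for c in consistent_states(control_profile):
        for s in consistent_states(stressed_profile):
            out.append(
                CodeExplanation(code, c, s, count_transition_events(c, s))
            )
    return out


def code_weights(code: str) -> EventVector:
    """Aggregated event weights of ``code``: the element-wise sum over all
    of its explanations (equal-probability assumption; raw sums, not
    averages)."""
    total = EventVector()
    for expl in enumerate_explanations(code):
        total = total + expl.events
    return total


@dataclass(frozen=True)
class WeightTable:
    """Event weights and explanation counts for all sixteen codes."""

    weights: Mapping[str, EventVector]
    n_explanations: Mapping[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per code, columns mirroring the weight
        report layout (``n_explanations`` first, then event columns)."""
        rows = {c: self.weights[c].as_series() for c in ALL_CODES}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.insert(0, "n_explanations", [self.n_explanations[c] for c in ALL_CODES])
        df.index.name = "code"
        return df


def build_weight_table() -> WeightTable:
    """Derive the full sixteen-code weight table from the enzyme model."""
    weights = {c: code_weights(c) for c in ALL_CODES}
    n_expl = {c: len(enumerate_explanations(c)) for c in ALL_CODES}
    return WeightTable(weights=weights, n_explanations=n_expl)
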