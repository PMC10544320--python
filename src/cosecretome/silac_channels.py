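"""Heavy/light channel assignment of SILAC-labeled PSMs.

In the co-culture, A549 cells carry heavy (13C6) arginine and lysine while
THP-1 monocytes carry the light forms, so the SILAC state of every K/R
residue identifies the cell of origin of a peptide.  A PSM is HEAVY when
every K/R site carries a heavy-label modification, LIGHT when none does,
and AMBIGUOUS otherwise — partial labeling (incomplete isotope
incorporation) and peptides without any K/R (protein C-terminal tryptic
peptides) cannot be attributed to a channel and are excluded from
quantification rather than fractionally allocated.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .psm_io import Condition, PsmRecord

__all__ = [
    "Channel",
    "ChannelAssignment",
    "ChannelError",
    "LabelingEfficiencyWarning",
    "DEFAULT_LABEL_NAMES",
    "assign_channel",
    "split_coculture",
    "check_monoculture_labeling",
]

#: Search engines name SILAC modifications differently; override as needed.
DEFAULT_LABEL_NAMES = frozenset({"Label:13C(6)"})

_LABELABLE = frozenset("KR")


class Channel(str, enum.Enum):
    HEAVY = "HEAVY"
    LIGHT = "LIGHT"
    AMBIGUOUS = "AMBIGUOUS"


class ChannelError(ValueError):
    """Corrupt input: a heavy-label modification sits on a non-K/R residue."""


class LabelingEfficiencyWarning(UserWarning):
    """A monoculture table contains more wrong-channel PSMs than tolerated."""


@dataclass(frozen=True)
class ChannelAssignment:
    channel: Channel
    n_labelable_sites: int
    n_labeled_sites: int


def assign_channel(
    psm: PsmRecord, label_names: frozenset[str] = DEFAULT_LABEL_NAMES
) -> ChannelAssignment:
    """Decide the SILAC channel of one PSM from its label modifications."""
    labelable = {i + 1 for i, residue in enumerate(psm.peptide) if residue in _LABELABLE}
    labeled = set()
    for pos, name in psm.modifications:
        if name in label_names:
            if pos not in labelable:
                raise ChannelError(
                    f"heavy label {name!r} at position {pos} of {psm.peptide!r} "
                    f"({psm.peptide[pos - 1]}) is not on a K/R residue"
                )
            labeled.add(pos)
    if not labelable:
        channel = Channel.AMBIGUOUS
    elif len(labeled) == len(labelable):
        channel = Channel.HEAVY
    elif not labeled:
        channel = Channel.LIGHT
    else:
        channel = Channel.AMBIGUOUS
    return ChannelAssignment(
        channel=channel,
        n_labelable_sites=len(labelable),
        n_labeled_sites=len(labeled),
    )


def split_coculture(
    psms: Sequence[PsmRecord],
    label_names: frozenset[str] = DEFAULT_LABEL_NAMES,
) -> tuple[list[PsmRecord], list[PsmRecord], int]:
    """Partition co-culture PSMs into heavy (A549) and light (THP-1) tables.

    Returns ``(heavy, light, n_ambiguous)``; the partition is exhaustive, so
    ``len(heavy) + len(light) + n_ambiguous == len(psms)``.  Raises if a
    non-co-culture record is present.
    """
    heavy: list[PsmRecord] = []
    light: list[PsmRecord] = []
    ambiguous = 0
    for psm in psms:
        if psm.condition is not Condition.COCULTURE:
            raise ValueError(
                f"split_coculture received a {psm.condition.value} record "
                f"({psm.spectrum_id})"
            )
        channel = assign_channel(psm, label_names).channel
        if channel is Channel.HEAVY:
            heavy.append(psm)
        elif channel is Channel.LIGHT:
            light.append(psm)
        else:
            ambiguous += 1
    return heavy, light, ambiguous


def check_monoculture_labeling(
    psms: Iterable[PsmRecord],
    expected: Channel,
    label_names: frozenset[str] = DEFAULT_LABEL_NAMES,
    tolerance: float = 0.02,
) -> float:
    """Fraction of monoculture PSMs assigned the *opposite* channel.

    Monoculture tables bypass splitting — their cell of origin is fixed by
    the condition — but with ~99% isotope incorporation a small fraction of
    PSMs looks mislabeled.  A fraction above ``tolerance`` raises a
    :class:`LabelingEfficiencyWarning`.
    """
    opposite = Channel.LIGHT if expected is Channel.HEAVY else Channel.HEAVY
    n_total = 0
    n_wrong = 0
    for psm in psms:
        n_total += 1
        if assign_channel(psm, label_names).channel is opposite:
            n_wrong += 1
    fraction = n_wrong / n_total if n_total else 0.0
    if fraction > tolerance:
        warnings.warn(
            f"{fraction:.1%} of monoculture PSMs look {opposite.value}-labeled "
            f"(expected {expected.value}; tolerance {tolerance:.0%}) — "
            f"check isotope incorporation",
            LabelingEfficiencyWarning,
            stacklevel=2,
        )
    return fraction
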