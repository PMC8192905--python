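"""Sleep-stage vocabulary.

Five stages are scored on 10-s epochs of mouse EEG: Wake, NREM, pre-REM
(the transitional stage between NREM and REM, also called intermediate
stage), REM, and an artifact class for contaminated epochs.  Integer codes
0..4 in the order below are the internal representation everywhere; reports
and confusion/transition matrices use :data:`REPORT_ORDER` instead.
"""

from __future__ import annotations

from enum import IntEnum

from .errors import DataError


class Stage(IntEnum):
    """Sleep stage of one 10-s epoch."""

    WAKE = 0
    NREM = 1
    PREREM = 2
    REM = 3
    ARTIFACT = 4

    @classmethod
    def from_token(cls, token: str) -> "Stage":
        """Parse a label token (case-insensitive; single-letter aliases allowed)."""
        key = str(token).strip().upper().replace("-", "").replace("_", "")
        try:
            return _ALIASES[key]
        except KeyError:
            raise DataError(f"unknown stage label: {token!r}") from None


_ALIASES = {
    "W": Stage.WAKE,
    "WAKE": Stage.WAKE,
    "N": Stage.NREM,
    "NREM": Stage.NREM,
    "P": Stage.PREREM,
    "PREREM": Stage.PREREM,
    "R": Stage.REM,
    "REM": Stage.REM,
    "A": Stage.ARTIFACT,
    "ARTIFACT": Stage.ARTIFACT,
}

#: All five stages in internal code order.
ALL_STAGES: tuple[Stage, ...] = (
    Stage.WAKE,
    Stage.NREM,
    Stage.PREREM,
    Stage.REM,
    Stage.ARTIFACT,
)

#: The three standard stages kept after reduction.
STANDARD_STAGES: tuple[Stage, ...] = (Stage.WAKE, Stage.NREM, Stage.REM)

#: Column/row order used for matrices and printed reports
#: (Wake, REM, NREM, pre-REM, artifact).
REPORT_ORDER: tuple[Stage, ...] = (
    Stage.WAKE,
    Stage.REM,
    Stage.NREM,
    Stage.PREREM,
    Stage.ARTIFACT,
)
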