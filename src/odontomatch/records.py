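"""The comparison record — one AM-vs-PM registration outcome."""

from __future__ import annotations

from dataclasses import dataclass

#: fixed CSV column order for results tables
CSV_COLUMNS = ("participant_a", "participant_b", "arch", "method",
               "replicate", "session", "operator", "is_match", "rms", "error")


@dataclass
class ComparisonRecord:
    """One AM-vs-PM comparison: who was compared, how, and the final RMS (mm).

    ``participant_a`` always holds the antemortem side, ``participant_b`` the
    postmortem side; ``is_match`` flags same-person comparisons.
    """

    participant_a: str
    participant_b: str
    arch: str
    method: str
    replicate: int
    session: int
    operator: int
    is_match: bool
    rms: float
    plane_used: object | None = None
    timestamp: float = 0.0
    error: str | None = None

    def __post_init__(self):
        if self.error is None and self.rms < 0:
            raise ValueError("rms must be >= 0")
        if (self.participant_a == self.participant_b) != self.is_match:
            raise ValueError("is_match must hold exactly when the participants coincide")

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in CSV_COLUMNS}
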