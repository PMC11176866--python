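"""Session- and patient-level intradialytic hypotension (IDH) outcomes.

The nadir-90 criterion labels a haemodialysis session hypotensive when the
lowest intradialytic systolic blood pressure (SBP) reading falls to
<= 90 mmHg, or to <= 100 mmHg when the pre-dialysis SBP was >= 160 mmHg.
Both thresholds are inclusive.  A patient is an "any-IDH" case after one
such session, and a "repeated-IDH" case when IDH occurred in strictly more
than 10 % of their monitored sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

NADIR_THRESHOLD = 90.0
HIGH_PRE_SBP = 160.0
HIGH_PRE_NADIR_THRESHOLD = 100.0
REPEATED_IDH_RATE = 0.10


@dataclass
class DialysisSession:
    session_id: str
    pre_sbp: float
    readings: Sequence[float]           # ordered intradialytic SBP, mmHg
    pre_dbp: Optional[float] = None
    post_sbp: Optional[float] = None
    post_dbp: Optional[float] = None
    uf_kg: Optional[float] = None
    patient_id: Optional[str] = None


@dataclass
class PatientOutcome:
    n_sessions: int
    n_idh: int
    idh_rate: float = field(init=False)
    any_idh: bool = field(init=False)
    repeated_idh: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.n_idh > self.n_sessions:
            raise ValueError("n_idh cannot exceed n_sessions")
        self.idh_rate = self.n_idh / self.n_sessions
        self.any_idh = self.n_idh >= 1
        self.repeated_idh = self.idh_rate > REPEATED_IDH_RATE


def classify_session(session: DialysisSession) -> tuple[bool, float]:
    """Apply the nadir-90 rule to one session.

    Returns ``(is_idh, nadir)``.  An unmonitored session (no readings) is an
    error rather than a silent non-IDH.
    """
    if len(session.readings) == 0:
        raise ValueError(f"session {session.session_id} has no SBP readings")
    nadir = float(min(session.readings))
    idh = nadir <= NADIR_THRESHOLD or (
        session.pre_sbp >= HIGH_PRE_SBP and nadir <= HIGH_PRE_NADIR_THRESHOLD
    )
    return idh, nadir


def patient_outcome(sessions: Sequence[DialysisSession]) -> PatientOutcome:
    """Aggregate one patient's sessions into any-/repeated-IDH labels."""
    if not sessions:
        raise ValueError("patient has no sessions")
    n_idh = sum(classify_session(s)[0] for s in sessions)
    return PatientOutcome(n_sessions=len(sessions), n_idh=int(n_idh))


def cohort_incidence(outcomes: Sequence[PatientOutcome]) -> dict:
    """Cohort summary with percentages rounded to one decimal."""
    if not outcomes:
        raise ValueError("no patients")
    n_sessions = sum(o.n_sessions for o in outcomes)
    n_idh_sessions = sum(o.n_idh for o in outcomes)
    n_any = sum(o.any_idh for o in outcomes)
    n_repeated = sum(o.repeated_idh for o in outcomes)
    n_patients = len(outcomes)
    return {
        "n_sessions": n_sessions,
        "n_idh_sessions": n_idh_sessions,
        "pct_idh_sessions": round(100.0 * n_idh_sessions / n_sessions, 1),
        "n_patients": n_patients,
        "n_any_idh": n_any,
        "pct_any_idh": round(100.0 * n_any / n_patients, 1),
        "n_repeated_idh": n_repeated,
        "pct_repeated_idh": round(100.0 * n_repeated / n_patients, 1),
    }
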