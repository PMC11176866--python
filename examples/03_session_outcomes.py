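"""Nadir-90 IDH classification of dialysis sessions.

Builds a handful of sessions, applies the nadir-90 rule (SBP <= 90 mmHg,
or <= 100 mmHg when pre-dialysis SBP >= 160 mmHg) and aggregates one
patient's 12-session monitoring block into outcome labels.
"""

from hrvidh import (DialysisSession, classify_session, patient_outcome,
                    simulate_session)

examples = [
    DialysisSession("a", pre_sbp=150, readings=[140, 130, 88, 120]),
    DialysisSession("b", pre_sbp=165, readings=[150, 120, 98]),
    DialysisSession("c", pre_sbp=158, readings=[130, 95, 110]),
]
for s in examples:
    idh, nadir = classify_session(s)
    print(f"session {s.session_id}: pre-SBP {s.pre_sbp:5.1f}, "
          f"nadir {nadir:5.1f} -> {'IDH' if idh else 'non-IDH'}")

# one patient's 12-session block at a moderate autonomic-dysfunction score
sessions = [simulate_session(0.7, pre_sbp=150.0, seed=k) for k in range(12)]
out = patient_outcome(sessions)
print(f"\nsimulated patient: {out.n_idh}/{out.n_sessions} IDH sessions "
      f"(rate {100 * out.idh_rate:.1f} %)")
print(f"any IDH: {out.any_idh}   repeated IDH (>10 % of sessions): "
      f"{out.repeated_idh}")
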