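"""Digit-span working-memory test scoring.

The test has up to five rounds; round ``r`` presents digit sequences of length
``3 + r`` (four digits in round 1, eight in round 5). A round's score is the
percentage of sequences recalled correctly, and a participant advances to the
next round only with a round score of at least 60%. The session score is the
mean of the per-round scores over the rounds actually attempted, on a 0-100
scale, and the session time is the sum of per-round completion times.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Minimum round score (percent) required to advance to the next round.
ADVANCE_THRESHOLD = 60.0

#: Sequence length in round 1; it increases by one digit per round.
FIRST_SEQUENCE_LENGTH = 4

#: Maximum number of rounds in a session.
MAX_ROUNDS = 5


@dataclass(frozen=True)
class Round:
    """One digit-span round: trial bookkeeping plus completion time."""

    sequence_length: int
    n_trials: int
    n_correct: int
    time_s: float = 0.0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("a round needs at least one trial")
        if not 0 <= self.n_correct <= self.n_trials:
            raise ValueError("n_correct must lie in [0, n_trials]")

    @property
    def score(self) -> float:
        return score_round(self.n_correct, self.n_trials)


@dataclass
class DigitSpanSession:
    """A scored digit-span session for one participant and state."""

    rounds: list
    subject_id: str | None = None
    state: str | None = None

    def __post_init__(self):
        if not self.rounds:
            raise ValueError("a session needs at least one round")
        expected = FIRST_SEQUENCE_LENGTH
        for rnd in self.rounds:
            if rnd.sequence_length != expected:
                raise ValueError(
                    f"round sequence lengths must increase by 1 starting at "
                    f"{FIRST_SEQUENCE_LENGTH}; got {rnd.sequence_length}, "
                    f"expected {expected}"
                )
            expected += 1

    @property
    def completed_rounds(self) -> int:
        return len(self.rounds)

    @property
    def final_score(self) -> float:
        return score_session(self)[0]

    @property
    def total_time(self) -> float:
        return score_session(self)[1]


def score_round(n_correct: int, n_trials: int) -> float:
    """Percent of correctly recalled sequences in one round (0-100)."""
    if n_trials < 1:
        raise ValueError("cannot score a round with zero trials")
    return 100.0 * n_correct / n_trials


def advances(round_score: float) -> bool:
    """Whether a round score permits moving on to the next round (>= 60%)."""
    if not 0.0 <= round_score <= 100.0:
        raise ValueError("round score must lie in [0, 100]")
    return round_score >= ADVANCE_THRESHOLD


def score_session(session: DigitSpanSession) -> tuple:
    """Final session score and total completion time.

    The final score is the mean of the per-round scores over the rounds the
    participant attempted (a failed round still counts as attempted). Rounds
    recorded after a failed advancement are ignored: the session is truncated
    at the first round scoring below the advancement threshold.
    """
    kept = []
    for rnd in session.rounds:
        kept.append(rnd)
        if not advances(rnd.score):
            break
    final = sum(r.score for r in kept) / len(kept)
    total_time = float(sum(r.time_s for r in kept))
    return final, total_time


def truncate_session(session: DigitSpanSession) -> DigitSpanSession:
    """Drop any rounds recorded after the first failed advancement."""
    kept = []
    for rnd in session.rounds:
        kept.append(rnd)
        if not advances(rnd.score):
            break
    return DigitSpanSession(kept, subject_id=session.subject_id, state=session.state)


def sessions_to_frame(sessions) -> pd.DataFrame:
    """Long-format table of sessions: one row per round."""
    rows = []
    for s in sessions:
        for i, rnd in enumerate(s.rounds, start=1):
            rows.append({
                "subject": s.subject_id, "state": s.state, "round": i,
                "seq_len": rnd.sequence_length, "trials": rnd.n_trials,
                "correct": rnd.n_correct, "time_s": rnd.time_s,
            })
    return pd.DataFrame(rows)


def write_sessions_tsv(sessions, path) -> None:
    sessions_to_frame(sessions).to_csv(path, sep="\t", index=False)


def read_sessions_tsv(path) -> list:
    """Read sessions from TSV (columns subject, state, round, seq_len, trials,
    correct, time_s); returns one :class:`DigitSpanSession` per subject-state."""
    df = pd.read_csv(path, sep="\t")
    sessions = []
    for (subject, state), grp in df.groupby(["subject", "state"], sort=False, dropna=False):
        grp = grp.sort_values("round")
        rounds = [
            Round(int(r.seq_len), int(r.trials), int(r.correct), float(r.time_s))
            for r in grp.itertuples()
        ]
        state = None if pd.isna(state) else state
        sessions.append(DigitSpanSession(rounds, subject_id=str(subject), state=state))
    return sessions
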