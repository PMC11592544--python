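"""System Usability Scale scoring and cognitive-walkthrough tallies.

SUS: ten statements answered on a 1–5 agreement scale, odd items phrased
positively and even items negatively.  The raw answers are rescaled to 0–100:
odd items contribute (answer - 1), even items (5 - answer), and the sum is
multiplied by 2.5.  A mean of 68 is conventionally "above average"; 84 and up
earns the top (A+) grade.  Cognitive-walkthrough outcomes are per-task
classifications — performed with ease, with difficulty, or failed — summarized
as percentages; "carried out" is ease plus difficulty.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

__all__ = ["sus_score", "sus_aggregate", "cwm_summary", "CWM_OUTCOMES"]

CWM_OUTCOMES = ("ease", "difficulty", "failed")

#: Inclusive grade thresholds on the mean SUS score.
SUS_TOP_GRADE_THRESHOLD = 84.0
SUS_ABOVE_AVERAGE_THRESHOLD = 68.0


def sus_score(response: Sequence[int]) -> float:
    """Score one 10-item SUS response on the 0–100 scale."""
    items = list(response)
    if len(items) != 10:
        raise ValueError(f"a SUS response has exactly 10 items, got {len(items)}")
    total = 0
    for i, ans in enumerate(items, start=1):
        if int(ans) != ans or not 1 <= ans <= 5:
            raise ValueError(f"item q{i}: answers must be integers 1-5, got {ans!r}")
        total += (ans - 1) if i % 2 == 1 else (5 - ans)
    return total * 2.5


def sus_grade(mean_score: float) -> str:
    if mean_score >= SUS_TOP_GRADE_THRESHOLD:
        return "A+"
    if mean_score >= SUS_ABOVE_AVERAGE_THRESHOLD:
        return "above average"
    return "below average"


def sus_aggregate(responses: Iterable[Sequence[int]]) -> dict:
    """Mean SUS score over respondents, with the grade band it falls in."""
    scores = [sus_score(r) for r in responses]
    if not scores:
        raise ValueError("need at least one SUS response")
    mean = sum(scores) / len(scores)
    return {"n": len(scores), "mean": mean, "scores": scores, "grade": sus_grade(mean)}


def cwm_summary(outcomes: Iterable[str]) -> dict[str, float]:
    """Percentage of task attempts in each cognitive-walkthrough category."""
    counts = Counter()
    total = 0
    for o in outcomes:
        if o not in CWM_OUTCOMES:
            raise ValueError(f"unknown CWM outcome {o!r}; expected one of {CWM_OUTCOMES}")
        counts[o] += 1
        total += 1
    if total == 0:
        raise ValueError("need at least one CWM outcome")
    pct = {k: 100.0 * counts[k] / total for k in CWM_OUTCOMES}
    pct["carried_out"] = pct["ease"] + pct["difficulty"]
    return pct
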