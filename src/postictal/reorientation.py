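"""Clinical reorientation scoring after ECT-induced seizures.

The reorientation-time (ROT) questionnaire asks five questions every
5 minutes: person (name, birthday), place (name of hospital), and time
(age, day of week). Per domain, time to reorientation is the time at which
the question was first answered correctly; two-question domains average the
two times. A domain in which the patient was already disoriented at baseline
is excluded from analysis. Questions never answered within the observation
window are censored (missing) rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import DOMAIN_QUESTIONS

logger = logging.getLogger(__name__)

DOMAINS = ("person", "place", "time")

__all__ = [
    "DOMAINS",
    "ROTRecord",
    "ClinicalOutcome",
    "time_to_reorientation",
    "score_rot_log",
    "domain_order",
    "compare_domains",
    "clinical_outcome",
]


@dataclass
class ROTRecord:
    """Per-session, per-domain time-to-reorientation."""

    session_id: str
    domain: str
    question_times: dict[str, float]
    baseline_oriented: bool
    rot: float  # minutes; NaN when invalid or censored
    censored: bool = False


@dataclass
class ClinicalOutcome:
    """Course-level depression outcome from HDRS scores.

    Response: post-course score decreased by at least 50% from pre-course.
    Remission: post-course score below 8.
    """

    pre_hdrs: float
    post_hdrs: float
    response: bool
    remission: bool


def time_to_reorientation(
    question_times: dict[str, float],
    domain: str,
    baseline_oriented: bool = True,
) -> tuple[float, bool]:
    """Domain time-to-reorientation in minutes.

    Returns (rot, censored). Single-question domains return that question's
    first-correct time; two-question domains the mean of the two. A
    baseline-disoriented domain, or any question never answered within the
    window (NaN time), yields NaN.
    """
    if domain not in DOMAIN_QUESTIONS:
        raise ValueError(f"unknown domain {domain!r}")
    if not baseline_oriented:
        logger.info("domain %s ignored: disoriented at baseline", domain)
        return np.nan, False
    times = [question_times.get(q, np.nan) for q in DOMAIN_QUESTIONS[domain]]
    if any(np.isnan(t) for t in times):
        return np.nan, True  # censored: question never correct
    if any(t < 0 for t in times):
        raise ValueError(f"negative question time in {question_times}")
    return float(np.mean(times)), False


def score_rot_log(rot_log: pd.DataFrame) -> pd.DataFrame:
    """Score a question-level log into one row per session.

    Expects columns session_id, question_id, domain, minutes_to_correct,
    baseline_oriented. Returns session_id, rot_person, rot_place, rot_time,
    order, classic_order_flag.
    """
    rows = []
    for sid, g in rot_log.groupby("session_id", sort=True):
        rots = {}
        for domain in DOMAINS:
            gd = g[g["domain"] == domain]
            if gd.empty:
                rots[domain] = np.nan
                continue
            qt = dict(zip(gd["question_id"], gd["minutes_to_correct"]))
            oriented = bool(gd["baseline_oriented"].all())
            rot, _ = time_to_reorientation(qt, domain, oriented)
            rots[domain] = rot
        order, flag = domain_order(rots)
        rows.append({
            "session_id": sid,
            "rot_person": rots["person"],
            "rot_place": rots["place"],
            "rot_time": rots["time"],
            "order": "-".join(order) if order else "",
            "classic_order_flag": flag,
        })
    return pd.DataFrame(rows)


def domain_order(rots: dict[str, float]) -> tuple[list[str], bool | None]:
    """Sort domains by time-to-reorientation.

    Returns (ordered domain names, classic-order flag). The flag is True iff
    rot_person <= rot_place <= rot_time (ties count as simultaneous, so
    simultaneous recovery does not falsify the classic sequence); None when
    fewer than two domains are available.
    """
    present = {d: v for d, v in rots.items() if not np.isnan(v)}
    if len(present) < 2:
        return [], None
    ordered = sorted(present, key=lambda d: (present[d], DOMAINS.index(d)))
    vals = [rots.get(d, np.nan) for d in DOMAINS]
    if any(np.isnan(v) for v in vals):
        flag = None
    else:
        flag = bool(vals[0] <= vals[1] <= vals[2])
    return ordered, flag


def compare_domains(
    subject_rots: pd.DataFrame, min_subjects: int = 6
) -> dict[str, float]:
    """Paired Wilcoxon signed-rank tests between domains.

    ``subject_rots`` holds per-subject medians across sessions in columns
    rot_person, rot_place, rot_time. Returns two-sided p-values for
    person-vs-place, place-vs-time and person-vs-time; NaN when every paired
    difference is zero (test undefined).
    """
    out = {}
    for a, b in (("person", "place"), ("place", "time"), ("person", "time")):
        pair = subject_rots[[f"rot_{a}", f"rot_{b}"]].dropna()
        if len(pair) < min_subjects:
            raise ValueError(
                f"{a}-vs-{b}: {len(pair)} paired subjects < {min_subjects}"
            )
        x = pair[f"rot_{a}"].to_numpy()
        y = pair[f"rot_{b}"].to_numpy()
        if np.all(x == y):
            logger.warning("%s-vs-%s: all differences zero, test undefined",
                           a, b)
            out[f"{a}_vs_{b}"] = np.nan
            continue
        res = stats.wilcoxon(x, y)
        out[f"{a}_vs_{b}"] = float(res.pvalue)
    return out


def clinical_outcome(pre_hdrs: float, post_hdrs: float) -> ClinicalOutcome:
    """Response/remission flags from pre- and post-course HDRS scores."""
    if pre_hdrs < 0 or post_hdrs < 0:
        raise ValueError("HDRS scores must be non-negative")
    return ClinicalOutcome(
        pre_hdrs=pre_hdrs,
        post_hdrs=post_hdrs,
        response=bool(post_hdrs <= 0.5 * pre_hdrs),
        remission=bool(post_hdrs < 8),
    )
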