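"""Scoring of recognition and verbal reports, image-set classification, and
the behavioral statistics of the disambiguation paradigm.

Each Mooney image is seen six times before and six times after its gray-scale
source is shown.  After each presentation the subject reports whether they
recognize the object; once per stage they also name it verbally, scored
against a pre-determined list of acceptable answers.  The per-subject
recognition counts classify images into the analysis sets:

* pre not-recognized: <= 2 of 6 "yes" before disambiguation,
* pre recognized:     >= 4 of 6 "yes" before disambiguation,
* exactly 3 of 6:     unclassified (the cut-offs deliberately leave a gap),
* post recognized:    >= 4 of 6 "yes" after disambiguation; post
  not-recognized images are excluded from all further analyses.

The Disambiguation set is (pre not-recognized AND post recognized); the
Repetition set is (pre recognized AND post recognized).  The two sets are
disjoint by construction.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats_core
from .stats_core import StatResult

PRE_NOT_RECOGNIZED_MAX = 2   # "yes" on two or fewer of six presentations
RECOGNIZED_MIN = 4           # "yes" on four or more of six presentations

__all__ = [
    "classify_images",
    "recognition_summary",
    "behavior_anova",
    "score_verbal",
    "image_sets",
]


def _validate_table(table: pd.DataFrame) -> None:
    required = {"subject", "image_id", "stage", "presentation", "recognized"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("behavior table is empty")
    bad_stage = set(table["stage"]) - {"pre", "post"}
    if bad_stage:
        raise ValueError(f"unknown stages: {sorted(bad_stage)}")


def classify_images(table: pd.DataFrame, n_presentations: int = 6) -> pd.DataFrame:
    """Classify each subject x image into the analysis sets from yes-counts.

    Returns a frame with columns (subject, image_id, pre_count, post_count,
    pre_status, post_status, set) where ``set`` is "disambiguation",
    "repetition" or "none".  Classification depends only on counts, so it is
    invariant to presentation order.
    """
    _validate_table(table)
    counts = (
        table.groupby(["subject", "image_id", "stage"])["recognized"]
        .agg(["sum", "count"]).reset_index()
    )
    bad = counts[counts["count"] != n_presentations]
    if not bad.empty:
        pairs = bad[["subject", "image_id", "stage"]].to_records(index=False).tolist()
        raise ValueError(f"expected {n_presentations} presentations per stage; "
                         f"offending (subject, image, stage): {pairs[:10]}")
    wide = counts.pivot_table(index=["subject", "image_id"], columns="stage",
                              values="sum").reset_index()
    for stage in ("pre", "post"):
        if stage not in wide:
            raise ValueError(f"no {stage}-stage rows in behavior table")
    pre, post = wide["pre"].to_numpy(), wide["post"].to_numpy()
    pre_status = np.select(
        [pre <= PRE_NOT_RECOGNIZED_MAX, pre >= RECOGNIZED_MIN],
        ["not-recognized", "recognized"], default="unclassified",
    )
    post_status = np.where(post >= RECOGNIZED_MIN, "recognized", "not-recognized-excluded")
    image_set = np.select(
        [(pre_status == "not-recognized") & (post_status == "recognized"),
         (pre_status == "recognized") & (post_status == "recognized")],
        ["disambiguation", "repetition"], default="none",
    )
    return pd.DataFrame({
        "subject": wide["subject"], "image_id": wide["image_id"],
        "pre_count": pre.astype(int), "post_count": post.astype(int),
        "pre_status": pre_status, "post_status": post_status, "set": image_set,
    })


def image_sets(classification: pd.DataFrame) -> dict[str, dict[str, list[str]]]:
    """Per-subject image lists for the disambiguation and repetition sets."""
    out: dict[str, dict[str, list[str]]] = {"disambiguation": {}, "repetition": {}}
    for set_name in out:
        sub = classification[classification["set"] == set_name]
        for subject, grp in sub.groupby("subject"):
            out[set_name][subject] = sorted(grp["image_id"].tolist())
    return out


def recognition_summary(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-subject recognition rates by stage and by presentation number.

    Returns ``{"by_stage": ..., "by_presentation": ..., "group": ...}``:
    percent recognized per subject x stage, the subject x stage x presentation
    rate table, and group mean +/- s.d. per stage.
    """
    _validate_table(table)
    by_stage = (
        table.groupby(["subject", "stage"])["recognized"].mean().mul(100)
        .rename("percent_recognized").reset_index()
    )
    by_presentation = (
        table.groupby(["subject", "stage", "presentation"])["recognized"]
        .mean().mul(100).rename("percent_recognized").reset_index()
    )
    group = (
        by_stage.groupby("stage")["percent_recognized"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    )
    return {"by_stage": by_stage, "by_presentation": by_presentation, "group": group}


def behavior_anova(table: pd.DataFrame) -> dict[str, object]:
    """Two-way repeated-measures ANOVA on recognition rate.

    Within factors: disambiguation stage (pre/post) x presentation number
    (1..6); plus Bonferroni-corrected post-hoc paired comparisons across
    presentations within each stage.
    """
    summary = recognition_summary(table)["by_presentation"]
    n_sub = summary["subject"].nunique()
    if n_sub < 2:
        raise ValueError("need at least 2 subjects for the ANOVA")
    effects = stats_core.rm_anova(
        summary, dv="percent_recognized", within=["stage", "presentation"],
        subject="subject", family="behavior_anova",
    )
    posthoc: dict[str, list[StatResult]] = {}
    for stage in ("pre", "post"):
        posthoc[stage] = stats_core.pairwise_posthoc(
            summary, dv="percent_recognized", within="presentation",
            subject="subject", restrict={"stage": stage},
            family=f"behavior_posthoc_{stage}",
        )
    return {"effects": effects, "posthoc": posthoc}


def _normalize(text: str) -> str:
    return " ".join(str(text).strip().lower().split())


def score_verbal(
    responses: Mapping[tuple[str, str, str], str],
    answer_key: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Score free-text naming responses against the acceptable-answer key.

    ``responses`` maps (subject, image_id, stage) -> raw response text;
    matching is case-insensitive and whitespace-normalized, exact against the
    key.  The reserved answer "unknown" is always incorrect.
    """
    normalized_key = {}
    for image_id, answers in answer_key.items():
        normalized_key[image_id] = {_normalize(a) for a in answers}
    rows = []
    for (subject, image_id, stage), response in responses.items():
        if image_id not in normalized_key:
            raise ValueError(f"image {image_id!r} missing from answer key")
        norm = _normalize(response)
        correct = norm != "unknown" and norm in normalized_key[image_id]
        rows.append({"subject": subject, "image_id": image_id, "stage": stage,
                     "response": response, "verbal_correct": correct})
    return pd.DataFrame(rows)
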