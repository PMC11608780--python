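"""End-to-end study analysis: dataset -> similarity tables -> statistics.

Thin orchestration over the preprocess, concordance, behavior and inference
modules; the numbered analysis scripts and the acceptance machinery all run
through these functions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import behavior, concordance, inference, preprocess
from .synth import GROUPS, StudyDataset

log = logging.getLogger("physiosync.pipeline")


def preprocessed_sc(dataset: StudyDataset, group: str,
                    cfg: preprocess.PreprocessConfig | None = None):
    """Cleaned skin-conductance recordings for one group."""
    cfg = cfg or preprocess.PreprocessConfig()
    return [preprocess.preprocess_sc(dataset.sc_recordings[p], cfg)
            for p in dataset.group_ids(group)]


def hr_series(dataset: StudyDataset, group: str,
              cfg: preprocess.PreprocessConfig | None = None):
    """Artifact-corrected, 32-Hz-resampled heart-period series for one group."""
    cfg = cfg or preprocess.PreprocessConfig()
    out = []
    for p in dataset.group_ids(group):
        corrected = preprocess.correct_ibi(dataset.hr_ibi[p].intervals_ms, cfg)
        out.append(preprocess.ibi_to_series(corrected, cfg.ibi_resample_hz, p))
    return out


def similarity_tables(recordings, window_s: float = 5.0, step_s: float = 1.0):
    """Slopes -> pairwise indices -> per-participant similarity for a group.

    Returns (pair_table, participant_table) DataFrames.
    """
    slopes = [concordance.rolling_slopes(r, window_s, step_s) for r in recordings]
    pair_table, parts = concordance.group_similarity(slopes)
    part_table = pd.DataFrame({
        "participant_id": [p.participant_id for p in parts],
        "channel": [p.channel for p in parts],
        "similarity": [p.value for p in parts],
    })
    return pair_table, part_table


def study_similarity(dataset: StudyDataset, channel: str = "SC",
                     cfg: preprocess.PreprocessConfig | None = None) -> pd.DataFrame:
    """Per-participant similarity for both groups on one channel."""
    frames = []
    for group in GROUPS:
        recs = (preprocessed_sc(dataset, group, cfg) if channel == "SC"
                else hr_series(dataset, group, cfg))
        _, part = similarity_tables(recs)
        part["group"] = group
        frames.append(part)
    return pd.concat(frames, ignore_index=True)


def measured_mediation_frame(dataset: StudyDataset,
                             similarity: pd.DataFrame) -> pd.DataFrame:
    """Mediation inputs with the *measured* concordance as mediator."""
    sim = similarity.set_index("participant_id")["similarity"]
    rows = []
    for pid in dataset.participants:
        pre = behavior.liking_index(dataset.ratings_pre[pid], "pre")
        post = behavior.liking_index(dataset.ratings_post[pid], "post")
        rows.append({
            "participant": pid,
            "x": float(dataset.group[pid] == "analytical"),
            "m": float(sim.get(pid, np.nan)),
            "y": behavior.liking_change(pre, post),
            "empathy": float(dataset.covariates.loc[pid, "empathy"]),
        })
    return pd.DataFrame(rows)


def behavior_table(dataset: StudyDataset) -> pd.DataFrame:
    """Per-participant liking and knowledge scores (2 tests x 2 phases)."""
    rows = []
    for pid in dataset.participants:
        pre = behavior.liking_index(dataset.ratings_pre[pid], "pre")
        post = behavior.liking_index(dataset.ratings_post[pid], "post")
        row = {"participant": pid, "group": dataset.group[pid],
               "n4_pre": pre.n4, "n5_pre": pre.n5, "liking_pre": pre.index,
               "n4_post": post.n4, "n5_post": post.n5, "liking_post": post.index,
               "liking_change": behavior.liking_change(pre, post)}
        for (test, phase), vecs in dataset.knowledge.items():
            row[f"{test}_{phase}"] = behavior.score_test(vecs[pid]).score
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(dataset: StudyDataset, n_perm: int = 0, seed: int | None = None,
              n_boot: int = 5000) -> dict:
    """Full qualitative pipeline on a dataset: group similarities, the
    between-group contrast, liking change, and the mediation model with the
    measured skin-conductance similarity as mediator. Permutation tests are
    run per group when ``n_perm`` > 0."""
    sim = study_similarity(dataset, "SC")
    by_group = {g: sim.loc[sim["group"] == g, "similarity"].to_numpy() for g in GROUPS}
    out: dict = {"similarity": sim}
    out["one_sample"] = {g: concordance.one_sample_test(v) for g, v in by_group.items()}
    out["group_contrast"] = inference.two_sample_t_from_raw(
        by_group["analytical"], by_group["historical"])
    frame = measured_mediation_frame(dataset, sim)
    out["mediation_frame"] = frame
    out["liking_gap"] = inference.two_sample_t_from_raw(
        frame.loc[frame.x == 1, "y"], frame.loc[frame.x == 0, "y"])
    out["psc_liking_r"] = {
        g: inference.pearson(frame.loc[frame.x == (g == "analytical"), "m"],
                             frame.loc[frame.x == (g == "analytical"), "y"])
        for g in GROUPS}
    out["mediation"] = inference.mediation_frame_analysis(
        frame, covariate="empathy", n_boot=n_boot, seed=seed)
    if n_perm > 0:
        out["permutation"] = {}
        for g in GROUPS:
            recs = preprocessed_sc(dataset, g)
            out["permutation"][g] = concordance.permutation_test(
                recs, n_perm=n_perm, seed=seed)
    return out
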