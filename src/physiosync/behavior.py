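"""Behavioral scoring: real-time liking index and knowledge-test scores.

Music liking is the weighted count of high-pleasure press episodes:
each level-4 episode contributes 1, each level-5 episode contributes 2
(levels 1-3 contribute nothing; episode duration is ignored). Liking change
is post-learning minus pre-learning. A knowledge score is the number of the
10 test items answered correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError
from .signal_io import KnowledgeVector, RatingStream


@dataclass
class LikingScore:
    participant_id: str
    phase: str
    n4: int
    n5: int
    index: float


@dataclass
class KnowledgeScore:
    participant_id: str
    test: str
    phase: str
    score: int


def liking_index(stream: RatingStream, phase: str = "pre",
                 weight_by_duration: bool = False) -> LikingScore:
    """Score a rating stream.

    With ``weight_by_duration`` the alternative seconds-held index is
    returned instead (seconds at level 4 + 2 x seconds at level 5), kept for
    sensitivity analysis; the episode-count index is the default.
    """
    n4 = sum(1 for _, _, lvl in stream.episodes if lvl == 4)
    n5 = sum(1 for _, _, lvl in stream.episodes if lvl == 5)
    if weight_by_duration:
        idx = sum((off - on) * {4: 1.0, 5: 2.0}.get(lvl, 0.0)
                  for on, off, lvl in stream.episodes)
    else:
        idx = float(n4 + 2 * n5)
    return LikingScore(stream.participant_id, phase, n4, n5, idx)


def liking_change(pre: LikingScore, post: LikingScore) -> float:
    if pre.participant_id != post.participant_id:
        raise ConfigError(
            f"participant mismatch: {pre.participant_id!r} vs {post.participant_id!r}")
    return post.index - pre.index


def score_test(k: KnowledgeVector) -> KnowledgeScore:
    """Sum of correct indicators (the Hamming weight of the answer vector)."""
    return KnowledgeScore(k.participant_id, k.test, k.phase, int(k.answers.sum()))
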