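"""The physiological-similarity statistic and its surrogate test.

The pipeline: 5-s moving-window slopes in 1-s steps per participant; zero-lag
Pearson correlations of slope series over running 15-slope windows per pair;
per-pair concordance index ln(sum of positive r / sum of |negative r|);
per-participant similarity = mean index over all within-group pairs containing
that participant; group-level one-sample t against zero. Significance of the
observed t is assessed against a null built by shuffling 1-s signal epochs
independently within each participant and re-running the whole chain, with
p = erfc((|s - mu0| / sigma0) / sqrt(2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special, stats

from .errors import ConfigError, DataQualityError
from .signal_io import KnowledgeVector, PhysioRecording

log = logging.getLogger("physiosync.concordance")

#: default regularizer added symmetrically to both correlation sums
DEFAULT_EPS = 1e-6
#: slopes per correlation window (15 one-second slope steps)
CORR_WINDOW = 15


@dataclass
class SlopeSeries:
    """1 Hz sequence of moving-window slopes (signal units per second)."""

    participant_id: str
    channel: str
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("slope series contains non-finite values")


@dataclass
class PairConcordance:
    id_a: str
    id_b: str
    index: float
    n_windows: int
    n_skipped: int


@dataclass
class ParticipantSimilarity:
    participant_id: str
    channel: str
    value: float


@dataclass
class PermutationResult:
    observed_t: float
    null_mean: float
    null_sd: float
    n_perm: int
    p: float
    null_t: np.ndarray


# ---------------------------------------------------------------------------
# slopes
# ---------------------------------------------------------------------------

def _ols_weights(w: int, rate_hz: float) -> np.ndarray:
    t = np.arange(w) / rate_hz
    c = t - t.mean()
    return c / np.dot(c, c)


def rolling_slopes(rec: PhysioRecording, window_s: float = 5.0, step_s: float = 1.0,
                   method: str = "ols") -> SlopeSeries:
    """Slope of value vs. time in a moving ``window_s`` window advanced by
    ``step_s`` (defaults 5 s / 1 s), one value per fully contained window.

    ``method='ols'`` uses the least-squares slope over all samples in the
    window; ``method='endpoint'`` uses (last - first) / span.
    """
    w = int(round(window_s * rec.rate_hz))
    s = int(round(step_s * rec.rate_hz))
    if w < 2 or s < 1:
        raise ConfigError("window/step too short for the sampling rate")
    if rec.samples.size < w:
        raise ConfigError(
            f"recording of {rec.samples.size} samples shorter than one "
            f"{window_s}-s window ({w} samples)")
    windows = sliding_window_view(rec.samples, w)[::s]
    if method == "ols":
        vals = windows @ _ols_weights(w, rec.rate_hz)
    elif method == "endpoint":
        vals = (windows[:, -1] - windows[:, 0]) * rec.rate_hz / (w - 1)
    else:
        raise ConfigError(f"unknown slope method {method!r}")
    return SlopeSeries(rec.participant_id, rec.channel, vals, t0=rec.t0)


# ---------------------------------------------------------------------------
# pairwise concordance
# ---------------------------------------------------------------------------

def _window_correlations(a: np.ndarray, b: np.ndarray, corr_window: int):
    """Zero-lag Pearson r over running windows; returns (r, valid mask)."""
    wa = sliding_window_view(a, corr_window)
    wb = sliding_window_view(b, corr_window)
    ca = wa - wa.mean(axis=1, keepdims=True)
    cb = wb - wb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ca, axis=1)
    nb = np.linalg.norm(cb, axis=1)
    valid = (na > 0) & (nb > 0)
    r = np.zeros(wa.shape[0])
    np.divide(np.einsum("ij,ij->i", ca, cb), na * nb, out=r, where=valid)
    return r, valid


def _log_ratio(r: np.ndarray, valid: np.ndarray, eps: float) -> float:
    rv = r[valid]
    pos = rv[rv > 0].sum()
    neg = -rv[rv < 0].sum()
    return float(np.log((pos + eps) / (neg + eps)))


def pair_concordance(a: SlopeSeries, b: SlopeSeries, corr_window: int = CORR_WINDOW,
                     eps: float = DEFAULT_EPS) -> PairConcordance:
    """Concordance index for one pair of slope series.

    The series are aligned on their start times and truncated to the common
    overlap; windows where either side has zero variance are skipped (Pearson
    r is undefined there) and counted in ``n_skipped``; r = 0 contributes to
    neither sum. Index = ln((sum positive r + eps) / (sum |negative r| + eps)).
    """
    if eps <= 0:
        raise ConfigError("eps must be positive")
    off = int(round(b.t0 - a.t0))
    va, vb = a.values, b.values
    if off > 0:
        va = va[off:]
    elif off < 0:
        vb = vb[-off:]
    n = min(va.size, vb.size)
    if n < corr_window:
        raise ConfigError(
            f"common overlap of {n} slopes shorter than one {corr_window}-slope window")
    r, valid = _window_correlations(va[:n], vb[:n], corr_window)
    n_windows = int(valid.sum())
    if n_windows == 0:
        raise DataQualityError("no usable correlation window (all zero-variance)")
    return PairConcordance(a.participant_id, b.participant_id,
                           _log_ratio(r, valid, eps), n_windows,
                           int((~valid).sum()))


def _stack_slopes(slopes: Sequence[SlopeSeries]) -> np.ndarray:
    """Align series on the latest start time (1-s slope steps, sub-step
    remainders tolerated) and truncate to the common span."""
    t_max = max(s.t0 for s in slopes)
    trimmed = [s.values[int(round(t_max - s.t0)):] for s in slopes]
    n = min(v.size for v in trimmed)
    if n < 1:
        raise ConfigError("no common time span across slope series")
    return np.stack([v[:n] for v in trimmed])


def _pair_index_matrix(S: np.ndarray, corr_window: int, eps: float):
    """Concordance index for every unordered pair of rows of S (P x L).

    Returns (indices, n_windows, n_skipped) arrays over pairs in
    itertools.combinations order.
    """
    P = S.shape[0]
    sw = sliding_window_view(S, corr_window, axis=1)        # (P, W, k)
    c = sw - sw.mean(axis=2, keepdims=True)
    nrm = np.linalg.norm(c, axis=2)                          # (P, W)
    ia, ib = np.triu_indices(P, k=1)
    num = np.einsum("pwk,pwk->pw", c[ia], c[ib])             # (n_pairs, W)
    den = nrm[ia] * nrm[ib]
    valid = den > 0
    r = np.zeros_like(num)
    np.divide(num, den, out=r, where=valid)
    pos = np.where(valid & (r > 0), r, 0.0).sum(axis=1)
    neg = -np.where(valid & (r < 0), r, 0.0).sum(axis=1)
    idx = np.log((pos + eps) / (neg + eps))
    return idx, valid.sum(axis=1), (~valid).sum(axis=1)


def _participant_means(P: int, pair_values: np.ndarray) -> np.ndarray:
    ia, ib = np.triu_indices(P, k=1)
    sums = np.zeros(P)
    np.add.at(sums, ia, pair_values)
    np.add.at(sums, ib, pair_values)
    return sums / (P - 1)


def group_similarity(slopes: Sequence[SlopeSeries], corr_window: int = CORR_WINDOW,
                     eps: float = DEFAULT_EPS):
    """All unordered pairwise indices plus each participant's mean index.

    Returns ``(pair_table, participants)`` where pair_table is a DataFrame
    (id_a, id_b, channel, index, n_windows, n_skipped) and participants a list
    of :class:`ParticipantSimilarity`.
    """
    if len(slopes) < 2:
        raise ConfigError("group similarity needs at least 2 participants")
    S = _stack_slopes(slopes)
    idx, n_win, n_skip = _pair_index_matrix(S, corr_window, eps)
    if (n_win == 0).any():
        raise DataQualityError("a pair has no usable correlation window")
    ids = [s.participant_id for s in slopes]
    channel = slopes[0].channel
    pairs = list(combinations(range(len(slopes)), 2))
    table = pd.DataFrame({
        "id_a": [ids[i] for i, _ in pairs],
        "id_b": [ids[j] for _, j in pairs],
        "channel": channel,
        "index": idx,
        "n_windows": n_win,
        "n_skipped": n_skip,
    })
    means = _participant_means(len(slopes), idx)
    parts = [ParticipantSimilarity(pid, channel, float(v)) for pid, v in zip(ids, means)]
    return table, parts


def participant_means_from_pairs(pair_table: pd.DataFrame) -> dict[str, float]:
    """Per-participant mean of pairwise indices from an explicit pair table."""
    acc: dict[str, list[float]] = {}
    for _, row in pair_table.iterrows():
        acc.setdefault(row["id_a"], []).append(row["index"])
        acc.setdefault(row["id_b"], []).append(row["index"])
    return {pid: float(np.mean(v)) for pid, v in acc.items()}


def one_sample_test(values: Sequence[ParticipantSimilarity] | np.ndarray):
    """Classical one-sample t of the participant similarities against zero."""
    vals = np.asarray([v.value if isinstance(v, ParticipantSimilarity) else v
                       for v in values], dtype=float)
    if vals.size < 2:
        raise ConfigError("one-sample t needs at least 2 values")
    if np.std(vals, ddof=1) == 0:
        raise ConfigError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(vals, 0.0)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# permutation surrogate test
# ---------------------------------------------------------------------------

def surrogate_p(s: float, mu0: float, sigma0: float) -> float:
    """p = erfc((|s - mu0| / sigma0) / sqrt(2)) — two-sided tail of the
    normal approximation to the surrogate null distribution."""
    if not sigma0 > 0:
        raise ConfigError("null standard deviation must be positive")
    return float(special.erfc((abs(s - mu0) / sigma0) / np.sqrt(2.0)))


def _group_t_from_signals(sig: np.ndarray, rate_hz: float, window_s: float,
                          step_s: float, corr_window: int, eps: float,
                          slope_weights: np.ndarray, slope_step: int) -> float:
    w = slope_weights.size
    windows = sliding_window_view(sig, w, axis=1)[:, ::slope_step]
    S = windows @ slope_weights
    idx, n_win, _ = _pair_index_matrix(S, corr_window, eps)
    means = _participant_means(sig.shape[0], idx)
    return float(means.mean() / (means.std(ddof=1) / np.sqrt(means.size)))


def permutation_test(recordings: Sequence[PhysioRecording], n_perm: int = 1000,
                     epoch_s: float = 1.0, seed: int | None = None,
                     window_s: float = 5.0, step_s: float = 1.0,
                     corr_window: int = CORR_WINDOW, eps: float = DEFAULT_EPS) -> PermutationResult:
    """Epoch-shuffling surrogate test of group-level concordance.

    Each participant's (preprocessed) signal is segmented into ``epoch_s``
    epochs which are independently shuffled in time per participant; the full
    slope -> concordance -> participant-average -> one-sample-t chain is
    re-run per permutation to build the null t distribution. The p-value is
    the erfc tail of the normal fit to that null.
    """
    if n_perm < 2:
        raise ConfigError("n_perm must be at least 2")
    if len(recordings) < 2:
        raise ConfigError("need at least 2 participants")
    rates = {r.rate_hz for r in recordings}
    if len(rates) != 1:
        raise ConfigError("recordings must share a sampling rate")
    rate = rates.pop()
    e = int(round(epoch_s * rate))
    L = min(r.samples.size for r in recordings)
    n_ep = L // e
    if n_ep < 1:
        raise ConfigError("epoch longer than the signal")
    L = n_ep * e
    if L < int(round(window_s * rate)):
        raise ConfigError("signal shorter than one slope window after epoching")
    sig = np.stack([r.samples[:L] for r in recordings])
    P = sig.shape[0]
    w = int(round(window_s * rate))
    slope_step = int(round(step_s * rate))
    weights = _ols_weights(w, rate)

    observed = _group_t_from_signals(sig, rate, window_s, step_s, corr_window,
                                     eps, weights, slope_step)
    rng = np.random.default_rng(seed)
    epochs = sig.reshape(P, n_ep, e)
    null_t = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = np.empty_like(sig)
        for p in range(P):
            order = rng.permutation(n_ep)
            shuffled[p] = epochs[p, order].reshape(-1)
        null_t[k] = _group_t_from_signals(shuffled, rate, window_s, step_s,
                                          corr_window, eps, weights, slope_step)
    mu0 = float(null_t.mean())
    sd0 = float(null_t.std(ddof=1))
    return PermutationResult(observed, mu0, sd0, n_perm,
                             surrogate_p(observed, mu0, sd0), null_t)


# ---------------------------------------------------------------------------
# knowledge similarity
# ---------------------------------------------------------------------------

def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """cos(theta) = x.y / (||x|| ||y||); undefined for a zero-norm vector."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ConfigError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(x, y) / (nx * ny))


def knowledge_similarity(vectors: Sequence[KnowledgeVector]) -> dict[str, float]:
    """Per-participant mean cosine similarity with everyone else in the group.

    Pairs involving an all-zero response vector are undefined; they are
    excluded and logged, and a participant whose every pair is excluded gets
    NaN.
    """
    if len(vectors) < 2:
        raise ConfigError("knowledge similarity needs at least 2 vectors")
    zero_norm = {v.participant_id for v in vectors if not v.answers.any()}
    if zero_norm:
        log.warning("excluding all pairs involving %s: zero-norm knowledge vector",
                    sorted(zero_norm))
    acc: dict[str, list[float]] = {v.participant_id: [] for v in vectors}
    for va, vb in combinations(vectors, 2):
        if va.participant_id in zero_norm or vb.participant_id in zero_norm:
            continue
        c = cosine_similarity(va.answers, vb.answers)
        acc[va.participant_id].append(c)
        acc[vb.participant_id].append(c)
    return {pid: (float(np.mean(v)) if v else float("nan")) for pid, v in acc.items()}


def knowledge_similarity_change(pre: Sequence[KnowledgeVector],
                                post: Sequence[KnowledgeVector]) -> dict[str, float]:
    """Post-minus-pre change in each participant's mean cosine similarity."""
    s_pre = knowledge_similarity(pre)
    s_post = knowledge_similarity(post)
    if set(s_pre) != set(s_post):
        raise ConfigError("pre and post vectors cover different participants")
    return {pid: s_post[pid] - s_pre[pid] for pid in s_pre}
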