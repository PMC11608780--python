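"""Synthetic study generator with known ground truth.

Emulates a two-group music-learning study: per-participant skin-conductance
signals built from a tonic random-walk plus SCR-shaped phasic events, a
tunable fraction of which come from a shared group-level event process
(coupling); inter-beat-interval series with slow shared/idiosyncratic
modulation and isolated missed/extra-beat artifacts; press-and-hold pleasure
rating streams; and binary 10-item knowledge vectors. A structural mediation
model (group dummy X -> latent alignment M -> liking change Y) is wired
through the dataset so that downstream inference can recover the generating
paths.

All randomness flows from a single seed through numpy.random.SeedSequence
spawning, so a fixed seed fixes every generated artifact exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .errors import ConfigError
from .signal_io import (KnowledgeVector, PhysioRecording, RatingStream,
                        read_ibi, read_knowledge, read_manifest, read_ratings,
                        read_recording, write_ibi, write_knowledge,
                        write_manifest, write_ratings, write_recording)

GROUPS = ("analytical", "historical")

# SCR kernel time constants (seconds): canonical fast-rise / slow-decay shape
SCR_RISE_S = 1.0
SCR_DECAY_S = 4.0
SCR_KERNEL_LEN_S = 25.0


@dataclass
class GenConfig:
    """Generator settings. Defaults emulate the study conditions: two groups
    of 24 female learners, ~10-minute recordings at 250 Hz, a strong
    shared-arousal coupling in the analytical-knowledge group and a weak one
    in the historical group, and a full-mediation structure (a, b > 0,
    c' = 0)."""

    n_per_group: int = 24
    duration_s: float = 600.0
    sc_rate_hz: float = 250.0
    #: fraction of phasic drive shared across participants, per group
    coupling: dict = field(default_factory=lambda: {"analytical": 0.7, "historical": 0.2})
    event_rate_hz: float = 0.05          # mean SCR rate (3 per minute)
    scr_amp_us: float = 0.4              # median SCR amplitude, uS
    event_jitter_s: float = 0.2          # per-participant jitter on shared events
    tonic_drift_sd: float = 0.02         # random-walk innovation, uS per sqrt(s)
    sc_baseline_us: float = 5.0
    noise_sd: float = 0.01               # additive white measurement noise, uS
    ibi_mean_ms: float = 800.0
    ibi_sd_ms: float = 50.0
    ibi_mod_weight: float = 1.0          # scale of the slow IBI modulation
    hr_coupling: float = 0.5             # shared-modulation weight, both groups
    artifact_rate: float = 1.0           # artifact beats per minute
    mediation_a: float = 0.6             # standardized path X -> M
    mediation_b: float = 0.5             # standardized path M -> Y
    mediation_c_prime: float = 0.0       # standardized direct path X -> Y
    coupling_m_scale: float = 0.15       # coupling shift per SD of mediator residual
    liking_base: float = 3.0             # expected level-4 press count, pre phase
    liking_gain: float = 3.0             # liking-index units per SD of outcome
    liking_change_mean: float = 2.7      # mean liking-index change
    empathy_loading: float = 0.35        # corr of empathy covariate with mediator
    knowledge_p_correct_pre: float = 0.35
    knowledge_p_correct_post: float = 0.78
    knowledge_item_sd: float = 0.15      # between-item easiness spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if not self.duration_s > 0:
            raise ConfigError("duration_s must be strictly positive")
        for name in ("sc_rate_hz", "event_rate_hz", "ibi_sd_ms"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not self.ibi_mean_ms > 200:
            raise ConfigError("ibi_mean_ms must exceed 200 ms")
        if self.artifact_rate < 0:
            raise ConfigError("artifact_rate must be non-negative")
        for g, c in self.coupling.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
            _check_unit(c, f"coupling[{g}]")
        _check_unit(self.hr_coupling, "hr_coupling")
        _check_unit(self.knowledge_p_correct_pre, "knowledge_p_correct_pre")
        _check_unit(self.knowledge_p_correct_post, "knowledge_p_correct_post")


def _check_unit(v: float, name: str) -> None:
    if not 0.0 <= v <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class IBISeries:
    participant_id: str
    intervals_ms: np.ndarray
    artifact_mask: np.ndarray


@dataclass
class StudyDataset:
    """Full study bundle as produced by :func:`generate_study` (truth present)
    or loaded from disk (truth restored from the manifest)."""

    participants: list
    group: dict                      # pid -> group label
    sc_recordings: dict              # pid -> PhysioRecording
    hr_ibi: dict                     # pid -> IBISeries
    ratings_pre: dict                # pid -> RatingStream
    ratings_post: dict
    knowledge: dict                  # (test, phase) -> {pid -> KnowledgeVector}
    covariates: pd.DataFrame         # indexed by pid; includes 'empathy'
    truth: dict | None = None        # {'config', 'table': per-participant frame}

    def group_ids(self, group: str) -> list:
        return [p for p in self.participants if self.group[p] == group]

    def mediation_frame(self) -> pd.DataFrame:
        """Tidy frame (x, m, y, empathy) for structural-parameter recovery:
        x the group dummy (analytical = 1), m the generated per-participant
        alignment score, y the liking change measured from the rating streams."""
        from .behavior import liking_change, liking_index

        if self.truth is None:
            raise ConfigError("mediation_frame needs generator truth")
        tab = self.truth["table"].set_index("participant")
        rows = []
        for pid in self.participants:
            y = liking_change(liking_index(self.ratings_pre[pid], "pre"),
                              liking_index(self.ratings_post[pid], "post"))
            rows.append({"participant": pid, "x": float(self.group[pid] == "analytical"),
                         "m": tab.loc[pid, "m"], "y": y,
                         "empathy": self.covariates.loc[pid, "empathy"]})
        return pd.DataFrame(rows)

    # -- persistence ------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        for sub in ("sc", "ibi", "ratings"):
            (path / sub).mkdir(parents=True, exist_ok=True)
        for pid in self.participants:
            write_recording(self.sc_recordings[pid], path / "sc" / f"{pid}.csv")
            write_ibi(self.hr_ibi[pid].intervals_ms, path / "ibi" / f"{pid}.csv")
            write_ratings(self.ratings_pre[pid], path / "ratings" / f"{pid}_pre.csv")
            write_ratings(self.ratings_post[pid], path / "ratings" / f"{pid}_post.csv")
        vectors = [v for d in self.knowledge.values() for v in d.values()]
        write_knowledge(vectors, path / "knowledge.csv")
        self.covariates.rename_axis("participant").reset_index().to_csv(
            path / "participants.csv", index=False)
        manifest = {"groups": {p: self.group[p] for p in self.participants}}
        if self.truth is not None:
            manifest["config"] = asdict(self.truth["config"])
            self.truth["table"].to_csv(path / "truth.csv", index=False)
            manifest["truth_table"] = "truth.csv"
        write_manifest(manifest, path / "manifest.yaml")

    @classmethod
    def from_dir(cls, path: str | Path) -> "StudyDataset":
        path = Path(path)
        manifest = read_manifest(path / "manifest.yaml")
        groups = manifest["groups"]
        pids = list(groups)
        sc = {p: read_recording(path / "sc" / f"{p}.csv", "SC") for p in pids}
        ibi = {}
        for p in pids:
            iv = read_ibi(path / "ibi" / f"{p}.csv")
            ibi[p] = IBISeries(p, iv, np.zeros(iv.size, bool))
        r_pre = {p: read_ratings(path / "ratings" / f"{p}_pre.csv") for p in pids}
        r_post = {p: read_ratings(path / "ratings" / f"{p}_post.csv") for p in pids}
        knowledge: dict = {}
        for v in read_knowledge(path / "knowledge.csv"):
            knowledge.setdefault((v.test, v.phase), {})[v.participant_id] = v
        cov = pd.read_csv(path / "participants.csv").set_index("participant")
        cov.index = cov.index.astype(str)
        truth = None
        if "config" in manifest:
            truth = {"config": GenConfig(**manifest["config"]),
                     "table": pd.read_csv(path / manifest["truth_table"])}
        return cls(pids, groups, sc, ibi, r_pre, r_post, knowledge, cov, truth)


# ---------------------------------------------------------------------------
# skin conductance
# ---------------------------------------------------------------------------

def scr_kernel(rate_hz: float, rise_s: float = SCR_RISE_S,
               decay_s: float = SCR_DECAY_S) -> np.ndarray:
    """Difference-of-exponentials SCR shape, normalized to unit peak."""
    t = np.arange(0.0, SCR_KERNEL_LEN_S, 1.0 / rate_hz)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def generate_sc_group(cfg: GenConfig, group_coupling, rng_seed,
                      id_prefix: str = "p") -> list[PhysioRecording]:
    """Skin-conductance signals for one group.

    Each participant keeps every shared-pool event with probability equal to
    their coupling (with per-participant onset jitter) and adds idiosyncratic
    events at the complementary rate, so the marginal SCR rate is
    ``event_rate_hz`` at every coupling. ``group_coupling`` may be a scalar or
    one value per participant.
    """
    coup = np.broadcast_to(np.asarray(group_coupling, float), (cfg.n_per_group,))
    for c in coup:
        _check_unit(c, "group_coupling")
    if not cfg.duration_s > 0:
        raise ConfigError("duration_s must be strictly positive")
    rng = np.random.default_rng(rng_seed)
    fs = cfg.sc_rate_hz
    L = int(round(cfg.duration_s * fs))
    if L < 1:
        raise ConfigError("duration too short for one sample")
    kernel = scr_kernel(fs)
    n_pool = rng.poisson(cfg.event_rate_hz * cfg.duration_s)
    pool_t = np.sort(rng.uniform(0.0, cfg.duration_s, n_pool))
    pool_amp = rng.lognormal(np.log(cfg.scr_amp_us), 0.5, n_pool)
    out = []
    for i in range(cfg.n_per_group):
        c = float(coup[i])
        keep = rng.random(n_pool) < c
        t_ev = pool_t[keep] + rng.normal(0.0, cfg.event_jitter_s, int(keep.sum()))
        a_ev = pool_amp[keep]
        n_idio = rng.poisson(cfg.event_rate_hz * (1.0 - c) * cfg.duration_s)
        t_ev = np.concatenate([t_ev, rng.uniform(0.0, cfg.duration_s, n_idio)])
        a_ev = np.concatenate([a_ev, rng.lognormal(np.log(cfg.scr_amp_us), 0.5, n_idio)])
        train = np.zeros(L)
        sidx = np.floor(t_ev * fs).astype(int)
        ok = (sidx >= 0) & (sidx < L)
        np.add.at(train, sidx[ok], a_ev[ok])
        phasic = fftconvolve(train, kernel)[:L]
        tonic = cfg.sc_baseline_us + np.cumsum(
            rng.normal(0.0, cfg.tonic_drift_sd / np.sqrt(fs), L))
        noise = rng.normal(0.0, cfg.noise_sd, L) if cfg.noise_sd > 0 else 0.0
        out.append(PhysioRecording(f"{id_prefix}{i + 1:02d}", "SC", fs,
                                   phasic + tonic + noise))
    return out


# ---------------------------------------------------------------------------
# inter-beat intervals
# ---------------------------------------------------------------------------

def _slow_modulation(rng: np.random.Generator, t: np.ndarray, duration_s: float,
                     knot_every_s: float = 10.0) -> np.ndarray:
    """Unit-variance smooth modulation: cubic spline through N(0,1) knots
    (kink-free, like slow autonomic drift)."""
    from scipy.interpolate import CubicSpline

    n_knots = max(4, int(np.ceil(duration_s / knot_every_s)) + 1)
    kt = np.linspace(0.0, duration_s, n_knots)
    kv = rng.standard_normal(n_knots)
    return CubicSpline(kt, kv)(np.clip(t, kt[0], kt[-1]))


def generate_ibi_group(cfg: GenConfig, group_coupling: float, rng_seed,
                       id_prefix: str = "p") -> list[IBISeries]:
    """IBI series: baseline + slow shared modulation (weight group_coupling)
    + idiosyncratic modulation + occasional artifact beats (isolated intervals
    doubled or halved — missed / extra beat), flagged in the mask."""
    _check_unit(group_coupling, "group_coupling")
    if not cfg.ibi_mean_ms > 200:
        raise ConfigError("ibi_mean_ms must exceed 200 ms")
    rng = np.random.default_rng(rng_seed)
    n_beats = int(round(cfg.duration_s * 1000.0 / cfg.ibi_mean_ms))
    if n_beats < 4:
        raise ConfigError("duration too short for an IBI series")
    t_nominal = np.arange(n_beats) * cfg.ibi_mean_ms / 1000.0
    shared = _slow_modulation(rng, t_nominal, cfg.duration_s)
    w = group_coupling
    out = []
    for i in range(cfg.n_per_group):
        own = _slow_modulation(rng, t_nominal, cfg.duration_s)
        mod = cfg.ibi_mod_weight * (w * shared + np.sqrt(max(0.0, 1.0 - w**2)) * own)
        jitter = rng.normal(0.0, 0.2 * cfg.ibi_sd_ms, n_beats)
        iv = cfg.ibi_mean_ms + cfg.ibi_sd_ms * mod + jitter
        iv = np.maximum(iv, 250.0)
        mask = np.zeros(n_beats, bool)
        n_art = rng.poisson(cfg.artifact_rate * cfg.duration_s / 60.0)
        candidates = rng.permutation(n_beats)
        placed = 0
        for idx in candidates:
            if placed >= n_art:
                break
            lo, hi = max(0, idx - 1), min(n_beats, idx + 2)
            if mask[lo:hi].any():
                continue  # keep artifacts isolated
            iv[idx] = iv[idx] * 2.0 if rng.random() < 0.5 else iv[idx] / 2.0
            mask[idx] = True
            placed += 1
        out.append(IBISeries(f"{id_prefix}{i + 1:02d}", iv, mask))
    return out


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def _episode_stream(pid: str, counts: dict[int, int], duration_s: float,
                    rng: np.random.Generator) -> RatingStream:
    """Non-overlapping episodes with exactly the given per-level counts,
    placed by pairing sorted uniform points as (onset, offset)."""
    levels = [lvl for lvl, k in sorted(counts.items()) for _ in range(k)]
    K = len(levels)
    if K == 0 or duration_s <= 0:
        return RatingStream(pid, [])
    pts = np.sort(rng.uniform(0.0, duration_s, 2 * K))
    order = rng.permutation(K)
    episodes = [(pts[2 * j], pts[2 * j + 1], levels[order[j]]) for j in range(K)]
    # degenerate zero-length intervals are vanishingly unlikely; drop them
    episodes = [(a, b, l) for a, b, l in episodes if b > a]
    return RatingStream(pid, episodes)


def generate_ratings(expected_count_4: float, expected_count_5: float,
                     duration_s: float, rng_seed, participant_id: str = "p",
                     expected_count_low: float = 2.0) -> RatingStream:
    """Rating stream whose level-4 and level-5 episode counts are Poisson with
    the stated means (plus a few low-pleasure episodes at levels 1-3)."""
    if expected_count_4 < 0 or expected_count_5 < 0 or expected_count_low < 0:
        raise ConfigError("expected counts must be non-negative")
    if duration_s < 0:
        raise ConfigError("duration must be non-negative")
    rng = np.random.default_rng(rng_seed)
    if duration_s == 0:
        return RatingStream(participant_id, [])
    counts = {4: int(rng.poisson(expected_count_4)),
              5: int(rng.poisson(expected_count_5))}
    n_low = int(rng.poisson(expected_count_low))
    low_levels = rng.integers(1, 4, n_low)
    for lvl in low_levels:
        counts[int(lvl)] = counts.get(int(lvl), 0) + 1
    return _episode_stream(participant_id, counts, duration_s, rng)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def generate_study(cfg: GenConfig) -> StudyDataset:
    """Complete study-shaped dataset with mediation truth.

    The structural model: x = 1 for the analytical group; latent mediator
    m = a*x + e_m scaled to unit marginal variance; outcome
    y = b*m + c'*x + e_y likewise. The mediator residual shifts each
    participant's shared-event coupling (so measured concordance tracks m),
    and y is carried into the post-learning rating stream as an integer
    liking-index change round(liking_change_mean + liking_gain * y).
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_struct, s_sc_a, s_sc_h, s_ibi_a, s_ibi_h, s_rate, s_knw = ss.spawn(7)
    rng = np.random.default_rng(s_struct)

    n = cfg.n_per_group
    ids = [f"a{i + 1:02d}" for i in range(n)] + [f"h{i + 1:02d}" for i in range(n)]
    groups = {pid: ("analytical" if pid.startswith("a") else "historical") for pid in ids}
    x = np.array([1.0] * n + [0.0] * n)

    a, b, cp = cfg.mediation_a, cfg.mediation_b, cfg.mediation_c_prime
    var_em = max(0.05, 1.0 - a * a / 4.0)           # unit marginal variance of m
    em = rng.normal(0.0, np.sqrt(var_em), 2 * n)
    m = a * x + em
    var_ey = max(0.05, 1.0 - (b * b + cp * cp / 4.0 + a * b * cp / 2.0))
    y = b * m + cp * x + rng.normal(0.0, np.sqrt(var_ey), 2 * n)
    rho = cfg.empathy_loading
    empathy = rho * m + rng.normal(0.0, np.sqrt(max(0.0, 1.0 - rho**2)), 2 * n)

    coup = np.clip(np.array([cfg.coupling[groups[p]] for p in ids])
                   + cfg.coupling_m_scale * em, 0.0, 1.0)

    sc = {}
    for grp, s_sc, sl in (("analytical", s_sc_a, slice(0, n)),
                          ("historical", s_sc_h, slice(n, 2 * n))):
        recs = generate_sc_group(cfg, coup[sl], s_sc, id_prefix=grp[0])
        for r in recs:
            sc[r.participant_id] = r
    ibi = {}
    for grp, s_ibi in (("analytical", s_ibi_a), ("historical", s_ibi_h)):
        for series in generate_ibi_group(cfg, cfg.hr_coupling, s_ibi, id_prefix=grp[0]):
            ibi[series.participant_id] = series

    rng_rate = np.random.default_rng(s_rate)
    ratings_pre, ratings_post = {}, {}
    pre_idx = np.zeros(2 * n)
    change = np.zeros(2 * n)
    for i, pid in enumerate(ids):
        n4 = int(rng_rate.poisson(cfg.liking_base))
        n5 = int(rng_rate.poisson(cfg.liking_base / 2.0))
        n_low = int(rng_rate.poisson(2.0))
        counts = {4: n4, 5: n5}
        for lvl in rng_rate.integers(1, 4, n_low):
            counts[int(lvl)] = counts.get(int(lvl), 0) + 1
        ratings_pre[pid] = _episode_stream(pid, counts, cfg.duration_s, rng_rate)
        pre = n4 + 2 * n5
        target_change = int(round(cfg.liking_change_mean + cfg.liking_gain * y[i]))
        post = max(0, pre + target_change)
        n5_post = int(rng_rate.integers(0, post // 2 + 1))
        n4_post = post - 2 * n5_post
        counts_post = {4: n4_post, 5: n5_post}
        for lvl in rng_rate.integers(1, 4, int(rng_rate.poisson(2.0))):
            counts_post[int(lvl)] = counts_post.get(int(lvl), 0) + 1
        ratings_post[pid] = _episode_stream(pid, counts_post, cfg.duration_s, rng_rate)
        pre_idx[i] = pre
        change[i] = post - pre

    rng_k = np.random.default_rng(s_knw)
    item_eff = {t: rng_k.normal(0.0, cfg.knowledge_item_sd, 10) for t in ("analytical", "historical")}
    knowledge: dict = {(t, ph): {} for t in ("analytical", "historical") for ph in ("pre", "post")}
    for pid in ids:
        own = groups[pid]
        for test in ("analytical", "historical"):
            for phase in ("pre", "post"):
                p_base = (cfg.knowledge_p_correct_post
                          if (phase == "post" and test == own)
                          else cfg.knowledge_p_correct_pre)
                p_items = np.clip(p_base + item_eff[test], 0.02, 0.98)
                answers = (rng_k.random(10) < p_items).astype(int)
                knowledge[(test, phase)][pid] = KnowledgeVector(pid, test, phase, answers)

    covariates = pd.DataFrame({"empathy": empathy},
                              index=pd.Index(ids, name="participant"))
    truth_table = pd.DataFrame({
        "participant": ids,
        "group": [groups[p] for p in ids],
        "x": x, "m": m, "y": y,
        "coupling": coup,
        "empathy": empathy,
        "pre_liking_index": pre_idx,
        "liking_change": change,
    })
    truth = {"config": cfg, "table": truth_table,
             "paths": {"a": a, "b": b, "c_prime": cp}}
    return StudyDataset(ids, groups, sc, ibi, ratings_pre, ratings_post,
                        knowledge, covariates, truth)
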