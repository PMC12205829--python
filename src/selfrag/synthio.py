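"""Synthetic study generator.

Emulates the statistical structure the downstream analysis assumes: 33 dyads
(66 participants), 120 trait adjectives with stable baseline offsets and
latent semantic clusters, 30 traits randomly assigned to each of the four
conditions per participant, a planted inter-cluster dispersion effect in
asyncSelf self-ratings, condition-specific recognition-memory strength,
ownership-questionnaire effects, and threat-evoked skin-conductance bumps
with 1/n habituation.

Generative model for ratings
----------------------------
Each trait ``t`` carries a baseline ``b_t ~ N(0, trait_baseline_sd^2)`` on top
of the scale midpoint 5 and a fixed cluster label ``k(t)``.  Each participant
assigns cluster centers ``c_k`` — an equally spaced, zero-mean grid with step
``between_cluster_spread``, randomly permuted over cluster labels — and the
latent self value is ``v = 5 + b_t + c_k + N(0, within_cluster_sd^2)``.  In
asyncSelf the centers are inflated to ``(1 + delta) * c_k``; that multiplier
is the planted fragmentation effect.  Friend ratings use an independent
center permutation and delta = 0.  Observed ratings are
``round(clip(v + N(0, rating_noise_sd^2), 1, 9))``; each trial times out
(missing rating and reaction time) with probability ``timeout_prob``.

Memory responses follow an equal-variance signal-detection model with a
single criterion at ``dprime_base / 2`` (unbiased for the base sensitivity):
old-item evidence ~ N(d'_c, 1) with d'_c = dprime_base minus
``dprime_async_deficit`` for asyncSelf items, new-item evidence ~ N(0, 1).

One RNG stream per participant and component is derived from the master
seed, so adding participants or skipping components never perturbs the
draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ingest import CONDITIONS, STATEMENTS, SAMPLING_RATE_HZ, StudyDataset, validate_study

ALL_COMPONENTS = ("ratings", "questionnaires", "memory", "scr")


class ConfigError(ValueError):
    """Invalid synthetic-study configuration."""


@dataclass
class SynthConfig:
    """Planted-effect configuration; defaults are the emulated study conditions."""

    n_dyads: int = 33
    n_traits: int = 120
    n_semantic_clusters: int = 4
    traits_per_condition: int = 30
    trait_baseline_sd: float = 1.0
    within_cluster_sd: float = 0.6
    between_cluster_spread: float = 1.5
    frag_effect_delta: float = 0.25      # asyncSelf center multiplier is 1 + delta
    rating_noise_sd: float = 0.5
    timeout_prob: float = 0.03
    dprime_base: float = 1.8
    dprime_async_deficit: float = 0.3
    memory_timeout_prob: float = 0.02
    ownership_sync: float = 2.0          # mean I1 in synchronous conditions
    ownership_async: float = -0.5
    scr_base_amp: float = 2.0            # uS, first-threat peak-minus-trough
    scr_ownership_attenuation: float = 0.4   # multiplies asyncSelf amplitudes by 1-x
    scr_noise_sd: float = 0.05
    scr_baseline_uS: float = 8.0
    scr_trace_duration_s: float = 60.0
    scr_event_onsets_s: tuple = (12.0, 24.0, 36.0)
    rt_lognormal_params: tuple = (0.7, 0.4)  # (mu, sigma) of log reaction time
    rt_max_s: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        pos = ("trait_baseline_sd", "within_cluster_sd", "rating_noise_sd",
               "scr_noise_sd")
        for name in pos:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0 <= self.timeout_prob < 1):
            raise ConfigError("timeout_prob must be in [0, 1)")
        if not (0 <= self.memory_timeout_prob < 1):
            raise ConfigError("memory_timeout_prob must be in [0, 1)")
        if not (0 <= self.scr_ownership_attenuation <= 1):
            raise ConfigError("scr_ownership_attenuation must be in [0, 1]")
        if self.frag_effect_delta < -1:
            raise ConfigError("frag_effect_delta must be >= -1")
        if self.n_traits % len(CONDITIONS) != 0:
            raise ConfigError("n_traits must divide evenly across conditions")
        if self.traits_per_condition * len(CONDITIONS) != self.n_traits:
            raise ConfigError("traits_per_condition * 4 must equal n_traits")
        if self.n_traits % self.n_semantic_clusters != 0:
            raise ConfigError("n_traits must divide across semantic clusters")
        if self.n_dyads < 1:
            raise ConfigError("need at least one dyad")
        if self.scr_base_amp < 0:
            raise ConfigError("scr_base_amp must be >= 0")


def generate_scr_trace(amp: float, onset_s: float, duration_s: float,
                       noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-baseline trace with one threat-response bump plus noise.

    The response rises monotonically from 0 at the event onset to ``amp``
    at onset + 6 s along ``u + sin(2*pi*u)/(2*pi)`` (steep at both ends, so
    the window extremes sit on isolated samples and noise inflates the
    measured max-minus-min only minimally), then recovers to baseline over
    a 2 s cosine ramp.  The peak-minus-trough amplitude inside
    [onset, onset + 6 s] equals ``amp`` exactly when ``noise_sd`` is 0.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if amp < 0:
        raise ValueError("amp must be >= 0")
    n = int(round(duration_s * SAMPLING_RATE_HZ)) + 1
    t = np.arange(n) / SAMPLING_RATE_HZ
    trace = np.zeros(n)
    rise = (t >= onset_s) & (t <= onset_s + 6.0)
    u = (t[rise] - onset_s) / 6.0
    trace[rise] = amp * (u + np.sin(2 * np.pi * u) / (2 * np.pi))
    fall = (t > onset_s + 6.0) & (t <= onset_s + 8.0)
    trace[fall] = amp * 0.5 * (1 + np.cos(np.pi * (t[fall] - onset_s - 6.0) / 2.0))
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    return trace


def _trait_world(cfg: SynthConfig):
    """Trait-level quantities shared by every participant."""
    rng = np.random.default_rng([cfg.seed, 0])
    baselines = rng.normal(0.0, cfg.trait_baseline_sd, size=cfg.n_traits)
    clusters = np.arange(cfg.n_traits) % cfg.n_semantic_clusters
    trait_ids = [f"t{i:03d}" for i in range(cfg.n_traits)]
    return trait_ids, baselines, clusters


def _center_grid(cfg: SynthConfig) -> np.ndarray:
    k = cfg.n_semantic_clusters
    return cfg.between_cluster_spread * (np.arange(k) - (k - 1) / 2.0)


def _discretize(latent: np.ndarray) -> np.ndarray:
    return np.clip(np.round(latent), 1, 9).astype(int)


def generate_study(cfg: SynthConfig | None = None,
                   components: tuple = ALL_COMPONENTS) -> StudyDataset:
    """Deterministically generate a complete synthetic study.

    ``components`` may be restricted (e.g. ``("ratings",)``) for replicate
    simulations; each component draws from its own per-participant RNG
    stream, so a subset generates exactly the rows the full run would.
    """
    cfg = cfg or SynthConfig()
    cfg.validate()
    trait_ids, baselines, clusters = _trait_world(cfg)
    grid = _center_grid(cfg)
    n_participants = 2 * cfg.n_dyads

    rating_rows, quest_rows, mem_rows = [], [], []
    scr_frames, event_rows = [], []

    mu_rt, sd_rt = cfg.rt_lognormal_params
    for p in range(n_participants):
        pid = f"p{p + 1:03d}"
        did = f"d{p // 2 + 1:03d}"
        design_rng = np.random.default_rng([cfg.seed, 1 + p, 0])

        # design: trait -> condition assignment and session condition order
        perm = design_rng.permutation(cfg.n_traits)
        trait_condition = np.empty(cfg.n_traits, dtype=object)
        for ci, cond in enumerate(CONDITIONS):
            sl = perm[ci * cfg.traits_per_condition:(ci + 1) * cfg.traits_per_condition]
            trait_condition[sl] = cond
        cond_order = [CONDITIONS[i] for i in design_rng.permutation(len(CONDITIONS))]
        self_centers = design_rng.permutation(grid)
        friend_centers = design_rng.permutation(grid)
        # timeouts live in the design stream so ratings and memory bookkeeping agree
        friend_timeout = design_rng.random(cfg.n_traits) < cfg.timeout_prob
        self_timeout = design_rng.random(cfg.n_traits) < cfg.timeout_prob

        if "ratings" in components:
            rng = np.random.default_rng([cfg.seed, 1 + p, 1])

            def draw_block(centers, mult, idx):
                lat = (5.0 + baselines[idx] + mult * centers[clusters[idx]]
                       + rng.normal(0, cfg.within_cluster_sd, size=len(idx))
                       + rng.normal(0, cfg.rating_noise_sd, size=len(idx)))
                obs = _discretize(lat)
                rt = np.minimum(rng.lognormal(mu_rt, sd_rt, size=len(idx)), cfg.rt_max_s)
                return obs, rt

            all_idx = np.arange(cfg.n_traits)
            obs, rt = draw_block(friend_centers, 1.0, all_idx)
            for i in all_idx:
                to = friend_timeout[i]
                rating_rows.append((pid, did, "friend", None, trait_ids[i],
                                    None if to else int(obs[i]),
                                    None if to else float(rt[i])))
            for cond in CONDITIONS:
                idx = np.flatnonzero(trait_condition == cond)
                mult = 1.0 + cfg.frag_effect_delta if cond == "asyncSelf" else 1.0
                obs, rt = draw_block(self_centers, mult, idx)
                for j, i in enumerate(idx):
                    to = self_timeout[i]
                    rating_rows.append((pid, did, "self", cond, trait_ids[i],
                                        None if to else int(obs[j]),
                                        None if to else float(rt[j])))

        if "questionnaires" in components:
            rng = np.random.default_rng([cfg.seed, 1 + p, 2])
            means = {"I1": None, "I2": None, "I3": None,
                     "C1": -2.0, "C2": -2.0, "C3": -2.0, "C4": -2.0, "L1": 0.0}
            for cond in CONDITIONS:
                own = cfg.ownership_sync if cond.startswith("sync") else cfg.ownership_async
                for st in STATEMENTS:
                    mu = own if st in ("I1", "I2", "I3") else means[st]
                    val = int(np.clip(np.round(mu + rng.normal()), -3, 3))
                    quest_rows.append((pid, cond, st, val))

        if "memory" in components:
            rng = np.random.default_rng([cfg.seed, 1 + p, 3])
            criterion = cfg.dprime_base / 2.0
            for i in range(cfg.n_traits):
                cond = trait_condition[i]
                dp = cfg.dprime_base - (cfg.dprime_async_deficit
                                        if cond == "asyncSelf" else 0.0)
                evidence = rng.normal(dp, 1.0)
                resp = "old" if evidence > criterion else "new"
                if rng.random() < cfg.memory_timeout_prob:
                    resp = "timeout"
                mem_rows.append((pid, trait_ids[i], "old", cond,
                                 bool(~friend_timeout[i] and ~self_timeout[i]), resp))
            for i in range(cfg.n_traits):
                evidence = rng.normal(0.0, 1.0)
                resp = "old" if evidence > criterion else "new"
                if rng.random() < cfg.memory_timeout_prob:
                    resp = "timeout"
                mem_rows.append((pid, f"n{i:03d}", "new", None, False, resp))

        if "scr" in components:
            rng = np.random.default_rng([cfg.seed, 1 + p, 4])
            for ci, cond in enumerate(CONDITIONS):
                order_pos = cond_order.index(cond)
                n = int(round(cfg.scr_trace_duration_s * SAMPLING_RATE_HZ)) + 1
                trace = np.full(n, cfg.scr_baseline_uS)
                atten = (1.0 - cfg.scr_ownership_attenuation
                         if cond == "asyncSelf" else 1.0)
                for k, onset in enumerate(cfg.scr_event_onsets_s):
                    rep = 3 * order_pos + k + 1
                    amp = atten * cfg.scr_base_amp / rep
                    trace = trace + generate_scr_trace(amp, onset,
                                                       cfg.scr_trace_duration_s,
                                                       0.0, rng)
                    event_rows.append((pid, cond, float(onset), rep))
                trace = trace + rng.normal(0, cfg.scr_noise_sd, size=n)
                scr_frames.append(pd.DataFrame({
                    "participant_id": pid, "condition": cond,
                    "sample_index": np.arange(n), "conductance_uS": trace,
                }))

    ratings = pd.DataFrame(rating_rows, columns=list(
        ("participant_id", "dyad_id", "target", "condition",
         "trait_id", "rating", "reaction_time_s")))
    ratings["rating"] = ratings["rating"].astype("Int64")
    ratings["reaction_time_s"] = ratings["reaction_time_s"].astype(float)
    quest = pd.DataFrame(quest_rows, columns=["participant_id", "condition",
                                              "statement_id", "rating"])
    memory = pd.DataFrame(mem_rows, columns=["participant_id", "trait_id", "status",
                                             "encoding_condition",
                                             "rated_at_encoding", "response"])
    scr = (pd.concat(scr_frames, ignore_index=True) if scr_frames
           else pd.DataFrame(columns=["participant_id", "condition",
                                      "sample_index", "conductance_uS"]))
    events = pd.DataFrame(event_rows, columns=["participant_id", "condition",
                                               "onset_s", "repetition"])
    ds = StudyDataset(ratings=ratings, questionnaires=quest, memory=memory,
                      scr=scr, scr_events=events,
                      meta={"source": "synthetic", "seed": cfg.seed,
                            "n_participants": n_participants,
                            "config": asdict(cfg)})
    if components == ALL_COMPONENTS:
        validate_study(ds)
    return ds


def ground_truth(cfg: SynthConfig) -> dict:
    """Planted trait-level quantities, for recovery tests."""
    trait_ids, baselines, clusters = _trait_world(cfg)
    return {"trait_ids": trait_ids, "baselines": baselines, "clusters": clusters}
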