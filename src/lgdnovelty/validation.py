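"""Calibration and recovery studies for the statistics chain.

These studies quantify what the pipeline does on data whose ground truth
is known by construction:

* :func:`run_null_calibration` — per-site type-I error of the
  cluster-based permutation test on label-exchangeable null epochs,
  before and after FDR across sites;
* :func:`run_recovery_study` — end-to-end recovery of planted
  state-dependent novelty effects (and the false-positive rate on null
  channels) through the full synthesize -> preprocess -> ERBP -> cluster
  test chain, plus the effect-count time courses used to check that
  local-deviance effects lead global-deviance effects in time;
* :func:`run_power_curve` — monotonicity of the flagged fraction in the
  planted effect amplitude.

The same functions back both the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import paradigm as par
from .clusterstats import (
    AEP_TEST,
    ClusterPermutationTest,
    ClusterTestConfig,
    fdr_adjust,
)
from .effects import call_site_effects, effect_timecourse
from .io import ContinuousRecording
from .paradigm import ParadigmConfig
from .pipeline import (
    EPOCH_WINDOW_MS,
    AnalysisConfig,
    channel_contrast_epochs,
    preprocess_recording,
    sequence_extents,
)
from .preprocess import reject_artifacts, smooth
from .synthgen import EffectSpec, GeneratorConfig, generate_recording


def _null_epochs(
    rng: np.random.Generator, n_trials: int, n_time: int, rate_hz: float = 1000.0
) -> np.ndarray:
    """Label-exchangeable null trials: 30-Hz low-passed white noise."""
    pad = 100
    x = rng.standard_normal((n_trials, n_time + 2 * pad))
    return smooth(x, rate_hz, 30.0)[:, pad:-pad]


def run_null_calibration(
    seed: int = 0,
    n_sites: int = 800,
    n_permutations: int = 1000,
    n_trials: tuple[int, int] = (50, 50),
    n_time: int = 200,
    config: ClusterTestConfig = AEP_TEST,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the site-level cluster test on pure-noise epochs.

    Returns the fraction of sites flagged at ``alpha`` before FDR (should
    sit near ``alpha``) and after BH correction across all sites' cluster
    p-values (should not exceed ``alpha`` in expectation).
    """
    cfg = ClusterTestConfig(
        window_ms=config.window_ms, n_permutations=n_permutations, tail=config.tail,
        percentile=config.percentile, alpha=alpha, seed=seed,
    )
    root = np.random.SeedSequence(seed)
    pre_flags = np.zeros(n_sites, dtype=bool)
    all_clusters: list[list] = []
    for i, ss in enumerate(root.spawn(n_sites)):
        rng = np.random.default_rng(ss)
        std = _null_epochs(rng, n_trials[0], n_time)
        dev = _null_epochs(rng, n_trials[1], n_time)
        res = ClusterPermutationTest(std, dev, config=cfg).fit(rng=rng)
        pre_flags[i] = res.significant(alpha, adjusted=False)
        all_clusters.append(res.clusters)
    flat = [c for site in all_clusters for c in site]
    if flat:
        p_adj, _ = fdr_adjust([c.p_mc for c in flat], q=alpha)
        for c, pa in zip(flat, p_adj):
            c.p_adj = float(pa)
    post_flags = np.array(
        [any(c.p_adj is not None and c.p_adj < alpha for c in site) for site in all_clusters]
    )
    return {
        "n_sites": n_sites,
        "pre_fdr_rate": float(pre_flags.mean()),
        "post_fdr_rate": float(post_flags.mean()),
        "alpha": alpha,
    }


def _recovery_generator_config(
    channel_ids_by_kind: dict[str, list[str]], n_channels: int, seed: int
) -> GeneratorConfig:
    effects = tuple(
        EffectSpec.detectable(ch, kind)
        for kind, chans in channel_ids_by_kind.items()
        for ch in chans
    )
    return GeneratorConfig(n_channels=n_channels, effects=effects, seed=seed)


def run_recovery_study(
    seed: int = 0,
    n_effect_channels_per_kind: int = 3,
    n_null_channels: int = 96,
    n_permutations: int = 1000,
    state: str = "awake",
    variant: str = "A",
    alpha: float = 0.05,
) -> dict:
    """Planted-effect recovery through the full pipeline.

    Synthesizes one block with the detectable-preset effect amplitudes on
    ``n_effect_channels_per_kind`` channels per effect kind and pure
    background on ``n_null_channels`` more, runs the complete chain, and
    scores, at per-site ``alpha`` pre-FDR:

    * recovery rate: fraction of planted (channel, contrast) pairs flagged;
    * false-positive rate: fraction of null (channel, contrast) tests flagged.

    Also returns the pooled-FDR site table and LD/GD time-course peaks.
    """
    kinds = ("AEP-LD", "HG-LD", "AEP-GD", "HG-GD")
    n_eff = n_effect_channels_per_kind * len(kinds)
    n_channels = n_eff + n_null_channels
    ids = [f"ch{i:03d}" for i in range(n_channels)]
    by_kind = {
        kind: ids[k * n_effect_channels_per_kind : (k + 1) * n_effect_channels_per_kind]
        for k, kind in enumerate(kinds)
    }
    # planted keys as (channel, effect, signal)
    planted = {
        (ch, kind.split("-")[1], kind.split("-")[0])
        for kind, chans in by_kind.items()
        for ch in chans
    }

    pcfg = ParadigmConfig(seed=seed)
    events = par.build_session(pcfg, variant=variant, n_blocks=1, rng_seed=seed)
    gcfg = _recovery_generator_config(by_kind, n_channels, seed)
    raw = generate_recording(gcfg, events, state=state, paradigm=pcfg)

    acfg = AnalysisConfig(
        paradigm=pcfg,
        aep_test=ClusterTestConfig(tail="two-tailed", percentile=99.5,
                                   n_permutations=n_permutations, seed=seed),
        hg_test=ClusterTestConfig(tail="one-tailed", percentile=99.0,
                                  n_permutations=n_permutations, seed=seed),
        alpha=alpha,
        seed=seed,
    )

    # Lazy per-channel providers keep only one channel's epochs in memory.
    cache: dict = {}

    def provider(ch: str, key: tuple):
        def build():
            if cache.get("channel") != ch:
                single = ContinuousRecording(
                    data=raw.data[raw.channel_index(ch)][None, :],
                    rate_hz=raw.rate_hz, channel_ids=[ch], state=raw.state,
                )
                rec = preprocess_recording(single, acfg)
                kept, _ = reject_artifacts(
                    rec, events, acfg.preprocess.artifact_sd_threshold,
                    window_ms=EPOCH_WINDOW_MS,
                )[ch]
                cache.clear()
                cache["channel"] = ch
                cache["epochs"] = channel_contrast_epochs(
                    rec, events, ch, acfg, kept, sequence_extents(events, rec.rate_hz)
                )
            return cache["epochs"][key]

        return build

    contrast_epochs = {
        (ch, effect, signal, state): provider(ch, (ch, effect, signal, state))
        for ch in ids
        for effect in ("LD", "GD")
        for signal in ("AEP", "HG")
    }
    table = call_site_effects(
        contrast_epochs, acfg.aep_test, acfg.hg_test, alpha=alpha, seed=seed
    )

    rec = table.records
    eff_ids = set(ids[:n_eff])
    is_planted = rec.apply(
        lambda r: (r["site"], r["effect"], r["signal"]) in planted, axis=1
    )
    planted_rows = rec[is_planted]
    null_rows = rec[~rec["site"].isin(eff_ids)]
    recovery = float(planted_rows["significant_pre_fdr"].mean())
    fp = float(null_rows["significant_pre_fdr"].mean())

    tc = effect_timecourse(table, roi_map={ch: "synthetic" for ch in ids})
    peaks = {}
    for effect in ("LD", "GD"):
        sel = tc[(tc["effect"] == effect) & (tc["signal"] == "AEP")]
        agg = sel.groupby("time_ms")["n_sites"].sum()
        peaks[effect] = float(agg.idxmax()) if agg.max() > 0 else float("nan")
    return {
        "n_planted_tests": int(len(planted_rows)),
        "n_null_tests": int(len(null_rows)),
        "recovery_rate": recovery,
        "false_positive_rate": fp,
        "site_table": table,
        "ld_peak_ms": peaks["LD"],
        "gd_peak_ms": peaks["GD"],
    }


def run_power_curve(
    amplitudes: tuple[float, ...] = (0.0, 0.4, 0.8),
    seed: int = 0,
    n_sites: int = 40,
    n_trials: tuple[int, int] = (60, 60),
    n_time: int = 200,
    n_permutations: int = 500,
    effect_window: tuple[int, int] = (60, 140),
    alpha: float = 0.05,
) -> list[float]:
    """Flagged fraction at each planted amplitude (units of the noise SD)."""
    rates = []
    cfg = ClusterTestConfig(n_permutations=n_permutations, seed=seed)
    for k, amp in enumerate(amplitudes):
        root = np.random.SeedSequence([seed, k])
        flags = []
        for ss in root.spawn(n_sites):
            rng = np.random.default_rng(ss)
            std = _null_epochs(rng, n_trials[0], n_time)
            dev = _null_epochs(rng, n_trials[1], n_time)
            dev[:, effect_window[0] : effect_window[1]] += amp
            res = ClusterPermutationTest(std, dev, config=cfg).fit(rng=rng)
            flags.append(res.significant(alpha, adjusted=False))
        rates.append(float(np.mean(flags)))
    return rates
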