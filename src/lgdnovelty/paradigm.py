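"""Local/global deviant (LGD) stimulus schedules.

The paradigm presents quintuples of two vowels (/a/ and /i/). Within a
trial, four identical vowels are followed by a fifth that either matches
(local standard, LS) or differs (local deviant, LD). Within a sequence,
one quintuple type is frequent (global standard, GS) and the base-matched
opposite-fifth type is rare (global deviant, GD), so the two axes of
novelty are crossed: a GD can be an LS or an LD depending on the sequence.

A recording block holds four sequences, one per quintuple type serving as
GS, in random order. Each sequence opens with habituation trials that
establish the global rule, followed by GS and GD test trials in
pseudorandom order. Two protocol variants are supported: variant ``A``
(80 GS + 20 GD test trials per sequence) and variant ``B`` (72 + 18, each
sequence preceded by a 15-s spoken-instruction gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VOWELS = ("a", "i")

#: Columns of the serialized event table, one row per trial.
EVENT_COLUMNS = [
    "trial_index",
    "block",
    "sequence",
    "onset_ms",
    "base_vowel",
    "fifth_vowel",
    "habituation",
    "local_label",
    "global_label",
]

# Test-trial counts per sequence for the two protocol variants.
_VARIANTS = {"A": (80, 20), "B": (72, 18)}

#: Silent gap, ms, replacing the spoken instruction before each variant-B sequence.
INSTRUCTION_GAP_MS = 15_000.0


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and counts of the LGD paradigm.

    Defaults follow the standard protocol: 100-ms vowels separated by
    50-ms gaps, five vowels per trial, 10 habituation trials per
    sequence, Gaussian onset-to-onset intervals (mean 1500 ms, SD 10 ms).
    """

    vowel_duration_ms: float = 100.0
    inter_vowel_gap_ms: float = 50.0
    n_vowels_per_trial: int = 5
    n_habituation: int = 10
    n_sequences_per_block: int = 4
    iti_mean_ms: float = 1500.0
    iti_sd_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vowel_duration_ms <= 0 or self.inter_vowel_gap_ms <= 0:
            raise ValueError("vowel duration and inter-vowel gap must be positive")
        if min(self.n_vowels_per_trial, self.n_habituation, self.n_sequences_per_block) <= 0:
            raise ValueError("all paradigm counts must be positive")
        if self.iti_sd_ms < 0:
            raise ValueError("inter-trial-interval SD must be nonnegative")


@dataclass
class EventTable:
    """Ordered trial records for one or more blocks plus protocol variant."""

    trials: pd.DataFrame
    variant: str

    def __len__(self) -> int:
        return len(self.trials)

    def copy(self) -> "EventTable":
        return EventTable(self.trials.copy(), self.variant)

    def to_tsv(self, path) -> None:
        df = self.trials[EVENT_COLUMNS].copy()
        df["habituation"] = df["habituation"].astype(int)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, variant: str = "A") -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        df["habituation"] = df["habituation"].astype(bool)
        return cls(df, variant)


def fifth_vowel_onset(cfg: ParadigmConfig) -> float:
    """Onset of the last vowel, ms relative to trial onset.

    With defaults, 4 x (100 + 50) = 600 ms.
    """
    return (cfg.n_vowels_per_trial - 1) * (cfg.vowel_duration_ms + cfg.inter_vowel_gap_ms)


def trial_span_ms(cfg: ParadigmConfig) -> float:
    """Acoustic duration of one quintuple, onset of first vowel to offset of last."""
    return fifth_vowel_onset(cfg) + cfg.vowel_duration_ms


def _deviant_positions(n_test: int, n_dev: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudorandom GD slots among ``n_test`` test trials.

    Constraints (convention, standard oddball practice): the first test
    trial is always a GS, and no two GD trials are adjacent. Uses the
    combinatorial bijection between non-adjacent subsets of {1..n-1} and
    unconstrained subsets of a shortened range, so every admissible
    placement is equally likely.
    """
    n_slots = n_test - 1  # slot 0 reserved for GS
    if n_dev > (n_slots + 1) // 2:
        raise ValueError("too many deviants for the no-adjacency constraint")
    base = rng.choice(n_slots - n_dev + 1, size=n_dev, replace=False)
    base.sort()
    return base + np.arange(n_dev) + 1  # spread out, then skip slot 0


def build_block_schedule(
    cfg: ParadigmConfig,
    variant: str = "A",
    rng_seed: int | None = None,
    block_index: int = 0,
) -> EventTable:
    """Construct one fully labeled block of the LGD paradigm.

    The four quintuple types each serve as the global standard of one
    sequence, in an order randomized per block. Habituation trials open
    each sequence and are all of the GS type. Onsets are left at NaN;
    call :func:`assign_onsets` to draw them.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown protocol variant {variant!r}; expected one of {sorted(_VARIANTS)}")
    n_gs, n_gd = _VARIANTS[variant]
    rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)

    # Quintuple types as (base vowel, fifth vowel); GD of a sequence is the
    # base-matched type with the opposite fifth vowel.
    types = [(b, f) for b in VOWELS for f in VOWELS]
    order = rng.permutation(len(types))

    rows = []
    trial_index = 0
    for seq_pos, type_idx in enumerate(order, start=1):
        base, fifth = types[type_idx]
        gd_fifth = VOWELS[1 - VOWELS.index(fifth)]
        n_test = n_gs + n_gd
        gd_slots = set(_deviant_positions(n_test, n_gd, rng).tolist())
        for i in range(cfg.n_habituation + n_test):
            habituation = i < cfg.n_habituation
            is_gd = (not habituation) and (i - cfg.n_habituation) in gd_slots
            fv = gd_fifth if is_gd else fifth
            rows.append(
                {
                    "trial_index": trial_index,
                    "block": block_index,
                    "sequence": seq_pos,
                    "onset_ms": np.nan,
                    "base_vowel": base,
                    "fifth_vowel": fv,
                    "habituation": habituation,
                    "local_label": "LD" if fv != base else "LS",
                    "global_label": "GD" if is_gd else "GS",
                }
            )
            trial_index += 1

    return EventTable(pd.DataFrame(rows, columns=EVENT_COLUMNS), variant)


def assign_onsets(
    table: EventTable, cfg: ParadigmConfig, rng_seed: int | None = None, start_ms: float = 1000.0
) -> EventTable:
    """Draw trial onsets with i.i.d. Normal(iti_mean, iti_sd) onset-to-onset intervals.

    Onsets restart the interval chain at each sequence boundary; variant B
    additionally inserts a silent instruction gap before each sequence.
    Intervals are floored at the acoustic trial span so onsets are
    strictly increasing even for extreme draws.
    """
    rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)
    out = table.copy()
    span = trial_span_ms(cfg)
    t = start_ms
    onsets = np.empty(len(out), dtype=float)
    prev_key = None
    for i, (_, row) in enumerate(out.trials.iterrows()):
        key = (row["block"], row["sequence"])
        if prev_key is not None:
            gap = max(float(rng.normal(cfg.iti_mean_ms, cfg.iti_sd_ms)), span + 1.0)
            t += gap
            if key != prev_key and table.variant == "B":
                t += INSTRUCTION_GAP_MS
        prev_key = key
        onsets[i] = t
    out.trials["onset_ms"] = onsets
    return out


def build_session(
    cfg: ParadigmConfig, variant: str = "A", n_blocks: int = 1, rng_seed: int | None = None
) -> EventTable:
    """Build and time ``n_blocks`` consecutive blocks under one seed."""
    seed = cfg.seed if rng_seed is None else rng_seed
    ss = np.random.SeedSequence(seed)
    block_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_blocks)]
    tables = [
        build_block_schedule(cfg, variant, rng_seed=block_seeds[b], block_index=b)
        for b in range(n_blocks)
    ]
    merged = pd.concat([t.trials for t in tables], ignore_index=True)
    merged["trial_index"] = np.arange(len(merged))
    return assign_onsets(EventTable(merged, variant), cfg, rng_seed=seed)


def relabel_local(table: EventTable) -> pd.Series:
    """Re-derive local labels from vowel identities (consistency check)."""
    return np.where(table.trials["fifth_vowel"] != table.trials["base_vowel"], "LD", "LS")
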