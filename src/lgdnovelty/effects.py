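"""Site-level effect calling, regional prevalence, Fisher/odds-ratio statistics.

This is the statistics layer that turns per-site cluster-test outcomes
into the quantities the field reports: per-ROI prevalence of each novelty
effect (AEP/high-gamma x local/global deviance x arousal state), Fisher
exact comparisons of prevalences with sample odds ratios and asymptotic
(Woolf) confidence intervals, and effect-count time courses.

Two site-count fixtures ship with the package, encoding the published
regional distribution of LGD effects in the dexmedetomidine (7
participants) and sleep (5 participants) cohorts; all headline odds
ratios and prevalences of those experiments are deterministic functions
of these counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .clusterstats import ClusterPermutationTest, ClusterTestConfig, fdr_adjust

EFFECTS = ("LD", "GD")
SIGNALS = ("AEP", "HG")

#: Whole-brain denominators as reported for each cohort. The
#: dexmedetomidine total exceeds the tabulated per-ROI rows by 2.
EXPERIMENT_TOTAL_SITES = {"dexmedetomidine": 863, "sleep": 764}
EXPERIMENT_STATES = {
    "dexmedetomidine": ("awake", "sedated", "unresponsive"),
    "sleep": ("awake", "drowsy", "asleep"),
}


# ---------------------------------------------------------------------------
# shipped count tables


def load_site_counts(experiment: str = "dexmedetomidine") -> pd.DataFrame:
    """Wide per-ROI significant-site counts for one cohort.

    Columns: roi_group, roi, n, then ``{effect}_{signal}_{state}`` counts
    (effect in ld/gd, signal in aep/hg, three states per cohort).
    """
    if experiment not in EXPERIMENT_TOTAL_SITES:
        raise ValueError(f"unknown experiment {experiment!r}")
    ref = resources.files("lgdnovelty.data") / f"{experiment}_site_counts.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def tidy_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide count table into (roi_group, roi, n, effect, signal, state, count)."""
    long = counts.melt(id_vars=["roi_group", "roi", "n"], var_name="key", value_name="count")
    parts = long["key"].str.split("_", expand=True)
    long["effect"] = parts[0].str.upper()
    long["signal"] = parts[1].str.upper()
    long["state"] = parts[2]
    return long.drop(columns="key")


def roi_group_map(counts: pd.DataFrame) -> dict[str, str]:
    return dict(zip(counts["roi"], counts["roi_group"]))


# ---------------------------------------------------------------------------
# Fisher exact test / odds ratios


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (a, b; c, d): rows are categories, columns outcome +/-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have a nonzero margin")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    odds_ratio: float  # sample (cross-product) OR = ad/bc; nan if a zero cell
    ci95: tuple[float, float]  # Woolf log-OR interval; (nan, nan) if a zero cell

    def __str__(self) -> str:
        if np.isnan(self.odds_ratio):
            return f"OR undefined (zero cell), p = {self.p_two_sided:.4g}"
        return (
            f"OR = {self.odds_ratio:.3g} [{self.ci95[0]:.3g}, {self.ci95[1]:.3g}], "
            f"p = {self.p_two_sided:.4g}"
        )


def fisher_exact(table: Contingency2x2) -> FisherResult:
    """Two-sided Fisher exact test with sample OR and Woolf 95% CI.

    The exact p sums hypergeometric probabilities no larger than the
    observed table's (margins fixed). OR = ad/bc; the CI is
    ``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``. With a zero
    cell the OR and CI are reported as NaN while p is still exact.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    _, p = sstats.fisher_exact(table.as_array(), alternative="two-sided")
    if min(a, b, c, d) == 0:
        return FisherResult(float(p), float("nan"), (float("nan"), float("nan")))
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(odds) + np.array([-1.96, 1.96]) * se)
    return FisherResult(float(p), float(odds), (float(lo), float(hi)))


def whole_brain_comparison(
    counts: pd.DataFrame, effect: str, experiment: str | None = None, state: str = "awake"
) -> tuple[Contingency2x2, FisherResult]:
    """AEP-vs-high-gamma prevalence comparison across all sites of a cohort.

    Rows of the 2x2 are the two signals; columns are significant /
    non-significant site counts out of the cohort total.
    """
    tidy = tidy_counts(counts)
    total = (
        EXPERIMENT_TOTAL_SITES[experiment] if experiment is not None else int(counts["n"].sum())
    )
    sel = tidy[(tidy["effect"] == effect.upper()) & (tidy["state"] == state)]
    n_aep = int(sel[sel["signal"] == "AEP"]["count"].sum())
    n_hg = int(sel[sel["signal"] == "HG"]["count"].sum())
    table = Contingency2x2(n_aep, total - n_aep, n_hg, total - n_hg)
    return table, fisher_exact(table)


def state_comparison_table(
    ld_state1: int, ld_state2: int, gd_state1: int, gd_state2: int
) -> Contingency2x2:
    """LD-vs-GD resistance to a state change (e.g. awake -> sedated).

    Rows are effect type (LD, GD), columns the two states; an OR below 1
    means the LD effect lost proportionally fewer sites than GD.
    """
    return Contingency2x2(ld_state1, ld_state2, gd_state1, gd_state2)


def state_comparison(
    counts: pd.DataFrame,
    roi_group: str,
    signal: str = "AEP",
    states: tuple[str, str] = ("awake", "sedated"),
) -> tuple[Contingency2x2, FisherResult]:
    """LD-vs-GD state comparison within one ROI group, from summed counts."""
    tidy = tidy_counts(counts)
    sel = tidy[(tidy["roi_group"] == roi_group) & (tidy["signal"] == signal.upper())]

    def count(effect: str, state: str) -> int:
        m = (sel["effect"] == effect) & (sel["state"] == state)
        return int(sel[m]["count"].sum())

    table = state_comparison_table(
        count("LD", states[0]), count("LD", states[1]),
        count("GD", states[0]), count("GD", states[1]),
    )
    return table, fisher_exact(table)


# ---------------------------------------------------------------------------
# site-level effect calling on epoched data


@dataclass(frozen=True)
class ContrastSpec:
    """Trial-selection rule for one novelty contrast.

    LD: standards are all non-habituation LS trials, deviants all LD
    trials, pooling vowel identities and global statuses. GD: standards
    are GS test trials, deviants GD test trials (habituation trials
    establish the global rule and are excluded from both averages).
    """

    effect: str  # "LD" | "GD"
    signal: str  # "AEP" | "HG"
    window_ms: tuple[float, float] = (0.0, 800.0)

    def select_trials(self, events) -> tuple[np.ndarray, np.ndarray]:
        trials = events.trials
        test = ~trials["habituation"]
        if self.effect == "LD":
            std = test & (trials["local_label"] == "LS")
            dev = test & (trials["local_label"] == "LD")
        elif self.effect == "GD":
            std = test & (trials["global_label"] == "GS")
            dev = test & (trials["global_label"] == "GD")
        else:
            raise ValueError(f"unknown effect {self.effect!r}")
        idx = trials["trial_index"].to_numpy()
        return idx[std.to_numpy()], idx[dev.to_numpy()]


@dataclass
class SiteEffectTable:
    """Per (site, effect, signal, state) significance flags and cluster extents."""

    records: pd.DataFrame  # site, roi, effect, signal, state, significant,
    #                        significant_pre_fdr, min_p, extents (list of (start, end) ms)

    def flags(self) -> pd.DataFrame:
        return self.records.pivot_table(
            index="site", columns=["effect", "signal", "state"], values="significant",
            aggfunc="first",
        )

    def to_tsv(self, path) -> None:
        df = self.records.copy()
        df["extents"] = df["extents"].apply(
            lambda ex: ";".join(f"{s:g}-{e:g}" for s, e in ex)
        )
        df.to_csv(path, sep="\t", index=False)


def call_site_effects(
    contrast_epochs: dict,
    aep_config: ClusterTestConfig,
    hg_config: ClusterTestConfig,
    alpha: float = 0.05,
    roi_map: dict[str, str] | None = None,
    seed: int = 0,
) -> SiteEffectTable:
    """Run the cluster test per site x contrast x state and FDR-correct.

    ``contrast_epochs`` maps ``(site, effect, signal, state)`` to a
    ``(standard_epochs, deviant_epochs)`` pair, or to a zero-argument
    callable returning that pair (lazy construction keeps memory flat
    when analyzing many channels). One Benjamini-Hochberg
    family is formed per (effect, signal, state) by pooling all cluster
    p-values across sites. Sites with fewer than two trials in a group
    are marked untestable (significant = False, min_p = NaN). Each test
    draws its permutations from an independent child stream of ``seed``.
    """
    keys = sorted(contrast_epochs.keys())
    streams = dict(zip(keys, np.random.SeedSequence(seed).spawn(len(keys))))
    fits = {}
    rows = []
    for key in keys:
        pair = contrast_epochs[key]
        std, dev = pair() if callable(pair) else pair
        site, effect, signal, state = key
        cfg = aep_config if signal == "AEP" else hg_config
        n_std = std.n_trials if hasattr(std, "n_trials") else len(std)
        n_dev = dev.n_trials if hasattr(dev, "n_trials") else len(dev)
        if n_std < 2 or n_dev < 2:
            rows.append(
                dict(site=site, roi=(roi_map or {}).get(site, ""), effect=effect,
                     signal=signal, state=state, significant=False,
                     significant_pre_fdr=False, min_p=np.nan, extents=[],
                     untestable=True)
            )
            continue
        time_ms = getattr(std, "time_ms", None)
        fits[key] = ClusterPermutationTest(std, dev, time_ms=time_ms, config=cfg).fit(
            rng=np.random.default_rng(streams[key])
        )

    # One FDR family per (effect, signal, state), pooled across sites.
    by_family: dict[tuple, list] = {}
    for key, res in fits.items():
        by_family.setdefault(key[1:], []).extend(res.clusters)
    for fam_clusters in by_family.values():
        if fam_clusters:
            p_adj, _ = fdr_adjust([c.p_mc for c in fam_clusters], q=alpha)
            for c, pa in zip(fam_clusters, p_adj):
                c.p_adj = float(pa)

    for key, res in fits.items():
        site, effect, signal, state = key
        rows.append(
            dict(site=site, roi=(roi_map or {}).get(site, ""), effect=effect,
                 signal=signal, state=state,
                 significant=res.significant(alpha, adjusted=True),
                 significant_pre_fdr=res.significant(alpha, adjusted=False),
                 min_p=res.min_p, extents=res.significant_extents(alpha, adjusted=True),
                 untestable=False)
        )
    return SiteEffectTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# prevalence and time courses


def prevalence(
    table: SiteEffectTable,
    roi_map: dict[str, str] | None = None,
    group_by: str = "roi",
) -> pd.DataFrame:
    """Percentage of sites exhibiting each effect, per ROI or ROI group."""
    df = table.records.copy()
    if roi_map is not None:
        missing = set(df["site"]) - set(roi_map)
        if missing:
            raise ValueError(f"sites without ROI mapping: {sorted(missing)}")
        df["roi"] = df["site"].map(roi_map)
    if group_by not in ("roi", "site"):
        raise ValueError("group_by must be 'roi' or 'site'")
    key = "roi" if group_by == "roi" else "site"
    out = (
        df.groupby([key, "effect", "signal", "state"])["significant"]
        .agg(n_significant="sum", n_sites="count")
        .reset_index()
    )
    out["prevalence_pct"] = 100.0 * out["n_significant"] / out["n_sites"]
    return out


def prevalence_from_counts(counts: pd.DataFrame, group_by: str = "roi") -> pd.DataFrame:
    """Prevalence percentages from a shipped count table.

    ``group_by`` is ``"roi"`` for per-ROI rows or ``"roi_group"`` for the
    four-group summary (group counts are the sums of their member ROIs).
    """
    tidy = tidy_counts(counts)
    if group_by not in ("roi", "roi_group"):
        raise ValueError("group_by must be 'roi' or 'roi_group'")
    grouped = (
        tidy.groupby([group_by, "effect", "signal", "state"])
        .agg(n_significant=("count", "sum"), n_sites=("n", "sum"))
        .reset_index()
    )
    grouped["prevalence_pct"] = 100.0 * grouped["n_significant"] / grouped["n_sites"]
    return grouped


def effect_timecourse(
    table: SiteEffectTable,
    roi_map: dict[str, str] | None = None,
    window_ms: tuple[float, float] = (0.0, 800.0),
    step_ms: float = 1.0,
) -> pd.DataFrame:
    """Number of sites with a significant cluster covering each time point.

    Returns one row per (effect, signal, state, roi, time_ms) with the
    count of sites whose any significant cluster spans that time.
    """
    times = np.arange(window_ms[0], window_ms[1], step_ms)
    df = table.records
    if roi_map is not None:
        df = df.assign(roi=df["site"].map(roi_map))
    rows = []
    for (effect, signal, state, roi), grp in df.groupby(
        ["effect", "signal", "state", "roi"], dropna=False
    ):
        counts = np.zeros(times.size, dtype=int)
        for extents in grp.loc[grp["significant"], "extents"]:
            covered = np.zeros(times.size, dtype=bool)
            for s, e in extents:
                covered |= (times >= s) & (times < e)
            counts += covered
        rows.append(
            pd.DataFrame(
                dict(effect=effect, signal=signal, state=state, roi=roi,
                     time_ms=times, n_sites=counts)
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["effect", "signal", "state", "roi", "time_ms", "n_sites"]
    )
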