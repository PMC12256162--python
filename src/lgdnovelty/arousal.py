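"""Does the sedation assessment itself perturb arousal? A BIS mixed model.

During sedation experiments the observer's alertness assessment (OAA/S)
requires addressing the participant, which could itself arouse them. The
check regresses bispectral-index (BIS, 0-100) values recorded
immediately before and after each of the four assessments on

    BIS ~ PrePost * Assessment# + (1 | Participant)

with PrePost coded 0/1 (before/after the assessment), assessment order
treated as numeric 1-4, their interaction, and a per-participant random
intercept. The model is fitted by maximum likelihood; fixed-effect
p-values are Wald tests. A negative assessment-order slope reflects
deepening sedation across the experiment; a null PrePost effect means
the assessment did not measurably perturb arousal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

REQUIRED_COLUMNS = ("participant", "assessment", "pre_post", "bis")


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if ((df["bis"] < 0) | (df["bis"] > 100)).any():
        raise ValueError("BIS values must lie in [0, 100]")
    if not df["assessment"].isin([1, 2, 3, 4]).all():
        raise ValueError("assessment order must be in 1..4")
    if df["participant"].nunique() < 2:
        raise ValueError("need at least two participants")
    if df["pre_post"].nunique() < 2:
        raise ValueError("degenerate design: pre_post takes a single value")
    if df["assessment"].nunique() < 2:
        raise ValueError("degenerate design: assessment order takes a single value")
    return df


class BisArousalModel:
    """Linear mixed model for before/after-assessment BIS values.

    ``records`` needs columns participant, assessment (1-4),
    pre_post (0 = before, 1 = after), bis.
    """

    def __init__(self, records: pd.DataFrame):
        self.records = _validate(records)

    @classmethod
    def from_tsv(cls, path) -> "BisArousalModel":
        return cls(pd.read_csv(path, sep="\t"))

    def fit(self) -> "BisArousalResult":
        model = smf.mixedlm(
            "bis ~ pre_post * assessment", data=self.records, groups=self.records["participant"]
        )
        fitted = model.fit(reml=False)
        fe = fitted.fe_params
        return BisArousalResult(
            params=dict(fe),
            pvalues={k: float(fitted.pvalues[k]) for k in fe.index},
            random_intercept_var=float(np.asarray(fitted.cov_re).ravel()[0]),
            residual_var=float(fitted.scale),
            n_obs=len(self.records),
            n_participants=int(self.records["participant"].nunique()),
            _sm_result=fitted,
        )


@dataclass
class BisArousalResult:
    params: dict[str, float]
    pvalues: dict[str, float]
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_participants: int
    _sm_result: object = None

    def summary(self) -> str:
        lines = [
            f"BIS ~ pre_post * assessment + (1 | participant)   "
            f"[{self.n_obs} obs, {self.n_participants} participants, ML fit]",
            f"{'term':<24}{'estimate':>12}{'p':>12}",
        ]
        for k, v in self.params.items():
            lines.append(f"{k:<24}{v:>12.4f}{self.pvalues[k]:>12.4g}")
        lines.append(
            f"random intercept var = {self.random_intercept_var:.3f}, "
            f"residual var = {self.residual_var:.3f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "pvalues": self.pvalues,
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
        }


def fit_bis_lme(records: pd.DataFrame) -> BisArousalResult:
    """Functional alias for :class:`BisArousalModel` followed by ``fit``."""
    return BisArousalModel(records).fit()


def simulate_bis(
    n_participants: int = 7,
    assessment_slope: float = -5.0,
    pre_post_effect: float = 0.0,
    interaction: float = 0.0,
    intercept: float = 90.0,
    intercept_sd: float = 5.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate before/after BIS around four assessments per participant."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        u = rng.normal(0, intercept_sd)
        for assessment in (1, 2, 3, 4):
            for pre_post in (0, 1):
                mu = (
                    intercept + u
                    + assessment_slope * assessment
                    + pre_post_effect * pre_post
                    + interaction * pre_post * assessment
                )
                rows.append(
                    dict(
                        participant=f"P{p:02d}",
                        assessment=assessment,
                        pre_post=pre_post,
                        bis=float(np.clip(mu + rng.normal(0, noise_sd), 0, 100)),
                    )
                )
    return pd.DataFrame(rows)
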