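"""Model/Results interface over the reliability analyses.

:class:`SpeechReliabilityModel` is constructed from a feature matrix (or a
long-format DataFrame, or a transcript corpus) and ``fit()`` runs the full
analysis: z-scoring, within-task-type reliability with resampling nulls,
the MCI-vs-intact comparison of per-feature reliabilities, and cross-task
intraindividual variability.  The returned
:class:`SpeechReliabilityResults` carries tidy DataFrames plus a
``summary()`` text table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import CohortRecord, FeatureMatrix, Transcript, classify_cognitive_status
from .errors import PreconditionError, ValidationError
from .features import Tagger, extract_features
from .lexicons import LexiconResources
from .reliability import (
    NullDistribution,
    compare_groups,
    grand_mean_correlation,
    intraindividual_variability,
    resample_null,
    within_feature_reliability,
    zscore,
)

_MIN_RESAMPLE_N = 4


def extract_corpus_features(
    transcripts: Sequence[Transcript],
    records: Sequence[CohortRecord],
    lexicons: LexiconResources,
    tagger: Tagger | None = None,
) -> FeatureMatrix:
    """Run feature extraction over a corpus, attaching group labels.

    Group labels come from the cohort records; records lacking a label but
    carrying T-scores are classified with the same-domain MCI rule.
    """
    groups: dict[str, str] = {}
    for rec in records:
        if rec.group is not None:
            groups[rec.participant_id] = rec.group
        elif rec.tscores:
            groups[rec.participant_id] = classify_cognitive_status(rec)
        else:
            groups[rec.participant_id] = "unspecified"
    rows = []
    for tr in transcripts:
        vec = extract_features(tr, lexicons, tagger)
        for name, value in vec.as_dict().items():
            rows.append(
                (tr.participant_id, tr.task_id, name, value,
                 groups.get(tr.participant_id, "unspecified"))
            )
    return FeatureMatrix(
        pd.DataFrame(rows, columns=list(FeatureMatrix.COLUMNS))
    )


@dataclass
class SpeechReliabilityResults:
    """Fitted reliability analysis.

    Attributes
    ----------
    reliability : DataFrame
        Per (feature, task_type, group): Fisher-averaged ``r_mean``, number
        of task pairs, one-sided resampling ``p_value`` and the null's
        mean/SD.
    grand : DataFrame
        Per (task_type, group): the grand-mean correlation over all features
        and pairs, with its null summary and p-value.
    itv : DataFrame
        Per (feature, group): mean within-person SD of the five z-scores.
    comparisons : DataFrame
        Per task_type: pooled t-test of MCI vs intact per-feature
        reliabilities on the Fisher-z scale (t, df, p, 95% CI on r scale).
    """

    reliability: pd.DataFrame
    grand: pd.DataFrame
    itv: pd.DataFrame
    comparisons: pd.DataFrame
    nulls: dict[tuple[str, str], NullDistribution] = field(default_factory=dict)
    reps: int = 0
    seed: int | None = None

    def group_feature_correlations(self, task_type: str, group: str) -> np.ndarray:
        sel = self.reliability[
            (self.reliability.task_type == task_type)
            & (self.reliability.group == group)
        ]
        return sel.set_index("feature_name")["r_mean"].to_numpy()

    def summary(self) -> str:
        lines = ["Speech feature reliability analysis",
                 "=" * 50,
                 f"resampling reps: {self.reps}   seed: {self.seed}",
                 "",
                 "Grand-mean within-feature correlations:"]
        for _, row in self.grand.iterrows():
            lines.append(
                f"  {row.task_type:<10s} {row.group:<8s} "
                f"r = {row.r_mean:+.4f}   null mean = {row.null_mean:+.4f}   "
                f"p = {row.p_value:.4g}"
            )
        if len(self.comparisons):
            lines += ["", "MCI vs intact (per-feature reliabilities, Fisher z):"]
            for _, row in self.comparisons.iterrows():
                lines.append(
                    f"  {row.task_type:<10s} t({int(row.df)}) = {row.t:.4f}, "
                    f"p = {row.p:.3g}, 95% CI [{row.ci_low:.2f}, {row.ci_high:.2f}]"
                )
        lines += ["", "Intraindividual variability (mean within-person SD):"]
        piv = self.itv.pivot(index="feature_name", columns="group", values="itv")
        lines.append(piv.round(3).to_string())
        return "\n".join(lines)


class SpeechReliabilityModel:
    """Reliability analysis of repeated speech-task features.

    Parameters
    ----------
    matrix :
        A :class:`FeatureMatrix` (participants x 5 tasks x features, long
        format, with group labels).
    itv_mode :
        ``"per_participant_sd"`` (default) or ``"variance_pooled"``.
    """

    def __init__(self, matrix: FeatureMatrix, itv_mode: str = "per_participant_sd"):
        if len(matrix) == 0:
            raise ValidationError("empty feature matrix")
        self.matrix = matrix
        self.itv_mode = itv_mode

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SpeechReliabilityModel":
        return cls(FeatureMatrix(df), **kwargs)

    @classmethod
    def from_corpus(
        cls,
        transcripts: Sequence[Transcript],
        records: Sequence[CohortRecord],
        lexicons: LexiconResources,
        tagger: Tagger | None = None,
        **kwargs,
    ) -> "SpeechReliabilityModel":
        return cls(extract_corpus_features(transcripts, records, lexicons, tagger), **kwargs)

    def _analysis_groups(self) -> list[str]:
        counts = self.matrix.group_of().value_counts()
        groups = ["full"]
        for g in ("MCI", "intact"):
            n = counts.get(g, 0)
            if 0 < n < _MIN_RESAMPLE_N:
                raise PreconditionError(
                    f"group {g!r} has only {n} participants; "
                    f"needs >= {_MIN_RESAMPLE_N} for the resampling null"
                )
            if n:
                groups.append(g)
        return groups

    def fit(self, reps: int = 10_000, seed: int | None = None) -> SpeechReliabilityResults:
        """Run the full analysis.

        ``seed`` drives every resampling null (one derived child seed per
        task type x group, in a fixed order) and is required.
        """
        if seed is None:
            raise ValidationError("fit() requires an explicit seed")
        groups = self._analysis_groups()
        z_full = zscore(self.matrix, stratify_by_group=False)
        z_strat = zscore(self.matrix, stratify_by_group=True) if len(groups) > 1 else None

        child_seeds = iter(
            int(s) for s in
            np.random.SeedSequence(seed).generate_state(2 * len(groups)) % (2**31)
        )
        rel_rows, grand_rows, nulls = [], [], {}
        for task_type in ("expository", "picture"):
            for group in groups:
                z = z_full if group == "full" else z_strat
                estimates = within_feature_reliability(z, task_type, group)
                null = resample_null(z, task_type, group, reps=reps,
                                     seed=next(child_seeds))
                nulls[(task_type, group)] = null
                for est in estimates:
                    rel_rows.append({
                        "feature_name": est.feature_name,
                        "task_type": task_type,
                        "group": group,
                        "r_mean": est.r_mean,
                        "n_pairs": est.n_pairs,
                        "p_value": null.p_value(est.r_mean),
                        "null_mean": null.mean,
                        "null_sd": null.sd,
                    })
                observed = grand_mean_correlation(z, task_type, group)
                grand_rows.append({
                    "task_type": task_type,
                    "group": group,
                    "r_mean": observed,
                    "p_value": null.p_value(observed),
                    "null_mean": null.mean,
                    "null_sd": null.sd,
                })

        reliability = pd.DataFrame(rel_rows)
        grand = pd.DataFrame(grand_rows)

        itv_rows = []
        for group in groups:
            z = z_full if group == "full" else z_strat
            for res in intraindividual_variability(z, group, mode=self.itv_mode):
                itv_rows.append({"feature_name": res.feature_name,
                                 "group": group, "itv": res.itv})
        itv = pd.DataFrame(itv_rows)

        comp_rows = []
        if {"MCI", "intact"} <= set(groups):
            for task_type in ("expository", "picture"):
                r_mci = reliability.query(
                    "task_type == @task_type and group == 'MCI'")["r_mean"].to_numpy()
                r_int = reliability.query(
                    "task_type == @task_type and group == 'intact'")["r_mean"].to_numpy()
                cmp = compare_groups(r_mci, r_int)
                comp_rows.append({"task_type": task_type, "t": cmp.t,
                                  "df": cmp.df, "p": cmp.p,
                                  "ci_low": cmp.ci_low, "ci_high": cmp.ci_high})
        comparisons = pd.DataFrame(
            comp_rows, columns=["task_type", "t", "df", "p", "ci_low", "ci_high"]
        )
        return SpeechReliabilityResults(
            reliability=reliability,
            grand=grand,
            itv=itv,
            comparisons=comparisons,
            nulls=nulls,
            reps=reps,
            seed=seed,
        )
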