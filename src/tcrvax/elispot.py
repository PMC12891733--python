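"""IFNγ ELISPOT immunogenicity cascade and responder statistic.

Spot-forming-unit (SFU) measurements per million PBMCs are collected per
subject × week × stimulation (six mutant-KRAS peptides, an irrelevant
control peptide, unstimulated wells) in replicate.  The cascade is:

1. average replicates;
2. normalize each antigen to the control-peptide stimulation at the same
   timepoint (difference of SFU by default, ratio selectable);
3. fold-change vs. the week-0 baseline, maximum taken within a 17-week
   window (the primary-endpoint definition; an unrestricted window is the
   secondary endpoint);
4. summarize per subject either as the pooled average over the six
   antigens or as the response to the subject's tumor KRAS mutation;
5. call a subject an *immune responder* when the pre-to-post change
   exceeds 2.77 × the standard deviation of the baseline values across
   patients — the two-sided α = 0.05 criterion for a difference of two
   equally variable measurements, since z(0.975)·√2 ≈ 2.77.

A small utility implements the companion multiplex-cytokine rule: readings
outside the standard curve ("OOR<" / "OOR>") are clamped to the curve
limits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .repertoire_io import MKRAS_ANTIGENS

__all__ = [
    "ANTIGENS",
    "STIMULATIONS",
    "ResponderCall",
    "MissingTimepointError",
    "responder_threshold_multiplier",
    "replicate_means",
    "fold_vs_control",
    "normalized_response",
    "response_series",
    "max_fold_change",
    "pooled_average",
    "responder_call",
    "antigen_positivity_count",
    "clamp_oor",
    "cohort_responder_analysis",
]

ANTIGENS: tuple[str, ...] = tuple(str(a) for a in MKRAS_ANTIGENS)
STIMULATIONS: tuple[str, ...] = ("unstimulated", "control_peptide") + ANTIGENS

#: Default responder threshold multiplier: z(0.975)·√2 rounded to 2 decimals.
K_DEFAULT = 2.77


class MissingTimepointError(ValueError):
    """No usable timepoint in the requested analysis window."""


@dataclass
class ResponderCall:
    """Per-subject responder classification in one analysis mode.

    ``responder`` is the directional call (increase greater than the
    threshold); ``significant_two_sided`` additionally counts decreases of
    the same magnitude and is the event whose null rate matches the
    two-sided α.
    """

    subject_id: str
    mode: str  # "pooled_average" | "tumor_matched"
    max_fold: float
    delta_sfu: float
    threshold: float
    responder: bool

    @property
    def significant_two_sided(self) -> bool:
        return abs(self.delta_sfu) > self.threshold


def responder_threshold_multiplier(alpha: float = 0.05, decimals: int = 2) -> float:
    """Critical multiplier for a pre/post difference at two-sided ``alpha``.

    The difference of two equally variable measurements has standard
    deviation √2·σ, so the two-sided α criterion on the difference is
    |Δ| > z(1−α/2)·√2·σ.  At α = 0.05 this rounds to 2.77.
    """
    return round(norm.ppf(1 - alpha / 2) * math.sqrt(2), decimals)


def replicate_means(sfu: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells to their mean SFU.

    Expects long-format columns ``subject_id, week, stimulation,
    replicate, sfu``; returns ``subject_id, week, stimulation, sfu``.
    """
    required = {"subject_id", "week", "stimulation", "sfu"}
    if not required <= set(sfu.columns):
        raise ValueError(f"SFU table needs columns {sorted(required)}")
    return (
        sfu.groupby(["subject_id", "week", "stimulation"], as_index=False)["sfu"]
        .mean()
        .sort_values(["subject_id", "week", "stimulation"], kind="stable")
        .reset_index(drop=True)
    )


def fold_vs_control(sfu_antigen: float, sfu_control: float, pseudocount: float = 1.0) -> float:
    """Antigen/control SFU ratio with a pseudocount guarding empty wells.

    Computed as (antigen + pseudocount) / (control + pseudocount); with
    ``pseudocount=0`` and both wells empty the fold is undefined.
    """
    if sfu_antigen < 0 or sfu_control < 0:
        raise ValueError("SFU means must be >= 0")
    if sfu_control + pseudocount == 0:
        raise ValueError("fold undefined: zero control SFU and zero pseudocount")
    return (sfu_antigen + pseudocount) / (sfu_control + pseudocount)


def normalized_response(
    sfu_antigen: float, sfu_control: float, scale: str = "sfu", pseudocount: float = 1.0
) -> float:
    """Control-normalized response on the requested scale.

    ``"sfu"``: difference antigen − control (may be negative);
    ``"fold"``: pseudocounted ratio.
    """
    if scale == "sfu":
        return sfu_antigen - sfu_control
    if scale == "fold":
        return fold_vs_control(sfu_antigen, sfu_control, pseudocount)
    raise ValueError(f"unknown scale {scale!r}")


def response_series(
    means: pd.DataFrame,
    subject_id: str,
    antigen: str,
    scale: str = "sfu",
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-week normalized response of one subject to one antigen.

    ``means`` is the replicate-mean table.  Weeks lacking either the
    antigen or the control-peptide well are dropped.
    """
    sub = means[means["subject_id"] == subject_id]
    ag = sub[sub["stimulation"] == antigen].set_index("week")["sfu"]
    ctrl = sub[sub["stimulation"] == "control_peptide"].set_index("week")["sfu"]
    weeks = sorted(set(ag.index) & set(ctrl.index))
    values = [
        normalized_response(ag[w], ctrl[w], scale=scale, pseudocount=pseudocount) for w in weeks
    ]
    return pd.Series(values, index=pd.Index(weeks, name="week"), name=antigen)


def max_fold_change(folds: pd.Series | Mapping[float, float], window_weeks: float = 17.0) -> float:
    """Maximum fold-change vs. baseline within the analysis window.

    ``folds`` maps week → fold-vs-baseline and must include week 0 (which
    is 1 by construction).  The window is inclusive (week ≤ window_weeks);
    pass ``math.inf`` for the any-time secondary-endpoint variant.

    Raises
    ------
    MissingTimepointError
        When no post-vaccine timepoint falls inside the window; the error
        lists the weeks that are available.
    """
    s = pd.Series(dict(folds)) if not isinstance(folds, pd.Series) else folds
    if 0 not in s.index:
        raise MissingTimepointError(f"baseline week 0 missing (weeks: {sorted(s.index)})")
    post = s[(s.index > 0) & (s.index <= window_weeks)]
    if post.empty:
        raise MissingTimepointError(
            f"no post-vaccine timepoint within {window_weeks} weeks "
            f"(available weeks: {sorted(s.index)})"
        )
    return float(post.max())


def pooled_average(per_antigen: Mapping[str, float] | Sequence[float]) -> float:
    """Arithmetic mean of per-antigen maximal fold changes.

    Antigens excluded from a vaccine lot are simply omitted by the caller;
    a warning (not imputation) records that fewer than six values entered
    the pool.
    """
    values = list(per_antigen.values()) if isinstance(per_antigen, Mapping) else list(per_antigen)
    if not values:
        raise ValueError("pooled average needs at least one antigen value")
    if len(values) < len(ANTIGENS):
        warnings.warn(
            f"pooled average over {len(values)}/{len(ANTIGENS)} antigens "
            "(excluded antigens omitted, not imputed)",
            stacklevel=2,
        )
    return float(np.mean(values))


def responder_call(
    subject_id: str,
    delta: float,
    baseline_sd: float,
    k: float = K_DEFAULT,
    mode: str = "pooled_average",
    max_fold: float = math.nan,
) -> ResponderCall:
    """Classify one subject against the k × baseline-SD threshold.

    ``baseline_sd`` is the standard deviation of the baseline values
    *across patients* in the same analysis mode; ``delta`` is the
    subject's pre-to-post change.  The comparison is strict: a change of
    exactly k·SD is not a response.

    Raises
    ------
    ValueError
        When ``baseline_sd`` is not positive (degenerate threshold).
    """
    if not baseline_sd > 0:
        raise ValueError(f"degenerate threshold: baseline_sd={baseline_sd}")
    threshold = k * baseline_sd
    return ResponderCall(
        subject_id=subject_id,
        mode=mode,
        max_fold=max_fold,
        delta_sfu=float(delta),
        threshold=float(threshold),
        responder=bool(delta > threshold),
    )


def antigen_positivity_count(
    deltas: Mapping[str, float], baseline_sds: Mapping[str, float], k: float = K_DEFAULT
) -> int:
    """Number of antigens with a significant pre-to-post increase (0–6)."""
    count = 0
    for antigen, delta in deltas.items():
        sd = baseline_sds[antigen]
        if not sd > 0:
            raise ValueError(f"degenerate threshold for antigen {antigen}: sd={sd}")
        count += delta > k * sd
    return count


def clamp_oor(value: float | str, lower: float, upper: float) -> float:
    """Clamp an out-of-range multiplex-assay reading to the curve limits.

    ``"OOR<"`` becomes ``lower`` (the lower limit of the standard curve),
    ``"OOR>"`` becomes ``upper``; numeric readings pass through unchanged.
    """
    if not lower < upper:
        raise ValueError(f"need lower < upper, got {lower} >= {upper}")
    if isinstance(value, str):
        v = value.strip().upper()
        if v == "OOR<":
            return float(lower)
        if v == "OOR>":
            return float(upper)
        return float(v)
    return float(value)


def _normalized_tables(
    means: pd.DataFrame, scale: str, pseudocount: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide (subject, week) × antigen tables of normalized responses.

    Returns the table on the requested scale and the fold-scale table
    (always needed for the reported maximal fold change).
    """
    wide = means.pivot(index=["subject_id", "week"], columns="stimulation", values="sfu")
    if "control_peptide" not in wide.columns:
        raise ValueError("SFU table lacks control_peptide stimulation")
    ags = [a for a in ANTIGENS if a in wide.columns]
    if not ags:
        raise ValueError("SFU table contains no mKRAS antigen stimulation")
    ctrl = wide["control_peptide"]
    fold = wide[ags].add(pseudocount).div(ctrl + pseudocount, axis=0)
    if scale == "fold":
        norm = fold
    elif scale == "sfu":
        norm = wide[ags].sub(ctrl, axis=0)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return norm, fold


def cohort_responder_analysis(
    sfu: pd.DataFrame,
    tumor_mutations: Mapping[str, str] | None = None,
    k: float = K_DEFAULT,
    window_weeks: float = 17.0,
    scale: str = "sfu",
    pseudocount: float = 1.0,
) -> dict:
    """Run the full responder cascade over a cohort SFU table.

    Parameters
    ----------
    sfu
        Long-format measurements (``subject_id, week, stimulation,
        replicate, sfu``).
    tumor_mutations
        Map subject → KRAS mutation of the resected tumor; enables the
        tumor-matched analysis mode.
    k, window_weeks, scale, pseudocount
        Threshold multiplier, analysis window, normalization scale and
        zero-well pseudocount.

    Returns
    -------
    dict with keys
        ``calls`` — list of :class:`ResponderCall` (both modes);
        ``positivity`` — per-subject count of significantly increased
        antigens; ``baseline_sd`` — per-mode cross-patient SD;
        ``excluded`` — subject → reason for exclusion (no baseline or no
        post-vaccine sample in the window); ``responses`` — tidy per
        subject × antigen × week normalized-response table.
    """
    means = replicate_means(sfu)
    norm, fold = _normalized_tables(means, scale, pseudocount)
    norm_by = {s: f.droplevel(0) for s, f in norm.groupby(level=0)}
    fold_by = {s: f.droplevel(0) for s, f in fold.groupby(level=0)}

    excluded: dict[str, str] = {}
    subject_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for subj in sorted(norm_by):
        sub = norm_by[subj]
        weeks = sub.index.to_numpy()
        if 0 not in weeks:
            excluded[subj] = "no baseline (week 0) sample"
            continue
        if not np.any((weeks > 0) & (weeks <= window_weeks)):
            excluded[subj] = f"no post-vaccine sample within {window_weeks} weeks"
            continue
        subject_tables[subj] = (sub, fold_by[subj])

    evaluable = sorted(subject_tables)
    if len(evaluable) < 2:
        raise ValueError("responder analysis needs >= 2 evaluable subjects for the baseline SD")

    def _pooled(sub: pd.DataFrame) -> pd.Series:
        return sub.mean(axis=1)

    baseline_sd: dict[str, float] = {
        "pooled_average": float(
            np.std([_pooled(subject_tables[s][0]).loc[0] for s in evaluable], ddof=1)
        )
    }
    ags = list(norm.columns)
    per_ag_sd = {
        ag: float(np.std([subject_tables[s][0][ag].loc[0] for s in evaluable], ddof=1))
        for ag in ags
    }

    calls: list[ResponderCall] = []
    positivity: dict[str, int] = {}
    rows = []
    for subj in evaluable:
        sub, sub_fold = subject_tables[subj]
        in_window = (sub.index > 0) & (sub.index <= window_weeks)
        pooled = _pooled(sub)
        delta = float(pooled[in_window].max() - pooled.loc[0])
        fold_pooled = _pooled(sub_fold)
        calls.append(
            responder_call(
                subj,
                delta,
                baseline_sd["pooled_average"],
                k=k,
                mode="pooled_average",
                max_fold=max_fold_change(fold_pooled / fold_pooled.loc[0], window_weeks),
            )
        )
        deltas = {}
        for ag in ags:
            s = sub[ag]
            post_max = s[in_window].max()
            if not (np.isnan(post_max) or np.isnan(s.loc[0])):
                deltas[ag] = float(post_max - s.loc[0])
            for week, val in s.dropna().items():
                rows.append((subj, ag, float(week), float(val)))
        positivity[subj] = antigen_positivity_count(
            deltas, {a: per_ag_sd[a] for a in deltas}, k=k
        )

    if tumor_mutations:
        tm_subjects = sorted(
            s for s in evaluable if tumor_mutations.get(s) in ags
        )
        if len(tm_subjects) >= 2:
            sd = float(
                np.std(
                    [subject_tables[s][0][tumor_mutations[s]].loc[0] for s in tm_subjects],
                    ddof=1,
                )
            )
            baseline_sd["tumor_matched"] = sd
            for subj in tm_subjects:
                sub, sub_fold = subject_tables[subj]
                ag = tumor_mutations[subj]
                s = sub[ag]
                in_window = (s.index > 0) & (s.index <= window_weeks)
                delta = float(s[in_window].max() - s.loc[0])
                f = sub_fold[ag]
                calls.append(
                    responder_call(
                        subj,
                        delta,
                        sd,
                        k=k,
                        mode="tumor_matched",
                        max_fold=max_fold_change(f / f.loc[0], window_weeks),
                    )
                )

    responses = pd.DataFrame(rows, columns=["subject_id", "antigen", "week", "value"])
    return {
        "calls": calls,
        "positivity": positivity,
        "baseline_sd": baseline_sd,
        "per_antigen_baseline_sd": per_ag_sd,
        "excluded": excluded,
        "responses": responses,
    }
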