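"""End-to-end study runs with reproducible, regression-friendly reports.

Orchestrates the stage modules over a whole study: per-subject clonality
summaries, expansion reports per antigen, the baseline-filtered
mKRAS-specific catalogue, cross-reactive/public summaries, optional tumor
overlap and high-similarity matching, and the ELISPOT responder cascade
with optional survival stratification.

All numeric report fields are serialized at 12 significant digits and all
tables are deterministically ordered, so identical configurations yield
byte-identical reports; every run emits a manifest (config hash, package
version, seed) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .elispot import cohort_responder_analysis
from .expansion import (
    ExpansionCall,
    ExpansionConfig,
    antigen_set_distribution,
    call_expanded,
    classify_cross_reactive,
    filter_baseline,
    find_public,
    shannon_equitability,
    test_expansion,
    tumor_overlap,
)
from .outcomes import SurvivalRecord, km_estimate, logrank_test, stratify_by_quantile
from .repertoire_io import Clonotype, Condition, MKRAS_ANTIGENS, Repertoire

__all__ = [
    "ExpansionReportBundle",
    "run_expansion_pipeline",
    "run_elispot_pipeline",
    "write_manifest",
]

logger = logging.getLogger("tcrvax.pipeline")

_SIG_DIGITS = 12


def _fmt(x: float) -> str:
    """Fixed-precision numeric rendering for bit-exact regression outputs."""
    return f"{x:.{_SIG_DIGITS}g}"


def _write_tsv(df: pd.DataFrame, path: Path, float_cols: tuple[str, ...] = ()) -> None:
    out = df.copy()
    for col in float_cols:
        if col in out.columns:
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_manifest(outdir: Path, config_payload: dict, seed: int, warnings: list[str]) -> dict:
    """Emit a provenance manifest: config hash, version, seed, warnings."""
    blob = json.dumps(config_payload, sort_keys=True)
    manifest = {
        "package": "tcrvax",
        "version": __version__,
        "seed": seed,
        "config": config_payload,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "warnings": warnings,
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest


@dataclass
class ExpansionReportBundle:
    """In-memory view of a full expansion run."""

    equitability: pd.DataFrame
    tests: dict[tuple[str, str], pd.DataFrame]  # (subject, antigen) -> table
    calls: dict[str, list[ExpansionCall]]  # subject -> all calls (flags set)
    specific: dict[str, list[ExpansionCall]]  # subject -> baseline-filtered calls
    summary: dict
    warnings: list[str] = field(default_factory=list)


def run_expansion_pipeline(
    repertoires: Mapping[str, Mapping[Condition, Repertoire]],
    config: ExpansionConfig | None = None,
    outdir: str | Path | None = None,
    seed: int = 0,
) -> ExpansionReportBundle:
    """Run clonality, expansion calling and classification over a cohort.

    ``repertoires`` maps subject → condition → repertoire.  Missing
    conditions are logged and skipped, never fatal.  When ``outdir`` is
    given, the full report set is written there: ``equitability.tsv``,
    ``expansion/<subject>__<antigen>.tsv``, ``specific_catalogue.tsv``,
    ``public_clonotypes.tsv``, ``summary.json`` and ``manifest.json``.
    """
    config = config or ExpansionConfig()
    warnings: list[str] = []
    eq_rows = []
    tests: dict[tuple[str, str], pd.DataFrame] = {}
    calls: dict[str, list[ExpansionCall]] = {}
    specific: dict[str, list[ExpansionCall]] = {}
    summary: dict = {
        "reference_condition": str(config.reference_condition),
        "subjects": {},
    }
    if not repertoires:
        warnings.append("empty subject list: nothing to do")

    for subject in sorted(repertoires):
        reps = repertoires[subject]
        subj_summary: dict = {"n_expanded_per_antigen": {}, "skipped_conditions": []}

        for cond in sorted(reps, key=lambda c: list(Condition).index(Condition(c))):
            rep = reps[cond]
            if rep.n_clonotypes >= 2:
                eq_rows.append(
                    (
                        subject,
                        str(Condition(cond)),
                        rep.n_clonotypes,
                        rep.total_reads,
                        shannon_equitability(rep),
                    )
                )

        ref = reps.get(config.reference_condition)
        if ref is None:
            msg = f"{subject}: missing reference condition {config.reference_condition}"
            logger.warning(msg)
            warnings.append(msg)
            summary["subjects"][subject] = subj_summary
            continue

        fragments = []
        for antigen in MKRAS_ANTIGENS:
            rep = reps.get(antigen)
            if rep is None:
                msg = f"{subject}: missing condition {antigen}, skipped"
                logger.warning(msg)
                subj_summary["skipped_conditions"].append(str(antigen))
                continue
            table = call_expanded(test_expansion(rep, ref, config), config)
            tests[(subject, str(antigen))] = table
            hits = table[table["expanded"]]
            subj_summary["n_expanded_per_antigen"][str(antigen)] = int(len(hits))
            for row in hits.itertuples(index=False):
                fragments.append((subject, Clonotype(row.v_gene, row.cdr3_aa), antigen))

        subject_calls = classify_cross_reactive(fragments)
        n_removed = 0
        baseline = reps.get(Condition.BASELINE)
        if baseline is not None:
            subject_calls, n_removed = filter_baseline(subject_calls, baseline)
        else:
            msg = f"{subject}: no baseline repertoire, baseline filter skipped"
            logger.warning(msg)
            warnings.append(msg)
        calls[subject] = subject_calls
        retained = [c for c in subject_calls if not c.filtered_by_baseline]
        specific[subject] = retained

        subj_summary["n_calls"] = len(subject_calls)
        subj_summary["n_filtered_by_baseline"] = n_removed
        subj_summary["n_specific"] = len(retained)
        subj_summary["n_cross_reactive"] = sum(c.cross_reactive for c in retained)
        subj_summary["antigen_set_distribution"] = {
            "+".join(k): v for k, v in sorted(antigen_set_distribution(retained).items())
        }

        tumor = reps.get(Condition.TUMOR_TISSUE)
        if tumor is not None and retained:
            ov = tumor_overlap({c.clonotype: c.antigens for c in retained}, tumor)
            subj_summary["tumor_overlap"] = {
                "count": ov.count,
                "fraction": float(ov.fraction),
                "per_antigen": ov.per_antigen,
            }
        summary["subjects"][subject] = subj_summary

    all_specific = [c for subj in sorted(specific) for c in specific[subj]]
    public = []
    if len({c.subject_id for c in all_specific}) >= 2:
        public = find_public(all_specific)
    summary["n_public_clonotypes"] = len(public)

    equitability = pd.DataFrame(
        eq_rows,
        columns=["subject_id", "condition", "n_clonotypes", "total_reads", "equitability"],
    )

    bundle = ExpansionReportBundle(
        equitability=equitability,
        tests=tests,
        calls=calls,
        specific=specific,
        summary=summary,
        warnings=warnings,
    )
    if outdir is not None:
        _write_expansion_reports(bundle, public, Path(outdir), config, seed)
    return bundle


def _calls_frame(calls: list[ExpansionCall]) -> pd.DataFrame:
    rows = [
        (
            c.subject_id,
            c.clonotype.v_gene,
            c.clonotype.cdr3_aa,
            "+".join(sorted(c.antigens)),
            c.cross_reactive,
            c.filtered_by_baseline,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "v_gene",
            "cdr3_aa",
            "antigens",
            "cross_reactive",
            "filtered_by_baseline",
        ],
    )


def _write_expansion_reports(
    bundle: ExpansionReportBundle,
    public,
    outdir: Path,
    config: ExpansionConfig,
    seed: int,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "expansion").mkdir(exist_ok=True)
    _write_tsv(bundle.equitability, outdir / "equitability.tsv", float_cols=("equitability",))
    for (subject, antigen), table in sorted(bundle.tests.items()):
        _write_tsv(
            table,
            outdir / "expansion" / f"{subject}__{antigen}.tsv",
            float_cols=("odds_ratio", "freq_cond", "p_value", "q_value"),
        )
    all_calls = [c for subj in sorted(bundle.calls) for c in bundle.calls[subj]]
    _write_tsv(_calls_frame(all_calls), outdir / "specific_catalogue.tsv")
    pub_rows = [
        (
            p.clonotype.v_gene,
            p.clonotype.cdr3_aa,
            ";".join(p.subjects),
            "+".join(sorted(p.shared_antigens)),
        )
        for p in public
    ]
    _write_tsv(
        pd.DataFrame(
            pub_rows, columns=["v_gene", "cdr3_aa", "subjects", "shared_antigens"]
        ),
        outdir / "public_clonotypes.tsv",
    )
    _write_json(bundle.summary, outdir / "summary.json")
    payload = {k: str(v) if isinstance(v, Condition) else v for k, v in asdict(config).items()}
    write_manifest(outdir, payload, seed, bundle.warnings)


def run_elispot_pipeline(
    sfu: pd.DataFrame,
    tumor_mutations: Mapping[str, str] | None = None,
    survival: list[SurvivalRecord] | None = None,
    outdir: str | Path | None = None,
    k: float = 2.77,
    window_weeks: float = 17.0,
    scale: str = "sfu",
    quantile: float = 0.25,
    seed: int = 0,
) -> dict:
    """ELISPOT responder cascade, optional quartile/KM/log-rank analysis.

    Returns a result dict (calls, positivity, exclusions, optional
    outcome statistics); when ``outdir`` is given also writes
    ``responder_calls.csv``, ``responses.csv``, ``cohort_summary.json``
    and, with survival data, ``outcomes.json`` plus a KM figure.
    """
    res = cohort_responder_analysis(
        sfu, tumor_mutations=tumor_mutations, k=k, window_weeks=window_weeks, scale=scale
    )
    calls = res["calls"]
    summary = {
        "n_evaluable": len({c.subject_id for c in calls}),
        "excluded": res["excluded"],
        "baseline_sd": {m: float(v) for m, v in res["baseline_sd"].items()},
        "n_responders": {
            mode: sum(c.responder for c in calls if c.mode == mode)
            for mode in sorted({c.mode for c in calls})
        },
        "positivity_histogram": {
            str(n): sum(1 for v in res["positivity"].values() if v == n) for n in range(7)
        },
    }

    outcome: dict | None = None
    if survival is not None:
        scores = {
            c.subject_id: c.max_fold for c in calls if c.mode == "pooled_average"
        }
        strata = stratify_by_quantile(scores, q=quantile)
        by_group = {"low": [], "high": []}
        for rec in survival:
            if rec.subject_id in strata:
                by_group[strata[rec.subject_id]].append(rec)
        outcome = {"quantile": quantile, "groups": {g: len(v) for g, v in by_group.items()}}
        if by_group["low"] and by_group["high"]:
            km = {g: km_estimate(v) for g, v in by_group.items()}
            stat, p = logrank_test(by_group["low"], by_group["high"])
            outcome["median_low"] = km["low"].median
            outcome["median_high"] = km["high"].median
            outcome["logrank_statistic"] = float(stat)
            outcome["logrank_p"] = float(p)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        call_rows = [
            (c.subject_id, c.mode, _fmt(c.max_fold), _fmt(c.delta_sfu), _fmt(c.threshold), c.responder)
            for c in calls
        ]
        pd.DataFrame(
            call_rows,
            columns=["subject_id", "mode", "max_fold", "delta", "threshold", "responder"],
        ).to_csv(outdir / "responder_calls.csv", index=False)
        responses = res["responses"].copy()
        responses["value"] = responses["value"].map(_fmt)
        responses.to_csv(outdir / "responses.csv", index=False)
        _write_json(summary, outdir / "cohort_summary.json")
        if outcome is not None:
            _write_json(outcome, outdir / "outcomes.json")
            if by_group["low"] and by_group["high"]:
                _plot_km(by_group, outdir / "km_dfs.png")
        write_manifest(
            outdir,
            {"k": k, "window_weeks": window_weeks, "scale": scale, "quantile": quantile},
            seed,
            [],
        )

    return {**res, "summary": summary, "outcome": outcome}


def _plot_km(by_group: Mapping[str, list[SurvivalRecord]], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, recs in sorted(by_group.items()):
        km = km_estimate(recs)
        ax.step(km.survival["time"], km.survival["survival"], where="post", label=group)
    ax.set_xlabel("months from first vaccine dose")
    ax.set_ylabel("disease-free survival")
    ax.set_ylim(0, 1.05)
    ax.legend(title="response stratum")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
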