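"""Antigen-stimulated TCRβ expansion calling.

A 7-day peptide expansion culture is compared against a reference culture
(vehicle-only by default, irrelevant control peptide selectable).  For every
clonotype observed in the expansion condition the module computes

* the read-count odds ratio OR = count_cond / count_ref (``+inf`` when the
  clonotype is absent from the reference; this is a raw count ratio, not a
  contingency-table odds ratio),
* a one-sided Fisher exact p-value for frequency enrichment in the
  condition, and
* a Benjamini–Yekutieli adjusted q-value, the family being all clonotypes
  tested in that subject × condition.

A clonotype is *called expanded* when q ≤ q_max, OR ≥ or_min and (optionally)
its condition frequency ≥ freq_min; defaults OR ≥ 5, frequency ≥ 0.1 %,
q ≤ 0.05, thresholds inclusive.  Downstream classification marks clonotypes
expanded to two or more mKRAS antigens as cross-reactive, clonotypes
expanded in two or more subjects as public, and filters out clonotypes seen
in the subject's unstimulated baseline repertoire (unlikely to be
vaccine-induced).  The module also provides the repertoire clonality summary
(Shannon-equitability-based index) and tumor-repertoire overlap counts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .repertoire_io import Clonotype, Condition, MKRAS_ANTIGENS, Repertoire

__all__ = [
    "ExpansionConfig",
    "ExpansionCall",
    "PublicClonotype",
    "TumorOverlap",
    "shannon_equitability",
    "odds_ratio",
    "fisher_one_sided",
    "by_adjust",
    "test_expansion",
    "call_expanded",
    "filter_baseline",
    "classify_cross_reactive",
    "antigen_set_distribution",
    "find_public",
    "tumor_overlap",
]


@dataclass(frozen=True)
class ExpansionConfig:
    """Thresholds of the expansion-calling cascade.

    ``or_min`` and ``freq_min`` follow the study's stated cut-offs (OR ≥ 5
    over the vehicle control, expansion frequency ≥ 0.1 %); boundaries are
    inclusive.  ``apply_freq_cutoff=False`` selects the relaxed OR-only
    mode used when mapping low-frequency (CD8) clonotypes.  ``q_max`` is the
    Benjamini–Yekutieli FDR threshold.
    """

    or_min: float = 5.0
    freq_min: float = 0.001
    q_max: float = 0.05
    apply_freq_cutoff: bool = True
    reference_condition: Condition = Condition.VEHICLE_ONLY

    def __post_init__(self) -> None:
        if self.or_min <= 0:
            raise ValueError("or_min must be > 0")
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must be in (0, 1]")
        object.__setattr__(self, "reference_condition", Condition(self.reference_condition))
        if self.reference_condition not in (Condition.VEHICLE_ONLY, Condition.CONTROL_PEPTIDE):
            raise ValueError("reference_condition must be vehicle_only or control_peptide")


@dataclass
class ExpansionCall:
    """Per-subject, per-clonotype expansion call with its antigen set."""

    clonotype: Clonotype
    subject_id: str
    antigens: frozenset[str]
    cross_reactive: bool = False
    filtered_by_baseline: bool = False

    def __post_init__(self) -> None:
        self.antigens = frozenset(str(Condition(a)) for a in self.antigens)
        self.cross_reactive = len(self.antigens) >= 2


@dataclass
class PublicClonotype:
    """A clonotype expanded (exact TRBV+CDR3 identity) in ≥ 2 subjects."""

    clonotype: Clonotype
    subjects: tuple[str, ...]
    antigen_sets: dict[str, frozenset[str]]
    shared_antigens: frozenset[str]


@dataclass
class TumorOverlap:
    """Overlap of the mKRAS-specific catalogue with a tumor repertoire."""

    count: int
    fraction: float
    per_antigen: dict[str, int] = field(default_factory=dict)


def shannon_equitability(repertoire: Repertoire) -> float:
    """Clonality index 1 − H/ln(n) of the clonotype frequency distribution.

    H is the natural-log Shannon entropy of the clonotype frequencies p_i
    and n the number of unique clonotypes.  The value is 0 for a perfectly
    even repertoire and approaches 1 at maximal clonality.

    .. note::
       "Shannon equitability" conventionally denotes the evenness H/ln(n)
       itself; this function implements its complement, the clonality
       index used as the expansion readout in this pipeline, and keeps the
       field name under which that readout is reported.

    Raises
    ------
    ValueError
        When the repertoire has fewer than two unique clonotypes (ln(1)=0
        would make the statistic undefined).
    """
    n = repertoire.n_clonotypes
    if n < 2:
        raise ValueError(f"equitability undefined for n={n} clonotypes (needs n >= 2)")
    counts = np.fromiter(repertoire.counts.values(), dtype=float, count=n)
    if np.all(counts == counts[0]):
        return 0.0  # exact by definition; avoids one-ulp float residue
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return 1.0 - h / math.log(n)


def odds_ratio(count_cond: int, count_ref: int) -> float:
    """Read-count ratio between expansion condition and reference.

    Returns ``+inf`` when the clonotype is absent from the reference.

    Raises
    ------
    ValueError
        When both counts are zero (the clonotype exists in neither sample).
    """
    if count_cond < 0 or count_ref < 0:
        raise ValueError("counts must be non-negative")
    if count_cond == 0 and count_ref == 0:
        raise ValueError("odds ratio undefined: clonotype absent from both samples")
    if count_ref == 0:
        return math.inf
    return count_cond / count_ref


def fisher_one_sided(
    count_cond: int, depth_cond: int, count_ref: int, depth_ref: int
) -> float:
    """One-sided Fisher exact p for enrichment in the expansion condition.

    Exact hypergeometric upper-tail probability of observing at least
    ``count_cond`` of the clonotype's ``count_cond + count_ref`` total reads
    in the condition sample, conditioning on the sample depths (the 2×2
    table ``[[count_cond, depth_cond−count_cond],
    [count_ref, depth_ref−count_ref]]``).
    """
    _validate_table(count_cond, depth_cond, count_ref, depth_ref)
    return float(
        hypergeom.sf(count_cond - 1, depth_cond + depth_ref, count_cond + count_ref, depth_cond)
    )


def _validate_table(a: int, da: int, c: int, dc: int) -> None:
    if min(a, da, c, dc) < 0 or a > da or c > dc or da == 0 or dc == 0:
        raise ValueError(
            f"invalid 2x2 margins: count_cond={a}, depth_cond={da}, "
            f"count_ref={c}, depth_ref={dc}"
        )


def _fisher_one_sided_vec(
    a: np.ndarray, depth_cond: int, c: np.ndarray, depth_ref: int
) -> np.ndarray:
    return hypergeom.sf(a - 1, depth_cond + depth_ref, a + c, depth_cond)


def by_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up FDR adjustment, input order preserved.

    q_(i) = min_{j ≥ i} min(1, m·c(m)·p_(j)/j) with c(m) = Σ_{k=1..m} 1/k,
    valid under arbitrary dependence of the tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def test_expansion(
    condition_rep: Repertoire,
    reference_rep: Repertoire,
    config: ExpansionConfig | None = None,
) -> pd.DataFrame:
    """Per-clonotype enrichment statistics for one expansion culture.

    Every clonotype observed in the condition repertoire is tested
    (reference-only clonotypes cannot be expanded and are not part of the
    family).  The returned frame has one row per tested clonotype with
    columns ``v_gene, cdr3_aa, count_cond, depth_cond, count_ref,
    depth_ref, odds_ratio, freq_cond, p_value, q_value`` where ``q_value``
    is the Benjamini–Yekutieli adjustment over this subject × condition
    family.  Rows are ordered by descending condition count with a stable
    ``(cdr3_aa, v_gene)`` tie-break.
    """
    if condition_rep.subject_id != reference_rep.subject_id:
        raise ValueError(
            f"subject mismatch: {condition_rep.subject_id!r} vs {reference_rep.subject_id!r}"
        )
    config = config or ExpansionConfig()
    items = sorted(
        condition_rep.counts.items(), key=lambda kv: (-kv[1], kv[0].cdr3_aa, kv[0].v_gene)
    )
    depth_cond = condition_rep.total_reads
    depth_ref = reference_rep.total_reads
    a = np.array([n for _, n in items], dtype=np.int64)
    c = np.array([reference_rep.counts.get(ct, 0) for ct, _ in items], dtype=np.int64)
    with np.errstate(divide="ignore"):
        or_ = np.where(c > 0, a / np.maximum(c, 1), np.inf)
    p = _fisher_one_sided_vec(a, depth_cond, c, depth_ref)
    q = by_adjust(p)
    return pd.DataFrame(
        {
            "v_gene": [ct.v_gene for ct, _ in items],
            "cdr3_aa": [ct.cdr3_aa for ct, _ in items],
            "count_cond": a,
            "depth_cond": depth_cond,
            "count_ref": c,
            "depth_ref": depth_ref,
            "odds_ratio": or_,
            "freq_cond": a / depth_cond,
            "p_value": p,
            "q_value": q,
        }
    )


def call_expanded(tests: pd.DataFrame, config: ExpansionConfig | None = None) -> pd.DataFrame:
    """Apply the threshold cascade; adds a boolean ``expanded`` column.

    expanded ⇔ q ≤ q_max ∧ OR ≥ or_min ∧ (freq ≥ freq_min when the
    frequency cutoff applies); all boundaries inclusive.
    """
    config = config or ExpansionConfig()
    out = tests.copy()
    expanded = (out["q_value"] <= config.q_max) & (out["odds_ratio"] >= config.or_min)
    if config.apply_freq_cutoff:
        expanded &= out["freq_cond"] >= config.freq_min
    out["expanded"] = expanded
    return out


def filter_baseline(
    calls: Iterable[ExpansionCall], baseline_repertoire: Repertoire
) -> tuple[list[ExpansionCall], int]:
    """Flag calls whose clonotype is present in the subject's baseline.

    Clonotypes already detectable in the unstimulated pre-vaccine sample
    are unlikely to be vaccine-induced and are removed from the
    mKRAS-specific set.  Returns the full call list with
    ``filtered_by_baseline`` set and the number of removed calls; the
    retained specific set is ``[c for c in calls if not
    c.filtered_by_baseline]``.

    Raises
    ------
    ValueError
        If the baseline repertoire belongs to a different subject.
    """
    out: list[ExpansionCall] = []
    n_removed = 0
    for call in calls:
        if call.subject_id != baseline_repertoire.subject_id:
            raise ValueError(
                f"baseline subject {baseline_repertoire.subject_id!r} does not "
                f"match call subject {call.subject_id!r}"
            )
        flagged = call.clonotype in baseline_repertoire
        n_removed += flagged
        out.append(replace(call, filtered_by_baseline=flagged))
    return out, n_removed


def classify_cross_reactive(
    fragments: Iterable[tuple[str, Clonotype, Condition | str]],
) -> list[ExpansionCall]:
    """Union per-condition call fragments into per-clonotype antigen sets.

    ``fragments`` are ``(subject_id, clonotype, antigen)`` triples, one per
    condition in which the clonotype met the expansion criteria.  A
    clonotype expanded to two or more mKRAS peptides is cross-reactive.
    Output is sorted by (subject, cdr3, v_gene) for reproducible reports.
    """
    grouped: dict[tuple[str, Clonotype], set[str]] = {}
    for subject_id, clonotype, antigen in fragments:
        grouped.setdefault((subject_id, clonotype), set()).add(str(Condition(antigen)))
    calls = [
        ExpansionCall(clonotype=ct, subject_id=subj, antigens=frozenset(ags))
        for (subj, ct), ags in grouped.items()
    ]
    calls.sort(key=lambda c: (c.subject_id, c.clonotype.cdr3_aa, c.clonotype.v_gene))
    return calls


def antigen_set_distribution(calls: Iterable[ExpansionCall]) -> Counter:
    """Multiplicity of each exact antigen combination (upset-plot summary)."""
    return Counter(tuple(sorted(c.antigens)) for c in calls)


def find_public(calls: Iterable[ExpansionCall]) -> list[PublicClonotype]:
    """Clonotypes expanded in two or more subjects.

    Identity is the exact (TRBV, CDR3) pair; a shared CDR3 on a different
    TRBV allele is *not* public here (it is a candidate for the
    high-similarity matcher instead).  Each hit is annotated with the
    per-subject antigen sets and their intersection, so callers can see
    whether the public response targets a shared antigen.

    Raises
    ------
    ValueError
        If the input spans fewer than two subjects.
    """
    calls = list(calls)
    subjects = {c.subject_id for c in calls}
    if len(subjects) < 2:
        raise ValueError("public-clonotype search needs calls from >= 2 subjects")
    by_ct: dict[Clonotype, dict[str, frozenset[str]]] = {}
    for c in calls:
        per = by_ct.setdefault(c.clonotype, {})
        per[c.subject_id] = per.get(c.subject_id, frozenset()) | c.antigens
    out: list[PublicClonotype] = []
    for ct in sorted(by_ct, key=lambda t: (t.cdr3_aa, t.v_gene)):
        per = by_ct[ct]
        if len(per) < 2:
            continue
        shared = frozenset.intersection(*per.values())
        out.append(
            PublicClonotype(
                clonotype=ct,
                subjects=tuple(sorted(per)),
                antigen_sets=dict(sorted(per.items())),
                shared_antigens=shared,
            )
        )
    return out


def tumor_overlap(
    specific_set: Iterable[Clonotype] | Mapping[Clonotype, frozenset[str]],
    tumor_repertoire: Repertoire,
) -> TumorOverlap:
    """Count mKRAS-specific clonotypes present in a tumor repertoire.

    ``specific_set`` may be a plain clonotype collection or a map
    clonotype → antigen set, in which case a per-antigen breakdown of the
    overlapping clonotypes is included.

    Raises
    ------
    ValueError
        If the repertoire is not a tumor-tissue sample or the specific set
        is empty (the overlap fraction would be undefined).
    """
    if tumor_repertoire.condition is not Condition.TUMOR_TISSUE:
        raise ValueError(
            f"tumor_overlap needs a tumor_tissue repertoire, got {tumor_repertoire.condition}"
        )
    antigen_map: Mapping[Clonotype, frozenset[str]] | None = None
    if isinstance(specific_set, Mapping):
        antigen_map = specific_set
        clonotypes = set(specific_set)
    else:
        clonotypes = set(specific_set)
    if not clonotypes:
        raise ValueError("overlap fraction undefined for an empty specific set")
    overlapping = {ct for ct in clonotypes if ct in tumor_repertoire}
    per_antigen: dict[str, int] = {}
    if antigen_map is not None:
        for ag in (str(a) for a in MKRAS_ANTIGENS):
            per_antigen[ag] = sum(1 for ct in overlapping if ag in antigen_map[ct])
    return TumorOverlap(
        count=len(overlapping),
        fraction=len(overlapping) / len(clonotypes),
        per_antigen=per_antigen,
    )
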