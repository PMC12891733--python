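"""High-similarity (HS-TCR) CDR3 matching.

Two expanded clonotypes raised against the same antigen in different
subjects can differ by a single CDR3 residue — near-identical "public-like"
receptors.  The same idea extends to external cohorts: a tumor sample
harbouring CDR3s within ≤ 2 amino-acid differences of a vaccine-expanded
clonotype carries *high-similarity* (HS) TCRs.

The default distance is optimal string alignment (OSA): Levenshtein edits
plus adjacent transpositions, each costing 1.  Plain Levenshtein and
Hamming are selectable.  Two deliberately different matching rules coexist:

* :func:`hs_matches` compares CDR3 strings only (external CDR3 calls often
  lack reliable V annotation);
* :func:`hs_public_pairs` additionally requires an identical TRBV allele,
  the rule used when describing near-identical public clonotype pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .expansion import ExpansionCall
from .repertoire_io import Clonotype

__all__ = [
    "HsMatch",
    "HsPublicPair",
    "cdr3_distance",
    "hs_matches",
    "summarize_per_sample",
    "samples_with_min_count",
    "hs_public_pairs",
    "read_targets_tsv",
]


@dataclass(frozen=True)
class HsMatch:
    """One (query clonotype, target CDR3) pair within the distance bound."""

    query: Clonotype
    target_cdr3: str
    distance: int
    target_sample: str


@dataclass(frozen=True)
class HsPublicPair:
    """Near-identical expanded clonotypes from two different subjects."""

    call_a: ExpansionCall
    call_b: ExpansionCall
    distance: int
    shared_antigens: frozenset[str]


def _osa(a: str, b: str, transpositions: bool) -> int:
    # Two-row (three with transpositions) DP over edit operations.
    la, lb = len(a), len(b)
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                transpositions
                and i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[lb]


def cdr3_distance(a: str, b: str, metric: str = "osa") -> int:
    """Edit distance between two CDR3 amino-acid strings.

    Parameters
    ----------
    a, b
        Non-empty amino-acid strings; lower-case input is normalized to
        upper case before comparison.
    metric
        ``"osa"`` (default): optimal string alignment — substitutions,
        insertions, deletions and adjacent transpositions, unit cost.
        ``"levenshtein"``: without transpositions.  ``"hamming"``:
        substitutions only; requires equal lengths.
    """
    if not a or not b:
        raise ValueError("CDR3 strings must be non-empty")
    a, b = a.strip().upper(), b.strip().upper()
    if metric == "osa":
        return _osa(a, b, transpositions=True)
    if metric == "levenshtein":
        return _osa(a, b, transpositions=False)
    if metric == "hamming":
        if len(a) != len(b):
            raise ValueError("hamming distance requires equal-length strings")
        return sum(x != y for x, y in zip(a, b))
    raise ValueError(f"unknown metric {metric!r}")


def hs_matches(
    queries: Iterable[Clonotype],
    targets: Mapping[str, Iterable[str]],
    max_dist: int = 2,
    metric: str = "osa",
    length_prefilter: bool = True,
) -> list[HsMatch]:
    """All (query, target) pairs with CDR3 distance ≤ ``max_dist``.

    ``targets`` maps sample identifiers to CDR3 string collections.  V genes
    are ignored on the target side.  The length pre-filter skips pairs whose
    length difference already exceeds ``max_dist`` (a lower bound for both
    OSA and Levenshtein); it never changes the match set.  Results are
    sorted by (sample, target CDR3, query) for reproducible reports.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    out: list[HsMatch] = []
    query_list = sorted(set(queries), key=lambda ct: (ct.cdr3_aa, ct.v_gene))
    for sample in sorted(targets):
        for target in sorted(set(targets[sample])):
            t_norm = target.strip().upper()
            for q in query_list:
                if length_prefilter and abs(len(q.cdr3_aa) - len(t_norm)) > max_dist:
                    continue
                d = cdr3_distance(q.cdr3_aa, t_norm, metric=metric)
                if d <= max_dist:
                    out.append(
                        HsMatch(query=q, target_cdr3=t_norm, distance=d, target_sample=sample)
                    )
    return out


def summarize_per_sample(matches: Iterable[HsMatch]) -> pd.DataFrame:
    """Distinct HS target CDR3s per sample.

    Returns a frame with columns ``sample_id, n_hs_clonotypes``, one row per
    sample with at least one match, sorted by sample identifier.
    """
    distinct: dict[str, set[str]] = {}
    for m in matches:
        distinct.setdefault(m.target_sample, set()).add(m.target_cdr3)
    return pd.DataFrame(
        {
            "sample_id": sorted(distinct),
            "n_hs_clonotypes": [len(distinct[s]) for s in sorted(distinct)],
        }
    )


def samples_with_min_count(summary: pd.DataFrame, k: int) -> list[str]:
    """Samples carrying at least ``k`` distinct HS clonotypes."""
    hit = summary[summary["n_hs_clonotypes"] >= k]
    return sorted(hit["sample_id"].tolist())


def hs_public_pairs(
    calls: Iterable[ExpansionCall], max_dist: int = 1, metric: str = "osa"
) -> list[HsPublicPair]:
    """Near-identical expanded clonotype pairs across subjects.

    Pairs must come from different subjects, use the identical TRBV allele
    label, and differ in CDR3 by at most ``max_dist`` (default 1, the
    single-residue rule).  Each pair carries the intersection of the two
    antigen sets.
    """
    calls = sorted(
        calls, key=lambda c: (c.clonotype.v_gene, c.clonotype.cdr3_aa, c.subject_id)
    )
    out: list[HsPublicPair] = []
    for i, a in enumerate(calls):
        for b in calls[i + 1 :]:
            if b.clonotype.v_gene != a.clonotype.v_gene:
                break  # sorted by v_gene
            if a.subject_id == b.subject_id:
                continue
            if a.clonotype == b.clonotype:
                continue  # exact identity is "public", not merely high-similarity
            if abs(len(a.clonotype.cdr3_aa) - len(b.clonotype.cdr3_aa)) > max_dist:
                continue
            d = cdr3_distance(a.clonotype.cdr3_aa, b.clonotype.cdr3_aa, metric=metric)
            if d <= max_dist:
                out.append(
                    HsPublicPair(
                        call_a=a,
                        call_b=b,
                        distance=d,
                        shared_antigens=a.antigens & b.antigens,
                    )
                )
    return out


def read_targets_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (sample_id, cdr3_aa) TSV of external target CDR3s."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"sample_id", "cdr3_aa"} <= set(df.columns):
        raise ValueError(
            f"{path}: expected columns sample_id, cdr3_aa; found {', '.join(df.columns)}"
        )
    out: dict[str, set[str]] = {}
    for sample, cdr3 in zip(df["sample_id"], df["cdr3_aa"]):
        out.setdefault(sample, set()).add(cdr3.strip().upper())
    return out
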