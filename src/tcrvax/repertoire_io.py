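"""Reading, validation and aggregation of bulk TCRβ rearrangement tables.

The unit of identity used throughout the package is the *clonotype*: the
combination of the TRBV gene/allele label and the CDR3β amino-acid sequence.
Two standard tabular dialects are supported:

* the AIRR Community Rearrangement TSV (``v_call`` / ``junction_aa`` /
  ``duplicate_count`` / ``productive``), and
* an Adaptive-immunoSEQ-style export (vendor column names, ``frame_type``
  carrying the productivity call, template/read counts).

Both are mapped onto the same row model (:class:`RearrangementRecord`) and
aggregated into a :class:`Repertoire` — a per-sample map clonotype → read
count with condition metadata.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "Condition",
    "MKRAS_ANTIGENS",
    "Clonotype",
    "RearrangementRecord",
    "Repertoire",
    "RepertoireFormatError",
    "EmptyRepertoireError",
    "normalize_v_gene",
    "normalize_cdr3",
    "is_valid_cdr3",
    "read_airr_tsv",
    "read_adaptive_tsv",
    "write_airr_tsv",
    "aggregate_clonotypes",
    "frequency",
]

#: The 20 proteinogenic amino acids; CDR3 sequences containing anything else
#: (stop codons ``*``, frameshift markers, ambiguity codes) are excluded
#: before clonotype aggregation.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Condition(str, enum.Enum):
    """Sample conditions of the immunomonitoring study design.

    Six mutant-KRAS peptide expansion cultures, a vehicle-only (DMSO + IL-2)
    culture, an irrelevant control-peptide culture, the unstimulated baseline
    PBMC sample and resected tumor tissue.
    """

    BASELINE = "baseline"
    VEHICLE_ONLY = "vehicle_only"
    CONTROL_PEPTIDE = "control_peptide"
    G12V = "G12V"
    G12A = "G12A"
    G12R = "G12R"
    G12C = "G12C"
    G12D = "G12D"
    G13D = "G13D"
    TUMOR_TISSUE = "tumor_tissue"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The six vaccine antigens, in vaccine-pool order.
MKRAS_ANTIGENS: tuple[Condition, ...] = (
    Condition.G12V,
    Condition.G12A,
    Condition.G12R,
    Condition.G12C,
    Condition.G12D,
    Condition.G13D,
)


class RepertoireFormatError(ValueError):
    """A rearrangement table does not conform to the expected dialect."""


class EmptyRepertoireError(ValueError):
    """No records survive filtering; a repertoire cannot be formed."""


def normalize_v_gene(label: str) -> str:
    """Normalize a TRBV gene/allele label for identity comparison.

    Case is upper-cased and the separators ``-`` and ``*`` are unified to
    ``.`` (Adaptive writes ``TCRBV28-01*01`` where other exports write
    ``TCRBV28.01.01``).  Allele information is *kept*: labels are never
    collapsed to the gene level, because public-clonotype identity in this
    pipeline is allele-resolved.
    """
    return label.strip().upper().replace("-", ".").replace("*", ".")


def normalize_cdr3(seq: str) -> str:
    """Upper-case and strip a CDR3 amino-acid string."""
    return seq.strip().upper()


def is_valid_cdr3(seq: str) -> bool:
    """True when ``seq`` is non-empty and drawn from the 20-letter alphabet."""
    return bool(seq) and set(seq) <= AA_ALPHABET


class Clonotype(NamedTuple):
    """TCRβ clonotype identity: TRBV label plus CDR3β amino-acid sequence.

    Equality is exact on the ``(v_gene, cdr3_aa)`` pair; the same CDR3 paired
    with a different TRBV gene is a different clonotype.
    """

    v_gene: str
    cdr3_aa: str

    @property
    def label(self) -> str:
        """Compact ``VGENE_CDR3`` label, e.g. ``TCRBV28.01.01_CASRLGNTGELFF``."""
        return f"{self.v_gene}_{self.cdr3_aa}"


@dataclass
class RearrangementRecord:
    """One row of a rearrangement table mapped onto the common model."""

    v_gene: str
    cdr3_aa: str
    read_count: int
    productive: bool = True
    raw_fields: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError(f"read_count must be >= 0, got {self.read_count}")


@dataclass
class Repertoire:
    """A per-sample clonotype → read-count map with condition metadata.

    ``total_reads`` is always the sum of ``counts``; every stored count is a
    positive integer.  Clonotype frequencies therefore sum to one and play
    the role of the species frequencies p_i in the repertoire clonality
    statistic.
    """

    sample_id: str
    subject_id: str
    condition: Condition
    counts: dict[Clonotype, int]

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        for ct, n in self.counts.items():
            if n < 1:
                raise ValueError(f"count for {ct.label} must be >= 1, got {n}")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clonotypes(self) -> int:
        return len(self.counts)

    def frequency(self, clonotype: Clonotype) -> float:
        """Read-count fraction of ``clonotype``; 0.0 when absent."""
        return self.counts.get(clonotype, 0) / self.total_reads

    def __contains__(self, clonotype: Clonotype) -> bool:
        return clonotype in self.counts


def frequency(repertoire: Repertoire, clonotype: Clonotype) -> float:
    """Functional alias of :meth:`Repertoire.frequency`."""
    return repertoire.frequency(clonotype)


_TRUE_STRINGS = {"T", "TRUE", "1", "YES", "Y"}


def _parse_bool(value: str, default: bool = True) -> bool:
    if value is None or value == "":
        return default
    return value.strip().upper() in _TRUE_STRINGS


def read_airr_tsv(path: str | Path, count_field: str = "duplicate_count") -> list[RearrangementRecord]:
    """Read an AIRR Rearrangement TSV into the common row model.

    Parameters
    ----------
    path
        Tab-separated file with an AIRR-C header.  ``v_call`` and
        ``junction_aa`` (or ``cdr3_aa``) are mandatory, as is the named
        count field.
    count_field
        Which AIRR count column carries the read/template count.  The AIRR
        standard offers both ``duplicate_count`` and ``consensus_count``;
        the default is ``duplicate_count``.

    Raises
    ------
    RepertoireFormatError
        If a mandatory column is missing (the error names it) or a count
        cannot be parsed as an integer (the error carries the row number).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cdr3_col = "junction_aa" if "junction_aa" in df.columns else "cdr3_aa"
    for col in ("v_call", cdr3_col, count_field):
        if col not in df.columns:
            raise RepertoireFormatError(
                f"{path}: missing mandatory column {col!r} "
                f"(found: {', '.join(df.columns)})"
            )
    has_productive = "productive" in df.columns
    records: list[RearrangementRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        raw = row._asdict()
        count_raw = raw[count_field]
        try:
            count = int(count_raw)
        except (TypeError, ValueError):
            raise RepertoireFormatError(
                f"{path}: row {i}: count field {count_field}={count_raw!r} "
                "is not an integer"
            ) from None
        records.append(
            RearrangementRecord(
                v_gene=normalize_v_gene(raw["v_call"]),
                cdr3_aa=normalize_cdr3(raw[cdr3_col]),
                read_count=count,
                productive=_parse_bool(raw["productive"]) if has_productive else True,
                raw_fields=raw,
            )
        )
    return records


def _default_adaptive_column_map() -> dict[str, list[str]]:
    with resources.files("tcrvax.data").joinpath("adaptive_columns.json").open() as fh:
        return json.load(fh)


def read_adaptive_tsv(
    path: str | Path, column_map: Mapping[str, list[str]] | None = None
) -> list[RearrangementRecord]:
    """Read an Adaptive-immunoSEQ-style TSV export.

    The vendor dialect has varied over export versions; ``column_map`` maps
    the logical fields (``v_gene``, ``cdr3_aa``, ``count``, ``frame``) to
    candidate column names, the first match winning.  The default map ships
    with the package (``tcrvax/data/adaptive_columns.json``).  A frame type
    of ``In`` maps to productive; anything else (``Out``, ``Stop``) to
    non-productive.

    Raises
    ------
    RepertoireFormatError
        When the dialect cannot be recognized; the error lists the columns
        that were detected.
    """
    cmap = dict(column_map) if column_map is not None else _default_adaptive_column_map()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def pick(logical: str, required: bool = True) -> str | None:
        for cand in cmap[logical]:
            if cand in df.columns:
                return cand
        if required:
            raise RepertoireFormatError(
                f"{path}: unrecognized Adaptive dialect, no column for "
                f"{logical!r}; detected columns: {', '.join(df.columns)}"
            )
        return None

    v_col = pick("v_gene")
    cdr3_col = pick("cdr3_aa")
    count_col = pick("count")
    frame_col = pick("frame", required=False)

    records: list[RearrangementRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = row._asdict()
        try:
            count = int(raw[count_col])
        except (TypeError, ValueError):
            raise RepertoireFormatError(
                f"{path}: row {i}: count column {count_col}={raw[count_col]!r} "
                "is not an integer"
            ) from None
        productive = True
        if frame_col is not None:
            productive = raw[frame_col].strip().lower() == "in"
        records.append(
            RearrangementRecord(
                v_gene=normalize_v_gene(raw[v_col]),
                cdr3_aa=normalize_cdr3(raw[cdr3_col]),
                read_count=count,
                productive=productive,
                raw_fields=raw,
            )
        )
    return records


def aggregate_clonotypes(
    records: Iterable[RearrangementRecord],
    *,
    sample_id: str,
    subject_id: str,
    condition: Condition | str,
    productive_only: bool = True,
) -> Repertoire:
    """Collapse rearrangement rows into a clonotype-count repertoire.

    Counts are summed over identical ``(v_gene, cdr3_aa)`` pairs.  Rows are
    dropped when (a) ``productive_only`` is set and the row is out-of-frame,
    (b) the CDR3 contains characters outside the 20-letter amino-acid
    alphabet (stop/frameshift markers), or (c) the read count is zero.

    Raises
    ------
    EmptyRepertoireError
        When nothing survives filtering.
    """
    counts: dict[Clonotype, int] = {}
    for rec in records:
        if productive_only and not rec.productive:
            continue
        if not is_valid_cdr3(rec.cdr3_aa):
            continue
        if rec.read_count == 0:
            continue
        ct = Clonotype(rec.v_gene, rec.cdr3_aa)
        counts[ct] = counts.get(ct, 0) + rec.read_count
    if not counts:
        raise EmptyRepertoireError(
            f"sample {sample_id!r}: no clonotypes survive filtering "
            f"(productive_only={productive_only})"
        )
    return Repertoire(
        sample_id=sample_id, subject_id=subject_id, condition=Condition(condition), counts=counts
    )


def write_airr_tsv(repertoire: Repertoire, path: str | Path) -> None:
    """Write a repertoire as an AIRR Rearrangement TSV.

    Rows are sorted by descending count with a stable ``(cdr3_aa, v_gene)``
    tie-break so outputs are bit-exact across runs.
    """
    items = sorted(
        repertoire.counts.items(), key=lambda kv: (-kv[1], kv[0].cdr3_aa, kv[0].v_gene)
    )
    df = pd.DataFrame(
        {
            "v_call": [ct.v_gene for ct, _ in items],
            "junction_aa": [ct.cdr3_aa for ct, _ in items],
            "duplicate_count": [n for _, n in items],
            "productive": ["T"] * len(items),
        }
    )
    df.to_csv(path, sep="\t", index=False)
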