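"""Synthetic cohort generator with known ground truth.

Emulates the three inputs of the immunomonitoring pipeline so every stage
is testable without access to deposited patient data:

* **TCRβ repertoires** — per subject, a pool of clonotypes with background
  frequencies drawn from a symmetric Dirichlet with small concentration
  (heavy-ish tail), read out by multinomial sampling at a fixed depth.
  Antigen-assigned ("spiked") clones have their frequency multiplied by
  ``spike_fold`` in their assigned antigen conditions only; condition and
  reference cultures share the same base frequencies, so spike-free
  comparisons are exchangeable and enrichment tests are calibrated.
  Designated clones recur in the unstimulated baseline (to exercise the
  baseline filter), in other subjects (public clonotypes with a shared
  antigen), and in a tumor-tissue repertoire (planted overlap).
* **ELISPOT panels** — negative-binomial SFU counts in triplicate over a
  week grid; responders receive a post-vaccine shift expressed in units of
  the cohort baseline standard deviation, with a peak-and-decay time
  course.
* **Survival records** — exponential event times with independent
  exponential censoring, for power/calibration checks of the log-rank
  utilities.

Every generator is a pure function of its configuration and seed:
identical seeds reproduce outputs byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .elispot import ANTIGENS
from .outcomes import SurvivalRecord
from .repertoire_io import Clonotype, Condition, MKRAS_ANTIGENS, Repertoire

__all__ = [
    "SimConfig",
    "SimTruth",
    "SubjectSpec",
    "build_cohort_specs",
    "simulate_repertoire",
    "simulate_cohort",
    "simulate_elispot",
    "simulate_survival",
    "toy_study_config",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: TRBV allele labels used for generated clonotypes (allele-resolved, in the
#: dotted normalized form).
V_GENES: tuple[str, ...] = tuple(
    f"TCRBV{g:02d}.01.0{a}" for g in (2, 4, 5, 6, 7, 9, 10, 11, 12, 14, 15, 18, 19, 20, 24, 25, 27, 28, 29, 30) for a in (1,)
)

#: Sampling weights used when drawing extra antigens for cross-reactive
#: clones; biased toward G12C/G12A/G12V (and mildly G12R), the combination
#: most often shared by cross-reactive receptors.
_CROSS_WEIGHTS: dict[str, float] = {
    "G12V": 3.0,
    "G12A": 3.0,
    "G12R": 1.5,
    "G12C": 3.0,
    "G12D": 0.5,
    "G13D": 0.5,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the monitored trial's scale: 12 subjects, repertoires
    of 2×10⁴ clonotypes sequenced at 10⁵ reads, ~20 truly expanding clones
    per antigen spiked 20-fold to reach at least 0.2 % of the expansion
    culture, a fifth of spikes cross-reactive, a few public clonotypes,
    and triplicate ELISPOT wells with negative-binomial counts.
    """

    n_subjects: int = 12
    n_clonotypes: int = 20_000
    depth: int = 100_000
    clone_freq_shape: float = 0.1
    n_spiked_per_antigen: int = 20
    spike_fold: float = 20.0
    spike_freq_floor: float = 0.002
    cross_reactive_fraction: float = 0.2
    public_clone_count: int = 3
    baseline_overlap_fraction: float = 0.1
    elispot_baseline_mean: float = 25.0
    elispot_dispersion: float = 20.0
    responder_effect_sd_units: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cross_reactive_fraction", "baseline_overlap_fraction", "spike_freq_floor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 1000:
            raise ValueError("depth must be >= 1000")
        if self.spike_fold < 1:
            raise ValueError("spike_fold must be >= 1")


@dataclass
class SimTruth:
    """Ground-truth labels emitted alongside the synthetic cohort.

    All clonotype sets are restricted to clonotypes actually emitted (count
    ≥ 1) in the relevant repertoire, so truth is always a subset of the
    observable data.
    """

    expanded: dict[str, dict[str, set[Clonotype]]] = field(default_factory=dict)
    antigen_assignments: dict[str, dict[Clonotype, frozenset[str]]] = field(default_factory=dict)
    cross_reactive: dict[str, set[Clonotype]] = field(default_factory=dict)
    public: dict[Clonotype, tuple[str, ...]] = field(default_factory=dict)
    public_antigen: dict[Clonotype, str] = field(default_factory=dict)
    baseline_designated: dict[str, set[Clonotype]] = field(default_factory=dict)
    baseline_present: dict[str, set[Clonotype]] = field(default_factory=dict)
    tumor_planted: dict[str, set[Clonotype]] = field(default_factory=dict)

    def specific_after_baseline_filter(self, subject_id: str) -> dict[Clonotype, frozenset[str]]:
        """Truth catalogue a perfect pipeline should recover for one subject."""
        present = self.baseline_present.get(subject_id, set())
        return {
            ct: ags
            for ct, ags in self.antigen_assignments[subject_id].items()
            if ct not in present
        }


@dataclass
class SubjectSpec:
    """Frozen per-subject latent state shared by all condition draws."""

    subject_id: str
    index: int
    clonotypes: list[Clonotype]
    base_freq: np.ndarray
    spiked: dict[int, frozenset[str]]  # pool index -> assigned antigens
    baseline_overlap: frozenset[int]
    tumor_planted: frozenset[int]


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(10, 19))
    middle = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length - 5))
    return "CASS" + middle + "F"


def _random_clonotype(rng: np.random.Generator) -> Clonotype:
    return Clonotype(V_GENES[int(rng.integers(len(V_GENES)))], _random_cdr3(rng))


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _public_plan(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[Clonotype, tuple[int, int], str]]:
    """Public clonotypes: identity, the two host subject indices, shared antigen."""
    plan = []
    seen: set[Clonotype] = set()
    for k in range(config.public_clone_count):
        ct = _random_clonotype(rng)
        while ct in seen:
            ct = _random_clonotype(rng)
        seen.add(ct)
        i = int(rng.integers(config.n_subjects))
        j = int(rng.integers(config.n_subjects - 1))
        j = j if j < i else j + 1
        antigen = str(MKRAS_ANTIGENS[k % len(MKRAS_ANTIGENS)])
        plan.append((ct, (min(i, j), max(i, j)), antigen))
    return plan


def build_cohort_specs(config: SimConfig) -> list[SubjectSpec]:
    """Build the latent per-subject states (pools, base frequencies, spikes)."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    public = _public_plan(config, np.random.default_rng([config.seed, 10_000_000]))
    specs: list[SubjectSpec] = []
    antigen_names = [str(a) for a in MKRAS_ANTIGENS]
    for idx, subject_id in enumerate(_subject_ids(config.n_subjects)):
        rng = np.random.default_rng([config.seed, idx])
        pool: list[Clonotype] = []
        seen: set[Clonotype] = set()
        while len(pool) < config.n_clonotypes:
            ct = _random_clonotype(rng)
            if ct not in seen:
                seen.add(ct)
                pool.append(ct)

        # antigen assignments: n_spiked_per_antigen primary clones per
        # antigen; a cross_reactive_fraction of them pick up 1-2 extra
        # antigens, biased toward the commonly shared G12C/G12A/G12V set.
        spiked: dict[int, frozenset[str]] = {}
        free = list(rng.permutation(config.n_clonotypes))
        for antigen in antigen_names:
            for _ in range(config.n_spiked_per_antigen):
                i = int(free.pop())
                ags = {antigen}
                if rng.random() < config.cross_reactive_fraction:
                    n_extra = int(rng.integers(1, 3))
                    others = [a for a in antigen_names if a != antigen]
                    w = np.array([_CROSS_WEIGHTS[a] for a in others])
                    extra = rng.choice(others, size=n_extra, replace=False, p=w / w.sum())
                    ags.update(str(a) for a in extra)
                spiked[i] = frozenset(ags)

        # plant public clonotypes assigned to this subject
        for ct, hosts, antigen in public:
            if idx in hosts:
                i = int(free.pop())
                pool[i] = ct
                spiked[i] = frozenset({antigen})

        # background frequencies + spiked-clone targets
        g = rng.gamma(config.clone_freq_shape, size=config.n_clonotypes)
        base = g / g.sum()
        spiked_idx = np.array(sorted(spiked), dtype=int)
        targets = config.spike_freq_floor * (1.0 + rng.uniform(size=spiked_idx.size))
        spike_base = targets / config.spike_fold
        if targets.sum() >= 1.0:
            raise ValueError(
                "spike mass exceeds 1 after scaling; lower n_spiked_per_antigen "
                "or spike_freq_floor"
            )
        mask = np.zeros(config.n_clonotypes, dtype=bool)
        mask[spiked_idx] = True
        base[mask] = 0.0
        base *= (1.0 - spike_base.sum()) / base.sum()
        base[spiked_idx] = spike_base

        # baseline overlap drawn from mono-reactive, non-public spikes so the
        # cross-reactive/public truth survives the baseline filter intact
        public_cts = {ct for ct, hosts, _ in public if idx in hosts}
        mono = [
            i for i in sorted(spiked)
            if len(spiked[i]) == 1 and pool[i] not in public_cts
        ]
        n_overlap = int(round(config.baseline_overlap_fraction * len(mono)))
        overlap = frozenset(
            int(i) for i in rng.choice(mono, size=n_overlap, replace=False)
        ) if n_overlap else frozenset()

        # tumor-planted clones: specific clones that survive the baseline
        # filter; all other spikes are zeroed in the tumor repertoire so the
        # planted count is exactly recoverable
        plantable = [i for i in sorted(spiked) if i not in overlap]
        n_plant = min(8, len(plantable))
        planted = frozenset(
            int(i) for i in rng.choice(plantable, size=n_plant, replace=False)
        ) if n_plant else frozenset()

        specs.append(
            SubjectSpec(
                subject_id=subject_id,
                index=idx,
                clonotypes=pool,
                base_freq=base,
                spiked=spiked,
                baseline_overlap=overlap,
                tumor_planted=planted,
            )
        )
    return specs


_COND_INDEX = {c: i for i, c in enumerate(Condition)}


def simulate_repertoire(
    config: SimConfig, condition: Condition | str, spec: SubjectSpec
) -> Repertoire:
    """Multinomially sample one condition repertoire from a subject state.

    Frequencies start from the subject's base vector; in an antigen
    condition the clones assigned to that antigen are multiplied by
    ``spike_fold`` and the vector renormalized.  The baseline repertoire
    omits all spiked clones except the designated baseline-overlap set;
    the tumor repertoire contains only the planted specific clones (at an
    elevated frequency) on top of the background.
    """
    condition = Condition(condition)
    rng = np.random.default_rng([config.seed, spec.index, 100 + _COND_INDEX[condition]])
    freq = spec.base_freq.copy()
    cond_name = str(condition)
    if condition in MKRAS_ANTIGENS:
        for i, ags in spec.spiked.items():
            if cond_name in ags:
                freq[i] *= config.spike_fold
    elif condition is Condition.BASELINE:
        for i in spec.spiked:
            if i not in spec.baseline_overlap:
                freq[i] = 0.0
    elif condition is Condition.TUMOR_TISSUE:
        for i in spec.spiked:
            freq[i] = 0.005 if i in spec.tumor_planted else 0.0
    freq = freq / freq.sum()
    counts = rng.multinomial(config.depth, freq)
    nz = np.flatnonzero(counts)
    return Repertoire(
        sample_id=f"{spec.subject_id}_{cond_name}",
        subject_id=spec.subject_id,
        condition=condition,
        counts={spec.clonotypes[i]: int(counts[i]) for i in nz},
    )


def simulate_cohort(
    config: SimConfig, include_tumor: bool = True
) -> tuple[dict[str, dict[Condition, Repertoire]], SimTruth]:
    """Generate all condition repertoires for every subject, plus truth.

    Returns ``(repertoires, truth)`` where ``repertoires[subject][condition]``
    is a :class:`~tcrvax.repertoire_io.Repertoire` covering baseline,
    vehicle-only, control-peptide, the six antigen expansions and
    (optionally) tumor tissue.
    """
    specs = build_cohort_specs(config)
    conditions = [Condition.BASELINE, Condition.VEHICLE_ONLY, Condition.CONTROL_PEPTIDE]
    conditions += list(MKRAS_ANTIGENS)
    if include_tumor:
        conditions.append(Condition.TUMOR_TISSUE)

    truth = SimTruth()
    repertoires: dict[str, dict[Condition, Repertoire]] = {}
    public_hosts: dict[Clonotype, list[str]] = {}
    for spec in specs:
        reps = {cond: simulate_repertoire(config, cond, spec) for cond in conditions}
        repertoires[spec.subject_id] = reps

        assignments: dict[Clonotype, frozenset[str]] = {}
        expanded: dict[str, set[Clonotype]] = {str(a): set() for a in MKRAS_ANTIGENS}
        for i, ags in spec.spiked.items():
            ct = spec.clonotypes[i]
            emitted = frozenset(a for a in ags if ct in reps[Condition(a)])
            if not emitted:
                continue
            assignments[ct] = emitted
            for a in emitted:
                expanded[a].add(ct)
        truth.antigen_assignments[spec.subject_id] = assignments
        truth.expanded[spec.subject_id] = expanded
        truth.cross_reactive[spec.subject_id] = {
            ct for ct, ags in assignments.items() if len(ags) >= 2
        }
        designated = {spec.clonotypes[i] for i in spec.baseline_overlap}
        truth.baseline_designated[spec.subject_id] = designated
        truth.baseline_present[spec.subject_id] = {
            ct for ct in designated if ct in reps[Condition.BASELINE]
        }
        if include_tumor:
            truth.tumor_planted[spec.subject_id] = {
                spec.clonotypes[i]
                for i in spec.tumor_planted
                if spec.clonotypes[i] in reps[Condition.TUMOR_TISSUE]
            }

    # public truth: clonotypes assigned (and emitted) in >= 2 subjects
    for spec in specs:
        for ct in truth.antigen_assignments[spec.subject_id]:
            public_hosts.setdefault(ct, []).append(spec.subject_id)
    for ct, hosts in public_hosts.items():
        if len(hosts) >= 2:
            truth.public[ct] = tuple(sorted(hosts))
            shared = frozenset.intersection(
                *(truth.antigen_assignments[s][ct] for s in hosts)
            )
            if shared:
                truth.public_antigen[ct] = sorted(shared)[0]
    return repertoires, truth


#: Peak-and-decay response profile knots (weeks -> fraction of full effect).
_PROFILE_WEEKS = np.array([0.0, 4.0, 8.0, 16.0, 26.0, 52.0])
_PROFILE_LEVEL = np.array([0.0, 0.5, 1.0, 1.0, 0.5, 0.1])


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    # negative binomial with var = mean + mean^2 / dispersion
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def pooled_baseline_sd(config: SimConfig, n_replicates: int = 3) -> float:
    """Theoretical cross-subject SD of the pooled baseline response.

    The pooled baseline value is mean(antigen wells) − control well, each a
    replicate mean of negative-binomial counts; the control well is shared
    by all six antigens, so Var = Var_NB/n_rep · (1/6 + 1).
    """
    mu, r = config.elispot_baseline_mean, config.elispot_dispersion
    var_nb = mu + mu * mu / r
    return math.sqrt(var_nb / n_replicates * (1.0 / len(ANTIGENS) + 1.0))


def simulate_elispot(
    config: SimConfig,
    weeks: Sequence[float] = (0, 4, 8, 12, 16, 26, 39, 52),
    responder_fraction: float = 0.75,
    n_subjects: int | None = None,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Simulate a long-format SFU panel with known responder labels.

    Every well (unstimulated, control peptide, six antigens) draws
    negative-binomial counts around ``elispot_baseline_mean``.  For
    responders, each antigen's post-vaccine mean is shifted by
    ``responder_effect_sd_units`` × the theoretical cross-subject SD of
    the pooled baseline response, scaled by a peak-and-decay time course
    (full effect weeks 8–16).  Non-responders are null at all weeks.

    Returns the measurement table (``subject_id, week, stimulation,
    replicate, sfu``) and the subject → responder truth map.
    """
    n = n_subjects if n_subjects is not None else config.n_subjects
    rng = np.random.default_rng([config.seed, 20_000_000])
    subjects = _subject_ids(n)
    responders = {s: bool(rng.random() < responder_fraction) for s in subjects}
    effect = config.responder_effect_sd_units * pooled_baseline_sd(config, n_replicates)
    rows: list[tuple[str, float, str, int, float]] = []
    for s_idx, subj in enumerate(subjects):
        srng = np.random.default_rng([config.seed, 20_000_000, s_idx])
        for week in weeks:
            level = float(np.interp(week, _PROFILE_WEEKS, _PROFILE_LEVEL))
            for stim in STIMULATIONS_ORDER:
                mean = config.elispot_baseline_mean
                if responders[subj] and stim in ANTIGENS:
                    mean = mean + effect * level
                draws = _nb_draw(srng, mean, config.elispot_dispersion, n_replicates)
                for rep, sfu in enumerate(draws, start=1):
                    rows.append((subj, float(week), stim, rep, float(sfu)))
    table = pd.DataFrame(
        rows, columns=["subject_id", "week", "stimulation", "replicate", "sfu"]
    )
    return table, responders


STIMULATIONS_ORDER: tuple[str, ...] = ("unstimulated", "control_peptide") + ANTIGENS


def simulate_survival(
    n_per_group: int,
    hazard_low: float,
    hazard_high: float,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """Two-arm exponential survival data with exponential censoring.

    Group ``"low"`` has hazard ``hazard_low`` (longer survival when lower),
    group ``"high"`` has ``hazard_high``.  ``censor_rate`` is the hazard of
    an independent exponential censoring time; 0 disables censoring.
    """
    if hazard_low <= 0 or hazard_high <= 0:
        raise ValueError("hazards must be > 0")
    rng = np.random.default_rng([seed, 30_000_000])
    records: list[SurvivalRecord] = []
    for group, hazard in (("low", hazard_low), ("high", hazard_high)):
        event_t = rng.exponential(1.0 / hazard, size=n_per_group)
        if censor_rate > 0:
            censor_t = rng.exponential(1.0 / censor_rate, size=n_per_group)
        else:
            censor_t = np.full(n_per_group, np.inf)
        for i in range(n_per_group):
            t = min(event_t[i], censor_t[i])
            records.append(
                SurvivalRecord(
                    subject_id=f"{group}{i + 1:03d}",
                    time=float(max(t, 1e-9)),
                    event=bool(event_t[i] <= censor_t[i]),
                    group=group,
                )
            )
    return records


def toy_study_config(seed: int = 20200528) -> SimConfig:
    """Small, fast study configuration used for the packaged toy study."""
    return SimConfig(
        n_subjects=3,
        n_clonotypes=300,
        depth=20_000,
        n_spiked_per_antigen=4,
        spike_fold=20.0,
        spike_freq_floor=0.005,
        cross_reactive_fraction=0.25,
        public_clone_count=2,
        baseline_overlap_fraction=0.15,
        seed=seed,
    )
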