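"""Ground-truth synthetic community generation.

Simulates absolute taxon abundances (genome copies per unit volume) for a
two-arm, two-timepoint intervention study: a shared log-normal community
archetype, per-subject multiplicative deviations (which induce the
taxon-wise correlation between subjects seen in real gut communities), a
treatment effect applied to a chosen set of responding taxa in the
treatment arm only, and random multiplicative temporal noise between the
two timepoints for every subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "c"
TREATMENT = "t"
BASELINE = "baseline"
POST = "post"

UNIDIRECTIONAL = "unidirectional"
BIDIRECTIONAL = "bidirectional"

#: Default community parameters: 100 taxa whose log-abundances are drawn
#: from Normal(12.5, 2.5) — a handful of dominant taxa and a long tail of
#: rare ones, resembling a genus-level gut profile.
DEFAULT_N_TAXA = 100
DEFAULT_LOG_MEAN = 12.5
DEFAULT_LOG_SD = 2.5
#: Per-subject multiplicative deviation from the archetype, log-scale sd.
DEFAULT_SUBJECT_LOG_SD = 0.5
#: Random between-timepoint change: each abundance is multiplied by an
#: independent Uniform(1 - f, 1 + f) draw with f = 0.25.
DEFAULT_NOISE_FRACTION = 0.25

#: The scenario grid: 5 effect magnitudes x 6 response proportions.
EFFECT_SIZES = (0.1, 0.5, 1.0, 5.0, 10.0)
PROPORTIONS = (0.01, 0.05, 0.10, 0.25, 0.50, 0.75)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid.

    Parameters
    ----------
    direction_regime:
        ``"unidirectional"`` (all responders increase) or
        ``"bidirectional"`` (responders split 1:1 between increases and
        decreases).
    effect_size:
        Non-negative magnitude ``e``; responders are multiplied by
        ``(1 + e)`` (increases) or divided by ``(1 + e)`` (decreases).
    proportion_responding:
        Fraction of taxa that respond to the treatment, in [0, 1].
    """

    direction_regime: str
    effect_size: float
    proportion_responding: float

    def __post_init__(self) -> None:
        if self.direction_regime not in (UNIDIRECTIONAL, BIDIRECTIONAL):
            raise ValueError(f"unknown direction regime: {self.direction_regime!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.proportion_responding <= 1.0:
            raise ValueError("proportion_responding must be in [0, 1]")


@dataclass(frozen=True)
class CohortDesign:
    """Subjects, their group assignment, and the two timepoints."""

    subject_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    timepoints: tuple[str, str] = (BASELINE, POST)

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.group_labels):
            raise ValueError("subject_ids and group_labels must align")
        if set(self.group_labels) != {CONTROL, TREATMENT}:
            raise ValueError("design must contain exactly the groups 'c' and 't'")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def group_of(self, subject: str) -> str:
        return self.group_labels[self.subject_ids.index(subject)]

    def sample_name(self, subject: str, timepoint: str) -> str:
        return f"{subject}_{self.group_of(subject)}_{timepoint}"

    def sample_names(self, timepoint: str) -> list[str]:
        return [self.sample_name(s, timepoint) for s in self.subject_ids]


def default_design(n_per_group: int = 10) -> CohortDesign:
    """The default cohort: ``n_per_group`` control then treatment subjects."""
    n = 2 * n_per_group
    ids = tuple(f"s{i + 1:02d}" for i in range(n))
    groups = (CONTROL,) * n_per_group + (TREATMENT,) * n_per_group
    return CohortDesign(subject_ids=ids, group_labels=groups)


@dataclass
class TruthTable:
    """Which taxa respond to the treatment, and in which direction."""

    responder: np.ndarray  # bool, one per taxon
    direction: np.ndarray  # int {+1, -1}; 0 for non-responders

    def __post_init__(self) -> None:
        self.responder = np.asarray(self.responder, dtype=bool)
        self.direction = np.asarray(self.direction, dtype=int)
        if self.responder.shape != self.direction.shape:
            raise ValueError("responder and direction must have equal length")
        if np.any(self.direction[~self.responder] != 0):
            raise ValueError("non-responders must have direction 0")
        if not np.all(np.isin(self.direction[self.responder], (-1, 1))):
            raise ValueError("responder directions must be +1 or -1")

    @property
    def n_taxa(self) -> int:
        return self.responder.size

    @property
    def n_responders(self) -> int:
        return int(self.responder.sum())


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def generate_baseline_profile(
    n_taxa: int = DEFAULT_N_TAXA,
    log_mean: float = DEFAULT_LOG_MEAN,
    log_sd: float = DEFAULT_LOG_SD,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the community archetype: ``exp(Normal(log_mean, log_sd))`` per taxon.

    Returns a strictly positive vector of absolute abundances. The absolute
    scale is arbitrary for every downstream compositional analysis; only
    the spread of the log-abundances matters.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng(rng)
    return np.exp(rng.normal(log_mean, log_sd, size=n_taxa))


def generate_cohort(
    baseline: np.ndarray,
    design: CohortDesign,
    subject_log_sd: float = DEFAULT_SUBJECT_LOG_SD,
    rng: np.random.Generator | None = None,
    taxon_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subject baseline profiles as multiplicative variants of the archetype.

    Each subject's abundance of taxon *i* is
    ``baseline[i] * exp(Normal(0, subject_log_sd))``, drawn independently
    per subject and taxon. Because all subjects share the archetype, their
    log-abundances are positively correlated taxon-wise with expected
    Pearson correlation ``log_sd^2 / (log_sd^2 + subject_log_sd^2)``.

    Returns a taxa x subjects DataFrame of baseline (pre-noise) abundances,
    columns named ``<subject>_<group>_baseline``.
    """
    if subject_log_sd < 0:
        raise ValueError("subject_log_sd must be >= 0")
    baseline = np.asarray(baseline, dtype=float)
    if baseline.ndim != 1 or np.any(baseline <= 0):
        raise ValueError("baseline must be a strictly positive vector")
    rng = np.random.default_rng(rng)
    dev = np.exp(rng.normal(0.0, subject_log_sd, size=(baseline.size, design.n_subjects)))
    values = baseline[:, None] * dev
    if taxon_ids is None:
        taxon_ids = [f"taxon{i + 1:03d}" for i in range(baseline.size)]
    return pd.DataFrame(values, index=taxon_ids, columns=design.sample_names(BASELINE))


def select_responders(
    n_taxa: int,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Draw the responding-taxon set for one scenario iteration.

    The responder count is exact: ``round(proportion * n_taxa)``
    (half away from zero, so 1% of 100 taxa is exactly one responder). In
    the bidirectional regime the responders are split 1:1 between
    increases and decreases; an odd count leaves the extra taxon on the
    increasing side. Responder identity is population-level: all treatment
    subjects share the same truth table.
    """
    rng = np.random.default_rng(rng)
    n_resp = _round_half_away(spec.proportion_responding * n_taxa)
    if n_resp > n_taxa:
        raise ValueError("proportion yields more responders than taxa")
    responder = np.zeros(n_taxa, dtype=bool)
    direction = np.zeros(n_taxa, dtype=int)
    idx = rng.choice(n_taxa, size=n_resp, replace=False)
    responder[idx] = True
    if spec.direction_regime == UNIDIRECTIONAL:
        direction[idx] = 1
    else:
        n_up = (n_resp + 1) // 2
        shuffled = rng.permutation(idx)
        direction[shuffled[:n_up]] = 1
        direction[shuffled[n_up:]] = -1
    return TruthTable(responder=responder, direction=direction)


def apply_treatment(
    baseline_matrix: pd.DataFrame,
    truth: TruthTable,
    effect_size: float,
    design: CohortDesign,
) -> pd.DataFrame:
    """Apply the intervention effect to treatment-arm subjects.

    Up-responders are multiplied by ``(1 + effect_size)``, down-responders
    divided by it; control subjects and non-responders are untouched. The
    result is the deterministic post-intervention state before temporal
    noise; columns are renamed to the post timepoint.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if truth.n_taxa != baseline_matrix.shape[0]:
        raise ValueError("truth table length does not match taxon count")
    post = baseline_matrix.to_numpy(dtype=float).copy()
    factor = np.ones(truth.n_taxa)
    factor[truth.direction == 1] = 1.0 + effect_size
    factor[truth.direction == -1] = 1.0 / (1.0 + effect_size)
    treated = [g == TREATMENT for g in design.group_labels]
    post[:, treated] = post[:, treated] * factor[:, None]
    return pd.DataFrame(
        post, index=baseline_matrix.index, columns=design.sample_names(POST)
    )


def apply_temporal_noise(
    matrix: pd.DataFrame,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    rng: np.random.Generator | None = None,
    log_symmetric: bool = False,
) -> pd.DataFrame:
    """Multiply every entry by an independent random between-timepoint change.

    The default draws multipliers from ``Uniform(1 - f, 1 + f)``; setting
    ``log_symmetric`` uses ``exp(Uniform(-log(1+f), log(1+f)))`` instead,
    which is symmetric on the log scale. Requires ``f < 1`` so abundances
    stay strictly positive.
    """
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in [0, 1)")
    rng = np.random.default_rng(rng)
    if log_symmetric:
        b = np.log1p(noise_fraction)
        mult = np.exp(rng.uniform(-b, b, size=matrix.shape))
    else:
        mult = rng.uniform(1.0 - noise_fraction, 1.0 + noise_fraction, size=matrix.shape)
    return matrix * mult


def simulate_cohort_study(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    n_taxa: int = DEFAULT_N_TAXA,
    log_mean: float = DEFAULT_LOG_MEAN,
    log_sd: float = DEFAULT_LOG_SD,
    subject_log_sd: float = DEFAULT_SUBJECT_LOG_SD,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    design: CohortDesign | None = None,
    log_symmetric_noise: bool = False,
) -> tuple[pd.DataFrame, TruthTable, CohortDesign]:
    """Generate one complete ground-truth dataset for a scenario.

    Composes archetype -> cohort -> responder draw -> treatment ->
    temporal noise and returns the taxa x (2 * n_subjects) absolute
    abundance matrix holding both timepoints, plus the truth table and
    design. Temporal noise applies to every subject (both arms), on top of
    the treatment effect in the treatment arm.
    """
    design = design or default_design()
    archetype = generate_baseline_profile(n_taxa, log_mean, log_sd, rng)
    base = generate_cohort(archetype, design, subject_log_sd, rng)
    truth = select_responders(n_taxa, spec, rng)
    post = apply_treatment(base, truth, spec.effect_size, design)
    post = apply_temporal_noise(post, noise_fraction, rng, log_symmetric=log_symmetric_noise)
    return pd.concat([base, post], axis=1), truth, design
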