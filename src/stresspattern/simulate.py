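"""Synthetic data generators with planted ground truth.

The expression generator emulates a three-strain (C57BL/6J "B", C57BL/6NJ
"N", DBA/2J "D") by four-treatment (NH, CMS, NH-R, CMS-R) hippocampal
microarray experiment on the log2 scale.  A configurable subset of
transcripts carries a planted stress-response template per strain:

* ``TRANSIENT`` (0:1:0 over CMS, CMS-R, NH-R) — only the chronic-plus-acute
  group is shifted, i.e. the acute response is conditional on chronic
  stress history.
* ``SUSTAINED`` (1:1:0) — every chronically stressed group is shifted,
  regardless of the acute challenge.

Down-regulated transcripts use the inverse patterns (1:0:1 and 0:0:1),
realised here as a negative shift of the same groups.  The NH group always
sits at baseline.  The generator records which transcript carries which
template in which strain (:class:`PlantedTruth`), which downstream tests
use as a recovery oracle.

Phenotype and fecal-corticosterone generators emulate the biometric arm of
the same design: a heart-weight deficit under chronic stress, strain
orderings for organ weights, an HPA-axis sensitization increment for the N
strain, and a fecal-CORT time course that rises in week 1 and habituates
back to baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TEMPLATES = ("TRANSIENT", "SUSTAINED")
DIRECTIONS = ("UP", "DOWN")

#: treatment groups over which response templates are defined, in order
TEMPLATE_GROUPS = ("CMS", "CMS-R", "NH-R")

#: groups whose mean is shifted by a planted template, per shape
SHIFTED_GROUPS = {"TRANSIENT": ("CMS-R",), "SUSTAINED": ("CMS", "CMS-R")}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class SimulationConfig:
    """Parameters of the expression simulation.

    Defaults mirror the emulated study: 25,858 annotated transcripts,
    3 strains x 4 treatments with 5 replicates per cell, Gaussian residuals
    of 0.25 log2 units, planted effects of 1.0 log2 unit, and per-strain
    planted fractions whose expected strain-unique counts echo 430 (B),
    258 (N) and 1363 (D) of 25,858.  ``up_fraction`` encodes the observed
    direction bias (N mostly up-regulated, D mostly down-regulated);
    ``overlap_spec`` fixes exact counts for the four multi-strain Venn
    regions and ``concordance_spec`` the probability that a shared
    transcript responds in the same direction in a strain pair.
    """

    n_transcripts: int = 25_858
    strains: Sequence[str] = ("B", "N", "D")
    treatments: Sequence[str] = ("NH", "CMS", "NH-R", "CMS-R")
    replicates_per_cell: int = 5
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    residual_sd: float = 0.25
    effect_size: float = 1.0
    planted_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"B": 0.017, "N": 0.010, "D": 0.053}
    )
    up_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"B": 0.5, "N": 0.7, "D": 0.3}
    )
    overlap_spec: Mapping[tuple[str, ...], int] = field(
        default_factory=lambda: {
            ("B", "N"): 9,
            ("B", "D"): 31,
            ("D", "N"): 130,
            ("B", "D", "N"): 6,
        }
    )
    concordance_spec: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("B", "N"): 1.0,
            ("B", "D"): 0.10,
            ("D", "N"): 0.115,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be positive")
        if self.replicates_per_cell < 2:
            raise ConfigurationError("replicates_per_cell must be >= 2")
        if not self.residual_sd > 0:
            raise ConfigurationError("residual_sd must be > 0")
        lo, hi = self.baseline_mean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_mean_range must be (low, high)")
        for s in self.strains:
            f = self.planted_fraction.get(s, 0.0)
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"planted fraction for {s!r} outside [0, 1]")
            u = self.up_fraction.get(s, 0.5)
            if not 0.0 <= u <= 1.0:
                raise ConfigurationError(f"up fraction for {s!r} outside [0, 1]")
        missing = set(TEMPLATE_GROUPS) - set(self.treatments)
        if missing or "NH" not in self.treatments:
            raise ConfigurationError(
                f"treatments must include NH and {TEMPLATE_GROUPS}, missing {missing}"
            )
        if self._total_planted() > self.n_transcripts:
            raise ConfigurationError(
                "overlap_spec regions plus strain-unique blocks exceed n_transcripts"
            )

    def _region_counts(self) -> dict[tuple[str, ...], int]:
        """Exclusive region -> planted transcript count, multi-strain first."""
        counts: dict[tuple[str, ...], int] = {}
        for region, n in self.overlap_spec.items():
            key = tuple(sorted(region))
            if not set(key) <= set(self.strains):
                raise ConfigurationError(f"overlap region {region} not within strains")
            if n < 0:
                raise ConfigurationError(f"overlap region {region} has negative count")
            counts[key] = int(n)
        for s in self.strains:
            counts[(s,)] = int(round(self.planted_fraction.get(s, 0.0) * self.n_transcripts))
        return counts

    def _total_planted(self) -> int:
        return sum(self._region_counts().values())


@dataclass
class PlantedTruth:
    """Ground-truth record of planted templates.

    ``table`` has one row per (transcript, strain) carrying a planted
    template, with columns transcript, strain, template, direction.
    Transcript/strain combinations absent from the table are
    non-responsive (template NONE, direction NONE).
    """

    table: pd.DataFrame

    def lookup(self, transcript: str, strain: str) -> tuple[str, str]:
        hit = self.table[
            (self.table["transcript"] == transcript) & (self.table["strain"] == strain)
        ]
        if hit.empty:
            return ("NONE", "NONE")
        row = hit.iloc[0]
        return (row["template"], row["direction"])

    @property
    def planted_transcripts(self) -> set[str]:
        return set(self.table["transcript"])


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for strain, treatment in itertools.product(config.strains, config.treatments):
        for rep in range(1, config.replicates_per_cell + 1):
            rows.append(
                {
                    "sample_id": f"{strain}_{treatment}_{rep}",
                    "strain": strain,
                    "treatment": treatment,
                }
            )
    return pd.DataFrame(rows)


def _plant_assignments(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign templates/directions to contiguous transcript-index blocks.

    Blocks (multi-strain Venn regions first, then strain-unique blocks)
    make the exclusive region counts exact by construction rather than by
    rejection sampling.  Within a shared region, the direction of the
    first strain (anchor) is drawn from its ``up_fraction``; each further
    strain agrees with the anchor with the pairwise concordance
    probability.
    """
    counts = config._region_counts()
    regions = [k for k in counts if len(k) > 1] + [k for k in counts if len(k) == 1]
    rows = []
    start = 0
    for region in regions:
        n = counts[region]
        anchor = region[0]
        for idx in range(start, start + n):
            tid = f"T{idx:05d}"
            anchor_dir = "UP" if rng.random() < config.up_fraction.get(anchor, 0.5) else "DOWN"
            for strain in region:
                if strain == anchor:
                    direction = anchor_dir
                else:
                    p_agree = config.concordance_spec.get(_pair_key(anchor, strain), 0.5)
                    agree = rng.random() < p_agree
                    direction = anchor_dir if agree else ("UP" if anchor_dir == "DOWN" else "DOWN")
                template = TEMPLATES[int(rng.random() < 0.5)]
                rows.append(
                    {
                        "transcript": tid,
                        "strain": strain,
                        "template": template,
                        "direction": direction,
                    }
                )
        start += n
    return pd.DataFrame(rows, columns=["transcript", "strain", "template", "direction"])


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate a log2 expression matrix with planted stress templates.

    Returns
    -------
    matrix : DataFrame, transcripts x samples (log2 scale)
    samples : DataFrame with columns sample_id, strain, treatment
    truth : PlantedTruth recovery oracle

    Baselines are uniform over ``baseline_mean_range`` per transcript;
    residuals are i.i.d. Gaussian on the log2 scale.  A planted template
    shifts the group means of :data:`SHIFTED_GROUPS` by ``+effect_size``
    (UP) or ``-effect_size`` (DOWN) within the carrying strain only.
    Identical seed and config give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _sample_table(config)
    transcript_ids = [f"T{i:05d}" for i in range(config.n_transcripts)]

    lo, hi = config.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=config.n_transcripts)
    values = baseline[:, None] + rng.normal(
        0.0, config.residual_sd, size=(config.n_transcripts, len(samples))
    )

    truth_table = _plant_assignments(config, rng)
    # index planted rows once, then add the shift per (strain, group) column block
    tid_to_row = {tid: i for i, tid in enumerate(transcript_ids)}
    for (strain, template, direction), grp in truth_table.groupby(
        ["strain", "template", "direction"]
    ):
        rows = [tid_to_row[t] for t in grp["transcript"]]
        shift = config.effect_size if direction == "UP" else -config.effect_size
        for treatment in SHIFTED_GROUPS[template]:
            cols = samples.index[
                (samples["strain"] == strain) & (samples["treatment"] == treatment)
            ].to_numpy()
            values[np.ix_(rows, cols)] += shift

    matrix = pd.DataFrame(values, index=pd.Index(transcript_ids, name="transcript"),
                          columns=samples["sample_id"].tolist())
    return matrix, samples, PlantedTruth(truth_table)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenoSimConfig:
    """Parameters of the biometric and endocrine simulation.

    Baseline fecal-CORT means/SDs are the emulated study's printed
    per-strain values.  Organ-weight means respect the printed strain
    orderings (heart D>N>B, thymus N>B>D, adrenal N>B>D, brain B~N>D);
    the chronic-stress heart deficit defaults to 10.4 mg.  Plasma-CORT
    means encode a larger restraint response in N and D than B, plus a
    cross-sensitization increment applied to the N strain's CMS-R group.
    Weights are in g (body, brain) or mg (organs); CORT in ng/mL; fCORT in
    RIA assay units.
    """

    strains: Sequence[str] = ("B", "N", "D")
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"NH": 6, "NH-R": 7, "CMS": 8, "CMS-R": 8}
    )
    fcort_baseline: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"B": (1.77, 0.20), "N": (1.73, 0.27), "D": (1.93, 0.22)}
    )
    fcort_elevation: float = 1.5          # week-1 multiplicative rise
    fcort_return_week: int = 4            # expected mean back at baseline from here on
    n_weeks: int = 7
    plasma_cort_restraint_mean: Mapping[str, float] = field(
        default_factory=lambda: {"B": 250.0, "N": 420.0, "D": 410.0}
    )
    plasma_cort_basal_mean: Mapping[str, float] = field(
        default_factory=lambda: {"B": 40.0, "N": 45.0, "D": 60.0}
    )
    plasma_cort_sd: float = 60.0
    plasma_cort_basal_sd: float = 15.0
    sensitization_strain: str = "N"
    sensitization_increment: float = 120.0
    heart_mean: Mapping[str, float] = field(
        default_factory=lambda: {"B": 138.0, "N": 145.0, "D": 160.0}
    )
    heart_cms_deficit: float = 10.4
    heart_sd: float = 8.0
    thymus_mean: Mapping[str, float] = field(
        default_factory=lambda: {"B": 45.0, "N": 60.0, "D": 30.0}
    )
    thymus_sd: float = 8.0
    adrenal_mean: Mapping[str, float] = field(
        default_factory=lambda: {"B": 4.6, "N": 5.2, "D": 3.8}
    )
    adrenal_sd: float = 0.5
    brain_mean: Mapping[str, float] = field(
        default_factory=lambda: {"B": 0.470, "N": 0.468, "D": 0.410}
    )
    brain_sd: float = 0.015
    body_weight_start_mean: float = 18.5
    body_weight_start_sd: float = 1.2
    weight_gain_mean: Mapping[str, float] = field(
        default_factory=lambda: {"B": 2.0, "N": 3.5, "D": 1.5}
    )
    weight_gain_sd: float = 1.0
    cms_gain_attenuation: Mapping[str, float] = field(
        default_factory=lambda: {"B": 1.0, "N": 1.0, "D": 0.0}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("plasma_cort_sd", "plasma_cort_basal_sd", "heart_sd", "thymus_sd",
                     "adrenal_sd", "brain_sd", "body_weight_start_sd", "weight_gain_sd"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        for s in self.strains:
            mu, sd = self.fcort_baseline[s]
            if not (mu > 0 and sd > 0):
                raise ConfigurationError(f"fCORT baseline for {s!r} must be positive")
        if not 1 <= self.fcort_return_week <= self.n_weeks:
            raise ConfigurationError("fcort_return_week must lie in 1..n_weeks")
        if self.fcort_elevation < 1.0:
            raise ConfigurationError("fcort_elevation must be >= 1 (multiplicative)")
        for t, n in self.group_sizes.items():
            if n < 0:
                raise ConfigurationError(f"group size for {t!r} must be >= 0")


def _positive(values: np.ndarray) -> np.ndarray:
    # biometric quantities are strictly positive; clip the (vanishingly
    # rare) negative Gaussian draws at a small epsilon
    return np.maximum(values, 1e-6)


def simulate_phenotypes(config: PhenoSimConfig) -> pd.DataFrame:
    """Simulate an animal-level phenotype table.

    One row per animal with strain, treatment, start/end body weight (g),
    organ weights (adrenal/thymus/heart mg, brain g), plasma CORT (ng/mL)
    and a counterbalanced sacrifice day in 1..4.  Chronically stressed
    animals (CMS, CMS-R) draw heart weights with the mean lowered by
    ``heart_cms_deficit`` and attenuated body-weight gain per strain.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    counter = itertools.count(1)
    for strain in config.strains:
        for treatment, n in config.group_sizes.items():
            stressed = treatment in ("CMS", "CMS-R")
            restrained = treatment in ("NH-R", "CMS-R")
            heart_mu = config.heart_mean[strain] - (config.heart_cms_deficit if stressed else 0.0)
            gain_mu = config.weight_gain_mean[strain]
            if stressed:
                gain_mu -= config.cms_gain_attenuation.get(strain, 0.0)
            if restrained:
                cort_mu = config.plasma_cort_restraint_mean[strain]
                cort_sd = config.plasma_cort_sd
                if treatment == "CMS-R" and strain == config.sensitization_strain:
                    cort_mu += config.sensitization_increment
            else:
                cort_mu = config.plasma_cort_basal_mean[strain]
                cort_sd = config.plasma_cort_basal_sd
            for i in range(n):
                start = rng.normal(config.body_weight_start_mean, config.body_weight_start_sd)
                gain = rng.normal(gain_mu, config.weight_gain_sd)
                rows.append(
                    {
                        "animal_id": f"A{next(counter):04d}",
                        "strain": strain,
                        "treatment": treatment,
                        "body_weight_start_g": float(_positive(np.array(start))),
                        "body_weight_end_g": float(_positive(np.array(start + gain))),
                        "adrenal_mg": float(_positive(
                            rng.normal(config.adrenal_mean[strain], config.adrenal_sd))),
                        "thymus_mg": float(_positive(
                            rng.normal(config.thymus_mean[strain], config.thymus_sd))),
                        "heart_mg": float(_positive(rng.normal(heart_mu, config.heart_sd))),
                        "brain_g": float(_positive(
                            rng.normal(config.brain_mean[strain], config.brain_sd))),
                        "plasma_cort_ng_ml": float(_positive(rng.normal(cort_mu, cort_sd))),
                        "sacrifice_day": (i % 4) + 1,
                    }
                )
    return pd.DataFrame(rows)


def fcort_week_multiplier(config: PhenoSimConfig, week: int) -> float:
    """Expected fCORT multiplier at a given week (1.0 = baseline).

    Week 0 is the pre-stress baseline.  The multiplier jumps to
    ``fcort_elevation`` at week 1 and declines linearly so that the
    expected mean is back at baseline from ``fcort_return_week`` onward —
    the habituation profile of the emulated time course.
    """
    if week <= 0 or week >= config.fcort_return_week:
        return 1.0
    # linear decline from elevation at week 1 to 1.0 at the return week
    frac = (config.fcort_return_week - week) / (config.fcort_return_week - 1)
    return 1.0 + (config.fcort_elevation - 1.0) * frac


def simulate_fcort_timecourse(config: PhenoSimConfig) -> pd.DataFrame:
    """Simulate weekly fecal-CORT measures for chronically stressed animals.

    Returns a long table: animal_id, strain, week (0..n_weeks), fcort.
    Values are simulated on the natural scale; the analysis layer applies
    the log transform.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n_animals = {
        s: config.group_sizes.get("CMS", 0) + config.group_sizes.get("CMS-R", 0)
        for s in config.strains
    }
    rows = []
    counter = itertools.count(1)
    for strain in config.strains:
        mu0, sd0 = config.fcort_baseline[strain]
        for _ in range(n_animals[strain]):
            aid = f"F{next(counter):04d}"
            for week in range(0, config.n_weeks + 1):
                mu = mu0 * fcort_week_multiplier(config, week)
                rows.append(
                    {
                        "animal_id": aid,
                        "strain": strain,
                        "week": week,
                        "fcort": float(_positive(rng.normal(mu, sd0))),
                    }
                )
    return pd.DataFrame(rows)
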