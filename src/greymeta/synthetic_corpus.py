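"""Synthetic review corpora with the structure of the studied sample.

The generator emulates a register of child-health systematic reviews drawn
from three review groups: a heavy-tailed number of studies per review
(median about 3), a low prevalence of grey-literature study types among
included studies (about 4.4% non-English, 1.9% unpublished, 1.9%
dissertations), near-universal searching for non-English and unpublished
studies but infrequent searching for dissertations, and a mix of
dichotomous and continuous primary outcomes.  An optional additive effect
shift for grey studies provides a single explicit bias knob for simulation
studies of language and publication bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corpus_summary import ReviewGroup, ReviewRecord, StudyRecord
from .impact_analysis import StudyTypeLabel
from .meta_engine import (
    ContinuousArms,
    DichotomousArms,
    PoolingMethod,
    PoolingModel,
    SummaryMeasure,
)

__all__ = ["GeneratorConfig", "ConfigError", "generate_corpus", "fixture_from_counts"]


class ConfigError(ValueError):
    """Raised for an invalid generator configuration; names the field."""


def _default_groups() -> dict:
    return {"ARI": 57, "ID": 38, "DPLP": 34}


def _default_prevalence() -> dict:
    return {"non_english": 0.044, "unpublished": 0.019, "dissertation": 0.019}


def _default_searched() -> dict:
    return {"non_english": 0.992, "unpublished": 0.961, "dissertation": 0.217}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus.

    studies_per_review is (r, p) of a shifted negative binomial
    1 + NB(r, p); the default (0.4, 0.0741) gives median 3, quartiles
    about (1, 7) and mean 6, matching a register dominated by small
    meta-analyses with a long right tail.  arm_size_distribution is (mu, sigma) of a
    log-normal for participants per arm (minimum 10); the default puts the
    median review (3 studies) near 600 participants.  true_effect is
    (mean, sd) of the per-review effect on the analysis scale (log scale
    for ratio measures).  grey_effect_shift is added, on the analysis
    scale, to the study-level effect of every study carrying at least one
    grey-literature label.
    """

    n_reviews_per_group: dict = field(default_factory=_default_groups)
    studies_per_review: tuple = (0.4, 0.0741)
    label_prevalence: dict = field(default_factory=_default_prevalence)
    searched_probability: dict = field(default_factory=_default_searched)
    outcome_mix: float = 0.6  # proportion of reviews with a dichotomous outcome
    true_effect: tuple = (0.0, 0.3)
    between_study_sd: float = 0.1
    grey_effect_shift: float = 0.0
    baseline_risk: float = 0.2
    arm_size_distribution: tuple = (4.4, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, value in self.n_reviews_per_group.items():
            if not isinstance(value, int) or value < 0:
                raise ConfigError(f"n_reviews_per_group[{name!r}] must be >= 0")
            if name not in ReviewGroup.__members__:
                raise ConfigError(f"n_reviews_per_group: unknown group {name!r}")
        r, p = self.studies_per_review
        if not (r > 0 and 0 < p < 1):
            raise ConfigError("studies_per_review must be (r > 0, 0 < p < 1)")
        for fname, mapping in (
            ("label_prevalence", self.label_prevalence),
            ("searched_probability", self.searched_probability),
        ):
            for label in StudyTypeLabel:
                prob = mapping.get(label.value)
                if prob is None or not 0 <= prob <= 1:
                    raise ConfigError(
                        f"{fname}[{label.value!r}] must be a probability in [0, 1]"
                    )
        if not 0 <= self.outcome_mix <= 1:
            raise ConfigError("outcome_mix must be in [0, 1]")
        if self.true_effect[1] < 0:
            raise ConfigError("true_effect sd must be >= 0")
        if self.between_study_sd < 0:
            raise ConfigError("between_study_sd must be >= 0")
        if not 0 < self.baseline_risk < 1:
            raise ConfigError("baseline_risk must be in (0, 1)")
        if self.arm_size_distribution[1] < 0:
            raise ConfigError("arm_size_distribution sigma must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        data = dict(data)
        for key in ("studies_per_review", "true_effect", "arm_size_distribution"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _draw_arm_size(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    mu, sigma = cfg.arm_size_distribution
    return max(10, int(round(float(rng.lognormal(mu, sigma)))))


def _draw_n_studies(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    r, p = cfg.studies_per_review
    return 1 + int(rng.negative_binomial(r, p))


def _dichotomous_study(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    theta: float,
    measure: SummaryMeasure,
) -> tuple[DichotomousArms, int]:
    n1, n2 = _draw_arm_size(cfg, rng), _draw_arm_size(cfg, rng)
    p0 = cfg.baseline_risk
    if measure is SummaryMeasure.OR:
        odds = p0 / (1 - p0) * math.exp(theta)
        p1 = odds / (1 + odds)
    else:  # RR
        p1 = min(0.99, p0 * math.exp(theta))
    arms = DichotomousArms(
        events_treatment=int(rng.binomial(n1, p1)),
        total_treatment=n1,
        events_control=int(rng.binomial(n2, p0)),
        total_control=n2,
    )
    return arms, n1 + n2


def _continuous_study(
    cfg: GeneratorConfig, rng: np.random.Generator, theta: float
) -> tuple[ContinuousArms, int]:
    # population sd fixed at 1, so MD and SMD share the effect scale
    n1, n2 = _draw_arm_size(cfg, rng), _draw_arm_size(cfg, rng)

    def sample_sd(n: int) -> float:
        return float(np.sqrt(rng.chisquare(n - 1) / (n - 1)))

    arms = ContinuousArms(
        mean_treatment=float(rng.normal(theta, 1 / math.sqrt(n1))),
        sd_treatment=sample_sd(n1),
        n_treatment=n1,
        mean_control=float(rng.normal(0.0, 1 / math.sqrt(n2))),
        sd_control=sample_sd(n2),
        n_control=n2,
    )
    return arms, n1 + n2


def generate_corpus(config: GeneratorConfig) -> list:
    """Generate a reproducible synthetic corpus of ReviewRecord objects.

    Each review draws a true effect on its analysis scale; each study draws
    a study-level effect (true effect + between-study noise +
    grey_effect_shift if the study carries any grey label), then arm-level
    data consistent with that effect.  Labels and searched flags are
    assigned independently per configured probability.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = list(StudyTypeLabel)
    corpus: list[ReviewRecord] = []
    idx = 0
    for group_name in sorted(config.n_reviews_per_group):
        group = ReviewGroup[group_name]
        for _ in range(config.n_reviews_per_group[group_name]):
            idx += 1
            review_id = f"SR{idx:04d}"
            dichotomous = rng.random() < config.outcome_mix
            if dichotomous:
                measure = (
                    SummaryMeasure.RR
                    if rng.random() < 0.8
                    else SummaryMeasure.OR
                )
            else:
                measure = (
                    SummaryMeasure.MD
                    if rng.random() < 0.6
                    else SummaryMeasure.SMD
                )
            model = (
                PoolingModel.random if rng.random() < 0.5 else PoolingModel.fixed
            )
            method = PoolingMethod.inverse_variance
            if (
                dichotomous
                and model is PoolingModel.fixed
                and rng.random() < 0.3
            ):
                method = PoolingMethod.mantel_haenszel
            searched = {
                label: bool(
                    rng.random() < config.searched_probability[label.value]
                )
                for label in labels
            }
            mu, sd = config.true_effect
            true_theta = float(rng.normal(mu, sd))
            n_studies = _draw_n_studies(config, rng)
            studies: list[StudyRecord] = []
            for k in range(n_studies):
                study_labels = frozenset(
                    label
                    for label in labels
                    if rng.random() < config.label_prevalence[label.value]
                )
                theta = true_theta + float(
                    rng.normal(0.0, config.between_study_sd)
                )
                if study_labels:
                    theta += config.grey_effect_shift
                if dichotomous:
                    outcome, n_part = _dichotomous_study(
                        config, rng, theta, measure
                    )
                else:
                    outcome, n_part = _continuous_study(config, rng, theta)
                studies.append(
                    StudyRecord(
                        study_id=f"{review_id}-S{k + 1:03d}",
                        labels=study_labels,
                        n_participants=n_part,
                        outcome=outcome,
                    )
                )
            corpus.append(
                ReviewRecord(
                    review_id=review_id,
                    group=group,
                    measure=measure,
                    model=model,
                    method=method,
                    studies=studies,
                    searched=searched,
                    year=int(rng.integers(1990, 2014)),
                )
            )
    return corpus


# ---------------------------------------------------------------------------
# Deterministic count-matched fixtures
# ---------------------------------------------------------------------------

_FIXTURE_OUTCOME = DichotomousArms(5, 10, 5, 10)


def fixture_from_counts(counts) -> list:
    """Minimal deterministic corpus reproducing given summary counts.

    ``counts`` is a table (DataFrame or list of dicts) with one row per
    (group, study_type) holding n_reviews, n_searched, n_included,
    n_studies_total and n_studies_of_type; n_reviews and n_studies_total
    must agree across a group's rows.  The returned corpus satisfies
    ``summarize(fixture_from_counts(C)) == C`` cell for cell.
    """
    import pandas as pd

    frame = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    required = {
        "group",
        "study_type",
        "n_reviews",
        "n_searched",
        "n_included",
        "n_studies_total",
        "n_studies_of_type",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ConfigError(f"counts table missing column(s): {sorted(missing)}")

    corpus: list[ReviewRecord] = []
    for group_name, rows in frame.groupby("group", sort=True):
        if group_name not in ReviewGroup.__members__:
            raise ConfigError(f"counts: unknown group {group_name!r}")
        n_reviews = rows["n_reviews"].unique()
        n_total = rows["n_studies_total"].unique()
        if len(n_reviews) != 1 or len(n_total) != 1:
            raise ConfigError(
                f"counts: n_reviews/n_studies_total inconsistent for {group_name}"
            )
        n_reviews, n_total = int(n_reviews[0]), int(n_total[0])
        per_label: dict[StudyTypeLabel, tuple[int, int, int]] = {}
        for _, row in rows.iterrows():
            label = StudyTypeLabel(row["study_type"])
            s, i, m = (
                int(row["n_searched"]),
                int(row["n_included"]),
                int(row["n_studies_of_type"]),
            )
            if not 0 <= i <= s <= n_reviews:
                raise ConfigError(
                    f"counts[{group_name}, {label.value}]: need "
                    "included <= searched <= reviews"
                )
            if (i == 0) != (m == 0) and i == 0:
                raise ConfigError(
                    f"counts[{group_name}, {label.value}]: typed studies "
                    "without an including review"
                )
            if i > 0 and m < i:
                raise ConfigError(
                    f"counts[{group_name}, {label.value}]: fewer typed "
                    "studies than including reviews"
                )
            per_label[label] = (s, i, m)

        searched_flags = [
            {
                label: j < per_label.get(label, (0, 0, 0))[0]
                for label in StudyTypeLabel
            }
            for j in range(n_reviews)
        ]
        typed_per_review: list[list[StudyTypeLabel]] = [
            [] for _ in range(n_reviews)
        ]
        for label, (s, i, m) in per_label.items():
            for j in range(i):
                extra = (m - i) if j == 0 else 0
                typed_per_review[j].extend([label] * (1 + extra))

        n_typed_total = sum(len(t) for t in typed_per_review)
        fillers = [1 if not t else 0 for t in typed_per_review]
        spare = n_total - n_typed_total - sum(fillers)
        if spare < 0:
            raise ConfigError(
                f"counts[{group_name}]: n_studies_total too small for the "
                "requested typed studies and one study per review"
            )
        fillers[0] += spare

        for j in range(n_reviews):
            review_id = f"{group_name}-R{j + 1:03d}"
            studies: list[StudyRecord] = []
            k = 0
            for label in typed_per_review[j]:
                k += 1
                studies.append(
                    StudyRecord(
                        study_id=f"{review_id}-S{k:03d}",
                        labels=frozenset([label]),
                        n_participants=20,
                        outcome=_FIXTURE_OUTCOME,
                    )
                )
            for _ in range(fillers[j]):
                k += 1
                studies.append(
                    StudyRecord(
                        study_id=f"{review_id}-S{k:03d}",
                        labels=frozenset(),
                        n_participants=20,
                        outcome=_FIXTURE_OUTCOME,
                    )
                )
            corpus.append(
                ReviewRecord(
                    review_id=review_id,
                    group=ReviewGroup[group_name],
                    measure=SummaryMeasure.RR,
                    model=PoolingModel.fixed,
                    method=PoolingMethod.inverse_variance,
                    studies=studies,
                    searched=searched_flags[j],
                )
            )
    return corpus
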