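"""Synthetic multi-reader study generator with known operating characteristics.

A one-dimensional latent severity drives every observer: subjects draw a
latent s ~ N(0, 1) for the normal class and N(d, 1) for the disease class,
and observer o perceives u = lambda_o * s + sqrt(1 - lambda_o^2) * eps with
independent noise.  The perceived severity maps to a disease-class (AD)
probability through a logistic link, the residual mass goes to the normal
class minus a fixed "leakage" profile over the other five categories, and an
optional tie event replaces the top two category values with their mean
(emulating human readers who record exact CN/AD ties).  Because the link is
monotone, a tie-free observer's population AUC is exactly
Phi(lambda * d / sqrt(2)), which makes the generator's operating
characteristics verifiable in closed form.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.special import expit
from scipy.stats import norm

from .data_model import AssessmentTable, CategorySet


@dataclass(frozen=True)
class ObserverProfile:
    """Latent-model parameters for one observer.

    loading
        Correlation of perceived severity with the latent truth signal
        (0 = pure noise, 1 = perfect); pairs of observers correlate at the
        product of their loadings.
    link_intercept, link_slope
        Logit-scale calibration of the AD-probability channel,
        p = expit(intercept + slope * perceived).
    tie_propensity
        Probability that a case is recorded with an exact top-two tie.
    leakage
        Fixed non-negative weights (summing to < 1) giving the share of the
        residual (non-AD) mass sent to each non-CN/AD category; the normal
        class keeps the remainder.
    rounding_decimals
        Recorded precision of the probability vector (3 corresponds to
        one-decimal percentages); None disables rounding.
    """

    loading: float
    link_intercept: float = 0.0
    link_slope: float = 1.0
    tie_propensity: float = 0.0
    leakage: Mapping[str, float] = field(default_factory=dict)
    rounding_decimals: int | None = 3

    def __post_init__(self) -> None:
        if not 0 <= self.loading <= 1:
            raise ValueError("loading must lie in [0, 1]")
        if not 0 <= self.tie_propensity <= 1:
            raise ValueError("tie_propensity must lie in [0, 1]")
        if any(w < 0 for w in self.leakage.values()):
            raise ValueError("leakage weights must be non-negative")
        if sum(self.leakage.values()) > 1:
            raise ValueError("leakage weights must sum to at most 1")

    @property
    def leak_total(self) -> float:
        return float(sum(self.leakage.values()))


@dataclass
class GeneratorConfig:
    """Full study design: class sizes, latent separation, named observers."""

    n_pos: int = 18
    n_neg: int = 20
    separation: float = 1.8125
    observers: dict[str, ObserverProfile] = field(default_factory=dict)
    seed: int = 0
    categories: CategorySet = field(default_factory=CategorySet)

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be at least 1")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        for name, profile in self.observers.items():
            for code in profile.leakage:
                if code not in self.categories.codes or code in (
                    self.categories.positive,
                    self.categories.negative,
                ):
                    raise ValueError(
                        f"leakage category {code!r} of observer {name!r} is not "
                        "a non-CN/AD member of the category set"
                    )

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "separation": self.separation,
            "seed": self.seed,
            "observers": {
                name: {
                    "loading": p.loading,
                    "link_intercept": p.link_intercept,
                    "link_slope": p.link_slope,
                    "tie_propensity": p.tie_propensity,
                    "leakage": dict(p.leakage),
                    "rounding_decimals": p.rounding_decimals,
                }
                for name, p in self.observers.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping, seed: int | None = None) -> "GeneratorConfig":
        observers = {
            name: ObserverProfile(
                loading=spec["loading"],
                link_intercept=spec.get("link_intercept", 0.0),
                link_slope=spec.get("link_slope", 1.0),
                tie_propensity=spec.get("tie_propensity", 0.0),
                leakage=dict(spec.get("leakage", {})),
                rounding_decimals=spec.get("rounding_decimals", 3),
            )
            for name, spec in data["observers"].items()
        }
        return cls(
            n_pos=int(data.get("n_pos", 18)),
            n_neg=int(data.get("n_neg", 20)),
            separation=float(data.get("separation", 1.8125)),
            observers=observers,
            seed=int(seed if seed is not None else data.get("seed", 0)),
        )


def _observer_rng(seed: int, name: str) -> np.random.Generator:
    # keyed by a stable hash of the name so adding or reordering observers
    # never perturbs another observer's draws
    return np.random.default_rng(
        np.random.SeedSequence((seed & 0x7FFFFFFF, 1, zlib.crc32(name.encode())))
    )


def _observer_vectors(
    profile: ObserverProfile,
    latents: np.ndarray,
    cats: CategorySet,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(latents)
    lam = profile.loading
    perceived = lam * latents + np.sqrt(1 - lam**2) * rng.standard_normal(n)
    p_ad = expit(profile.link_intercept + profile.link_slope * perceived)
    residual = 1 - p_ad
    vectors = np.zeros((n, cats.n))
    vectors[:, cats.positive_index] = p_ad
    vectors[:, cats.negative_index] = residual * (1 - profile.leak_total)
    for code, weight in profile.leakage.items():
        vectors[:, cats.index(code)] = residual * weight
    tie_mask = rng.random(n) < profile.tie_propensity
    for i in np.flatnonzero(tie_mask):
        order = np.argsort(-vectors[i], kind="stable")
        top2 = order[:2]
        vectors[i, top2] = vectors[i, top2].mean()
    if profile.rounding_decimals is not None:
        rounded = np.round(vectors, profile.rounding_decimals)
        sums = rounded.sum(axis=1)
        ok = sums > 0
        vectors[ok] = rounded[ok]  # degenerate all-zero roundings keep raw values
    return vectors / vectors.sum(axis=1, keepdims=True)


def generate_study(config: GeneratorConfig) -> AssessmentTable:
    """Draw one complete synthetic study, fully reproducible from the seed."""
    if not config.observers:
        raise ValueError("config must define at least one observer")
    cats = config.categories
    n = config.n_pos + config.n_neg
    subject_rng = np.random.default_rng(
        np.random.SeedSequence((config.seed & 0x7FFFFFFF, 0))
    )
    latents = subject_rng.standard_normal(n)
    latents[: config.n_pos] += config.separation
    subjects = [f"sub-{i + 1:03d}" for i in range(n)]
    truth = [
        cats.positive if i < config.n_pos else cats.negative for i in range(n)
    ]
    probs = {
        name: _observer_vectors(
            profile, latents, cats, _observer_rng(config.seed, name)
        )
        for name, profile in config.observers.items()
    }
    return AssessmentTable.from_arrays(
        subjects, list(config.observers), truth, probs, cats
    )


def expected_auc(profile: ObserverProfile, d: float) -> float:
    """Population AUC of a tie-free observer: Phi(loading * d / sqrt(2)).

    Exact because AUC is invariant under the monotone logistic link; requires
    a strictly increasing link (positive slope).
    """
    if profile.link_slope <= 0:
        raise ValueError("expected_auc requires a monotone link (link_slope > 0)")
    if d < 0:
        raise ValueError("separation must be non-negative")
    return float(norm.cdf(profile.loading * d / np.sqrt(2)))


_PRESETS = {"paper_shaped": "paper_shaped.yaml"}


def load_preset(name: str, seed: int | None = None) -> GeneratorConfig:
    """Load a named preset shipped with the package."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    text = (
        resources.files("raterbench.presets").joinpath(_PRESETS[name]).read_text()
    )
    return GeneratorConfig.from_dict(yaml.safe_load(text), seed=seed)


def paper_shaped_config(seed: int | None = None) -> GeneratorConfig:
    """The documented 18 AD / 20 CN preset: one high-discrimination automated
    observer leaking residual mass predominantly to DLB, and two human readers
    with CN/AD-concentrated mass and nonzero exact-tie propensity."""
    return load_preset("paper_shaped", seed=seed)
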