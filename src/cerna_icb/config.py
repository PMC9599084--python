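"""Simulation configuration.

:class:`SimConfig` describes one synthetic cohort: group sizes, the
circRNA caller panel (with per-caller coordinate conventions and dropout),
negative-binomial expression parameters with planted two-group effects,
miRNA-interaction support, and an exponential survival model whose hazard
is tied to a planted expression signature.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence


class ConfigError(ValueError):
    """A configuration field violates its declared range."""


#: Per-caller coordinate conventions, expressed as the (start, end) shift
#: that converts the caller's reported coordinates into canonical 0-based
#: half-open.  CIRCexplorer2 emits BED (already canonical); the other four
#: callers report 1-based inclusive starts.
DEFAULT_CALLER_PROFILES: Mapping[str, tuple[int, int]] = {
    "CIRI": (-1, 0),
    "CIRCexplorer2": (0, 0),
    "DCC": (-1, 0),
    "STARchip": (-1, 0),
    "CIRIquant": (-1, 0),
}

#: Decoy tool-support distribution over 1..7 predicting tools: most
#: spurious miRNA-mRNA predictions are supported by very few tools.
DEFAULT_SUPPORT_DISTRIBUTION: tuple[float, ...] = (
    0.35, 0.25, 0.15, 0.10, 0.07, 0.05, 0.03,
)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the pilot-cohort conditions the analysis is designed
    for: 12 metastatic biopsies split 8 responders / 4 non-responders,
    five circRNA callers, and negative-binomial counts with a planted
    two-fold-per-log2-unit response effect.
    """

    n_responders: int = 8
    n_nonresponders: int = 4

    # circRNA caller panel
    n_circ_loci: int = 300
    n_callers: int = 5
    caller_detection_prob: float = 0.8
    caller_offset_profile: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CALLER_PROFILES)
    )

    # expression matrices
    n_lnc: int = 400
    n_mrna: int = 800
    n_mirna: int = 150
    de_fraction: float = 0.1
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    mean_expression: float = 100.0

    # miRNA interaction support
    n_pred_tools: int = 7
    support_distribution: Sequence[float] = DEFAULT_SUPPORT_DISTRIBUTION
    n_planted_triples: int = 20

    # survival
    baseline_hazard: float = 0.05  # events per month
    signature_hazard_beta: float = 1.0  # log-hazard per unit risk signal
    censor_rate: float = 0.2

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = (
            "n_responders", "n_nonresponders", "n_circ_loci", "n_callers",
            "n_lnc", "n_mrna", "n_mirna", "n_pred_tools",
        )
        for name in counts:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if self.n_planted_triples < 0:
            raise ConfigError(
                f"n_planted_triples must be >= 0, got {self.n_planted_triples!r}"
            )
        probs = ("caller_detection_prob", "de_fraction", "censor_rate")
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.nb_dispersion <= 0:
            raise ConfigError(
                f"nb_dispersion must be > 0, got {self.nb_dispersion!r}"
            )
        if self.mean_expression <= 0:
            raise ConfigError(
                f"mean_expression must be > 0, got {self.mean_expression!r}"
            )
        if self.baseline_hazard <= 0:
            raise ConfigError(
                f"baseline_hazard must be > 0, got {self.baseline_hazard!r}"
            )
        if len(self.caller_offset_profile) < self.n_callers:
            raise ConfigError(
                "caller_offset_profile must define at least n_callers "
                f"({self.n_callers}) callers, got "
                f"{len(self.caller_offset_profile)}"
            )
        dist = list(self.support_distribution)
        if len(dist) != self.n_pred_tools:
            raise ConfigError(
                "support_distribution must have n_pred_tools "
                f"({self.n_pred_tools}) entries, got {len(dist)}"
            )
        if any(p < 0 for p in dist) or abs(sum(dist) - 1.0) > 1e-6:
            raise ConfigError(
                "support_distribution must be a probability vector summing to 1"
            )

    @property
    def n_samples(self) -> int:
        return self.n_responders + self.n_nonresponders

    @property
    def callers(self) -> list[str]:
        return list(self.caller_offset_profile)[: self.n_callers]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["caller_offset_profile"] = {
            k: list(v) for k, v in self.caller_offset_profile.items()
        }
        d["support_distribution"] = list(self.support_distribution)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "caller_offset_profile" in d:
            d["caller_offset_profile"] = {
                k: tuple(v) for k, v in d["caller_offset_profile"].items()
            }
        if "support_distribution" in d:
            d["support_distribution"] = tuple(d["support_distribution"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d)
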