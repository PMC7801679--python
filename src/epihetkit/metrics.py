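"""Per-locus epigenetic heterogeneity metrics and the user-extensible registry.

Three built-in metrics summarize the epiallele distribution of a locus:

* ``pdr`` — proportion of discordant reads: the fraction of reads that are
  neither fully methylated nor fully unmethylated.
* ``epipolymorphism`` — probability that two epialleles sampled at random
  from the locus differ, ``1 - sum(p_i**2)`` (the Gini–Simpson index).
* ``shannon`` — Shannon entropy ``-sum(p_i log p_i)`` of the 16 pattern
  fractions, in bits by default.

Custom metrics are registered with :func:`register_metric` and are accepted
by every downstream stage that takes a metric name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np

from .epiallele import EmptyLocusError, EpialleleProfile, EpihetError, _plogp


class MetricRegistryError(EpihetError):
    """Unknown or duplicate metric name."""


def pdr(profile: EpialleleProfile) -> float:
    """Proportion of discordant reads, in [0, 1].

    A read is concordant iff all four CpGs agree (pattern code 0 or 15).
    """
    if profile.total == 0:
        raise EmptyLocusError(f"locus {profile.locus.id} has zero reads")
    concordant = int(profile.counts[0] + profile.counts[15])
    return (profile.total - concordant) / profile.total


def epipolymorphism(profile: EpialleleProfile) -> float:
    """Gini–Simpson diversity of the pattern distribution, in [0, 0.9375]."""
    p = profile.proportions()
    return float(1.0 - (p ** 2).sum())


def shannon_entropy(profile: EpialleleProfile, log_base: float = 2.0) -> float:
    """Shannon entropy of the pattern fractions; max 4 in base 2."""
    p = profile.proportions()
    return float(-_plogp(p, log_base).sum())


@dataclass(frozen=True)
class MetricDescriptor:
    name: str
    function: Callable[[EpialleleProfile], float]
    value_range: tuple[float, float]


_REGISTRY: Dict[str, MetricDescriptor] = {}


def register_metric(descriptor: MetricDescriptor, overwrite: bool = False) -> None:
    """Add a metric to the registry; names must be unique unless ``overwrite``."""
    if descriptor.name in _REGISTRY and not overwrite:
        raise MetricRegistryError(f"metric {descriptor.name!r} is already registered")
    _REGISTRY[descriptor.name] = descriptor


def unregister_metric(name: str) -> None:
    _REGISTRY.pop(name, None)


def available_metrics() -> list[str]:
    return sorted(_REGISTRY)


def get_metric(name: str) -> MetricDescriptor:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise MetricRegistryError(
            f"unknown metric {name!r}; available: {', '.join(available_metrics())}"
        ) from None


def evaluate_metric(name: str, profile: EpialleleProfile) -> float:
    """Evaluate a registered metric by name on one profile."""
    return get_metric(name).function(profile)


register_metric(MetricDescriptor("pdr", pdr, (0.0, 1.0)))
register_metric(MetricDescriptor("epipolymorphism", epipolymorphism, (0.0, 0.9375)))
register_metric(MetricDescriptor("shannon", shannon_entropy, (0.0, 4.0)))
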