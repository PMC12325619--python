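"""Simplified analytical-greenness scorers (AGREE and GAPI style).

AGREE condenses the twelve principles of Green Analytical Chemistry into
a single 0–1 score: each principle is scored in [0, 1] and the final
value is their weighted mean. GAPI instead keeps fifteen criteria —
grouped over sample handling, reagents and solvents, instrumentation,
waste management, and occupational safety — each labelled green, yellow
or red, and reports the colour distribution rather than one number.

These scorers reproduce the *mechanics* of the published metrics. The
example profiles shipped here are illustrative: the principle-level
inputs behind published scores of specific methods are generally not
disclosed, so no example claims to reproduce one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AgreeProfile",
    "GapiProfile",
    "GapiSummary",
    "agree_score",
    "gapi_summary",
    "GAPI_DOMAINS",
    "EXAMPLE_AGREE_DIRECT_UV",
    "EXAMPLE_AGREE_REFERENCE",
    "EXAMPLE_GAPI_DIRECT_UV",
]

_N_PRINCIPLES = 12
_N_CRITERIA = 15

#: Default grouping of the fifteen criteria into the five GAPI domains.
GAPI_DOMAINS: tuple[tuple[str, int], ...] = (
    ("sample handling", 3),
    ("reagents and solvents", 3),
    ("instrumentation", 3),
    ("waste management", 3),
    ("occupational safety", 3),
)

_GAPI_LABELS = ("green", "yellow", "red")


@dataclass
class AgreeProfile:
    """Twelve principle scores in [0, 1] with positive weights (default equal)."""

    principle_scores: list[float]
    weights: list[float] = field(default_factory=lambda: [1.0] * _N_PRINCIPLES)

    def __post_init__(self) -> None:
        if len(self.principle_scores) != _N_PRINCIPLES:
            raise ValueError(
                f"exactly {_N_PRINCIPLES} principle scores required, "
                f"got {len(self.principle_scores)}"
            )
        if any(not 0.0 <= s <= 1.0 for s in self.principle_scores):
            raise ValueError("principle scores must lie in [0, 1]")
        if len(self.weights) != _N_PRINCIPLES:
            raise ValueError(f"exactly {_N_PRINCIPLES} weights required")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")


def agree_score(p: AgreeProfile) -> float:
    """Weighted mean of the twelve principle scores (full precision).

    Round to two decimals for display; the raw value is returned.
    """
    scores = np.asarray(p.principle_scores, dtype=float)
    weights = np.asarray(p.weights, dtype=float)
    return float(np.average(scores, weights=weights))


@dataclass
class GapiProfile:
    """Fifteen green/yellow/red criterion labels over the five domains."""

    labels: list[str]
    domains: tuple[tuple[str, int], ...] = GAPI_DOMAINS

    def __post_init__(self) -> None:
        n = sum(size for _, size in self.domains)
        if n != _N_CRITERIA:
            raise ValueError(f"domain sizes must sum to {_N_CRITERIA}, got {n}")
        if len(self.labels) != _N_CRITERIA:
            raise ValueError(
                f"exactly {_N_CRITERIA} labels required, got {len(self.labels)}"
            )
        for lab in self.labels:
            if lab not in _GAPI_LABELS:
                raise ValueError(f"unknown GAPI label {lab!r}; use green/yellow/red")


@dataclass
class GapiSummary:
    """Colour counts, per-domain breakdown and a pictogram-ready structure."""

    counts: dict[str, int]
    per_domain: dict[str, dict[str, int]]
    pictogram: list[tuple[str, str]]  # (domain, label) per criterion, in order


def gapi_summary(p: GapiProfile) -> GapiSummary:
    """Summarise a GAPI profile; counts always sum to fifteen."""
    counts = {lab: 0 for lab in _GAPI_LABELS}
    per_domain: dict[str, dict[str, int]] = {}
    pictogram: list[tuple[str, str]] = []
    i = 0
    for domain, size in p.domains:
        sub = {lab: 0 for lab in _GAPI_LABELS}
        for _ in range(size):
            lab = p.labels[i]
            counts[lab] += 1
            sub[lab] += 1
            pictogram.append((domain, lab))
            i += 1
        per_domain[domain] = sub
    return GapiSummary(counts=counts, per_domain=per_domain, pictogram=pictogram)


# ---------------------------------------------------------------------------
# illustrative profiles (mechanics demonstration only)

#: A direct UV method in a benign solvent: favourable on reagent, energy
#: and waste principles; weaker on throughput/automation.
EXAMPLE_AGREE_DIRECT_UV = AgreeProfile(
    principle_scores=[0.8, 0.9, 0.75, 0.9, 0.7, 0.85, 0.9, 0.75, 0.8, 0.85, 0.9, 0.7]
)

#: A wet-chemistry-heavy reference workflow for comparison.
EXAMPLE_AGREE_REFERENCE = AgreeProfile(
    principle_scores=[0.6, 0.7, 0.55, 0.7, 0.6, 0.65, 0.8, 0.6, 0.65, 0.7, 0.75, 0.6]
)

EXAMPLE_GAPI_DIRECT_UV = GapiProfile(
    labels=[
        "green", "green", "yellow",   # sample handling
        "green", "yellow", "green",   # reagents and solvents
        "green", "green", "yellow",   # instrumentation
        "yellow", "green", "green",   # waste management
        "green", "green", "green",    # occupational safety
    ]
)
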