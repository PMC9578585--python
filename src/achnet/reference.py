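"""Published design of the seven-site Iowa ACH coalition study.

The package's synthetic generator emulates the seven Accountable
Communities of Health (ACH) sites established across Iowa under a State
Innovation Model grant: per-site roster sizes, organizational response
rates, steering-committee sizes, and the reported counts of preexisting,
grant-stimulated, and likely-sustained collaborations. These published
site characteristics are the default study conditions for
:class:`achnet.synth.SynthConfig` and the inputs to the arithmetic
consistency checks in the acceptance script.
"""

from __future__ import annotations

from math import comb
from typing import Dict, List

__all__ = [
    "SITE_IDS",
    "SITE_SIZES",
    "RESPONSE_RATES",
    "STEERING_COUNTS",
    "PREEXISTING_EDGES",
    "STIMULATED_EDGES",
    "SUSTAINED_EDGES",
    "responder_counts",
    "possible_dyads",
    "missing_dyad_pct",
]

SITE_IDS = ("A", "B", "C", "D", "E", "F", "G")

#: Organizations on each site's roster (sums to 169 across the coalition).
SITE_SIZES = (28, 23, 36, 11, 29, 16, 26)

#: Fraction of each site's organizations that completed the survey.
RESPONSE_RATES = (0.536, 0.435, 0.389, 0.455, 0.379, 0.438, 0.577)

#: Steering-committee members per site.
STEERING_COUNTS = (6, 4, 9, 2, 4, 2, 10)

#: Reported edge counts per site, by layer.
PREEXISTING_EDGES = (49, 56, 81, 10, 54, 41, 55)
STIMULATED_EDGES = (29, 33, 53, 4, 3, 6, 19)
SUSTAINED_EDGES = (55, 32, 91, 10, 42, 32, 49)


def responder_counts() -> List[int]:
    """Number of responding organizations per site implied by the response
    rates (nearest integer of rate x roster size)."""
    return [round(r * n) for r, n in zip(RESPONSE_RATES, SITE_SIZES)]


def possible_dyads(n: int) -> int:
    """Unordered pairs among ``n`` organizations: n(n-1)/2."""
    return comb(n, 2)


def missing_dyad_pct(n: int, n_responders: int) -> float:
    """Percentage of dyads with neither endpoint responding,
    ``C(n - responders, 2) / C(n, 2)`` x 100."""
    return 100.0 * comb(n - n_responders, 2) / comb(n, 2)
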