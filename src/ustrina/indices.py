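"""Weight-ratio indices for commingled cremated bone.

Two indices summarise a cremation deposit:

* the **fragmentation index** — weight of fragments < 20 mm over weight of
  fragments > 20 mm, times 100; the higher the value the more fragmented
  the assemblage;
* the **CPC (cranial/post-cranial) index** — cranial weight over
  post-cranial weight, times 100; departures from the anatomical
  expectation flag post-cremation selection or displacement of remains.

Both are reported together with their numerator and denominator in grams
and a ``defined`` flag: a zero denominator yields a flagged undefined
result rather than an exception, so per-square maps over sparse grids do
not abort.  Values are kept at full precision internally; rounding
(half away from zero, 1 decimal) is presentation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .deposit import Deposit


class IndexDomainError(ValueError):
    """Negative weight passed to a weight-ratio index."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (as printed in reports), not banker's rounding."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class IndexResult:
    """A weight-ratio index: ``value = numerator / denominator * 100``."""

    value: float
    numerator: float
    denominator: float
    defined: bool

    def rounded(self, ndigits: int = 1) -> float:
        if not self.defined:
            return float("nan")
        return round_half_up(self.value, ndigits)

    def as_dict(self) -> dict:
        return {
            "value": self.value if self.defined else None,
            "numerator_g": self.numerator,
            "denominator_g": self.denominator,
            "defined": self.defined,
        }


def _ratio_index(numerator: float, denominator: float) -> IndexResult:
    if numerator < 0 or denominator < 0:
        raise IndexDomainError(
            f"weights must be non-negative, got ({numerator}, {denominator})"
        )
    if denominator == 0:
        return IndexResult(float("nan"), numerator, denominator, defined=False)
    return IndexResult(numerator / denominator * 100.0, numerator, denominator, defined=True)


def fragmentation_index(w_lt20: float, w_ge20: float) -> IndexResult:
    """Fragmentation index: ``w_lt20 / w_ge20 * 100``.

    Undefined (flagged, not raised) when there is no > 20 mm weight.
    """
    return _ratio_index(w_lt20, w_ge20)


def cpc_index(w_cranial: float, w_postcranial: float) -> IndexResult:
    """Cranial/post-cranial index: ``w_cranial / w_postcranial * 100``."""
    return _ratio_index(w_cranial, w_postcranial)


def cranial_share(w_cranial: float, w_postcranial: float) -> float:
    """Cranial weight as a percentage of the identified > 20 mm weight."""
    if w_cranial < 0 or w_postcranial < 0:
        raise IndexDomainError("weights must be non-negative")
    total = w_cranial + w_postcranial
    if total == 0:
        raise IndexDomainError("cranial share undefined: no identified weight")
    return w_cranial / total * 100.0


def composition_shares(deposit: Deposit) -> dict[str, float]:
    """Percent of total deposit weight per size class (lt20, ge20, tooth).

    The three shares sum to 100 up to floating-point rounding.
    """
    total = deposit.total_weight()
    if total <= 0:
        raise IndexDomainError("composition shares undefined for an empty deposit")
    return {
        sc: deposit.total_weight(size_class=sc) / total * 100.0
        for sc in ("lt20", "ge20", "tooth")
    }


def deposit_fragmentation_index(deposit: Deposit, **filters) -> IndexResult:
    """Pooled fragmentation index of a (filtered) deposit.

    Pooled means the ratio of summed weights, not a mean of per-square
    ratios; see :func:`ustrina.spatial.region_fragmentation` for the
    per-square-mean variant.
    """
    return fragmentation_index(
        deposit.total_weight(size_class="lt20", **filters),
        deposit.total_weight(size_class="ge20", **filters),
    )


def deposit_cpc_index(deposit: Deposit, **filters) -> IndexResult:
    """Pooled cranial/post-cranial index of a (filtered) deposit."""
    return cpc_index(
        deposit.total_weight(region="cranial", **filters),
        deposit.total_weight(region="postcranial", **filters),
    )
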