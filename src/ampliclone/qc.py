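"""Per-well coverage QC: the pooling-uniformity rule.

Pooling the barcoded PCR products without per-well normalization is
justified when sequencing depth stays reasonably even across wells.  The
rule used here flags wells whose depth falls outside the closed interval
[mean/5, 5 x mean], the mean taken over wells that received at least one
read (empty wells reflect failed clones, not pooling skew, and are reported
separately).  The rule is scale-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

LOWER_FACTOR = 5.0  # lower bound = mean / 5, upper = 5 x mean


@dataclass(frozen=True)
class CoverageReport:
    per_well_depth: dict
    mean_depth: float
    min_depth: int
    max_depth: int
    uniform_fraction: float
    flagged_wells: tuple[str, ...]
    empty_wells: tuple[str, ...]

    @property
    def lower_bound(self) -> float:
        return self.mean_depth / LOWER_FACTOR

    @property
    def upper_bound(self) -> float:
        return self.mean_depth * LOWER_FACTOR


def coverage_qc(per_well_depth: Mapping[str, int]) -> CoverageReport:
    """Compute depth statistics and flag wells outside [mean/5, 5 x mean].

    uniform_fraction is the fraction of covered wells inside the (closed)
    bounds.  Raises when every well is empty.
    """
    covered = {w: int(d) for w, d in per_well_depth.items() if d > 0}
    empty = tuple(sorted(w for w, d in per_well_depth.items() if d <= 0))
    if not covered:
        raise ValueError("no data: every well has zero reads")
    depths = list(covered.values())
    mean = sum(depths) / len(depths)
    lo, hi = mean / LOWER_FACTOR, mean * LOWER_FACTOR
    flagged = tuple(sorted(w for w, d in covered.items() if not lo <= d <= hi))
    return CoverageReport(
        per_well_depth=dict(per_well_depth),
        mean_depth=mean,
        min_depth=min(depths),
        max_depth=max(depths),
        uniform_fraction=1.0 - len(flagged) / len(covered),
        flagged_wells=flagged,
        empty_wells=empty,
    )
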