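"""Evaluation criteria for contamination-removal experiments.

Given truth tags and an observed (mapped or filtered) read set, compute:

- **CRT** — contamination rate after treatment: contaminant reads remaining
  divided by all reads remaining;
- **LRE** — loss rate of endogenous DNA: endogenous reads lost by the step
  divided by endogenous reads entering it;
- **removal fraction** — contaminant reads removed divided by contaminant
  reads entering.

All three are pure count ratios, so a report is exactly recomputable from
its counts.  Runtime (the MT criterion) is carried as an informational
field only — it is hardware-dependent and never part of a comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from paleosift.ancfil import FilterStats
from paleosift.io_bridge import AlignmentRecord, ReadTag
from paleosift.simulator import TruthSet

__all__ = [
    "MetricsReport",
    "crt",
    "evaluate_run",
    "lre",
    "removal_fraction",
]

#: A mapping hit counts as valid only at or above this mapping quality.
VALID_MAPQ = 30


def crt(cont_after: int, total_after: int) -> float:
    """Contamination rate after treatment: cont_after / total_after.

    An empty after-set makes the ratio undefined: returns NaN with a warning.
    """
    if cont_after < 0 or total_after < 0:
        raise ValueError("counts must be non-negative")
    if cont_after > total_after:
        raise ValueError("cont_after exceeds total_after")
    if total_after == 0:
        warnings.warn("CRT undefined: no reads after treatment", stacklevel=2)
        return math.nan
    return cont_after / total_after


def lre(endo_before: int, endo_after: int) -> float:
    """Loss rate of endogenous DNA: (endo_before - endo_after) / endo_before."""
    if endo_after < 0 or endo_before < endo_after:
        raise ValueError("need endo_before >= endo_after >= 0")
    if endo_before == 0:
        raise ValueError("no endogenous reads in truth")
    return (endo_before - endo_after) / endo_before


def removal_fraction(cont_before: int, cont_after: int) -> float:
    """Fraction of contaminant reads removed: (before - after) / before."""
    if cont_after < 0 or cont_before < cont_after:
        raise ValueError("need cont_before >= cont_after >= 0")
    if cont_before == 0:
        raise ValueError("no contaminant reads in truth")
    return (cont_before - cont_after) / cont_before


@dataclass
class MetricsReport:
    """CRT/LRE/removal counts and ratios for one mapping or filtering run."""

    stage: str  # "mapping" | "filtering"
    endo_before: int
    cont_before: int
    endo_after: int
    cont_after: int
    unknown_after: int = 0
    crt: float = math.nan
    lre: float = math.nan
    removal_fraction: float = math.nan
    runtime_seconds: float | None = None

    @classmethod
    def from_counts(
        cls,
        stage: str,
        endo_before: int,
        cont_before: int,
        endo_after: int,
        cont_after: int,
        unknown_after: int = 0,
        runtime_seconds: float | None = None,
    ) -> "MetricsReport":
        report = cls(
            stage=stage,
            endo_before=endo_before,
            cont_before=cont_before,
            endo_after=endo_after,
            cont_after=cont_after,
            unknown_after=unknown_after,
            runtime_seconds=runtime_seconds,
        )
        report.crt = crt(cont_after, endo_after + cont_after)
        report.lre = lre(endo_before, endo_after)
        if cont_before > 0:
            report.removal_fraction = removal_fraction(cont_before, cont_after)
        return report

    def to_tsv_row(self, header: bool = True) -> str:
        cols = (
            "stage endo_before cont_before endo_after cont_after "
            "crt lre removal_fraction runtime_seconds"
        ).split()
        vals = [
            self.stage,
            str(self.endo_before),
            str(self.cont_before),
            str(self.endo_after),
            str(self.cont_after),
            f"{self.crt:.10g}",
            f"{self.lre:.10g}",
            f"{self.removal_fraction:.10g}",
            "" if self.runtime_seconds is None else f"{self.runtime_seconds:.3f}",
        ]
        row = "\t".join(vals)
        return "\t".join(cols) + "\n" + row if header else row

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv_row() + "\n")


def evaluate_run(
    truth: TruthSet | Sequence,
    observed: Iterable[AlignmentRecord],
    stage: str = "filtering",
    runtime_seconds: float | None = None,
) -> MetricsReport:
    """Tally tagged counts before/after a step and derive CRT/LRE/removal.

    ``truth`` may be a :class:`TruthSet` or any sequence of tagged reads /
    alignment records.  At the mapping stage only records that are mapped
    with MAPQ ≥ 30 count as valid hits; at the filtering stage every
    observed record counts.  Observed reads with unknown tags are tallied
    separately with a warning and excluded from CRT.
    """
    if stage not in ("mapping", "filtering"):
        raise ValueError(f"unknown stage {stage!r}")
    truth_items = truth.reads if isinstance(truth, TruthSet) else truth
    before: dict[ReadTag, int] = {}
    for item in truth_items:
        tag = item.read.tag if isinstance(item, AlignmentRecord) else item.tag
        before[tag] = before.get(tag, 0) + 1

    after: dict[ReadTag, int] = {}
    for rec in observed:
        if stage == "mapping" and not (rec.is_mapped and rec.mapq >= VALID_MAPQ):
            continue
        after[rec.read.tag] = after.get(rec.read.tag, 0) + 1
    unknown = after.get(ReadTag.unknown, 0)
    if unknown:
        warnings.warn(
            f"{unknown} observed reads carry no endo/cont tag; "
            "excluded from CRT/LRE",
            stacklevel=2,
        )
    return MetricsReport.from_counts(
        stage=stage,
        endo_before=before.get(ReadTag.endo, 0),
        cont_before=before.get(ReadTag.cont, 0),
        endo_after=after.get(ReadTag.endo, 0),
        cont_after=after.get(ReadTag.cont, 0),
        unknown_after=unknown,
        runtime_seconds=runtime_seconds,
    )
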