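"""Summary statistics and two-ensemble comparison of descriptor series.

The quantitative core of the apo-versus-metal comparison: each descriptor
series is reduced to mean ± SD plus order statistics, and two labelled
ensembles are compared by difference of means, ratio of SDs, and a
Tukey-fence overlap fraction (the fraction of one ensemble's values inside
the other's [q1 − 1.5·IQR, q3 + 1.5·IQR] box-whisker span) — a concrete
stand-in for the qualitative "the distributions occasionally overlap".
Quartiles use the linear-interpolation convention; SDs are sample SDs
(n − 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .descriptors import DescriptorSeries
from .errors import InsufficientDataError, UnitError

__all__ = ["EnsembleSummary", "ComparisonReport", "summarize", "compare"]


@dataclass
class EnsembleSummary:
    descriptor: str
    units: str
    n: int
    mean: float
    sd: float
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonReport:
    descriptor: str
    units: str
    label_a: str
    label_b: str
    summary_a: EnsembleSummary
    summary_b: EnsembleSummary
    difference_of_means: float  # mean(a) − mean(b)
    sd_ratio: float  # sd(a) / sd(b)
    overlap_a_in_b: float  # fraction of a's values inside b's Tukey fences
    overlap_b_in_a: float

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        a, b = self.summary_a, self.summary_b
        lines = [
            f"descriptor: {self.descriptor} [{self.units}]",
            f"{'':>12} {'n':>6} {'mean':>10} {'sd':>8} {'q1':>8} "
            f"{'median':>8} {'q3':>8}",
        ]
        for label, s in ((self.label_a, a), (self.label_b, b)):
            lines.append(
                f"{label:>12} {s.n:>6d} {s.mean:>10.3f} {s.sd:>8.3f} "
                f"{s.q1:>8.3f} {s.median:>8.3f} {s.q3:>8.3f}"
            )
        lines.append(
            f"difference of means ({self.label_a} − {self.label_b}): "
            f"{self.difference_of_means:.3f} {self.units}"
        )
        lines.append(f"SD ratio: {self.sd_ratio:.3f}")
        lines.append(
            f"overlap: {self.overlap_a_in_b:.3f} of {self.label_a} inside "
            f"{self.label_b}'s fences; {self.overlap_b_in_a:.3f} conversely"
        )
        return "\n".join(lines)


def summarize(series: DescriptorSeries) -> EnsembleSummary:
    """Mean, sample SD and quartiles of one descriptor series."""
    v = np.asarray(series.values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("summary needs at least 2 values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return EnsembleSummary(
        descriptor=series.name,
        units=series.units,
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        min=float(v.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(v.max()),
    )


def _tukey_fences(s: EnsembleSummary) -> tuple[float, float]:
    iqr = s.q3 - s.q1
    return s.q1 - 1.5 * iqr, s.q3 + 1.5 * iqr


def compare(
    label_a: str,
    series_a: DescriptorSeries,
    label_b: str,
    series_b: DescriptorSeries,
) -> ComparisonReport:
    """Compare two labelled ensembles of the same descriptor."""
    if series_a.name != series_b.name or series_a.units != series_b.units:
        raise UnitError(
            f"cannot compare {series_a.name}[{series_a.units}] with "
            f"{series_b.name}[{series_b.units}]"
        )
    sa = summarize(series_a)
    sb = summarize(series_b)
    lo_b, hi_b = _tukey_fences(sb)
    lo_a, hi_a = _tukey_fences(sa)
    va = np.asarray(series_a.values, dtype=float)
    vb = np.asarray(series_b.values, dtype=float)
    return ComparisonReport(
        descriptor=sa.descriptor,
        units=sa.units,
        label_a=label_a,
        label_b=label_b,
        summary_a=sa,
        summary_b=sb,
        difference_of_means=sa.mean - sb.mean,
        sd_ratio=sa.sd / sb.sd if sb.sd > 0 else float("inf"),
        overlap_a_in_b=float(np.mean((va >= lo_b) & (va <= hi_b))),
        overlap_b_in_a=float(np.mean((vb >= lo_a) & (vb <= hi_a))),
    )
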