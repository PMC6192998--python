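"""Dual-luciferase reporter-assay ratio statistics.

A candidate regulatory site is cloned into the 3'UTR of a Renilla
luciferase reporter alongside a site-mutant counterpart; Renilla signal is
normalized to a co-transfected firefly control.  The site's regulatory
activity is the ratio of normalized wildtype to mutant activity (WT/mut);
a ratio below 1 indicates a repressive site.  Technical replicates with a
coefficient of variation above 50% are omitted.  WT-vs-mutant comparisons
within a cell condition use a two-tailed paired t-test across biological
replicates; WT/mut ratios are compared between cell conditions by a
two-tailed Welch's t-test.  Tests run on log-transformed ratios by default
(ratios are multiplicative); the raw scale is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from clipcoreg.core import ClipCoregError, ValidationError

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ReporterMeasurement:
    """Technical-replicate normalized luminescence for one transfection.

    ``values`` are renilla / firefly ratios, one per technical replicate.
    """

    construct: str  # "WT" or "mut"
    condition: str  # cell background, e.g. "WT", "DICER_KO", "PDKO"
    bio_rep: int
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValidationError(
                "a measurement needs >= 2 technical replicates"
            )
        if any(v <= 0 for v in self.values):
            raise ValidationError("normalized luminescence must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def cv(self) -> float:
        """Coefficient of variation (sample SD over mean)."""
        return float(np.std(self.values, ddof=1) / np.mean(self.values))


@dataclass
class ReporterResult:
    """Per-condition WT/mut ratios and the associated tests."""

    condition_ratios: dict[str, list[float]]  # condition -> per-bio-rep ratio
    paired_t: dict[str, tuple[float, float]]  # condition -> (t, p)
    welch_t: dict[tuple[str, str], tuple[float, float]]
    omitted: list[tuple[str, str, int]]  # (construct, condition, bio_rep)
    degenerate: set[str] = field(default_factory=set)
    alpha: float = SIGNIFICANCE_LEVEL

    def significant(self, condition: str) -> bool:
        return self.paired_t[condition][1] < self.alpha


def cv_filter(
    measurement: ReporterMeasurement, threshold: float = 0.5
) -> bool:
    """Keep (True) unless technical CV strictly exceeds the threshold."""
    mean = measurement.mean
    if mean <= 0:
        raise ValidationError("non-positive mean luminescence")
    return measurement.cv <= threshold


def wtmut_ratio(wt: ReporterMeasurement, mut: ReporterMeasurement) -> float:
    """WT over mutant activity for one paired biological replicate."""
    if (wt.bio_rep, wt.condition) != (mut.bio_rep, mut.condition):
        raise ValidationError(
            "WT and mutant measurements must come from the same biological "
            "replicate and condition"
        )
    return wt.mean / mut.mean


def _paired_t_log(
    wt_means: Sequence[float], mut_means: Sequence[float], log: bool
) -> tuple[float, float, bool]:
    """Two-tailed paired t; returns (t, p, degenerate).

    All-zero differences have zero variance; the test is undefined and
    p = 1 is reported by convention with the degenerate flag set.
    """
    wt = np.asarray(wt_means, dtype=float)
    mut = np.asarray(mut_means, dtype=float)
    diffs = np.log2(wt) - np.log2(mut) if log else wt - mut
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0, True
    if np.allclose(diffs, diffs.mean()):
        # constant nonzero differences: zero variance, limiting t
        return math.copysign(math.inf, diffs.mean()), 0.0, True
    t, p = stats.ttest_rel(
        np.log2(wt) if log else wt, np.log2(mut) if log else mut
    )
    return float(t), float(p), False


def reporter_tests(
    measurements: Sequence[ReporterMeasurement],
    condition_pairs: Sequence[tuple[str, str]] = (),
    cv_threshold: float = 0.5,
    log_scale: bool = True,
) -> ReporterResult:
    """Full reporter analysis for one construct pair across conditions.

    Measurements failing the CV filter are omitted together with their
    paired counterpart (a ratio needs both sides).  Each condition needs
    >= 3 surviving biological replicates.  Within each condition, WT vs
    mutant is a two-tailed paired t-test; for each requested condition
    pair, WT/mut ratios are compared by two-tailed Welch's t-test.
    """
    omitted: list[tuple[str, str, int]] = []
    by_key: dict[tuple[str, int], dict[str, ReporterMeasurement]] = {}
    for m in measurements:
        if not cv_filter(m, cv_threshold):
            omitted.append((m.construct, m.condition, m.bio_rep))
            continue
        slot = by_key.setdefault((m.condition, m.bio_rep), {})
        if m.construct in slot:
            raise ValidationError(
                f"duplicate measurement for {m.construct}/{m.condition}/"
                f"rep{m.bio_rep}"
            )
        slot[m.construct] = m

    conditions: dict[str, list[tuple[ReporterMeasurement, ReporterMeasurement]]]
    conditions = {}
    for (cond, _rep), pair in sorted(by_key.items()):
        if "WT" in pair and "mut" in pair:
            conditions.setdefault(cond, []).append((pair["WT"], pair["mut"]))

    condition_ratios: dict[str, list[float]] = {}
    paired: dict[str, tuple[float, float]] = {}
    degenerate: set[str] = set()
    for cond, pairs in conditions.items():
        if len(pairs) < 3:
            raise ValidationError(
                f"condition {cond!r}: need >= 3 paired biological "
                f"replicates after CV filtering, got {len(pairs)}"
            )
        condition_ratios[cond] = [wtmut_ratio(w, m) for w, m in pairs]
        t, p, degen = _paired_t_log(
            [w.mean for w, _ in pairs],
            [m.mean for _, m in pairs],
            log=log_scale,
        )
        paired[cond] = (t, p)
        if degen:
            degenerate.add(cond)

    welch: dict[tuple[str, str], tuple[float, float]] = {}
    for ca, cb in condition_pairs:
        ra = np.asarray(condition_ratios[ca], dtype=float)
        rb = np.asarray(condition_ratios[cb], dtype=float)
        if log_scale:
            ra, rb = np.log2(ra), np.log2(rb)
        if np.allclose(ra, ra.mean()) and np.allclose(rb, rb.mean()) and np.isclose(ra.mean(), rb.mean()):
            welch[(ca, cb)] = (0.0, 1.0)
            degenerate.add(f"{ca}~{cb}")
            continue
        t, p = stats.ttest_ind(ra, rb, equal_var=False)
        welch[(ca, cb)] = (float(t), float(p))

    return ReporterResult(
        condition_ratios=condition_ratios,
        paired_t=paired,
        welch_t=welch,
        omitted=omitted,
        degenerate=degenerate,
    )


def read_reporter_table(path: str | Path) -> list[ReporterMeasurement]:
    """Read a tab-delimited reporter table.

    Columns (with header): construct, condition, bio_rep, tech_rep,
    renilla, firefly.  Technical replicates of one transfection are
    grouped into one :class:`ReporterMeasurement` with values
    renilla / firefly.
    """
    path = Path(path)
    grouped: dict[tuple[str, str, int], list[tuple[int, float]]] = {}
    with open(path) as fh:
        header: dict[str, int] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = {c: i for i, c in enumerate(fields)}
                missing = {
                    "construct", "condition", "bio_rep", "tech_rep",
                    "renilla", "firefly",
                } - set(header)
                if missing:
                    raise ClipCoregError(
                        f"{path}: header lacks columns {sorted(missing)}"
                    )
                continue
            key = (
                fields[header["construct"]],
                fields[header["condition"]],
                int(fields[header["bio_rep"]]),
            )
            renilla = float(fields[header["renilla"]])
            firefly = float(fields[header["firefly"]])
            if firefly <= 0:
                raise ValidationError(
                    f"{path}:{lineno}: non-positive firefly signal"
                )
            grouped.setdefault(key, []).append(
                (int(fields[header["tech_rep"]]), renilla / firefly)
            )
    out = []
    for (construct, condition, bio_rep), vals in sorted(grouped.items()):
        vals.sort()
        out.append(
            ReporterMeasurement(
                construct=construct,
                condition=condition,
                bio_rep=bio_rep,
                values=tuple(v for _, v in vals),
            )
        )
    return out
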