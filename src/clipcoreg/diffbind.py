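"""mRNA-normalized differential CLIP binding and transcript-class tests.

A site's CLIP signal under a condition is its counts-per-million, averaged
across the condition's replicates.  The raw log2 fold change between a
control and a perturbed condition confounds two effects: a change in the
protein's binding per transcript and a change in the transcript's
abundance.  Subtracting the transcript-level mRNA log2 fold change (an
external measurement supplied as an input table) isolates the binding
effect:

    normalized_lfc = log2((signal_perturbed + c) / (signal_control + c))
                     - mrna_lfc

Per-UTR extreme-site statistics (the minimal and maximal normalized LFC
among a UTR's sites) target the sites most likely to participate in an
interaction, since only a minority of sites on a bound UTR are expected to
couple to the perturbed partner.  Transcript classes (e.g. co-bound vs
bound by one protein alone) are compared by two-sample Kolmogorov-Smirnov
tests on these per-UTR statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from clipcoreg.core import (
    BindingSite,
    ClipCoregError,
    HostFeature,
    SampleDesign,
    ValidationError,
)
from clipcoreg.cooccupancy import overlap_sites
from clipcoreg.motifs import SeedMatch, family_tallies

logger = logging.getLogger(__name__)


@dataclass
class SiteLFC:
    """Raw and mRNA-normalized log2 fold change for one site."""

    site_id: str
    feature_id: str
    raw_lfc: float
    mrna_lfc: float
    normalized_lfc: float
    conditions: tuple[str, str]  # (control, perturbed)


@dataclass
class UtrExtremes:
    """Extreme normalized LFCs among one UTR's sites."""

    feature_id: str
    min_lfc: float
    max_lfc: float
    n_sites: int


@dataclass
class ClassComparison:
    """Two-sample KS comparison between transcript (or site) classes.

    ``ecdf_support`` maps each class label to the sorted sample values, from
    which the empirical CDF is a step function rising 1/n at each value.
    """

    class_labels: tuple[str, str]
    n: tuple[int, int]
    statistic: float  # KS D, sup-norm distance between the two ECDFs
    p_value: float
    ecdf_support: dict[str, np.ndarray]


def site_signal(
    site: BindingSite, design: SampleDesign, condition: str
) -> float:
    """Mean counts-per-million for a site across a condition's replicates."""
    samples = design.samples_for(condition)
    cpms = []
    for sample in samples:
        if sample not in site.counts:
            raise ValidationError(
                f"site {site.site_id}: no counts for sample {sample!r}"
            )
        cpms.append(site.counts[sample] / design.library_size[sample] * 1e6)
    return float(np.mean(cpms))


def compute_lfc(
    site: BindingSite,
    design: SampleDesign,
    control: str,
    perturbed: str,
    pseudocount: float = 1.0,
) -> float:
    """Raw log2 fold change of CLIP signal, perturbed over control.

    A pseudocount (in CPM, default 1) stabilizes the ratio at low signal.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    sig_c = site_signal(site, design, control)
    sig_p = site_signal(site, design, perturbed)
    return math.log2((sig_p + pseudocount) / (sig_c + pseudocount))


def normalize_lfc(
    raw_lfc: float,
    site: BindingSite,
    feature: HostFeature,
    condition: str,
    conditions: tuple[str, str] = ("control", "perturbed"),
) -> SiteLFC:
    """Subtract the transcript-level mRNA LFC from a site's raw LFC.

    Raises KeyError when the feature carries no mRNA measurement for the
    condition; callers batch-processing sites should exclude such sites and
    report them (see :func:`site_lfc_table`).
    """
    if condition not in feature.mrna_lfc:
        raise KeyError(
            f"feature {feature.feature_id} has no mRNA LFC for {condition!r}"
        )
    mrna = feature.mrna_lfc[condition]
    return SiteLFC(
        site_id=site.site_id,
        feature_id=site.feature_id,
        raw_lfc=raw_lfc,
        mrna_lfc=mrna,
        normalized_lfc=raw_lfc - mrna,
        conditions=conditions,
    )


def site_lfc_table(
    sites: Sequence[BindingSite],
    features: Mapping[str, HostFeature],
    design: SampleDesign,
    control: str,
    perturbed: str,
    mrna_condition: str | None = None,
    pseudocount: float = 1.0,
) -> tuple[list[SiteLFC], list[str]]:
    """Per-site normalized LFCs for a whole site set.

    Sites on transcripts lacking an mRNA measurement are excluded, not
    silently: their ids are returned (and logged) as the second element.
    ``mrna_condition`` names the column of the mRNA LFC table to subtract;
    it defaults to the perturbed condition label.
    """
    cond = mrna_condition if mrna_condition is not None else perturbed
    out: list[SiteLFC] = []
    excluded: list[str] = []
    for site in sites:
        feature = features[site.feature_id]
        raw = compute_lfc(site, design, control, perturbed, pseudocount)
        try:
            out.append(
                normalize_lfc(
                    raw, site, feature, cond, conditions=(control, perturbed)
                )
            )
        except KeyError:
            excluded.append(site.site_id)
    if excluded:
        logger.info(
            "excluded %d/%d sites lacking an mRNA LFC for %r",
            len(excluded), len(sites), cond,
        )
    return out, excluded


def utr_extremes(site_lfcs: Iterable[SiteLFC]) -> list[UtrExtremes]:
    """Exact min and max normalized LFC among each UTR's sites."""
    by_feature: dict[str, list[float]] = {}
    for s in site_lfcs:
        by_feature.setdefault(s.feature_id, []).append(s.normalized_lfc)
    return [
        UtrExtremes(
            feature_id=fid,
            min_lfc=min(vals),
            max_lfc=max(vals),
            n_sites=len(vals),
        )
        for fid, vals in by_feature.items()
    ]


def ks_class_compare(
    values_by_class: Mapping[str, Sequence[float]],
    class_a: str,
    class_b: str,
) -> ClassComparison:
    """Two-sided two-sample Kolmogorov-Smirnov test between two classes.

    Uses the asymptotic p-value; D is the sup-norm distance between the
    empirical CDFs.  The sorted samples are returned for ECDF plotting.
    """
    a = np.asarray(values_by_class[class_a], dtype=float)
    b = np.asarray(values_by_class[class_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"KS comparison needs >= 2 values per class, got "
            f"{len(a)} ({class_a!r}) and {len(b)} ({class_b!r})"
        )
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return ClassComparison(
        class_labels=(class_a, class_b),
        n=(len(a), len(b)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        ecdf_support={class_a: np.sort(a), class_b: np.sort(b)},
    )


def stratify_sites_by_overlap(
    sites_a: Sequence[BindingSite], sites_b: Sequence[BindingSite]
) -> dict[str, bool]:
    """Label each a-site by whether it overlaps any b-site.

    Returns site_id -> True (overlapping) / False; the partition is
    exhaustive and exclusive over ``sites_a``.
    """
    pairs, _, _ = overlap_sites(sites_a, sites_b)
    overlapping = {sa.site_id for sa, _ in pairs}
    return {s.site_id: s.site_id in overlapping for s in sites_a}


def seed_repertoire_correlation(
    sites_group1: Sequence[BindingSite],
    sites_group2: Sequence[BindingSite],
    seed_matches: Iterable[SeedMatch],
    window: int = 0,
) -> float | None:
    """Spearman correlation of per-family seed tallies between site groups.

    Tallies seed-complement occurrences per miRNA family within each site
    group, then rank-correlates the two tally vectors over the union of
    families (average ranks on ties).  Returns None when either vector is
    constant (the correlation is undefined) and raises on fewer than three
    families with any occurrences.
    """
    matches = list(seed_matches)
    t1 = family_tallies(sites_group1, matches, window)
    t2 = family_tallies(sites_group2, matches, window)
    families = sorted(set(t1) | set(t2))
    families = [f for f in families if t1.get(f, 0) + t2.get(f, 0) > 0]
    if len(families) < 3:
        raise ValidationError(
            "repertoire comparison needs >= 3 miRNA families with nonzero "
            f"tallies, got {len(families)}"
        )
    v1 = np.array([t1.get(f, 0) for f in families], dtype=float)
    v2 = np.array([t2.get(f, 0) for f in families], dtype=float)
    if np.all(v1 == v1[0]) or np.all(v2 == v2[0]):
        return None
    rho, _ = stats.spearmanr(v1, v2)
    return float(rho)
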