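"""Site- and transcript-level co-occupancy statistics.

Implements the within-UTR randomization null: each site is independently
repositioned uniformly among all valid starts on its own host feature,
preserving its width, and the statistic of interest (overlap count,
positional density) is recomputed over many such randomizations to yield
a permutation mean, SD, z-score, or envelope.  Shuffling never leaves the
host feature — the question is always about arrangement *within* a UTR,
not about which UTRs are bound.

Overlap is defined as >= 1 shared nucleotide under half-open interval
arithmetic.  Randomized sites may overlap each other and their own set:
the null models independent repositioning without rejection, which would
bias results on short UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from clipcoreg.core import BindingSite, ClipCoregError, HostFeature, ValidationError


@dataclass
class OverlapNullResult:
    """Observed overlap count against a permutation null.

    ``z`` is (observed - null_mean) / null_sd and is None (undefined) when
    the null has zero variance, e.g. when every randomization necessarily
    overlaps.
    """

    observed: int
    null_mean: float
    null_sd: float
    z: float | None
    n_randomizations: int


@dataclass
class DensityProfile:
    """Binned positional density of query elements around reference sites.

    Offsets are query center minus reference center in nucleotides, signed
    5'(-) / 3'(+).  ``observed`` is counts per bin divided by the number of
    reference sites; ``null_mean``/``null_sd`` are the per-bin moments over
    randomizations of the query set within its hosts.
    """

    bin_edges: np.ndarray  # length n_bins + 1
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_randomizations: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class CooccupancyClasses:
    """Per-feature bound-by flags and Venn-region counts for >= 1 proteins."""

    proteins: tuple[str, ...]
    membership: dict[str, frozenset[str]]  # feature_id -> bound proteins
    venn: dict[frozenset[str], int] = field(init=False)

    def __post_init__(self) -> None:
        venn: dict[frozenset[str], int] = {}
        for combo in _powerset(self.proteins):
            venn[frozenset(combo)] = 0
        for bound in self.membership.values():
            venn[bound] += 1
        self.venn = venn

    def bound_by(self, *proteins: str, exclusive: bool = False) -> list[str]:
        """Feature ids bound by all the named proteins.

        With ``exclusive``, features bound by any *other* protein in the
        universe of tracked proteins are excluded.
        """
        want = set(proteins)
        out = []
        for fid, bound in self.membership.items():
            if want <= bound and (not exclusive or bound == want):
                out.append(fid)
        return out

    def count(self, *proteins: str) -> int:
        """Exact Venn-region count: bound by these proteins and no others."""
        return self.venn[frozenset(proteins)]


def _powerset(items: Sequence[str]):
    n = len(items)
    for mask in range(1 << n):
        yield tuple(items[i] for i in range(n) if mask >> i & 1)


def _intervals_intersect(a: BindingSite, b: BindingSite) -> bool:
    return a.feature_id == b.feature_id and a.start < b.end and b.start < a.end


def overlap_sites(
    a: Sequence[BindingSite], b: Sequence[BindingSite]
) -> tuple[list[tuple[BindingSite, BindingSite]], int, int]:
    """All overlapping site pairs between two sets, plus per-set counts.

    Two sites overlap when they lie on the same host feature and share at
    least one nucleotide (intervals intersect under half-open arithmetic).
    Returns (pairs, number of distinct a-sites with >= 1 partner, same for
    b).  Pair production is symmetric: swapping the arguments transposes
    the pairs and the counts.
    """
    b_by_feature: dict[str, list[BindingSite]] = {}
    for site in b:
        b_by_feature.setdefault(site.feature_id, []).append(site)
    for sites in b_by_feature.values():
        sites.sort(key=lambda s: s.start)

    pairs: list[tuple[BindingSite, BindingSite]] = []
    a_hit: set[str] = set()
    b_hit: set[str] = set()
    for sa in a:
        candidates = b_by_feature.get(sa.feature_id, ())
        for sb in candidates:
            if sb.start >= sa.end:
                break
            if sa.start < sb.end:
                pairs.append((sa, sb))
                a_hit.add(sa.site_id)
                b_hit.add(sb.site_id)
    return pairs, len(a_hit), len(b_hit)


def utr_cooccupancy(
    site_sets: Mapping[str, Sequence[BindingSite]],
    universe: Mapping[str, HostFeature],
) -> CooccupancyClasses:
    """Per-feature bound-by membership and Venn counts over a universe.

    The universe must include every feature carrying a site; features with
    no sites fall in the empty (neither) Venn region, which is how the
    "rest of the transcriptome" class is defined.
    """
    proteins = tuple(site_sets)
    membership: dict[str, set[str]] = {fid: set() for fid in universe}
    for protein, sites in site_sets.items():
        for site in sites:
            if site.feature_id not in membership:
                raise ValidationError(
                    f"site {site.site_id} on feature {site.feature_id!r} "
                    f"outside the supplied universe"
                )
            membership[site.feature_id].add(protein)
    return CooccupancyClasses(
        proteins=proteins,
        membership={fid: frozenset(s) for fid, s in membership.items()},
    )


def randomize_within_host(
    sites: Sequence[BindingSite],
    features: Mapping[str, HostFeature],
    rng: np.random.Generator | int,
) -> list[BindingSite]:
    """Reposition each site uniformly among valid starts on its own host.

    Width and counts are preserved; each of the (length - width + 1) starts
    is equiprobable and sites are repositioned independently.  Deterministic
    given the generator state or integer seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[BindingSite] = []
    for site in sites:
        host = features[site.feature_id]
        n_starts = host.length - site.width + 1
        if n_starts < 1:
            raise ValidationError(
                f"site {site.site_id}: width {site.width} exceeds host "
                f"{site.feature_id} length {host.length}"
            )
        start = int(rng.integers(0, n_starts))
        out.append(replace(site, start=start, end=start + site.width))
    return out


def overlap_zscore(
    a: Sequence[BindingSite],
    b: Sequence[BindingSite],
    features: Mapping[str, HostFeature],
    which: str = "randomize_a",
    n: int = 100,
    rng_seed: int | None = 0,
) -> OverlapNullResult:
    """Observed overlap count against a within-host randomization null.

    The observed statistic is the number of sites in the randomized set
    with >= 1 overlapping partner in the fixed set.  The null distribution
    comes from ``n`` independent within-host randomizations of the chosen
    set (the other held fixed).  z is undefined (None) when the null SD is
    zero, e.g. a saturated null where every placement overlaps.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if which not in ("randomize_a", "randomize_b"):
        raise ValueError("which must be 'randomize_a' or 'randomize_b'")
    if not a or not b:
        raise ValidationError("overlap_zscore requires non-empty site sets")

    moving, fixed = (a, b) if which == "randomize_a" else (b, a)
    _, count_a, count_b = overlap_sites(a, b)
    observed = count_a if which == "randomize_a" else count_b

    rng = np.random.default_rng(rng_seed)
    null = np.empty(n)
    for i in range(n):
        shuffled = randomize_within_host(moving, features, rng)
        _, c_shuf, _ = overlap_sites(shuffled, fixed)
        null[i] = c_shuf
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else None
    return OverlapNullResult(
        observed=observed, null_mean=mean, null_sd=sd, z=z, n_randomizations=n
    )


def _signed_offsets(
    reference: Sequence[BindingSite],
    query_centers: Mapping[str, list[int]],
    window: int,
) -> list[int]:
    offsets: list[int] = []
    for ref in reference:
        rc = ref.center
        for qc in query_centers.get(ref.feature_id, ()):
            d = qc - rc
            if -window <= d <= window:
                offsets.append(d)
    return offsets


def _query_centers(
    query: Sequence[BindingSite] | Sequence[tuple[str, int]],
) -> dict[str, list[int]]:
    centers: dict[str, list[int]] = {}
    for q in query:
        if isinstance(q, BindingSite):
            centers.setdefault(q.feature_id, []).append(q.center)
        else:
            fid, pos = q
            centers.setdefault(fid, []).append(int(pos))
    return centers


def density_profile(
    reference_sites: Sequence[BindingSite],
    query: Sequence[BindingSite],
    features: Mapping[str, HostFeature],
    window: int = 500,
    bin: int = 10,
    n: int = 100,
    rng_seed: int | None = 0,
) -> DensityProfile:
    """Positional density of query sites around reference-site centers.

    For each reference site, signed center-to-center offsets of query sites
    on the same host within +/- ``window`` nt are binned (bin width ``bin``
    nt); density is counts per bin divided by the number of reference
    sites.  The null envelope is the per-bin mean and SD over ``n``
    within-host randomizations of the query set with references fixed.
    """
    if not reference_sites:
        raise ValidationError("density_profile requires reference sites")
    if window % bin != 0:
        raise ValueError("window must be a multiple of bin")
    edges = np.arange(-window, window + bin, bin, dtype=float)
    n_ref = len(reference_sites)

    def profile_of(q: Sequence[BindingSite]) -> np.ndarray:
        offs = _signed_offsets(reference_sites, _query_centers(q), window)
        counts, _ = np.histogram(offs, bins=edges)
        return counts / n_ref

    observed = profile_of(query)
    rng = np.random.default_rng(rng_seed)
    null = np.empty((n, len(edges) - 1))
    for i in range(n):
        null[i] = profile_of(randomize_within_host(query, features, rng))
    return DensityProfile(
        bin_edges=edges,
        observed=observed,
        null_mean=null.mean(axis=0),
        null_sd=null.std(axis=0, ddof=1),
        n_randomizations=n,
    )
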