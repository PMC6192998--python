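"""Pumilio motif and miRNA seed-complement scanning.

The canonical Pumilio recognition element is the 8-mer 5'-UGUAnAUA, where
each of the eight Pum-HD repeats reads one nucleotide and position 5 ("n")
is unconstrained.  Degenerate variants relax the more weakly specified
3' half of the element: UGUAnnUA, UGUAnAnA and UGUAnAUn.

miRNA target sites are typed by the canonical seed-match conventions: for a
miRNA with seed nucleotides 2-8, the 7mer-m8 site is the reverse complement
of nt 2-8, the 7mer-A1 site is the reverse complement of nt 2-7 followed by
an A in the target, and the 8mer site is the 7mer-m8 followed by that A.

Scanning is sense-strand only on the mature mRNA: 3'UTR regulation is
single-stranded and both RBP binding and miRNA targeting are resolved by
transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from clipcoreg.core import BindingSite, ClipCoregError, HostFeature

PUM_MOTIF_CLASSES = ("PERFECT", "UGUAnnUA", "UGUAnAnA", "UGUAnAUn")
SEED_SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_ANY = frozenset("ACGU")  # 'n' in a motif pattern: any base, but never N

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


class MissingSequenceError(ClipCoregError):
    """Scanning requested on a feature that carries no sequence."""


@dataclass(frozen=True)
class MotifHit:
    """A Pumilio-element match: 0-based start of the 8-mer window."""

    feature_id: str
    position: int
    motif_class: str


@dataclass(frozen=True)
class SeedMatch:
    """A miRNA seed-complement match in a target sequence.

    ``mirna_family`` is the seed (miRNA nt 2-8), which defines the family;
    ``position`` is the 0-based start of the matched target substring.
    """

    feature_id: str
    position: int
    mirna_family: str
    site_type: str


def _classify_window(window: str) -> str | None:
    """Classify one 8-mer window; returns a motif class or None.

    PERFECT takes priority; degenerate classes are mutually exclusive with
    it and with each other, precedence UGUAnnUA > UGUAnAnA > UGUAnAUn
    (UGUAnnUA subsumes the other two relaxations).  Windows containing N
    never match.
    """
    if window[:4] != "UGUA" or window[4] not in _ANY:
        return None
    p5, p6, p7, p8 = window[4], window[5], window[6], window[7]
    if p6 == "A" and p7 == "U" and p8 == "A":
        return "PERFECT"
    if p6 in _ANY and p7 == "U" and p8 == "A":
        return "UGUAnnUA"
    if p6 == "A" and p7 in _ANY and p8 == "A":
        return "UGUAnAnA"
    if p6 == "A" and p7 == "U" and p8 in _ANY:
        return "UGUAnAUn"
    return None


def scan_pum_motifs(
    feature: HostFeature, allow_degenerate: bool = False
) -> list[MotifHit]:
    """Scan a host feature for Pumilio elements.

    Every 8-mer window is tested; overlapping hits are all reported.
    Without ``allow_degenerate`` only PERFECT (UGUA[ACGU]AUA) matches are
    returned; with it, a window that is not PERFECT may additionally match
    one degenerate class.
    """
    if feature.sequence is None:
        raise MissingSequenceError(
            f"feature {feature.feature_id} has no sequence"
        )
    seq = feature.sequence
    hits: list[MotifHit] = []
    for pos in range(len(seq) - 7):
        cls = _classify_window(seq[pos : pos + 8])
        if cls is None:
            continue
        if cls == "PERFECT" or allow_degenerate:
            hits.append(MotifHit(feature.feature_id, pos, cls))
    return hits


def reverse_complement(seq: str) -> str:
    """Reverse complement in the RNA alphabet (input may use T or U)."""
    s = seq.upper().replace("T", "U")
    try:
        return "".join(_RC[b] for b in reversed(s))
    except KeyError as exc:
        raise ValueError(f"cannot complement base {exc.args[0]!r}") from exc


def seed_patterns(mirna_sequence: str) -> dict[str, str]:
    """Target-site patterns for one miRNA, by canonical site type.

    7mer-m8 = reverse complement of miRNA nt 2-8; 7mer-A1 = reverse
    complement of nt 2-7 followed by A; 8mer = 7mer-m8 followed by A.
    """
    seq = mirna_sequence.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError(
            f"miRNA sequence must be >= 8 nt, got {len(seq)}"
        )
    m8 = reverse_complement(seq[1:8])  # nt 2-8, 1-based
    a1 = reverse_complement(seq[1:7]) + "A"  # nt 2-7 + target A1
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": a1}


def seed_of(mirna_sequence: str) -> str:
    """The miRNA family seed: nucleotides 2-8 of the mature sequence."""
    seq = mirna_sequence.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError("miRNA sequence must be >= 8 nt")
    return seq[1:8]


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_seed_complements(
    feature: HostFeature,
    mirnas: Mapping[str, str] | Sequence[str],
) -> list[SeedMatch]:
    """Scan a target sequence for canonical seed-complement sites.

    ``mirnas`` maps names to mature sequences (or is a bare sequence list).
    Families are deduplicated by seed (nt 2-8).  At each locus the single
    longest-matching site type per family is reported, with precedence
    8mer > 7mer-m8 > 7mer-A1: an 8mer match suppresses the 7mer-m8 it
    contains and the 7mer-A1 one base downstream.
    """
    if feature.sequence is None:
        raise MissingSequenceError(
            f"feature {feature.feature_id} has no sequence"
        )
    if not isinstance(mirnas, Mapping):
        mirnas = {f"mirna_{i}": s for i, s in enumerate(mirnas)}
    seq = feature.sequence
    matches: list[SeedMatch] = []
    seen_seeds: set[str] = set()
    for _name, mseq in mirnas.items():
        family = seed_of(mseq)
        if family in seen_seeds:
            continue
        seen_seeds.add(family)
        pats = seed_patterns(mseq)
        eightmer_starts = set(_find_all(seq, pats["8mer"]))
        for p in sorted(eightmer_starts):
            matches.append(SeedMatch(feature.feature_id, p, family, "8mer"))
        for p in _find_all(seq, pats["7mer-m8"]):
            if p not in eightmer_starts:
                matches.append(
                    SeedMatch(feature.feature_id, p, family, "7mer-m8")
                )
        for p in _find_all(seq, pats["7mer-A1"]):
            if (p - 1) not in eightmer_starts:
                matches.append(
                    SeedMatch(feature.feature_id, p, family, "7mer-A1")
                )
    return matches


def motif_tally_per_site(
    sites: Sequence[BindingSite],
    hits: Iterable[MotifHit | SeedMatch],
    window: int = 0,
) -> dict[str, int]:
    """Count sequence elements near each site.

    An element is attributed to a site when its start position lies within
    [site.start - window, site.end + window) on the same host feature.
    Returns site_id -> count (zero-filled for hitless sites).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    hits_by_feature: dict[str, list[int]] = {}
    for h in hits:
        hits_by_feature.setdefault(h.feature_id, []).append(h.position)
    tally: dict[str, int] = {}
    for site in sites:
        positions = hits_by_feature.get(site.feature_id, ())
        lo, hi = site.start - window, site.end + window
        tally[site.site_id] = sum(1 for p in positions if lo <= p < hi)
    return tally


def family_tallies(
    sites: Sequence[BindingSite],
    seed_matches: Iterable[SeedMatch],
    window: int = 0,
) -> dict[str, int]:
    """Total seed-complement occurrences per miRNA family within sites.

    Feeds the repertoire comparison between two site populations.
    """
    by_family: dict[str, list[SeedMatch]] = {}
    for m in seed_matches:
        by_family.setdefault(m.mirna_family, []).append(m)
    return {
        family: sum(motif_tally_per_site(sites, ms, window).values())
        for family, ms in by_family.items()
    }
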