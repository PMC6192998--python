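"""Data model and I/O for host features, binding sites, counts and mRNA LFCs.

Coordinates are 0-based, half-open and transcript-relative (5'->3' on the
mature mRNA) throughout the package.  Genomic BED6 input is accepted only
together with a genomically annotated host-feature table and is mapped onto
transcript-relative coordinates at ingest; strand is consumed during the
mapping and never stored on sites, because every downstream analysis
(shuffling, density, overlap) operates within the host feature.

T and U are interchangeable; sequences are upper-cased on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_CATEGORIES = ("UTR3", "UTR5", "CDS", "ncRNA")
_SEQ_ALPHABET = frozenset("ACGUN")


class ClipCoregError(Exception):
    """Base class for package errors."""


class ParseError(ClipCoregError):
    """A malformed input line; the message names the file and line number."""


class ValidationError(ClipCoregError):
    """Inputs are structurally parseable but mutually inconsistent."""


def _normalize_seq(seq: str) -> str:
    """Upper-case and convert T->U (RNA alphabet internally)."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _SEQ_ALPHABET
    if bad:
        raise ValidationError(f"sequence contains invalid characters: {sorted(bad)}")
    return s


@dataclass
class GenomicSpan:
    """Genomic footprint of a host feature, used only to map BED input."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid genomic span [{self.start}, {self.end}) on {self.chrom}"
            )


@dataclass
class HostFeature:
    """A transcript-relative region (3'UTR by default) hosting binding sites.

    The feature is the universe within which sites live and are shuffled.
    ``mrna_lfc`` maps a perturbation label (e.g. ``"PUM_KD"``) to the
    transcript-level log2 fold change of mRNA abundance under that
    perturbation, used to correct CLIP-signal fold changes for changes in
    substrate availability.
    """

    feature_id: str
    transcript_id: str
    length: int
    sequence: str | None = None
    category: str = "UTR3"
    mrna_lfc: dict[str, float] = field(default_factory=dict)
    genomic: GenomicSpan | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(
                f"feature {self.feature_id}: length must be >= 1, got {self.length}"
            )
        if self.category not in _VALID_CATEGORIES:
            raise ValidationError(
                f"feature {self.feature_id}: unknown category {self.category!r}"
            )
        if self.sequence is not None:
            self.sequence = _normalize_seq(self.sequence)
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"feature {self.feature_id}: declared length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
        for cond, v in self.mrna_lfc.items():
            if not _isfinite(v):
                raise ValidationError(
                    f"feature {self.feature_id}: non-finite mRNA LFC for {cond!r}"
                )
        if self.genomic is not None and (self.genomic.end - self.genomic.start) != self.length:
            raise ValidationError(
                f"feature {self.feature_id}: genomic span width != length"
            )


def _isfinite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass
class BindingSite:
    """One protein's CLIP peak on a host feature, with per-sample counts.

    ``counts`` holds PCR-collapsed (UMI-deduplicated) read counts per sample
    label; it may be empty, in which case count-requiring operations raise.
    """

    site_id: str
    protein: str
    feature_id: str
    start: int  # 0-based inclusive, transcript-relative
    end: int  # exclusive
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"site {self.site_id}: invalid interval [{self.start}, {self.end})"
            )
        for sample, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValidationError(
                    f"site {self.site_id}: count for sample {sample!r} must be a "
                    f"non-negative integer, got {c}"
                )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # midpoint rounded half-down for even widths
        return self.start + (self.width - 1) // 2

    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class SampleDesign:
    """Maps samples to (condition, replicate) and records library sizes."""

    samples: dict[str, tuple[str, int]]
    library_size: dict[str, int]

    def __post_init__(self) -> None:
        for sample, size in self.library_size.items():
            if size <= 0:
                raise ValidationError(
                    f"library size for sample {sample!r} must be positive"
                )
        for sample in self.samples:
            if sample not in self.library_size:
                raise ValidationError(f"sample {sample!r} has no library size")
        if not self.samples:
            raise ValidationError("design has no samples")

    def samples_for(self, condition: str) -> list[str]:
        out = [s for s, (c, _) in self.samples.items() if c == condition]
        if not out:
            raise ValidationError(f"no samples for condition {condition!r}")
        return out

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c, _ in self.samples.values():
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def n_samples(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_host_features(
    path: str | Path,
    fasta_path: str | Path | None = None,
    category: str = "UTR3",
) -> dict[str, HostFeature]:
    """Read host features from a BED6 file or a 2-column (id, length) table.

    BED6 lines carry the genomic footprint (chrom, start, end, name, score,
    strand); feature length is end - start and the span is retained so that
    genomic site input can later be mapped onto the feature.  A 2-column
    table declares transcript-relative features directly.  An optional FASTA
    attaches sequences; record ids must match feature ids and lengths must
    agree with the declared lengths.

    Returns an ordered mapping feature_id -> HostFeature.
    """
    path = Path(path)
    features: dict[str, HostFeature] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 6:  # BED6
                    chrom, gstart, gend, name, _score, strand = fields[:6]
                    span = GenomicSpan(chrom, int(gstart), int(gend), strand)
                    feat = HostFeature(
                        feature_id=name,
                        transcript_id=name,
                        length=span.end - span.start,
                        category=category,
                        genomic=span,
                    )
                elif len(fields) == 2:
                    name, length = fields
                    feat = HostFeature(
                        feature_id=name,
                        transcript_id=name,
                        length=int(length),
                        category=category,
                    )
                else:
                    raise ValueError(
                        f"expected BED6 (>=6 columns) or 2-column table, "
                        f"got {len(fields)} columns"
                    )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.feature_id in features:
                raise ParseError(
                    f"{path}:{lineno}: duplicate feature id {feat.feature_id!r}"
                )
            features[feat.feature_id] = feat

    if fasta_path is not None:
        attach_sequences(features, fasta_path)
    return features


def attach_sequences(
    features: dict[str, HostFeature], fasta_path: str | Path
) -> None:
    """Attach FASTA sequences to features in place, validating lengths."""
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in features:
            continue
        feat = features[record.id]
        seq = _normalize_seq(str(record.seq))
        if len(seq) != feat.length:
            raise ValidationError(
                f"feature {feat.feature_id}: FASTA sequence length {len(seq)} "
                f"!= declared length {feat.length}"
            )
        feat.sequence = seq


def read_mrna_lfc(
    path: str | Path, features: dict[str, HostFeature] | None = None
) -> dict[str, dict[str, float]]:
    """Read a (transcript_id, condition, log2fc) table.

    Returns transcript_id -> {condition: log2fc} and, when ``features`` is
    given, annotates matching features' ``mrna_lfc`` in place (matching on
    transcript_id).
    """
    path = Path(path)
    table: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("transcript_id", "transcript"):
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            tid, cond, val = fields[0], fields[1], fields[2]
            try:
                lfc = float(val)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad log2fc {val!r}") from exc
            if not _isfinite(lfc):
                raise ParseError(f"{path}:{lineno}: non-finite log2fc")
            table.setdefault(tid, {})[cond] = lfc
    if features is not None:
        for feat in features.values():
            if feat.transcript_id in table:
                feat.mrna_lfc.update(table[feat.transcript_id])
    return table


def _map_genomic_to_transcript(
    feat: HostFeature, gstart: int, gend: int, site_id: str
) -> tuple[int, int]:
    span = feat.genomic
    if span is None:
        raise ValidationError(
            f"site {site_id}: feature {feat.feature_id} has no genomic "
            f"annotation; cannot map genomic coordinates"
        )
    if gstart < span.start or gend > span.end:
        raise ValidationError(
            f"site {site_id}: genomic interval [{gstart}, {gend}) extends "
            f"outside feature {feat.feature_id}; sites spanning annotation "
            f"boundaries are not supported"
        )
    if span.strand == "+":
        return gstart - span.start, gend - span.start
    return span.end - gend, span.end - gstart


def read_sites(
    path: str | Path,
    features: dict[str, HostFeature],
    coordinates: str = "transcript",
    one_based: bool = False,
) -> list[BindingSite]:
    """Read binding sites from a headered table or a BED6 file.

    The headered dialect has columns ``feature_id start end site_id protein``
    followed by zero or more ``count:<sample>`` columns.  The BED6 dialect
    (no header) has name = site_id, score = total count, and is interpreted
    per ``coordinates``: ``"transcript"`` means chrom is a feature id and
    start/end are transcript-relative, ``"genomic"`` means chrom/start/end
    are genomic and are mapped through the features' genomic annotation.
    ``one_based`` converts inclusive 1-based starts to the internal 0-based
    half-open convention (peak callers differ; the flag makes the choice
    explicit rather than guessed).
    """
    if coordinates not in ("transcript", "genomic"):
        raise ValueError(f"coordinates must be 'transcript' or 'genomic'")
    path = Path(path)
    sites: list[BindingSite] = []
    seen_ids: set[str] = set()
    header: dict[str, int] | None = None
    count_cols: list[tuple[int, str]] = []
    by_chrom: dict[str, list[HostFeature]] | None = None
    offset = 1 if one_based else 0

    def _set_header(cols: list[str]) -> None:
        nonlocal header, count_cols
        header = {c: i for i, c in enumerate(cols)}
        count_cols = [
            (i, c.split(":", 1)[1])
            for i, c in enumerate(cols)
            if c.startswith("count:")
        ]
        for required in ("feature_id", "start", "end", "site_id"):
            if required not in header:
                raise ParseError(f"{path}: header lacks column {required!r}")

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                maybe = line.lstrip("#").split("\t")
                if maybe and maybe[0] == "feature_id":
                    _set_header(maybe)
                continue
            fields = line.split("\t")
            if header is None and fields[0] == "feature_id":
                _set_header(fields)
                continue
            try:
                if header is not None:
                    fid = fields[header["feature_id"]]
                    start = fields[header["start"]]
                    end = fields[header["end"]]
                    site_id = fields[header["site_id"]]
                    protein = (
                        fields[header["protein"]]
                        if "protein" in header
                        else "unknown"
                    )
                    counts = {
                        sample: int(fields[i]) for i, sample in count_cols
                    }
                else:  # BED6-like: chrom start end name score strand [protein]
                    if len(fields) < 5:
                        raise ValueError("expected >=5 BED columns")
                    fid, start, end, site_id, score = fields[:5]
                    if len(fields) > 6:
                        protein = fields[6]
                    elif not score.lstrip("-").isdigit():
                        protein = score  # 5-column shorthand: name then protein
                    else:
                        protein = "unknown"
                    counts = {}
                start_i, end_i = int(start) - offset, int(end)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc

            if coordinates == "genomic":
                if by_chrom is None:
                    by_chrom = {}
                    for f in features.values():
                        if f.genomic is not None:
                            by_chrom.setdefault(f.genomic.chrom, []).append(f)
                host = None
                for f in by_chrom.get(fid, []):
                    if f.genomic.start <= start_i and end_i <= f.genomic.end:
                        host = f
                        break
                if host is None:
                    raise ValidationError(
                        f"{path}:{lineno}: site {site_id!r} at {fid}:{start_i}-"
                        f"{end_i} is not contained in any annotated feature"
                    )
                start_i, end_i = _map_genomic_to_transcript(
                    host, start_i, end_i, site_id
                )
                fid = host.feature_id
            elif fid not in features:
                raise ValidationError(
                    f"{path}:{lineno}: unknown feature id {fid!r}"
                )

            if site_id in seen_ids:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate site id {site_id!r}"
                )
            seen_ids.add(site_id)
            site = BindingSite(
                site_id=site_id,
                protein=protein,
                feature_id=fid,
                start=start_i,
                end=end_i,
                counts=counts,
            )
            host_len = features[fid].length
            if site.end > host_len:
                raise ValidationError(
                    f"{path}:{lineno}: site {site_id!r} end {site.end} exceeds "
                    f"host {fid!r} length {host_len}"
                )
            sites.append(site)
    return sites


def validate_sites(
    sites: Iterable[BindingSite], features: Mapping[str, HostFeature]
) -> None:
    """Check every site lies within a known host; raise ValidationError."""
    for site in sites:
        if site.feature_id not in features:
            raise ValidationError(
                f"site {site.site_id}: unknown feature {site.feature_id!r}"
            )
        if site.end > features[site.feature_id].length:
            raise ValidationError(
                f"site {site.site_id}: end {site.end} exceeds host length "
                f"{features[site.feature_id].length}"
            )


def filter_sites_by_count(
    sites: Sequence[BindingSite], min_total: int
) -> list[BindingSite]:
    """Keep sites whose summed collapsed counts across samples >= min_total.

    The conventional cutoff equals the number of samples in the CLIP set
    (one supporting ligation event per sample on average).
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if min_total == 0:
        return list(sites)
    return [s for s in sites if s.total_count() >= min_total]


def write_sites(sites: Sequence[BindingSite], path: str | Path) -> None:
    """Write sites as a headered, BED6-compatible tab table.

    Columns: feature_id, start, end, site_id, score (total counts), protein,
    then one ``count:<sample>`` column per sample seen across the collection.
    Rows are sorted by (feature_id, start).  Round-trips losslessly through
    :func:`read_sites`.
    """
    samples: list[str] = []
    for s in sites:
        for k in s.counts:
            if k not in samples:
                samples.append(k)
    samples.sort()
    cols = ["feature_id", "start", "end", "site_id", "score", "protein"] + [
        f"count:{s}" for s in samples
    ]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for s in sorted(sites, key=lambda x: (x.feature_id, x.start)):
            row = [
                s.feature_id,
                str(s.start),
                str(s.end),
                s.site_id,
                str(s.total_count()),
                s.protein,
            ] + [str(s.counts.get(k, 0)) for k in samples]
            fh.write("\t".join(row) + "\n")


def write_fasta(features: Mapping[str, HostFeature], path: str | Path) -> None:
    """Write feature sequences as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for feat in features.values():
            if feat.sequence is None:
                continue
            fh.write(f">{feat.feature_id}\n")
            for i in range(0, len(feat.sequence), 60):
                fh.write(feat.sequence[i : i + 60] + "\n")
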