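"""Synthetic CLIP study generator with known co-regulatory structure.

The generator emulates a reciprocal-perturbation CLIP design on 3'UTRs:

* a focal protein (default ``AGO2``) is CLIPped under a control and a
  partner-knockdown condition;
* a partner protein (default ``PUM``) is CLIPped under a control and a
  condition abolishing the focal protein's targeting (default
  ``DICER_KO``, which removes miRNA guidance of Argonaute).

UTRs are assigned deterministically to co-occupancy classes (co-bound,
focal-only, partner-only, unbound) according to the configured fractions.
On co-bound UTRs, one focal site is cooperative (its CLIP signal drops
2^-delta upon partner knockdown), one is antagonistic (rises 2^+delta);
partner sites placed overlapping a focal site are cooperative with respect
to focal-protein loss.  All other sites are independent.  Transcript-level
mRNA log fold changes are generated separately from the binding effects
and added to every site's perturbed-condition mean, so the raw CLIP LFC is
contaminated by transcript abundance and the mRNA-normalization step is
genuinely exercised.

Collapsed read counts are negative binomial (mean mu, dispersion k;
variance mu + mu^2/k), reflecting over-dispersed CLIP ligation-event
counts.  Sequences have i.i.d. uniform base composition, so background
motif rates are closed-form for tests.  Everything is deterministic given
the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from clipcoreg.core import (
    BindingSite,
    HostFeature,
    SampleDesign,
    ValidationError,
)

#: Example mature miRNA repertoire used when none is supplied (well-known
#: abundant human miRNAs).
DEFAULT_MIRNAS: dict[str, str] = {
    "let-7a": "UGAGGUAGUAGGUUGUAUAGUU",
    "miR-21": "UAGCUUAUCAGACUGAUGUUGA",
    "miR-17": "CAAAGUGCUUACAGUGCAGGUAG",
    "miR-221": "AGCUACAUUGUCUGCUGGGUUUC",
    "miR-16": "UAGCAGCACGUAAAUAUUGGCG",
    "miR-19b": "UGUGCAAAUCCAUGCAAAACUGA",
    "miR-92a": "UAUUGCACUUGUCCCGGCCUGU",
    "miR-103": "AGCAGCAUUGUACAGGGCUAUGA",
}

UTR_CLASSES = ("cobound", "focal_only", "partner_only", "unbound")
SITE_CLASSES = ("cooperative", "antagonistic", "independent")


@dataclass
class SimConfig:
    """Parameters of the synthetic reciprocal-perturbation CLIP study."""

    n_utrs: int = 600
    utr_length: tuple[int, int] = (500, 1500)  # nt, inclusive bounds
    sites_per_utr: int = 2  # per bound protein on each bound UTR
    site_width: tuple[int, int] = (20, 40)  # nt, inclusive bounds
    fraction_cobound: float = 0.4
    fraction_focal_only: float = 0.4
    fraction_partner_only: float = 0.1
    fraction_overlapping: float = 0.5  # partner sites on co-bound UTRs
    coupling: dict[str, float] = field(
        default_factory=lambda: {"cooperative": 1.0, "antagonistic": 1.0}
    )
    nb_mu: float = 100.0  # mean collapsed counts per site per sample
    nb_dispersion: float = 10.0  # k; var = mu + mu^2/k
    site_mu_log2_sd: float = 0.5  # per-site baseline abundance spread
    n_replicates: int = 3
    library_size: int = 1_000_000
    mrna_lfc_sd: float = 0.2
    mrna_class_effect: dict[str, float] = field(
        default_factory=lambda: {"cobound": 0.5, "partner_only": 0.5}
    )
    focal_protein: str = "AGO2"
    partner_protein: str = "PUM"
    focal_perturbation: str = "PUM_KD"
    partner_perturbation: str = "DICER_KO"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_cobound,
            self.fraction_focal_only,
            self.fraction_partner_only,
            self.fraction_overlapping,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(fracs[:3]) > 1.0 + 1e-9:
            raise ValueError("UTR class fractions must sum to <= 1")
        if self.nb_mu <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mu and nb_dispersion must be positive")
        if self.site_width[0] < 1 or self.site_width[0] > self.site_width[1]:
            raise ValueError("invalid site width range")
        if self.utr_length[0] < 1 or self.utr_length[0] > self.utr_length[1]:
            raise ValueError("degenerate UTR length range")


@dataclass
class GroundTruth:
    """Planted structure of a simulated study."""

    utr_class: dict[str, str]  # feature_id -> UTR class
    site_class: dict[str, str]  # site_id -> site coupling class
    motif_positions: dict[str, list[int]]  # feature_id -> planted PUM motifs
    seed_positions: dict[str, list[int]]  # feature_id -> planted seed sites
    overlapping_partner_sites: set[str] = field(default_factory=set)

    def class_frequencies(self) -> dict[str, int]:
        freq: dict[str, int] = {c: 0 for c in UTR_CLASSES}
        for c in self.utr_class.values():
            freq[c] += 1
        return freq


@dataclass
class SimulatedStudy:
    """Everything the analysis pipeline consumes, plus the ground truth."""

    config: SimConfig
    features: dict[str, HostFeature]
    sites: dict[str, list[BindingSite]]  # protein -> sites
    designs: dict[str, SampleDesign]  # protein -> its CLIP design
    mrna_lfc: dict[str, dict[str, float]]  # transcript -> cond -> log2fc
    truth: GroundTruth


def simulate_utrs(
    config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, HostFeature]:
    """I.i.d. uniform-composition UTR sequences of sampled lengths."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.utr_length
    features: dict[str, HostFeature] = {}
    for i in range(config.n_utrs):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(
            np.array(list("ACGU"))[rng.integers(0, 4, size=length)]
        )
        fid = f"utr{i:04d}"
        features[fid] = HostFeature(
            feature_id=fid, transcript_id=fid, length=length, sequence=seq
        )
    return features


def _render_motif(motif: str, rng: np.random.Generator) -> str:
    """Instantiate 'n' positions of a motif pattern uniformly."""
    return "".join(
        "ACGU"[rng.integers(0, 4)] if c == "n" else c for c in motif
    )


def _splice(seq: str, pos: int, insert: str) -> str:
    return seq[:pos] + insert + seq[pos + len(insert) :]


def plant_motifs(
    features: Mapping[str, HostFeature],
    rng: np.random.Generator | int,
    motif: str = "UGUAnAUA",
    n_per_feature: int = 1,
    positions: Mapping[str, Sequence[int]] | None = None,
    max_retries: int = 50,
) -> dict[str, list[int]]:
    """Write motif instances into feature sequences (in place).

    Positions are drawn uniformly unless given explicitly; a draw that
    collides with an already-planted element on the same feature is
    re-drawn up to ``max_retries`` times, then raises.  Returns the planted
    positions per feature (the ground truth for recovery tests).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    width = len(motif)
    planted: dict[str, list[int]] = {}
    for fid, feat in features.items():
        if feat.sequence is None:
            raise ValidationError(f"feature {fid} has no sequence to plant in")
        wanted: Sequence[int]
        if positions is not None:
            wanted = positions.get(fid, ())
        else:
            wanted = [None] * n_per_feature  # type: ignore[list-item]
        placed: list[int] = []
        for want in wanted:
            if want is not None:
                pos = int(want)
                if pos < 0 or pos + width > feat.length:
                    raise ValidationError(
                        f"feature {fid}: planted element at {pos} does not fit"
                    )
                if any(abs(pos - p) < width for p in placed):
                    raise ValidationError(
                        f"feature {fid}: planted elements collide at {pos}"
                    )
            else:
                pos = -1
                for _ in range(max_retries):
                    cand = int(rng.integers(0, feat.length - width + 1))
                    if all(abs(cand - p) >= width for p in placed):
                        pos = cand
                        break
                if pos < 0:
                    raise ValidationError(
                        f"feature {fid}: could not place element after "
                        f"{max_retries} retries"
                    )
            feat.sequence = _splice(
                feat.sequence, pos, _render_motif(motif, rng)
            )
            placed.append(pos)
        planted[fid] = sorted(placed)
    return planted


def _nb_draw(
    rng: np.random.Generator, mu: float, k: float, size: int
) -> np.ndarray:
    # numpy parameterization: n = k, p = k / (k + mu)
    return rng.negative_binomial(k, k / (k + mu), size=size)


def _place_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    width: int,
    occupied: list[tuple[int, int]],
    max_retries: int = 200,
) -> int:
    """Uniform start avoiding the occupied intervals; bounded retries."""
    n_starts = length - width + 1
    if n_starts < 1:
        raise ValidationError("site wider than host")
    for _ in range(max_retries):
        s = int(rng.integers(0, n_starts))
        if all(s >= e or s + width <= b for b, e in occupied):
            return s
    raise ValidationError(
        "could not place a site without overlap; hosts too crowded"
    )


def simulate_sites_and_counts(
    features: Mapping[str, HostFeature],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedStudy:
    """Generate site sets, count tables and mRNA LFCs with planted coupling.

    UTR classes are assigned deterministically in feature order (the first
    ``round(fraction_cobound * n)`` features are co-bound, and so on), so
    ground-truth class frequencies match the configured fractions exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    cfg = config
    fids = list(features)
    n = len(fids)
    n_cb = round(cfg.fraction_cobound * n)
    n_fo = round(cfg.fraction_focal_only * n)
    n_po = round(cfg.fraction_partner_only * n)
    if n_cb + n_fo + n_po > n:
        raise ValidationError("UTR class counts exceed universe size")
    utr_class = {}
    for i, fid in enumerate(fids):
        if i < n_cb:
            utr_class[fid] = "cobound"
        elif i < n_cb + n_fo:
            utr_class[fid] = "focal_only"
        elif i < n_cb + n_fo + n_po:
            utr_class[fid] = "partner_only"
        else:
            utr_class[fid] = "unbound"

    # sample designs: one CLIP set per protein, control + perturbation
    def make_design(protein: str, perturbation: str) -> SampleDesign:
        samples: dict[str, tuple[str, int]] = {}
        for cond in ("control", perturbation):
            for r in range(1, cfg.n_replicates + 1):
                samples[f"{protein}_{cond}_{r}"] = (cond, r)
        return SampleDesign(
            samples=samples,
            library_size={s: cfg.library_size for s in samples},
        )

    designs = {
        cfg.focal_protein: make_design(
            cfg.focal_protein, cfg.focal_perturbation
        ),
        cfg.partner_protein: make_design(
            cfg.partner_protein, cfg.partner_perturbation
        ),
    }

    # transcript-level mRNA LFCs: class effect + noise, per perturbation
    mrna_lfc: dict[str, dict[str, float]] = {}
    for fid in fids:
        eff = cfg.mrna_class_effect.get(utr_class[fid], 0.0)
        mrna_lfc[fid] = {
            cfg.focal_perturbation: float(
                eff + rng.normal(0.0, cfg.mrna_lfc_sd)
            ),
            cfg.partner_perturbation: float(rng.normal(0.0, cfg.mrna_lfc_sd)),
        }
        features[fid].mrna_lfc.update(mrna_lfc[fid])

    # site placement and coupling assignment
    sites: dict[str, list[BindingSite]] = {
        cfg.focal_protein: [],
        cfg.partner_protein: [],
    }
    site_class: dict[str, str] = {}
    overlapping_partner: set[str] = set()
    n_overlap_per_utr = round(cfg.fraction_overlapping * cfg.sites_per_utr)
    wlo, whi = cfg.site_width

    for fid in fids:
        cls = utr_class[fid]
        feat = features[fid]
        occupied: dict[str, list[tuple[int, int]]] = {
            cfg.focal_protein: [],
            cfg.partner_protein: [],
        }
        focal_sites_here: list[BindingSite] = []
        if cls in ("cobound", "focal_only"):
            for j in range(cfg.sites_per_utr):
                w = int(rng.integers(wlo, whi + 1))
                # same-protein sites never overlap; cross-protein overlap is
                # controlled explicitly below
                s = _place_nonoverlapping(
                    rng, feat.length, w, occupied[cfg.focal_protein]
                )
                occupied[cfg.focal_protein].append((s, s + w))
                sid = f"{cfg.focal_protein}_{fid}_s{j}"
                site = BindingSite(
                    site_id=sid,
                    protein=cfg.focal_protein,
                    feature_id=fid,
                    start=s,
                    end=s + w,
                )
                if cls == "cobound" and j == 0:
                    site_class[sid] = "cooperative"
                elif cls == "cobound" and j == 1:
                    site_class[sid] = "antagonistic"
                else:
                    site_class[sid] = "independent"
                sites[cfg.focal_protein].append(site)
                focal_sites_here.append(site)
        if cls in ("cobound", "partner_only"):
            for j in range(cfg.sites_per_utr):
                w = int(rng.integers(wlo, whi + 1))
                sid = f"{cfg.partner_protein}_{fid}_s{j}"
                if cls == "cobound" and j < n_overlap_per_utr:
                    # straddle the j-th focal site's center: guaranteed >= 1
                    # shared nucleotide
                    anchor = focal_sites_here[j % len(focal_sites_here)]
                    jitter = int(rng.integers(-(w // 2), w // 2 + 1))
                    s = max(
                        0, min(anchor.center + jitter - w // 2, feat.length - w)
                    )
                    if not (s < anchor.end and anchor.start < s + w):
                        s = max(0, min(anchor.center, feat.length - w))
                    overlapping_partner.add(sid)
                    site_class[sid] = "cooperative"
                else:
                    avoid = occupied[cfg.partner_protein] + [
                        (f.start, f.end) for f in focal_sites_here
                    ]
                    s = _place_nonoverlapping(rng, feat.length, w, avoid)
                    site_class[sid] = "independent"
                occupied[cfg.partner_protein].append((s, s + w))
                sites[cfg.partner_protein].append(
                    BindingSite(
                        site_id=sid,
                        protein=cfg.partner_protein,
                        feature_id=fid,
                        start=s,
                        end=s + w,
                    )
                )

    # counts: NB around per-site baseline; perturbed mean scaled by the
    # coupling effect and the transcript's mRNA LFC
    sign = {"cooperative": -1.0, "antagonistic": +1.0, "independent": 0.0}
    for protein, protein_sites in sites.items():
        design = designs[protein]
        perturbation = (
            cfg.focal_perturbation
            if protein == cfg.focal_protein
            else cfg.partner_perturbation
        )
        for site in protein_sites:
            base_mu = cfg.nb_mu * 2.0 ** rng.normal(0.0, cfg.site_mu_log2_sd)
            s = sign[site_class[site.site_id]]
            delta = cfg.coupling.get(
                "cooperative" if s < 0 else "antagonistic", 0.0
            )
            shift = s * delta + mrna_lfc[site.feature_id][perturbation]
            for sample, (cond, _rep) in design.samples.items():
                mu = base_mu if cond == "control" else base_mu * 2.0**shift
                site.counts[sample] = int(
                    _nb_draw(rng, mu, cfg.nb_dispersion, 1)[0]
                )

    truth = GroundTruth(
        utr_class=utr_class,
        site_class=site_class,
        motif_positions={},
        seed_positions={},
        overlapping_partner_sites=overlapping_partner,
    )
    return SimulatedStudy(
        config=cfg,
        features=dict(features),
        sites=sites,
        designs=designs,
        mrna_lfc=mrna_lfc,
        truth=truth,
    )


def simulate_study(
    config: SimConfig | None = None,
    mirnas: Mapping[str, str] | None = None,
) -> SimulatedStudy:
    """End-to-end study: UTRs, planted sequence elements, sites and counts.

    A perfect Pumilio element is planted inside every partner-protein site
    and a miRNA seed complement (8mer) inside every focal-protein site,
    mirroring the geometry the scanners and density profiles are meant to
    detect.  The miRNA family for each site is drawn from a fixed,
    geometrically skewed abundance distribution over the repertoire, as
    cellular miRNA expression is dominated by a few abundant families; the
    same distribution targets every site population, so repertoires of
    different site groups should rank-correlate strongly.
    """
    if config is None:
        config = SimConfig()
    if mirnas is None:
        mirnas = DEFAULT_MIRNAS
    rng = np.random.default_rng(config.rng_seed)
    features = simulate_utrs(config, rng)
    study = simulate_sites_and_counts(features, config, rng)

    from clipcoreg.motifs import seed_patterns  # local import, no cycle

    mirna_items = list(mirnas.items())
    motif_positions: dict[str, list[int]] = {}
    seed_positions: dict[str, list[int]] = {}
    occupied_elements: dict[str, list[tuple[int, int]]] = {}

    def plant_in_site(site: BindingSite, pattern: str) -> int | None:
        """Plant near the site center, dodging earlier planted elements.

        Overlapping sites of the two proteins each receive an element, so
        the preferred position may be taken; the nearest free position
        within the host is used instead.  Returns None only when the host
        is saturated (practically impossible at default geometry).
        """
        feat = features[site.feature_id]
        width = len(pattern)
        taken = occupied_elements.setdefault(site.feature_id, [])
        preferred = max(0, min(site.center - width // 2, feat.length - width))
        for delta in range(0, feat.length):
            for pos in (preferred - delta, preferred + delta):
                if pos < 0 or pos + width > feat.length:
                    continue
                if all(pos >= e or pos + width <= b for b, e in taken):
                    feat.sequence = _splice(feat.sequence, pos, pattern)
                    taken.append((pos, pos + width))
                    return pos
            if preferred - delta < 0 and preferred + delta + width > feat.length:
                break
        return None

    weights = np.array([0.5**i for i in range(len(mirna_items))])
    weights /= weights.sum()
    for site in study.sites[config.partner_protein]:
        pos = plant_in_site(site, _render_motif("UGUAnAUA", rng))
        if pos is not None:
            motif_positions.setdefault(site.feature_id, []).append(pos)
    for site in study.sites[config.focal_protein]:
        _name, mseq = mirna_items[int(rng.choice(len(mirna_items), p=weights))]
        pattern = seed_patterns(mseq)["8mer"]
        pos = plant_in_site(site, pattern)
        if pos is not None:
            seed_positions.setdefault(site.feature_id, []).append(pos)
    study.truth.motif_positions = {
        k: sorted(v) for k, v in motif_positions.items()
    }
    study.truth.seed_positions = {
        k: sorted(v) for k, v in seed_positions.items()
    }
    return study


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Emit a study in the exact on-disk formats the readers ingest.

    Writes per-protein site tables, the UTR table + FASTA, the mRNA LFC
    table, a design table and a ground-truth table; returns the paths.
    """
    from pathlib import Path

    from clipcoreg.core import write_fasta, write_sites

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    utr_table = outdir / "utrs.tsv"
    with open(utr_table, "w") as fh:
        for feat in study.features.values():
            fh.write(f"{feat.feature_id}\t{feat.length}\n")
    paths["utrs"] = str(utr_table)

    fasta = outdir / "utrs.fa"
    write_fasta(study.features, fasta)
    paths["fasta"] = str(fasta)

    for protein, sites in study.sites.items():
        p = outdir / f"sites_{protein}.tsv"
        write_sites(sites, p)
        paths[f"sites_{protein}"] = str(p)

    mrna = outdir / "mrna_lfc.tsv"
    with open(mrna, "w") as fh:
        fh.write("transcript_id\tcondition\tlog2fc\n")
        for tid, conds in study.mrna_lfc.items():
            for cond, v in conds.items():
                fh.write(f"{tid}\t{cond}\t{v:.6f}\n")
    paths["mrna_lfc"] = str(mrna)

    design = outdir / "design.tsv"
    with open(design, "w") as fh:
        fh.write("sample\tprotein\tcondition\treplicate\tlibrary_size\n")
        for protein, d in study.designs.items():
            for sample, (cond, rep) in d.samples.items():
                fh.write(
                    f"{sample}\t{protein}\t{cond}\t{rep}\t"
                    f"{d.library_size[sample]}\n"
                )
    paths["design"] = str(design)

    truth = outdir / "ground_truth.tsv"
    with open(truth, "w") as fh:
        fh.write("kind\tid\tvalue\n")
        for fid, c in study.truth.utr_class.items():
            fh.write(f"utr_class\t{fid}\t{c}\n")
        for sid, c in study.truth.site_class.items():
            fh.write(f"site_class\t{sid}\t{c}\n")
        for sid in sorted(study.truth.overlapping_partner_sites):
            fh.write(f"overlapping_partner\t{sid}\t1\n")
    paths["ground_truth"] = str(truth)
    return paths
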