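"""Pipeline orchestration: run configs, stage ordering, report output.

A run config (YAML or dict) names either a synthetic study to generate or
a set of input files, plus the analyses to perform.  Stages execute in
dependency order and write tab-delimited tables plus a machine-readable
``summary.json`` recording seeds and parameters sufficient to reproduce
the run byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from clipcoreg.core import (
    ClipCoregError,
    HostFeature,
    SampleDesign,
    filter_sites_by_count,
    read_host_features,
    read_mrna_lfc,
    read_sites,
)
from clipcoreg.cooccupancy import (
    density_profile,
    overlap_sites,
    overlap_zscore,
    utr_cooccupancy,
)
from clipcoreg.diffbind import (
    ks_class_compare,
    seed_repertoire_correlation,
    site_lfc_table,
    stratify_sites_by_overlap,
    utr_extremes,
)
from clipcoreg.motifs import scan_pum_motifs, scan_seed_complements
from clipcoreg.simulate import (
    DEFAULT_MIRNAS,
    SimConfig,
    SimulatedStudy,
    simulate_study,
    write_study,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("cooccupancy", "density", "lfc", "motifs", "repertoire")


def _load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise ClipCoregError("run config must be a mapping")
        return loaded
    return dict(config)


def load_study_from_files(inputs: Mapping[str, Any]) -> SimulatedStudy:
    """Assemble an in-memory study from the on-disk input formats."""
    features = read_host_features(
        inputs["utrs"], fasta_path=inputs.get("fasta")
    )
    if "mrna_lfc" in inputs:
        read_mrna_lfc(inputs["mrna_lfc"], features)
    sites = {
        protein: read_sites(path, features)
        for protein, path in inputs["sites"].items()
    }
    designs: dict[str, SampleDesign] = {}
    if "design" in inputs:
        df = pd.read_csv(inputs["design"], sep="\t")
        for protein, grp in df.groupby("protein"):
            designs[str(protein)] = SampleDesign(
                samples={
                    r["sample"]: (r["condition"], int(r["replicate"]))
                    for _, r in grp.iterrows()
                },
                library_size={
                    r["sample"]: int(r["library_size"])
                    for _, r in grp.iterrows()
                },
            )
    return SimulatedStudy(
        config=SimConfig(),
        features=features,
        sites=sites,
        designs=designs,
        mrna_lfc={f.transcript_id: dict(f.mrna_lfc) for f in features.values()},
        truth=None,  # type: ignore[arg-type]
    )


def run_pipeline(config: Mapping[str, Any] | str | Path) -> Path:
    """Execute the configured stages; returns the report directory.

    Config keys: ``outdir`` (required), ``seed`` (default 0), either
    ``simulate`` (SimConfig field overrides, possibly empty) or ``inputs``
    (paths: utrs, fasta, sites {protein: path}, mrna_lfc, design),
    ``analyses`` (subset of {cooccupancy, density, lfc, motifs,
    repertoire}; default all feasible), ``n_randomizations`` (default 100),
    ``min_count_filter`` (bool, default True).
    """
    cfg = _load_config(config)
    if "outdir" not in cfg:
        raise ClipCoregError("run config must name an 'outdir'")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    n_rand = int(cfg.get("n_randomizations", 100))
    analyses = tuple(cfg.get("analyses", ALL_STAGES))
    unknown = set(analyses) - set(ALL_STAGES)
    if unknown:
        raise ClipCoregError(f"unknown analyses: {sorted(unknown)}")

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    root = logging.getLogger("clipcoreg")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict[str, Any] = {"seed": seed, "analyses": list(analyses)}

    try:
        if "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"] or {})
            sim_kwargs.setdefault("rng_seed", seed)
            sim = SimConfig(**sim_kwargs)
            study = simulate_study(sim)
            write_study(study, outdir / "inputs")
            summary["sim_config"] = dataclasses.asdict(sim)
            logger.info("simulated study: %d UTRs, seed %d", sim.n_utrs, seed)
        elif "inputs" in cfg:
            study = load_study_from_files(cfg["inputs"])
            summary["inputs"] = {
                k: str(v) for k, v in cfg["inputs"].items() if k != "sites"
            }
        else:
            raise ClipCoregError(
                "run config must contain 'simulate' or 'inputs'"
            )

        if cfg.get("min_count_filter", True) and study.designs:
            for protein in list(study.sites):
                if protein in study.designs:
                    cutoff = study.designs[protein].n_samples
                    before = len(study.sites[protein])
                    study.sites[protein] = filter_sites_by_count(
                        study.sites[protein], cutoff
                    )
                    logger.info(
                        "%s: readcount cutoff %d kept %d/%d sites",
                        protein, cutoff, len(study.sites[protein]), before,
                    )

        if "lfc" in analyses:
            needs_mrna = any(f.mrna_lfc for f in study.features.values())
            if not needs_mrna:
                raise ClipCoregError(
                    "LFC normalization requested but no mRNA LFC table is "
                    "available"
                )

        results = run_analyses(
            study, outdir, analyses=analyses, n_randomizations=n_rand,
            seed=seed,
        )
        summary.update(results)
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    logger.info("report written to %s", outdir)
    return outdir


def run_analyses(
    study: SimulatedStudy,
    outdir: Path,
    analyses=ALL_STAGES,
    n_randomizations: int = 100,
    seed: int = 0,
) -> dict[str, Any]:
    """Run the requested analysis stages on an in-memory study."""
    out: dict[str, Any] = {}
    proteins = list(study.sites)
    features = study.features
    focal = study.config.focal_protein if study.config else proteins[0]
    partner = (
        study.config.partner_protein if study.config else proteins[-1]
    )
    if focal not in study.sites or partner not in study.sites:
        focal, partner = proteins[0], proteins[-1]

    if "cooccupancy" in analyses:
        classes = utr_cooccupancy(study.sites, features)
        venn_rows = [
            {
                "proteins": "+".join(sorted(k)) if k else "(none)",
                "n_features": v,
            }
            for k, v in classes.venn.items()
        ]
        pd.DataFrame(venn_rows).to_csv(
            outdir / "venn.tsv", sep="\t", index=False
        )
        znull = overlap_zscore(
            study.sites[focal], study.sites[partner], features,
            which="randomize_a", n=n_randomizations, rng_seed=seed,
        )
        pd.DataFrame([dataclasses.asdict(znull)]).to_csv(
            outdir / "overlap_zscore.tsv", sep="\t", index=False
        )
        pairs, c_focal, c_partner = overlap_sites(
            study.sites[focal], study.sites[partner]
        )
        out["cooccupancy"] = {
            "venn": {r["proteins"]: r["n_features"] for r in venn_rows},
            "n_overlap_pairs": len(pairs),
            f"n_{focal}_overlapping": c_focal,
            f"n_{partner}_overlapping": c_partner,
            "overlap_z": znull.z,
        }

    if "density" in analyses:
        prof = density_profile(
            study.sites[focal], study.sites[partner], features,
            window=500, bin=10, n=n_randomizations, rng_seed=seed,
        )
        pd.DataFrame(
            {
                "offset": prof.bin_centers,
                "observed": prof.observed,
                "null_mean": prof.null_mean,
                "null_sd": prof.null_sd,
            }
        ).to_csv(outdir / "density.tsv", sep="\t", index=False)
        peak = int(np.argmax(prof.observed))
        out["density"] = {
            "peak_offset": float(prof.bin_centers[peak]),
            "peak_excess_sd": float(
                (prof.observed[peak] - prof.null_mean[peak])
                / prof.null_sd[peak]
            )
            if prof.null_sd[peak] > 0
            else None,
        }

    if "lfc" in analyses and study.designs:
        design = study.designs[focal]
        control = "control"
        perturbed = [c for c in design.conditions if c != control][0]
        lfcs, excluded = site_lfc_table(
            study.sites[focal], features, design, control, perturbed
        )
        pd.DataFrame([dataclasses.asdict(s) for s in lfcs]).to_csv(
            outdir / f"site_lfc_{focal}.tsv", sep="\t", index=False
        )
        extremes = utr_extremes(lfcs)
        pd.DataFrame([dataclasses.asdict(e) for e in extremes]).to_csv(
            outdir / f"utr_extremes_{focal}.tsv", sep="\t", index=False
        )
        classes = utr_cooccupancy(study.sites, features)
        cobound = set(classes.bound_by(focal, partner))
        focal_only = {
            fid
            for fid in classes.bound_by(focal)
            if partner not in classes.membership[fid]
        }
        comparisons = []
        for stat in ("min_lfc", "max_lfc"):
            vals = {
                "cobound": [
                    getattr(e, stat) for e in extremes
                    if e.feature_id in cobound
                ],
                "focal_only": [
                    getattr(e, stat) for e in extremes
                    if e.feature_id in focal_only
                ],
            }
            cmp_res = ks_class_compare(vals, "cobound", "focal_only")
            comparisons.append(
                {
                    "statistic_compared": stat,
                    "class_a": "cobound",
                    "class_b": "focal_only",
                    "n_a": cmp_res.n[0],
                    "n_b": cmp_res.n[1],
                    "D": cmp_res.statistic,
                    "p": cmp_res.p_value,
                    "median_shift": float(
                        np.median(vals["cobound"])
                        - np.median(vals["focal_only"])
                    ),
                }
            )
        pd.DataFrame(comparisons).to_csv(
            outdir / "class_comparisons.tsv", sep="\t", index=False
        )
        out["lfc"] = {
            "n_sites": len(lfcs),
            "n_excluded_no_mrna": len(excluded),
            "comparisons": comparisons,
        }

        # reciprocal analysis: partner-site LFCs stratified by focal overlap
        if partner in study.designs:
            pdesign = study.designs[partner]
            ppert = [c for c in pdesign.conditions if c != control][0]
            plfcs, _ = site_lfc_table(
                study.sites[partner], features, pdesign, control, ppert
            )
            labels = stratify_sites_by_overlap(
                study.sites[partner], study.sites[focal]
            )
            vals = {
                "overlapping": [
                    s.normalized_lfc for s in plfcs if labels[s.site_id]
                ],
                "non_overlapping": [
                    s.normalized_lfc for s in plfcs if not labels[s.site_id]
                ],
            }
            strat = ks_class_compare(vals, "overlapping", "non_overlapping")
            out["lfc"]["overlap_stratified"] = {
                "D": strat.statistic,
                "p": strat.p_value,
                "median_shift": float(
                    np.median(vals["overlapping"])
                    - np.median(vals["non_overlapping"])
                ),
            }

    if "motifs" in analyses:
        rows = []
        n_hits = 0
        for feat in features.values():
            if feat.sequence is None:
                continue
            for h in scan_pum_motifs(feat, allow_degenerate=True):
                rows.append(dataclasses.asdict(h))
                n_hits += 1
        pd.DataFrame(rows).to_csv(
            outdir / "pum_motifs.tsv", sep="\t", index=False
        )
        out["motifs"] = {"n_hits": n_hits}

    if "repertoire" in analyses:
        matches = []
        for feat in features.values():
            if feat.sequence is not None:
                matches.extend(scan_seed_complements(feat, DEFAULT_MIRNAS))
        labels = stratify_sites_by_overlap(
            study.sites[focal], study.sites[partner]
        )
        g1 = [s for s in study.sites[focal] if labels[s.site_id]]
        g2 = [s for s in study.sites[focal] if not labels[s.site_id]]
        rho = None
        if g1 and g2:
            try:
                rho = seed_repertoire_correlation(g1, g2, matches)
            except ClipCoregError:
                rho = None
        out["repertoire"] = {
            "n_seed_matches": len(matches),
            "spearman_overlap_vs_not": rho,
        }
    return out
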