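"""Shared plumbing for the numbered analysis drivers.

The drivers operate on the synthetic reciprocal-perturbation study written
by ``01_simulate_study.py``; if it has not been generated yet it is
created on the fly with the same seed, so every driver is runnable on its
own and all of them see byte-identical inputs.
"""

from pathlib import Path

from clipcoreg.pipeline import load_study_from_files
from clipcoreg.simulate import SimConfig, simulate_study, write_study

SEED = 20260926
RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "study"


def get_study():
    """The in-memory study all drivers analyze (generated if missing)."""
    if not (STUDY_DIR / "design.tsv").exists():
        write_study(simulate_study(SimConfig(rng_seed=SEED)), STUDY_DIR)
    study = load_study_from_files(
        {
            "utrs": STUDY_DIR / "utrs.tsv",
            "fasta": STUDY_DIR / "utrs.fa",
            "mrna_lfc": STUDY_DIR / "mrna_lfc.tsv",
            "design": STUDY_DIR / "design.tsv",
            "sites": {
                "AGO2": STUDY_DIR / "sites_AGO2.tsv",
                "PUM": STUDY_DIR / "sites_PUM.tsv",
            },
        }
    )
    return study


def get_truth():
    """Ground-truth labels written alongside the study tables."""
    get_study()  # ensure files exist
    utr_class: dict[str, str] = {}
    site_class: dict[str, str] = {}
    overlapping: set[str] = set()
    with open(STUDY_DIR / "ground_truth.tsv") as fh:
        next(fh)
        for line in fh:
            kind, key, value = line.rstrip("\n").split("\t")
            if kind == "utr_class":
                utr_class[key] = value
            elif kind == "site_class":
                site_class[key] = value
            elif kind == "overlapping_partner":
                overlapping.add(key)
    return utr_class, site_class, overlapping
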