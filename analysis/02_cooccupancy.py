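"""Transcript- and site-level co-occupancy of AGO2 and PUM.

Counts the UTR-level Venn regions, the overlapping site pairs, and scores
the site overlap against a within-UTR randomization null (100 control
randomizations), writing results/venn.tsv and results/overlap_zscore.tsv.
"""

import dataclasses

import pandas as pd
from study_io import RESULTS, SEED, get_study

from clipcoreg.cooccupancy import overlap_sites, overlap_zscore, utr_cooccupancy


def main() -> None:
    study = get_study()
    ago2, pum = study.sites["AGO2"], study.sites["PUM"]

    occ = utr_cooccupancy(study.sites, study.features)
    rows = [
        {"proteins": "+".join(sorted(k)) or "(none)", "n_utrs": v}
        for k, v in occ.venn.items()
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "venn.tsv", sep="\t", index=False)
    print("UTR-level co-occupancy (Venn regions):")
    for r in rows:
        print(f"  {r['proteins']:>10}: {r['n_utrs']}")

    pairs, n_ago2, n_pum = overlap_sites(ago2, pum)
    print(
        f"\nsite-level overlap: {n_ago2}/{len(ago2)} AGO2 sites and "
        f"{n_pum}/{len(pum)} PUM sites overlap ({len(pairs)} pairs)"
    )

    res = overlap_zscore(
        ago2, pum, study.features, which="randomize_a", n=100, rng_seed=SEED
    )
    pd.DataFrame([dataclasses.asdict(res)]).to_csv(
        RESULTS / "overlap_zscore.tsv", sep="\t", index=False
    )
    print(
        f"within-UTR randomization null ({res.n_randomizations} controls): "
        f"mean {res.null_mean:.1f}, SD {res.null_sd:.1f} -> z = {res.z:.1f}"
    )
    print(
        "the observed overlap far exceeds the positional null, as expected "
        "for planted co-binding"
    )


if __name__ == "__main__":
    main()
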