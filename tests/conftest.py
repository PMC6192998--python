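import numpy as np
import pytest

from clipcoreg.core import BindingSite, HostFeature, SampleDesign


@pytest.fixture
def utr300():
    return HostFeature(
        feature_id="utrA", transcript_id="utrA", length=300,
        sequence="ACGU" * 75,
    )


@pytest.fixture
def simple_features():
    """Ten sequence-free hosts of length 100 for interval arithmetic."""
    return {
        f"f{i}": HostFeature(
            feature_id=f"f{i}", transcript_id=f"f{i}", length=100
        )
        for i in range(10)
    }


@pytest.fixture
def two_condition_design():
    samples = {}
    for cond in ("control", "perturbed"):
        for r in (1, 2, 3):
            samples[f"{cond}_{r}"] = (cond, r)
    return SampleDesign(
        samples=samples, library_size={s: 1_000_000 for s in samples}
    )


def make_site(site_id, feature_id, start, end, protein="AGO2", counts=None):
    return BindingSite(
        site_id=site_id, protein=protein, feature_id=feature_id,
        start=start, end=end, counts=counts or {},
    )


def random_sites(rng, features, n, protein, max_width=15):
    """Random valid sites for brute-force overlap comparisons."""
    fids = list(features)
    out = []
    for i in range(n):
        fid = fids[rng.integers(0, len(fids))]
        length = features[fid].length
        w = int(rng.integers(1, min(max_width, length) + 1))
        s = int(rng.integers(0, length - w + 1))
        out.append(make_site(f"{protein}_{i}", fid, s, s + w, protein))
    return out
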