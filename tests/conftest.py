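import numpy as np
import pytest
from hypothesis import settings
from scipy import ndimage

from munflow import wt_profile
from munflow.pipeline import run_cohort

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def wt_prof():
    return wt_profile()


@pytest.fixture(scope="session")
def wt_run(wt_prof):
    """One seeded wild-type cohort pushed through the full pipeline,
    shared by gating/classification/summary tests."""
    return run_cohort(wt_prof, 2000, seed=202)


def flood_fill_nuclearity(image, channel="Draq5", frac=0.45, min_px=4):
    """Independent oracle: count disjoint supra-threshold nuclear blobs on a
    (noiseless) raster by flood-fill labeling.

    Blobs are first grouped coarsely, then counted within each group at a
    threshold relative to the group's own peak, so staining halos (rendered
    well below the peak) and dim-versus-bright cells in one frame do not
    distort the count.  Deliberately independent of the morphometry chain.
    """
    a = image.channel(channel).astype(float)
    border = np.concatenate([a[0], a[-1], a[1:-1, 0], a[1:-1, -1]])
    sig = a - np.median(border)
    if sig.max() <= 0:
        return 0
    coarse = sig > max(1.0, 0.05 * sig.max())
    groups, n_groups = ndimage.label(coarse)
    total = 0
    for g in range(1, n_groups + 1):
        region = groups == g
        peak = sig[region].max()
        sub, n_sub = ndimage.label(region & (sig > frac * peak))
        for s in range(1, n_sub + 1):
            if (sub == s).sum() >= min_px:
                total += 1
    return total
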