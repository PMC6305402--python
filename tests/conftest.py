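import numpy as np
import pytest
from shapely.geometry import box

from immunocontext.global_features import CatalogConfig
from immunocontext.slide_model import RegionSet, SlideObjects

MARKER_POOL = ["Ki67", "CD4", "CD4", "CD8", "CD8"]


def make_random_slide(seed, n=120, edge=600.0, with_tumor=True, slide_id=None):
    """Small random slide with mixed cell types for oracle comparisons."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, edge, n)
    y = rng.uniform(0, edge, n)
    marker = rng.choice(MARKER_POOL, size=n)
    prolif = rng.random(n) < 0.4
    prolif[marker == "Ki67"] = True
    tumor = box(edge * 0.2, edge * 0.2, edge * 0.7, edge * 0.8) if with_tumor else None
    regions = RegionSet.from_annotations(tissue=box(0, 0, edge, edge), tumor=tumor)
    return SlideObjects.from_arrays(
        slide_id=slide_id or f"rand{seed}", regions=regions,
        x=x, y=y, marker=marker, prolif=prolif,
    )


@pytest.fixture
def random_slide():
    return make_random_slide(7)


@pytest.fixture(scope="session")
def default_config():
    return CatalogConfig()
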