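import numpy as np
import pytest

from ascopy import (
    GenomeLayout,
    SampleProfile,
    Segment,
    demo_specs,
    generate_cohort,
    synthetic_gene_annotation,
)


@pytest.fixture(scope="session")
def layout():
    return GenomeLayout.default()


@pytest.fixture(scope="session")
def layout_no_y():
    return GenomeLayout.default(include_y=False)


def make_profile(segs, sample="S1", **kw):
    """segs: (chrom, start, end, a, b) tuples."""
    return SampleProfile(
        sample, [Segment(sample, *s) for s in segs], **kw
    )


@pytest.fixture
def flat_diploid(layout):
    """A (1,1)-balanced genome tiling every arm of the default layout."""
    segs = [(arm.chrom, arm.start, arm.end, 1, 1) for arm in layout.arms]
    return make_profile(segs, sample="diploid")


@pytest.fixture(scope="session")
def demo_cohort(layout_no_y):
    """Small two-group cohort with matched expression and truth tables."""
    annotation = synthetic_gene_annotation(layout_no_y, n_genes=300, seed=7)
    return generate_cohort(
        layout_no_y, demo_specs(n_per_group=15), annotation,
        cis_fraction=0.2, beta=1.0, noise_sd=0.5, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
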