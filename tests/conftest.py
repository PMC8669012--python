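import numpy as np
import pytest

from histotile.synthetic import SyntheticSlideSpec, generate_cohort, generate_slide


@pytest.fixture(scope="session")
def slide_pair():
    """One S and one NS slide, 660x660, single fragment, no stain shift."""
    spec_s = SyntheticSlideSpec("S000", "S", 660, 660, n_fragments=1,
                                tumour_fraction=0.8, seed=11)
    spec_ns = SyntheticSlideSpec("NS000", "NS", 660, 660, n_fragments=1,
                                 tumour_fraction=0.8, seed=12)
    s_slide, s_anns = generate_slide(spec_s)
    ns_slide, ns_anns = generate_slide(spec_ns)
    return {"S": (s_slide, s_anns), "NS": (ns_slide, ns_anns)}


@pytest.fixture(scope="session")
def small_template():
    return SyntheticSlideSpec(
        "template", "NS", 660, 660, n_fragments=1, tumour_fraction=0.8,
        stain_shift=(0.1, 0.1, 0.1), seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory, small_template):
    """12-slide balanced cohort on disk (enough for a 60/20/20 split)."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(6, small_template, seed=3, out_dir=out)
    return manifest, out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
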