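import numpy as np
import pytest

from serialseg import PhantomSpec, SectionImage, generate_phantom
from serialseg.pipeline import run_chain


def make_section(pixels, z_index=0, pitch=(30.0, 30.0), spacing=30.0):
    return SectionImage(
        z_index=z_index,
        pixels=np.asarray(pixels, dtype=float),
        pixel_pitch=pitch,
        section_spacing_nm=spacing,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """Quick 3-tube phantom for unit-level checks."""
    spec = PhantomSpec(n_sections=16, section_shape=(256, 256), n_processes=3, seed=11)
    sections, truth = generate_phantom(spec)
    return spec, sections, truth


@pytest.fixture(scope="session")
def small_chain(small_phantom):
    spec, sections, truth = small_phantom
    table, recon, tau_log = run_chain(sections, equalize=False)
    return spec, sections, truth, table, recon, tau_log
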