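import numpy as np
import pytest

from chemseg.library import load_library
from chemseg.model import ChemSegModel, EncoderConfig
from chemseg.refine import RefineConfig
from chemseg.synthesis import SynthesisConfig, synthesize_pages


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def tiny_cfg():
    return EncoderConfig.tiny()


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    return ChemSegModel(tiny_cfg, seed=0)


@pytest.fixture()
def refine_cfg():
    return RefineConfig()


@pytest.fixture(scope="session")
def ten_pages():
    """Ten deterministic synthetic pages shared across training/pipeline tests."""
    return list(synthesize_pages(SynthesisConfig(n_pages=10, seed=7)))


@pytest.fixture(scope="session")
def twenty_pages():
    """The 20-page evaluation set used by round-trip tests."""
    return list(synthesize_pages(SynthesisConfig(n_pages=20, seed=11)))


def manifest_from_pairs(pairs):
    return [
        {
            "page": i,
            "placements": [
                {"kind": p.kind, "bbox": list(p.bbox), "angle": p.angle}
                for p in pair.placements
            ],
        }
        for i, pair in enumerate(pairs)
    ]


@pytest.fixture(scope="session")
def twenty_page_manifest(twenty_pages):
    return manifest_from_pairs(twenty_pages)
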