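import numpy as np
import pandas as pd
import pytest

from hcscreen import synthgen as sg
from hcscreen.imaging import measure_cells, segment_field


@pytest.fixture(scope="session")
def rendered_field():
    """One rendered disease-preset field with ground truth (shared, read-only)."""
    disease, _ = sg.preset_pair("neuroblastoma_cargo")
    return sg.render_field(disease, n_cells=20, image_shape=(512, 512), seed=3)


@pytest.fixture(scope="session")
def measured_cells(rendered_field):
    field, _ = rendered_field
    seg = segment_field(field)
    return measure_cells(field, seg)


@pytest.fixture(scope="session")
def null_screen_wells():
    """Six-plate tabular screen of inactive compounds (primary-stage presets)."""
    disease, control = sg.preset_pair("fibroblast_primary")
    presets = {sg.ROLE_NEGATIVE: disease, sg.ROLE_POSITIVE: control}
    cids = [f"C{i:04d}" for i in range(352)]
    effects = {c: sg.CompoundEffect(c, efficacy=0.0) for c in cids}
    layout = sg.make_layout(384, 16, [(c, 10.0) for c in cids])
    return sg.simulate_well_table(layout, presets, effects, n_plates=6, seed=11)
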