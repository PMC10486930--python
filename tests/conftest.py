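import numpy as np
import pytest

from gliaquant import mitoquant


def match_planted(stack, truth, **quant_kwargs):
    """Run the detection pipeline and map detected components onto planted
    puncta by voxel overlap.

    Returns ``(detected_enclosed_ids, true_enclosed_ids, n_components,
    n_planted)`` where ids refer to the planted puncta.  Asserts that every
    detected component overlaps exactly one planted punctum.
    """
    _, records, comps = mitoquant.quantify_stack(stack, **quant_kwargs)
    planted = {r.id: set(map(tuple, r.voxels)) for r in truth.mito_records}
    detected_enclosed = set()
    for comp, rec in zip(comps.components, records):
        voxels = set(map(tuple, comp.coords))
        hits = [pid for pid, pv in planted.items() if voxels & pv]
        assert len(hits) == 1, f"component overlaps {len(hits)} planted puncta"
        if rec.enclosed:
            detected_enclosed.add(hits[0])
    true_enclosed = {r.id for r in truth.mito_records if r.planted_enclosed}
    return detected_enclosed, true_enclosed, len(comps.components), len(planted)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
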