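import numpy as np
import pytest

import cytograd as cg


@pytest.fixture(scope="session")
def reference_result():
    """Converged deterministic steady state of the shipped 14-cell reference."""
    res = cg.run_to_steady_state(cg.reference_params())
    assert res.converged
    return res


@pytest.fixture(scope="session")
def reference12_result():
    """The 12-cell D-P-axis variant of the reference configuration."""
    res = cg.run_to_steady_state(cg.reference_params(n_cells=12))
    assert res.converged
    return res


@pytest.fixture(scope="session")
def small_scene():
    """A small deterministic scene shared by read-only tests."""
    cfg = cg.SceneConfig(n_cells=8, seed=11,
                         gradient=cg.GradientConfig(Cmax=100.0, lam=25.0))
    stack, truth = cg.render_scene(cfg)
    return cfg, stack, truth


def average_profile(configs, channel="ligand"):
    """Mean of band profiles over replicate scenes (trend-fit input)."""
    profs = []
    for cfg in configs:
        stack, _ = cg.render_scene(cfg)
        mid = cg.axis_midline(cfg.axis_length)
        profs.append(cg.extract_profile(stack, mid, channel=channel))
    n = min(len(p.values) for p in profs)
    vals = np.mean([p.values[:n] for p in profs], axis=0)
    return cg.profile_from_values(profs[0].positions[:n], vals)
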