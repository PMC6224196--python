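import dataclasses

import numpy as np
import pytest

import cytograd as cg
from cytograd.model import class_proportions, expected_long_counts


def _params(**kw):
    return cg.reference_params(**kw)


# --------------------------------------------------------------------------
# single-step and fixed-point arithmetic
# --------------------------------------------------------------------------

def test_first_step_from_rest_is_pure_uptake():
    """One step from the all-zero state: C_1 = u * B * n * p(1) * S * a."""
    p = _params()
    st0 = cg.initial_state(p)
    st1 = cg.step(st0, p)
    pc = p.p_contact()
    demand = float(np.sum(p.uptake * st0.B * st0.n * pc))
    avail = 1.0 / (1.0 + demand / p.demand_half)
    expected = p.uptake * p.B_base * p.n_base * pc[0] * p.source_strength * avail
    assert st1.C[0] == pytest.approx(expected, rel=1e-12)


def test_no_source_decays_to_repressed_resting_state():
    p = _params(source_strength=0.0)
    res = cg.run_to_steady_state(p)
    assert res.converged
    st = res.state
    assert np.allclose(st.C, 0.0, atol=1e-6)
    assert np.allclose(st.P, 0.0, atol=1e-6)
    # with no ligand, the repressors derepress fully and emission floors out
    assert np.all(st.K > 0.9)
    assert np.all(st.Y > 0.9)
    assert np.allclose(st.n, p.n_floor)


def test_geometric_fixed_point_without_feedback():
    """With all feedback gains zero and an unlimited source, steady C is the
    closed-form geometric profile u*B*n*p(d)*S / delta."""
    p = _params(alpha_n=0.0, beta_n=0.0, gamma_n=0.0,
                alpha_B=0.0, beta_B=0.0, gamma_B=0.0,
                demand_half=float("inf"))
    res = cg.run_to_steady_state(p)
    assert res.converged
    expected = (p.uptake * p.B_base * p.n_base * p.p_contact()
                * p.source_strength / p.decay_C)
    assert np.allclose(res.state.C, expected, rtol=1e-6)


def test_mass_bookkeeping_closes():
    res = cg.run_to_steady_state(_params())
    st = res.state
    assert abs(st.C.sum() - (st.cum_uptake - st.cum_decay)) < 1e-9


def test_reference_converges_with_monotone_gradient(reference_result):
    st = reference_result.state
    assert np.all(np.diff(st.C) < 0)
    assert np.all(st.n >= _params().n_floor)


def test_symmetric_two_sided_source_gives_mirror_steady_state():
    p = _params()
    p = cg.apply_clone(p, None, "ectopic_source",
                       position=p.n_cells * p.cell_diameter,
                       strength=1.0, range=p.contact_range)
    res = cg.run_to_steady_state(p)
    assert res.converged
    for v in (res.state.C, res.state.P, res.state.K, res.state.n):
        assert np.allclose(v, v[::-1], rtol=1e-6, atol=1e-9)


def test_non_finite_state_aborts_with_diagnostic():
    p = _params()
    st = cg.initial_state(p)
    st.C[3] = np.nan
    with pytest.raises(FloatingPointError, match="NaN"):
        cg.step(st, p)


# --------------------------------------------------------------------------
# feedback signs and invariants
# --------------------------------------------------------------------------

def test_positive_feedback_gain_raises_tip_ligand(reference_result):
    C1 = reference_result.state.C[0]
    up = cg.run_to_steady_state(_params(alpha_n=0.4, alpha_B=0.3)).state.C[0]
    assert up > C1


def test_negative_feedback_gains_lower_proximal_ligand():
    """The feedback sign in isolation: with an unlimited source (no
    demand sharing) and the emission floor relaxed, stronger Cut / Yan
    gains strictly lower steady ligand in their expression domains."""
    base = _params(demand_half=float("inf"), n_floor=1e-3, long_floor=1e-3)
    C = cg.run_to_steady_state(base).state.C
    st_b = cg.run_to_steady_state(dataclasses.replace(base, beta_n=0.8)).state
    st_g = cg.run_to_steady_state(dataclasses.replace(base, gamma_n=0.5)).state
    assert np.all(st_b.C[8:] < C[8:])
    assert np.all(st_g.C[11:] < C[11:])


def test_mutual_inhibition_exclusivity(reference_result):
    st = reference_result.state
    assert not np.any((st.P > 0.9) & (st.K > 0.9))


def test_stochastic_contacts_preserve_expected_uptake():
    """A single stochastic step has the deterministic step as its mean."""
    p = _params()
    st0 = cg.initial_state(p)
    det = cg.step(st0, p)
    p_s = dataclasses.replace(p, mode="stochastic")
    rng = np.random.default_rng(0)
    draws = np.array([cg.step(st0, p_s, rng).C for _ in range(4000)])
    se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
    assert np.all(np.abs(draws.mean(axis=0) - det.C) <= 4 * se + 1e-12)


# --------------------------------------------------------------------------
# readouts
# --------------------------------------------------------------------------

def test_reference_expression_domains(reference_result):
    dom = cg.expression_domains(reference_result)
    assert dom.domain("sty") == (1, 3)
    assert dom.domain("pntP1") == (1, 7)
    assert dom.domain("cut") == (7, 14)
    assert dom.domain("yan") == (11, 14)
    assert dom.table["contiguous"].all()
    # sty domain nested in the pntP1 domain
    s, p = dom.domain("sty"), dom.domain("pntP1")
    assert s[0] >= p[0] and s[1] <= p[1]


def test_all_off_gene_yields_empty_domain():
    res = cg.run_to_steady_state(_params(source_strength=0.0))
    dom = cg.expression_domains(res)
    assert dom.domain("sty") == (None, None)
    assert dom.domain("cut") == (1, 14)


def test_long_cytoneme_zone_spans_seven_cells(reference12_result):
    nl = expected_long_counts(reference12_result.params, reference12_result.state)
    above = nl > nl[-1]
    zone = 0
    while zone < len(above) and above[zone]:
        zone += 1
    assert zone == 7
    # proximal cells share the clamped stalk baseline exactly
    assert np.allclose(nl[7:], nl[-1])


def test_class_proportions_sum_to_one(reference_result):
    props = class_proportions(reference_result.params, reference_result.state.P,
                              reference_result.state.K, reference_result.state.Y)
    assert np.allclose(props.sum(axis=1), 1.0)
    assert np.all(props >= 0)


# --------------------------------------------------------------------------
# clones and perturbations
# --------------------------------------------------------------------------

def test_conflicting_clone_overrides_rejected():
    p = cg.apply_clone(_params(), [2, 3], "cut_GOF")
    with pytest.raises(ValueError, match="conflict"):
        cg.apply_clone(p, [3], "pnt_GOF")


def test_unknown_override_rejected():
    with pytest.raises(ValueError):
        cg.apply_clone(_params(), [1], "nonsense_GOF")


def test_cut_gof_tip_clone_suppresses_cytonemes_and_uptake(reference_result):
    st0 = reference_result.state
    st = cg.run_to_steady_state(
        cg.apply_clone(_params(), [1, 2, 3], "cut_GOF")).state
    assert np.all(st.n[:3] < st0.n[:3])
    assert np.all(st.C[:3] < st0.C[:3])


def test_pnt_gof_stalk_clone_induces_long_cytonemes_and_uptake(reference_result):
    st0 = reference_result.state
    params = _params()
    st = cg.run_to_steady_state(cg.apply_clone(params, [9, 10], "pnt_GOF")).state
    sel = slice(8, 10)
    assert np.all(st.n[sel] > st0.n[sel])
    assert np.all(st.C[sel] > st0.C[sel])
    assert np.all(expected_long_counts(params, st)[sel]
                  > expected_long_counts(params, st0)[sel])


def test_btl_lof_clone_loses_ligand_autonomously(reference_result):
    st0 = reference_result.state
    st = cg.run_to_steady_state(cg.apply_clone(_params(), [11, 12], "btl_LOF")).state
    assert np.all(st.C[10:12] < 1e-12)
    others = [i for i in range(14) if i not in (10, 11)]
    assert np.all(np.abs(st.C[others] / st0.C[others] - 1.0) < 0.05)


def test_ectopic_source_creates_local_signaling_center(reference_result):
    res = cg.run_to_steady_state(cg.apply_clone(
        _params(), None, "ectopic_source", position=105.0, strength=1.0))
    C = res.state.C
    i = 10  # cell 11 at d = 105 um
    assert C[i] > C[i - 1] and C[i] > C[i + 1]
    st = res.state
    assert st.P[i] >= 0.5 * st.P.max()          # pntP1 ON near the new source
    assert st.K[i] < 0.5 * st.K.max()           # cut locally OFF


def test_source_overexpression_retracts_repressor_domains(reference_result):
    dom0 = cg.expression_domains(reference_result)
    res = cg.run_to_steady_state(cg.apply_clone(
        _params(), None, "source_overexpression", factor=5.0))
    dom = cg.expression_domains(res)
    assert dom.domain("cut")[0] > dom0.domain("cut")[0]
    assert dom.domain("yan")[0] > dom0.domain("yan")[0]


# --------------------------------------------------------------------------
# scaling and export
# --------------------------------------------------------------------------

def test_minimal_axis_converges():
    table = cg.scaling_experiment(_params(), [4])
    assert table["converged"].all()


def test_scaling_requires_four_cells():
    with pytest.raises(ValueError):
        cg.scaling_experiment(_params(), [3])


def test_export_scene_round_trip(reference_result):
    cfg = cg.export_scene_config(reference_result)
    fit_direct = cg.fit_exponential(reference_result.profile)
    stack, _ = cg.render_scene(cfg)
    prof = cg.extract_profile(stack, cg.axis_midline(cfg.axis_length),
                              channel="ligand")
    fit_scene = cg.fit_exponential(prof)
    assert fit_scene.lam == pytest.approx(fit_direct.lam, rel=0.10)


def test_export_zero_ligand_gives_empty_scene():
    res = cg.run_to_steady_state(_params(source_strength=0.0))
    cfg = cg.export_scene_config(res)
    assert np.allclose(cfg.per_cell_intensity, 0.0)
    _, truth = cg.render_scene(cfg)
    assert len(truth.puncta) == 0


def test_export_marks_clone_cells():
    res = cg.run_to_steady_state(cg.apply_clone(_params(), [4, 5], "cut_GOF"))
    cfg = cg.export_scene_config(res)
    assert [tuple(c.cell_range) for c in cfg.clones] == [(4, 5)]


def test_sim_params_yaml_roundtrip(tmp_path):
    p = _params()
    path = tmp_path / "params.yaml"
    cg.save_sim_params(p, path)
    assert cg.load_sim_params(path) == p
    with pytest.raises(ValueError, match="unknown"):
        path.write_text(path.read_text() + "\nbogus_key: 1\n")
        cg.load_sim_params(path)


def test_threshold_ordering_enforced():
    with pytest.raises(ValueError, match="theta"):
        _params(theta_P=10.0)  # would exceed theta_sty
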