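"""Calibrate and freeze the reference feedback-simulator configuration.

Structural choices (functional forms, feedback gains, geometry, source
coupling) are fixed here as design constants.  The four gene-response
thresholds are then solved by bisection so that the deterministic 14-cell
steady state places the expression-domain boundaries at sty 1-3, pntP1 1-7,
cut 7-14 and yan 11-14 under the half-maximum ON rule, and the cytoneme
floors are placed between the cell-7 and cell-8 feedback responses of the
12-cell run so that the distal zone of above-baseline long source-oriented
cytonemes spans exactly 7 cells.  The result is written to
``src/cytograd/data/reference.yaml`` and version-controlled; the package
never re-runs this script at analysis time.

Run from the repository root:  python scripts/calibrate_reference.py
"""

from __future__ import annotations

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cytograd.model import (SimParams, expected_long_counts, expression_domains,
                            run_to_steady_state, save_sim_params,
                            scaling_experiment)

OUT = Path(__file__).resolve().parents[1] / "src" / "cytograd" / "data" / "reference.yaml"

# structural design constants (see docs/methods.md for rationale)
BASE = dict(
    n_cells=14, cell_diameter=10.0, contact_range=55.0,
    source_strength=13.0, demand_half=1.2, uptake=1.0, decay_C=0.3,
    hill_sty=3.0, hill_P=3.0, hill_K=1.0, hill_Y=2.0,
    w_KP=0.2, w_PK=0.05, w_PY=0.2,
    n_base=1.0, alpha_n=0.2, beta_n=0.4, gamma_n=0.15, n_cap=3.0,
    B_base=1.0, alpha_B=0.16, beta_B=0.25, gamma_B=0.1, B_floor=0.2, B_cap=3.0,
    long_base=0.1, long_P=0.6, long_K=0.5, long_Y=0.15, long_cap=0.9,
    short_of_rest=0.65,
    relax_rate=0.2, tol=1e-8, max_steps=100_000,
)

TARGETS = {"sty": ("last", 3), "pntP1": ("last", 7), "cut": ("first", 7),
           "yan": ("first", 11)}
THETA_OF = {"sty": "theta_sty", "pntP1": "theta_P", "cut": "theta_K",
            "yan": "theta_Y"}


def boundary(params: SimParams, gene: str) -> int:
    res = run_to_steady_state(params)
    dom = expression_domains(res)
    first, last = dom.domain(gene)
    kind, _ = TARGETS[gene]
    return (last if kind == "last" else first) or 0


def bisect_theta(params: SimParams, gene: str, lo: float, hi: float,
                 iters: int = 40) -> float:
    """Find a threshold placing the gene's domain boundary at its target.

    For the activated genes (sty, pntP1) a rising threshold shrinks the ON
    domain; for the derepressed genes (cut, yan) it extends the ON region
    distally.  Either way the boundary index is non-increasing in theta, so
    there is a theta-plateau on which the boundary equals the target; both
    plateau edges are located by bisection and the geometric center is
    taken, clipped to the allowed [lo, hi] ordering window.
    """
    _, target = TARGETS[gene]
    name = THETA_OF[gene]

    def b_of(theta: float) -> int:
        return boundary(replace(params, **{name: theta}), gene)

    def smallest_theta_with(level: int, lo_: float, hi_: float) -> float:
        """Smallest theta in [lo_, hi_] with boundary <= level (hi_ if none
        exists below; lo_ if already satisfied at lo_)."""
        if b_of(lo_) <= level:
            return lo_
        if b_of(hi_) > level:
            return hi_
        a, b = lo_, hi_
        for _ in range(iters):
            mid = np.sqrt(a * b)
            if b_of(mid) <= level:
                b = mid
            else:
                a = mid
        return b

    edge_in = smallest_theta_with(target, lo, hi)      # enters the plateau
    edge_out = smallest_theta_with(target - 1, edge_in, hi)  # leaves it
    theta = float(np.sqrt(edge_in * edge_out))
    got = b_of(theta)
    if got != target:
        raise RuntimeError(f"{gene}: boundary {got} != target {target} at "
                           f"theta={theta:.4g} (plateau [{edge_in:.4g}, {edge_out:.4g}])")
    return theta


def place_floors(params: SimParams) -> SimParams:
    """Put n_floor / long_floor between the raw cell-7 and cell-8 responses
    of the 12-cell run, so cells 8+ clamp to a common stalk baseline."""
    st = run_to_steady_state(replace(params, n_cells=12)).state
    g = params.n_base + params.alpha_n * st.P - params.beta_n * st.K \
        - params.gamma_n * st.Y
    f = params.long_base + params.long_P * st.P - params.long_K * st.K \
        - params.long_Y * st.Y
    n_floor = float(np.sqrt(max(g[7], 1e-3) * g[6]))
    long_floor = float(np.sqrt(max(f[7], 1e-3) * f[6]))
    return replace(params, n_floor=n_floor, long_floor=long_floor)


def long_zone(params: SimParams) -> int:
    res = run_to_steady_state(replace(params, n_cells=12))
    nl = expected_long_counts(params, res.state)
    above = nl > nl[-1]
    k = 0
    while k < len(above) and above[k]:
        k += 1
    return k


def main() -> None:
    params = SimParams(theta_sty=3.0, theta_P=1.0, theta_K=0.7, theta_Y=0.25,
                       n_floor=0.05, long_floor=0.02, **BASE)
    for cycle in range(3):
        # brackets stay strictly inside the theta ordering of the neighbours
        for gene in ("sty", "pntP1", "cut", "yan"):
            name = THETA_OF[gene]
            lo, hi = getattr(params, name) / 20, getattr(params, name) * 20
            if gene == "sty":
                lo = max(lo, params.theta_P * 1.02)
            elif gene == "pntP1":
                lo, hi = max(lo, params.theta_K * 1.02), min(hi, params.theta_sty * 0.98)
            elif gene == "cut":
                lo, hi = max(lo, params.theta_Y * 1.02), min(hi, params.theta_P * 0.98)
            else:
                hi = min(hi, params.theta_K * 0.98)
            theta = bisect_theta(params, gene, lo=lo, hi=hi)
            params = replace(params, **{name: theta})
            print(f"cycle {cycle}: {name} = {theta:.5f}")
        params = place_floors(params)
        print(f"cycle {cycle}: n_floor = {params.n_floor:.5f}, "
              f"long_floor = {params.long_floor:.5f}")

    # ---- verification ----------------------------------------------------
    res = run_to_steady_state(params)
    dom = expression_domains(res)
    print(dom.table.to_string(index=False))
    assert dom.domain("sty") == (1, 3)
    assert dom.domain("pntP1") == (1, 7)
    assert dom.domain("cut") == (7, 14)
    assert dom.domain("yan") == (11, 14)
    zone = long_zone(params)
    print("12-cell long-cytoneme zone:", zone)
    assert zone == 7
    scal = scaling_experiment(params, [6, 8, 10, 12, 14])
    print(scal.to_string(index=False))
    assert np.all(np.diff(scal["slope"]) < 0), "slopes not strictly decreasing"
    assert not (params.theta_sty <= params.theta_P or params.theta_P <= params.theta_K
                or params.theta_K <= params.theta_Y)

    save_sim_params(replace(params, clones=[], ectopic_sources=[]), OUT)
    print("wrote", OUT)


if __name__ == "__main__":
    main()
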