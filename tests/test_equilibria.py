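"""Equilibria, regime classification, stability and bifurcation direction."""

import numpy as np
import pytest

from gangdyn import (
    State,
    assess_stability,
    bifurcation_direction,
    classify_existence,
    endemic_coefficients,
    eta_star,
    beta_star,
    gang_free_equilibrium,
    gang_free_point,
    gang_reproduction_number,
    jacobian,
    rg_star,
    rhs_array,
    solve_endemic,
)
from gangdyn.equilibria import gang_free_quadratic_factor

from conftest import sample_parameters


def numeric_jacobian(params, state, step=1e-7):
    """Central finite differences of the vector field."""
    y0 = state.as_array()
    out = np.empty((4, 4))
    for j in range(4):
        h = step * max(1.0, abs(y0[j]))
        hi, lo = y0.copy(), y0.copy()
        hi[j] += h
        lo[j] -= h
        out[:, j] = (rhs_array(hi, params) - rhs_array(lo, params)) / (2 * h)
    return out


# ---------------------------------------------------------------- gang-free


def test_gang_free_equilibrium_fig2(fig2):
    state = gang_free_equilibrium(fig2)
    assert state.Sn == pytest.approx(0.125333, abs=1e-6)
    assert state.Sr == pytest.approx(2.224667, abs=1e-6)
    assert state.G == 0.0 and state.C == 0.0


def test_gang_free_equilibrium_is_a_root(rng):
    for _ in range(20):
        params = sample_parameters(rng)
        state = gang_free_equilibrium(params)
        assert np.max(np.abs(rhs_array(state.as_array(), params))) < 1e-12 * max(1.0, params.Lambda)


def test_gang_free_sn_vanishes_when_all_entrants_at_risk(fig2):
    assert gang_free_equilibrium(fig2.replace(p=0.0)).Sn == 0.0


# ------------------------------------------------------- endemic quadratic


def test_endemic_coefficients_fig2(fig2):
    coef = endemic_coefficients(fig2)
    assert coef.a == pytest.approx(-0.00663, abs=1e-6)
    assert coef.b == pytest.approx(0.0017396, abs=1e-6)
    assert coef.c == pytest.approx(-5.194e-5, abs=1e-8)
    assert coef.disc > 0 and coef.disc_normalized > 0


def test_coefficient_sign_structure(rng):
    """a < 0 for eta > 0; sign(c) = sign(Rg - 1)."""
    for _ in range(100):
        params = sample_parameters(rng)
        coef = endemic_coefficients(params)
        assert coef.a < 0
        assert np.sign(coef.c) == np.sign(gang_reproduction_number(params) - 1.0)


def test_linear_coefficient_vanishes_at_eta_star(fig2):
    assert abs(endemic_coefficients(fig2.replace(eta=eta_star(fig2))).b) < 1e-12


def test_constant_coefficient_vanishes_at_beta_star(fig2):
    assert abs(endemic_coefficients(fig2.replace(beta=beta_star(fig2))).c) < 1e-12


def test_solve_endemic_fig2_roots(fig2):
    """Two admissible roots; cross-checked against numpy's root finder."""
    points = solve_endemic(fig2)
    roots = [pt.state.G for pt in points]
    coef = endemic_coefficients(fig2)
    oracle = sorted(r for r in np.roots([coef.a, coef.b, coef.c]) if r > 0)
    assert roots == pytest.approx(oracle, rel=1e-10)
    assert roots == pytest.approx([0.034352, 0.228037], abs=1e-5)


def test_solve_endemic_back_substitution(fig2, rng):
    for params in [fig2] + [sample_parameters(rng) for _ in range(50)]:
        for pt in solve_endemic(params):
            assert pt.residual < 1e-9 * params.Lambda
            assert min(pt.state.Sn, pt.state.Sr, pt.state.G, pt.state.C) >= 0


def test_solve_endemic_bilinear_unique_root(fig2):
    """eta = 0 with Rg > 1: the quadratic degenerates to one positive root."""
    params = fig2.replace(eta=0.0, beta=0.5)  # Rg ~ 1.37
    assert gang_reproduction_number(params) > 1
    points = solve_endemic(params)
    coef = endemic_coefficients(params)
    assert len(points) == 1
    assert points[0].state.G == pytest.approx(-coef.c / coef.b, rel=1e-12)


def test_solve_endemic_empty_below_fold(fig2):
    """Deep subthreshold (Rg < 1 - Rg*) leaves no gang-persistent state."""
    params = fig2.replace(beta=0.15)
    assert gang_reproduction_number(params) < 1 - rg_star(params)
    assert params.eta > eta_star(params)
    assert solve_endemic(params) == []


def test_tangent_root_at_fold(fig2):
    """Tuning beta onto the fold Rg = 1 - Rg* merges the two roots.

    Both Rg and Rg* are linear in beta, so the fold is at
    beta = beta_now / (Rg + Rg*)."""
    k = gang_reproduction_number(fig2) + rg_star(fig2)
    fold = fig2.replace(beta=fig2.beta / k)
    coef = endemic_coefficients(fold)
    assert abs(coef.disc_normalized) < 1e-10
    points = solve_endemic(fold)
    assert len(points) == 1
    assert points[0].state.G == pytest.approx(-coef.b / (2 * coef.a), rel=1e-6)


# ---------------------------------------------------------------- regimes


@pytest.mark.parametrize(
    "changes,label,n_roots",
    [
        ({}, "H2iii_two", 2),                      # eta=10 > eta*, fold < Rg < 1
        ({"eta": 0.0, "beta": 0.5}, "H1_unique", 1),
        ({"beta": 0.5}, "H2i_unique", 1),          # eta > eta*, Rg > 1
        ({"eta": 1.0, "beta": 0.5}, "H2ii_unique", 1),
        ({"beta": 0.15}, "H2iv_none", 0),          # Rg < 1 - Rg*
        ({"eta": 1.0}, "H2v_none", 0),             # eta < eta*, Rg < 1
        ({"eta": 0.0}, "H2v_none", 0),             # bilinear, Rg < 1
    ],
)
def test_classify_existence_regimes(fig2, changes, label, n_roots):
    params = fig2.replace(**changes)
    regime = classify_existence(params)
    assert regime.label == label
    assert len(regime.witnesses) == n_roots == regime.predicted_roots


def test_regime_agrees_with_root_count_on_random_sets(rng):
    for _ in range(200):
        params = sample_parameters(rng)
        regime = classify_existence(params)
        if not regime.boundary:
            assert len(regime.witnesses) == regime.predicted_roots, params


# ---------------------------------------------------------------- Jacobian


def test_jacobian_printed_entries_at_gang_free(fig2):
    J = jacobian(fig2, gang_free_equilibrium(fig2))
    q = fig2
    sr0 = gang_free_equilibrium(q).Sr
    assert J[0, 0] == pytest.approx(-(q.theta + q.mu))
    assert J[0, 3] == pytest.approx(q.nu * q.epsilon * q.sigma1)
    assert J[1, 0] == pytest.approx(q.theta)
    assert J[1, 2] == pytest.approx(q.sigma2 - q.beta * sr0)
    assert J[2, 1] == 0.0  # d(force)/dSr vanishes at G = 0
    assert J[2, 2] == pytest.approx(q.beta * sr0 - (q.mu + q.gamma + q.sigma2))
    assert J[3, 2] == pytest.approx(q.gamma)
    assert J[3, 3] == pytest.approx(-(q.mu + q.sigma1))


def test_jacobian_matches_finite_differences(rng):
    for _ in range(20):
        params = sample_parameters(rng)
        state = State(*rng.uniform(0, 5, size=4))
        assert jacobian(params, state) == pytest.approx(
            numeric_jacobian(params, state), abs=1e-6
        )


# --------------------------------------------------------------- stability


def test_gang_free_stable_iff_rg_below_one(rng):
    for _ in range(100):
        params = sample_parameters(rng)
        rg = gang_reproduction_number(params)
        if abs(rg - 1) < 1e-6:
            continue
        point = gang_free_point(params)
        assert point.stability == ("stable" if rg < 1 else "unstable")


def test_gang_free_spectrum_structure(fig2):
    """Eigenvalues contain -(mu+theta) and -mu; the other two solve the
    quadratic factor with the Q1, Q2, Q3 intermediates."""
    point = gang_free_point(fig2)
    eig = sorted(point.eigenvalues.real)
    q = fig2
    for expected in (-(q.mu + q.theta), -q.mu):
        assert min(abs(e - expected) for e in eig) < 1e-9
    lin, const = gang_free_quadratic_factor(fig2)
    quad_roots = np.roots([1.0, lin, const])
    remaining = [e for e in eig if min(abs(e + q.mu + q.theta), abs(e + q.mu)) > 1e-9]
    assert sorted(remaining) == pytest.approx(sorted(quad_roots.real), abs=1e-9)


def test_bistable_branch_stability_at_printed_set(fig2):
    """At the example set (beta = 0.3) the lower root is a saddle and the
    upper root is an *unstable spiral*: a Hopf bifurcation sits inside the
    bistable window, so the gang-persistent attractor there is a limit
    cycle around the upper root, while the gang-free state stays stable.

    Frozen eigenvalues confirmed by exact rational arithmetic:
    lower root max Re = +0.073270, upper root 0.023881 +/- 0.279342i.
    """
    lower, upper = (assess_stability(fig2, pt) for pt in solve_endemic(fig2))
    assert lower.stability == "unstable"
    assert max(lower.eigenvalues.real) == pytest.approx(0.073270, abs=1e-6)
    assert upper.stability == "unstable"
    pair = upper.eigenvalues[np.abs(upper.eigenvalues.imag) > 1e-12]
    assert pair.real.max() == pytest.approx(0.023881, abs=1e-6)
    assert abs(pair.imag).max() == pytest.approx(0.279342, abs=1e-6)
    assert gang_free_point(fig2).stability == "stable"


@pytest.mark.filterwarnings("ignore::DeprecationWarning")
def test_endemic_spectrum_exact_arithmetic(fig2):
    """Exact rational-arithmetic oracle for the endemic spectrum.

    Rebuilds the vector field symbolically with exact rationals, solves
    for the positive equilibria and their eigenvalues, and checks the
    floating-point pipeline against them — in particular the positive
    real part of the upper root's complex pair (the Hopf instability)."""
    sympy = pytest.importorskip("sympy")
    vals = {k: sympy.Rational(str(v)) for k, v in fig2.as_dict().items()}
    Sn, Sr, G, C = sympy.symbols("Sn Sr G C")
    force = vals["beta"] * G * (1 + vals["eta"] * G) * Sr
    f = sympy.Matrix(
        [
            vals["p"] * vals["Lambda"] + vals["nu"] * vals["epsilon"] * vals["sigma1"] * C
            - (vals["mu"] + vals["theta"]) * Sn,
            (1 - vals["p"]) * vals["Lambda"] + vals["theta"] * Sn + vals["sigma2"] * G
            + (1 - vals["nu"]) * vals["epsilon"] * vals["sigma1"] * C - force - vals["mu"] * Sr,
            force + (1 - vals["epsilon"]) * vals["sigma1"] * C
            - (vals["mu"] + vals["sigma2"] + vals["gamma"]) * G,
            vals["gamma"] * G - (vals["mu"] + vals["sigma1"]) * C,
        ]
    )
    exact = []
    for sol in sympy.solve(list(f), [Sn, Sr, G, C], dict=True):
        g = sol[G]
        if g.is_real and g > 0:
            J = f.jacobian([Sn, Sr, G, C]).subs(sol)
            eigs = sorted(
                (complex(sympy.N(e)) for e in J.eigenvals()), key=lambda z: (z.real, z.imag)
            )
            exact.append((float(g), eigs))
    exact.sort()
    points = [assess_stability(fig2, pt) for pt in solve_endemic(fig2)]
    assert len(points) == len(exact) == 2
    for pt, (g_exact, eig_exact) in zip(points, exact):
        assert pt.state.G == pytest.approx(g_exact, rel=1e-12)
        eig_num = sorted(map(complex, pt.eigenvalues), key=lambda z: (z.real, z.imag))
        for a, b in zip(eig_num, eig_exact):
            assert a == pytest.approx(b, abs=1e-9)


def test_bistable_branch_stability_above_hopf(fig2):
    """Deeper into the window (beta = 0.35, Rg ~ 0.959, still H2iii) the
    textbook backward-bifurcation picture holds: saddle lower root,
    attracting upper root, stable gang-free state."""
    params = fig2.replace(beta=0.35)
    assert classify_existence(params).label == "H2iii_two"
    lower, upper = (assess_stability(params, pt) for pt in solve_endemic(params))
    assert lower.stability == "unstable"
    assert upper.stability == "stable"
    assert gang_free_point(params).stability == "stable"


def test_unique_endemic_root_is_stable_above_threshold(fig2):
    params = fig2.replace(beta=0.5)
    (point,) = (assess_stability(params, pt) for pt in solve_endemic(params))
    assert point.stability == "stable"
    assert gang_free_point(params).stability == "unstable"


# ------------------------------------------------------------- bifurcation


def test_backward_bifurcation_fig2(fig2):
    rep = bifurcation_direction(fig2)
    assert rep.direction == "backward"
    assert rep.a_cm > 0 and rep.b_cm > 0
    assert rep.beta_star == pytest.approx(0.3648, abs=1e-4)


def test_forward_bifurcation_below_eta_star(fig2):
    rep = bifurcation_direction(fig2.replace(eta=1.0))
    assert rep.direction == "forward"
    assert rep.a_cm < 0 and rep.b_cm > 0


def test_null_eigenvectors_at_beta_star(fig2):
    """w and v are right/left null vectors of the Jacobian at beta = beta*."""
    rep = bifurcation_direction(fig2)
    params = fig2.replace(beta=rep.beta_star)
    J = jacobian(params, gang_free_equilibrium(params))
    assert np.max(np.abs(J @ rep.w)) / np.linalg.norm(rep.w) < 1e-9
    assert np.max(np.abs(rep.v @ J)) / np.linalg.norm(rep.v) < 1e-9


def test_center_manifold_coefficients_match_numeric_contraction(fig2):
    """Independent oracle: a_cm and b_cm from finite-difference second
    derivatives of the vector field, contracted with w and v."""
    rep = bifurcation_direction(fig2)
    params = fig2.replace(beta=rep.beta_star)
    x0 = gang_free_equilibrium(params).as_array()
    w, v = rep.w, rep.v

    def f(y, q):
        return rhs_array(y, q)

    h = 1e-4
    # a = sum_k v_k * w^T H_k w, H_k the Hessian of component k
    a_num = 0.0
    for k in range(4):
        if v[k] == 0.0:
            continue
        H = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                ei = np.zeros(4)
                ej = np.zeros(4)
                ei[i] = h
                ej[j] = h
                H[i, j] = (
                    f(x0 + ei + ej, params)[k]
                    - f(x0 + ei - ej, params)[k]
                    - f(x0 - ei + ej, params)[k]
                    + f(x0 - ei - ej, params)[k]
                ) / (4 * h * h)
        a_num += v[k] * w @ H @ w
    # b = sum_k v_k * w^T d/dbeta (grad f_k)
    hb = 1e-6 * rep.beta_star
    b_num = 0.0
    for k in range(4):
        if v[k] == 0.0:
            continue
        grad = np.empty(4)
        for i in range(4):
            ei = np.zeros(4)
            ei[i] = h
            hi = params.replace(beta=rep.beta_star + hb)
            lo = params.replace(beta=rep.beta_star - hb)
            grad[i] = (
                (f(x0 + ei, hi)[k] - f(x0 - ei, hi)[k]) - (f(x0 + ei, lo)[k] - f(x0 - ei, lo)[k])
            ) / (4 * h * hb)
        b_num += v[k] * w @ grad
    assert a_num == pytest.approx(rep.a_cm, rel=1e-4)
    assert b_num == pytest.approx(rep.b_cm, rel=1e-4)


def test_a_cm_changes_sign_exactly_at_eta_star(fig2, rng):
    eta_s = eta_star(fig2)
    assert bifurcation_direction(fig2.replace(eta=eta_s * 1.001)).a_cm > 0
    assert bifurcation_direction(fig2.replace(eta=eta_s * 0.999)).a_cm < 0
    for _ in range(30):
        params = sample_parameters(rng)
        rep = bifurcation_direction(params)
        assert rep.b_cm > 0
        assert (rep.a_cm > 0) == (params.eta > eta_star(params))
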