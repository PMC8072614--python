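"""Selection-index machinery over per-trait GEBV information sources.

Standard index theory: with information sources x and aggregate genotype
H = v'g, the index I = b'x maximises corr(I, H) at b = P^{-1} G v, where
P = var(x), G = cov(x, g) and v are the economic values. Responses per
selection round follow DG_j = i * (G'b)_j / sigma_I with selection
intensity i.

Here the sources are one GEBV per trait. Under the pseudo-phenotype
treatment, cov(GEBV_i, GEBV_j) = cov(GEBV_i, g_j) = r_i r_j rg_ij s_gi s_gj,
so P = G and the unrestricted weights reduce to b = v; the machinery still
matters for restricted indices, trait-holding economic values, and accuracy
accounting. An alternative convention (r_i^2 scaling of cross-covariances)
is available via ``convention="squared"``.

Zero genetic change for chosen traits is available two ways: the
Kempthorne-Nordskog restricted index (a linear constraint G'b = 0 on the
restricted coordinates) and root-finding on the trait's economic value until
its response vanishes, which mirrors how breeding-program software holds
type traits constant. Both are exposed; they are cross-checked in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .params import ParameterError, correlation_to_covariance

#: responses below this (trait units) count as "held at zero"
HOLD_TOL = 1e-8


@dataclass(frozen=True)
class BreedingGoal:
    """Ordered traits with their economic values (CAD per trait unit)."""

    traits: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.traits),):
            raise ParameterError("economic values must match the trait list")
        if not np.all(np.isfinite(v)):
            raise ParameterError("economic values must be finite")
        object.__setattr__(self, "values", v)

    def with_value(self, trait: str, value: float) -> "BreedingGoal":
        v = self.values.copy()
        v[self.traits.index(trait)] = value
        return BreedingGoal(self.traits, v)


@dataclass(frozen=True)
class IndexMatrices:
    """P = var(sources), G = cov(sources, TBV), C = var(TBV)."""

    traits: tuple[str, ...]
    P: np.ndarray
    G: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.traits)
        for name, m in (("P", self.P), ("G", self.G), ("C", self.C)):
            if np.asarray(m).shape != (k, k):
                raise ParameterError(f"{name} must be {k}x{k}")
        p = np.asarray(self.P, dtype=float)
        if not np.allclose(p, p.T, atol=1e-10):
            raise ParameterError("P must be symmetric")
        if np.linalg.eigvalsh(p).min() <= 0:
            raise ParameterError(
                "P is not positive definite; repair the correlation inputs")


@dataclass(frozen=True)
class IndexSolution:
    """Index weights with accuracy and per-unit-intensity responses."""

    traits: tuple[str, ...]
    b: np.ndarray
    sigma_index: float
    accuracy: float          # r_HI = corr(index, aggregate genotype)
    response_per_intensity: np.ndarray   # G'b / sigma_I, trait units
    degenerate: bool = False
    restricted: tuple[str, ...] = field(default=())


def build_gebv_index_matrices(
    params,
    rg: np.ndarray,
    convention: str = "pseudo-phenotype",
) -> IndexMatrices:
    """Assemble P, G and the TBV covariance C from Table-style parameters.

    ``params`` is the list of TraitParams in goal order; ``rg`` the complete
    genetic correlation matrix in the same order. Under the default
    pseudo-phenotype convention P[i,j] = G[i,j] = r_i r_j rg_ij s_gi s_gj;
    ``convention="squared"`` instead uses r_i r_j on P but r_i^2 (own-trait)
    scaling on G's columns, i.e. G[i,j] = r_i^2 rg_ij s_gi s_gj.
    """
    traits = tuple(p.trait.code for p in params)
    sg = np.array([p.sigma_g for p in params])
    r = np.array([p.r_gebv for p in params])
    rg = np.asarray(rg.to_numpy() if hasattr(rg, "to_numpy") else rg, float)
    c = correlation_to_covariance(rg, sg)
    p_mat = np.outer(r, r) * c
    if convention == "pseudo-phenotype":
        g_mat = p_mat.copy()
    elif convention == "squared":
        g_mat = (r[:, None] ** 2) * c
    else:
        raise ParameterError(f"unknown GEBV convention {convention!r}")
    return IndexMatrices(traits=traits, P=p_mat, G=g_mat, C=c)


def solve_index_weights(m: IndexMatrices, goal: BreedingGoal) -> IndexSolution:
    """Unrestricted optimum b = P^{-1} G v."""
    _check_goal(m, goal)
    v = goal.values
    if np.array_equal(m.P, m.G):
        b = v.copy()        # P^{-1} G = I analytically; skip the solver
    else:
        b = np.linalg.solve(m.P, m.G @ v)
    return _finish(m, goal, b, restricted=())


def restricted_index_weights(
    m: IndexMatrices, goal: BreedingGoal, restricted: tuple[str, ...] | list[str]
) -> IndexSolution:
    """Kempthorne-Nordskog index with zero expected change on ``restricted``.

    Maximises corr(I, H) subject to (G'b)_j = 0 for each restricted trait j:
    b = [I - P^{-1} Gr (Gr' P^{-1} Gr)^{-1} Gr'] P^{-1} G v with Gr the
    restricted columns of G. An empty restriction set falls back to the
    unrestricted solution; restricting every trait is degenerate (b = 0).
    """
    _check_goal(m, goal)
    restricted = tuple(restricted)
    unknown = set(restricted) - set(m.traits)
    if unknown:
        raise ParameterError(f"unknown restricted traits {sorted(unknown)}")
    if not restricted:
        return solve_index_weights(m, goal)

    idx = [m.traits.index(t) for t in restricted]
    gr = m.G[:, idx]
    p_inv_gr = np.linalg.solve(m.P, gr)
    inner = gr.T @ p_inv_gr
    if np.linalg.matrix_rank(inner, tol=1e-12) < inner.shape[0]:
        raise ParameterError("restriction constraint matrix is rank deficient")
    b0 = np.linalg.solve(m.P, m.G @ goal.values)
    b = b0 - p_inv_gr @ np.linalg.solve(inner, gr.T @ b0)
    return _finish(m, goal, b, restricted=restricted)


def _check_goal(m: IndexMatrices, goal: BreedingGoal) -> None:
    if goal.traits != m.traits:
        raise ParameterError("goal and index matrices disagree on trait order")


def _finish(m: IndexMatrices, goal: BreedingGoal, b: np.ndarray,
            restricted: tuple[str, ...]) -> IndexSolution:
    v = goal.values
    var_i = float(b @ m.P @ b)
    sigma_i = np.sqrt(max(var_i, 0.0))
    var_h = float(v @ m.C @ v)
    degenerate = sigma_i < 1e-10 * max(1.0, np.abs(np.diag(m.P)).max())
    if degenerate:
        sigma_i = 0.0
        response = np.zeros(len(m.traits))
        accuracy = 0.0
    else:
        response = (m.G.T @ b) / sigma_i
        accuracy = sigma_i / np.sqrt(var_h) if var_h > 0 else 0.0
    return IndexSolution(
        traits=m.traits,
        b=b,
        sigma_index=float(sigma_i),
        accuracy=float(min(max(accuracy, 0.0), 1.0)),
        response_per_intensity=response,
        degenerate=degenerate,
        restricted=restricted,
    )


def selection_intensity(p: float) -> float:
    """Intensity of truncation selection: i = phi(z_p) / p, p = selected
    proportion; p = 1 means no selection (i = 0)."""
    if not 0 < p <= 1:
        raise ParameterError("selected proportion must lie in (0, 1]")
    if p == 1.0:
        return 0.0
    z = stats.norm.isf(p)
    return float(stats.norm.pdf(z) / p)


def response_to_selection(
    sol: IndexSolution, m: IndexMatrices, intensity: float,
    sigma_g: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-trait response for one selection round at the given intensity.

    DG_j = i * (b'G e_j) / sigma_I (trait units); also in genetic-SD units
    (SDU) when ``sigma_g`` is supplied.
    """
    if sol.degenerate:
        units = np.zeros(len(sol.traits))
    else:
        units = intensity * sol.response_per_intensity
    out = {"units": units}
    if sigma_g is not None:
        out["sdu"] = units / np.asarray(sigma_g, dtype=float)
    return out


def solve_holding_economic_value(
    m: IndexMatrices,
    goal: BreedingGoal,
    trait_to_hold: str,
    bracket: tuple[float, float] = (-1e4, 1e4),
    tol: float = HOLD_TOL,
) -> float:
    """Economic value for one trait that zeroes its own expected response.

    Bisection on the trait's economic value, all other values fixed; the
    response is linear in the value, so a sign change over the bracket
    guarantees a unique root. Raises if the bracket does not straddle zero
    response, reporting the endpoint responses.
    """
    if trait_to_hold not in m.traits:
        raise ParameterError(f"unknown trait {trait_to_hold!r}")
    j = m.traits.index(trait_to_hold)

    def resp(value: float) -> float:
        sol = solve_index_weights(m, goal.with_value(trait_to_hold, value))
        return float(sol.response_per_intensity[j])

    lo, hi = bracket
    r_lo, r_hi = resp(lo), resp(hi)
    if r_lo == 0.0:
        return float(lo)
    if r_hi == 0.0:
        return float(hi)
    if np.sign(r_lo) == np.sign(r_hi):
        raise ParameterError(
            f"no sign change for {trait_to_hold} over bracket {bracket}: "
            f"responses ({r_lo:.4g}, {r_hi:.4g})"
        )
    root = optimize.bisect(resp, lo, hi, xtol=1e-10, maxiter=200)
    if abs(resp(root)) > tol:
        raise ParameterError(
            f"bisection converged but |response| = {abs(resp(root)):.2e} > {tol}")
    return float(root)


def solve_holding_economic_values(
    m: IndexMatrices, goal: BreedingGoal, traits_to_hold
) -> BreedingGoal:
    """Economic values holding several traits at zero response jointly.

    The response vector is proportional to (G' P^{-1} G) v, linear in v, so
    holding a set H of traits is the linear system M_HH v_H = -M_HF v_F.
    Returns the goal with the held traits' values replaced.
    """
    traits_to_hold = list(traits_to_hold)
    if not traits_to_hold:
        return goal
    mm = m.G.T @ np.linalg.solve(m.P, m.G)
    hold = [m.traits.index(t) for t in traits_to_hold]
    free = [i for i in range(len(m.traits)) if i not in hold]
    a = mm[np.ix_(hold, hold)]
    rhs = -mm[np.ix_(hold, free)] @ goal.values[free]
    if np.linalg.matrix_rank(a, tol=1e-12) < len(hold):
        raise ParameterError("holding system is singular for these traits")
    v_hold = np.linalg.solve(a, rhs)
    v = goal.values.copy()
    v[hold] = v_hold
    return BreedingGoal(goal.traits, v)


def progeny_test_accuracy(n_daughters: int, h2: float) -> float:
    """Accuracy of a sire's progeny test: r = sqrt(n / (n + lambda)),
    lambda = (4 - h2)/h2."""
    if n_daughters < 0:
        raise ParameterError("daughter count must be >= 0")
    if not 0 < h2 < 1:
        raise ParameterError("h2 must lie in (0, 1)")
    lam = (4.0 - h2) / h2
    return float(np.sqrt(n_daughters / (n_daughters + lam)))
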