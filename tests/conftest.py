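"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

import locusrt as lr


# ---------------------------------------------------------------------------
# independent oracles (never routed through the code they check)

def brute_force_digest(sequence: str, missed_cleavages: int) -> set[str]:
    """Enumerate tryptic products by concatenating consecutive base fragments.

    Base fragments come from a direct scan for K/R-not-before-P sites; a
    product with k missed cleavages is the concatenation of k+1 consecutive
    base fragments.
    """
    cuts = [0]
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            cuts.append(i + 1)
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    base = [sequence[a:b] for a, b in zip(cuts, cuts[1:])]
    out = set()
    for k in range(missed_cleavages + 1):
        for i in range(len(base) - k):
            out.add("".join(base[i : i + k + 1]))
    return out


def svr_dual_qp(K: np.ndarray, y: np.ndarray, C: float, eps: float):
    """Solve the epsilon-SVR dual QP directly with a trust-region solver.

    Returns (beta, b) where f(x) = sum_i beta_i K(x_i, x) + b; the intercept
    comes from the KKT conditions at free (strictly-inside-bounds) support
    vectors.
    """
    from scipy.optimize import LinearConstraint, minimize

    n = len(y)

    def obj(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta + eps * z.sum() - y @ beta

    def grad(z):
        Kb = K @ (z[:n] - z[n:])
        return np.concatenate([Kb + eps - y, -Kb + eps + y])

    hessian = np.block([[K, -K], [-K, K]])

    balance = np.concatenate([np.ones(n), -np.ones(n)])[None, :]
    res = minimize(
        obj,
        np.zeros(2 * n),
        jac=grad,
        hess=lambda z: hessian,
        bounds=[(0.0, C)] * (2 * n),
        constraints=[LinearConstraint(balance, 0.0, 0.0)],
        method="trust-constr",
        options={
            "maxiter": 50_000,
            "gtol": 1e-14,
            "xtol": 1e-16,
            "barrier_tol": 1e-14,
        },
    )
    assert res.constr_violation < 1e-9, res.message
    a, s = res.x[:n], res.x[n:]
    beta = a - s
    f0 = K @ beta
    tol = 1e-6 * C
    bs = []
    for i in range(n):
        if tol < a[i] < C - tol:
            bs.append(y[i] - eps - f0[i])
        if tol < s[i] < C - tol:
            bs.append(y[i] + eps - f0[i])
    assert bs, "no free support vectors; intercept undetermined"
    return beta, float(np.mean(bs))


def minimal_symmetric_window(errors: np.ndarray, coverage: float = 0.95) -> float:
    """Smallest width 2h with |error| <= h for at least *coverage* of points,
    found by scanning every |error| as a candidate half-width."""
    a = np.abs(np.asarray(errors, float))
    n = a.size
    best = np.inf
    for h in np.unique(a):
        if np.count_nonzero(a <= h) / n >= coverage:
            best = min(best, 2.0 * h)
    return float(best)


def composition_counts(dataset: lr.RTDataset) -> np.ndarray:
    """(n, 21) residue-count design matrix with an intercept column."""
    X = np.zeros((len(dataset), 21))
    for i, p in enumerate(dataset):
        for aa in p.sequence:
            X[i, lr.AA_TO_INDEX[aa]] += 1
        X[i, 20] = 1.0
    return X


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def noiseless_model() -> lr.GroundTruthRTModel:
    gt = lr.GroundTruthRTModel.default()
    gt.noise_sd = 0.0
    return gt


@pytest.fixture(scope="session")
def tiny_dataset() -> lr.RTDataset:
    """20 synthetic peptides with noisy RTs for fast model tests."""
    return lr.generate_dataset(20, seed=3)


@pytest.fixture(scope="session")
def one_point_grid() -> lr.HyperparamGrid:
    return lr.HyperparamGrid(
        C_values=(64.0,), gamma_values=(2.0**-6,), epsilon_values=(0.1,)
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, one_point_grid) -> lr.TrainedModel:
    return lr.grid_search_train(tiny_dataset, one_point_grid)
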