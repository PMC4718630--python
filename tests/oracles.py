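"""Independent oracle implementations used only by the tests."""

import itertools

import numpy as np


def enumerate_log_likelihood(history, params) -> float:
    """Marginal likelihood by exhaustive enumeration of every latent
    occupancy configuration (2^(J*T) terms) — independent of the forward
    recursion it checks."""
    k, n = history.annual_summaries()
    J, T = k.shape
    psi1 = np.broadcast_to(np.asarray(params.psi1, dtype=float), (J,))
    phi = np.broadcast_to(np.asarray(params.phi, dtype=float),
                          (J, max(T - 1, 1)))
    gam = np.broadcast_to(np.asarray(params.gamma, dtype=float),
                          (J, max(T - 1, 1)))
    p = float(params.p)
    total = 1.0
    for j in range(J):
        s = 0.0
        for zs in itertools.product((0, 1), repeat=T):
            prob = psi1[j] if zs[0] else 1 - psi1[j]
            for t in range(T - 1):
                if zs[t]:
                    prob *= phi[j, t] if zs[t + 1] else 1 - phi[j, t]
                else:
                    prob *= gam[j, t] if zs[t + 1] else 1 - gam[j, t]
            for t in range(T):
                if zs[t]:
                    prob *= p ** k[j, t] * (1 - p) ** (n[j, t] - k[j, t])
                elif k[j, t] > 0:
                    prob = 0.0
            s += prob
        total *= s
    return float(np.log(total)) if total > 0 else -np.inf


def random_instance(rng, max_points=4, max_years=3, max_periods=3):
    """A random small detection history + parameter set."""
    from wpimon import DetectionHistory, ModelParams

    J = int(rng.integers(1, max_points + 1))
    T = int(rng.integers(1, max_years + 1))
    K = int(rng.integers(1, max_periods + 1))
    vals = rng.choice([0.0, 1.0, np.nan], size=(J, T, K), p=[0.5, 0.2, 0.3])
    hist = DetectionHistory(vals, [f"p{j}" for j in range(J)],
                            list(range(2010, 2010 + T)))
    params = ModelParams(psi1=float(rng.uniform(0.05, 0.95)),
                         phi=float(rng.uniform(0.05, 0.95)),
                         gamma=float(rng.uniform(0.05, 0.95)),
                         p=float(rng.uniform(0.05, 0.95)))
    return hist, params


def irls_logistic_curve_slope(psi, t):
    """Fit psi(t) = logistic(a + b t) to one continuous trajectory by
    iteratively-reweighted least squares (statsmodels binomial GLM)."""
    import statsmodels.api as sm
    import warnings

    X = sm.add_constant(np.asarray(t, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(np.asarray(psi, dtype=float), X,
                     family=sm.families.Binomial()).fit()
    return float(fit.params[1])
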