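import math

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def sample_within(rng, n=1):
    """Random in-domain single-population parameter sets."""
    out = []
    for _ in range(n):
        out.append({
            "n_train": int(rng.integers(10, 100_000)),
            "h2": float(rng.uniform(0.01, 0.99)),
            "h2_m": float(rng.uniform(0.01, 0.99)),
            "me": float(rng.uniform(1.0, 50_000.0)),
            "ne": float(rng.uniform(1.0, 10_000.0)),
            "b": float(rng.uniform(0.0, 1.0)),
            "eterm": float(rng.uniform(0.0, 10.0)),
        })
    return out


def sample_corr_triple(rng):
    """(r_ab, r_ac, r_bc) from a random positive semi-definite 3x3
    correlation matrix (random-factor construction), so the three
    population correlations are mutually consistent."""
    W = rng.normal(size=(3, 3))
    S = W @ W.T + np.diag(rng.uniform(0.05, 0.5, size=3))
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    return float(R[0, 1]), float(R[0, 2]), float(R[1, 2])


def sample_multipop(rng, common_b=True):
    """Random in-domain two-population parameter set with a consistent
    correlation structure; ``common_b`` ties the two marker-capture
    coefficients together (the regime where accuracy is provably <= 1)."""
    r_ab, r_ac, r_bc = sample_corr_triple(rng)
    b1 = float(rng.uniform(0.0, 1.0))
    b2 = b1 if common_b else float(rng.uniform(0.0, 1.0))
    return {
        "n_a": int(rng.integers(10, 50_000)),
        "n_b": int(rng.integers(10, 50_000)),
        "h2_a": float(rng.uniform(0.05, 0.95)),
        "h2_b": float(rng.uniform(0.05, 0.95)),
        "me_ac": float(rng.uniform(10.0, 20_000.0)),
        "me_bc": float(rng.uniform(10.0, 20_000.0)),
        "r_g_ab": r_ab, "r_g_ac": r_ac, "r_g_bc": r_bc,
        "b_ac": b1, "b_bc": b2,
    }


def goddard2009_printed(n_train, h2, me, ne, prec=50):
    """High-precision evaluation of the published expression, term for term:
    sqrt(1 - lambda/(2 N sqrt(alpha)) * ln((1+alpha+2 sqrt(alpha)) /
    (1+alpha-2 sqrt(alpha)))).  Computed with 50-digit decimal arithmetic
    because the denominator 1+alpha-2*sqrt(alpha) cancels catastrophically
    in binary doubles as alpha -> 1 (large N); the oracle must not share
    the implementation's rearrangement, only its value."""
    from decimal import Decimal, localcontext

    with localcontext() as ctx:
        ctx.prec = prec
        n = Decimal(n_train)
        log2ne = (Decimal(2) * Decimal(ne)).ln()
        lam = Decimal(me) / (Decimal(h2) * log2ne)
        alpha = 1 + 2 * lam / n
        sa = alpha.sqrt()
        ratio = (1 + alpha + 2 * sa) / (1 + alpha - 2 * sa)
        radicand = 1 - lam / (2 * n * sa) * ratio.ln()
        return float(radicand.sqrt())


def eterm_bruteforce(geno, lam):
    """Explicit-inverse oracle for the expectation-term estimate."""
    X = geno.train_matrix
    V = X @ X.T + lam * np.eye(X.shape[0])
    Vinv = np.linalg.inv(V)
    vals = []
    for x in geno.test_matrix:
        v = x @ X.T @ Vinv
        vals.append(float(v @ v))
    return float(np.mean(vals))
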