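"""Independent reference implementations used as test oracles.

These stay deliberately naive (explicit branch chains, scalar loops,
brute-force optimization) and share no code with the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


def conut_reference(albumin_gl: float, chol_mmol: float, lymph_1e9: float) -> int:
    """Band-by-band CONUT lookup written as explicit comparisons."""
    if albumin_gl >= 35:
        a = 0
    elif albumin_gl >= 30:
        a = 2
    elif albumin_gl >= 25:
        a = 4
    else:
        a = 6
    if chol_mmol >= 4.65:
        c = 0
    elif chol_mmol >= 3.62:
        c = 1
    elif chol_mmol >= 2.59:
        c = 2
    else:
        c = 3
    if lymph_1e9 >= 1.6:
        ly = 0
    elif lymph_1e9 >= 1.2:
        ly = 1
    elif lymph_1e9 >= 0.8:
        ly = 2
    else:
        ly = 3
    return a + c + ly


def pni_reference(albumin_gl: float, lymph_1e9: float) -> float:
    return 10.0 * (albumin_gl / 10.0) + 0.005 * (lymph_1e9 * 1000.0)


def nri_reference(albumin_gl: float, weight: float, height: float,
                  sex: str) -> float:
    if sex == "male":
        ideal = (height - 100.0) - (height - 150.0) / 4.0
    else:
        ideal = (height - 100.0) - (height - 150.0) / 2.5
    return 1.489 * albumin_gl + 41.7 * weight / ideal


def random_lab_records(n: int, seed: int) -> pd.DataFrame:
    """Random records spanning all score bands, with band edges included."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "albumin": rng.uniform(15.0, 55.0, n),
        "total_cholesterol": rng.uniform(1.0, 9.0, n),
        "lymphocytes": rng.uniform(0.1, 4.0, n),
        "weight": rng.uniform(45.0, 130.0, n),
        "height": rng.uniform(152.0, 200.0, n),
        "sex": rng.choice(["male", "female"], n),
    })
    # sprinkle exact band boundaries to probe closure conventions
    edges = {
        "albumin": [25.0, 30.0, 35.0],
        "total_cholesterol": [2.59, 3.62, 4.65],
        "lymphocytes": [0.8, 1.2, 1.6],
    }
    for col, vals in edges.items():
        idx = rng.choice(n, size=min(30, n), replace=False)
        df.loc[idx, col] = rng.choice(vals, size=len(idx))
    return df


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Partial log-likelihood for one covariate, no tied event times."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    xv = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.where(d)[0]:
        risk = t >= t[i]
        ll += beta * xv[i] - np.log(np.sum(np.exp(beta * xv[risk])))
    return ll


def brute_force_cox_beta(times, events, x) -> float:
    """1-D maximization of the partial likelihood by bounded search."""
    res = minimize_scalar(lambda b: -cox_partial_loglik(b, times, events, x),
                          bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def chi_square_reference(table: np.ndarray):
    """Sum (O-E)^2/E with E from the product of the marginals."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = ((obs - expected) ** 2 / expected).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df
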