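"""Single-hit Poisson limiting-dilution analysis (extreme LDA).

In a limiting dilution assay, wells are seeded with decreasing cell doses
and scored positive (spheroid/tumor) or negative. Under the single-hit
model a well responds iff it received at least one active (stem-like)
cell, so with active-cell frequency lambda:

    P(well negative | dose d) = exp(-lambda * d)

The binomial log-likelihood over doses j with pos_j responding and neg_j
non-responding wells is

    l(lambda) = sum_j [ neg_j * (-lambda d_j) + pos_j * log(1 - exp(-lambda d_j)) ]

lambda is estimated by maximum likelihood (equivalently, an intercept-only
complementary-log-log binomial regression with log-dose offset); 95%
confidence limits come from the profile likelihood (drop of
chi2(1)_0.95 / 2 = 1.9207 log-units), which is stable across the
decades-wide dose ranges these assays use. Frequencies are quoted as
"1 in N" with N = 1/lambda.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

_CHI2_95_HALF = chi2.ppf(0.95, df=1) / 2.0  # 1.92073...
REQUIRED_COLUMNS = ("dose", "tested", "responding")


@dataclass(frozen=True)
class FrequencyEstimate:
    """MLE of the active-cell frequency lambda with 95% profile CI.

    flag is None for a regular interior MLE, 'all_positive' when every well
    responded (lambda unbounded above; ci_lower is still finite) and
    'all_negative' when none did (MLE 0; ci_upper still finite).
    """

    lambda_hat: float
    ci_lower: float
    ci_upper: float
    loglik: float
    flag: Optional[str] = None

    @property
    def one_in(self) -> float:
        """Frequency quoted the assay's usual way: 1 cell in N."""
        return np.inf if self.lambda_hat == 0 else 1.0 / self.lambda_hat


def validate_dose_table(data: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"dose table missing column(s): {sorted(missing)}")
    df = data.loc[:, list(REQUIRED_COLUMNS)].astype(float)
    if (df["dose"] <= 0).any():
        raise ValueError("doses must be > 0")
    if ((df["responding"] < 0) | (df["responding"] > df["tested"])).any():
        raise ValueError("responding must lie in [0, tested] for every dose")
    return df


def read_dose_tables(path) -> dict[str, pd.DataFrame]:
    """Read a delimited `condition dose tested responding` file, one table
    per condition."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if "condition" not in df.columns:
        df["condition"] = "all"
    return {
        str(cond): validate_dose_table(sub)
        for cond, sub in df.groupby("condition", sort=False)
    }


def log_likelihood(lam: float, data: pd.DataFrame) -> float:
    """Single-hit binomial log-likelihood at lambda (natural log)."""
    d = data["dose"].to_numpy(dtype=float)
    pos = data["responding"].to_numpy(dtype=float)
    neg = data["tested"].to_numpy(dtype=float) - pos
    if lam <= 0:
        return -np.inf if pos.sum() > 0 else 0.0
    # log(1 - exp(-lam d)) computed stably as log(-expm1(-lam d))
    with np.errstate(divide="ignore"):
        log_p_pos = np.log(-np.expm1(-lam * d))
    return float(np.sum(neg * (-lam * d) + pos * log_p_pos))


def fit_single_hit(data: pd.DataFrame) -> FrequencyEstimate:
    """Maximum-likelihood single-hit fit with 95% profile-likelihood CI."""
    df = validate_dose_table(data)
    pos_total = df["responding"].sum()
    neg_total = (df["tested"] - df["responding"]).sum()
    if neg_total == 0:  # lambda unbounded above
        ci_lower = _profile_bound(df, loglik_max=0.0, side="lower", t_ref=np.log(10.0 / df["dose"].min()))
        return FrequencyEstimate(np.inf, ci_lower, np.inf, 0.0, flag="all_positive")
    if pos_total == 0:  # MLE at the boundary lambda = 0
        ci_upper = _CHI2_95_HALF / float((df["tested"] * df["dose"]).sum())
        return FrequencyEstimate(0.0, 0.0, ci_upper, 0.0, flag="all_negative")
    lam_hat = _solve_score(df)
    ll_hat = log_likelihood(lam_hat, df)
    t_hat = float(np.log(lam_hat))
    lo = _profile_bound(df, ll_hat, "lower", t_hat)
    hi = _profile_bound(df, ll_hat, "upper", t_hat)
    return FrequencyEstimate(lam_hat, lo, hi, ll_hat)


def _solve_score(df: pd.DataFrame) -> float:
    """Root of dl/dlambda. The log-likelihood is concave in lambda (each
    log(1 - exp(-lambda d)) term is concave, the rest linear), so the score
    is monotone decreasing with a unique root."""
    d = df["dose"].to_numpy(dtype=float)
    pos = df["responding"].to_numpy(dtype=float)
    neg = df["tested"].to_numpy(dtype=float) - pos

    def score(lam: float) -> float:
        em = np.exp(-lam * d)
        return float(np.sum(-neg * d + pos * d * em / (1.0 - em)))

    # score -> +inf as lambda -> 0+, < 0 for large lambda: expand to bracket
    hi = 1.0 / float(np.average(d, weights=df["tested"]))
    while score(hi) > 0:
        hi *= 4.0
    lo = hi / 4.0
    while score(lo) < 0:
        lo /= 4.0
    return float(optimize.brentq(score, lo, hi, xtol=1e-300, rtol=1e-15, maxiter=200))


def _profile_bound(df: pd.DataFrame, loglik_max: float, side: str, t_ref: float) -> float:
    """Solve l(lambda) = l_max - 1.9207 on one side of t_ref (log scale)."""
    target = loglik_max - _CHI2_95_HALF

    def g(t: float) -> float:
        return log_likelihood(np.exp(t), df) - target

    step = -1.0 if side == "lower" else 1.0
    a = t_ref
    b = t_ref + step
    for _ in range(200):
        if g(b) < 0:
            break
        a, b = b, b + step
    else:
        return 0.0 if side == "lower" else np.inf
    lo, hi = (b, a) if side == "lower" else (a, b)
    t = optimize.brentq(g, lo, hi, xtol=1e-12)
    return float(np.exp(t))


def compare_frequencies(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Likelihood-ratio test of equal active-cell frequency in two assays.

    LR = 2[l(lambda_a) + l(lambda_b) - l(lambda_pooled)]; p from chi2(1).
    Degenerate groups propagate their flags via fit_single_hit's estimates.
    """
    fa, fb = fit_single_hit(a), fit_single_hit(b)
    pooled = pd.concat([validate_dose_table(a), validate_dose_table(b)], ignore_index=True)
    fp = fit_single_hit(pooled)
    lr = max(0.0, 2.0 * (fa.loglik + fb.loglik - fp.loglik))
    return lr, float(chi2.sf(lr, df=1))


# the standard 48-well in vitro design: two-fold dilutions from 5000 cells/well
DEFAULT_DOSES = (5000, 2500, 1250, 625, 312, 156, 78, 39)


def simulate_dose_response(
    lam: float,
    doses=DEFAULT_DOSES,
    wells_per_dose: int = 12,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw well outcomes from the single-hit model at frequency `lam`:
    responding ~ Binomial(wells, 1 - exp(-lam * dose)) per dose."""
    if rng is None:
        rng = np.random.default_rng()
    d = np.asarray(doses, dtype=float)
    p = -np.expm1(-lam * d)
    responding = rng.binomial(wells_per_dose, p)
    return pd.DataFrame({"dose": d, "tested": wells_per_dose, "responding": responding})


def estimates_frame(fits: dict[str, FrequencyEstimate]) -> pd.DataFrame:
    """Per-condition summary in the assay's conventional '1 in N' form."""
    return pd.DataFrame(
        {
            "condition": list(fits),
            "frequency_1_in": [f.one_in for f in fits.values()],
            "lambda_hat": [f.lambda_hat for f in fits.values()],
            "ci_lower_lambda": [f.ci_lower for f in fits.values()],
            "ci_upper_lambda": [f.ci_upper for f in fits.values()],
            "loglik": [f.loglik for f in fits.values()],
            "flag": [f.flag or "" for f in fits.values()],
        }
    )
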