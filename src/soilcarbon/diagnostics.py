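"""Posterior summaries and convergence diagnostics.

Covers the three quantities reported for a fitted soil-carbon model: the
SOC-change functional g = X_TOC(t) - X_TOC(1) (carbon gained or lost since
the first trial year; negative means loss), empirical percentile bands of
the TOC trajectory, and the Gelman-Rubin potential scale reduction factor
R-hat, with R-hat < 1.2 read as no evidence of non-convergence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RHAT_THRESHOLD = 1.2

DEFAULT_BAND_PROBS = (0.025, 0.25, 0.5, 0.75, 0.975)


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_iterations).  Classic (non-split) form: with
    within-chain variance W (mean of per-chain sample variances, n-1
    denominators) and between-chain variance B = n * var(chain means),

        R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

    ``split=True`` halves each chain first (a stricter variant that also
    detects non-stationarity within chains).
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    if chains.shape[1] < 2:
        raise ValueError("chains must have length >= 2")
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    n = chains.shape[1]
    within = chains.var(axis=1, ddof=1).mean()
    between = n * chains.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else np.inf
    v_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(v_hat / within))


def gelman_rubin_frame(draws: dict[str, np.ndarray], split: bool = False) -> pd.DataFrame:
    """R-hat per parameter from a mapping name -> (n_chains, n_iter)."""
    rows = [
        {
            "parameter": name,
            "rhat": (r := gelman_rubin(arr, split=split)),
            "converged": bool(r < RHAT_THRESHOLD),
        }
        for name, arr in draws.items()
    ]
    return pd.DataFrame(rows)


def soc_change(toc_draws: np.ndarray, t: int) -> dict:
    """Posterior summary of X_TOC(t) - X_TOC(1) for one field.

    ``toc_draws`` is (n_draws, T) with column 0 the first trial year; ``t``
    is the 1-based trial-year index.  Returns the Monte-Carlo mean, sample
    variance (n-1 denominator) and 2.5/97.5 percentiles of the per-draw
    differences.
    """
    toc_draws = np.asarray(toc_draws, float)
    if toc_draws.ndim != 2 or toc_draws.shape[0] == 0:
        raise ValueError("need a nonempty (n_draws, T) array")
    T = toc_draws.shape[1]
    if not 1 <= t <= T:
        raise ValueError(f"year index {t} outside 1..{T}")
    diff = toc_draws[:, t - 1] - toc_draws[:, 0]
    var = float(diff.var(ddof=1)) if diff.size > 1 else 0.0
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return {
        "t": t,
        "mean": float(diff.mean()),
        "var": var,
        "p2.5": float(lo),
        "p97.5": float(hi),
    }


def soc_change_summary(toc_draws: np.ndarray, years: np.ndarray, field_id: str) -> pd.DataFrame:
    """Per-year SOC-change summary table for one field."""
    rows = []
    for t in range(1, toc_draws.shape[1] + 1):
        rec = soc_change(toc_draws, t)
        rec["year"] = int(years[t - 1])
        rec["field"] = field_id
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["field", "year", "t", "mean", "var", "p2.5", "p97.5"]]


def credible_band(
    toc_draws: np.ndarray,
    probabilities=DEFAULT_BAND_PROBS,
) -> np.ndarray:
    """Empirical per-year percentiles of the TOC trajectory across draws.

    Returns (len(probabilities), T); default probabilities give the 2.5th,
    25th, 50th, 75th and 97.5th percentile bands.
    """
    toc_draws = np.asarray(toc_draws, float)
    if toc_draws.ndim != 2 or toc_draws.shape[0] == 0:
        raise ValueError("need a nonempty (n_draws, T) array")
    probs = np.asarray(probabilities, float)
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    return np.percentile(toc_draws, 100 * probs, axis=0)


def credible_band_frame(
    toc_draws: np.ndarray,
    years: np.ndarray,
    probabilities=DEFAULT_BAND_PROBS,
) -> pd.DataFrame:
    band = credible_band(toc_draws, probabilities)
    df = pd.DataFrame({"year": np.asarray(years, int)})
    for p, row in zip(probabilities, band):
        df[f"p{100 * p:g}"] = row
    return df
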