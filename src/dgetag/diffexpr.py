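"""Audic-Claverie exact test for two tag-count libraries, with BH FDR.

For a gene with x tags in a library of N1 clean tags, the probability of
seeing y tags in a second library of N2 clean tags under equal
underlying expression is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

which is a negative-binomial mass in y with size x+1 and success
probability N1/(N1+N2).  The two-sided p-value doubles the smaller of
the two inclusive tails and caps at 1.  Because the conditional mass is
not exchangeable in its two libraries, the conditioning orientation is
canonicalised (condition on the smaller observed count, ties broken by
library size) so that swapping the libraries provably returns the same
p-value.

Significance calling follows the DGE convention: genes with raw counts
at or below an intensity floor in BOTH libraries are filtered off before
testing; Benjamini-Hochberg adjustment runs over the tested set only;
a gene is significant when p < 0.005, FDR <= 0.001 and |log2 fold
change| > 2, with fold changes computed on floored TPM so that
zero-count genes stay finite.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from dgetag.quantify import TPM_FLOOR, tpm_normalize

_LOG_EPS = -37.0  # chunk contributions below exp(-37) of the running tail are negligible


def _check_counts(x: int, y: int, n1: float, n2: float) -> None:
    if x < 0 or y < 0:
        raise ValueError(f"counts must be nonnegative, got x={x}, y={y}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library totals must be positive, got N1={n1}, N2={n2}")


def _log_mass(x: int, ks: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """log p(k | x) for an array of k, evaluated stably via log-gamma."""
    log_r = np.log(n2) - np.log(n1)
    log_1pr = np.logaddexp(0.0, log_r)
    return (
        ks * log_r
        + gammaln(x + ks + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ks + 1.0)
        - (x + ks + 1.0) * log_1pr
    )


def ac_probability(x: int, y: int, n1: float, n2: float) -> float:
    """Audic-Claverie mass p(y | x) for library depths N1, N2."""
    _check_counts(x, y, n1, n2)
    return float(np.exp(_log_mass(x, np.array([y], dtype=float), n1, n2)[0]))


def _log_lower_tail(x: int, y: int, n1: float, n2: float) -> float:
    """log Σ_{k<=y} p(k|x)."""
    ks = np.arange(0, y + 1, dtype=float)
    return float(logsumexp(_log_mass(x, ks, n1, n2)))


def _log_upper_tail(x: int, y: int, n1: float, n2: float, chunk: int = 512) -> float:
    """log Σ_{k>=y} p(k|x), summed upward in chunks to convergence.

    Terms decay geometrically once k exceeds the conditional mode, so the
    loop stops when a chunk adds a negligible fraction of the total.
    """
    acc = -np.inf
    k0 = y
    while True:
        ks = np.arange(k0, k0 + chunk, dtype=float)
        part = float(logsumexp(_log_mass(x, ks, n1, n2)))
        acc = float(np.logaddexp(acc, part))
        k0 += chunk
        # safe to stop only past the mode, where terms are decreasing
        if part < acc + _LOG_EPS and k0 > (x + 1) * (n2 / n1):
            return acc


def ac_pvalue_two_sided(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided exact p-value: doubled smaller inclusive tail, capped at 1.

    Exchangeable in its libraries: ac_pvalue_two_sided(x, y, N1, N2) ==
    ac_pvalue_two_sided(y, x, N2, N1) exactly, by canonical orientation.
    """
    _check_counts(x, y, n1, n2)
    if (y, n2) < (x, n1):  # canonical orientation: condition on the smaller count
        x, y, n1, n2 = y, x, n2, n1
    log_lower = _log_lower_tail(x, y, n1, n2)
    log_upper = _log_upper_tail(x, y, n1, n2)
    log_p = np.log(2.0) + min(log_lower, log_upper)
    return float(min(1.0, np.exp(log_p)))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    counts1: pd.Series,
    counts2: pd.Series,
    n1: int,
    n2: int,
    *,
    fc_threshold_log2: float = 2.0,
    p_threshold: float = 0.005,
    fdr_threshold: float = 0.001,
    intensity_floor: int = 40,
    tpm_floor: float = TPM_FLOOR,
) -> pd.DataFrame:
    """Full two-library DE table with prefilter, exact test, and BH FDR.

    Genes with raw count <= intensity_floor in BOTH libraries are
    prefiltered: they receive no p-value and can never be significant.
    The BH adjustment is computed over the tested genes only.
    """
    if not counts1.index.equals(counts2.index):
        counts2 = counts2.reindex(counts1.index)
        if counts2.isna().any():
            raise ValueError("count series must share one gene universe")
    x = counts1.astype("int64")
    y = counts2.astype("int64")
    tpm1 = tpm_normalize(x, n1, tpm_floor)
    tpm2 = tpm_normalize(y, n2, tpm_floor)
    log2fc = np.log2(tpm2 / tpm1)

    prefiltered = (x <= intensity_floor) & (y <= intensity_floor)
    pvals = pd.Series(np.nan, index=x.index, name="p")
    tested = x.index[~prefiltered]
    pvals.loc[tested] = [
        ac_pvalue_two_sided(int(x[g]), int(y[g]), n1, n2) for g in tested
    ]
    fdr = pd.Series(np.nan, index=x.index, name="fdr")
    if len(tested):
        fdr.loc[tested] = bh_fdr(pvals.loc[tested].to_numpy())

    significant = (
        ~prefiltered
        & (pvals < p_threshold)
        & (fdr <= fdr_threshold)
        & (log2fc.abs() > fc_threshold_log2)
    ).fillna(False)

    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "tpm1": tpm1,
            "tpm2": tpm2,
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "prefiltered": prefiltered,
            "significant": significant,
        }
    )
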