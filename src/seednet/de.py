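"""Differential expression for unreplicated two-library count data.

With one sequencing library per condition there is no dispersion to
estimate, so features are tested with the exact conditional binomial test:
conditioning on the feature's total count ``m = x + y``, the treated count
``x`` is Binomial(m, p0) under the null, with ``p0`` the treated share of
the combined library depth.  Two-sided p-values use the minimum-likelihood
rule (sum over outcomes no more probable than the one observed).  The
significance gate combines a fold-change threshold (CPM scale, pseudocount
0.5) with raw-p and BH-FDR cutoffs, all strict inequalities:
FC > 2 or FC < 0.5, p < 0.05, FDR < 0.05.

Also provides the 2^-ddCt relative-quantification utility used to compare
sequencing calls with qPCR validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Relative tolerance when deciding that an outcome's probability ties the
#: observed one in the minimum-likelihood two-sided rule.
_TIE_RTOL = 1e-12


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; every library total must be positive."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"library totals must be positive; offending samples: {bad}")
    return counts / totals * 1e6


def unreplicated_count_test(x: int, y: int, n_t: int, n_c: int) -> float:
    """Exact conditional test of equal relative abundance in two libraries.

    ``x``/``y`` are treated/control counts of one feature, ``n_t``/``n_c``
    the library totals.  Returns the two-sided minimum-likelihood p-value
    of Binomial(x + y, n_t / (n_t + n_c)); ``x = y = 0`` returns 1.0 by
    convention (untestable).
    """
    if n_t <= 0 or n_c <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    m = x + y
    if m == 0:
        return 1.0
    p0 = n_t / (n_t + n_c)
    pmf = stats.binom.pmf(np.arange(m + 1), m, p0)
    # normalize by the total mass so that including every outcome gives 1.0
    p = float(pmf[pmf <= pmf[x] * (1.0 + _TIE_RTOL)].sum() / pmf.sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    counts: pd.DataFrame,
    treated: str,
    control: str,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature DE table from a two-column count matrix.

    Fold change is treated/control on the CPM scale with a 0.5 pseudocount
    added to both counts; p-values come from :func:`unreplicated_count_test`
    and are BH-adjusted over the testable features only (features with zero
    counts in both libraries are untestable and excluded from the family,
    reported with p = 1 and missing FDR).
    """
    for col in (treated, control):
        if col not in counts.columns:
            raise ValueError(f"sample {col!r} not in count matrix")
    x = counts[treated].to_numpy()
    y = counts[control].to_numpy()
    n_t, n_c = int(x.sum()), int(y.sum())
    if n_t <= 0 or n_c <= 0:
        raise ValueError("both libraries must contain reads")

    fc = ((x + 0.5) / n_t) / ((y + 0.5) / n_c)
    testable = (x + y) > 0
    pvalues = np.ones(len(counts))
    for i in np.nonzero(testable)[0]:
        pvalues[i] = unreplicated_count_test(int(x[i]), int(y[i]), n_t, n_c)
    fdr = np.full(len(counts), np.nan)
    fdr[testable] = bh_fdr(pvalues[testable])

    direction = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    with np.errstate(invalid="ignore"):
        significant = (
            ((fc > fc_min) | (fc < 1.0 / fc_min))
            & (pvalues < alpha)
            & (np.nan_to_num(fdr, nan=1.0) < fdr_alpha)
            & testable
        )
    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "fc": fc,
            "log2fc": np.log2(fc),
            "pvalue": pvalues,
            "fdr": fdr,
            "direction": direction,
            "significant": significant,
            "tested": testable,
        }
    ).set_index("feature_id")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values for one target/reference pair in treated and control."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    @property
    def ddct(self) -> float:
        return (self.ct_target_treated - self.ct_ref_treated) - (
            self.ct_target_control - self.ct_ref_control
        )

    @property
    def ratio(self) -> float:
        return float(2.0 ** (-self.ddct))


def ddct_ratio(m: QpcrMeasurement) -> float:
    """Relative expression change by the 2^-ddCt method."""
    return m.ratio
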