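"""Parameter-score correlation analysis.

After model selection, each essay contributes a parameter vector
(mu_1..mu_K, sigma_1..sigma_K, pi_1..pi_K, components ordered by mean).
This module correlates those parameters with the two human strand scores
using Pearson r with Fisher-z confidence intervals, mirroring the
reporting convention of an asterisk for intervals excluding zero.  No
multiplicity correction is applied; the output metadata says so.

Scores are treated as numeric for Pearson r (the ordinal scale is
small); ``method="spearman"`` switches to a rank-based coefficient for
sensitivity checks.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import EssayRecord, ValidationError
from .em import MixtureFit


def pearson_ci(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Sample Pearson r with a Fisher-z confidence interval.

    z = atanh(r) is treated as Normal with SE 1/sqrt(n-3); the interval
    is back-transformed with tanh.  Requires n >= 4 and non-constant
    inputs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 4:
        raise ValidationError("need at least 4 observations for a Fisher-z interval")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for a constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, r, r
    z = math.atanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return r, math.tanh(z - half), math.tanh(z + half)


def parameter_score_table(
    corpus: Sequence[EssayRecord],
    fits: dict[str, MixtureFit | None],
    K: int,
) -> tuple[pd.DataFrame, int]:
    """One row per essay with a converged K-component fit.

    Columns mu_1..mu_K, sigma_1..sigma_K, pi_1..pi_K (ordered
    components) plus strand1/strand3.  Returns the table and the number
    of essays dropped for lacking a converged fit at this K.
    """
    rows, dropped = [], 0
    for essay in corpus:
        fit = fits.get(essay.essay_id)
        if fit is None or not fit.converged or fit.K != K:
            dropped += 1
            continue
        row = {"essay_id": essay.essay_id}
        for k in range(K):
            row[f"mu_{k + 1}"] = float(fit.spec.mu[k])
            row[f"sigma_{k + 1}"] = float(fit.spec.sigma[k])
            row[f"pi_{k + 1}"] = float(fit.spec.pi[k])
        row["strand1"] = essay.strand1
        row["strand3"] = essay.strand3
        rows.append(row)
    return pd.DataFrame(rows), dropped


def parameter_score_correlations(
    table: pd.DataFrame, alpha: float = 0.05, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate every mixture parameter with both strand scores.

    One row per parameter with r, CI bounds and a CI-excludes-zero flag
    for each strand.  ``attrs['multiplicity_correction']`` records that
    none is applied.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError("method must be 'pearson' or 'spearman'")
    params = [c for c in table.columns if c.partition("_")[0] in ("mu", "sigma", "pi")]
    if not params:
        raise ValidationError("table has no parameter columns")
    if len(table) < 4:
        raise ValidationError("need at least 4 essays")
    out = []
    for p in params:
        row: dict = {"parameter": p}
        for strand in ("strand1", "strand3"):
            x = table[p].to_numpy(float)
            y = table[strand].to_numpy(float)
            if method == "spearman":
                x = stats.rankdata(x)
                y = stats.rankdata(y)
            r, lo, hi = pearson_ci(x, y, alpha=alpha)
            row[f"r_{strand}"] = r
            row[f"ci_lo_{strand}"] = lo
            row[f"ci_hi_{strand}"] = hi
            row[f"sig_{strand}"] = bool(lo > 0 or hi < 0)
        out.append(row)
    df = pd.DataFrame(out)
    df.attrs["alpha"] = alpha
    df.attrs["method"] = method
    df.attrs["multiplicity_correction"] = "none"
    return df


def score_band_dispersion(table: pd.DataFrame, parameter: str, score_column: str) -> pd.DataFrame:
    """Spread of a parameter within each observed score level.

    Quantifies the funnel pattern (low-score essays spread widely in
    pi_1, high-score essays do not) as per-level count, IQR and SD.
    Levels with a single essay get NaN spreads and ``defined=False``.
    """
    if parameter not in table.columns or score_column not in table.columns:
        raise ValidationError("unknown parameter or score column")
    levels = table[score_column].unique()
    if len(levels) < 2:
        raise ValidationError("need at least 2 score levels")
    rows = []
    for level, grp in table.groupby(score_column):
        vals = grp[parameter].to_numpy(float)
        defined = vals.size >= 2
        rows.append(
            {
                "score": level,
                "n": vals.size,
                "iqr": float(np.subtract(*np.percentile(vals, [75, 25]))) if defined else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if defined else float("nan"),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows).sort_values("score").reset_index(drop=True)


def plot_parameter_score_matrix(table: pd.DataFrame, columns=None, path=None):
    """Scatter matrix of parameters vs scores (optional report figure)."""
    import matplotlib

    matplotlib.use("Agg")
    from pandas.plotting import scatter_matrix
    import matplotlib.pyplot as plt

    cols = list(columns) if columns else [c for c in table.columns if c != "essay_id"]
    axes = scatter_matrix(table[cols], figsize=(2 * len(cols), 2 * len(cols)), diagonal="hist")
    fig = axes[0, 0].get_figure()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
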