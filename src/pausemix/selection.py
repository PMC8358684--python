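"""Model-order selection: AIC/BIC over K plus a component-separation screen.

Each essay is fit with K = 2..5 mixtures; information criteria compare
them (lower is better).  A K-component lognormal mixture has 3K - 1 free
parameters: K means, K SDs, and K - 1 free mixing proportions (the last
is fixed by the simplex constraint), i.e. 5, 8, 11, 14 for K = 2..5.

Information criteria reward added components even when the extra means
sit nearly on top of each other, where parameter precision collapses.
The separation screen computes all pairwise distances |mu_i - mu_j|
between the ordered component means (on the log scale the model is fit
on) and grades each fit against two cut-points: distances >= 1 are "well
separated", >= 0.3 "reasonably separated".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import MixtureSpec, ValidationError
from .em import MixtureFit


class NoModelSelectedError(ValueError):
    """No converged fit was available to choose among."""


def count_parameters(K: int) -> int:
    """Free parameters of a K-component mixture: 3K - 1."""
    if K < 1:
        raise ValidationError("K must be >= 1")
    return 3 * K - 1


def aic(loglik: float, p: int) -> float:
    """Akaike information criterion, -2*loglik + 2p."""
    return -2.0 * loglik + 2.0 * p


def bic(loglik: float, p: int, N: int) -> float:
    """Bayesian information criterion, -2*loglik + p*ln(N).

    N is the number of pause events the mixture was fit to.
    """
    if N < 1:
        raise ValidationError("N must be >= 1")
    return -2.0 * loglik + p * math.log(N)


@dataclass
class SelectionRecord:
    """Per-essay model comparison across the K sweep.

    ``per_k`` maps each candidate K to a dict with keys p, loglik, aic,
    bic, converged (loglik/aic/bic are None for inestimable fits).  The
    chosen K is the argmin over *converged* fits only, ties to the
    smaller K; ``agreement`` records whether AIC and BIC picked the same
    model.
    """

    essay_id: str
    n_events: int
    per_k: dict[int, dict] = field(default_factory=dict)
    chosen_k_aic: int | None = None
    chosen_k_bic: int | None = None

    @property
    def agreement(self) -> bool | None:
        if self.chosen_k_aic is None:
            return None
        return self.chosen_k_aic == self.chosen_k_bic


@dataclass(frozen=True)
class SeparationConfig:
    """Cut-points (log scale) for the mean-distance screen."""

    cut_well: float = 1.0
    cut_reasonable: float = 0.3

    def __post_init__(self) -> None:
        if not (self.cut_well > self.cut_reasonable > 0):
            raise ValidationError("require cut_well > cut_reasonable > 0")


def select_model(fits: dict[int, MixtureFit | None], N: int, essay_id: str = "") -> SelectionRecord:
    """Choose K by AIC and by BIC over the converged fits.

    ``fits`` maps K to a fit (or None when K was not estimable).  Raises
    :class:`NoModelSelectedError` when no fit converged.
    """
    rec = SelectionRecord(essay_id=essay_id, n_events=N)
    for K in sorted(fits):
        fit = fits[K]
        p = count_parameters(K)
        if fit is None:
            rec.per_k[K] = {"p": p, "loglik": None, "aic": None, "bic": None, "converged": False}
        else:
            rec.per_k[K] = {
                "p": p,
                "loglik": fit.loglik,
                "aic": aic(fit.loglik, p),
                "bic": bic(fit.loglik, p, N),
                "converged": bool(fit.converged),
            }
    candidates = [K for K, d in rec.per_k.items() if d["converged"]]
    if not candidates:
        raise NoModelSelectedError(f"essay {essay_id!r}: no converged fit among K={sorted(fits)}")
    # min() over sorted K ties to the smaller K
    rec.chosen_k_aic = min(candidates, key=lambda K: (rec.per_k[K]["aic"], K))
    rec.chosen_k_bic = min(candidates, key=lambda K: (rec.per_k[K]["bic"], K))
    return rec


def pairwise_mean_distances(spec: MixtureSpec) -> list[float]:
    """|mu_i - mu_j| for all pairs i < j of an ordered spec.

    K(K-1)/2 quantities in the order (1,2), (1,3), ..., (K-1,K); three at
    K=3, six at K=4.  Empty for a single component.
    """
    if not spec.is_ordered:
        raise ValidationError("spec must be ordered by mean before computing distances")
    mu = spec.mu
    return [float(abs(mu[j] - mu[i])) for i in range(spec.K) for j in range(i + 1, spec.K)]


def separation_summary(
    fits: list[MixtureFit],
    config: SeparationConfig | None = None,
    unit: str = "essays",
) -> dict:
    """Percent of well- and reasonably-separated cases among same-K fits.

    With ``unit="essays"`` (the strict reading) an essay counts as well
    separated only if *every* pairwise mean distance clears the cut;
    ``unit="pairs"`` instead pools all pairwise distances and reports the
    percentage of pairs clearing each cut.  Cut comparisons are
    inclusive (distance equal to the cut-point passes).
    """
    cfg = config or SeparationConfig()
    if not fits:
        raise ValidationError("separation_summary needs at least one fit")
    Ks = {f.K for f in fits}
    if len(Ks) != 1:
        raise ValidationError(f"all fits must share the same K, got {sorted(Ks)}")
    if unit not in ("essays", "pairs"):
        raise ValidationError("unit must be 'essays' or 'pairs'")
    dists = [pairwise_mean_distances(f.spec) for f in fits]
    if unit == "essays":
        well = np.mean([all(d >= cfg.cut_well for d in ds) for ds in dists])
        reasonable = np.mean([all(d >= cfg.cut_reasonable for d in ds) for ds in dists])
    else:
        flat = np.concatenate(dists) if dists[0] else np.empty(0)
        well = np.mean(flat >= cfg.cut_well) if flat.size else float("nan")
        reasonable = np.mean(flat >= cfg.cut_reasonable) if flat.size else float("nan")
    return {
        "unit": unit,
        "K": Ks.pop(),
        "cut_well": cfg.cut_well,
        "cut_reasonable": cfg.cut_reasonable,
        "pct_well_separated": 100.0 * float(well),
        "pct_reasonably_separated": 100.0 * float(reasonable),
        "n_fits": len(fits),
    }


def convergence_census(converged_flags: dict[str, dict[int, bool]], k_values=(2, 3, 4, 5)) -> dict:
    """Nested convergence counts across the corpus.

    ``converged_flags[essay_id][K]`` says whether the K-component fit of
    that essay converged.  The census counts essays converging to K=2,
    to K=2 and 3, to K=2..4, and to K=2..5 — a non-increasing sequence by
    construction.
    """
    ks = sorted(k_values)
    counts = {}
    for j in range(len(ks)):
        prefix = ks[: j + 1]
        n = sum(
            1
            for flags in converged_flags.values()
            if all(flags.get(K, False) for K in prefix)
        )
        counts["K<=%d" % prefix[-1]] = n
    return {
        "n_essays": len(converged_flags),
        "k_values": ks,
        "nested_counts": counts,
    }
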