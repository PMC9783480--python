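"""Dataset-level quantities: ln-RMA slope, SDTD, male-female correlation,
gradient length, and corpus-level diagnostics.

The effect size for a dataset is the natural log of the reduced major axis
(RMA) regression slope of ln(male development time) on ln(female development
time) across treatments.  Zero means proportional plasticity in the two
sexes; positive values mean males respond more strongly, negative values
females.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import EffectSize, PrimaryDataset
from .errors import NegativeSlopeError, UndefinedSlopeError

__all__ = [
    "rma_ln_slope",
    "sdtd",
    "gradient_length",
    "compute_effect",
    "compute_effects",
    "corpus_diagnostics",
]


def _cross_products(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ xc), float(yc @ yc), float(xc @ yc)


def rma_ln_slope(ds: PrimaryDataset) -> Tuple[float, Optional[float]]:
    """Return ``(ln_slope, r_mf)`` for a dataset.

    The RMA slope is SD(y)/SD(x) with the sign of the correlation, where
    x = ln(female means) and y = ln(male means); for k = 2 this degenerates
    to |dy|/|dx| with the sign of the paired differences (the same formula).
    ``r_mf`` is the Pearson correlation of the log means, reported only for
    k >= 3.

    Raises
    ------
    UndefinedSlopeError
        If either sex is invariant across treatments (zero spread).
    NegativeSlopeError
        If the correlation is negative or zero (ln of a non-positive slope).
    """
    if ds.k < 2:
        raise ValueError(f"dataset {ds.dataset_id!r}: need k >= 2 treatments")
    x = np.log(ds.female_means)
    y = np.log(ds.male_means)
    sxx, syy, sxy = _cross_products(x, y)
    if sxx <= 0.0 or syy <= 0.0:
        raise UndefinedSlopeError(
            f"dataset {ds.dataset_id!r}: a sex is invariant across treatments"
        )
    if sxy <= 0.0:
        raise NegativeSlopeError(
            f"dataset {ds.dataset_id!r}: ln-slope undefined for negative slope"
        )
    # 0.5*(log syy - log sxx) == log(SD(y)/SD(x)); written this way the
    # sex-swap antisymmetry ln_slope -> -ln_slope is exact in floating point.
    ln_slope = 0.5 * (math.log(syy) - math.log(sxx))
    r_mf: Optional[float] = None
    if ds.k >= 3:
        r_mf = min(1.0, max(-1.0, sxy / math.sqrt(sxx * syy)))
    return ln_slope, r_mf


def sdtd(ds: PrimaryDataset) -> float:
    """Mean signed sexual development-time dimorphism over treatments.

    Per treatment: (longer sex / shorter sex) - 1, positive when females
    develop longer, negative when males do, 0 on an exact tie; the dataset
    value is the arithmetic mean over treatments.
    """
    vals = []
    for r in ds.records:
        f, m = r.female_mean_dt, r.male_mean_dt
        if f > m:
            vals.append(f / m - 1.0)
        elif m > f:
            vals.append(-(m / f - 1.0))
        else:
            vals.append(0.0)
    return float(np.mean(vals))


def gradient_length(ds: PrimaryDataset, per_sex: bool = False) -> float:
    """Fold-difference between maximum and minimum mean development times.

    By default the max/min ratio pools both sexes' treatment means.  With
    ``per_sex=True`` the geometric mean of the two within-sex max/min ratios
    is returned instead.
    """
    m, f = ds.male_means, ds.female_means
    if per_sex:
        rm = m.max() / m.min()
        rf = f.max() / f.min()
        return float(math.sqrt(rm * rf))
    allv = np.concatenate([m, f])
    return float(allv.max() / allv.min())


def compute_effect(ds: PrimaryDataset) -> EffectSize:
    """Compute the EffectSize row for one dataset (no uncertainty yet)."""
    ln_slope, r_mf = rma_ln_slope(ds)
    return EffectSize(
        dataset_id=ds.dataset_id,
        study_id=ds.study_id,
        species=ds.species,
        order_name=ds.order_name,
        trait=ds.trait,
        factor=ds.factor,
        k=ds.k,
        ln_slope=ln_slope,
        sdtd=sdtd(ds),
        gradient_length=gradient_length(ds),
        r_mf=r_mf,
    )


def compute_effects(
    datasets: Iterable[PrimaryDataset],
) -> Tuple[list, list]:
    """Compute effects for every dataset; return ``(effects, failures)``.

    ``failures`` is a list of ``(dataset_id, reason)`` for datasets whose
    ln-slope is undefined (invariant sex or negative slope); such datasets
    are flagged for manual review rather than silently dropped.
    """
    effects, failures = [], []
    for ds in datasets:
        try:
            effects.append(compute_effect(ds))
        except (UndefinedSlopeError, NegativeSlopeError) as exc:
            failures.append((ds.dataset_id, str(exc)))
    return effects, failures


def corpus_diagnostics(
    effects: Iterable[EffectSize],
    r_threshold: float = 0.98,
    n_bins: int = 20,
) -> dict:
    """Corpus-level descriptive summaries.

    Returns a dict with, per trait: counts of female-longer / male-longer /
    tied datasets by SDTD sign; among k >= 3 datasets the number whose
    male-female log-scale correlation reaches ``r_threshold``; mean gradient
    length by factor; and ln-slope histogram bin counts by factor.
    """
    effects = list(effects)
    out: dict = {"r_threshold": r_threshold, "by_trait": {}, "by_factor": {}}
    df = pd.DataFrame(
        {
            "trait": [e.trait for e in effects],
            "factor": [e.factor for e in effects],
            "sdtd": [e.sdtd for e in effects],
            "r_mf": [math.nan if e.r_mf is None else e.r_mf for e in effects],
            "k": [e.k for e in effects],
            "ln_slope": [e.ln_slope for e in effects],
            "gradient_length": [e.gradient_length for e in effects],
        }
    )
    for trait, sub in df.groupby("trait"):
        k3 = sub[sub["k"] >= 3]
        out["by_trait"][trait] = {
            "n_datasets": int(len(sub)),
            "n_female_longer": int((sub["sdtd"] > 0).sum()),
            "n_male_longer": int((sub["sdtd"] < 0).sum()),
            "n_tied": int((sub["sdtd"] == 0).sum()),
            "n_k3": int(len(k3)),
            "n_k3_high_r": int((k3["r_mf"] >= r_threshold).sum()),
        }
    for factor, sub in df.groupby("factor"):
        counts, edges = np.histogram(sub["ln_slope"].to_numpy(), bins=n_bins)
        out["by_factor"][factor] = {
            "n_datasets": int(len(sub)),
            "mean_gradient_length": float(sub["gradient_length"].mean()),
            "ln_slope_hist_counts": counts.tolist(),
            "ln_slope_hist_edges": edges.tolist(),
        }
    return out
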