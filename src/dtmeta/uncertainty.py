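"""Bootstrap sampling variability of the ln-slope and meta-analytic weights.

For each replicate, one value per (sex, treatment) mean is drawn from a
uniform distribution centred on the reported mean whose width is set by the
reported SE; the ln-slope is recomputed on the perturbed dataset.  The SD of
the replicate ln-slopes is the sampling-variability estimate, and its squared
inverse the meta-analytic weight.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .datatypes import BootstrapConfig, EffectSize, PrimaryDataset
from .errors import BootstrapUnstableError

__all__ = ["BootstrapResult", "bootstrap_slope_sd", "attach_uncertainty", "child_rng"]

_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class BootstrapResult:
    boot_sd: float
    weight: float
    n_rejected: int


def half_width(se: np.ndarray, width_rule: str) -> np.ndarray:
    """Half-width of the uniform draw interval for the given rule.

    ``sd_matched`` uses sqrt(3)*SE so the uniform's SD equals the SE;
    ``half_width_se`` uses the SE itself as the half-width.
    """
    if width_rule == "sd_matched":
        return _SQRT3 * se
    if width_rule == "half_width_se":
        return np.asarray(se, dtype=float)
    raise ValueError(f"unknown width_rule {width_rule!r}")


def child_rng(seed: int, key: str) -> np.random.Generator:
    """Deterministic per-dataset generator derived from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(key.encode("utf-8")),))
    )


def _batch_ln_slopes(fx: np.ndarray, mx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ln-slope over a (reps, k) batch of female/male draws.

    Returns ``(ln_slopes, valid)`` where invalid rows had non-positive draws,
    zero spread in a sex, or a non-positive cross-product (negative slope).
    """
    pos = (fx > 0).all(axis=1) & (mx > 0).all(axis=1)
    fx = np.where(fx > 0, fx, 1.0)  # placeholder; masked out below
    mx = np.where(mx > 0, mx, 1.0)
    x = np.log(fx)
    y = np.log(mx)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    valid = pos & (sxx > 0) & (syy > 0) & (sxy > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ln_slopes = 0.5 * (np.log(syy) - np.log(sxx))
    return ln_slopes, valid


def bootstrap_slope_sd(
    ds: PrimaryDataset,
    cfg: BootstrapConfig,
    rng: Optional[np.random.Generator] = None,
) -> BootstrapResult:
    """Bootstrap SD of a dataset's ln-slope and the derived weight.

    Replicates with an undefined slope (sign flip or zero spread) are redrawn
    so that exactly ``cfg.n_reps`` replicates contribute; the rejection count
    is reported.  If more than half of all attempted replicates are rejected
    the dataset is flagged as unstable.
    """
    if not ds.has_se:
        raise ValueError(
            f"dataset {ds.dataset_id!r} lacks SEs; it is qualitative-only"
        )
    if rng is None:
        rng = child_rng(cfg.seed, ds.dataset_id)
    f_mean, m_mean = ds.female_means, ds.male_means
    f_half = half_width(ds.female_ses, cfg.width_rule)
    m_half = half_width(ds.male_ses, cfg.width_rule)

    n = cfg.n_reps
    slopes = np.empty(n)
    filled = 0
    rejected = 0
    attempts = 0
    while filled < n:
        todo = n - filled
        fx = f_mean + f_half * rng.uniform(-1.0, 1.0, size=(todo, ds.k))
        mx = m_mean + m_half * rng.uniform(-1.0, 1.0, size=(todo, ds.k))
        ln_slopes, valid = _batch_ln_slopes(fx, mx)
        good = ln_slopes[valid]
        slopes[filled : filled + good.size] = good
        filled += good.size
        rejected += todo - good.size
        attempts += todo
        if attempts > 20 * n:
            raise BootstrapUnstableError(
                f"bootstrap unstable for dataset {ds.dataset_id!r}: "
                f"{rejected}/{attempts} replicates rejected"
            )
    if rejected > attempts // 2:
        raise BootstrapUnstableError(
            f"bootstrap unstable for dataset {ds.dataset_id!r}: "
            f"{rejected}/{attempts} replicates rejected"
        )
    boot_sd = float(np.std(slopes, ddof=1))
    boot_sd = max(boot_sd, cfg.degenerate_floor)
    return BootstrapResult(boot_sd=boot_sd, weight=boot_sd**-2, n_rejected=rejected)


def attach_uncertainty(
    effects: Iterable[EffectSize],
    datasets: Sequence[PrimaryDataset],
    cfg: BootstrapConfig,
) -> list:
    """Fill ``boot_sd`` and ``weight`` on every quantitative effect.

    Qualitative-only datasets (missing SEs) are left untouched.  Each dataset
    gets its own generator derived from ``cfg.seed`` and its id, so results
    do not depend on iteration order.
    """
    by_id = {ds.dataset_id: ds for ds in datasets}
    effects = list(effects)
    for eff in effects:
        ds = by_id.get(eff.dataset_id)
        if ds is None:
            raise KeyError(f"no dataset matches effect {eff.dataset_id!r}")
        if not ds.has_se:
            continue
        res = bootstrap_slope_sd(ds, cfg)
        eff.boot_sd = res.boot_sd
        eff.weight = res.weight
        eff.n_boot_rejected = res.n_rejected
    return effects
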