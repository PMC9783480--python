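"""Permutation reference distributions.

Three bespoke tests:

* overall pooled-mean test — male and female columns (means with their SEs)
  are independently swapped within each treatment of each dataset, effect
  sizes recomputed, and the multilevel model refitted to build the null
  distribution of the z statistic;
* moderator test — dataset-level moderator values (SDTD) are shuffled across
  effect sizes with everything else held fixed;
* paired factor comparison — per-species differences of absolute
  standardized ln-slopes between two factors, tested by random sign flips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    BootstrapConfig,
    EffectSize,
    MetaFit,
    PairedRecord,
    PermutationConfig,
    PhyloCorrelation,
    PrimaryDataset,
)
from .effect_size import compute_effect, rma_ln_slope
from .errors import DegenerateModeratorError, FitError
from .phylo_meta import MultilevelModel, build_model, fit_meta
from .uncertainty import bootstrap_slope_sd

__all__ = [
    "sex_permute_dataset",
    "PermutationTestResult",
    "permutation_test_overall",
    "permutation_test_moderator",
    "standardize_slopes",
    "PairedTestResult",
    "paired_temp_diet_test",
]


def sex_permute_dataset(ds: PrimaryDataset, rng: np.random.Generator) -> PrimaryDataset:
    """Independently per treatment, swap the sexes with probability 1/2."""
    records = tuple(
        r.swapped() if rng.random() < 0.5 else r for r in ds.records
    )
    return replace(ds, records=records)


def _perm_p(null: np.ndarray, obs: float, two_sided: bool) -> float:
    if two_sided:
        hits = int(np.sum(np.abs(null) >= abs(obs)))
    else:
        hits = int(np.sum(null >= obs))
    return (1 + hits) / (1 + null.size)


@dataclass
class PermutationTestResult:
    z_obs: float
    p_perm: float
    null_z: np.ndarray
    fit_obs: MetaFit
    n_failed: int = 0
    n_resampled_datasets: int = 0

    def null_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_null": self.null_z})


class _CorpusPermuter:
    """Vectorized within-treatment sex swapping for a whole corpus.

    Stores the log-mean arrays per dataset and recomputes all permuted
    ln-slopes in a handful of numpy operations per replicate.  Swap patterns
    that leave a dataset with an undefined slope (negative correlation or
    zero spread) are redrawn for that dataset alone.
    """

    def __init__(self, datasets: Sequence[PrimaryDataset]):
        self.datasets = list(datasets)
        self._groups = {}
        for i, ds in enumerate(self.datasets):
            x = np.log(ds.female_means)
            y = np.log(ds.male_means)
            self._groups.setdefault(ds.k, []).append((i, x, y))
        self._stacks = []
        for k in sorted(self._groups):
            members = self._groups[k]
            idx = np.array([m[0] for m in members])
            X = np.stack([m[1] for m in members])
            Y = np.stack([m[2] for m in members])
            self._stacks.append((k, idx, X, Y))
        self.n = len(self.datasets)

    @staticmethod
    def _slopes(X: np.ndarray, Y: np.ndarray):
        xc = X - X.mean(axis=1, keepdims=True)
        yc = Y - Y.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", xc, xc)
        syy = np.einsum("ij,ij->i", yc, yc)
        sxy = np.einsum("ij,ij->i", xc, yc)
        valid = (sxx > 0) & (syy > 0) & (sxy > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = 0.5 * (np.log(syy) - np.log(sxx))
        return s, valid

    def permuted_slopes(self, rng: np.random.Generator, max_tries: int = 100):
        """One replicate of permuted ln-slopes; returns (slopes, n_redrawn)."""
        out = np.empty(self.n)
        redrawn = 0
        for k, idx, X, Y in self._stacks:
            mask = rng.random(X.shape) < 0.5
            Xp = np.where(mask, Y, X)
            Yp = np.where(mask, X, Y)
            s, valid = self._slopes(Xp, Yp)
            tries = 0
            while not valid.all():
                tries += 1
                if tries > max_tries:
                    bad = idx[~valid]
                    raise FitError(
                        f"cannot find a valid swap pattern for dataset(s) "
                        f"{[self.datasets[i].dataset_id for i in bad]}"
                    )
                bad = np.where(~valid)[0]
                redrawn += bad.size
                mask = rng.random((bad.size, k)) < 0.5
                Xp = np.where(mask, Y[bad], X[bad])
                Yp = np.where(mask, X[bad], Y[bad])
                s2, v2 = self._slopes(Xp, Yp)
                s[bad] = s2
                valid[bad] = v2
            out[idx] = s
        return out, redrawn


def _refit_z(model_template: MultilevelModel, y: np.ndarray, v: np.ndarray,
             X: np.ndarray, warm: Optional[np.ndarray], test_idx: int,
             maxiter: int, ftol: float, gtol: float) -> float:
    m = MultilevelModel(y, v, X, model_template.A, model_template.S)
    # looser default tolerances: a replicate only feeds one draw of the null z
    theta, _, _ = m.fit(n_restarts=1, warm_start=warm, maxiter=maxiter,
                        ftol=ftol, gtol=gtol)
    beta, cov = m.gls(np.exp(theta))
    return float(beta[test_idx] / math.sqrt(cov[test_idx, test_idx]))


def permutation_test_overall(
    datasets: Sequence[PrimaryDataset],
    corr: Optional[PhyloCorrelation],
    cfg: PermutationConfig,
    boot_cfg: Optional[BootstrapConfig] = None,
    recompute_variances: bool = True,
    max_failure_rate: float = 0.01,
    fit_restarts: int = 3,
    perm_maxiter: int = 100,
    perm_ftol: float = 1e-9,
    perm_gtol: float = 1e-6,
) -> PermutationTestResult:
    """Permutation test of the pooled mean effect size.

    ``recompute_variances=True`` (default) reruns the bootstrap on every
    permuted dataset, mirroring the permutation of means together with their
    SEs; the fast mode reuses the observed per-dataset bootstrap SDs, which
    are sex-swap invariant in distribution.
    """
    boot_cfg = boot_cfg or BootstrapConfig(seed=cfg.seed)
    datasets = list(datasets)
    effects = [compute_effect(ds) for ds in datasets]
    for eff, ds in zip(effects, datasets):
        res = bootstrap_slope_sd(ds, boot_cfg)
        eff.boot_sd, eff.weight = res.boot_sd, res.weight
    fit_obs = fit_meta(effects, corr, n_restarts=fit_restarts)
    z_obs = fit_obs.z_stat
    warm = getattr(fit_obs, "_theta", None)

    model = build_model(effects, corr)
    v_obs = np.array([e.boot_sd**2 for e in effects])
    rng = np.random.default_rng(cfg.seed)
    permuter = _CorpusPermuter(datasets)

    null_z = np.empty(cfg.n_perms)
    n_failed = 0
    n_redrawn = 0
    for b in range(cfg.n_perms):
        try:
            if recompute_variances:
                y, v, nr = _permute_full(datasets, rng, boot_cfg)
                n_redrawn += nr
            else:
                y, nr = permuter.permuted_slopes(rng)
                v = v_obs
                n_redrawn += nr
            null_z[b] = _refit_z(model, y, v, model.X, warm, 0, perm_maxiter,
                                 perm_ftol, perm_gtol)
            if not np.isfinite(null_z[b]):
                raise FitError("non-finite z")
        except FitError:
            null_z[b] = np.nan
            n_failed += 1
    if n_failed > max_failure_rate * cfg.n_perms:
        raise FitError(
            f"{n_failed}/{cfg.n_perms} permutation replicates failed to fit"
        )
    null_z = null_z[np.isfinite(null_z)]
    return PermutationTestResult(
        z_obs=z_obs,
        p_perm=_perm_p(null_z, z_obs, cfg.two_sided),
        null_z=null_z,
        fit_obs=fit_obs,
        n_failed=n_failed,
        n_resampled_datasets=n_redrawn,
    )


def _permute_full(datasets, rng, boot_cfg, max_tries: int = 100):
    """Object-level permutation replicate with bootstrap recomputation."""
    y = np.empty(len(datasets))
    v = np.empty(len(datasets))
    redrawn = 0
    for i, ds in enumerate(datasets):
        for attempt in range(max_tries):
            perm = sex_permute_dataset(ds, rng)
            try:
                y[i], _ = rma_ln_slope(perm)
            except Exception:
                redrawn += 1
                continue
            res = bootstrap_slope_sd(perm, boot_cfg, rng=rng)
            v[i] = res.boot_sd**2
            break
        else:
            raise FitError(f"no valid swap pattern for dataset {ds.dataset_id!r}")
    return y, v, redrawn


def permutation_test_moderator(
    effects: Sequence[EffectSize],
    corr: Optional[PhyloCorrelation],
    cfg: PermutationConfig,
    moderator: str = "sdtd",
    max_failure_rate: float = 0.01,
    fit_restarts: int = 3,
    perm_maxiter: int = 100,
    perm_ftol: float = 1e-9,
    perm_gtol: float = 1e-6,
) -> PermutationTestResult:
    """Permutation test of the moderator coefficient.

    Null replicates shuffle the dataset-level moderator values across effect
    sizes; ln-slopes, sampling variances and grouping stay fixed.
    """
    effects = list(effects)
    values = np.array([getattr(e, moderator) for e in effects], dtype=float)
    if np.ptp(values) == 0:
        raise DegenerateModeratorError(
            f"moderator {moderator!r} has no variation; nothing to permute"
        )
    fit_obs = fit_meta(effects, corr, moderator=moderator, n_restarts=fit_restarts)
    z_obs = fit_obs.z_stat
    warm = getattr(fit_obs, "_theta", None)
    model = build_model(effects, corr, moderator=moderator)
    y = model.y
    v = model.v
    rng = np.random.default_rng(cfg.seed)
    null_z = np.empty(cfg.n_perms)
    n_failed = 0
    for b in range(cfg.n_perms):
        X = np.column_stack([np.ones(len(effects)), rng.permutation(values)])
        try:
            null_z[b] = _refit_z(model, y, v, X, warm, 1, perm_maxiter,
                                 perm_ftol, perm_gtol)
            if not np.isfinite(null_z[b]):
                raise FitError("non-finite z")
        except FitError:
            null_z[b] = np.nan
            n_failed += 1
    if n_failed > max_failure_rate * cfg.n_perms:
        raise FitError(
            f"{n_failed}/{cfg.n_perms} permutation replicates failed to fit"
        )
    null_z = null_z[np.isfinite(null_z)]
    return PermutationTestResult(
        z_obs=z_obs,
        p_perm=_perm_p(null_z, z_obs, cfg.two_sided),
        null_z=null_z,
        fit_obs=fit_obs,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# Paired factor comparison
# ---------------------------------------------------------------------------

STD_RULES = ("none", "gradient_scaled")


def _std_value(e: EffectSize, std_rule: str) -> float:
    if std_rule == "none":
        return abs(e.ln_slope)
    if std_rule == "gradient_scaled":
        # cumulative log male/female divergence across the observed gradient
        return abs(e.ln_slope) * math.log(e.gradient_length)
    raise ValueError(f"unknown std_rule {std_rule!r}")


def standardize_slopes(
    effects: Iterable[EffectSize],
    std_rule: str = "none",
) -> Tuple[List[PairedRecord], List[Tuple[str, str]]]:
    """Build per-species temperature/diet pairs of |standardized ln-slope|.

    A species qualifies when it contributes at least one effect for each
    factor on the same development-time trait ("total" preferred when both
    qualify); multiple effects per (species, factor, trait) are averaged.
    Returns ``(pairs, skipped)`` with skip reasons.
    """
    if std_rule not in STD_RULES:
        raise ValueError(f"std_rule must be one of {STD_RULES}")
    by_species: dict = {}
    for e in effects:
        by_species.setdefault(e.species, {}).setdefault(
            (e.factor, e.trait), []
        ).append(_std_value(e, std_rule))
    pairs: List[PairedRecord] = []
    skipped: List[Tuple[str, str]] = []
    for sp in sorted(by_species):
        slots = by_species[sp]
        traits = [t for t in ("total", "larval")
                  if ("temperature", t) in slots and ("diet", t) in slots]
        if not traits:
            skipped.append((sp, "no factor pair on a common trait"))
            continue
        trait = traits[0]
        pairs.append(PairedRecord(
            species=sp,
            abs_std_slope_temp=float(np.mean(slots[("temperature", trait)])),
            abs_std_slope_diet=float(np.mean(slots[("diet", trait)])),
            trait=trait,
            std_rule=std_rule,
        ))
    return pairs, skipped


@dataclass
class PairedTestResult:
    statistic: float  # mean over species of (diet - temperature) magnitudes
    p_perm: float
    table: pd.DataFrame
    null: np.ndarray
    n_excluded: int
    exact: bool


def paired_temp_diet_test(
    pairs: Sequence[PairedRecord],
    cfg: Optional[PermutationConfig] = None,
    exclusions: Sequence[str] = (),
    exact: bool = False,
) -> PairedTestResult:
    """Sign-flip permutation test for the paired factor comparison.

    The statistic is the species-mean of (diet - temperature) absolute
    standardized ln-slopes; the null flips each species' difference sign
    independently.  ``exact=True`` enumerates all 2^n sign patterns (n <= 20)
    instead of Monte-Carlo sampling.
    """
    cfg = cfg or PermutationConfig()
    excl = set(exclusions)
    used = [p for p in pairs if p.species not in excl]
    if len(used) < 2:
        raise ValueError("need at least 2 species pairs after exclusions")
    diffs = np.array([p.abs_std_slope_diet - p.abs_std_slope_temp for p in used])
    t_obs = float(diffs.mean())
    n = diffs.size
    if exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20 pairs")
        patterns = np.array([[1 if (m >> i) & 1 else -1 for i in range(n)]
                             for m in range(2**n)], dtype=float)
        null = patterns @ diffs / n
        if cfg.two_sided:
            p = float(np.mean(np.abs(null) >= abs(t_obs) - 1e-15))
        else:
            p = float(np.mean(null >= t_obs - 1e-15))
    else:
        rng = np.random.default_rng(cfg.seed)
        signs = rng.integers(0, 2, size=(cfg.n_perms, n)) * 2 - 1
        null = (signs * diffs).mean(axis=1)
        p = _perm_p(null, t_obs, cfg.two_sided)
    table = pd.DataFrame({
        "species": [p_.species for p_ in used],
        "trait": [p_.trait for p_ in used],
        "abs_std_slope_temp": [p_.abs_std_slope_temp for p_ in used],
        "abs_std_slope_diet": [p_.abs_std_slope_diet for p_ in used],
        "larger_factor": [
            "temperature" if d < 0 else ("diet" if d > 0 else "tie")
            for d in diffs
        ],
    })
    return PairedTestResult(
        statistic=t_obs, p_perm=p, table=table, null=null,
        n_excluded=len(pairs) - len(used), exact=exact,
    )
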