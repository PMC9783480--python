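"""Core domain types.

The unit of analysis is the *primary dataset*: an ordered set of treatment
levels from one experiment on one species, each carrying paired male/female
mean development times (days) and their standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

TRAITS = ("total", "larval")
FACTORS = ("temperature", "diet")


def _is_finite_pos(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x) and x > 0


@dataclass(frozen=True)
class TreatmentRecord:
    """One treatment level's paired male/female means and SEs.

    ``treatment_value`` is a temperature in deg C for the temperature factor
    and an arbitrary (possibly non-numeric) label for diet levels; its
    magnitude never enters any effect-size computation.
    """

    treatment_value: object
    male_mean_dt: float
    female_mean_dt: float
    male_se: Optional[float] = None
    female_se: Optional[float] = None

    def __post_init__(self) -> None:
        if not _is_finite_pos(self.male_mean_dt):
            raise ValueError(f"male_mean_dt must be finite and > 0, got {self.male_mean_dt!r}")
        if not _is_finite_pos(self.female_mean_dt):
            raise ValueError(f"female_mean_dt must be finite and > 0, got {self.female_mean_dt!r}")
        for name in ("male_se", "female_se"):
            se = getattr(self, name)
            if se is not None and not (math.isfinite(se) and se >= 0):
                raise ValueError(f"{name} must be >= 0 or missing, got {se!r}")

    @property
    def has_se(self) -> bool:
        return self.male_se is not None and self.female_se is not None

    def swapped(self) -> "TreatmentRecord":
        """Return the record with male and female columns exchanged."""
        return TreatmentRecord(
            treatment_value=self.treatment_value,
            male_mean_dt=self.female_mean_dt,
            female_mean_dt=self.male_mean_dt,
            male_se=self.female_se,
            female_se=self.male_se,
        )


@dataclass(frozen=True)
class PrimaryDataset:
    """An ordered collection of :class:`TreatmentRecord` from one experiment."""

    dataset_id: str
    study_id: str
    species: str
    order_name: str
    trait: str
    factor: str
    records: tuple

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}, got {self.trait!r}")
        if self.factor not in FACTORS:
            raise ValueError(f"factor must be one of {FACTORS}, got {self.factor!r}")
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        if len(recs) < 1:
            raise ValueError("a dataset needs at least one treatment record")
        values = [r.treatment_value for r in recs]
        if len(set(values)) != len(values):
            raise ValueError(f"duplicate treatment_value in dataset {self.dataset_id!r}")

    @property
    def k(self) -> int:
        return len(self.records)

    @property
    def has_se(self) -> bool:
        return all(r.has_se for r in self.records)

    @property
    def male_means(self) -> np.ndarray:
        return np.array([r.male_mean_dt for r in self.records], dtype=float)

    @property
    def female_means(self) -> np.ndarray:
        return np.array([r.female_mean_dt for r in self.records], dtype=float)

    @property
    def male_ses(self) -> np.ndarray:
        return np.array(
            [math.nan if r.male_se is None else r.male_se for r in self.records], dtype=float
        )

    @property
    def female_ses(self) -> np.ndarray:
        return np.array(
            [math.nan if r.female_se is None else r.female_se for r in self.records], dtype=float
        )

    def swapped(self) -> "PrimaryDataset":
        """Dataset with male and female columns exchanged in every record."""
        return replace(self, records=tuple(r.swapped() for r in self.records))


@dataclass
class EffectSize:
    """Dataset-level effect size and its companions.

    ``ln_slope`` is the natural log of the RMA slope of ln(male DT) on
    ln(female DT); ``weight`` is ``boot_sd ** -2`` once uncertainty has been
    attached.  ``r_mf`` is defined only for k >= 3.
    """

    dataset_id: str
    study_id: str
    species: str
    order_name: str
    trait: str
    factor: str
    k: int
    ln_slope: float
    sdtd: float
    gradient_length: float
    r_mf: Optional[float] = None
    boot_sd: Optional[float] = None
    weight: Optional[float] = None
    n_boot_rejected: Optional[int] = None
    qc_flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isfinite(self.ln_slope):
            raise ValueError("ln_slope must be finite")
        if self.gradient_length < 1.0 - 1e-12:
            raise ValueError("gradient_length must be >= 1")
        if self.r_mf is not None and not -1.0 <= self.r_mf <= 1.0:
            raise ValueError("r_mf must lie in [-1, 1]")
        if self.k < 3 and self.r_mf is not None:
            raise ValueError("r_mf is undefined for k < 3")

    @property
    def sampling_variance(self) -> Optional[float]:
        return None if self.boot_sd is None else self.boot_sd**2


@dataclass(frozen=True)
class SpeciesMapping:
    """Maps corpus species names to tree tip labels.

    ``entries`` maps data species -> (tree_tip, substitution_kind) where the
    kind is one of ``exact``, ``congener``, ``tribe``.
    """

    entries: dict

    KINDS = ("exact", "congener", "tribe")

    def __post_init__(self) -> None:
        for sp, (tip, kind) in self.entries.items():
            if kind not in self.KINDS:
                raise ValueError(f"unknown substitution kind {kind!r} for {sp!r}")

    def tip_for(self, species: str) -> Optional[str]:
        pair = self.entries.get(species)
        return None if pair is None else pair[0]

    @classmethod
    def identity(cls, species: Sequence[str]) -> "SpeciesMapping":
        return cls({sp: (sp, "exact") for sp in species})


@dataclass
class Phylogeny:
    """A rooted tree plus a flag for whether branch lengths were supplied."""

    tree: object  # dendropy.Tree
    has_branch_lengths: bool

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


@dataclass
class PhyloCorrelation:
    """Species-by-species Brownian-motion correlation matrix.

    Unit diagonal, entries in [0, 1], symmetric, positive semidefinite.
    """

    species: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.species)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        m = 0.5 * (m + m.T)
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("matrix must have a unit diagonal")
        if m.min() < -1e-12 or m.max() > 1.0 + 1e-10:
            raise ValueError("entries must lie in [0, 1]")
        eig = np.linalg.eigvalsh(m)
        if eig.min() < -1e-10:
            raise ValueError(f"matrix is not PSD (min eigenvalue {eig.min():.3e})")
        if eig.min() < 0:  # numerically tiny negatives: clip
            w, q = np.linalg.eigh(m)
            m = (q * np.clip(w, 0.0, None)) @ q.T
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 1.0)
        self.matrix = m

    def submatrix(self, species: Sequence[str]) -> "PhyloCorrelation":
        idx = {sp: i for i, sp in enumerate(self.species)}
        missing = [sp for sp in species if sp not in idx]
        if missing:
            raise KeyError(f"species not in correlation matrix: {missing}")
        ix = np.array([idx[sp] for sp in species])
        return PhyloCorrelation(tuple(species), self.matrix[np.ix_(ix, ix)])

    @classmethod
    def identity(cls, species: Sequence[str]) -> "PhyloCorrelation":
        return cls(tuple(species), np.eye(len(species)))


@dataclass
class MetaFit:
    """REML fit of the multilevel meta-analytic model."""

    mu_hat: float
    se_mu: float
    sigma2_phylo: float
    sigma2_study: float
    sigma2_obs: float
    z_stat: float
    n_effects: int
    converged: bool
    loglik_reml: float
    beta_hat: Optional[float] = None
    se_beta: Optional[float] = None
    moderator: Optional[str] = None
    p_param: Optional[float] = None
    p_perm: Optional[float] = None
    df: Optional[float] = None  # Satterthwaite df for the tested coefficient

    @property
    def phylo_var_share(self) -> Optional[float]:
        total = self.sigma2_phylo + self.sigma2_study + self.sigma2_obs
        if total <= 0:
            return None
        return self.sigma2_phylo / total


@dataclass(frozen=True)
class PairedRecord:
    """Per-species pair of absolute standardized ln-slopes for two factors."""

    species: str
    abs_std_slope_temp: float
    abs_std_slope_diet: float
    trait: str
    std_rule: str

    def __post_init__(self) -> None:
        if self.abs_std_slope_temp < 0 or self.abs_std_slope_diet < 0:
            raise ValueError("standardized slope magnitudes must be >= 0")
        if self.trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}")


@dataclass(frozen=True)
class BootstrapConfig:
    n_reps: int = 1000
    width_rule: str = "sd_matched"  # or "half_width_se"
    seed: int = 0
    degenerate_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.width_rule not in ("sd_matched", "half_width_se"):
            raise ValueError(f"unknown width_rule {self.width_rule!r}")
        if self.degenerate_floor < 0:
            raise ValueError("degenerate_floor must be >= 0")


@dataclass(frozen=True)
class PermutationConfig:
    n_perms: int = 10_000
    seed: int = 0
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.n_perms < 99:
            raise ValueError("n_perms must be >= 99")
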