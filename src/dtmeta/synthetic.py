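"""Synthetic corpora with the statistical structure the analysis assumes.

Generates pure-birth phylogenies, species-level true ln-slopes with
phylogenetic signal plus study- and observation-level heterogeneity, and
treatment-level primary datasets in which development time declines
monotonically with temperature in both sexes and the male/female responses
are near-proportional on the log scale.  Every corpus ships its generating
parameters so recovery tests never have to re-derive the truth.
"""

from __future__ import annotations

import math
import random
from dataclasses import asdict, dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import Phylogeny, PrimaryDataset, TreatmentRecord
from .phylo_meta import phylo_correlation

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_true_slopes",
    "simulate_primary_dataset",
    "simulate_corpus",
    "Corpus",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for corpus generation; defaults emulate the observed corpus shape."""

    n_species: int = 40
    extra_dataset_prob: float = 0.2  # chance a species contributes a 2nd dataset
    k_poisson_mean: float = 2.0      # k = 2 + min(Poisson(mean), 9) -> support 2..11
    mu_true: float = 0.0
    beta_true: float = 0.0
    sigma2_phylo: float = 0.002
    sigma2_study: float = 0.002
    sigma2_obs: float = 0.003
    sdtd_mean: float = 0.08
    sdtd_sd: float = 0.10
    temp_grid: Tuple[float, float] = (10.0, 30.0)
    gradient_fold: float = 3.27      # target max/min development-time ratio
    base_dt_days: float = 20.0       # development time at the warmest treatment
    se_rel: float = 0.02             # reported SE relative to the mean
    meas_sd: float = 0.0             # log-scale noise on realized treatment means
    diet_mode: bool = False
    trait: str = "total"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if min(self.sigma2_phylo, self.sigma2_study, self.sigma2_obs) < 0:
            raise ValueError("variance components must be >= 0")
        if self.temp_grid[1] <= self.temp_grid[0]:
            raise ValueError("temp_grid must be strictly increasing")
        if self.gradient_fold <= 1:
            raise ValueError("gradient_fold must exceed 1")


@dataclass
class Corpus:
    datasets: List[PrimaryDataset]
    tree: Phylogeny
    truth: dict  # config snapshot + per-dataset latent values


def simulate_tree(n_species: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree, ultrametric, scaled to unit depth."""
    import dendropy
    from dendropy.simulate import treesim

    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    taxa = dendropy.TaxonNamespace(
        [f"sp{i:04d}" for i in range(1, n_species + 1)]
    )
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    # normalize to unit root-to-tip depth
    for node in tree.preorder_node_iter():
        node._depth = 0.0 if node.parent_node is None else (
            node.parent_node._depth + (node.edge.length or 0.0)
        )
    depth = max(leaf._depth for leaf in tree.leaf_node_iter())
    if depth <= 0:  # degenerate (e.g. n=2 with an immediate split)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 1.0 if node.is_leaf() else 0.0
        depth = 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return Phylogeny(tree=tree, has_branch_lengths=True)


def simulate_true_slopes(
    tree: Phylogeny,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[dict]:
    """Latent per-dataset truth: ln-slope decomposition and SDTD draw.

    Species effects are Brownian on the tree (covariance sigma2_phylo * A);
    each dataset additionally receives a study effect and an observation
    effect.  Returns one dict per dataset.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    corr = phylo_correlation(tree)
    species = list(corr.species)
    L = np.linalg.cholesky(corr.matrix + 1e-10 * np.eye(len(species)))
    u = math.sqrt(cfg.sigma2_phylo) * (L @ rng.standard_normal(len(species)))
    out: List[dict] = []
    for sp, u_sp in zip(species, u):
        n_ds = 1 + int(rng.random() < cfg.extra_dataset_prob)
        s_study = math.sqrt(cfg.sigma2_study) * rng.standard_normal()
        for j in range(n_ds):
            o = math.sqrt(cfg.sigma2_obs) * rng.standard_normal()
            sdtd_true = rng.normal(cfg.sdtd_mean, cfg.sdtd_sd)
            sdtd_true = max(sdtd_true, -0.9)
            out.append({
                "species": sp,
                "study_id": f"study_{sp}",
                "dataset_index": j,
                "u_species": float(u_sp),
                "s_study": float(s_study),
                "o_obs": float(o),
                "sdtd_true": float(sdtd_true),
                "ln_slope_true": float(
                    cfg.mu_true + cfg.beta_true * sdtd_true + u_sp + s_study + o
                ),
            })
    return out


def _male_center(ln_f_center: float, sdtd: float) -> float:
    # SDTD > 0: females longer, m = f/(1+sdtd); SDTD < 0: males longer,
    # m = f*(1-sdtd).  Both keep the ratio positive.
    if sdtd >= 0:
        return ln_f_center - math.log1p(sdtd)
    return ln_f_center + math.log1p(-sdtd)


def simulate_primary_dataset(
    truth: dict,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    dataset_id: Optional[str] = None,
    order_name: str = "SimOrder",
) -> PrimaryDataset:
    """Realize one treatment-level dataset around a latent true ln-slope.

    Female log development time declines linearly with temperature over the
    configured gradient; male log development time is the female curve scaled
    by exp(true ln-slope) around the gradient centre and offset to realize
    the drawn SDTD.  With ``meas_sd = 0`` the recovered RMA ln-slope equals
    the latent one exactly.
    """
    k = 2 + min(int(rng.poisson(cfg.k_poisson_mean)), 9)
    t_lo, t_hi = cfg.temp_grid
    temps = np.linspace(t_lo, t_hi, k)
    b = math.log(cfg.gradient_fold) / (t_hi - t_lo)
    ln_f = math.log(cfg.base_dt_days) + b * (t_hi - temps)  # decreasing in T
    rho = math.exp(truth["ln_slope_true"])
    center = float(ln_f.mean())
    ln_m = _male_center(center, truth["sdtd_true"]) + rho * (ln_f - center)
    if cfg.meas_sd > 0:
        ln_f = ln_f + rng.normal(0.0, cfg.meas_sd, size=k)
        ln_m = ln_m + rng.normal(0.0, cfg.meas_sd, size=k)
    f_mean = np.exp(ln_f)
    m_mean = np.exp(ln_m)
    if cfg.diet_mode:
        values: Sequence[object] = [f"diet_level_{i + 1}" for i in range(k)]
        factor = "diet"
    else:
        values = [float(t) for t in temps]
        factor = "temperature"
    records = tuple(
        TreatmentRecord(
            treatment_value=values[i],
            male_mean_dt=float(m_mean[i]),
            female_mean_dt=float(f_mean[i]),
            male_se=float(cfg.se_rel * m_mean[i]),
            female_se=float(cfg.se_rel * f_mean[i]),
        )
        for i in range(k)
    )
    did = dataset_id or f"{truth['species']}_{factor}_{truth['dataset_index']}"
    return PrimaryDataset(
        dataset_id=did,
        study_id=truth["study_id"],
        species=truth["species"],
        order_name=order_name,
        trait=cfg.trait,
        factor=factor,
        records=records,
    )


def simulate_corpus(
    cfg: SimulationConfig,
    tree: Optional[Phylogeny] = None,
    paired_diet_cfg: Optional[SimulationConfig] = None,
) -> Corpus:
    """Generate a full corpus: tree, latent truth and primary datasets.

    With ``paired_diet_cfg`` each species additionally contributes one
    diet-factor dataset generated from independently drawn true slopes under
    that config (sharing this corpus's tree), enabling the paired
    temperature-vs-diet comparison.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = tree or simulate_tree(cfg.n_species, seed=cfg.seed)
    truths = simulate_true_slopes(tree, cfg, rng)
    datasets = [simulate_primary_dataset(t, cfg, rng) for t in truths]
    truth_record = {
        "config": asdict(cfg),
        "datasets": truths,
    }
    if paired_diet_cfg is not None:
        diet_cfg = paired_diet_cfg
        diet_truths = simulate_true_slopes(tree, diet_cfg, rng)
        # one diet dataset per species is enough for pairing
        seen = set()
        diet_sets = []
        kept_truths = []
        for t in diet_truths:
            if t["species"] in seen:
                continue
            seen.add(t["species"])
            t = dict(t, study_id=f"study_{t['species']}_diet")
            diet_sets.append(simulate_primary_dataset(t, diet_cfg, rng))
            kept_truths.append(t)
        datasets.extend(diet_sets)
        truth_record["diet_config"] = asdict(diet_cfg)
        truth_record["diet_datasets"] = kept_truths
    return Corpus(datasets=datasets, tree=tree, truth=truth_record)
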