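"""Reading and validating primary tables, trees and species mappings;
inclusion rules; effect-table round-tripping.

Default CSV schema for primary data (override via :class:`TableDialect`):

    dataset_id, study_id, species, order_name, trait, factor,
    treatment_value, male_mean_dt, male_se, female_mean_dt, female_se

Empty SE cells mean "not reported"; such records make their dataset
qualitative-only (it is excluded from the weighted meta-analysis but kept for
descriptive summaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    EffectSize,
    Phylogeny,
    PrimaryDataset,
    SpeciesMapping,
    TreatmentRecord,
)
from .errors import FormatError, ResolutionError, SchemaError

__all__ = [
    "TableDialect",
    "IngestResult",
    "read_primary_table",
    "apply_inclusion_rules",
    "InclusionResult",
    "read_tree",
    "read_species_mapping",
    "resolve_species",
    "effects_to_frame",
    "write_effect_table",
    "read_effect_table",
    "write_reject_report",
    "datasets_to_frame",
    "write_primary_table",
    "write_tree",
]

MANDATORY_COLUMNS = (
    "dataset_id",
    "study_id",
    "species",
    "order_name",
    "trait",
    "factor",
    "treatment_value",
    "male_mean_dt",
    "female_mean_dt",
)
OPTIONAL_COLUMNS = ("male_se", "female_se")


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping and number formatting for literature tables."""

    column_map: dict = field(default_factory=dict)  # canonical -> actual name
    decimal: str = "."

    def actual(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


@dataclass
class IngestResult:
    datasets: List[PrimaryDataset]
    rejects: pd.DataFrame  # original rows + "reject_reason"

    @property
    def n_rows_kept(self) -> int:
        return sum(ds.k for ds in self.datasets)


def _parse_se(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_primary_table(path, dialect: Optional[TableDialect] = None) -> IngestResult:
    """Read a treatment-level CSV into grouped :class:`PrimaryDataset` objects.

    Every input row lands either in a dataset or in the reject report with a
    reason; treatment order within a dataset follows file order.  A duplicate
    (dataset_id, treatment_value) rejects the whole dataset.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, decimal=dialect.decimal,
                     dtype={dialect.actual("dataset_id"): str},
                     float_precision="round_trip")
    rename = {dialect.actual(c): c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS
              if dialect.actual(c) in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan

    reject_rows: List[Tuple[pd.Series, str]] = []
    kept: dict = {}
    meta: dict = {}
    for _, row in df.iterrows():
        did = str(row["dataset_id"])
        try:
            rec = TreatmentRecord(
                treatment_value=row["treatment_value"],
                male_mean_dt=float(row["male_mean_dt"]),
                female_mean_dt=float(row["female_mean_dt"]),
                male_se=_parse_se(row["male_se"]),
                female_se=_parse_se(row["female_se"]),
            )
        except (ValueError, TypeError) as exc:
            reject_rows.append((row, f"invalid record: {exc}"))
            continue
        kept.setdefault(did, []).append((row, rec))
        meta.setdefault(did, row)

    datasets: List[PrimaryDataset] = []
    for did, pairs in kept.items():
        rows = [p[0] for p in pairs]
        recs = [p[1] for p in pairs]
        values = [r.treatment_value for r in recs]
        if len(set(values)) != len(values):
            for row in rows:
                reject_rows.append((row, "duplicate (dataset_id, treatment_value)"))
            continue
        m = meta[did]
        try:
            ds = PrimaryDataset(
                dataset_id=did,
                study_id=str(m["study_id"]),
                species=str(m["species"]),
                order_name=str(m["order_name"]),
                trait=str(m["trait"]),
                factor=str(m["factor"]),
                records=tuple(recs),
            )
        except ValueError as exc:
            for row in rows:
                reject_rows.append((row, f"invalid dataset: {exc}"))
            continue
        datasets.append(ds)

    if reject_rows:
        rejects = pd.DataFrame([r for r, _ in reject_rows])
        rejects["reject_reason"] = [reason for _, reason in reject_rows]
    else:
        rejects = pd.DataFrame(columns=list(df.columns) + ["reject_reason"])
    return IngestResult(datasets=datasets, rejects=rejects)


@dataclass
class InclusionResult:
    included: List[PrimaryDataset]          # quantitative: k >= 2 and full SEs
    qualitative_only: List[PrimaryDataset]  # k >= 2 but missing SEs
    excluded: List[Tuple[PrimaryDataset, str]]

    @property
    def analyzable(self) -> List[PrimaryDataset]:
        return self.included + self.qualitative_only


def apply_inclusion_rules(datasets: Iterable[PrimaryDataset]) -> InclusionResult:
    """Classify datasets for analysis.

    Datasets with fewer than 2 treatments are excluded outright; datasets
    without complete SEs are kept for descriptive summaries only.  The
    classification is a pure function (idempotent).
    """
    included, qualitative, excluded = [], [], []
    for ds in datasets:
        if ds.k < 2:
            excluded.append((ds, "fewer than 2 treatments"))
        elif not ds.has_se:
            qualitative.append(ds)
        else:
            included.append(ds)
    return InclusionResult(included, qualitative, excluded)


def read_tree(path) -> Phylogeny:
    """Read a rooted Newick tree; branch lengths retained if present."""
    import dendropy

    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises various parse errors
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise FormatError(f"duplicate tip labels: {dupes}")
    has_bl = any(e.length is not None for e in tree.preorder_edge_iter()
                 if e.head_node.parent_node is not None)
    return Phylogeny(tree=tree, has_branch_lengths=has_bl)


def read_species_mapping(path) -> SpeciesMapping:
    """Read a CSV with columns data_species, tree_tip, substitution_kind."""
    df = pd.read_csv(path)
    needed = {"data_species", "tree_tip", "substitution_kind"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"mapping file missing column(s): {sorted(missing)}")
    entries = {}
    for _, row in df.iterrows():
        entries[str(row["data_species"])] = (str(row["tree_tip"]),
                                             str(row["substitution_kind"]))
    return SpeciesMapping(entries)


def resolve_species(
    datasets: Sequence[PrimaryDataset],
    mapping: Optional[SpeciesMapping],
    tree: Phylogeny,
    strict: bool = True,
):
    """Link every dataset's species to a tree tip.

    Species present verbatim on the tree map to themselves; otherwise the
    mapping file is consulted (congener / tribe substitutions).  Returns
    ``(tip_by_species, unmapped, substitutions)``; with ``strict=True`` any
    unmapped species aborts.
    """
    tips = set(tree.tip_labels)
    if mapping is not None:
        bad = sorted({tip for tip, _ in mapping.entries.values()} - tips)
        if bad:
            raise ResolutionError(f"mapping names tips absent from tree: {bad}")
    tip_by_species: dict = {}
    substitutions: List[Tuple[str, str, str]] = []
    unmapped: List[str] = []
    for sp in sorted({ds.species for ds in datasets}):
        mapped = mapping.tip_for(sp) if mapping is not None else None
        if mapped is not None:
            tip_by_species[sp] = mapped
            kind = mapping.entries[sp][1]
            if mapped != sp or kind != "exact":
                substitutions.append((sp, mapped, kind))
        elif sp in tips:
            tip_by_species[sp] = sp
        else:
            unmapped.append(sp)
    if unmapped and strict:
        raise ResolutionError(f"unmapped species: {unmapped}")
    return tip_by_species, unmapped, substitutions


# ---------------------------------------------------------------------------
# Effect-table serialization
# ---------------------------------------------------------------------------

EFFECT_COLUMNS = [
    "dataset_id", "study_id", "species", "order_name", "trait", "factor",
    "k", "ln_slope", "boot_sd", "weight", "sdtd", "r_mf", "gradient_length",
    "n_boot_rejected", "qc_flags",
]


def effects_to_frame(effects: Iterable[EffectSize]) -> pd.DataFrame:
    rows = []
    for e in effects:
        rows.append({
            "dataset_id": e.dataset_id, "study_id": e.study_id,
            "species": e.species, "order_name": e.order_name,
            "trait": e.trait, "factor": e.factor, "k": e.k,
            "ln_slope": e.ln_slope, "boot_sd": e.boot_sd, "weight": e.weight,
            "sdtd": e.sdtd, "r_mf": e.r_mf,
            "gradient_length": e.gradient_length,
            "n_boot_rejected": e.n_boot_rejected,
            "qc_flags": ";".join(e.qc_flags),
        })
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)


def write_effect_table(effects: Iterable[EffectSize], path) -> None:
    """Write the effect-size table as CSV (floats at full repr precision)."""
    df = effects_to_frame(effects)
    # repr-roundtrip float formatting so read_effect_table restores bits
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_effect_table(path) -> List[EffectSize]:
    df = pd.read_csv(path, dtype={"dataset_id": str, "study_id": str},
                     float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        def opt(name):
            val = row[name]
            return None if pd.isna(val) else float(val)
        flags = row.get("qc_flags")
        out.append(EffectSize(
            dataset_id=str(row["dataset_id"]), study_id=str(row["study_id"]),
            species=str(row["species"]), order_name=str(row["order_name"]),
            trait=str(row["trait"]), factor=str(row["factor"]),
            k=int(row["k"]), ln_slope=float(row["ln_slope"]),
            sdtd=float(row["sdtd"]), gradient_length=float(row["gradient_length"]),
            r_mf=opt("r_mf"), boot_sd=opt("boot_sd"), weight=opt("weight"),
            n_boot_rejected=None if pd.isna(row["n_boot_rejected"]) else int(row["n_boot_rejected"]),
            qc_flags=[] if pd.isna(flags) or not str(flags) else str(flags).split(";"),
        ))
    return out


def write_reject_report(rejects: pd.DataFrame, path) -> None:
    rejects.to_csv(path, index=False)


def datasets_to_frame(datasets: Iterable[PrimaryDataset]) -> pd.DataFrame:
    """Flatten datasets back into the treatment-level table schema."""
    rows = []
    for ds in datasets:
        for r in ds.records:
            rows.append({
                "dataset_id": ds.dataset_id, "study_id": ds.study_id,
                "species": ds.species, "order_name": ds.order_name,
                "trait": ds.trait, "factor": ds.factor,
                "treatment_value": r.treatment_value,
                "male_mean_dt": r.male_mean_dt, "male_se": r.male_se,
                "female_mean_dt": r.female_mean_dt, "female_se": r.female_se,
            })
    return pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS[:7]) + [
        "male_mean_dt", "male_se", "female_mean_dt", "female_se"])


def write_primary_table(datasets: Iterable[PrimaryDataset], path) -> None:
    datasets_to_frame(datasets).to_csv(
        path, index=False, float_format=lambda x: repr(float(x)))


def write_tree(phylo: Phylogeny, path) -> None:
    phylo.tree.write(path=str(path), schema="newick")
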