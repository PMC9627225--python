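"""Domain containers and file readers for archipelago occurrence datasets.

The analysis consumes four inputs: a species trait table (morphological
measurements plus genus), an area table (environment values and centroid
coordinates for each recording area), a binary species-by-area occurrence
matrix, and a rooted phylogeny with branch lengths.  This module defines
lightweight validated containers around :class:`pandas.DataFrame` /
:class:`dendropy.Tree` and the CSV / Newick readers and writers.

All CSV files are comma-separated UTF-8 with a header row.  Species with any
missing morphological measurement are dropped (and counted), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "MEASUREMENT_COLUMNS",
    "TraitTable",
    "AreaTable",
    "OccurrenceMatrix",
    "Dataset",
    "ValidationError",
    "read_trait_table",
    "read_area_table",
    "read_occurrence",
    "read_newick",
    "write_newick",
    "validate_dataset",
]

#: Morphological measurement columns, in canonical order.  Heights in metres,
#: all other lengths in centimetres.
MEASUREMENT_COLUMNS = [
    "height_max",
    "leaf_length_min",
    "leaf_length_max",
    "leaf_width_min",
    "leaf_width_max",
    "fruit_size_max",
    "calyx_length_max",
    "corolla_length_max",
]

AREA_COLUMNS = ["lon", "lat", "ultramafic_pct", "rainfall_min", "lowland_pct"]


class ValidationError(ValueError):
    """Raised when an input file or dataset violates a structural invariant."""


@dataclass(frozen=True)
class TraitTable:
    """Species-level morphological measurements.

    Parameters
    ----------
    data
        DataFrame indexed by species name with a ``genus`` column and the
        eight :data:`MEASUREMENT_COLUMNS`.  All measurements strictly
        positive; leaf minima never exceed maxima.
    dropped
        Species removed because one or more measurements were missing.
    """

    data: pd.DataFrame
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ["genus", *MEASUREMENT_COLUMNS] if c not in df.columns]
        if missing:
            raise ValidationError(f"trait table missing columns: {missing}")
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate species in trait table: {dups}")
        vals = df[MEASUREMENT_COLUMNS]
        if vals.isna().any().any():
            raise ValidationError("trait table contains missing measurements")
        bad = vals.index[(vals <= 0).any(axis=1)]
        if len(bad):
            raise ValidationError(
                f"non-positive measurement for species: {sorted(bad)}"
            )
        for dim in ("leaf_length", "leaf_width"):
            flipped = df.index[df[f"{dim}_min"] > df[f"{dim}_max"]]
            if len(flipped):
                raise ValidationError(
                    f"{dim}_min exceeds {dim}_max for species: {sorted(flipped)}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def genus_map(self) -> dict[str, str]:
        return dict(self.data["genus"])

    @property
    def n_species(self) -> int:
        return len(self.data)

    @property
    def n_genera(self) -> int:
        return self.data["genus"].nunique()


@dataclass(frozen=True)
class AreaTable:
    """Recording areas: centroid coordinates and environment values.

    ``data`` is indexed by area name with columns ``lon``/``lat`` (decimal
    degrees WGS84), ``ultramafic_pct`` and ``lowland_pct`` (percentage of
    area), and ``rainfall_min`` (mm/month).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in AREA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"area table missing columns: {missing}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate area names")
        if len(df) < 3:
            raise ValidationError("need at least 3 areas")
        if ((df["lat"].abs() > 90) | (df["lon"].abs() > 360)).any():
            raise ValidationError("coordinates outside valid ranges")
        for col in ("ultramafic_pct", "lowland_pct"):
            if ((df[col] < 0) | (df[col] > 100)).any():
                raise ValidationError(f"{col} outside [0, 100]")
        if (df["rainfall_min"] < 0).any():
            raise ValidationError("rainfall_min must be non-negative")

    @property
    def areas(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_areas(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary species-by-area presence/absence matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValidationError("duplicate species in occurrence matrix")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate areas in occurrence matrix")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("occurrence entries must be 0 or 1")
        nowhere = df.index[df.sum(axis=1) == 0]
        if len(nowhere):
            raise ValidationError(
                f"species present nowhere: {sorted(nowhere)}"
            )

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def areas(self) -> list[str]:
        return list(self.data.columns)

    def richness(self) -> pd.Series:
        """Species richness (column sums) per area."""
        return self.data.sum(axis=0)


@dataclass
class Dataset:
    """The four harmonized analysis inputs plus a validation report."""

    traits: TraitTable
    areas: AreaTable
    occurrence: OccurrenceMatrix
    tree: dendropy.Tree
    report: dict = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return self.occurrence.species


# ---------------------------------------------------------------------------
# readers / writers


def read_trait_table(path) -> TraitTable:
    """Read a species trait CSV; rows with missing measurements are dropped.

    The file must carry ``species``, ``genus`` and the eight measurement
    columns.  Returns a :class:`TraitTable` whose ``dropped`` attribute lists
    the excluded species.
    """
    df = pd.read_csv(path)
    required = ["species", "genus", *MEASUREMENT_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"trait CSV missing columns: {missing}")
    df = df.set_index("species")
    incomplete = df.index[df[MEASUREMENT_COLUMNS].isna().any(axis=1)]
    kept = df.drop(index=incomplete)
    return TraitTable(data=kept[["genus", *MEASUREMENT_COLUMNS]],
                      dropped=tuple(incomplete))


def read_area_table(path) -> AreaTable:
    df = pd.read_csv(path)
    if "area" not in df.columns:
        raise ValidationError("area CSV must have an 'area' column")
    return AreaTable(data=df.set_index("area")[AREA_COLUMNS])


def read_occurrence(path) -> OccurrenceMatrix:
    """Read an occurrence CSV, wide (species x areas) or long format.

    Long format has exactly the columns ``species``, ``area``, ``presence``;
    anything else with a ``species`` column is treated as wide.
    """
    df = pd.read_csv(path)
    if set(df.columns) == {"species", "area", "presence"}:
        wide = df.pivot(index="species", columns="area", values="presence")
        wide = wide.fillna(0)
    else:
        if "species" not in df.columns:
            raise ValidationError("occurrence CSV must have a 'species' column")
        wide = df.set_index("species")
    wide.columns.name = None
    return OccurrenceMatrix(data=wide.astype(int))


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree; tip labels are species names."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate tip labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def write_trait_table(table: TraitTable, path) -> None:
    table.data.rename_axis("species").to_csv(path)


def write_area_table(areas: AreaTable, path) -> None:
    areas.data.rename_axis("area").to_csv(path)


def write_occurrence(occ: OccurrenceMatrix, path) -> None:
    occ.data.rename_axis("species").to_csv(path)


# ---------------------------------------------------------------------------
# cross-dataset validation


def validate_dataset(
    traits: TraitTable,
    areas: AreaTable,
    occurrence: OccurrenceMatrix,
    tree: dendropy.Tree,
) -> Dataset:
    """Harmonize the four inputs and report dropped / to-impute species.

    Occurrence species must all have trait rows; trait species without
    occurrence rows are dropped (reported).  Occurrence areas must match the
    area table exactly.  Species absent from the tree are flagged
    ``needs_imputation`` when a congener tip exists, otherwise an error is
    raised (the congeneric imputation rule requires at least one congener).

    Idempotent: validating an already-validated dataset returns identical
    components and an empty-drop report.
    """
    occ_species = set(occurrence.species)
    trait_species = set(traits.species)
    unknown = sorted(occ_species - trait_species)
    if unknown:
        raise ValidationError(
            f"occurrence species absent from trait table: {unknown}"
        )
    shared = sorted(occ_species)
    if len(shared) < 2:
        raise ValidationError("fewer than 2 species shared across inputs")
    if set(occurrence.areas) != set(areas.areas):
        raise ValidationError(
            "area mismatch between occurrence matrix and area table: "
            f"{sorted(set(occurrence.areas) ^ set(areas.areas))}"
        )

    extra_traits = sorted(trait_species - occ_species)
    traits_h = TraitTable(
        data=traits.data.loc[shared], dropped=traits.dropped
    )
    occ_h = OccurrenceMatrix(data=occurrence.data.loc[shared, areas.areas])

    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    genus_map = traits_h.genus_map
    genera_in_tree = {genus_map[s] for s in shared if s in tip_labels}
    needs_imputation, orphans = [], []
    for sp in shared:
        if sp in tip_labels:
            continue
        if genus_map[sp] in genera_in_tree:
            needs_imputation.append(sp)
        else:
            orphans.append(sp)
    if orphans:
        raise ValidationError(
            f"species missing from tree with no congener tip: {orphans}"
        )

    report = {
        "dropped_trait_species": extra_traits,
        "dropped_incomplete": list(traits.dropped),
        "needs_imputation": needs_imputation,
    }
    return Dataset(traits=traits_h, areas=areas, occurrence=occ_h,
                   tree=tree, report=report)
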