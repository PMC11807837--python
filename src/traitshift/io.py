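"""Data model, CSV ingestion, validation and inclusion filters.

Four tables feed the pipeline: plot metadata, a plots x species abundance
matrix (long or wide CSV), a species trait table, and a per-plot x buffer
scale landscape disturbance table.  Loading cross-references keys, types
the columns, and emits a validation report; the filters implement the two
inclusion rules used throughout the analyses:

* plots enter a trait's analyses only with >= 50% species-level and >= 80%
  total (species-or-genus) trait coverage of community abundance;
* species-level analyses use species occurring in at least five plots of a
  region, assessed per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .metrics import degradation_index
from .synthetic import CONTINUOUS_TRAITS, SYNDROMES

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityData",
    "TraitTable",
    "DisturbanceTable",
    "load_and_validate",
    "write_tables",
    "filter_plots_by_trait_coverage",
    "filter_species_min_occupancy",
    "CoverageFilter",
]

PLOT_META_COLUMNS = ("region", "x", "y", "plot_area", "basal_area")


@dataclass
class CommunityData:
    """Stem counts (plots x species) plus plot metadata."""

    abundance: pd.DataFrame
    plot_meta: pd.DataFrame

    def __post_init__(self) -> None:
        ab, meta = self.abundance, self.plot_meta
        if not ab.index.equals(meta.index):
            missing = ab.index.difference(meta.index).tolist()
            extra = meta.index.difference(ab.index).tolist()
            raise KeyError(
                f"abundance/plot_meta plot mismatch (missing meta for {missing[:5]}, "
                f"unused meta rows {extra[:5]})"
            )
        if ab.index.has_duplicates or ab.columns.has_duplicates:
            raise KeyError("duplicate plot or species keys in abundance table")
        if (ab.to_numpy() < 0).any():
            raise ValueError("negative stem counts")
        for col in ("x", "y"):
            if not np.isfinite(meta[col].to_numpy(float)).all():
                raise ValueError(f"non-finite coordinates in {col!r}")
        if (meta["basal_area"].to_numpy(float) <= 0).any():
            raise ValueError("basal_area must be > 0")
        if meta["region"].isna().any():
            raise ValueError("every plot must belong to exactly one region")

    @property
    def regions(self) -> pd.Series:
        return self.plot_meta["region"]

    def subset_plots(self, plots) -> "CommunityData":
        plots = pd.Index(plots)
        return CommunityData(self.abundance.loc[plots], self.plot_meta.loc[plots])


@dataclass
class TraitTable:
    """Species x traits, continuous traits plus dispersal syndrome.

    Missing values are NaN; the syndrome one-hot expansion yields rows
    summing to one where the syndrome is known.  An optional ``genus``
    column supports the genus-level fallback in total-coverage screening.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise KeyError("duplicate species keys in trait table")
        for col in CONTINUOUS_TRAITS:
            if col in df and (df[col].dropna() <= 0).any():
                raise ValueError(f"trait {col!r} must be positive where present")
        if "syndrome" in df:
            bad = df["syndrome"].dropna()[~df["syndrome"].dropna().isin(SYNDROMES)]
            if len(bad):
                raise ValueError(f"unknown syndrome values: {sorted(bad.unique())}")

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def genus(self) -> pd.Series | None:
        return self.data["genus"] if "genus" in self.data else None

    def one_hot(self) -> pd.DataFrame:
        syn = self.data["syndrome"]
        out = pd.DataFrame(
            {s: (syn == s).astype(float) for s in SYNDROMES}, index=self.data.index
        )
        out[syn.isna()] = np.nan
        return out

    def analysis_traits(self) -> pd.DataFrame:
        """Continuous traits plus one-hot syndrome columns (7 columns)."""
        cont = self.data[[c for c in CONTINUOUS_TRAITS if c in self.data]]
        return pd.concat([cont, self.one_hot()], axis=1)

    def reindex(self, species) -> "TraitTable":
        return TraitTable(self.data.reindex(pd.Index(species)))


@dataclass
class DisturbanceTable:
    """Per plot x scale landscape metrics plus the per-plot degradation index."""

    data: pd.DataFrame  # long: plot, scale, forest_loss, n_patches, edge_density
    degradation: pd.Series  # per plot, 1 / (basal area per sample area)

    def __post_init__(self) -> None:
        df = self.data
        if df.duplicated(["plot", "scale"]).any():
            raise KeyError("duplicate (plot, scale) rows in landscape table")
        fl = df["forest_loss"].to_numpy(float)
        if ((fl < 0) | (fl > 100)).any():
            raise ValueError("forest_loss must lie in [0, 100] percent")
        if (df["n_patches"].to_numpy(float) < 1).any():
            raise ValueError("n_patches must be >= 1")
        ed = df["edge_density"].to_numpy(float)
        if ((ed < 0) | (ed > 1)).any():
            raise ValueError("edge_density must lie in [0, 1]")
        if (self.degradation.to_numpy(float) <= 0).any():
            raise ValueError("degradation index must be positive")

    @property
    def scales(self) -> list[int]:
        return sorted(self.data["scale"].unique())

    def at_scale(self, scale: int) -> pd.DataFrame:
        sub = self.data[self.data["scale"] == scale].set_index("plot")
        if sub.empty:
            raise KeyError(f"scale {scale} not present (have {self.scales})")
        out = sub[["forest_loss", "n_patches", "edge_density"]].copy()
        out["degradation"] = self.degradation.reindex(out.index)
        return out


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _read_csv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, **kw)
    return df


def _abundance_from_any(df: pd.DataFrame) -> pd.DataFrame:
    """Accept long (plot, species, count) or wide (plot x species) dialects."""
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if {"plot", "species", "count"}.issubset(cols):
        dup = df.duplicated(["plot", "species"])
        if dup.any():
            raise KeyError(f"duplicate (plot, species) rows at indices {list(df.index[dup][:5])}")
        wide = df.pivot(index="plot", columns="species", values="count").fillna(0)
    else:
        wide = df.set_index(df.columns[0])
        wide.index.name = "plot"
        wide.columns.name = "species"
    bad = wide.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna() & wide.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"non-numeric abundance at plot {wide.index[r]!r}, species {wide.columns[c]!r}")
    wide = wide.astype(float)
    if not np.allclose(wide.to_numpy() % 1, 0):
        raise ValueError("stem counts must be integers")
    return wide.astype(int).sort_index().sort_index(axis=1)


def load_and_validate(
    paths: Mapping[str, str | Path],
) -> tuple[CommunityData, TraitTable, DisturbanceTable, dict]:
    """Load the four CSVs, cross-reference keys, and report counts/missingness.

    ``paths`` maps {'plots', 'abundance', 'traits', 'landscape'} to files.
    Species present in the abundance table but absent from the trait table
    are retained with a fully missing trait row.  Unknown plot keys are hard
    errors.  Returns (community, traits, disturbance, report).
    """
    plots = _read_csv(paths["plots"]).set_index("plot")
    abundance = _abundance_from_any(_read_csv(paths["abundance"]))
    traits_df = _read_csv(paths["traits"]).set_index("species")
    landscape = _read_csv(paths["landscape"])

    unknown = abundance.index.difference(plots.index)
    if len(unknown):
        raise KeyError(f"abundance references plots missing from plot table: {list(unknown[:5])}")
    unknown = pd.Index(landscape["plot"].unique()).difference(plots.index)
    if len(unknown):
        raise KeyError(f"landscape references unknown plots: {list(unknown[:5])}")
    if plots.index.has_duplicates:
        raise KeyError("duplicate plot keys in plot table")

    community = CommunityData(abundance, plots.loc[abundance.index])
    trait_table = TraitTable(traits_df).reindex(
        traits_df.index.union(abundance.columns)
    )
    orphan_species = abundance.columns.difference(traits_df.index)

    deg = degradation_index(
        community.plot_meta["basal_area"], community.plot_meta["plot_area"]
    )
    disturbance = DisturbanceTable(landscape, deg)

    analysis = trait_table.reindex(abundance.columns).data
    report = {
        "n_plots": int(abundance.shape[0]),
        "n_species": int(abundance.shape[1]),
        "n_stems": int(abundance.to_numpy().sum()),
        "n_regions": int(community.regions.nunique()),
        "scales": disturbance.scales,
        "species_without_traits": int(len(orphan_species)),
        "trait_missingness": {
            c: float(analysis[c].isna().mean()) for c in analysis.columns if c != "genus"
        },
    }
    logger.info("loaded %s", report)
    return community, trait_table, disturbance, report


def write_tables(outdir, community: CommunityData, traits: TraitTable, disturbance: DisturbanceTable) -> None:
    """Write the canonical long-form CSVs (inverse of load_and_validate)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    community.plot_meta.to_csv(outdir / "plots.csv", index_label="plot")
    long = (
        community.abundance.stack()
        .rename("count")
        .reset_index()
        .rename(columns={"level_0": "plot", "level_1": "species"})
    )
    long = long[long["count"] > 0]
    long.to_csv(outdir / "abundance.csv", index=False)
    traits.data.to_csv(outdir / "traits.csv", index_label="species")
    disturbance.data.to_csv(outdir / "landscape.csv", index=False)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


@dataclass
class CoverageFilter:
    """Per-trait plot retention decided by trait-coverage thresholds."""

    retained: dict[str, pd.Index]
    report: pd.DataFrame = field(repr=False)

    def plots_for(self, trait: str) -> pd.Index:
        return self.retained[trait]


def _coverage(abundance: pd.DataFrame, has_trait: pd.Series) -> pd.Series:
    w = abundance.to_numpy(float)
    tot = w.sum(axis=1)
    cov = (w * has_trait.reindex(abundance.columns).to_numpy(float)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(tot > 0, cov / np.where(tot > 0, tot, 1.0), np.nan)
    return pd.Series(out, index=abundance.index)


def filter_plots_by_trait_coverage(
    community: CommunityData,
    traits: TraitTable,
    min_species_level: float = 0.50,
    min_total: float = 0.80,
) -> CoverageFilter:
    """Apply the two abundance-coverage inclusion rules, per trait.

    Species-level coverage is the abundance share of stems whose species has
    the trait; total coverage additionally counts stems whose genus carries
    trait information (requires a ``genus`` column; without one the total
    rule falls back to species-level data, which is logged).  Both rules are
    inclusive ("at least").
    """
    for thr in (min_species_level, min_total):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("coverage thresholds must lie in [0, 1]")
    tt = traits.reindex(community.abundance.columns)
    analysis = tt.analysis_traits()
    genus = tt.genus
    if genus is None:
        logger.info("trait table has no genus column; total-coverage rule uses species-level data")
    retained: dict[str, pd.Index] = {}
    rows = []
    for trait in analysis.columns:
        has_sp = analysis[trait].notna()
        if genus is not None:
            genus_has = has_sp.groupby(genus).transform("any")
            has_total = has_sp | genus_has.reindex(has_sp.index).fillna(False).astype(bool)
        else:
            has_total = has_sp
        cov_sp = _coverage(community.abundance, has_sp)
        cov_tot = _coverage(community.abundance, has_total)
        keep = (cov_sp >= min_species_level) & (cov_tot >= min_total)
        retained[trait] = community.abundance.index[keep.fillna(False)]
        for plot in community.abundance.index:
            rows.append(
                dict(
                    trait=trait,
                    plot=plot,
                    coverage_species=float(cov_sp[plot]),
                    coverage_total=float(cov_tot[plot]),
                    retained=bool(keep[plot]),
                )
            )
        dropped = int((~keep).sum())
        if dropped:
            logger.info("trait %s: excluded %d plots by coverage rules", trait, dropped)
    return CoverageFilter(retained=retained, report=pd.DataFrame(rows))


def filter_species_min_occupancy(
    community: CommunityData, min_plots: int = 5
) -> dict[str, pd.Index]:
    """Per-region species lists: species occurring in >= min_plots plots of that region."""
    if min_plots < 1:
        raise ValueError("min_plots must be >= 1")
    out: dict[str, pd.Index] = {}
    occ = community.abundance > 0
    for region, sub in occ.groupby(community.regions):
        n_occ = sub.sum(axis=0)
        out[str(region)] = community.abundance.columns[(n_occ >= min_plots).to_numpy()]
    return out
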