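"""Data model, I/O, and census summarization for fully mapped forest plots.

A stem map is the universal input: one record per tagged woody stem inside a
rectangular plot, with coordinates in meters from the southwest corner,
species code, diameter at breast height (dbh, cm, measured at 1.37 m), and a
live/snag status.  Live stems are tagged down to 1 cm dbh; snags (standing
dead trees) are recorded at >= 10 cm dbh and >= 1.8 m height.

The census summaries reproduce the arithmetic of the standard forest
dynamics plot tables: per-species stem counts and basal areas above the
1 / 10 / 100 cm thresholds, the large-diameter (>= 100 cm) proportions, and
quadrat-grid statistics of stem density and basal area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from forestspat.errors import FormatError, GeometryError, ValidationError

#: dbh threshold (cm) above which a live tree counts as large-diameter.
LARGE_DBH_CM = 100.0

#: Columns every stem-map file must provide, in canonical order.
REQUIRED_COLUMNS = ("tag", "species", "x", "y", "dbh", "status")
OPTIONAL_COLUMNS = ("growth_form", "snag_height", "decay_class")

VALID_STATUS = frozenset({"live", "snag"})
VALID_GROWTH_FORMS = frozenset({"tree", "tall_shrub", "liana"})


@dataclass(frozen=True)
class Window:
    """Rectangular plot window, origin at the southwest corner.

    x increases east, y increases north; both extents in meters.
    """

    width: float
    height: float

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0):
            raise GeometryError("window extents must be positive")

    @property
    def area(self) -> float:
        """Window area in m^2."""
        return self.width * self.height

    @property
    def area_ha(self) -> float:
        """Window area in hectares."""
        return self.area / 1e4

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


@dataclass(frozen=True)
class StemRecord:
    """One tagged, mapped woody stem."""

    tag: str
    species: str
    x: float
    y: float
    dbh: float
    status: str = "live"
    growth_form: str = "tree"
    snag_height: Optional[float] = None
    decay_class: Optional[int] = None


def basal_area(dbh):
    """Cross-sectional area at breast height, in m^2, from dbh in cm.

    basal area = pi * (dbh / 200)^2.
    """
    arr = np.asarray(dbh, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("dbh must be positive and finite")
    out = np.pi * (arr / 200.0) ** 2
    return float(out) if np.isscalar(dbh) or arr.ndim == 0 else out


def _validate_frame(df: pd.DataFrame, window: Window) -> list[str]:
    """Return row-level diagnostics (empty list means valid)."""
    problems = []
    dup = df["tag"][df["tag"].duplicated()]
    for t in dup.unique():
        problems.append(f"tag {t!r}: duplicated")
    bad_status = ~df["status"].isin(VALID_STATUS)
    for t in df.loc[bad_status, "tag"]:
        problems.append(f"tag {t!r}: status not in {sorted(VALID_STATUS)}")
    bad_form = ~df["growth_form"].isin(VALID_GROWTH_FORMS)
    for t in df.loc[bad_form, "tag"]:
        problems.append(f"tag {t!r}: unknown growth_form")
    outside = ~window.contains(df["x"].to_numpy(), df["y"].to_numpy())
    for t in df.loc[outside, "tag"]:
        problems.append(f"tag {t!r}: coordinates outside window")
    live = df["status"] == "live"
    small_live = live & (df["dbh"] < 1.0)
    for t in df.loc[small_live, "tag"]:
        problems.append(f"tag {t!r}: live stem below the 1 cm tagging threshold")
    snag = df["status"] == "snag"
    small_snag = snag & (df["dbh"] < 10.0)
    for t in df.loc[small_snag, "tag"]:
        problems.append(f"tag {t!r}: snag below the 10 cm threshold")
    short_snag = snag & df["snag_height"].notna() & (df["snag_height"] < 1.8)
    for t in df.loc[short_snag, "tag"]:
        problems.append(f"tag {t!r}: snag shorter than 1.8 m")
    nonpos = df["dbh"] <= 0
    for t in df.loc[nonpos, "tag"]:
        problems.append(f"tag {t!r}: non-positive dbh")
    return problems


class StemMap:
    """A validated collection of stem records inside a window.

    Parameters
    ----------
    window : Window
    stems : DataFrame or iterable of StemRecord
        Must carry the canonical columns; optional columns are filled with
        defaults.
    shrub_patches : mapping of species -> patch area (m^2), optional
        Continuous low-shrub/fern cover reduced to per-species areas
        (polygon geometry is out of scope).
    """

    def __init__(self, window: Window, stems, shrub_patches: Optional[dict] = None,
                 validate: bool = True):
        self.window = window
        if isinstance(stems, pd.DataFrame):
            df = stems.copy()
        else:
            df = pd.DataFrame([s.__dict__ for s in stems])
        if df.empty:
            df = pd.DataFrame(columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"stem table is missing columns: {missing}")
        if "growth_form" not in df.columns:
            df["growth_form"] = "tree"
        df["growth_form"] = df["growth_form"].fillna("tree")
        for col in ("snag_height", "decay_class"):
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)]
        df = df.astype({"x": float, "y": float, "dbh": float, "species": str,
                        "status": str, "growth_form": str})
        df["tag"] = df["tag"].astype(str)
        df = df.reset_index(drop=True)
        if validate and len(df):
            problems = _validate_frame(df, window)
            if problems:
                raise ValidationError(
                    f"{len(problems)} invalid stem record(s): "
                    + "; ".join(problems[:10])
                    + ("; ..." if len(problems) > 10 else "")
                )
        self.stems = df
        self.shrub_patches = dict(shrub_patches or {})

    def __len__(self) -> int:
        return len(self.stems)

    def __repr__(self) -> str:
        return (f"StemMap({len(self)} stems, "
                f"{self.window.width:g} x {self.window.height:g} m)")

    @property
    def live_trees(self) -> pd.DataFrame:
        s = self.stems
        return s[(s["status"] == "live") & (s["growth_form"] == "tree")]

    @property
    def snags(self) -> pd.DataFrame:
        return self.stems[self.stems["status"] == "snag"]

    def subset(self, mask) -> "StemMap":
        """A new StemMap holding the rows selected by a boolean mask."""
        return StemMap(self.window, self.stems[np.asarray(mask)],
                       self.shrub_patches, validate=False)

    def points(self, mask=None) -> np.ndarray:
        """(n, 2) coordinate array for the selected (default: all) stems."""
        df = self.stems if mask is None else self.stems[np.asarray(mask)]
        return df[["x", "y"]].to_numpy(dtype=float)


def read_stem_map(path, window: Window, shrub_patches: Optional[dict] = None,
                  on_invalid: str = "raise") -> StemMap:
    """Read a stem map from a delimited-text (CSV) file.

    The file must carry a header row with at least
    ``tag,species,x,y,dbh,status``; ``growth_form``, ``snag_height`` and
    ``decay_class`` are optional.  Rows violating the data-model invariants
    raise a :class:`ValidationError` naming the offending tags
    (``on_invalid='raise'``) or are dropped with the diagnostics attached to
    the returned map (``on_invalid='drop'``).
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse stem-map file {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stem-map file {path} is missing columns: {missing}")
    if on_invalid == "drop" and len(df):
        if "growth_form" not in df.columns:
            df["growth_form"] = "tree"
        for col in ("snag_height", "decay_class"):
            if col not in df.columns:
                df[col] = np.nan
        df["tag"] = df["tag"].astype(str)
        problems = _validate_frame(df, window)
        bad_tags = {p.split("'")[1] for p in problems}
        kept = df[~df["tag"].isin(bad_tags)]
        smap = StemMap(window, kept, shrub_patches)
        smap.diagnostics = problems
        return smap
    return StemMap(window, df, shrub_patches)


def write_stem_map(smap: StemMap, path) -> None:
    """Write a stem map in the canonical CSV dialect (UTF-8, '.' decimal)."""
    smap.stems.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Census summarization
# ---------------------------------------------------------------------------

_CENSUS_COLUMNS = [
    "density_per_ha", "stems_ge1", "stems_ge10", "stems_ge100",
    "large_stem_prop_pct", "ba_ge1_m2_ha", "ba_ge10_m2_ha",
    "ba_ge100_m2_ha", "large_ba_prop_pct",
]

_POPULATIONS = {"live_tree": ("live", "tree"),
                "tall_shrub": ("live", "tall_shrub"),
                "liana": ("live", "liana")}


def _census_row(df: pd.DataFrame, area_ha: float, snag: bool = False) -> dict:
    dbh = df["dbh"].to_numpy(dtype=float)
    ba = np.pi * (dbh / 200.0) ** 2
    row = {}
    if snag:
        # Snags are censused at >= 10 cm only.
        row["density_per_ha"] = np.nan
        row["stems_ge1"] = np.nan
        row["ba_ge1_m2_ha"] = np.nan
    else:
        row["density_per_ha"] = len(df) / area_ha
        row["stems_ge1"] = int(len(df))
        row["ba_ge1_m2_ha"] = ba.sum() / area_ha
    row["stems_ge10"] = int((dbh >= 10).sum())
    row["stems_ge100"] = int((dbh >= 100).sum())
    row["ba_ge10_m2_ha"] = ba[dbh >= 10].sum() / area_ha
    row["ba_ge100_m2_ha"] = ba[dbh >= 100].sum() / area_ha
    n_base = row["stems_ge10"] if snag else row["stems_ge1"]
    ba_base = row["ba_ge10_m2_ha"] if snag else row["ba_ge1_m2_ha"]
    row["large_stem_prop_pct"] = (
        100.0 * row["stems_ge100"] / n_base if n_base else 0.0)
    row["large_ba_prop_pct"] = (
        100.0 * row["ba_ge100_m2_ha"] / ba_base if ba_base else 0.0)
    return {c: row[c] for c in _CENSUS_COLUMNS}


@dataclass
class CensusSummary:
    """Per-species and per-population census rows plus totals.

    ``species`` is indexed by (population, species); ``totals`` by population
    (one row per live population, a combined ``live_woody`` row, and a
    ``snag`` row).  Densities are stems/ha, basal areas m^2/ha; the
    large-diameter proportions are percentages of the >= 1 cm quantities
    (>= 10 cm for snags).
    """

    species: pd.DataFrame
    totals: pd.DataFrame
    plot_area_ha: float

    def formatted(self) -> pd.DataFrame:
        """Census table rendered with the reporting conventions:

        densities to 0.1 stems/ha with values below 0.05 shown as trace
        ``'t'``; basal areas to 0.01 m^2/ha; proportions to 0.1 %.
        """
        def fmt(df):
            out = df.copy()
            out["density_per_ha"] = [
                "t" if (np.isfinite(v) and v < 0.05) else
                ("" if not np.isfinite(v) else f"{v:.1f}")
                for v in df["density_per_ha"]]
            for c in ("ba_ge1_m2_ha", "ba_ge10_m2_ha", "ba_ge100_m2_ha"):
                out[c] = [
                    "" if not np.isfinite(v) else
                    ("t" if 0 < v < 0.005 else f"{v:.2f}") for v in df[c]]
            for c in ("large_stem_prop_pct", "large_ba_prop_pct"):
                out[c] = [f"{v:.1f}%" if np.isfinite(v) else "" for v in df[c]]
            return out
        species = fmt(self.species).reset_index()
        totals = fmt(self.totals).reset_index()
        totals.insert(1, "species", "(total)")
        return pd.concat([species, totals], ignore_index=True)

    def to_json(self) -> str:
        return json.dumps({
            "plot_area_ha": self.plot_area_ha,
            "species": json.loads(self.species.reset_index()
                                  .to_json(orient="records")),
            "totals": json.loads(self.totals.reset_index()
                                 .to_json(orient="records")),
        }, indent=1)


def summarize_census(smap: StemMap, plot_area_ha: Optional[float] = None
                     ) -> CensusSummary:
    """Census summary: per-species rows and population totals.

    Live populations (trees, tall shrubs, lianas) are summarized over the
    >= 1, >= 10 and >= 100 cm dbh thresholds; snags over >= 10 and >= 100 cm.
    Large-diameter proportions are the >= 100 cm share of the >= 1 cm
    quantity (>= 10 cm for snags), in percent.  An empty map yields a
    summary of zeros.
    """
    if plot_area_ha is None:
        plot_area_ha = smap.window.area_ha
    if plot_area_ha <= 0:
        raise ValueError("plot area must be positive")
    s = smap.stems
    sp_rows, tot_rows = {}, {}
    for pop, (status, form) in _POPULATIONS.items():
        sub = s[(s["status"] == status) & (s["growth_form"] == form)]
        for species, grp in sub.groupby("species"):
            sp_rows[(pop, species)] = _census_row(grp, plot_area_ha)
        tot_rows[pop] = _census_row(sub, plot_area_ha)
    live = s[s["status"] == "live"]
    tot_rows["live_woody"] = _census_row(live, plot_area_ha)
    sn = s[s["status"] == "snag"]
    for species, grp in sn.groupby("species"):
        sp_rows[("snag", species)] = _census_row(grp, plot_area_ha, snag=True)
    tot_rows["snag"] = _census_row(sn, plot_area_ha, snag=True)
    if sp_rows:
        species = pd.DataFrame.from_dict(sp_rows, orient="index")
        species.index = pd.MultiIndex.from_tuples(species.index,
                                                  names=["population",
                                                         "species"])
    else:
        species = pd.DataFrame(
            columns=_CENSUS_COLUMNS,
            index=pd.MultiIndex.from_tuples([], names=["population",
                                                       "species"]))
    totals = pd.DataFrame.from_dict(tot_rows, orient="index")
    totals.index.name = "population"
    return CensusSummary(species=species, totals=totals,
                         plot_area_ha=plot_area_ha)


# ---------------------------------------------------------------------------
# Diameter distributions
# ---------------------------------------------------------------------------

@dataclass
class DiameterHistogram:
    """Binned diameter distribution of one species (counts and basal area).

    First bin is [1, 5) cm; subsequent bins are half-open
    [a, a + bin_width).  ``edges`` has one more entry than ``counts``.
    """

    species: str
    edges: np.ndarray
    counts: np.ndarray
    basal_area_m2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dbh_low_cm": self.edges[:-1],
            "dbh_high_cm": self.edges[1:],
            "count": self.counts,
            "basal_area_m2": self.basal_area_m2,
        })


def diameter_distribution(smap: StemMap, species: str,
                          bin_width: float = 5.0) -> DiameterHistogram:
    """Histogram of stem counts and basal area for one species.

    Bins: [1, 5), then [5, 5 + bin_width), ... up past the largest stem.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sub = smap.stems[smap.stems["species"] == species]
    if sub.empty and species not in set(smap.stems["species"]):
        raise KeyError(f"species {species!r} not present in the map")
    dbh = sub["dbh"].to_numpy(dtype=float)
    top = max(5.0 + bin_width, (math.floor((dbh.max() - 5.0) / bin_width) + 1)
              * bin_width + 5.0) if len(dbh) else 5.0 + bin_width
    edges = np.concatenate([[1.0], np.arange(5.0, top + 0.5 * bin_width,
                                             bin_width)])
    counts, _ = np.histogram(dbh, bins=edges)
    ba = np.pi * (dbh / 200.0) ** 2
    ba_bins, _ = np.histogram(dbh, bins=edges, weights=ba)
    return DiameterHistogram(species=species, edges=edges,
                             counts=counts.astype(int),
                             basal_area_m2=ba_bins)


# ---------------------------------------------------------------------------
# Quadrat statistics
# ---------------------------------------------------------------------------

@dataclass
class QuadratGrid:
    """Per-quadrat stem counts and basal areas on a square grid.

    Quadrats are indexed row-major from the southwest corner; a stem on an
    interior boundary belongs to the quadrat to the north/east, and stems on
    the far window edge are clamped into the last quadrat.
    """

    grain_m2: float
    side_m: float
    nx: int
    ny: int
    counts: np.ndarray        # shape (ny, nx), row 0 = southernmost
    basal_area_m2: np.ndarray

    @property
    def n_quadrats(self) -> int:
        return self.nx * self.ny

    @property
    def basal_area_m2_ha(self) -> np.ndarray:
        return self.basal_area_m2 / (self.grain_m2 / 1e4)

    def percentiles(self, probs: Sequence[float] = (5, 25, 50, 75, 95)
                    ) -> pd.DataFrame:
        """Distribution summaries for boxplot-style reporting."""
        rows = {
            "count": np.percentile(self.counts.ravel(), probs),
            "basal_area_m2_ha": np.percentile(self.basal_area_m2_ha.ravel(),
                                              probs),
        }
        return pd.DataFrame(rows, index=pd.Index(probs, name="percentile"))

    def to_frame(self) -> pd.DataFrame:
        iy, ix = np.indices(self.counts.shape)
        return pd.DataFrame({
            "ix": ix.ravel(), "iy": iy.ravel(),
            "count": self.counts.ravel(),
            "basal_area_m2": self.basal_area_m2.ravel(),
            "basal_area_m2_ha": self.basal_area_m2_ha.ravel(),
        })


def quadrat_index(x, y, window: Window, side: float):
    """Row-major quadrat assignment by floor(x/side), floor(y/side)."""
    nx = int(round(window.width / side))
    ny = int(round(window.height / side))
    ix = np.minimum(np.floor(np.asarray(x) / side).astype(int), nx - 1)
    iy = np.minimum(np.floor(np.asarray(y) / side).astype(int), ny - 1)
    return ix, iy


def quadrat_basal_area(x, y, ba, window: Window, grain_m2: float) -> np.ndarray:
    """Quadrat totals of a per-stem quantity ``ba`` (flat, row-major from SW)."""
    side = math.sqrt(grain_m2)
    _check_grain(window, side)
    nx = int(round(window.width / side))
    ny = int(round(window.height / side))
    ix, iy = quadrat_index(x, y, window, side)
    flat = np.bincount(iy * nx + ix, weights=ba, minlength=nx * ny)
    return flat


def _check_grain(window: Window, side: float) -> None:
    for extent, name in ((window.width, "width"), (window.height, "height")):
        k = extent / side
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise GeometryError(
                f"quadrat side {side:g} m does not tile the window {name} "
                f"({extent:g} m)")


def quadrat_statistics(smap: StemMap, grain_m2: float,
                       predicate: Optional[Callable[[pd.DataFrame],
                                                    np.ndarray]] = None
                       ) -> QuadratGrid:
    """Quadrat grid of stem count and basal area for a stem subset.

    ``predicate`` maps the stem DataFrame to a boolean mask (default: all
    stems).  The grain must tile the window exactly.
    """
    side = math.sqrt(grain_m2)
    _check_grain(smap.window, side)
    nx = int(round(smap.window.width / side))
    ny = int(round(smap.window.height / side))
    df = smap.stems
    if predicate is not None:
        df = df[np.asarray(predicate(df), dtype=bool)]
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    ba = np.pi * (df["dbh"].to_numpy(dtype=float) / 200.0) ** 2
    ix, iy = quadrat_index(x, y, smap.window, side)
    flat_idx = iy * nx + ix
    counts = np.bincount(flat_idx, minlength=nx * ny).reshape(ny, nx)
    bas = np.bincount(flat_idx, weights=ba, minlength=nx * ny).reshape(ny, nx)
    return QuadratGrid(grain_m2=grain_m2, side_m=side, nx=nx, ny=ny,
                       counts=counts, basal_area_m2=bas)
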