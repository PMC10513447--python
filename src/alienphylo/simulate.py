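"""Synthetic world generator for the invasion-stage community-phylogenetics
pipeline.

Emulates the statistical structure of a national alien-flora dataset: an
ultrametric species tree, phylogenetically conserved climate niches evolved
by Brownian motion, a smooth climate surface, invasion-status labels
(introduced / naturalized / invasive) in realistic proportions, and
occurrence clouds placed where the climate matches each species' niche.
Because niches are heritable on the tree and placement filters on climate,
assemblages sampled from small regions are phylogenetically clustered — the
signal every downstream stage is designed to detect.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import itertools
import json
import math
import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from shapely.geometry import box, mapping, shape

from .phylo import PhyloTree, tip_labels

__all__ = [
    "EMULATED_COMPOSITION",
    "DEFAULT_EXTENT",
    "DEFAULT_STATUS_PROPORTIONS",
    "DEFAULT_SCALE_UNITS",
    "STATUSES",
    "NicheModel",
    "dataset_composition",
    "simulate_yule_tree",
    "brownian_trait",
    "assign_statuses",
    "simulate_regions",
    "simulate_climate_grid",
    "simulate_occurrences",
    "regions_to_geojson",
    "regions_from_geojson",
]

STATUSES = ("introduced", "naturalized", "invasive")

# Composition of the Chinese alien-flora study system this generator
# emulates: species counts per invasion stage and per largest family, and
# cleaned occurrence-record counts per source database.
EMULATED_COMPOSITION = {
    "species_by_status": {"introduced": 165, "naturalized": 222, "invasive": 319},
    "species_by_family": {"Asteraceae": 114, "Fabaceae": 90, "Poaceae": 75},
    "asteraceae_by_status": {"introduced": 17, "naturalized": 32, "invasive": 65},
    "records_by_source": {"gbif": 17924, "nsii": 69736},
    "n_genera": 397,
    "n_families": 94,
}

DEFAULT_STATUS_PROPORTIONS = (165 / 706, 222 / 706, 319 / 706)

#: lon_min, lon_max, lat_min, lat_max — a China-like study extent
DEFAULT_EXTENT = (73.0, 135.0, 18.0, 54.0)

#: spatial-unit counts per scale, finest (ecoregion-like) to coarsest
#: (habitat-type-like) partitions of the extent
DEFAULT_SCALE_UNITS = {"habitat": 7, "climate": 16, "province": 34, "ecoregion": 47}


def dataset_composition() -> dict:
    """Derived totals and percentage shares of the emulated study system.

    Everything here is recomputed from the raw counts in
    :data:`EMULATED_COMPOSITION` at call time.
    """
    c = EMULATED_COMPOSITION
    n_species = sum(c["species_by_status"].values())
    n_records = sum(c["records_by_source"].values())
    family_pct = {
        fam: 100.0 * n / n_species for fam, n in c["species_by_family"].items()
    }
    ast_total = sum(c["asteraceae_by_status"].values())
    return {
        "n_species": n_species,
        "n_records": n_records,
        "family_percent": family_pct,
        "status_proportions": {
            s: n / n_species for s, n in c["species_by_status"].items()
        },
        "asteraceae_invasive_percent": 100.0
        * c["asteraceae_by_status"]["invasive"] / ast_total,
    }


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0, label_fmt: str = "sp{:04d}"
) -> PhyloTree:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_tips`` tips.

    The simulator stops when the ``n_tips``-th lineage is born; the final
    Exp(n·λ) waiting interval is then added to every pendant edge so the tree
    is a proper draw from the Yule process conditioned on the tip count
    (otherwise the newest cherry has zero-length pendant branches).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    extra = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = label_fmt.format(i)
    return tree


def brownian_trait(
    tree: PhyloTree, sigma2: float, root_value: float = 0.0, seed: int = 0
) -> pd.Series:
    """Evolve a continuous trait along the tree by Brownian motion.

    Each node's value is its parent's plus a Normal(0, sigma2 × branch
    length) increment; tip values are returned indexed by tip label.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(seed)
    values = {tree.seed_node: float(root_value)}
    out = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            bl = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, math.sqrt(sigma2 * bl)
            )
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return pd.Series(out, name="trait")


@dataclass
class NicheModel:
    """Per-species climate niche: a temperature-like optimum and tolerance.

    Optima are evolved on the tree by Brownian motion, so close relatives
    prefer similar climates (phylogenetic niche conservatism); tolerance is
    the Gaussian niche breadth in the same units as the optimum.
    """

    optima: pd.Series
    tolerance: float | pd.Series = 2.0

    def __post_init__(self):
        tol = self.tolerance
        if np.any(np.asarray(tol) <= 0):
            raise ValueError("tolerance must be positive")

    def tol_for(self, species: str) -> float:
        if isinstance(self.tolerance, pd.Series):
            return float(self.tolerance[species])
        return float(self.tolerance)

    @classmethod
    def evolve(
        cls,
        tree: PhyloTree,
        sigma2: float = 8.0,
        root_optimum: float = 12.0,
        tolerance: float = 2.0,
        seed: int = 0,
    ) -> "NicheModel":
        optima = brownian_trait(tree, sigma2=sigma2, root_value=root_optimum, seed=seed)
        return cls(optima=optima.rename("optimum"), tolerance=tolerance)


def _largest_remainder(n: int, proportions) -> list[int]:
    props = np.asarray(proportions, dtype=float)
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    for i in np.argsort(-remainder, kind="stable")[:short]:
        counts[i] += 1
    return counts.tolist()


def assign_statuses(
    tips,
    proportions=DEFAULT_STATUS_PROPORTIONS,
    mode: str = "random",
    tree: PhyloTree | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Label every tip introduced / naturalized / invasive.

    Counts follow ``proportions`` with largest-remainder rounding. In
    ``clade_biased`` mode the invasive labels are concentrated inside one
    clade (the smallest clade covering at least the invasive share of tips,
    ties broken at random), emulating the phylogenetic non-randomness of
    invasion success; ``random`` mode scatters all labels uniformly.
    """
    tips = list(tips)
    counts = _largest_remainder(len(tips), proportions)
    rng = np.random.default_rng(seed)
    if mode == "random":
        order = list(rng.permutation(tips))
    elif mode == "clade_biased":
        if tree is None:
            raise ValueError("clade_biased mode requires the tree")
        n_inv = counts[2]
        candidates = []
        for node in tree.preorder_node_iter():
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            if len(leaves) >= n_inv:
                candidates.append(leaves)
        smallest = min(len(c) for c in candidates)
        candidates = [c for c in candidates if len(c) == smallest]
        clade = candidates[rng.integers(len(candidates))]
        invasive = list(rng.choice(clade, size=n_inv, replace=False))
        rest = [t for t in tips if t not in set(invasive)]
        order = list(rng.permutation(rest)) + invasive
    else:
        raise ValueError(f"unknown mode {mode!r}")
    statuses = {}
    i = 0
    for status, k in zip(STATUSES, counts):
        for t in order[i:i + k]:
            statuses[t] = status
        i += k
    return {t: statuses[t] for t in tips}


def _banded_partition(extent, n_units: int, rng) -> list[tuple[float, float, float, float]]:
    """Tile the extent with exactly ``n_units`` rectangles.

    The extent is cut into horizontal bands; each band is cut into columns.
    Interior breakpoints are jittered (±20% of a band/column width) so the
    partitions at different scales are not nested, mirroring how habitat,
    climate, administrative and ecoregion boundaries cross-cut one another.
    """
    lon0, lon1, lat0, lat1 = extent
    rows = max(1, int(round(math.sqrt(n_units))))
    base, extra = divmod(n_units, rows)
    cols_per_row = [base + 1] * extra + [base] * (rows - extra)

    def breaks(a, b, k):
        pts = np.linspace(a, b, k + 1)
        if k > 1:
            w = (b - a) / k
            pts[1:-1] += rng.uniform(-0.2 * w, 0.2 * w, size=k - 1)
        return pts

    lat_breaks = breaks(lat0, lat1, rows)
    cells = []
    for r in range(rows):
        lon_breaks = breaks(lon0, lon1, cols_per_row[r])
        for c in range(cols_per_row[r]):
            cells.append(
                (lon_breaks[c], lon_breaks[c + 1], lat_breaks[r], lat_breaks[r + 1])
            )
    return cells


def simulate_regions(
    extent=DEFAULT_EXTENT,
    units_per_scale=None,
    seed: int = 0,
) -> dict[str, list[tuple[str, "box"]]]:
    """One rectangular-lattice region partition per spatial scale.

    Returns ``{scale_name: [(unit_id, polygon), ...]}``; every point of the
    extent falls in exactly one unit per scale. Defaults mirror the four
    study scales: 7 habitat types, 16 climate classes, 34 provinces, 47
    ecoregions.
    """
    lon0, lon1, lat0, lat1 = extent
    if not (lon1 > lon0 and lat1 > lat0):
        raise ValueError("empty extent")
    if units_per_scale is None:
        units_per_scale = DEFAULT_SCALE_UNITS
    elif not isinstance(units_per_scale, dict):
        units_per_scale = {f"scale{n}": n for n in units_per_scale}
    rng = np.random.default_rng(seed)
    partitions = {}
    for scale, n_units in units_per_scale.items():
        if n_units < 1:
            raise ValueError(f"scale {scale!r}: unit count must be >= 1")
        cells = _banded_partition(extent, n_units, rng)
        partitions[scale] = [
            (f"{scale}_{i:03d}", box(x0, y0, x1, y1))
            for i, (x0, x1, y0, y1) in enumerate(cells, start=1)
        ]
    return partitions


def simulate_climate_grid(
    extent=DEFAULT_EXTENT,
    n_cells: int | tuple[int, int] = (62, 36),
    temp_gradient: float = -0.7,
    precip_gradient: float = 20.0,
    noise_sd: float = 1.0,
    precip_noise_sd: float = 50.0,
    seed: int = 0,
    bio1_base: float = 25.0,
    bio12_base: float = 200.0,
) -> pd.DataFrame:
    """Smooth climate surface on a rectangular cell lattice.

    BIO1 (mean annual temperature, °C-like) varies linearly with latitude at
    ``temp_gradient`` °C per degree from ``bio1_base`` at the southern edge;
    BIO12 (annual precipitation, mm-like) varies with longitude at
    ``precip_gradient`` mm per degree from ``bio12_base`` at the western
    edge. Gaussian noise is added per cell. Defaults give a China-like
    surface: ~25 °C in the far south falling to ~0 °C in the north.
    """
    lon0, lon1, lat0, lat1 = extent
    if isinstance(n_cells, int):
        ny = max(1, int(round(math.sqrt(n_cells))))
        nx = math.ceil(n_cells / ny)
    else:
        nx, ny = n_cells
    if nx < 1 or ny < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    xs = np.linspace(lon0, lon1, nx + 1)
    ys = np.linspace(lat0, lat1, ny + 1)
    rows = []
    for j, i in itertools.product(range(ny), range(nx)):
        lon_c = 0.5 * (xs[i] + xs[i + 1])
        lat_c = 0.5 * (ys[j] + ys[j + 1])
        rows.append(
            {
                "cell_id": f"cell_{j * nx + i + 1:04d}",
                "lon_min": xs[i], "lon_max": xs[i + 1],
                "lat_min": ys[j], "lat_max": ys[j + 1],
                "lon": lon_c, "lat": lat_c,
                "bio1": bio1_base + temp_gradient * (lat_c - lat0),
                "bio12": bio12_base + precip_gradient * (lon_c - lon0),
            }
        )
    grid = pd.DataFrame(rows)
    grid["bio1"] += rng.normal(0.0, noise_sd, size=len(grid))
    grid["bio12"] += rng.normal(0.0, precip_noise_sd, size=len(grid))
    return grid


def simulate_occurrences(
    tree: PhyloTree,
    statuses: dict[str, str],
    niche: NicheModel,
    grid: pd.DataFrame,
    points_per_species: int = 124,
    seed: int = 0,
    use_precip: bool = False,
    precip_niche: NicheModel | None = None,
) -> pd.DataFrame:
    """Place occurrence points for every species by climate filtering.

    Each point picks a grid cell with probability proportional to the
    Gaussian niche density at the cell's BIO1 value (optionally multiplied by
    a BIO12 niche) and then a uniform position within the cell. Output
    columns: species, lon, lat, status.
    """
    species = tip_labels(tree)
    missing = set(species) - set(niche.optima.index)
    if missing:
        raise ValueError(f"species without niche optimum: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    bio1 = grid["bio1"].to_numpy()
    recs = []
    for sp in species:
        logw = -0.5 * ((bio1 - niche.optima[sp]) / niche.tol_for(sp)) ** 2
        if use_precip:
            pn = precip_niche if precip_niche is not None else niche
            logw = logw - 0.5 * (
                (grid["bio12"].to_numpy() - pn.optima[sp]) / pn.tol_for(sp)
            ) ** 2
        if not np.all(np.isfinite(logw)):
            raise ValueError(f"zero total placement probability for {sp}")
        w = np.exp(logw - logw.max())
        w /= w.sum()
        cells = rng.choice(len(grid), size=points_per_species, p=w)
        u = rng.random((points_per_species, 2))
        g = grid.iloc[cells]
        lon = g["lon_min"].to_numpy() + u[:, 0] * (
            g["lon_max"].to_numpy() - g["lon_min"].to_numpy()
        )
        lat = g["lat_min"].to_numpy() + u[:, 1] * (
            g["lat_max"].to_numpy() - g["lat_min"].to_numpy()
        )
        recs.append(
            pd.DataFrame(
                {"species": sp, "lon": lon, "lat": lat, "status": statuses[sp]}
            )
        )
    return pd.concat(recs, ignore_index=True)


def regions_to_geojson(partitions: dict) -> dict:
    """Region partitions as one GeoJSON FeatureCollection (scale + id props)."""
    features = []
    for scale, units in partitions.items():
        for unit_id, poly in units:
            features.append(
                {
                    "type": "Feature",
                    "properties": {"id": unit_id, "scale": scale},
                    "geometry": mapping(poly),
                }
            )
    return {"type": "FeatureCollection", "features": features}


def regions_from_geojson(obj) -> dict:
    """Inverse of :func:`regions_to_geojson`; accepts a dict or a file path."""
    if not isinstance(obj, dict):
        with open(obj) as fh:
            obj = json.load(fh)
    partitions: dict[str, list] = {}
    for feat in obj["features"]:
        props = feat["properties"]
        scale = props.get("scale", "default")
        partitions.setdefault(scale, []).append(
            (props["id"], shape(feat["geometry"]))
        )
    return partitions
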