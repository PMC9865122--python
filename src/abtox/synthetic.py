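"""Synthetic arrayed deletion-screen data with known ground truth.

Emulates a genome-wide yeast knock-out screen for amyloid-beta (Aβ)
toxicity modifiers: each deletion strain carries a galactose-inducible
Aβ construct and is pinned in duplicate onto inducing (galactose) and
non-inducing (glucose) solid medium.  Colony sizes are read after 3, 4
and 5 days of induction and after 3 days without induction; the
per-strain toxicity statistic downstream is the Gal/Glu size ratio.

The generator plants four deviant strain classes among neutral strains:

``enhancer_gene``
    deletion rescues growth under induction (the deleted gene enhances
    toxicity) — induced sizes near the uninduced level;
``protective_gene``
    deletion abolishes growth under induction (the gene normally
    protects) — induced colonies below the detection floor at all days;
``gal_deficient``
    grows poorly on galactose regardless of Aβ (confounds the
    protective-gene phenotype; excluded downstream via a known list);
``glu_deficient``
    grows poorly on glucose, so the ratio denominator is unmeasurable
    (excluded downstream from the observed data).

The module also simulates a STRING-style scored interactome with
planted dense modules and a GMT gene-set collection with one planted
enriched set, so every downstream stage (hit calling, module detection,
over-representation, propagation) can be tested against known truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenDesign",
    "GroundTruth",
    "InvalidDesignError",
    "simulate_screen",
    "render_plate_image",
    "simulate_interactome",
    "simulate_genesets",
]

# Control-with-Aβ Gal/Glu trajectory: strong suppression at day 4 with
# partial recovery by day 5 (0.09 / 0.39).  The empty-vector profile
# (no Aβ) is 1.04 / 1.83.  Day-3 values are not separately reported for
# the arrayed screen; 0.05 reflects that induced colonies are barely
# visible before day 4.
CONTROL_ABETA_PROFILE = {3: 0.05, 4: 0.09, 5: 0.39}
EMPTY_VECTOR_PROFILE = {3: 0.80, 4: 1.04, 5: 1.83}

CONDITION_INDUCED = "GAL"
CONDITION_UNINDUCED = "GLU"

MEASUREMENT_COLUMNS = [
    "plate", "row", "col", "strain", "condition", "day", "replicate", "size",
]


class InvalidDesignError(ValueError):
    """Raised when a ScreenDesign is internally inconsistent."""


@dataclass(frozen=True)
class ScreenDesign:
    """Parameters of a simulated arrayed deletion screen.

    Defaults mirror the screen being emulated: a 5154-strain deletion
    library pinned in 16x24 (384) format, screened in duplicate, scored
    at days 3/4/5 of induction against uninduced day 3.
    """

    n_strains: int = 5154
    plate_rows: int = 16
    plate_cols: int = 24
    n_replicates: int = 2
    days_induced: tuple[int, ...] = (3, 4, 5)
    day_uninduced: int = 3
    enhancer_fraction: float = 0.0
    protective_fraction: float = 0.0
    gal_deficient_fraction: float = 0.0
    glu_deficient_fraction: float = 0.0
    noise_cv: float = 0.15
    detection_floor: float = 30.0
    base_size: float = 1000.0
    rescue_level: float = 0.9
    neutral_profile: dict[int, float] = field(
        default_factory=lambda: dict(CONTROL_ABETA_PROFILE))
    glu_deficient_level: float = 0.02
    n_controls_per_plate: int = 4
    edge_gradient: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.enhancer_fraction, self.protective_fraction,
                 self.gal_deficient_fraction, self.glu_deficient_fraction)
        if any(f < 0 or f > 1 for f in fracs):
            raise InvalidDesignError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise InvalidDesignError(
                f"class fractions sum to {sum(fracs):.3f} > 1")
        if self.n_strains < 1:
            raise InvalidDesignError("n_strains must be positive")
        if self.n_replicates < 1:
            raise InvalidDesignError("n_replicates must be positive")
        if self.day_uninduced not in (3, 4, 5):
            raise InvalidDesignError("day_uninduced must be one of 3/4/5")
        if self.noise_cv < 0:
            raise InvalidDesignError("noise_cv must be non-negative")
        if self.n_controls_per_plate >= self.plate_rows * self.plate_cols:
            raise InvalidDesignError("controls exceed plate capacity")
        missing = [d for d in self.days_induced if d not in self.neutral_profile]
        if missing:
            raise InvalidDesignError(
                f"neutral_profile lacks days {missing}")

    @property
    def positions_per_plate(self) -> int:
        return self.plate_rows * self.plate_cols

    @property
    def strains_per_plate(self) -> int:
        return self.positions_per_plate - self.n_controls_per_plate

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_strains / self.strains_per_plate)


@dataclass
class GroundTruth:
    """Truth labels and growth multipliers behind a simulated screen."""

    classes: dict[str, str]
    induced_multipliers: dict[str, dict[int, float]]
    uninduced_multipliers: dict[str, float]
    control_strains: list[str]

    @property
    def known_gal_deficient(self) -> list[str]:
        """Strains on the 'reported galactose-deficient' exclusion list."""
        return sorted(s for s, c in self.classes.items()
                      if c == "gal_deficient")

    def strains_of_class(self, cls: str) -> list[str]:
        return sorted(s for s, c in self.classes.items() if c == cls)

    def to_json(self) -> str:
        payload = {
            "classes": self.classes,
            "induced_multipliers": {
                s: {str(d): m for d, m in mult.items()}
                for s, mult in self.induced_multipliers.items()},
            "uninduced_multipliers": self.uninduced_multipliers,
            "control_strains": self.control_strains,
        }
        return json.dumps(payload, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        return cls(
            classes=payload["classes"],
            induced_multipliers={
                s: {int(d): m for d, m in mult.items()}
                for s, mult in payload["induced_multipliers"].items()},
            uninduced_multipliers=payload["uninduced_multipliers"],
            control_strains=payload["control_strains"],
        )


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       n: int) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=n)


def _assign_classes(design: ScreenDesign,
                    rng: np.random.Generator) -> list[str]:
    n = design.n_strains
    counts = {
        "enhancer_gene": round(design.enhancer_fraction * n),
        "protective_gene": round(design.protective_fraction * n),
        "gal_deficient": round(design.gal_deficient_fraction * n),
        "glu_deficient": round(design.glu_deficient_fraction * n),
    }
    total_planted = sum(counts.values())
    if total_planted > n:
        raise InvalidDesignError(
            f"planted classes ({total_planted}) exceed n_strains ({n})")
    labels = (["enhancer_gene"] * counts["enhancer_gene"]
              + ["protective_gene"] * counts["protective_gene"]
              + ["gal_deficient"] * counts["gal_deficient"]
              + ["glu_deficient"] * counts["glu_deficient"]
              + ["neutral"] * (n - total_planted))
    order = rng.permutation(n)
    return [labels[i] for i in order]


def simulate_screen(design: ScreenDesign) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate colony sizes for an arrayed induced/uninduced screen.

    Returns a long-format measurement table (one row per colony:
    plate, row, col, strain, condition, day, replicate, size) and the
    GroundTruth.  Noise is multiplicative lognormal per colony with the
    design's coefficient of variation; with ``noise_cv=0`` every
    Gal/Glu ratio equals its configured multiplier exactly.

    Control positions (``n_controls_per_plate`` per plate) carry the
    neutral control-with-Aβ profile and provide the reference pool for
    the downstream volcano statistic.
    """
    rng = np.random.default_rng(design.rng_seed)
    classes = _assign_classes(design, rng)
    strain_ids = [f"KO{i + 1:05d}" for i in range(design.n_strains)]

    # Sub-floor draw level for strains whose induced growth is
    # genuinely abolished: models residual scanner/agar signal rather
    # than an exact zero, exercising the zero-calling rule downstream.
    subfloor = 0.25 * design.detection_floor / design.base_size

    induced_mult: dict[str, dict[int, float]] = {}
    uninduced_mult: dict[str, float] = {}
    truth_classes: dict[str, str] = {}
    for sid, cls in zip(strain_ids, classes):
        truth_classes[sid] = cls
        if cls == "neutral":
            im = {d: design.neutral_profile[d] for d in design.days_induced}
            um = 1.0
        elif cls == "enhancer_gene":
            im = {d: (design.rescue_level if d >= 4
                      else 0.8 * design.rescue_level)
                  for d in design.days_induced}
            um = 1.0
        elif cls == "protective_gene":
            im = {d: subfloor for d in design.days_induced}
            um = 1.0
        elif cls == "gal_deficient":
            im = {d: subfloor for d in design.days_induced}
            um = 1.0
        else:  # glu_deficient
            im = {d: design.neutral_profile[d] for d in design.days_induced}
            um = design.glu_deficient_level
        induced_mult[sid] = im
        uninduced_mult[sid] = um

    # Plate layout: controls occupy the first positions of each plate,
    # library strains fill the rest in id order; identical layout across
    # replicates (replicate = independent pinning of the same array).
    control_ids: list[str] = []
    layout: list[tuple[str, int, int, int]] = []  # (strain, plate, row, col)
    strain_iter = iter(strain_ids)
    placed = 0
    for plate in range(1, design.n_plates + 1):
        pos = 0
        for r in range(1, design.plate_rows + 1):
            for c in range(1, design.plate_cols + 1):
                if pos < design.n_controls_per_plate:
                    sid = f"CTRL-ABETA-P{plate:02d}-{pos + 1}"
                    control_ids.append(sid)
                    truth_classes[sid] = "neutral"
                    induced_mult[sid] = {d: design.neutral_profile[d]
                                         for d in design.days_induced}
                    uninduced_mult[sid] = 1.0
                    layout.append((sid, plate, r, c))
                elif placed < design.n_strains:
                    sid = next(strain_iter)
                    layout.append((sid, plate, r, c))
                    placed += 1
                pos += 1

    rows: list[tuple] = []
    n_cells = len(layout)
    for rep in range(1, design.n_replicates + 1):
        # uninduced (glucose), read at the denominator day
        noise = _lognormal_factors(rng, design.noise_cv, n_cells)
        for (sid, plate, r, c), nz in zip(layout, noise):
            size = design.base_size * uninduced_mult[sid] * nz
            size *= _edge_factor(design, r, c)
            rows.append((plate, r, c, sid, CONDITION_UNINDUCED,
                         design.day_uninduced, rep, size))
        # induced (galactose) at each scored day
        for day in design.days_induced:
            noise = _lognormal_factors(rng, design.noise_cv, n_cells)
            for (sid, plate, r, c), nz in zip(layout, noise):
                size = design.base_size * induced_mult[sid][day] * nz
                size *= _edge_factor(design, r, c)
                rows.append((plate, r, c, sid, CONDITION_INDUCED,
                             day, rep, size))

    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    truth = GroundTruth(
        classes=truth_classes,
        induced_multipliers=induced_mult,
        uninduced_multipliers=uninduced_mult,
        control_strains=control_ids,
    )
    return table, truth


def _edge_factor(design: ScreenDesign, row: int, col: int) -> float:
    """Optional linear edge gradient (outer positions grow larger)."""
    if design.edge_gradient == 0.0:
        return 1.0
    dr = min(row - 1, design.plate_rows - row)
    dc = min(col - 1, design.plate_cols - col)
    edge_dist = min(dr, dc)
    max_dist = min(design.plate_rows, design.plate_cols) // 2
    return 1.0 + design.edge_gradient * (1.0 - edge_dist / max(max_dist, 1))


# ---------------------------------------------------------------------------
# Plate image rendering


def render_plate_image(measurements: pd.DataFrame, grid,
                       background: float = 100.0,
                       shape: tuple[int, int] | None = None) -> tuple[np.ndarray, dict]:
    """Render one plate's colonies as radially decaying disks.

    ``measurements`` must describe a single plate/condition/day/replicate
    (unique row/col positions).  Each colony is a truncated-Gaussian
    disk of radius ``grid.cell_radius`` whose integrated intensity above
    background equals its size, so quantification closes the loop.

    Returns (float64 image, metadata dict with the background level).
    """
    from .quantify import GridSpec  # avoid import cycle at module load

    if not isinstance(grid, GridSpec):
        raise TypeError("grid must be a GridSpec")
    dup = measurements.duplicated(subset=["row", "col"])
    if dup.any():
        raise ValueError("duplicate grid positions in measurement subset; "
                         "pass a single plate/condition/day/replicate")
    if ((measurements["row"] < 1) | (measurements["row"] > grid.n_rows)
            | (measurements["col"] < 1)
            | (measurements["col"] > grid.n_cols)).any():
        raise ValueError("measurement positions fall outside the grid")

    radius = grid.cell_radius
    if shape is None:
        ys = [grid.top_left[0], grid.top_right[0],
              grid.bottom_left[0], grid.bottom_right[0]]
        xs = [grid.top_left[1], grid.top_right[1],
              grid.bottom_left[1], grid.bottom_right[1]]
        margin = int(math.ceil(radius)) + 4
        shape = (int(math.ceil(max(ys))) + margin + 1,
                 int(math.ceil(max(xs))) + margin + 1)

    image = np.full(shape, float(background), dtype=np.float64)
    sigma = radius / 3.0
    for _, rec in measurements.iterrows():
        cy, cx = grid.center(int(rec["row"]), int(rec["col"]))
        y0, y1 = int(math.floor(cy - radius)), int(math.ceil(cy + radius))
        x0, x1 = int(math.floor(cx - radius)), int(math.ceil(cx + radius))
        if y0 < 0 or x0 < 0 or y1 >= shape[0] or x1 >= shape[1]:
            raise ValueError("colony disk extends beyond image bounds")
        yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask = r2 <= radius * radius
        kernel = np.where(mask, np.exp(-r2 / (2.0 * sigma * sigma)), 0.0)
        total = kernel.sum()
        if total > 0:
            image[y0:y1 + 1, x0:x1 + 1] += float(rec["size"]) * kernel / total
    meta = {"background": float(background), "cell_radius": float(radius)}
    return image, meta


# ---------------------------------------------------------------------------
# Interactome simulation

STRING_COLUMNS = ["protein1", "protein2", "experiments", "database",
                  "fusion", "combined_score"]


def simulate_interactome(n_genes: int,
                         background_edge_prob: float,
                         planted_modules: list[tuple[int, float]] = (),
                         seed: int = 0,
                         gene_prefix: str = "G",
                         background_score_range: tuple[float, float] = (0.40, 0.95),
                         planted_score_range: tuple[float, float] = (0.60, 0.999),
                         ) -> tuple[pd.DataFrame, dict]:
    """Erdős–Rényi background plus planted dense modules, STRING-style.

    Planted modules occupy disjoint leading blocks of the gene list;
    inside a planted block each pair is an edge with the requested
    density, elsewhere with ``background_edge_prob``.  Combined scores
    are sampled at or above the medium-confidence cutoff (0.4) so the
    sampled graph survives default confidence filtering intact; channel
    scores (experiments, database, fusion) are derived from the
    combined score with at least one positive channel per edge.

    Returns (edge table on the 0–1000 score scale, truth dict with the
    planted module memberships).
    """
    rng = np.random.default_rng(seed)
    total_planted = sum(size for size, _ in planted_modules)
    if total_planted > n_genes:
        raise ValueError("planted modules exceed n_genes")
    for size, density in planted_modules:
        if size < 2:
            raise ValueError("planted module size must be >= 2")
        if not (background_edge_prob < density <= 1.0):
            raise ValueError(
                "planted density must exceed background_edge_prob and be <= 1")

    width = max(4, len(str(n_genes)))
    genes = np.array([f"{gene_prefix}{i + 1:0{width}d}"
                      for i in range(n_genes)])
    module_members: list[list[str]] = []
    block_of = np.full(n_genes, -1, dtype=int)
    start = 0
    for m, (size, _) in enumerate(planted_modules):
        block_of[start:start + size] = m
        module_members.append(list(genes[start:start + size]))
        start += size

    iu, ju = np.triu_indices(n_genes, k=1)
    same_block = (block_of[iu] >= 0) & (block_of[iu] == block_of[ju])
    prob = np.full(iu.shape, background_edge_prob, dtype=float)
    for m, (_, density) in enumerate(planted_modules):
        in_m = same_block & (block_of[iu] == m)
        prob[in_m] = density
    keep = rng.random(iu.shape[0]) < prob
    ei, ej, planted_edge = iu[keep], ju[keep], same_block[keep]

    n_edges = ei.shape[0]
    lo_b, hi_b = background_score_range
    lo_p, hi_p = planted_score_range
    combined = np.where(planted_edge,
                        rng.uniform(lo_p, hi_p, n_edges),
                        rng.uniform(lo_b, hi_b, n_edges))
    # experiments channel carries the evidence; database/fusion sparse
    experiments = combined
    database = np.where(rng.random(n_edges) < 0.5,
                        combined * rng.uniform(0.2, 1.0, n_edges), 0.0)
    fusion = np.where(rng.random(n_edges) < 0.05,
                      combined * rng.uniform(0.2, 1.0, n_edges), 0.0)

    table = pd.DataFrame({
        "protein1": genes[ei],
        "protein2": genes[ej],
        "experiments": np.round(experiments * 1000).astype(int),
        "database": np.round(database * 1000).astype(int),
        "fusion": np.round(fusion * 1000).astype(int),
        "combined_score": np.round(combined * 1000).astype(int),
    })
    truth = {
        "genes": list(genes),
        "modules": module_members,
        "background_edge_prob": background_edge_prob,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Gene-set (GMT) simulation


def simulate_genesets(genes: list[str], n_sets: int,
                      set_size_range: tuple[int, int] = (5, 50),
                      enriched_set: list[str] = (),
                      seed: int = 0,
                      enriched_name: str = "PLANTED_SET") -> dict[str, list[str]]:
    """Random gene sets plus one designated set holding ``enriched_set``.

    Returns an ordered name -> member-list mapping (valid GMT content;
    serialize with :func:`abtox.enrich.write_gmt`).  Random sets draw
    members uniformly without replacement; the designated set contains
    every gene of ``enriched_set`` padded with random genes up to a
    size inside ``set_size_range``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid set_size_range")
    genes = list(genes)
    missing = set(enriched_set) - set(genes)
    if missing:
        raise ValueError(f"enriched genes not in universe: {sorted(missing)}")

    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(genes))
        members = list(rng.choice(genes, size=size, replace=False))
        sets[f"SET_{i + 1:04d}"] = sorted(members)

    if enriched_set:
        if enriched_name in sets:
            raise ValueError(f"duplicate set name {enriched_name!r}")
        target = max(lo, min(hi, len(enriched_set) + max(2, lo)))
        members = list(enriched_set)
        pool = [g for g in genes if g not in set(members)]
        n_pad = max(0, target - len(members))
        if n_pad and pool:
            members += list(rng.choice(pool, size=min(n_pad, len(pool)),
                                       replace=False))
        sets[enriched_name] = sorted(members)
    return sets
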