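"""Synthetic orchard-foraging studies with known ground truth.

Generates the exact inputs the pipeline consumes — bee metadata, per-locus
allele-presence calls — plus the underlying truth (pollen loads as
cultivar fractions, true carriage categories), so every downstream stage
is testable without field data.

The model: an orchard is a grid of trees in single-cultivar row blocks,
with a configurable rate of off-type replacement trees.  A bee performs a
discrete tree-level random walk (mostly along its row, switching rows
with a small probability), depositing-and-diluting pollen with geometric
carryover: after each tree visit the existing load is retained at a
fraction rho and a fixed pickup of the current tree's pollen is added.
The bee is netted during a uniformly chosen flower visit; the assay fires
a locus when the pollen ALT-dosage fraction clears a detection threshold,
with per-locus false-negative/positive noise.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolution import AlleleCallSet, Category
from .panel import PanelDesign

__all__ = [
    "OrchardLayout",
    "ForagingParams",
    "AssayParams",
    "PollenLoad",
    "PRESET_ORCHARDS",
    "build_orchard",
    "simulate_trip",
    "simulate_assay",
    "generate_study",
    "true_category",
]

#: Orchard presets: block layouts and spacings of the two study designs.
PRESET_ORCHARDS: dict[str, dict] = {
    "wide": {
        "orchard_type": "WIDE",
        "blocks": [["816", 42], ["Daddow", 48]],
        "row_spacing_m": 8.0,
        "tree_spacing_m": 4.0,
        "trees_per_row": 100,
        "transects": [
            {"block": "816", "from_block": "Daddow",
             "rows": [1, 2, 3, 11], "n_transects": 8},
        ],
    },
    "narrow": {
        "orchard_type": "NARROW",
        "blocks": [["A203", 5], ["842", 5], ["816", 5], ["A4", 5], ["741", 5]],
        "row_spacing_m": 10.0,
        "tree_spacing_m": 2.0,
        "trees_per_row": 100,
        "transects": [
            {"block": "816", "from_block": "A4",
             "rows": [1, 2, 3, 4], "n_transects": 4},
            {"block": "A4", "from_block": "816",
             "rows": [1, 2, 3, 4], "n_transects": 3},
        ],
    },
}


@dataclass
class OrchardLayout:
    orchard_type: str
    blocks: list[tuple[str, int]]
    trees_per_row: int
    row_spacing_m: float
    tree_spacing_m: float
    offtype_rate: float
    offtype_pool: tuple[str, ...]
    grid: np.ndarray  # (n_rows, trees_per_row) of cultivar names
    transects: list[dict] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    def block_span(self, cultivar: str) -> tuple[int, int]:
        """Global row range [start, end] (inclusive) of a block."""
        start = 0
        for name, n in self.blocks:
            if name == cultivar:
                return start, start + n - 1
            start += n
        raise KeyError(f"no block of cultivar {cultivar!r}")


@dataclass(frozen=True)
class ForagingParams:
    p_row_switch: float = 0.1
    n_visits: int = 30
    carryover_retention: float = 0.7  # rho: load retained per tree visit
    pickup_grains: float = 1.0
    capture_visit: int | str = "uniform"
    #: SD (in trees) of each bee's netting position along the sampling row:
    #: a netting session spans neighbouring trees, not one fixed tree.
    capture_jitter_sd: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p_row_switch <= 1.0:
            raise ValueError("p_row_switch must be in [0, 1]")
        if not 0.0 <= self.carryover_retention < 1.0:
            raise ValueError("carryover_retention must be in [0, 1)")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")


@dataclass(frozen=True)
class AssayParams:
    theta_detect: float = 0.02  # min ALT-dosage fraction for detection
    fn_rate: float = 0.01
    fp_rate: float = 0.001

    def __post_init__(self):
        for name in ("theta_detect", "fn_rate", "fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PollenLoad:
    bee_id: str
    grains: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.grains.values()))

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {c: g / t for c, g in self.grains.items() if g > 0} if t > 0 else {}


def build_orchard(
    config: dict,
    universe: tuple[str, ...] | None = None,
    rng: np.random.Generator | int | None = None,
) -> OrchardLayout:
    """Build a tree grid from a preset name or an explicit block list.

    Off-type replacement trees are drawn per tree with probability
    ``offtype_rate`` from ``offtype_pool`` (seeded, deterministic).
    """
    cfg = dict(config)
    if "preset" in cfg:
        preset = copy.deepcopy(PRESET_ORCHARDS[cfg.pop("preset")])
        preset.update(cfg)
        cfg = preset
    blocks = [(str(c), int(n)) for c, n in cfg["blocks"]]
    if any(n < 1 for _, n in blocks):
        raise ValueError("every block needs >= 1 row")
    offtype_rate = float(cfg.get("offtype_rate", 0.0))
    if not 0.0 <= offtype_rate <= 1.0:
        raise ValueError("offtype_rate must be in [0, 1]")
    offtype_pool = tuple(str(c) for c in cfg.get("offtype_pool", ()))
    if offtype_rate > 0 and not offtype_pool:
        raise ValueError("offtype_rate > 0 requires a non-empty offtype_pool")
    if universe is not None:
        known = set(universe)
        bad = ({c for c, _ in blocks} | set(offtype_pool)) - known
        if bad:
            raise ValueError(f"cultivars not in panel: {sorted(bad)}")
    trees_per_row = int(cfg.get("trees_per_row", 100))
    row_spacing = float(cfg["row_spacing_m"])
    tree_spacing = float(cfg["tree_spacing_m"])
    if row_spacing <= 0 or tree_spacing <= 0 or trees_per_row < 1:
        raise ValueError("spacings must be positive and trees_per_row >= 1")

    rows = [c for c, n in blocks for _ in range(n)]
    grid = np.array([[c] * trees_per_row for c in rows], dtype=object)
    if offtype_rate > 0:
        rng = np.random.default_rng(rng)
        mask = rng.random(grid.shape) < offtype_rate
        repl = rng.choice(np.array(offtype_pool, dtype=object), size=grid.shape)
        grid = np.where(mask, repl, grid)
    return OrchardLayout(
        orchard_type=str(cfg.get("orchard_type", "WIDE")),
        blocks=blocks,
        trees_per_row=trees_per_row,
        row_spacing_m=row_spacing,
        tree_spacing_m=tree_spacing,
        offtype_rate=offtype_rate,
        offtype_pool=offtype_pool,
        grid=grid,
        transects=list(cfg.get("transects", ())),
    )


def _step(pos: tuple[int, int], layout: OrchardLayout, fp: ForagingParams,
          rng: np.random.Generator) -> tuple[int, int]:
    r, k = pos
    if rng.random() < fp.p_row_switch:
        dr = 1 if rng.random() < 0.5 else -1
        if not 0 <= r + dr < layout.n_rows:
            dr = -dr  # reflect at the orchard edge
        return (r + dr, k)
    dk = 1 if rng.random() < 0.5 else -1
    if not 0 <= k + dk < layout.trees_per_row:
        dk = -dk
    return (r, k + dk)


def _accumulate(path, layout: OrchardLayout, fp: ForagingParams) -> dict[str, float]:
    """Exact carryover bookkeeping along a visit sequence."""
    load: dict[str, float] = {}
    for r, k in path:
        for c in load:
            load[c] *= fp.carryover_retention
        cultivar = layout.grid[r, k]
        load[cultivar] = load.get(cultivar, 0.0) + fp.pickup_grains
    return {c: g for c, g in load.items() if g > 0.0}


def simulate_trip(
    layout: OrchardLayout,
    fp: ForagingParams,
    start: tuple[int, int],
    rng: np.random.Generator | int | None = None,
    bee_id: str = "bee",
) -> PollenLoad:
    """Forward random walk from ``start``; load returned at the capture visit."""
    rng = np.random.default_rng(rng)
    r, k = start
    if not (0 <= r < layout.n_rows and 0 <= k < layout.trees_per_row):
        raise ValueError(f"start tree {start} outside the orchard")
    if fp.capture_visit == "uniform":
        capture = int(rng.integers(1, fp.n_visits + 1))
    else:
        capture = int(fp.capture_visit)
        if not 1 <= capture <= fp.n_visits:
            raise ValueError("capture_visit must be in 1..n_visits")
    path = [(r, k)]
    for _ in range(capture - 1):
        path.append(_step(path[-1], layout, fp, rng))
    return PollenLoad(bee_id=bee_id, grains=_accumulate(path, layout, fp))


def _history_load(layout, fp, capture_tree, capture_visit, rng) -> dict[str, float]:
    """Pollen load of a bee netted at ``capture_tree``.

    The bee's earlier visits are modelled as a random walk backwards from
    the capture tree (the step kernel is symmetric, so the reversed path
    has the same law as a forward walk conditioned on ending here).
    """
    path = [capture_tree]
    for _ in range(capture_visit - 1):
        path.append(_step(path[-1], layout, fp, rng))
    return _accumulate(list(reversed(path)), layout, fp)


def simulate_assay(
    load: PollenLoad,
    panel: PanelDesign,
    ap: AssayParams,
    rng: np.random.Generator | int | None = None,
) -> AlleleCallSet:
    """Threshold-plus-noise model of the two extension assays.

    ALT-dosage fraction at a locus = sum over load cultivars of
    fraction x (ALT copies)/2, where copies = 2 for the homozygous target,
    1 for het carriers, 0 otherwise (MISSING genotypes contribute 0 — their
    dosage is unknowable).  Detection when the fraction reaches
    ``theta_detect``, then flipped by the error rates.  The REF assay is
    modelled the same way on REF copies.
    """
    rng = np.random.default_rng(rng)
    frac = load.fractions
    unknown = set(frac) - set(panel.cultivars)
    if unknown:
        raise ValueError(f"load cultivars not in panel: {sorted(unknown)}")
    calls: dict[str, tuple[bool, bool | None]] = {}
    for pl in panel.loci:
        alt_dose = ref_dose = 0.0
        for cultivar, f in frac.items():
            if cultivar in pl.missing_set:
                continue  # ALT status unknown; contributes no dosage
            if cultivar == pl.target_cultivar:
                d_alt = 2
            elif cultivar in pl.het_carrier_set:
                d_alt = 1
            else:
                d_alt = 0
            d_ref = 2 - d_alt - (1 if cultivar in pl.anomalous_set else 0)
            alt_dose += f * d_alt / 2.0
            ref_dose += f * max(d_ref, 0) / 2.0
        alt = alt_dose >= ap.theta_detect and load.total > 0
        ref = ref_dose >= ap.theta_detect and load.total > 0
        if alt:
            alt = rng.random() >= ap.fn_rate
        else:
            alt = rng.random() < ap.fp_rate
        if ref:
            ref = rng.random() >= ap.fn_rate
        else:
            ref = rng.random() < ap.fp_rate
        calls[pl.locus_id] = (bool(alt), bool(ref))
    return AlleleCallSet(bee_id=load.bee_id, calls=calls)


def true_category(load: PollenLoad, host: str) -> str:
    """Ground-truth carriage category of a load against the host tree."""
    present = {c for c, g in load.grains.items() if g > 0}
    has_self = host in present
    has_cross = bool(present - {host})
    if has_cross and has_self:
        return Category.MIXED.value
    if has_cross:
        return Category.CROSS_ONLY.value
    if has_self:
        return Category.SELF_ONLY.value
    return Category.UNDETERMINED.value


def _transect_rows(layout: OrchardLayout, spec: dict) -> list[tuple[int, int]]:
    """Map transect row indices (1 = adjacent to the cross-pollen source)
    to global grid rows; returns [(row_index, global_row), ...]."""
    b_start, b_end = layout.block_span(str(spec["block"]))
    f_start, _ = layout.block_span(str(spec["from_block"]))
    out = []
    for ri in spec["rows"]:
        ri = int(ri)
        if ri < 1:
            raise ValueError("transect rows are 1-based")
        g = b_end - (ri - 1) if f_start > b_start else b_start + (ri - 1)
        if not b_start <= g <= b_end:
            raise ValueError(
                f"row {ri} falls outside block {spec['block']!r} "
                f"({b_end - b_start + 1} rows)"
            )
        out.append((ri, g))
    return out


def generate_study(
    config: dict, seed: int | np.random.SeedSequence
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a complete synthetic study: (metadata, calls, ground truth).

    ``config`` carries ``orchards`` (list of orchard sections, each a
    preset/blocks spec with its transect plan), ``foraging``, ``assay``,
    ``bees_per_point`` and the panel is taken from
    ``config["panel"]`` (a PanelDesign).  All randomness flows from
    ``seed`` through per-stage child streams.
    """
    panel: PanelDesign = config["panel"]
    bees_per_point = int(config.get("bees_per_point", 6))
    if bees_per_point < 1:
        raise ValueError("bees_per_point must be >= 1")
    fp = ForagingParams(**config.get("foraging", {}))
    ap = AssayParams(**config.get("assay", {}))
    orchard_cfgs = config.get("orchards")
    if not orchard_cfgs:
        raise ValueError("config needs a non-empty 'orchards' list")

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(int(seed)))
    meta_rows, call_rows, truth_rows = [], [], []
    for oi, ocfg in enumerate(orchard_cfgs):
        layout_seed, walk_seed, assay_seed = ss.spawn(3)
        layout = build_orchard(ocfg, universe=panel.cultivars,
                               rng=np.random.default_rng(layout_seed))
        walk_rng = np.random.default_rng(walk_seed)
        assay_rng = np.random.default_rng(assay_seed)
        if not layout.transects:
            raise ValueError(f"orchard {oi}: no transects configured")
        prefix = layout.orchard_type[0]
        t_counter = 0
        for spec in layout.transects:
            rows = _transect_rows(layout, spec)
            for _ in range(int(spec.get("n_transects", 1))):
                t_counter += 1
                transect_id = f"{prefix}{t_counter:02d}"
                pos = int(walk_rng.integers(0, layout.trees_per_row))
                for row_index, grow in rows:
                    for b in range(bees_per_point):
                        bee_id = f"{transect_id}-R{row_index:02d}-B{b + 1}"
                        bpos = pos
                        if fp.capture_jitter_sd > 0:
                            bpos = int(np.clip(
                                round(pos + walk_rng.normal(0, fp.capture_jitter_sd)),
                                0, layout.trees_per_row - 1))
                        host = str(layout.grid[grow, bpos])
                        if fp.capture_visit == "uniform":
                            cap = int(walk_rng.integers(1, fp.n_visits + 1))
                        else:
                            cap = int(fp.capture_visit)
                            if not 1 <= cap <= fp.n_visits:
                                raise ValueError(
                                    "capture_visit must be in 1..n_visits")
                        grains = _history_load(layout, fp, (grow, bpos), cap,
                                               walk_rng)
                        load = PollenLoad(bee_id=bee_id, grains=grains)
                        calls = simulate_assay(load, panel, ap, assay_rng)
                        meta_rows.append({
                            "bee_id": bee_id,
                            "host_cultivar": host,
                            "transect_id": transect_id,
                            "row_index": row_index,
                            "distance_m": row_index * layout.row_spacing_m,
                            "orchard_type": layout.orchard_type,
                        })
                        for locus_id, (alt, ref) in calls.calls.items():
                            call_rows.append({"bee_id": bee_id,
                                              "locus_id": locus_id,
                                              "assay": "ALT",
                                              "detected": int(alt)})
                            call_rows.append({"bee_id": bee_id,
                                              "locus_id": locus_id,
                                              "assay": "REF",
                                              "detected": int(bool(ref))})
                        fracs = load.fractions
                        truth_rows.append({
                            "bee_id": bee_id,
                            "true_load": ";".join(
                                f"{c}={fracs[c]:.6f}" for c in sorted(fracs)),
                            "true_category": true_category(load, host),
                            "true_cross_cultivars": ";".join(
                                sorted(set(fracs) - {host})),
                        })
    return (pd.DataFrame(meta_rows), pd.DataFrame(call_rows),
            pd.DataFrame(truth_rows))
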