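"""Synthetic tumors, cohorts and genomic matrices with known ground truth.

Cell maps are habitat mosaics: axis-aligned rectangular habitats, each
with its own cell-type composition and density.  Cells are placed by a
homogeneous Poisson process within each habitat and typed by a draw from
the habitat's composition, so the only noise in the regional diversity
scores is multinomial sampling noise.  The intended EDI of a mosaic is the
number of distinct Shannon values among its habitat compositions.

Cohort tables use an exponential baseline hazard with multiplicative
(proportional-hazards) covariate effects, and independent uniform
censoring calibrated to a target censoring rate.  Copy-number matrices
plant a block of genes whose aberration odds are multiplied in the
EDI-high group.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .diversity import shannon_index
from .io import CELL_TYPES, CellMap

LN3 = float(np.log(3.0))


@dataclass
class Habitat:
    """Axis-aligned rectangular habitat with a fixed cell ecology.

    ``rect`` = (x0, y0, x1, y1) in micrometres; ``composition`` is a
    probability 3-vector over (cancer, lymphocyte, stromal); ``density``
    is expected cells per square micrometre.
    """

    rect: tuple[float, float, float, float]
    composition: tuple[float, float, float]
    density: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"zero-area habitat rect {self.rect}")
        comp = np.asarray(self.composition, float)
        if (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
            raise ValueError("composition must be a probability vector")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)

    @property
    def shannon(self) -> float:
        return shannon_index(self.composition)


@dataclass
class SyntheticTumorSpec:
    """A habitat mosaic with known expected heterogeneity."""

    habitats: list[Habitat]
    tumor_id: str = "synthetic"

    @property
    def width(self) -> float:
        return max(h.rect[2] for h in self.habitats)

    @property
    def height(self) -> float:
        return max(h.rect[3] for h in self.habitats)


def expected_edi(spec: SyntheticTumorSpec, tol: float = 1e-6) -> int:
    """Number of distinct habitat Shannon values (clipped to 5).

    Compositions that are permutations of each other share a Shannon value
    and therefore count once.
    """
    levels: list[float] = []
    for h in spec.habitats:
        s = h.shannon
        if not any(abs(s - l) <= tol for l in levels):
            levels.append(s)
    return min(len(levels), 5)


def composition_for_entropy(h: float) -> tuple[float, float, float]:
    """A 3-type composition (p, q, q) with Shannon index ``h`` nats.

    Entropy of (p, (1-p)/2, (1-p)/2) decreases monotonically from ln 3 at
    p = 1/3 to 0 at p = 1, so any target in [0, ln 3] is attainable.
    """
    if not 0 <= h <= LN3:
        raise ValueError(f"target entropy must lie in [0, {LN3:.4f}]")
    if h >= LN3 - 1e-12:
        return (1 / 3, 1 / 3, 1 / 3)
    if h <= 1e-12:
        return (1.0, 0.0, 0.0)

    def ent(p: float) -> float:
        q = (1 - p) / 2
        return -(p * np.log(p) + (1 - p) * np.log(q))

    p = brentq(lambda p: ent(p) - h, 1 / 3 + 1e-12, 1 - 1e-12, xtol=1e-14)
    return (p, (1 - p) / 2, (1 - p) / 2)


def diversity_levels(k: int, low: float = 0.15, high: float = 1.06) -> np.ndarray:
    """Evenly spaced target Shannon levels for a K-level mosaic.

    Spread over [0.15, 1.06] nats: most of the attainable range [0, ln 3],
    with the low end kept away from the degenerate boundary.  Very near
    H = 0 a habitat yields many exactly single-type regions, so the score
    distribution acquires a point mass at 0 that reads as a genuine extra
    mixture component rather than sampling noise.  For K = 5 adjacent
    levels are about 0.23 nats apart.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.array([(low + high) / 2])
    return np.linspace(low, high, k)


def mosaic_spec(
    k: int,
    n_regions_per_level: int = 60,
    cells_per_region: int = 300,
    region_size: float = 200.0,
    tumor_id: str | None = None,
) -> SyntheticTumorSpec:
    """A K-level striped mosaic aligned with the default quadrat grid.

    Each diversity level occupies one horizontal strip, one region high
    and ``n_regions_per_level`` regions wide, at a density giving
    ``cells_per_region`` expected cells per 200-um quadrat.  Defaults (60
    regions and 300 expected cells per level) keep adjacent mixture
    components about 5 sampling standard deviations apart for K = 5, the
    hardest case.
    """
    levels = diversity_levels(k)
    width = n_regions_per_level * region_size
    density = cells_per_region / region_size**2
    habitats = [
        Habitat(
            rect=(0.0, i * region_size, width, (i + 1) * region_size),
            composition=composition_for_entropy(h),
            density=density,
        )
        for i, h in enumerate(levels)
    ]
    return SyntheticTumorSpec(
        habitats=habitats, tumor_id=tumor_id or f"synthetic_k{k}"
    )


def simulate_cellmap(
    spec: SyntheticTumorSpec, seed: int = 0
) -> tuple[CellMap, dict]:
    """Sample a cell map from a mosaic spec.

    Homogeneous Poisson placement within each habitat; cell types drawn
    independently from the habitat composition.  Returns the map and a
    ground-truth dict (per-habitat Shannon values, expected EDI, expected
    cell counts).
    """
    rng = np.random.default_rng(seed)
    xs, ys, types = [], [], []
    truth_counts = []
    for hab in spec.habitats:
        x0, y0, x1, y1 = hab.rect
        n = rng.poisson(hab.density * hab.area)
        truth_counts.append(hab.density * hab.area)
        if n == 0:
            continue
        xs.append(rng.uniform(x0, x1, n))
        ys.append(rng.uniform(y0, y1, n))
        types.append(rng.choice(len(CELL_TYPES), size=n, p=np.asarray(hab.composition)))
    if xs:
        cells = pd.DataFrame(
            {
                "x_um": np.concatenate(xs),
                "y_um": np.concatenate(ys),
                "cell_type": np.array(CELL_TYPES)[np.concatenate(types)],
            }
        )
    else:
        cells = pd.DataFrame(columns=["x_um", "y_um", "cell_type"])
    truth = {
        "habitat_shannon": [h.shannon for h in spec.habitats],
        "expected_edi": expected_edi(spec),
        "expected_cells": truth_counts,
    }
    return CellMap(cells=cells, tumor_id=spec.tumor_id), truth


@dataclass
class CohortSpec:
    """Specification of a synthetic survival cohort.

    ``n`` tumors; exponential baseline hazard ``baseline_hazard`` (events
    per month) for the reference group; hazard ratios for EDI-high and
    optionally TP53-mutant, node-positive and large-size tumors;
    ``frac_high`` the prevalence of EDI-high; ``censoring_rate`` the
    target fraction of uniformly censored observations (before the
    administrative 120-month cap applied downstream).
    """

    n: int = 500
    baseline_hazard: float = 0.01
    hr_edi_high: float = 2.0
    hr_tp53_mut: float = 1.0
    hr_node: float = 1.0
    hr_size: float = 1.0
    frac_high: float = 0.2
    frac_tp53_mut: float = 0.35
    frac_node_pos: float = 0.5
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        for name in ("hr_edi_high", "hr_tp53_mut", "hr_node", "hr_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")


def _uniform_censor_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound c of U(0, c) censoring achieving the target rate.

    For T ~ Exp(rate) and C ~ U(0, c), P(C < T) = (1 - e^(-rate c))/(rate c);
    the overall censoring probability is averaged over subjects and solved
    for c by bisection.
    """
    if target <= 0:
        return np.inf

    def frac(c: float) -> float:
        rc = rates * c
        return float(np.mean((1 - np.exp(-rc)) / rc))

    lo, hi = 1e-6, 1e7
    if frac(hi) > target:
        warnings.warn(
            f"censoring target {target} not attainable; achieved {frac(hi):.3f}"
        )
        return hi
    return brentq(lambda c: frac(c) - target, lo, hi, xtol=1e-9)


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Sample a clinical table under proportional hazards.

    Survival times are exponential with per-subject rate
    ``baseline_hazard * prod(HR^covariate)``; censoring is independent
    U(0, c) with c calibrated to the target rate.  Times are in months;
    the 120-month administrative cap is left to ``validate_cohort``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    edi_score = np.where(
        rng.random(n) < spec.frac_high, 5, rng.integers(1, 5, size=n)
    )
    edi_high = (edi_score == 5).astype(int)
    tp53 = np.where(rng.random(n) < spec.frac_tp53_mut, "MUT", "WT")
    node = (rng.random(n) < spec.frac_node_pos).astype(int)
    size_cat = rng.choice([1, 2, 3], size=n, p=[0.35, 0.55, 0.10])
    grade = rng.choice([1, 2, 3], size=n, p=[0.1, 0.35, 0.55])
    er = (rng.random(n) < 0.75).astype(int)

    log_hr = (
        edi_high * np.log(spec.hr_edi_high)
        + (tp53 == "MUT") * np.log(spec.hr_tp53_mut)
        + node * np.log(spec.hr_node)
        + (size_cat - 1) * np.log(spec.hr_size)
    )
    rates = spec.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / rates)
    c = _uniform_censor_bound(rates, spec.censoring_rate)
    t_cens = rng.uniform(0, c, n) if np.isfinite(c) else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # validation requires strictly positive times

    return pd.DataFrame(
        {
            "tumor_id": [f"T{i:04d}" for i in range(n)],
            "survival_months": time,
            "event": event,
            "grade": grade,
            "size_cat": size_cat,
            "node": node,
            "er": er,
            "tp53": tp53,
            "edi_score": edi_score,
            "edi_group": np.where(edi_high == 1, "high", "low"),
        }
    )


def simulate_cna(
    n_genes: int,
    n_samples: int,
    groups,
    enriched_block: dict | None = None,
    background_p: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a genes x samples copy-number call matrix in {-1, 0, 1}.

    Each gene carries one aberration direction (loss or gain, assigned
    round-robin) occurring with probability ``background_p`` per sample.
    ``enriched_block`` = {"genes": [...], "direction": "loss"|"gain",
    "odds": float} multiplies the aberration odds in the EDI-high group
    for the named genes (gene names are ``g0000``...).
    """
    groups = np.asarray(groups)
    if groups.size != n_samples:
        raise ValueError("groups length must equal n_samples")
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    block_genes: set[str] = set()
    odds_mult = 1.0
    block_dir = "loss"
    if enriched_block is not None:
        block_genes = set(enriched_block["genes"])
        if not block_genes <= set(gene_ids):
            raise ValueError("enriched block names genes outside the matrix")
        odds_mult = float(enriched_block["odds"])
        block_dir = enriched_block["direction"]
        if odds_mult <= 0:
            raise ValueError("enrichment odds must be positive")
    rng = np.random.default_rng(seed)
    high = groups == "high"
    base_odds = background_p / (1 - background_p)
    p_enriched = (base_odds * odds_mult) / (1 + base_odds * odds_mult)
    mat = np.zeros((n_genes, n_samples), dtype=int)
    for i, g in enumerate(gene_ids):
        direction = block_dir if g in block_genes else ("loss" if i % 2 else "gain")
        p = np.full(n_samples, background_p)
        if g in block_genes:
            p[high] = p_enriched
        hit = rng.random(n_samples) < p
        mat[i, hit] = -1 if direction == "loss" else 1
    return pd.DataFrame(mat, index=gene_ids, columns=[f"s{j:04d}" for j in range(n_samples)])


def simulate_expression(
    n_genes: int,
    n_samples: int,
    edi_scores=None,
    planted: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian expression matrix, optionally with genes tracking the EDI.

    Null genes are independent standard normals.  ``planted`` =
    {"genes": [...], "slope": float, "noise_sd": float} makes the named
    genes equal ``slope * edi_score + noise``.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_genes, n_samples))
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    df = pd.DataFrame(X, index=gene_ids, columns=[f"s{j:04d}" for j in range(n_samples)])
    if planted is not None:
        scores = np.asarray(edi_scores, float)
        for g in planted["genes"]:
            df.loc[g] = planted["slope"] * scores + rng.normal(
                scale=planted.get("noise_sd", 0.1), size=n_samples
            )
    return df
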