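"""Scale selection and stability experiments for the EDI.

Spatial heterogeneity measures are scale dependent: the quadrat side sets
how many cells inform each local score and how many regions inform the
mixture.  This module implements the supporting experiments used to choose
and defend a scale:

* a region-size sweep collecting cells/region, regions/tumor and the EDI
  at each scale;
* clustering instability — the standard deviation of the selected K under
  bootstrap resampling of regions;
* cross-scale correlation of EDI over a cohort;
* agreement of the high/low EDI subtype under subsampling of regions
  (simulating loss of tumor area).

All resampling is reproducible bit-for-bit given (seed, inputs, config).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity import DiversityProfile, EmptyInputError
from .io import CellMap
from .mixture import EDIMixture
from .pipeline import EDIScorer, InsufficientDataError

DEFAULT_SIZES = (166.0, 200.0, 250.0, 333.0, 500.0)
DEFAULT_FRACTIONS = (1.0, 0.95, 0.90, 0.85, 0.80)


def clustering_instability(
    d, n_boot: int = 50, seed: int = 0, k_max: int = 5, **mixture_params
) -> float:
    """SD of the selected K under bootstrap resampling of regions.

    Regions are the exchangeable unit: each replicate resamples the score
    vector with replacement and re-runs BIC selection.  Returns NaN if no
    replicate can be fitted.

    The bootstrap is smoothed: resampled scores are jittered with a
    Gaussian kernel at the Silverman bandwidth.  A plain bootstrap
    duplicates scores exactly, and an unequal-variance mixture fits those
    ties as spurious variance-floor spike components, inflating K on every
    replicate; jittering restores the continuity of the underlying score
    distribution.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    scores = d.d if isinstance(d, DiversityProfile) else np.asarray(d, float).ravel()
    rng = np.random.default_rng(seed)
    bandwidth = 0.9 * scores.std() * scores.size ** (-1 / 5)
    ks = []
    for _ in range(n_boot):
        boot = rng.choice(scores, size=scores.size, replace=True)
        boot = boot + rng.normal(0.0, bandwidth, size=boot.size)
        try:
            ks.append(
                EDIMixture(k_max=k_max, compute_qq=False, **mixture_params)
                .fit(boot)
                .edi_
            )
        except ValueError:
            continue
    if not ks:
        return float("nan")
    return float(np.std(ks))


def scale_scan(
    cellmaps,
    sizes=DEFAULT_SIZES,
    n_boot: int = 0,
    seed: int = 0,
    **scorer_params,
) -> pd.DataFrame:
    """Re-tile, re-score and re-select K at each region size.

    Returns one row per size: mean cells per retained region, number of
    retained regions, the EDI, the Q-Q fit correlation and (if ``n_boot``
    > 0) the clustering instability.  Sizes that leave too few regions are
    marked unavailable rather than failing the whole sweep.
    """
    if any(s <= 0 for s in sizes):
        raise ValueError("region sizes must be positive")
    cellmaps = [cellmaps] if isinstance(cellmaps, CellMap) else list(cellmaps)
    rows = []
    for r in sizes:
        row = {"region_size": float(r), "available": True}
        try:
            scorer = EDIScorer(region_size=r, **scorer_params).fit(cellmaps)
        except (InsufficientDataError, EmptyInputError):
            rows.append(
                {
                    **row,
                    "available": False,
                    "n_regions": 0,
                    "mean_cells_per_region": np.nan,
                    "edi": np.nan,
                    "qq_correlation": np.nan,
                    "instability": np.nan,
                }
            )
            continue
        prof = scorer.profile_
        totals = (
            prof.regions[[c for c in prof.regions.columns if c.startswith("n_")]]
            .to_numpy()
            .sum(axis=1)
        )
        row.update(
            n_regions=prof.n,
            mean_cells_per_region=float(totals.mean()),
            edi=int(scorer.edi_),
            qq_correlation=scorer.qq_correlation_,
        )
        if n_boot >= 2:
            mix_params = {
                k: v
                for k, v in scorer.get_params().items()
                if k
                in ("k_max", "n_restarts", "max_iter", "tol", "variance_floor")
            }
            row["instability"] = clustering_instability(
                prof, n_boot=n_boot, seed=seed, **mix_params
            )
        else:
            row["instability"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_scale_scan(
    tumors: dict, sizes=DEFAULT_SIZES, **scorer_params
) -> pd.DataFrame:
    """EDI per tumor per size: rows = tumor ids, columns = region sizes.

    ``tumors`` maps tumor id -> CellMap or list of section CellMaps.
    Infeasible (tumor, size) combinations are NaN.
    """
    out = {}
    for tid, maps in tumors.items():
        scan = scale_scan(maps, sizes=sizes, **scorer_params)
        out[tid] = scan.set_index("region_size")["edi"]
    return pd.DataFrame(out).T.rename_axis("tumor_id")


def cross_scale_correlation(edi_by_size: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-tumor EDI vectors between region sizes.

    ``edi_by_size``: rows = tumors, columns = sizes (e.g. from
    :func:`cohort_scale_scan`).  Entries involving a size with constant
    EDI across tumors are NaN (undefined); the diagonal is 1 by
    convention.
    """
    if edi_by_size.shape[1] < 2:
        raise ValueError("need at least two region sizes")
    if edi_by_size.shape[0] < 3:
        raise ValueError("need at least three tumors")
    corr = edi_by_size.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def region_subsample_stability(
    cellmaps,
    fractions=DEFAULT_FRACTIONS,
    n_repeats: int = 200,
    seed: int = 0,
    high_threshold: int = 5,
    **scorer_params,
) -> pd.DataFrame:
    """Agreement of EDI subtyping when tumor regions are subsampled.

    The tumor is scored once on all retained regions; its subtype is
    "high" when EDI >= ``high_threshold`` (= 5: the top heterogeneity
    score).  For each fraction f, ``n_repeats`` subsets of round(f * n)
    regions are drawn without replacement (modelling loss of tumor area),
    K is re-selected on each subset, and the proportion of repeats whose
    subtype matches the full-data subtype is reported.

    At f = 1 the subset is the full region set, so agreement is exactly 1:
    fits depend only on the multiset of scores.
    """
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    cellmaps = [cellmaps] if isinstance(cellmaps, CellMap) else list(cellmaps)
    scorer = EDIScorer(**scorer_params).fit(cellmaps)
    d = scorer.profile_.d
    n = d.size
    full_high = scorer.edi_ >= high_threshold
    mix_params = {
        k: v
        for k, v in scorer.get_params().items()
        if k in ("k_max", "n_restarts", "max_iter", "tol", "variance_floor")
    }
    min_regions = scorer.min_regions
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        size = int(round(f * n))
        if size < min_regions:
            rows.append(
                {
                    "fraction": float(f),
                    "available": False,
                    "agreement": np.nan,
                    "n_repeats": 0,
                }
            )
            continue
        agree = 0
        for _ in range(n_repeats):
            sub = rng.choice(d, size=size, replace=False)
            k_sub = (
                EDIMixture(
                    random_state=scorer.random_state, compute_qq=False, **mix_params
                )
                .fit(sub)
                .edi_
            )
            agree += (k_sub >= high_threshold) == full_high
        rows.append(
            {
                "fraction": float(f),
                "available": True,
                "agreement": agree / n_repeats,
                "n_repeats": n_repeats,
            }
        )
    return pd.DataFrame(rows)
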