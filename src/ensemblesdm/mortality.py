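"""Carcass-site analysis: mortality ensemble, habitat comparison, demography.

The mortality run mirrors the habitat run on the carcass points: the
covariate stack is clipped to the high-density study polygon, exactly 50
background points are drawn inside it, and the same VIF / forward-selection /
gate / median-ensemble machinery is applied. The two runs are then compared
by their shared selected variables, the Jaccard overlap of their binary maps
and the rank correlation of their suitability surfaces.

The demographic statistic summarises the carcass table: the percentage of
age-classed carcasses that were young animals (age class Yearling or
Juvenile, i.e. under three years) or pregnant females, truncated to one
decimal place. A strict reading that counts only the Yearling age class is
available via ``strict_yearling``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ensemble import EnsembleSDM, EnsembleSDMResults
from .grids import OccurrenceSet, RasterStack, StudyRegion, clip_stack
from .preprocess import BackgroundConfig, sample_background

#: the mortality run always uses exactly this many background points
MORTALITY_BACKGROUND_N = 50

AGE_CLASSES = ("Yearling", "Juvenile", "Adult", "unknown")
YOUNG_CLASSES = ("Yearling", "Juvenile")


@dataclass(frozen=True)
class CarcassRecord:
    id: str
    observed_date: str = ""
    collected_date: str = ""
    sex: str = "unknown"          # M | F | unknown
    age_class: str = "unknown"    # Yearling | Juvenile | Adult | unknown
    estimated_age: str = ""
    pregnant: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "unknown"):
            raise ValueError(f"record {self.id}: bad sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"record {self.id}: bad age class "
                             f"{self.age_class!r}")
        if self.pregnant and self.sex != "F":
            raise ValueError(f"record {self.id}: pregnant implies sex F")


def read_carcass_table(path: str | Path) -> list[CarcassRecord]:
    """Parse a carcass CSV (id, observed, collected, sex, age_class,
    estimated_age, pregnant) into records; blanks become 'unknown'."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"id", "sex", "age_class", "pregnant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"carcass CSV missing column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(CarcassRecord(
            id=str(row["id"]),
            observed_date=row.get("observed_date", ""),
            collected_date=row.get("collected_date", ""),
            sex=row["sex"] or "unknown",
            age_class=row["age_class"] or "unknown",
            estimated_age=row.get("estimated_age", ""),
            pregnant=row["pregnant"].strip().upper() in ("Y", "YES", "TRUE", "1"),
        ))
    return records


def carcass_vulnerable_fraction(records: Sequence[CarcassRecord],
                                strict_yearling: bool = False) -> float:
    """Percent of age-classed carcasses that were young or pregnant females.

    Numerator: records whose age class is Yearling/Juvenile (only Yearling
    when ``strict_yearling``) or that were pregnant. Denominator: records
    with a known age class. Truncated (not rounded) to one decimal place.
    """
    classed = [r for r in records if r.age_class != "unknown"]
    if not classed:
        raise ValueError("no carcass record has a known age class")
    young = ("Yearling",) if strict_yearling else YOUNG_CLASSES
    hits = sum(1 for r in classed if r.age_class in young or r.pregnant)
    pct = 100.0 * hits / len(classed)
    return math.floor(pct * 10) / 10


def run_mortality_pipeline(carcasses: OccurrenceSet, stack: RasterStack,
                           region: StudyRegion, *, seed: int = 0,
                           **model_kwargs) -> EnsembleSDMResults:
    """Clip to the region, draw 50 background points, run the full ensemble.

    ``model_kwargs`` are forwarded to :class:`EnsembleSDM` (vif, selection,
    cv, gate, algorithms, hyper).
    """
    clipped = clip_stack(stack, region)
    inside = region.contains_points(carcasses.xy[:, 0], carcasses.xy[:, 1])
    if inside.sum() < 2:
        raise ValueError("fewer than two carcass points inside the region")
    carcasses = carcasses.subset(inside)
    background = sample_background(
        BackgroundConfig(n_points=MORTALITY_BACKGROUND_N, region=region,
                         seed=seed),
        clipped.grid, nodata_mask=clipped.combined_mask())
    model = EnsembleSDM.from_stack(clipped, carcasses, background,
                                   seed=seed, **model_kwargs)
    return model.fit()


@dataclass
class ComparisonReport:
    """Habitat-vs-mortality comparison on the common clipped grid."""

    shared_variables: list[str]
    habitat_only: list[str]
    mortality_only: list[str]
    jaccard: float
    suitability_correlation: float
    n_cells: int

    @property
    def shared_fraction(self) -> float:
        """Shared variables over the union of both selected sets."""
        union = len(self.shared_variables) + len(self.habitat_only) \
            + len(self.mortality_only)
        return len(self.shared_variables) / union if union else 1.0

    def to_dict(self) -> dict:
        return {
            "shared_variables": self.shared_variables,
            "habitat_only": self.habitat_only,
            "mortality_only": self.mortality_only,
            "shared_fraction": self.shared_fraction,
            "jaccard": self.jaccard,
            "suitability_correlation": self.suitability_correlation,
            "n_cells": self.n_cells,
        }


def compare_runs(habitat: EnsembleSDMResults, mortality: EnsembleSDMResults,
                 stack: RasterStack, region: StudyRegion | None = None
                 ) -> ComparisonReport:
    """Compare the two ensembles on one stack (optionally clipped).

    Jaccard is computed between the binary maps' presence cells over the
    common unmasked cells; the correlation is Spearman's rank correlation of
    the two suitability surfaces on those cells. Jaccard of two empty
    presence sets is defined as 1 (identical maps).
    """
    if region is not None:
        stack = clip_stack(stack, region)
    hab_suit = habitat.predict_stack(stack, name="habitat")
    mor_suit = mortality.predict_stack(stack, name="mortality")
    common = ~(hab_suit.mask | mor_suit.mask)
    if not common.any():
        raise ValueError("the two runs share no unmasked cells")
    hab_bin = hab_suit.values >= habitat.threshold
    mor_bin = mor_suit.values >= mortality.threshold
    inter = int((hab_bin & mor_bin & common).sum())
    union = int(((hab_bin | mor_bin) & common).sum())
    jaccard = inter / union if union else 1.0
    rho = spearmanr(hab_suit.values[common], mor_suit.values[common])[0]
    shared = sorted(set(habitat.variables) & set(mortality.variables))
    return ComparisonReport(
        shared_variables=shared,
        habitat_only=sorted(set(habitat.variables) - set(mortality.variables)),
        mortality_only=sorted(set(mortality.variables) - set(habitat.variables)),
        jaccard=float(jaccard),
        suitability_correlation=float(rho),
        n_cells=int(common.sum()),
    )


def binary_jaccard(a: np.ndarray, b: np.ndarray,
                   valid: np.ndarray | None = None) -> float:
    """Jaccard overlap of two boolean maps (symmetric; empty union -> 1)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if valid is None:
        valid = np.ones(a.shape, dtype=bool)
    inter = int((a & b & valid).sum())
    union = int(((a | b) & valid).sum())
    return inter / union if union else 1.0
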