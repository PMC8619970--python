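"""Synthetic microtumor cohorts and lattice initial states.

The invasion pipeline is exercised on generated cohorts whose statistical
structure matches what the assays produce: a bimodal invasion-depth
distribution (a non-invasive gel-deformation mode below 50 µm and an
invasive mode above it) and condition-dependent occupancy of the four
multilayer regions.  Named presets encode the qualitative levels observed
per condition — e.g. a non-invasive luminal line places almost no mass in
the collagen layer, DLL4 knockdown places exactly none, and co-culture
shifts roughly a fifth of microtumors into collagen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .invasion import REGIONS
from .lattice import CellField, LatticeConfig

__all__ = [
    "SyntheticAssayParams",
    "generate_cohort",
    "default_scenarios",
    "generate_lattice_init",
]

DEPTH_BOUNDARY_UM = 50.0


@dataclass(frozen=True)
class SyntheticAssayParams:
    """Generator settings for one condition's cohort.

    Depths are a two-component mixture: with probability
    ``invasive_weight`` a shifted-lognormal invasive depth
    ``boundary + LogNormal(meanlog, sdlog)``, otherwise a truncated-normal
    deformation depth on ``[0, boundary)``.  Regions are drawn
    independently from ``region_probs`` (in :data:`REGIONS` order).
    """

    condition: str = "default"
    n_microtumors: int = 100
    invasive_weight: float = 0.3
    noninvasive_mean_um: float = 25.0
    noninvasive_sd_um: float = 10.0
    invasive_meanlog: float = math.log(30.0)
    invasive_sdlog: float = 0.6
    boundary_um: float = DEPTH_BOUNDARY_UM
    region_probs: tuple[float, float, float, float] | None = None
    heterogeneous_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.invasive_weight <= 1:
            raise ValueError("invasive_weight must lie in [0, 1]")
        if not 0 <= self.heterogeneous_fraction <= 1:
            raise ValueError("heterogeneous_fraction must lie in [0, 1]")
        if self.n_microtumors < 1:
            raise ValueError("n_microtumors must be positive")
        if self.region_probs is not None:
            p = np.asarray(self.region_probs, dtype=float)
            if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    "region_probs must be four non-negative values summing to 1"
                )


def generate_cohort(params: SyntheticAssayParams, seed: int | None = None) -> pd.DataFrame:
    """Generate one condition's record table, reproducibly from the seed.

    Columns: id, condition, composition, depth_um, region (NaN when the
    preset has no region model, i.e. a single-layer assay).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_microtumors

    invasive = rng.random(n) < params.invasive_weight
    depths = np.empty(n)

    n_non = int(np.count_nonzero(~invasive))
    if n_non:
        a = (0.0 - params.noninvasive_mean_um) / params.noninvasive_sd_um
        b = (params.boundary_um - params.noninvasive_mean_um) / params.noninvasive_sd_um
        depths[~invasive] = stats.truncnorm.rvs(
            a, b, loc=params.noninvasive_mean_um, scale=params.noninvasive_sd_um,
            size=n_non, random_state=rng,
        )
    n_inv = int(np.count_nonzero(invasive))
    if n_inv:
        depths[invasive] = params.boundary_um + rng.lognormal(
            params.invasive_meanlog, params.invasive_sdlog, size=n_inv
        )

    if params.region_probs is not None:
        regions = rng.choice(len(REGIONS), size=n, p=np.asarray(params.region_probs))
        region_col = [REGIONS[i] for i in regions]
    else:
        region_col = [None] * n

    hetero = rng.random(n) < params.heterogeneous_fraction
    return pd.DataFrame(
        {
            "id": [f"{params.condition}-{i:04d}" for i in range(n)],
            "condition": params.condition,
            "composition": np.where(hetero, "heterogeneous", "homogeneous"),
            "depth_um": depths,
            "region": region_col,
        }
    )


def default_scenarios(n: int = 100) -> dict[str, SyntheticAssayParams]:
    """Named presets mirroring the qualitative per-condition levels of the
    multilayer assay.

    * ``umuc1`` / ``scaber`` — homogeneous lines; most microtumors stay at
      the medium–Matrigel interface or inside the Matrigel, under 5 %
      reach the collagen layer; UM-UC-1 has a 0 % invasive fraction.
    * ``cocult`` — luminal/basal co-culture; about 20 % reach the
      Matrigel–collagen interface and about 20 % invade into collagen.
    * ``dll4_kd`` — DLL4 knockdown; nothing reaches collagen (exact 0).
    * ``notch1_kd_one`` — NOTCH1 knockdown in one line (maximal NOTCH1
      diversity); about 30 % in collagen, none trapped at the
      Matrigel–collagen interface.
    * ``notch1_kd_both`` — NOTCH1 knockdown in both lines removes the
      diversity; no collagen enhancement, some trapping at the interface.
    * ``foxa1_ko_mix`` — wild-type/FOXA1-knockout co-culture; both the
      invasive fraction and the collagen fraction rise, little trapping.
    """
    base = dict(n_microtumors=n)
    return {
        "umuc1": SyntheticAssayParams(
            condition="umuc1", invasive_weight=0.0,
            region_probs=(0.58, 0.39, 0.02, 0.01), **base,
        ),
        "scaber": SyntheticAssayParams(
            condition="scaber", invasive_weight=0.08,
            region_probs=(0.55, 0.41, 0.02, 0.02), **base,
        ),
        "cocult": SyntheticAssayParams(
            condition="cocult", invasive_weight=0.25,
            region_probs=(0.35, 0.25, 0.20, 0.20),
            heterogeneous_fraction=0.5, **base,
        ),
        "dll4_kd": SyntheticAssayParams(
            condition="dll4_kd", invasive_weight=0.02,
            region_probs=(0.60, 0.40, 0.0, 0.0), **base,
        ),
        "notch1_kd_one": SyntheticAssayParams(
            condition="notch1_kd_one", invasive_weight=0.35,
            region_probs=(0.45, 0.25, 0.0, 0.30),
            heterogeneous_fraction=0.5, **base,
        ),
        "notch1_kd_both": SyntheticAssayParams(
            condition="notch1_kd_both", invasive_weight=0.15,
            region_probs=(0.45, 0.35, 0.15, 0.05),
            heterogeneous_fraction=0.5, **base,
        ),
        "foxa1_ko_mix": SyntheticAssayParams(
            condition="foxa1_ko_mix", invasive_weight=0.35,
            region_probs=(0.35, 0.30, 0.10, 0.25),
            heterogeneous_fraction=0.5, **base,
        ),
    }


def generate_lattice_init(config: LatticeConfig, seed: int) -> CellField:
    """Random initial lattice state: N and D iid uniform on [0, 0.1].

    The symmetric dynamics fix the homogeneous state, so patterning needs
    this initial noise.  ``R_N_cell`` is initialized to 1 and is meant to
    be overwritten by the heterogeneity module.
    """
    rng = np.random.default_rng(seed)
    shape = config.shape
    return CellField(
        N=rng.uniform(0.0, 0.1, size=shape),
        D=rng.uniform(0.0, 0.1, size=shape),
        R_N_cell=np.ones(shape),
    )
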