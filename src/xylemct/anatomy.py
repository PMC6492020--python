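"""Anatomical statistics of conduit populations.

Per-conduit diameter is the equivalent-circle diameter; the organ-level
mean is the unweighted mean over conduits, while the hydraulic mean
``sum(d^5)/sum(d^4)`` weights each conduit by its conductance share.
Diameter histograms use half-open, lower-closed classes ``[k*w, (k+1)*w)``
of width 2 um by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .segmentation import ConduitMap

__all__ = [
    "AnatomyStats",
    "WallMeasurement",
    "WallReinforcement",
    "hydraulic_diameter",
    "vessel_density",
    "diameter_histogram",
    "wall_reinforcement",
    "compute_anatomy",
]


@dataclass(frozen=True)
class WallMeasurement:
    """Wall thickness / lumen breadth of one conduit pair (um)."""

    t_um: float
    b_um: float
    pair_mean_d_um: float
    sample_id: str = ""

    def __post_init__(self):
        if self.t_um <= 0 or self.b_um <= 0:
            raise ValidationError("wall thickness and lumen breadth must be > 0")

    @property
    def tb2(self) -> float:
        return (self.t_um / self.b_um) ** 2


@dataclass(frozen=True)
class WallReinforcement:
    mean_tb2: float
    se_tb2: float
    n_pairs: int
    n_samples: int


@dataclass(frozen=True)
class AnatomyStats:
    mean_d_um: float
    d_h_um: float
    vd_per_mm2: float
    n_conduits: int
    histogram: pd.DataFrame  # class_low_um, class_high_um, count


def hydraulic_diameter(diameters_um) -> float:
    """Hydraulically weighted mean diameter ``sum(d^5)/sum(d^4)`` (um).

    Always >= the arithmetic mean, with equality iff all diameters equal.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        raise ValidationError("need at least one diameter")
    if np.any(d <= 0):
        raise ValidationError("diameters must be positive")
    return float(np.sum(d**5) / np.sum(d**4))


def vessel_density(cmap: ConduitMap) -> float:
    """Conduit count per mm2 of xylem cross-section."""
    if cmap.xylem_area_mm2 <= 0:
        raise ValidationError("xylem area must be > 0")
    return len(cmap.conduits) / cmap.xylem_area_mm2


def diameter_histogram(diameters_um, class_width_um: float = 2.0) -> pd.DataFrame:
    """Counts per half-open diameter class ``[k*w, (k+1)*w)``.

    The returned frame has one row per class from 0 up to the class holding
    the largest diameter; counts sum to the number of conduits.
    """
    if class_width_um <= 0:
        raise ValidationError("class width must be > 0")
    d = np.asarray(diameters_um, dtype=float)
    if np.any(d < 0):
        raise ValidationError("diameters must be nonnegative")
    if d.size == 0:
        return pd.DataFrame({"class_low_um": [], "class_high_um": [], "count": []})
    idx = np.floor(d / class_width_um).astype(int)
    counts = np.bincount(idx)
    k = np.arange(counts.size)
    return pd.DataFrame(
        {
            "class_low_um": k * class_width_um,
            "class_high_um": (k + 1) * class_width_um,
            "count": counts,
        }
    )


def wall_reinforcement(pairs: list[WallMeasurement], d_h_um: float,
                       window_um: float = 2.0) -> WallReinforcement:
    """Mean and SE of the thickness-to-span ratio ``(t/b)**2``.

    Only pairs whose mean diameter lies within ``d_h_um +/- window_um``
    are retained (the conduits that dominate conductance). With multiple
    samples the SE is computed across per-sample means; with a single
    sample it is the SE across its pairs.
    """
    kept = [p for p in pairs
            if abs(p.pair_mean_d_um - d_h_um) <= window_um]
    if not kept:
        raise ValidationError(
            f"no conduit pair within {window_um} um of d_h = {d_h_um:.2f} um")
    df = pd.DataFrame({"sample": [p.sample_id for p in kept],
                       "tb2": [p.tb2 for p in kept]})
    by_sample = df.groupby("sample")["tb2"].mean()
    n_samples = by_sample.size
    if n_samples > 1:
        mean = float(by_sample.mean())
        se = float(by_sample.std(ddof=1) / np.sqrt(n_samples))
    else:
        mean = float(df["tb2"].mean())
        se = (float(df["tb2"].std(ddof=1) / np.sqrt(len(df)))
              if len(df) > 1 else 0.0)
    return WallReinforcement(mean_tb2=mean, se_tb2=se,
                             n_pairs=len(kept), n_samples=n_samples)


def compute_anatomy(cmap: ConduitMap, class_width_um: float = 2.0) -> AnatomyStats:
    """Summarise one conduit map: mean d, hydraulic d, density, histogram."""
    d = cmap.diameters_um()
    if d.size == 0:
        raise ValidationError("conduit map is empty")
    return AnatomyStats(
        mean_d_um=float(np.mean(d)),
        d_h_um=hydraulic_diameter(d),
        vd_per_mm2=vessel_density(cmap),
        n_conduits=d.size,
        histogram=diameter_histogram(d, class_width_um),
    )
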